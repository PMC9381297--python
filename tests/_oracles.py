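"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (textbook formulas,
definitional loops, exhaustive enumeration) and never calls the package's
own statistics.
"""

import itertools
import math


def pooled_t(case, control):
    """Textbook equal-variance two-sample t with n1 + n2 - 2 df."""
    n1, n2 = len(case), len(control)
    m1 = sum(case) / n1
    m2 = sum(control) / n2
    ss1 = sum((x - m1) ** 2 for x in case)
    ss2 = sum((x - m2) ** 2 for x in control)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    return (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


def bh_stepup(p_values):
    """Definitional BH step-up: adj_(k) = min_{j>=k} min(1, m p_(j) / j)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [None] * m
    for rank_pos, idx in enumerate(order, start=1):
        best = min(
            min(1.0, m * p_values[order[j - 1]] / j) for j in range(rank_pos, m + 1)
        )
        adjusted[idx] = best
    return adjusted


def hypergeom_tail_enumeration(universe, term, query_size, observed_overlap):
    """P(overlap >= observed) by enumerating every query_size-subset."""
    universe = sorted(universe)
    term = set(term)
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, query_size):
        total += 1
        if len(term.intersection(draw)) >= observed_overlap:
            hits += 1
    return hits / total


def jaccard_brute(a, b):
    """Jaccard by explicit element-by-element counting."""
    inter = sum(1 for x in set(a) if x in set(b))
    union_elems = []
    for x in list(a) + list(b):
        if x not in union_elems:
            union_elems.append(x)
    return inter / len(union_elems)


def degree_brute(nodes, edges):
    """Degree by counting incident edges one by one."""
    deg = {n: 0 for n in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    return deg
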