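"""Differential-expression calling: t-test, log2 fold change, BH-FDR.

A gene is called upregulated when it passes the p-value criterion and
logFC >= +threshold, downregulated when it passes the p-value criterion and
logFC <= -threshold (both comparisons inclusive; defaults p <= 0.05,
|logFC| >= 1). logFC is the difference of group means on the log2 scale
(case - control), the standard two-group convention. The p-value criterion
defaults to the raw p; the BH-adjusted p is always reported alongside and
can be made the criterion via :class:`DEGConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from diseasome.datasets import ExpressionDataset, normalize_symbol
from diseasome.errors import ValidationError
from diseasome.network import DiseaseGeneSets

logger = logging.getLogger(__name__)

TESTS = ("student", "welch")
P_CRITERIA = ("raw", "adjusted")


@dataclass
class DEGConfig:
    p_threshold: float = 0.05
    logfc_threshold: float = 1.0
    p_criterion: str = "raw"
    test: str = "student"

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must be in (0, 1)")
        if self.logfc_threshold <= 0:
            raise ValidationError("logfc_threshold must be > 0")
        if self.p_criterion not in P_CRITERIA:
            raise ValidationError(f"p_criterion must be one of {P_CRITERIA}")
        if self.test not in TESTS:
            raise ValidationError(f"test must be one of {TESTS}")


@dataclass
class DEGTable:
    """Per-gene statistics for one disease cohort.

    ``table`` columns: logfc, t_stat, p_value, p_adjusted, direction
    (up / down / none), indexed by gene symbol.
    """

    disease_id: str
    table: pd.DataFrame
    config: DEGConfig

    def up_genes(self) -> frozenset:
        return frozenset(self.table.index[self.table["direction"] == "up"])

    def down_genes(self) -> frozenset:
        return frozenset(self.table.index[self.table["direction"] == "down"])

    def to_tsv(self, path) -> None:
        out = self.table.sort_values(["p_value", "t_stat"], kind="mergesort")
        out = out.rename(
            columns={"logfc": "logFC", "t_stat": "t", "p_value": "p", "p_adjusted": "p_adj"}
        )
        out.to_csv(path, sep="\t", index_label="gene")


def t_test_gene(case_values, control_values, test: str = "student"):
    """Two-sided unpaired t-test for one gene.

    ``student`` pools variances (df = n1 + n2 - 2); ``welch`` uses the
    Welch-Satterthwaite df. Degenerate inputs with zero within-group
    variance return t=0, p=1 when the means agree, and p=0 (perfect
    separation) with a warning when they differ.
    """
    if test not in TESTS:
        raise ValidationError(f"test must be one of {TESTS}")
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise ValidationError("each group needs >=2 values")
    if not (np.isfinite(case).all() and np.isfinite(ctrl).all()):
        raise ValidationError("non-finite values in t-test input")
    if case.var(ddof=1) == 0 and ctrl.var(ddof=1) == 0:
        if case.mean() == ctrl.mean():
            return 0.0, 1.0
        logger.warning("degenerate separation: zero variance, unequal means")
        return float(np.sign(case.mean() - ctrl.mean()) * np.inf), 0.0
    res = stats.ttest_ind(case, ctrl, equal_var=(test == "student"))
    return float(res.statistic), float(res.pvalue)


def log_fold_change(case_values, control_values) -> float:
    """Difference of group means (case - control), values on the log2 scale."""
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValidationError("empty group in log_fold_change")
    return float(case.mean() - ctrl.mean())


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(ds: ExpressionDataset, cfg: DEGConfig | None = None) -> DEGTable:
    """Compute per-gene logFC, t, p, BH-adjusted p and direction calls.

    Expects a preprocessed (probe-collapsed, log2-scale) dataset. Genes with
    zero variance in both groups get t=0 and p=1 (p=0 for the degenerate
    perfectly-separated case) so the table always covers every gene.
    """
    cfg = cfg or DEGConfig()
    case = ds.case_matrix()
    ctrl = ds.control_matrix()

    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=(cfg.test == "student"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    # zero variance in both groups -> scipy yields nan
    degenerate = np.isnan(t)
    if degenerate.any():
        same = degenerate & (logfc == 0)
        sep = degenerate & (logfc != 0)
        t[same], p[same] = 0.0, 1.0
        t[sep] = np.sign(logfc[sep]) * np.inf
        p[sep] = 0.0
        if sep.any():
            logger.warning(
                "%s: %d genes with zero variance but unequal means", ds.disease_id, int(sep.sum())
            )

    p_adj = benjamini_hochberg(p)
    p_crit = p if cfg.p_criterion == "raw" else p_adj
    passed = p_crit <= cfg.p_threshold
    direction = np.where(
        passed & (logfc >= cfg.logfc_threshold),
        "up",
        np.where(passed & (logfc <= -cfg.logfc_threshold), "down", "none"),
    )
    table = pd.DataFrame(
        {
            "logfc": logfc,
            "t_stat": t,
            "p_value": p,
            "p_adjusted": p_adj,
            "direction": direction,
        },
        index=ds.values.index,
    )
    return DEGTable(ds.disease_id, table, cfg)


def deg_sets(table: DEGTable) -> DiseaseGeneSets:
    """Extract the up- and down-regulated gene symbol sets from a DEG table."""
    up = frozenset(normalize_symbol(g) for g in table.up_genes())
    down = frozenset(normalize_symbol(g) for g in table.down_genes())
    return DiseaseGeneSets(table.disease_id, up, down)
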