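"""Expression-matrix container and I/O.

A cohort is a genes x samples numeric matrix with a case/control label per
sample. Matrices arrive as TSV with a header row of sample IDs and a first
column of gene (or probe) identifiers; group labels arrive as a two-column
TSV mapping each sample to ``case`` or ``control``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from diseasome.errors import InputError, ValidationError

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
COLLAPSE_RULES = ("max_abs_logfc", "max_abs_t", "mean")


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form used for all cross-dataset matching.

    HGNC symbols are uppercase; datasets vary, so both sides of every
    comparison are uppercased and stripped.
    """
    return symbol.strip().upper()


@dataclass
class ExpressionDataset:
    """One disease cohort: genes x samples expression plus group labels.

    ``values`` is a pandas DataFrame indexed by gene/probe identifier with
    one column per sample; ``groups`` maps every sample ID to ``case`` or
    ``control``.
    """

    disease_id: str
    values: pd.DataFrame
    groups: dict = field(repr=False)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        index = self.values.index.astype(str)
        self.values.index = index
        if (index == "").any():
            raise ValidationError("empty gene identifiers present")
        if index.duplicated().any():
            dup = index[index.duplicated()][0]
            raise ValidationError(f"duplicate gene identifier: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise InputError(f"samples missing from groups file: {missing}")
        bad = {s: g for s, g in self.groups.items() if g not in (CASE, CONTROL)}
        if bad:
            raise InputError(f"group labels must be 'case' or 'control', got {bad}")
        if len(self.case_samples) < 2 or len(self.control_samples) < 2:
            raise ValidationError(
                f"{self.disease_id}: need >=2 case and >=2 control samples, "
                f"got {len(self.case_samples)} case / {len(self.control_samples)} control"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def case_samples(self) -> list:
        return [s for s in self.values.columns if self.groups[s] == CASE]

    @property
    def control_samples(self) -> list:
        return [s for s in self.values.columns if self.groups[s] == CONTROL]

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def case_matrix(self) -> np.ndarray:
        return self.values[self.case_samples].to_numpy()

    def control_matrix(self) -> np.ndarray:
        return self.values[self.control_samples].to_numpy()

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        return ExpressionDataset(self.disease_id, values, dict(self.groups))


def read_groups(groups_path) -> dict:
    """Parse a two-column sample->group TSV."""
    groups = {}
    with open(groups_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{groups_path}:{lineno}: expected 'sample<TAB>group'")
            sample, group = parts[0].strip(), parts[1].strip().lower()
            if sample == "sample_id" and group not in (CASE, CONTROL):
                continue  # optional header
            if group not in (CASE, CONTROL):
                raise InputError(
                    f"{groups_path}:{lineno}: group must be case/control, got {group!r}"
                )
            groups[sample] = group
    return groups


def read_expression(matrix_path, groups_path, disease_id: str) -> ExpressionDataset:
    """Read an expression TSV plus its groups file into a validated dataset.

    Rows whose gene identifier is empty are removed (routine microarray
    table clean-up: annotation tables carry blank symbol rows).
    """
    try:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputError(f"cannot parse {matrix_path}: {exc}") from exc
    df.index = df.index.astype(str).str.strip().fillna("")
    n_before = len(df)
    df = df[df.index != ""]
    df = df[df.index.str.lower() != "nan"]
    dropped = n_before - len(df)
    if dropped:
        logger.info("%s: dropped %d rows with empty gene identifier", disease_id, dropped)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        gene, sample = bad[bad].index[0]
        raise InputError(
            f"{matrix_path}: non-numeric value at gene {gene!r}, sample {sample!r}"
        )
    groups = read_groups(groups_path)
    missing = [s for s in numeric.columns if s not in groups]
    if missing:
        raise InputError(f"samples missing from groups file: {missing}")
    groups = {s: groups[s] for s in numeric.columns}
    return ExpressionDataset(disease_id, numeric, groups)


def _group_delta(ds: ExpressionDataset) -> pd.Series:
    """Per-row case-mean minus control-mean on the current scale."""
    case = ds.values[ds.case_samples].mean(axis=1)
    ctrl = ds.values[ds.control_samples].mean(axis=1)
    return case - ctrl


def _group_t(ds: ExpressionDataset) -> pd.Series:
    from scipy import stats

    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(ds.case_matrix(), ds.control_matrix(), axis=1)
    return pd.Series(np.nan_to_num(t, nan=0.0), index=ds.values.index)


def collapse_probes(
    ds: ExpressionDataset, probe_map: dict, rule: str = "max_abs_logfc"
) -> ExpressionDataset:
    """Collapse probe-level rows to one row per gene symbol.

    ``probe_map`` maps probe ID to gene symbol; probes absent from the map or
    mapped to an empty symbol are dropped (count logged). For ``max_abs_logfc``
    the retained probe is the one with the largest |case mean - control mean|
    on the current scale; ``max_abs_t`` keeps the largest |t|; ``mean``
    averages all probes of a gene. Ties keep the lexicographically smallest
    probe ID so collapsing is deterministic.
    """
    if rule not in COLLAPSE_RULES:
        raise ValidationError(f"unknown collapse rule {rule!r}; choose from {COLLAPSE_RULES}")
    symbols = {}
    n_unmapped = 0
    for probe in ds.values.index:
        sym = probe_map.get(probe, "")
        sym = normalize_symbol(sym) if sym else ""
        if sym:
            symbols[probe] = sym
        else:
            n_unmapped += 1
    if n_unmapped:
        logger.info("%s: dropped %d unmapped probes", ds.disease_id, n_unmapped)
    if not symbols:
        raise ValidationError("no probes mapped to a gene symbol")

    kept = ds.values.loc[list(symbols)]
    gene_of = pd.Series({p: symbols[p] for p in kept.index})

    if rule == "mean":
        collapsed = kept.groupby(gene_of).mean()
        collapsed = collapsed.sort_index()
    else:
        sub = ds.with_values(kept)
        score = _group_delta(sub).abs() if rule == "max_abs_logfc" else _group_t(sub).abs()
        order = pd.DataFrame({"gene": gene_of, "score": score, "probe": kept.index})
        order = order.sort_values(
            ["gene", "score", "probe"], ascending=[True, False, True], kind="mergesort"
        )
        winners = order.drop_duplicates("gene", keep="first")["probe"]
        collapsed = kept.loc[winners]
        collapsed.index = [symbols[p] for p in winners]
        collapsed = collapsed.sort_index()
    return ExpressionDataset(ds.disease_id, collapsed, dict(ds.groups))
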