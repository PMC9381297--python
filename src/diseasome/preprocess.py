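"""Log2 and Z-score transformations applied before differential testing.

Microarray cohorts arrive on heterogeneous scales (raw intensity vs already
log-transformed). ``maybe_log2`` normalises to the log2 scale, optionally
auto-detecting whether a matrix is already logged; ``zscore_rows`` then
standardises every gene row to mean 0 / sd 1 across all samples so cohorts
from different platforms are comparable:

    z_ij = (x_ij - mean_i) / sd_i

Fold changes are computed on the log2 scale *before* Z-scoring: row-wise
standardisation rescales every gene differently, which would make a fixed
fold-change cutoff unit-dependent, while the t statistic is invariant to
per-row affine maps so p-values are unaffected by the order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from diseasome.datasets import ExpressionDataset, collapse_probes
from diseasome.errors import ValidationError

logger = logging.getLogger(__name__)

LOG2_POLICIES = ("auto", "always", "never")


@dataclass
class PreprocessConfig:
    """Preprocessing knobs.

    log2_policy
        ``auto`` applies log2(x + pseudocount) only when the matrix looks
        unlogged (99th percentile above ``log2_detect_quantile_threshold``
        and no negative values — the usual GEO heuristic); ``always`` forces
        the transform (unless negatives reveal the data are already logged);
        ``never`` leaves values untouched.
    pseudocount
        Added before the log to keep zeros finite. Default 1.
    collapse_rule
        How multiple probes of one gene are reduced to a single row.
    zscore_ddof
        0 for population, 1 for sample standard deviation in the Z-score.
    """

    log2_policy: str = "auto"
    log2_detect_quantile_threshold: float = 50.0
    pseudocount: float = 1.0
    collapse_rule: str = "max_abs_logfc"
    zscore_ddof: int = 1

    def __post_init__(self) -> None:
        if self.log2_policy not in LOG2_POLICIES:
            raise ValidationError(f"log2_policy must be one of {LOG2_POLICIES}")
        if self.log2_detect_quantile_threshold <= 0:
            raise ValidationError("log2 detection threshold must be > 0")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.zscore_ddof not in (0, 1):
            raise ValidationError("zscore_ddof must be 0 or 1")


def maybe_log2(ds: ExpressionDataset, cfg: PreprocessConfig | None = None) -> ExpressionDataset:
    """Apply log2(x + pseudocount) according to the configured policy."""
    cfg = cfg or PreprocessConfig()
    values = ds.values
    if values.isna().any().any():
        raise ValidationError(f"{ds.disease_id}: NaN values in expression matrix")
    if cfg.log2_policy == "never":
        return ds
    arr = values.to_numpy()
    has_negatives = bool((arr < 0).any())
    if has_negatives:
        # negative intensities only arise on an already-logged scale
        logger.info("%s: negative values present, treating as already log2", ds.disease_id)
        return ds
    if cfg.log2_policy == "auto":
        q99 = float(np.percentile(arr, 99))
        if q99 <= cfg.log2_detect_quantile_threshold:
            logger.info(
                "%s: 99th percentile %.3g <= %.3g, treating as already log2",
                ds.disease_id, q99, cfg.log2_detect_quantile_threshold,
            )
            return ds
    logged = np.log2(values + cfg.pseudocount)
    logger.info("%s: applied log2(x + %g)", ds.disease_id, cfg.pseudocount)
    return ds.with_values(logged)


def zscore_rows(ds: ExpressionDataset, ddof: int = 1) -> ExpressionDataset:
    """Standardise every gene row to mean 0 / sd 1 across all samples.

    Rows with zero variance cannot be standardised and are dropped with a
    warning (their count is logged).
    """
    if ddof not in (0, 1):
        raise ValidationError("ddof must be 0 or 1")
    values = ds.values
    if values.isna().any().any():
        raise ValidationError(f"{ds.disease_id}: NaN values in expression matrix")
    sd = values.std(axis=1, ddof=ddof)
    zero = sd == 0
    if zero.any():
        logger.warning(
            "%s: dropping %d zero-variance gene rows before Z-scoring",
            ds.disease_id, int(zero.sum()),
        )
        values = values[~zero]
        sd = sd[~zero]
    centered = values.sub(values.mean(axis=1), axis=0)
    return ds.with_values(centered.div(sd, axis=0))


def preprocess(
    ds: ExpressionDataset,
    cfg: PreprocessConfig | None = None,
    probe_map: dict | None = None,
) -> ExpressionDataset:
    """Collapse probes (if a map is given) and move to the log2 scale.

    Returns the log2-scale dataset on which fold changes and t-tests are
    computed; apply :func:`zscore_rows` separately where a standardised
    matrix is needed for cross-cohort comparison.
    """
    cfg = cfg or PreprocessConfig()
    if probe_map is not None:
        ds = collapse_probes(ds, probe_map, cfg.collapse_rule)
    return maybe_log2(ds, cfg)
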