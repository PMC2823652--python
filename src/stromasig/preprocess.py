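"""Sequential quality filtering and standardization of two-colour arrays.

The fixed pipeline order is: spot QC -> presence filter -> variation
filter -> (standardize to untreated) -> (collapse clones).  Filters only
remove rows or set measurements missing; values are altered only by the
standardization and clone-collapse steps.

A spot survives QC when its regression correlation exceeds 0.6 AND at
least one channel's mean intensity exceeds 1.5x its median background —
strict inequalities throughout — and it was not manually flagged.  The
presence filter keeps genes measured in at least 60% of samples; the
variation filter keeps genes deviating from their row mean by at least
1.5-fold (log2(1.5) on the log scale) in at least two samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    min_regression_correlation: float = 0.6
    min_intensity_over_background: float = 1.5
    min_presence_fraction: float = 0.60
    min_fold_deviation: float = 1.5
    min_deviating_samples: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.min_presence_fraction <= 1):
            raise ValidationError("presence fraction must be in (0, 1]")
        for name in (
            "min_regression_correlation",
            "min_intensity_over_background",
            "min_fold_deviation",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.min_deviating_samples < 1:
            raise ValidationError("min_deviating_samples must be >= 1")


def spot_passes(
    regression_correlation: float,
    ch1_mean: float,
    ch1_background: float,
    ch2_mean: float,
    ch2_background: float,
    manual_flag: bool,
    config: PreprocessConfig,
) -> bool:
    """Quality predicate for a single spot."""
    if manual_flag:
        return False
    if not regression_correlation > config.min_regression_correlation:
        return False
    return (
        ch1_mean / ch1_background > config.min_intensity_over_background
        or ch2_mean / ch2_background > config.min_intensity_over_background
    )


def apply_spot_qc(
    matrix: ExpressionMatrix,
    quality: pd.DataFrame,
    config: PreprocessConfig | None = None,
) -> ExpressionMatrix:
    """Mask measurements failing spot quality criteria.

    ``quality`` must carry one record per (probe_id, sample_id) with
    columns regression_correlation, ch1_mean, ch1_background, ch2_mean,
    ch2_background, manual_flag.
    """
    config = config or PreprocessConfig()
    required = {
        "probe_id",
        "sample_id",
        "regression_correlation",
        "ch1_mean",
        "ch1_background",
        "ch2_mean",
        "ch2_background",
        "manual_flag",
    }
    missing_cols = required - set(quality.columns)
    if missing_cols:
        raise ValidationError(f"quality table missing columns {sorted(missing_cols)}")
    q = quality.set_index(["probe_id", "sample_id"])
    if q.index.duplicated().any():
        raise ValidationError("duplicate (probe, sample) quality records")

    full_index = pd.MultiIndex.from_product(
        [matrix.probe_ids, matrix.sample_ids], names=["probe_id", "sample_id"]
    )
    missing_records = full_index.difference(q.index)
    if len(missing_records):
        probe, sample = missing_records[0]
        raise ValidationError(f"no quality record for spot ({probe}, {sample})")
    q = q.reindex(full_index)

    shape = (matrix.n_genes, matrix.n_samples)
    corr = q["regression_correlation"].to_numpy(float).reshape(shape)
    r1 = (q["ch1_mean"].to_numpy(float) / q["ch1_background"].to_numpy(float)).reshape(shape)
    r2 = (q["ch2_mean"].to_numpy(float) / q["ch2_background"].to_numpy(float)).reshape(shape)
    flagged = q["manual_flag"].to_numpy(bool).reshape(shape)
    passes = (
        ~flagged
        & (corr > config.min_regression_correlation)
        & (
            (r1 > config.min_intensity_over_background)
            | (r2 > config.min_intensity_over_background)
        )
    )
    out = matrix.copy()
    n_masked = int((~passes & ~matrix.missing).sum())
    out.values[~passes] = np.nan
    logger.info("spot QC masked %d measurements", n_masked)
    return out


def filter_presence(
    matrix: ExpressionMatrix, config: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """Keep genes with a non-missing fraction >= the presence threshold."""
    config = config or PreprocessConfig()
    if matrix.n_samples < 1 or matrix.n_genes < 1:
        raise ValidationError("presence filter requires a non-empty matrix")
    frac = (~matrix.missing).mean(axis=1)
    keep = np.flatnonzero(frac >= config.min_presence_fraction)
    logger.info("presence filter kept %d of %d genes", keep.size, matrix.n_genes)
    return matrix.subset_genes(keep)


def filter_variation(
    matrix: ExpressionMatrix, config: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """Keep genes deviating >= log2(min_fold_deviation) from their own
    mean in at least ``min_deviating_samples`` samples."""
    config = config or PreprocessConfig()
    if matrix.n_genes < 1:
        raise ValidationError("variation filter requires a non-empty matrix")
    threshold = np.log2(config.min_fold_deviation)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(matrix.values, axis=1, keepdims=True)
        deviates = np.abs(matrix.values - row_mean) >= threshold
    n_dev = np.nansum(np.where(matrix.missing, 0, deviates), axis=1)
    keep = np.flatnonzero(n_dev >= config.min_deviating_samples)
    logger.info("variation filter kept %d of %d genes", keep.size, matrix.n_genes)
    return matrix.subset_genes(keep)


def standardize_to_reference(
    matrix: ExpressionMatrix,
    reference_sample_ids: list[str],
    group_by_cell_type: bool = True,
) -> ExpressionMatrix:
    """Subtract, per gene, the mean over untreated (reference) samples,
    within each cell-type group separately.

    Genes with no non-missing reference value in a group become missing
    for every sample of that group.
    """
    unknown = set(reference_sample_ids) - set(matrix.sample_ids)
    if unknown:
        raise ValidationError(f"reference sample ids not in matrix: {sorted(unknown)}")
    ref_mask = np.array([s in set(reference_sample_ids) for s in matrix.sample_ids])
    if group_by_cell_type:
        groups = matrix.samples["cell_type"].to_numpy()
    else:
        groups = np.array([""] * matrix.n_samples)

    out = matrix.copy()
    for group in pd.unique(groups):
        cols = np.flatnonzero(groups == group)
        ref_cols = cols[ref_mask[cols]]
        if ref_cols.size == 0:
            raise ValidationError(
                f"cell-type group '{group}' has no reference (untreated) sample"
            )
        with np.errstate(invalid="ignore"):
            ref_mean = np.nanmean(matrix.values[:, ref_cols], axis=1)
        out.values[:, cols] = matrix.values[:, cols] - ref_mean[:, None]
    return out


def collapse_clones(matrix: ExpressionMatrix, key: str = "gene_symbol") -> ExpressionMatrix:
    """Average rows (clones/probes) sharing the same ``key`` annotation.

    Cells average the non-missing constituent values and are missing only
    when every constituent is missing.  Rows with an empty key are
    dropped with a logged count.  Output rows are ordered by first
    appearance of each key.
    """
    if key not in ("gene_symbol", "unigene_id"):
        raise ValidationError("collapse key must be gene_symbol or unigene_id")
    keys = matrix.features[key].to_numpy()
    nonempty = keys != ""
    n_dropped = int((~nonempty).sum())
    if n_dropped:
        logger.info("collapse_clones: dropped %d rows with empty %s", n_dropped, key)

    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i in np.flatnonzero(nonempty):
        k = keys[i]
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(i)

    values = np.full((len(order), matrix.n_samples), np.nan)
    feats = {"probe_id": [], "gene_symbol": [], "unigene_id": []}
    for r, k in enumerate(order):
        idx = groups[k]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            values[r] = np.nanmean(matrix.values[idx], axis=0)
        first = matrix.features.iloc[idx[0]]
        feats["probe_id"].append(k)
        feats["gene_symbol"].append(
            k if key == "gene_symbol" else first["gene_symbol"]
        )
        feats["unigene_id"].append(
            k if key == "unigene_id" else first["unigene_id"]
        )
    return ExpressionMatrix(values, pd.DataFrame(feats), matrix.samples.copy())
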