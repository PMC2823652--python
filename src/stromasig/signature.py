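"""Signature extraction, cohort projection and scoring.

A signature is derived from the stimulation experiment either by the
fold-change rule (mean induction in stimulated samples above 1.5-fold,
on a matrix standardized so the untreated mean is zero per gene) or
from the significant up/down calls of a paired SAM fit.

Projection onto a tumour cohort matches signature genes to cohort rows
by upper-cased gene symbol (Unigene id as fallback), averages multiple
probes per gene, keeps genes with > 80% data values present and
mean-centres each row across the cohort.  The continuous score of a
patient is the mean of the projected signature rows; the median of the
scores splits the cohort into high/low groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneSignature, ValidationError
from .preprocess import collapse_clones

logger = logging.getLogger(__name__)


# --------------------------------------------------------- extraction
def extract_signature_foldchange(
    matrix: ExpressionMatrix,
    min_fold: float = 1.5,
    name: str = "foldchange_up",
) -> GeneSignature:
    """Genes whose mean log2 ratio over stimulated samples strictly
    exceeds log2(min_fold), ordered by mean induction descending.

    The matrix must already be standardized to the untreated samples
    (untreated mean zero per gene), so values are inductions.
    """
    stim = matrix.samples["treatment"].to_numpy() == "stimulated"
    if not stim.any():
        raise ValidationError("no stimulated samples in matrix")
    with np.errstate(invalid="ignore"):
        mean_induction = np.nanmean(matrix.values[:, stim], axis=1)
    threshold = np.log2(min_fold)
    idx = np.flatnonzero(mean_induction > threshold)
    idx = idx[np.argsort(-mean_induction[idx], kind="stable")]
    symbols = matrix.features["gene_symbol"].to_numpy()
    genes = [symbols[i] if symbols[i] else matrix.probe_ids[i] for i in idx]
    return GeneSignature(
        name,
        genes,
        direction="up",
        provenance=f"fold-change rule: mean stimulated induction > {min_fold}-fold",
    )


def extract_signature_from_sam(
    sam_results,
    matrix: ExpressionMatrix | None = None,
    direction: str = "up",
    name: str | None = None,
) -> GeneSignature:
    """Signature from SAM calls, collapsed to unique gene symbols.

    When ``matrix`` is given, called probe ids are translated to gene
    symbols through its feature annotations; otherwise the called ids
    are used directly.
    """
    called = sam_results.up_called if direction == "up" else sam_results.down_called
    if not called:
        logger.warning("SAM call set is empty; returning empty signature")
    genes = called
    if matrix is not None:
        sym = dict(zip(matrix.probe_ids, matrix.features["gene_symbol"]))
        genes = [sym.get(g, "") or g for g in called]
    prov = (
        f"paired SAM: delta={sam_results.delta:.4g}, "
        f"estimated FDR={sam_results.fdr:.4g}, s0={sam_results.s0:.4g}, "
        f"seed={sam_results.config.seed}"
    )
    return GeneSignature(
        name or f"sam_{direction}", genes, direction=direction, provenance=prov
    )


# --------------------------------------------------------- projection
@dataclass
class ProjectionReport:
    found: list[str]
    missing: list[str]
    dropped_low_presence: list[str]


def project_signature(
    sig: GeneSignature,
    cohort: ExpressionMatrix,
    min_presence: float = 0.80,
) -> tuple[ExpressionMatrix, ProjectionReport]:
    """Extract, average, filter and mean-centre signature rows of a
    cohort matrix.

    Rows must retain strictly more than ``min_presence`` non-missing
    values to survive.  Returns the projected sub-matrix and a match
    report listing found/missing signature genes.
    """
    by_symbol = collapse_clones(cohort, key="gene_symbol")
    symbol_rows = {g: i for i, g in enumerate(by_symbol.features["gene_symbol"])}
    unigene_rows: dict[str, int] = {}
    if (cohort.features["unigene_id"] != "").any():
        by_unigene = collapse_clones(cohort, key="unigene_id")
        unigene_rows = {
            u.upper(): i for i, u in enumerate(by_unigene.features["unigene_id"])
        }

    rows: list[np.ndarray] = []
    found: list[str] = []
    missing: list[str] = []
    for gene in sig.genes:
        if gene in symbol_rows:
            rows.append(by_symbol.values[symbol_rows[gene]])
            found.append(gene)
        elif gene in unigene_rows:
            rows.append(by_unigene.values[unigene_rows[gene]])
            found.append(gene)
        else:
            missing.append(gene)
    if not found:
        raise ValidationError("no signature genes matched the cohort")
    if missing:
        logger.info(
            "projection: %d of %d signature genes missing from cohort",
            len(missing), len(sig.genes),
        )

    values = np.vstack(rows)
    presence = (~np.isnan(values)).mean(axis=1)
    keep = presence > min_presence
    dropped = [g for g, k in zip(found, keep) if not k]
    values = values[keep]
    kept_genes = [g for g, k in zip(found, keep) if k]
    if values.shape[0] == 0:
        raise ValidationError("all matched signature genes failed the presence filter")
    with np.errstate(invalid="ignore"):
        values = values - np.nanmean(values, axis=1, keepdims=True)

    projected = ExpressionMatrix(
        values,
        pd.DataFrame(
            {"probe_id": kept_genes, "gene_symbol": kept_genes, "unigene_id": ""}
        ),
        cohort.samples.copy(),
    )
    return projected, ProjectionReport(kept_genes, missing, dropped)


# ------------------------------------------------------------ scoring
@dataclass
class ScoreResult:
    """Per-sample continuous scores and the median-split grouping."""

    scores: pd.Series              # index: sample_id; NaN if unscorable
    median: float
    groups: pd.Series              # 'high' / 'low'; excluded samples absent
    n_genes_used: pd.Series

    @property
    def high(self) -> list[str]:
        return list(self.groups.index[self.groups == "high"])

    @property
    def low(self) -> list[str]:
        return list(self.groups.index[self.groups == "low"])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample_id": self.scores.index, "score": self.scores.values}
        )
        df["group"] = [self.groups.get(s, "") for s in df["sample_id"]]
        df["n_genes_used"] = self.n_genes_used.values
        return df


def continuous_score(projected: ExpressionMatrix) -> ScoreResult:
    """Mean signature expression per sample, split at the median.

    Scores strictly above the median are 'high'; scores at or below it
    are 'low'.  Samples with every signature value missing get a missing
    score and are excluded from the split with a warning.
    """
    vals = projected.values
    n_used = (~np.isnan(vals)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        score = np.where(n_used > 0, np.nanmean(vals, axis=0), np.nan)
    scores = pd.Series(score, index=projected.sample_ids, name="score")
    usable = scores.dropna()
    if len(usable) < len(scores):
        logger.warning(
            "%d samples have no signature values and are excluded from the split",
            len(scores) - len(usable),
        )
    if usable.empty:
        raise ValidationError("no sample has any signature value")
    med = float(usable.median())
    groups = pd.Series(
        np.where(usable.values > med, "high", "low"), index=usable.index
    )
    return ScoreResult(
        scores=scores,
        median=med,
        groups=groups,
        n_genes_used=pd.Series(n_used, index=projected.sample_ids),
    )


def label_cluster_groups(
    group_a: list[str],
    group_b: list[str],
    projected: ExpressionMatrix,
) -> dict[str, list[str]]:
    """Name the two clustering groups 'high'/'low' by mean signature
    expression; a tie goes to the larger group with a warning."""
    col = {s: j for j, s in enumerate(projected.sample_ids)}
    def group_mean(group: list[str]) -> float:
        cols = [col[s] for s in group if s in col]
        if not cols:
            raise ValidationError("cluster group has no samples in the matrix")
        return float(np.nanmean(projected.values[:, cols]))

    mean_a, mean_b = group_mean(group_a), group_mean(group_b)
    if mean_a > mean_b:
        return {"high": list(group_a), "low": list(group_b)}
    if mean_b > mean_a:
        return {"high": list(group_b), "low": list(group_a)}
    logger.warning("equal group means; tie broken toward the larger group as high")
    if len(group_a) >= len(group_b):
        return {"high": list(group_a), "low": list(group_b)}
    return {"high": list(group_b), "low": list(group_a)}


# --------------------------------------------------------- comparison
@dataclass
class SignatureComparison:
    name_a: str
    name_b: str
    centroids: pd.DataFrame
    r: float
    p_value: float


def centroid_correlation(
    scores_a: ScoreResult | pd.Series,
    scores_b: ScoreResult | pd.Series,
    name_a: str = "A",
    name_b: str = "B",
) -> SignatureComparison:
    """Pearson correlation of two signatures' per-sample centroids."""
    sa = scores_a.scores if isinstance(scores_a, ScoreResult) else scores_a
    sb = scores_b.scores if isinstance(scores_b, ScoreResult) else scores_b
    if list(sa.index) != list(sb.index):
        common = sa.index.intersection(sb.index)
        if len(common) != len(sa) or len(common) != len(sb):
            raise ValidationError("score vectors must cover the same samples")
        sb = sb.loc[sa.index]
    both = ~(sa.isna() | sb.isna())
    x, y = sa[both].to_numpy(), sb[both].to_numpy()
    if x.size < 3:
        raise ValidationError("need at least 3 jointly scored samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("centroid correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    centroids = pd.DataFrame({name_a: sa, name_b: sb})
    return SignatureComparison(name_a, name_b, centroids, float(r), float(p))
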