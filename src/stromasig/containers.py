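"""Core in-memory containers for the signature pipeline.

Expression data are two-colour microarray measurements stored as log2
ratios of sample over common-reference fluorescence, genes in rows and
hybridizations in columns.  Missing measurements (flagged spots, empty
cells) are carried as NaN in ``values`` alongside an explicit boolean
mask so downstream statistics are missing-aware throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("stimulated", "unstimulated", "n/a")
ENDPOINTS = ("overall", "disease_specific", "distant_metastasis")

FEATURE_COLUMNS = ["probe_id", "gene_symbol", "unigene_id"]
SAMPLE_COLUMNS = ["sample_id", "cell_type", "treatment", "pair_id"]


class ValidationError(ValueError):
    """Raised when a container or input file violates its contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-ratio matrix with annotations.

    Parameters
    ----------
    values : (n_genes, n_samples) float array; NaN marks missing.
    features : DataFrame with columns probe_id, gene_symbol, unigene_id.
    samples : DataFrame with columns sample_id, cell_type, treatment, pair_id.
    """

    values: np.ndarray
    features: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (genes x samples)")
        self.features = _normalize_features(self.features, self.values.shape[0])
        self.samples = _normalize_samples(self.samples, self.values.shape[1])
        if not np.all(np.isfinite(self.values[~np.isnan(self.values)])):
            raise ValidationError("non-missing expression values must be finite")

    # -- basic views -------------------------------------------------
    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.features["probe_id"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def subset_genes(self, row_idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(row_idx, dtype=int)
        return ExpressionMatrix(
            self.values[idx],
            self.features.iloc[idx].reset_index(drop=True),
            self.samples.copy(),
        )

    def subset_samples(self, col_idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(col_idx, dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            self.features.copy(),
            self.samples.iloc[idx].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.probe_ids, columns=self.sample_ids
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            self.features.copy(),
            self.samples.copy(),
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            np.array_equal(self.values, other.values, equal_nan=True)
            and self.features.equals(other.features)
            and self.samples.equals(other.samples)
        )


def _normalize_features(features: pd.DataFrame, n_rows: int) -> pd.DataFrame:
    features = features.copy().reset_index(drop=True)
    for col in FEATURE_COLUMNS:
        if col not in features.columns:
            features[col] = ""
    features = features[FEATURE_COLUMNS].fillna("").astype(str)
    if len(features) != n_rows:
        raise ValidationError(
            f"feature table has {len(features)} rows for {n_rows} genes"
        )
    dupes = features["probe_id"][features["probe_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"duplicate probe ids: {', '.join(sorted(dupes))}")
    return features


def _normalize_samples(samples: pd.DataFrame, n_cols: int) -> pd.DataFrame:
    samples = samples.copy().reset_index(drop=True)
    if "sample_id" not in samples.columns:
        raise ValidationError("sample table requires a sample_id column")
    for col in ("cell_type", "treatment", "pair_id"):
        if col not in samples.columns:
            samples[col] = "n/a" if col == "treatment" else ""
    samples = samples[SAMPLE_COLUMNS].fillna("").astype(str)
    if len(samples) != n_cols:
        raise ValidationError(
            f"sample table has {len(samples)} rows for {n_cols} samples"
        )
    dupes = samples["sample_id"][samples["sample_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"duplicate sample ids: {', '.join(sorted(dupes))}")
    bad = set(samples["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValidationError(f"unknown treatment labels: {sorted(bad)}")
    return samples


@dataclass
class ClinicalTable:
    """Per-sample follow-up records: survival time (years), 0/1 event
    indicator, endpoint label and arbitrary named covariates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy().reset_index(drop=True)
        for col in ("sample_id", "time", "event"):
            if col not in df.columns:
                raise ValidationError(f"clinical table missing column '{col}'")
        if "endpoint_label" not in df.columns:
            df["endpoint_label"] = "overall"
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        df["time"] = df["time"].astype(float)
        if (df["time"] < 0).any():
            bad = df.loc[df["time"] < 0, "sample_id"].tolist()
            raise ValidationError(f"negative survival time for {bad}")
        df["event"] = df["event"].astype(int)
        if not df["event"].isin([0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")
        unknown = set(df["endpoint_label"]) - set(ENDPOINTS)
        if unknown:
            raise ValidationError(f"unknown endpoint labels: {sorted(unknown)}")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def covariate_names(self) -> list[str]:
        core = {"sample_id", "time", "event", "endpoint_label"}
        return [c for c in self.data.columns if c not in core]


@dataclass
class GeneSignature:
    """Ordered gene set with direction of regulation and provenance."""

    name: str
    genes: list[str]
    direction: str = "up"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError("direction must be 'up' or 'down'")
        folded: list[str] = []
        seen: set[str] = set()
        dropped = 0
        for g in self.genes:
            gu = str(g).strip().upper()
            if not gu:
                continue
            if gu in seen:
                dropped += 1
                continue
            seen.add(gu)
            folded.append(gu)
        if dropped:
            logger.warning(
                "signature %s: %d duplicate symbols collapsed after case-folding",
                self.name,
                dropped,
            )
        self.genes = folded

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class AnnotationSet:
    """Pre-propagated term -> gene-symbol map with a declared background.

    Ontology structure is assumed resolved upstream: each term's gene set
    already includes genes annotated to its descendants.
    """

    term_to_genes: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        self.term_to_genes = {
            str(t): {str(g).upper() for g in genes}
            for t, genes in self.term_to_genes.items()
        }
        for term, genes in self.term_to_genes.items():
            if not genes:
                raise ValidationError(f"term '{term}' annotates no genes")
        self.background = {str(g).upper() for g in self.background}

    @property
    def annotated_background(self) -> set[str]:
        """Background genes carrying at least one annotation."""
        annotated: set[str] = set()
        for genes in self.term_to_genes.values():
            annotated |= genes & self.background
        return annotated


@dataclass
class Dendrogram:
    """Binary agglomeration tree.

    merges[i] = (left, right, height, size): children are leaf indices
    (< n_leaves) or prior merge ids (n_leaves + j).  Heights are merge
    distances, non-decreasing from first merge to root.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("dendrogram leaf labels must be unique")
        n = len(self.labels)
        if self.merges and len(self.merges) != n - 1:
            raise ValidationError("a binary tree on n leaves has n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_leaves(self, node: int) -> list[int]:
        """Leaf indices under ``node`` in left-to-right order."""
        n = self.n_leaves
        if node < n:
            return [node]
        left, right, _, _ = self.merges[node - n]
        return self.node_leaves(left) + self.node_leaves(right)

    def leaf_order(self) -> list[int]:
        if not self.merges:
            return list(range(self.n_leaves))
        return self.node_leaves(self.n_leaves + len(self.merges) - 1)

    def root_children_leafsets(self) -> tuple[list[int], list[int]]:
        if not self.merges:
            raise ValidationError("dendrogram has no merges (need >= 2 leaves)")
        left, right, _, _ = self.merges[-1]
        return self.node_leaves(left), self.node_leaves(right)


def make_expression_matrix(
    values: np.ndarray,
    probe_ids: Iterable[str],
    sample_ids: Iterable[str],
    gene_symbols: Iterable[str] | None = None,
    unigene_ids: Iterable[str] | None = None,
    cell_types: Iterable[str] | None = None,
    treatments: Iterable[str] | None = None,
    pair_ids: Iterable[str] | None = None,
) -> ExpressionMatrix:
    """Convenience constructor from parallel annotation lists."""
    values = np.asarray(values, dtype=float)
    probe_ids = [str(p) for p in probe_ids]
    sample_ids = [str(s) for s in sample_ids]
    features = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_symbol": list(gene_symbols) if gene_symbols is not None else "",
            "unigene_id": list(unigene_ids) if unigene_ids is not None else "",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cell_type": list(cell_types) if cell_types is not None else "",
            "treatment": list(treatments) if treatments is not None else "n/a",
            "pair_id": list(pair_ids) if pair_ids is not None else "",
        }
    )
    return ExpressionMatrix(values, features, samples)
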