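"""End-to-end orchestration of the two analysis flows.

``run_derive``  : stimulation experiment -> spot QC -> presence ->
variation -> standardize to untreated -> (paired SAM | fold-change) ->
clone collapse -> signature (+ optional term enrichment).

``run_validate``: cohort + signature -> projection -> both
stratification modes (root split of the sample dendrogram, and the
median split of the continuous score) -> KM / log-rank / Cox
(univariate and covariate-adjusted), reported side by side.

Each run can write its outputs plus a JSON manifest (config snapshot,
seeds, input digests, per-stage row counts, package version) from which
the numeric outputs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import ClusteringConfig, cluster_axis, cut_two_groups
from .containers import (
    AnnotationSet,
    ClinicalTable,
    ExpressionMatrix,
    GeneSignature,
    ValidationError,
)
from .enrichment import EnrichmentResults, TermEnrichment
from .io import write_cdt_gtr, write_signature
from .preprocess import (
    PreprocessConfig,
    apply_spot_qc,
    collapse_clones,
    filter_presence,
    filter_variation,
    standardize_to_reference,
)
from .sam import PairedSAM, SamConfig
from .signature import (
    ScoreResult,
    continuous_score,
    extract_signature_foldchange,
    extract_signature_from_sam,
    label_cluster_groups,
    project_signature,
)
from .survival import SurvivalFit, compare_groups

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc


def _digest(obj) -> str:
    if isinstance(obj, ExpressionMatrix):
        h = hashlib.sha256()
        h.update(np.nan_to_num(obj.values, nan=-1e30).tobytes())
        h.update(",".join(obj.probe_ids).encode())
        h.update(",".join(obj.sample_ids).encode())
        return h.hexdigest()[:16]
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    flow: str
    config: dict
    seeds: dict
    input_digests: dict
    stage_counts: dict
    version: str = __version__

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)


# ------------------------------------------------------------- derive
@dataclass
class DeriveResult:
    signature: GeneSignature
    sam_results: object | None
    enrichment: EnrichmentResults | None
    manifest: RunManifest


def run_derive(
    matrix: ExpressionMatrix,
    quality: pd.DataFrame | None = None,
    annotations: AnnotationSet | None = None,
    method: str = "sam",
    preprocess_config: PreprocessConfig | None = None,
    sam_config: SamConfig | None = None,
    min_fold: float = 1.5,
    enrichment_resamples: int = 50,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> DeriveResult:
    """Derive an induced-gene signature from a stimulation experiment."""
    if method not in ("sam", "foldchange"):
        raise ValidationError("method must be 'sam' or 'foldchange'")
    pp = preprocess_config or PreprocessConfig()
    counts: dict[str, int] = {"input_genes": matrix.n_genes}
    digests = {"matrix": _digest(matrix)}

    work = matrix
    if quality is not None:
        work = _stage("spot_qc", apply_spot_qc, work, quality, pp)
    work = _stage("presence_filter", filter_presence, work, pp)
    counts["after_presence"] = work.n_genes
    work = _stage("variation_filter", filter_variation, work, pp)
    counts["after_variation"] = work.n_genes
    untreated = [
        s for s, t in zip(work.sample_ids, work.samples["treatment"]) if t == "unstimulated"
    ]
    work = _stage("standardize", standardize_to_reference, work, untreated)

    sam_results = None
    if method == "sam":
        cfg = sam_config or SamConfig(seed=seed)
        sam_results = _stage("sam", lambda: PairedSAM(work, cfg).fit())
        signature = _stage(
            "signature", extract_signature_from_sam, sam_results, work, "up"
        )
    else:
        collapsed = _stage("collapse", collapse_clones, work, "gene_symbol")
        counts["after_collapse"] = collapsed.n_genes
        signature = _stage(
            "signature", extract_signature_foldchange, collapsed, min_fold
        )
    counts["signature_genes"] = len(signature)

    enrichment = None
    if annotations is not None:
        enrichment = _stage(
            "enrichment",
            lambda: TermEnrichment(
                set(signature.genes), annotations,
                n_resamples=enrichment_resamples, seed=seed,
            ).fit(),
        )
    manifest = RunManifest(
        flow="derive",
        config={
            "method": method,
            "min_fold": min_fold,
            "preprocess": pp.__dict__,
            "sam": (sam_config or SamConfig(seed=seed)).__dict__ if method == "sam" else None,
        },
        seeds={"seed": seed},
        input_digests=digests,
        stage_counts=counts,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_signature(signature, out_dir / "signature.tsv")
        if sam_results is not None:
            sam_results.to_tsv(out_dir / "sam_result.tsv")
        if enrichment is not None:
            enrichment.to_tsv(out_dir / "enrichment.tsv")
        manifest.write(out_dir / "manifest.json")
    return DeriveResult(signature, sam_results, enrichment, manifest)


# ----------------------------------------------------------- validate
@dataclass
class ValidateResult:
    scores: ScoreResult
    cluster_groups: dict[str, list[str]]
    survival_by_mode: dict[str, SurvivalFit]
    agreement: float
    manifest: RunManifest


def run_validate(
    cohort: ExpressionMatrix,
    clinical: ClinicalTable,
    signature: GeneSignature,
    adjust: list[str] | None = None,
    clustering_config: ClusteringConfig | None = None,
    min_presence: float = 0.80,
    out_dir: str | Path | None = None,
) -> ValidateResult:
    """Project a signature onto a cohort and stratify survival by both
    the clustering root split and the continuous-score median split."""
    counts: dict[str, int] = {
        "cohort_genes": cohort.n_genes,
        "cohort_samples": cohort.n_samples,
        "signature_genes": len(signature),
    }
    projected, report = _stage(
        "projection", project_signature, signature, cohort, min_presence
    )
    counts["projected_genes"] = projected.n_genes

    scores = _stage("continuous_score", continuous_score, projected)
    sample_tree = _stage(
        "clustering", cluster_axis, projected, "samples", clustering_config
    )
    group_a, group_b = _stage("two_group_cut", cut_two_groups, sample_tree)
    cluster_groups = _stage(
        "label_groups", label_cluster_groups, group_a, group_b, projected
    )

    cluster_series = pd.Series(
        {s: "high" for s in cluster_groups["high"]}
        | {s: "low" for s in cluster_groups["low"]}
    )
    median_series = scores.groups
    common = median_series.index.intersection(cluster_series.index)
    agreement = float(
        (median_series.loc[common] == cluster_series.loc[common]).mean()
    )

    if int(clinical.data["event"].sum()) == 0:
        raise StageError("survival", ValidationError("cohort has zero events"))
    survival_by_mode = {
        "cluster_split": _stage(
            "survival", compare_groups, clinical, cluster_series, adjust
        ),
        "median_split": _stage(
            "survival", compare_groups, clinical, median_series, adjust
        ),
    }
    manifest = RunManifest(
        flow="validate",
        config={"adjust": adjust or [], "min_presence": min_presence},
        seeds={},
        input_digests={"cohort": _digest(cohort)},
        stage_counts=counts
        | {
            "genes_missing_from_cohort": len(report.missing),
            "genes_dropped_low_presence": len(report.dropped_low_presence),
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        scores.to_frame().to_csv(out_dir / "scores.tsv", sep="\t", index=False)
        gene_tree = cluster_axis(projected, axis="genes")
        write_cdt_gtr(projected, gene_tree, sample_tree, out_dir / "clustered")
        with open(out_dir / "survival.txt", "w", encoding="utf-8") as fh:
            for mode, fit in survival_by_mode.items():
                fh.write(f"== {mode} ==\n{fit.summary()}\n\n")
        manifest.write(out_dir / "manifest.json")
    return ValidateResult(scores, cluster_groups, survival_by_mode, agreement, manifest)
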