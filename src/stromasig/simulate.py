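"""Synthetic generators for every input the pipeline consumes.

Three generators, all pure functions of (config, seed):

* a paired stimulated/unstimulated fibroblast experiment with a planted
  set of induced genes whose fold induction is drawn around 2.35-fold
  (sd 0.45 on the fold scale), measurement noise on the log2 scale and
  spot-quality metrics drawn so a configured fraction of spots fails QC;
* a tumour cohort in which a latent per-patient activity drives both
  the expression of the signature genes (through per-gene loadings) and
  an exponential proportional-hazards survival time, with independent
  censoring and an optional binary covariate correlated with activity;
* a term -> gene annotation map with one planted enriched term
  overlapping a given query at a configured enrichment factor.

Ground truth (induced gene set, per-patient activity, planted term) is
returned alongside the data for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    AnnotationSet,
    ClinicalTable,
    ExpressionMatrix,
    ValidationError,
    make_expression_matrix,
)

logger = logging.getLogger(__name__)


# ------------------------------------------------------- stimulation
@dataclass
class StimulationSimConfig:
    n_genes: int = 5000
    n_pairs: int = 6  # three patients, a normal and a tumour-derived culture each
    frac_induced: float = 0.04
    induced_fold_mean: float = 2.35   # fold scale; converted to log2
    induced_fold_sd: float = 0.45
    noise_sd: float = 0.15            # log2 replicate noise
    missing_rate: float = 0.02
    qc_fail_rate: float = 0.05        # fraction of spots drawn to fail QC
    cell_type: str = "fibroblast"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_induced <= 1) or not (0 <= self.missing_rate <= 1):
            raise ValidationError("fractions must be in [0, 1]")
        if self.noise_sd <= 0 or self.induced_fold_sd <= 0:
            raise ValidationError("standard deviations must be positive")
        if self.frac_induced * self.n_genes < 1:
            raise ValidationError("config plants fewer than one induced gene")


@dataclass
class StimulationTruth:
    induced_genes: list[str]
    log2_effects: pd.Series   # per induced gene


def simulate_stimulation_experiment(
    config: StimulationSimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, StimulationTruth]:
    """Paired experiment: returns (matrix, spot-quality table, truth).

    Samples are u1..um (unstimulated) and s1..sm (stimulated), pair ids
    p1..pm.  Gene baselines are zero-centred log2 ratios; induced genes
    gain log2(fold) in the stimulated member of every pair.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genes, config.n_pairs
    n_induced = int(round(config.frac_induced * n))

    probe_ids = [f"CLONE{i:05d}" for i in range(n)]
    symbols = [f"G{i:05d}" for i in range(n)]
    induced_idx = rng.choice(n, size=n_induced, replace=False) if n_induced else np.array([], int)
    folds = rng.normal(config.induced_fold_mean, config.induced_fold_sd, n_induced)
    folds = np.clip(folds, 1.05, None)  # induction means fold > 1
    effects = np.zeros(n)
    effects[induced_idx] = np.log2(folds)

    sample_ids = [f"u{j + 1}" for j in range(m)] + [f"s{j + 1}" for j in range(m)]
    treatments = ["unstimulated"] * m + ["stimulated"] * m
    pair_ids = [f"p{j + 1}" for j in range(m)] * 2

    baseline = rng.normal(0.0, 0.5, size=n)  # gene-specific log2 baseline
    values = np.empty((n, 2 * m))
    for j in range(m):
        values[:, j] = baseline + rng.normal(0, config.noise_sd, n)
        values[:, m + j] = baseline + effects + rng.normal(0, config.noise_sd, n)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan

    matrix = make_expression_matrix(
        values,
        probe_ids,
        sample_ids,
        gene_symbols=symbols,
        cell_types=[config.cell_type] * (2 * m),
        treatments=treatments,
        pair_ids=pair_ids,
    )
    quality = _simulate_spot_quality(rng, probe_ids, sample_ids, config.qc_fail_rate)
    truth = StimulationTruth(
        induced_genes=[symbols[i] for i in sorted(induced_idx)],
        log2_effects=pd.Series(
            effects[sorted(induced_idx)], index=[symbols[i] for i in sorted(induced_idx)]
        ),
    )
    return matrix, quality, truth


def _simulate_spot_quality(
    rng: np.random.Generator,
    probe_ids: list[str],
    sample_ids: list[str],
    fail_rate: float,
) -> pd.DataFrame:
    """Spot metrics: most spots pass comfortably; a ``fail_rate``
    fraction is drawn with sub-threshold correlation."""
    n_spots = len(probe_ids) * len(sample_ids)
    fails = rng.random(n_spots) < fail_rate
    corr = np.where(
        fails,
        rng.uniform(0.0, 0.6, n_spots),
        rng.uniform(0.8, 1.0, n_spots),
    )
    ch1 = rng.uniform(500, 5000, n_spots)
    ch2 = rng.uniform(500, 5000, n_spots)
    bg1 = rng.uniform(50, 200, n_spots)
    bg2 = rng.uniform(50, 200, n_spots)
    return pd.DataFrame(
        {
            "probe_id": np.repeat(probe_ids, len(sample_ids)),
            "sample_id": np.tile(sample_ids, len(probe_ids)),
            "regression_correlation": corr,
            "ch1_mean": ch1,
            "ch1_background": bg1,
            "ch2_mean": ch2,
            "ch2_background": bg2,
            "manual_flag": False,
        }
    )


# ------------------------------------------------------------ cohort
@dataclass
class CohortSimConfig:
    n_samples: int = 295              # early-breast-cancer cohort scale
    n_genes: int = 2000
    signature_size: int = 50
    activity_sd: float = 1.0
    activity_dist: str = "normal"     # or "bimodal" (two planted clusters)
    loading_mean: float = 1.0
    loading_sd: float = 0.3
    noise_sd: float = 0.5
    true_log_hr: float = 0.9          # per sd of activity; HR ~ 2.46
    baseline_hazard: float = 0.08     # events / year
    censoring_rate: float = 0.05      # independent censoring / year
    followup_cap: float = 15.0        # administrative censoring, years
    covariate_effect: float = 0.0     # log-odds link of ER status to activity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValidationError("cohort needs at least 10 samples")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline hazard must be positive")
        if self.censoring_rate < 0 or self.followup_cap <= 0:
            raise ValidationError("invalid censoring configuration")
        if self.activity_dist not in ("normal", "bimodal"):
            raise ValidationError("activity_dist must be 'normal' or 'bimodal'")
        if self.signature_size > self.n_genes:
            raise ValidationError("signature_size cannot exceed n_genes")


@dataclass
class CohortTruth:
    activity: pd.Series          # per sample
    signature_genes: list[str]
    true_hr: float


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, "GeneSignatureLike", CohortTruth]:
    """Latent-factor cohort with proportional-hazards survival.

    Returns (expression, clinical, signature, truth).  Signature-gene
    expression is loading * activity + noise; all other genes are pure
    noise.  Survival times are exponential with hazard
    baseline * exp(true_log_hr * standardized activity); censoring is
    independent exponential, capped at the follow-up horizon.
    """
    rng = np.random.default_rng(config.seed)
    n_s, n_g, k = config.n_samples, config.n_genes, config.signature_size

    if config.activity_dist == "bimodal":
        signs = rng.choice([-1.0, 1.0], size=n_s)
        activity = signs * config.activity_sd + rng.normal(0, 0.2 * config.activity_sd, n_s)
    else:
        activity = rng.normal(0.0, config.activity_sd, n_s)
    std_activity = (activity - activity.mean()) / activity.std()

    sig_idx = np.arange(k)  # planted in the first k rows; ids are shuffled names
    loadings = rng.normal(config.loading_mean, config.loading_sd, k)
    values = rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    values[sig_idx] += loadings[:, None] * activity[None, :]

    symbols = [f"SIG{i:04d}" if i < k else f"BG{i:04d}" for i in range(n_g)]
    probe_ids = [f"P{i:05d}" for i in range(n_g)]
    sample_ids = [f"T{j + 1:03d}" for j in range(n_s)]
    matrix = make_expression_matrix(
        values, probe_ids, sample_ids, gene_symbols=symbols,
        cell_types=["tumour"] * n_s,
    )

    hazard = config.baseline_hazard * np.exp(config.true_log_hr * std_activity)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, n_s)
    else:
        censor_time = np.full(n_s, np.inf)
    censor_time = np.minimum(censor_time, config.followup_cap)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    clin = {"sample_id": sample_ids, "time": time, "event": event,
            "endpoint_label": "overall"}
    if config.covariate_effect != 0.0:
        p_pos = 1.0 / (1.0 + np.exp(config.covariate_effect * std_activity))
        clin["ER_status"] = np.where(rng.random(n_s) < p_pos, "pos", "neg")
    clinical = ClinicalTable(pd.DataFrame(clin))

    from .containers import GeneSignature

    signature = GeneSignature(
        "planted", [symbols[i] for i in sig_idx], direction="up",
        provenance="synthetic latent-factor cohort",
    )
    truth = CohortTruth(
        activity=pd.Series(activity, index=sample_ids),
        signature_genes=list(signature.genes),
        true_hr=float(np.exp(config.true_log_hr)),
    )
    return matrix, clinical, signature, truth


GeneSignatureLike = object  # forward alias for the return annotation


# ------------------------------------------------------- annotations
@dataclass
class AnnotationSimConfig:
    n_terms: int = 30
    term_size_min: int = 10
    term_size_max: int = 120
    enrichment_factor: float = 4.0   # planted term's overlap multiplier
    planted_term_size: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.term_size_min < 1 or self.term_size_max < self.term_size_min:
            raise ValidationError("invalid term size bounds")
        if self.enrichment_factor < 0:
            raise ValidationError("enrichment factor must be non-negative")


def simulate_annotations(
    query_genes: list[str],
    background_genes: list[str],
    config: AnnotationSimConfig,
) -> tuple[AnnotationSet, str]:
    """Random term map over ``background_genes`` with one planted term.

    The planted term draws its genes so that the expected query overlap
    is ``enrichment_factor`` times the chance expectation (factor 1
    reproduces the null).  Returns (annotations, planted term id).
    """
    rng = np.random.default_rng(config.seed)
    background = sorted({str(g).upper() for g in background_genes})
    query = sorted({str(g).upper() for g in query_genes} & set(background))
    if not query:
        raise ValidationError("query has no genes in the background")
    non_query = sorted(set(background) - set(query))

    term_map: dict[str, set[str]] = {}
    for t in range(config.n_terms):
        size = int(rng.integers(config.term_size_min, config.term_size_max + 1))
        size = min(size, len(background))
        term_map[f"TERM{t:03d}"] = set(rng.choice(background, size, replace=False))

    planted = "TERM_PLANTED"
    size = min(config.planted_term_size, len(background))
    base_rate = size / len(background)
    q_rate = min(1.0, config.enrichment_factor * base_rate)
    in_query = [g for g in query if rng.random() < q_rate]
    n_rest = max(0, size - len(in_query))
    rest = rng.choice(non_query, min(n_rest, len(non_query)), replace=False)
    genes = set(in_query) | set(rest)
    if not genes:
        genes = {query[0]}
    term_map[planted] = genes
    return AnnotationSet(term_map, set(background)), planted
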