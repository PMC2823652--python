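"""Hypergeometric over-representation analysis of a gene list.

Given a query gene list and a pre-propagated term -> gene map, each
term is scored with the upper-tail hypergeometric probability of seeing
at least k annotated query genes when n annotated query genes are drawn
from an annotated background of N genes of which K carry the term:

    P = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N, n)

Genes without any annotation are excluded from both the query (n) and
the background (N).  Raw P-values receive a Bonferroni correction with
factor T = number of terms with at least one annotated query gene, and
a resampling FDR: random queries of the same size are drawn from the
annotated background and the expected number of false-positive terms at
each observed corrected-P threshold is estimated.

``TermEnrichment`` is the model; ``fit()`` returns
``EnrichmentResults`` whose table mirrors the classic GO-term report
(cluster frequency, background frequency, corrected P, FDR, expected
false positives).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import AnnotationSet, ValidationError

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n).

    Computed through the survival function, which scipy evaluates
    stably in log space for extreme tails.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N or n < 0 or K < 0:
        raise ValidationError(
            f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    query_genes: set[str] | list[str], annotations: AnnotationSet
) -> pd.DataFrame:
    """Per-term counts and P-values for a query gene list.

    Returns a frame sorted by corrected P ascending with columns term,
    k, n, K, N, cluster_frequency_pct, background_frequency_pct, raw_p,
    corrected_p and bonferroni_factor.
    """
    query = {str(g).upper() for g in query_genes}
    background = annotations.annotated_background
    annotated_query = query & background
    if not annotated_query:
        raise ValidationError("no annotated query genes (after background intersection)")
    n = len(annotated_query)
    N = len(background)

    rows = []
    for term, genes in annotations.term_to_genes.items():
        term_bg = genes & background
        k = len(annotated_query & term_bg)
        if k == 0:
            continue
        K = len(term_bg)
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "cluster_frequency_pct": 100.0 * k / n,
                "background_frequency_pct": 100.0 * K / N,
                "raw_p": hypergeom_tail(k, n, K, N),
            }
        )
    if not rows:
        raise ValidationError("no term annotates any query gene")
    T = len(rows)
    table = pd.DataFrame(rows)
    table["corrected_p"] = np.minimum(1.0, table["raw_p"] * T)
    table["bonferroni_factor"] = T
    table = table.sort_values(
        ["corrected_p", "raw_p", "term"], kind="stable"
    ).reset_index(drop=True)
    return table


def resampling_fdr(
    observed: pd.DataFrame,
    annotations: AnnotationSet,
    n_resamples: int = 50,
    seed: int | None = None,
) -> pd.DataFrame:
    """Attach resampling-based FDR columns to an observed enrichment table.

    For each resample, ``n`` genes are drawn uniformly without
    replacement from the annotated background and re-scored; for each
    observed corrected-P threshold the expected number of random-query
    terms at or below it estimates the false positives, and FDR =
    expected false positives / observed count (clamped to [0, 1]).
    """
    n = int(observed["n"].iloc[0])
    background = sorted(annotations.annotated_background)
    if n > len(background):
        raise ValidationError("query size exceeds annotated background size")
    rng = np.random.default_rng(seed)
    null_corrected: list[np.ndarray] = []
    for _ in range(n_resamples):
        draw = rng.choice(background, size=n, replace=False)
        try:
            tab = enrich_terms(set(draw), annotations)
            null_corrected.append(tab["corrected_p"].to_numpy())
        except ValidationError:
            null_corrected.append(np.array([]))
    pooled = np.sort(np.concatenate(null_corrected)) if null_corrected else np.array([])

    out = observed.copy()
    thresholds = out["corrected_p"].to_numpy()
    expected_fp = np.array(
        [np.searchsorted(pooled, t, side="right") / n_resamples for t in thresholds]
    )
    observed_count = np.arange(1, len(out) + 1)  # table sorted by corrected P
    fdr = np.clip(expected_fp / observed_count, 0.0, 1.0)
    # enforce monotonicity down the sorted table (step-up convention)
    fdr = np.maximum.accumulate(fdr)
    out["expected_false_positives"] = expected_fp
    out["fdr"] = fdr
    return out


class TermEnrichment:
    """Over-representation model for a query gene list against a
    pre-propagated annotation map."""

    def __init__(
        self,
        query_genes: set[str] | list[str],
        annotations: AnnotationSet,
        n_resamples: int = 50,
        seed: int | None = None,
    ):
        self.query_genes = {str(g).upper() for g in query_genes}
        self.annotations = annotations
        self.n_resamples = n_resamples
        self.seed = seed

    def fit(self) -> "EnrichmentResults":
        table = enrich_terms(self.query_genes, self.annotations)
        if self.n_resamples > 0:
            table = resampling_fdr(
                table, self.annotations, self.n_resamples, self.seed
            )
        else:
            table["expected_false_positives"] = np.nan
            table["fdr"] = np.nan
        return EnrichmentResults(table=table, n_resamples=self.n_resamples)


@dataclass
class EnrichmentResults:
    table: pd.DataFrame
    n_resamples: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self, top: int = 10) -> str:
        lines = [
            "Term enrichment (hypergeometric, Bonferroni, resampling FDR)",
            "============================================================",
            f"{'term':<28}{'cluster freq':>16}{'background':>16}"
            f"{'corrected P':>14}{'FDR':>8}{'false pos':>11}",
        ]
        for _, row in self.table.head(top).iterrows():
            lines.append(
                f"{row['term']:<28}"
                f"{row['k']:>4d}/{row['n']:<4d}{row['cluster_frequency_pct']:>5.1f}% "
                f"{row['K']:>5d}/{row['N']:<5d}{row['background_frequency_pct']:>4.1f}%"
                f"{row['corrected_p']:>14.3g}"
                f"{100 * row['fdr']:>7.1f}%"
                f"{row['expected_false_positives']:>11.2f}"
            )
        return "\n".join(lines)
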