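"""Paired two-class significance analysis of microarrays.

For each gene the paired design reduces to within-pair differences
z_j = stimulated_j - unstimulated_j, j = 1..m.  The test statistic is a
regularized one-sample t:

    d = zbar / (s + s0),    s = sqrt( sum_j (z_j - zbar)^2 / (m (m-1)) )

where the fudge factor s0 damps the statistic for genes whose scatter s
is estimated near zero.  The null distribution is generated by sign
flips of the pair differences (the exchangeability implied by the paired
design): all 2^m flip vectors are enumerated when feasible, otherwise a
seeded uniform sample is drawn.  Significance is declared by comparing
the sorted observed statistics d_(i) with the permutation-expected order
statistics dbar_(i): for a chosen threshold delta, genes beyond the
first crossing |d_(i) - dbar_(i)| >= delta are called, and the false
discovery rate is estimated as pi0 times the median number of null
statistics beyond the same cut points, divided by the number called.

``PairedSAM`` is the model object; ``fit()`` returns ``SAMResults``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .containers import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

_S0_FLOOR = 1e-8


@dataclass
class SamConfig:
    target_fdr: float = 0.0005          # the study's FDR <= 0.05%
    n_permutations: int = 1000          # used only above the enumeration limit
    enumeration_limit: int = 4096       # enumerate all flips when 2^m <= limit
    s0_method: str = "percentile_grid"  # or "fixed"
    s0_fixed: float = 0.0
    delta_grid_size: int = 101
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.target_fdr < 1):
            raise ValidationError("target_fdr must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.s0_method not in ("percentile_grid", "fixed"):
            raise ValidationError("s0_method must be percentile_grid or fixed")


# ------------------------------------------------------- statistics
def paired_moments(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene (zbar, s, m_complete) over non-missing pair differences."""
    z = np.asarray(z, dtype=float)
    m = (~np.isnan(z)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        zbar = np.nansum(z, axis=1) / np.where(m > 0, m, np.nan)
        ss = np.nansum((z - zbar[:, None]) ** 2, axis=1)
        denom = np.where(m >= 2, m * (m - 1), np.nan)
        s = np.sqrt(ss / denom)
    return zbar, s, m


def paired_d_statistics(z: np.ndarray, s0: float) -> np.ndarray:
    """d = zbar / (s + s0) per gene; NaN for genes with < 2 complete pairs."""
    if s0 < 0:
        raise ValidationError("s0 must be non-negative")
    zbar, s, _ = paired_moments(z)
    return zbar / (s + s0)


def choose_s0(z: np.ndarray, n_bins: int = 10) -> float:
    """Fudge factor minimizing the coefficient of variation of d.

    Candidates are the percentiles 0, 5, ..., 100 of the gene scatters s.
    For each candidate the genes are split into quantile bins of s and
    the spread of d (normal-scaled MAD) is computed per bin; the
    candidate with the smallest coefficient of variation of these
    spreads wins.  Ties resolve to the smallest candidate.
    """
    zbar, s, m = paired_moments(z)
    ok = m >= 2
    zbar, s = zbar[ok], s[ok]
    if zbar.size < 10:
        logger.warning("choose_s0: only %d genes; estimate is unstable", zbar.size)
    if zbar.size == 0:
        raise ValidationError("choose_s0 requires at least one gene")
    if np.all(s == 0):
        logger.warning("choose_s0: all gene scatters are zero; using floor %g", _S0_FLOOR)
        return _S0_FLOOR
    percentiles = np.arange(0, 101, 5)
    candidates = np.percentile(s, percentiles)
    n_bins = int(min(n_bins, max(2, zbar.size // 2)))
    # quantile bins of s (shared across candidates)
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)

    best_cv, best_s0 = np.inf, float(candidates[0])
    for cand in candidates:
        d = zbar / (s + cand)
        spreads = []
        for b in range(n_bins):
            db = d[bin_idx == b]
            if db.size >= 2:
                spreads.append(median_abs_deviation(db, scale="normal"))
        spreads = np.asarray(spreads)
        if spreads.size < 2 or np.mean(spreads) == 0:
            continue
        cv = np.std(spreads) / np.mean(spreads)
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(cand)
    if not np.isfinite(best_cv):
        best_s0 = float(np.median(s))  # too few genes to bin: robust default
    if best_s0 == 0.0 and np.any(s == 0):
        best_s0 = _S0_FLOOR  # keep d finite for zero-scatter genes
    return best_s0


def sign_flip_vectors(
    m: int, config: SamConfig | None = None
) -> tuple[np.ndarray, bool]:
    """All (or a seeded sample of) sign-flip vectors, shape (B, m).

    Returns (flips, enumerated).  Full enumeration when 2^m does not
    exceed the configured limit; otherwise uniform sampling, which
    requires a seed.
    """
    config = config or SamConfig()
    if m < 2:
        raise ValidationError("permutation null requires at least 2 pairs")
    if 2**m <= config.enumeration_limit:
        bits = np.arange(2**m)[:, None] >> np.arange(m) & 1
        return np.where(bits == 1, -1.0, 1.0), True
    if config.seed is None:
        raise ValidationError("sampling permutations requires a seed")
    rng = np.random.default_rng(config.seed)
    flips = rng.choice([-1.0, 1.0], size=(config.n_permutations, m))
    return flips, False


def permutation_null(
    z: np.ndarray, s0: float, config: SamConfig | None = None
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Null order statistics from sign flips of the pair differences.

    Returns (dbar, null_sorted, enumerated) where null_sorted has shape
    (B, n_genes), each row the sorted d of one permutation, and
    dbar[i] is the mean i-th order statistic.
    """
    config = config or SamConfig()
    z = np.asarray(z, dtype=float)
    flips, enumerated = sign_flip_vectors(z.shape[1], config)
    null_sorted = np.empty((flips.shape[0], z.shape[0]))
    for b, eps in enumerate(flips):
        null_sorted[b] = np.sort(paired_d_statistics(z * eps[None, :], s0))
    dbar = null_sorted.mean(axis=0)
    return dbar, null_sorted, enumerated


def estimate_pi0(d: np.ndarray, null_sorted: np.ndarray) -> float:
    """pi0 = #{d within the pooled-null interquartile range} / (n/2),
    clamped to [0, 1]."""
    pooled = null_sorted.ravel()
    q25, q75 = np.percentile(pooled, [25, 75])
    n = d.size
    inside = int(np.sum((d >= q25) & (d <= q75)))
    return float(min(1.0, inside / (0.5 * n)))


def _cut_indices(d_sorted: np.ndarray, dbar: np.ndarray, delta: float):
    """Indices (i_down, i_up) bounding the called tails; None if no call."""
    diff = d_sorted - dbar
    n = d_sorted.size
    centre = int(np.searchsorted(d_sorted, 0.0, side="left"))
    i_up = None
    for i in range(centre, n):
        if diff[i] >= delta:
            i_up = i
            break
    i_down = None
    for i in range(centre - 1, -1, -1):
        if -diff[i] >= delta:
            i_down = i
            break
    return i_down, i_up


def call_significant(
    d: np.ndarray,
    dbar: np.ndarray,
    delta: float,
    null_sorted: np.ndarray,
    pi0: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float, tuple[float, float]]:
    """Call genes beyond the delta crossings of the observed-vs-expected
    order-statistic plot.

    Returns (up_mask, down_mask, fdr, (cut_low, cut_up)) with masks in
    the original gene order.
    """
    if delta < 0:
        raise ValidationError("delta must be non-negative")
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    i_down, i_up = _cut_indices(d_sorted, dbar, delta)
    cut_up = d_sorted[i_up] if i_up is not None else np.inf
    cut_low = d_sorted[i_down] if i_down is not None else -np.inf
    up_mask = d >= cut_up
    down_mask = d <= cut_low
    n_called = int(up_mask.sum() + down_mask.sum())
    if n_called == 0:
        return up_mask, down_mask, 0.0, (cut_low, cut_up)
    exceed = (null_sorted >= cut_up).sum(axis=1) + (null_sorted <= cut_low).sum(axis=1)
    fdr = pi0 * float(np.median(exceed)) / n_called
    return up_mask, down_mask, float(min(1.0, fdr)), (cut_low, cut_up)


def choose_delta_for_fdr(
    d: np.ndarray,
    dbar: np.ndarray,
    null_sorted: np.ndarray,
    pi0: float,
    target_fdr: float,
    grid_size: int = 101,
) -> float:
    """Smallest delta on a linear grid over [0, max|d_(i) - dbar_(i)|]
    whose estimated FDR is at or below the target."""
    d_sorted = np.sort(d)
    max_gap = float(np.max(np.abs(d_sorted - dbar)))
    grid = np.linspace(0.0, max_gap + 1e-12, grid_size)
    for delta in grid:
        _, _, fdr, _ = call_significant(d, dbar, float(delta), null_sorted, pi0)
        if fdr <= target_fdr:
            return float(delta)
    logger.warning(
        "no delta on the grid attains FDR <= %g; returning grid max (no calls)",
        target_fdr,
    )
    return float(grid[-1])


# ------------------------------------------------------------- model
class PairedSAM:
    """Paired SAM model over an expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix whose samples carry ``treatment`` in
        {stimulated, unstimulated} and a shared ``pair_id`` per pair.
    config : SamConfig.
    """

    def __init__(self, matrix: ExpressionMatrix, config: SamConfig | None = None):
        self.config = config or SamConfig()
        self.matrix = matrix
        self.z, self.gene_ids = self._pair_differences(matrix)

    @staticmethod
    def _pair_differences(matrix: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
        samples = matrix.samples
        pairs: dict[str, dict[str, int]] = {}
        for j, row in samples.iterrows():
            if row["treatment"] not in ("stimulated", "unstimulated"):
                raise ValidationError(
                    f"sample {row['sample_id']} has treatment '{row['treatment']}'"
                )
            if not row["pair_id"]:
                raise ValidationError(f"sample {row['sample_id']} has no pair_id")
            slot = pairs.setdefault(row["pair_id"], {})
            if row["treatment"] in slot:
                raise ValidationError(
                    f"pair {row['pair_id']} has two {row['treatment']} samples"
                )
            slot[row["treatment"]] = j
        bad = [p for p, slot in pairs.items() if len(slot) != 2]
        if bad:
            raise ValidationError(f"unpaired samples in pairs: {sorted(bad)}")
        pair_ids = sorted(pairs)
        z = np.column_stack(
            [
                matrix.values[:, pairs[p]["stimulated"]]
                - matrix.values[:, pairs[p]["unstimulated"]]
                for p in pair_ids
            ]
        )
        return z, matrix.probe_ids

    @classmethod
    def from_differences(
        cls, z: np.ndarray, gene_ids: list[str] | None = None,
        config: SamConfig | None = None,
    ) -> "PairedSAM":
        obj = cls.__new__(cls)
        obj.config = config or SamConfig()
        obj.matrix = None
        obj.z = np.asarray(z, dtype=float)
        obj.gene_ids = (
            list(gene_ids) if gene_ids is not None
            else [f"g{i}" for i in range(obj.z.shape[0])]
        )
        return obj

    def fit(self, delta: float | None = None) -> "SAMResults":
        """Estimate s0, build the sign-flip null, choose delta for the
        target FDR (unless given) and call significant genes."""
        _, _, m = paired_moments(self.z)
        usable = m >= 2
        n_excluded = int((~usable).sum())
        if n_excluded:
            logger.info("excluding %d genes with < 2 complete pairs", n_excluded)
        z = self.z[usable]
        gene_ids = [g for g, u in zip(self.gene_ids, usable) if u]
        if z.shape[0] == 0:
            raise ValidationError("no genes with >= 2 complete pairs")

        if self.config.s0_method == "fixed":
            s0 = float(self.config.s0_fixed)
            if s0 < 0:
                raise ValidationError("fixed s0 must be non-negative")
        else:
            s0 = choose_s0(z)
        zbar, s, _ = paired_moments(z)
        d = zbar / (s + s0)
        dbar, null_sorted, enumerated = permutation_null(z, s0, self.config)
        pi0 = estimate_pi0(d, null_sorted)
        if delta is None:
            delta = choose_delta_for_fdr(
                d, dbar, null_sorted, pi0,
                self.config.target_fdr, self.config.delta_grid_size,
            )
        up, down, fdr, cuts = call_significant(d, dbar, float(delta), null_sorted, pi0)
        return SAMResults(
            gene_ids=gene_ids, zbar=zbar, s=s, d=d, s0=s0, dbar=dbar,
            null_sorted=null_sorted, delta=float(delta), pi0=pi0, fdr=fdr,
            cuts=cuts, up_mask=up, down_mask=down, enumerated=enumerated,
            config=self.config, n_excluded=n_excluded,
        )


@dataclass
class SAMResults:
    """Fitted paired-SAM results: per-gene statistics, the chosen
    threshold and the FDR estimate at that threshold."""

    gene_ids: list[str]
    zbar: np.ndarray
    s: np.ndarray
    d: np.ndarray
    s0: float
    dbar: np.ndarray
    null_sorted: np.ndarray
    delta: float
    pi0: float
    fdr: float
    cuts: tuple[float, float]
    up_mask: np.ndarray
    down_mask: np.ndarray
    enumerated: bool
    config: SamConfig
    n_excluded: int = 0
    _table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def up_called(self) -> list[str]:
        return [g for g, u in zip(self.gene_ids, self.up_mask) if u]

    @property
    def down_called(self) -> list[str]:
        return [g for g, u in zip(self.gene_ids, self.down_mask) if u]

    @property
    def table(self) -> pd.DataFrame:
        if self._table is None:
            called = np.where(self.up_mask, "up", np.where(self.down_mask, "down", "no"))
            self._table = pd.DataFrame(
                {
                    "gene": self.gene_ids,
                    "zbar": self.zbar,
                    "s": self.s,
                    "d": self.d,
                    "called": called,
                }
            )
        return self._table

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        lines = [
            "Paired SAM results",
            "==================",
            f"genes tested        : {len(self.gene_ids)}"
            + (f" ({self.n_excluded} excluded, < 2 complete pairs)" if self.n_excluded else ""),
            f"permutations        : {self.null_sorted.shape[0]}"
            + (" (full enumeration)" if self.enumerated else " (sampled)"),
            f"fudge factor s0     : {self.s0:.6g}",
            f"pi0 estimate        : {self.pi0:.4f}",
            f"delta               : {self.delta:.6g}",
            f"cut points (lo, up) : ({self.cuts[0]:.4g}, {self.cuts[1]:.4g})",
            f"up-called genes     : {int(self.up_mask.sum())}",
            f"down-called genes   : {int(self.down_mask.sum())}",
            f"estimated FDR       : {self.fdr:.6g} (target {self.config.target_fdr:g})",
        ]
        return "\n".join(lines)
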