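"""Combination of dependent per-locus p-values into per-interval scores.

The chain is: fold each p-value to a nonnegative Z score,
Z = Phi^-1(1 - p/2); decorrelate the Z vector of an interval with the upper
Cholesky factor of its estimated correlation matrix (solving C z* = z, never
inverting); aggregate with the weighted Stouffer statistic
R = sum(w z*) / sqrt(sum(w^2)); and finally remove the dependence of R on the
number of combined values with a quantile-permutation adjustment, because an
aggregate of folded (all-positive) Z scores grows with the number of loci it
combines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

logger = logging.getLogger(__name__)

P_FLOOR_DEFAULT = 1e-16


@dataclass
class ContextScore:
    """Aggregated, size-adjusted, direction-signed score for one gene x context."""

    gene_id: str
    context_name: str
    n_combined: int
    raw_stouffer: float
    adjusted_p: float
    direction: int
    locus_p_list: list[float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.adjusted_p <= 1.0):
            raise ValueError("adjusted_p must be in (0, 1]")
        if self.n_combined < 1:
            raise ValueError("n_combined must be >= 1")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")


def z_transform(p, p_floor: float = P_FLOOR_DEFAULT):
    """Fold p-values to nonnegative Z scores: Z = Phi^-1(1 - p/2).

    Values are clamped to [p_floor, 1] first (with a warning when a zero is
    seen); inputs outside [0, 1] are rejected. Accepts scalars or arrays.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(arr < p_floor):
        warnings.warn("p-values at or below the floor were clamped", stacklevel=2)
        arr = np.clip(arr, p_floor, 1.0)
    out = stats.norm.isf(arr / 2.0)
    return float(out) if np.isscalar(p) else out


def decorrelate(z_vector, interval_corr) -> np.ndarray:
    """Whiten a Z vector with the Cholesky factor of its correlation matrix.

    With the upper factor C satisfying Sigma = C'C, the solution of
    C' z* = z has identity covariance when z is N(0, Sigma):
    cov(z*) = C'^-1 Sigma C^-1 = I. A triangular solve is used for numerical
    stability (the factor is never inverted); when Sigma is the identity,
    z* equals z exactly.
    """
    z = np.asarray(z_vector, dtype=float)
    c = interval_corr.cholesky_upper
    if z.shape[0] != c.shape[0]:
        raise ValueError(f"dimension mismatch: {z.shape[0]} values vs {c.shape[0]}x{c.shape[0]} matrix")
    return linalg.solve_triangular(c, z, trans="T", lower=False)


def stouffer_aggregate(z_star_vector, locus_weights) -> float:
    """Weighted Stouffer statistic: sum(w z*) / sqrt(sum(w^2))."""
    z = np.asarray(z_star_vector, dtype=float)
    w = np.asarray(locus_weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    denom = np.sqrt(np.sum(w**2))
    if denom == 0:
        raise ValueError("weights must not all be zero")
    return float(np.sum(w * z) / denom)


# Alternative per-interval combiners behind the same interface. They operate
# on the (decorrelated) folded Z scores' implied p-values and are offered as
# simple drop-ins; Stouffer is the default and the only combiner routed
# through the decorrelation calibration guarantees.

def sidak_aggregate(z_star_vector, locus_weights=None) -> float:
    p = 2 * stats.norm.sf(np.abs(np.asarray(z_star_vector, dtype=float)))
    n = len(p)
    p_min = float(np.min(p))
    combined = 1.0 - (1.0 - p_min) ** n
    return float(stats.norm.isf(max(combined, P_FLOOR_DEFAULT) / 2.0))


def fisher_aggregate(z_star_vector, locus_weights=None) -> float:
    p = 2 * stats.norm.sf(np.abs(np.asarray(z_star_vector, dtype=float)))
    stat = -2.0 * np.sum(np.log(np.clip(p, P_FLOOR_DEFAULT, 1.0)))
    combined = float(stats.chi2.sf(stat, df=2 * len(p)))
    return float(stats.norm.isf(max(combined, P_FLOOR_DEFAULT) / 2.0))


def binomial_aggregate(z_star_vector, locus_weights=None, alpha: float = 0.05) -> float:
    p = 2 * stats.norm.sf(np.abs(np.asarray(z_star_vector, dtype=float)))
    k = int(np.sum(p <= alpha))
    combined = float(stats.binom.sf(k - 1, len(p), alpha)) if k > 0 else 1.0
    return float(stats.norm.isf(max(combined, P_FLOOR_DEFAULT) / 2.0))


AGGREGATORS = {
    "stouffer": stouffer_aggregate,
    "sidak": sidak_aggregate,
    "fisher": fisher_aggregate,
    "binomial": binomial_aggregate,
}


def _merge_sparse_strata(strata: list[np.ndarray], min_size: int = 5) -> list[np.ndarray]:
    """Merge index strata smaller than ``min_size`` into a neighbor stratum."""
    merged: list[np.ndarray] = []
    for s in strata:
        if merged and (len(s) < min_size or len(merged[-1]) < min_size):
            merged[-1] = np.concatenate([merged[-1], s])
        else:
            merged.append(s)
    # the first stratum may still be sparse if it had no left neighbor
    if len(merged) > 1 and len(merged[0]) < min_size:
        merged[1] = np.concatenate([merged[0], merged[1]])
        merged = merged[1:]
    return merged


def quantile_permutation_adjust(
    scores: list[tuple[float, int]],
    n_null_distributions: int = 100,
    n_strata: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Correct aggregate scores for the number of p-values they combine.

    Scores are stratified into quantile strata of ``n_combined`` (so each
    score is only compared with scores built from a similar number of
    values). For each observed score, ``n_null_distributions`` same-size
    resamples of its stratum are drawn with replacement; within each resample
    the proportion of scores at or above the observed one is computed — ties
    counted with the midrank convention (half weight), and with a
    (count+1)/(size+1) floor so the result is never exactly 0 — and the mean
    proportion over resamples is returned as the adjusted p.

    With fewer than 20 scores overall, the adjustment is skipped (normal
    upper-tail p of the raw score is returned, with a warning). Strata
    smaller than 5 are merged with a neighbor.
    """
    arr = np.asarray([(s, n) for s, n in scores], dtype=float)
    raw, n_comb = arr[:, 0], arr[:, 1]
    m_total = len(raw)
    if m_total < 20:
        warnings.warn("fewer than 20 scores: quantile-permutation adjustment skipped", stacklevel=2)
        return np.clip(stats.norm.sf(raw), P_FLOOR_DEFAULT, 1.0)

    rng = np.random.default_rng(seed)
    order = np.argsort(n_comb, kind="stable")
    edges = np.unique(np.quantile(n_comb, np.linspace(0, 1, n_strata + 1)[1:-1]))
    # split sorted indices at the quantile boundaries of n_combined
    split_points = np.searchsorted(n_comb[order], edges, side="right")
    strata = [s for s in np.split(order, split_points) if len(s)]
    n_before = len(strata)
    strata = _merge_sparse_strata(strata)
    if len(strata) < n_before:
        logger.info("merged %d sparse n_combined strata", n_before - len(strata))

    adjusted = np.empty(m_total)
    for idx in strata:
        vals = raw[idx]
        m = len(vals)
        samples = rng.choice(vals, size=(n_null_distributions, m), replace=True)
        samples.sort(axis=1)
        counts = np.empty((n_null_distributions, m))
        for d in range(n_null_distributions):
            # "at or more extreme" with midrank handling of ties
            lo = np.searchsorted(samples[d], vals, side="left")
            hi = np.searchsorted(samples[d], vals, side="right")
            counts[d] = (m - hi) + 0.5 * (hi - lo)
        props = (counts + 1.0) / (m + 1.0)
        adjusted[idx] = props.mean(axis=0)
    return np.clip(adjusted, P_FLOOR_DEFAULT, 1.0)


def assign_direction(effects, locus_weights, z_values) -> int:
    """Weighted Z-majority effect direction: sign of sum(w sign(effect) z).

    An exact zero (perfectly balanced evidence) resolves to +1 and is logged.
    """
    e = np.sign(np.asarray(effects, dtype=float))
    w = np.asarray(locus_weights, dtype=float)
    z = np.asarray(z_values, dtype=float)
    if len(e) == 0:
        raise ValueError("at least one effect is required")
    total = float(np.sum(w * e * z))
    if total == 0.0:
        logger.info("direction tie (weighted sum exactly 0); resolved to +1")
        return 1
    return 1 if total > 0 else -1
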