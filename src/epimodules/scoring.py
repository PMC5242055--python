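"""Gene-level combination of context scores into a single p-value and Fisher score.

Each gene's normalized context p-values are folded back to Z scores and
combined with a second weighted Stouffer step. Context weights w_j express
the analyst's priorities (e.g. up-weight expression); direction coefficients
B_j encode prior biology: B_j = -1 for contexts expected to oppose the
phenotype direction (promoter methylation vs expression), +1 for concordant
contexts, and 0 for agnostic contexts, which contribute magnitude only. The
combined statistic is referred to an empirical bootstrap null built by
resampling context scores across genes, giving a combined p-value p_i per
gene and the Fisher score G_i = -2 ln(p_i).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from epimodules.combine import z_transform
from epimodules.genome_context import ContextDefinition

logger = logging.getLogger(__name__)


@dataclass
class GeneScore:
    """Final combined significance for one gene."""

    gene_id: str
    combined_p: float
    fisher_score: float = field(init=False)
    statistic: float = 0.0            # signed combined Stouffer statistic
    contexts_used: list[str] = field(default_factory=list)
    component_table: dict[str, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.combined_p <= 1.0):
            raise ValueError("combined_p must be in (0, 1]")
        if not self.contexts_used:
            raise ValueError("contexts_used must be non-empty")
        self.fisher_score = fisher_score(self.combined_p)


def _signed_z(adjusted_p: float, direction: int, b_j: int) -> float:
    """Directional contribution of one context: s_j * Phi^-1(1 - p/2)."""
    z = z_transform(adjusted_p)
    s = direction * b_j if b_j != 0 else 1
    return s * z


def combine_gene(
    component_table: dict[str, tuple[float, int]],
    context_defs: list[ContextDefinition],
) -> float:
    """Weighted, direction-signed Stouffer statistic over a gene's present contexts.

    ``component_table`` maps context name -> (adjusted_p, direction). Only
    contexts present for the gene enter the sum; the root-sum-of-squares
    denominator runs over the same present contexts, so missing data
    renormalizes the weights implicitly rather than penalizing the gene.
    """
    defs = {c.name: c for c in context_defs}
    num = 0.0
    sumsq = 0.0
    n_used = 0
    for name, (adj_p, direction) in component_table.items():
        cdef = defs.get(name)
        if cdef is None or cdef.context_weight == 0:
            continue
        num += cdef.context_weight * _signed_z(adj_p, direction, cdef.direction_coefficient)
        sumsq += cdef.context_weight**2
        n_used += 1
    if n_used == 0:
        raise ValueError("gene has no scored context with positive weight")
    return num / np.sqrt(sumsq)


def bootstrap_gene_p(
    statistics: dict[str, float],
    component_tables: dict[str, dict[str, tuple[float, int]]],
    context_defs: list[ContextDefinition],
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict[str, float]:
    """Bootstrap p-value for each gene's combined statistic.

    The null resamples each context's (adjusted_p, direction) pairs from that
    context's gene-wide pool — an exchangeability null that preserves every
    context's marginal distribution — and recombines them with the same
    weights and direction coefficients. Genes sharing a context pattern share
    a null distribution (cached). Significance is two-sided on |statistic|;
    p = (count(|null| >= |observed|) + 1) / (n_boot + 1).
    """
    if len(statistics) < 50:
        logger.warning("bootstrap null built from only %d genes", len(statistics))
    if n_boot < 100:
        warnings.warn("n_boot < 100: bootstrap p-values will have an unstable tail", stacklevel=2)
    rng = np.random.default_rng(seed)
    defs = {c.name: c for c in context_defs}

    # gene-wide pools of signed z contributions, one per context
    pools: dict[str, np.ndarray] = {}
    for table in component_tables.values():
        for name, (adj_p, direction) in table.items():
            cdef = defs.get(name)
            if cdef is None or cdef.context_weight == 0:
                continue
            pools.setdefault(name, [])  # type: ignore[arg-type]
    for name in pools:
        vals = [
            _signed_z(t[name][0], t[name][1], defs[name].direction_coefficient)
            for t in component_tables.values()
            if name in t
        ]
        pools[name] = np.asarray(vals, dtype=float)

    null_cache: dict[frozenset, np.ndarray] = {}
    out: dict[str, float] = {}
    for gene, stat in statistics.items():
        pattern = frozenset(
            n for n in component_tables[gene]
            if n in defs and defs[n].context_weight > 0
        )
        if pattern not in null_cache:
            num = np.zeros(n_boot)
            sumsq = 0.0
            for name in sorted(pattern):
                w = defs[name].context_weight
                num += w * rng.choice(pools[name], size=n_boot, replace=True)
                sumsq += w**2
            null_cache[pattern] = np.abs(num / np.sqrt(sumsq))
        null = null_cache[pattern]
        out[gene] = float((np.sum(null >= abs(stat)) + 1.0) / (n_boot + 1.0))
    return out


def fisher_score(combined_p: float) -> float:
    """Fisher score G = -2 ln(p); chi-square with 2 degrees of freedom under the null."""
    if not (0.0 < combined_p <= 1.0):
        raise ValueError("combined_p must be in (0, 1]")
    return float(-2.0 * np.log(combined_p))


def select_high_scoring(
    gene_scores: dict[str, float],
    n_resamples: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[str]:
    """Genes whose Fisher score reaches the bootstrap background (1 - alpha) quantile.

    The background is ``n_resamples`` bootstrap draws of the observed score
    vector pooled together; genes at or above its (1 - alpha) quantile are
    returned. ``alpha = 1`` keeps every gene, ``alpha = 0`` keeps only the
    maximum (or nothing when scores are untied at the top).
    """
    if len(gene_scores) < 50:
        logger.warning("high-score background estimated from only %d genes", len(gene_scores))
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = list(gene_scores)
    vals = np.asarray([gene_scores[n] for n in names], dtype=float)
    background = rng.choice(vals, size=(n_resamples, len(vals)), replace=True).ravel()
    threshold = float(np.quantile(background, 1.0 - alpha))
    selected = [n for n, v in zip(names, vals) if v >= threshold]
    if not selected:
        logger.warning("no gene reached the background threshold %.4g", threshold)
    return selected


def background_threshold(
    gene_scores: dict[str, float],
    n_resamples: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """The bootstrap background (1 - alpha) quantile used by :func:`select_high_scoring`."""
    rng = np.random.default_rng(seed)
    vals = np.asarray(list(gene_scores.values()), dtype=float)
    background = rng.choice(vals, size=(n_resamples, len(vals)), replace=True).ravel()
    return float(np.quantile(background, 1.0 - alpha))
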