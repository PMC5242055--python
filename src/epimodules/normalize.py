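"""Cross-context normalization of adjusted p-value distributions.

Even after size adjustment, contexts (promoter methylation, gene body
hydroxymethylation, expression, ...) can have slightly different score
distributions, and the better-spread context would dominate the gene-level
combination. Two monotone, rank-preserving normalizations are offered:

* ``logit_rescale`` (default): logit-transform each context's p-values,
  rescale to the pooled mean/sd across contexts, and invert. Minimal
  distortion of the data.
* ``boxcox_normalize``: a power-transform variant operating on -ln(p); the
  Box-Cox exponent is chosen by grid-search maximum likelihood, the
  transformed values are standardized to pooled moments and mapped back.

The pooled mean/sd across all contexts defines the "common scale", making
the operation symmetric in the contexts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

_EPS = 1e-300


@dataclass
class NormalizationReport:
    context_name: str
    method: str
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    rank_check: bool

    def __post_init__(self) -> None:
        if not self.rank_check:
            raise ValueError(f"normalization of {self.context_name} broke rank order")


def _summary(p: np.ndarray) -> tuple[float, float]:
    neglog = -np.log(np.clip(p, _EPS, 1.0))
    return float(neglog.mean()), float(neglog.std(ddof=0))


def _ranks_preserved(before: np.ndarray, after: np.ndarray) -> bool:
    if len(before) < 2 or np.ptp(before) == 0:
        return True  # constant input: order trivially preserved
    rho = stats.spearmanr(before, after).statistic
    return bool(np.isclose(rho, 1.0))


def logit_rescale(
    context_p_lists: dict[str, np.ndarray],
) -> tuple[dict[str, np.ndarray], list[NormalizationReport]]:
    """Rescale each context's p-values to the pooled location/spread on the logit scale.

    x = logit(p); x' = (x - mean_ctx) / sd_ctx * sd_pooled + mean_pooled;
    p' = expit(x'). Ranks within each context are unchanged. Contexts with
    zero spread are returned unchanged with a warning.
    """
    xs = {k: logit(np.clip(np.asarray(v, float), 1e-15, 1 - 1e-15)) for k, v in context_p_lists.items()}
    pooled = np.concatenate(list(xs.values()))
    m_t, s_t = float(pooled.mean()), float(pooled.std(ddof=0))

    out: dict[str, np.ndarray] = {}
    reports: list[NormalizationReport] = []
    for name, x in xs.items():
        p_in = np.asarray(context_p_lists[name], dtype=float)
        m, s = float(x.mean()), float(x.std(ddof=0))
        if s < 1e-12:
            logger.warning("context %s has zero spread; returned unchanged", name)
            p_out = p_in.copy()
        else:
            p_out = expit((x - m) / s * s_t + m_t)
        pre = _summary(p_in)
        post = _summary(p_out)
        reports.append(
            NormalizationReport(name, "logit_rescale", pre[0], pre[1], post[0], post[1],
                                _ranks_preserved(p_in, p_out))
        )
        out[name] = np.clip(p_out, 1e-15, 1.0)
    return out, reports


def _boxcox(x: np.ndarray, lam: float) -> np.ndarray:
    return np.log(x) if lam == 0.0 else (x**lam - 1.0) / lam


def _boxcox_inv(y: np.ndarray, lam: float) -> np.ndarray:
    return np.exp(y) if lam == 0.0 else (lam * y + 1.0) ** (1.0 / lam)


def _best_lambda(x: np.ndarray, grid: np.ndarray) -> float:
    lls = [stats.boxcox_llf(lam, x) for lam in grid]
    return float(grid[int(np.argmax(lls))])


def boxcox_normalize(
    context_p_lists: dict[str, np.ndarray],
    lambda_grid: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], list[NormalizationReport]]:
    """Box-Cox power-transform normalization on the -ln(p) scale.

    Per context, the exponent lambda maximizing the Box-Cox log-likelihood is
    selected on a grid over [-2, 2] (step 0.01), the transformed values are
    standardized to the pooled moments of all transformed contexts, and the
    result is mapped back through the inverse power transform to the p scale.
    The target spread is shrunk just enough to keep every standardized value
    inside the inverse transform's domain, so the map stays strictly
    monotone (no clipping ties). Degenerate (constant) contexts pass through
    unchanged with a warning.
    """
    if lambda_grid is None:
        lambda_grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)

    neglog = {k: -np.log(np.clip(np.asarray(v, float), _EPS, 1.0 - 1e-16))
              for k, v in context_p_lists.items()}
    lams: dict[str, float] = {}
    ys: dict[str, np.ndarray] = {}
    for name, x in neglog.items():
        x = np.clip(x, 1e-12, None)  # Box-Cox needs strictly positive support
        if float(x.std(ddof=0)) < 1e-12:
            lams[name] = float("nan")
            ys[name] = x
            continue
        lam = _best_lambda(x, lambda_grid)
        lams[name] = lam
        ys[name] = _boxcox(x, lam)

    pooled = np.concatenate(list(ys.values()))
    m_t, s_t = float(pooled.mean()), float(pooled.std(ddof=0))

    out: dict[str, np.ndarray] = {}
    reports: list[NormalizationReport] = []
    for name, y in ys.items():
        p_in = np.asarray(context_p_lists[name], dtype=float)
        lam = lams[name]
        m, s = float(y.mean()), float(y.std(ddof=0))
        if not np.isfinite(lam) or s < 1e-12:
            logger.warning("context %s is degenerate; returned unchanged", name)
            p_out = p_in.copy()
        else:
            scale = s_t
            y_std = (y - m) / s
            if lam != 0.0:
                # require lam * (scale*y_std + m_t) + 1 > 0 for all values
                bound = lam * (scale * y_std + m_t) + 1.0
                if bound.min() <= 0:
                    viol = y_std[np.argmin(bound)]
                    # largest scale keeping the domain constraint with margin
                    scale = 0.95 * (-1.0 / lam - m_t) / viol
                    logger.warning(
                        "context %s: target spread shrunk (%.3g -> %.3g) to keep "
                        "the inverse Box-Cox transform in-domain", name, s_t, scale,
                    )
            x_out = _boxcox_inv(scale * y_std + m_t, lam)
            p_out = np.exp(-np.clip(x_out, 0.0, None))
        pre = _summary(p_in)
        post = _summary(p_out)
        reports.append(
            NormalizationReport(name, "boxcox", pre[0], pre[1], post[0], post[1],
                                _ranks_preserved(p_in, p_out))
        )
        out[name] = np.clip(p_out, 1e-15, 1.0)
    return out, reports


METHODS = {"logit_rescale": logit_rescale, "boxcox": boxcox_normalize}


def normalize_contexts(context_p_lists, method: str = "logit_rescale"):
    """Dispatch to the configured normalization method; ``none`` passes through."""
    if method == "none":
        return {k: np.asarray(v, float) for k, v in context_p_lists.items()}, []
    if method not in METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    return METHODS[method](context_p_lists)
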