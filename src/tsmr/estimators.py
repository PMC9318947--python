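"""Causal-effect estimators for summary-data Mendelian randomization.

Three estimators, each consuming the aligned per-SNP effects
(beta_exp, se_exp, beta_out, se_out):

Inverse-variance weighted (IVW)
    The weighted regression of outcome betas on exposure betas through
    the origin with weights w_j = 1/se_out,j²:

        b = Σ w_j βX_j βY_j / Σ w_j βX_j²,   se_FE = (Σ w_j βX_j²)^{-1/2}

    Under the multiplicative random-effects model the SE is inflated by
    the residual dispersion, floored at the fixed-effect value:

        se_RE = se_FE · max(1, sqrt(Q_reg / (J − 1))),
        Q_reg = Σ w_j (βY_j − b βX_j)².

MR-Egger
    The same weighted regression with a free intercept, each SNP oriented
    so βX_j > 0.  The slope is a pleiotropy-adjusted causal estimate, the
    intercept the average directional pleiotropy; SEs carry the same
    multiplicative floor with J − 2 degrees of freedom and p-values are
    from t(J − 2).

Weighted median
    The 0.5-quantile of the per-SNP Wald ratios under weights
    1/ratio_se_j², consistent when instruments carrying more than half of
    the weight are valid.  Its SE comes from a seeded parametric
    bootstrap.

P-values are two-sided; 95% intervals use the normal multiplier
1.959964 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MRResult",
    "PleiotropyResult",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_median_estimate",
    "to_or_scale",
    "Z95",
]

Z95 = 1.959964


@dataclass(slots=True)
class MRResult:
    """One method's causal estimate on the per-SD linear scale, with the
    OR scale populated for binary outcomes."""

    method: str
    nsnp: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None


@dataclass(slots=True)
class PleiotropyResult:
    """MR-Egger intercept test for average directional pleiotropy."""

    intercept: float
    intercept_se: float
    intercept_pval: float


def _as_arrays(*xs):
    return tuple(np.asarray(x, dtype=float) for x in xs)


def _normal_p(z: float) -> float:
    return max(float(2 * stats.norm.sf(abs(z))), 5e-324)


def ivw(
    beta_exp: Sequence[float],
    beta_out: Sequence[float],
    se_out: Sequence[float],
    mode: str = "random",
) -> MRResult:
    """Inverse-variance-weighted estimate (the study's primary analysis).

    ``mode='random'`` applies the multiplicative random-effects SE
    inflation floored at the fixed-effect SE; ``mode='fixed'`` does not.
    """
    if mode not in ("random", "fixed"):
        raise ValueError("mode must be 'random' or 'fixed'")
    bx, by, sy = _as_arrays(beta_exp, beta_out, se_out)
    J = bx.size
    if J < 2:
        raise ValueError(
            "IVW requires at least 2 instruments; use the single-SNP Wald ratio instead"
        )
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    estimate = float(np.sum(w * bx * by)) / denom
    se_fe = math.sqrt(1.0 / denom)
    if mode == "random":
        q_reg = float(np.sum(w * (by - estimate * bx) ** 2))
        scale = max(1.0, math.sqrt(q_reg / (J - 1)))
    else:
        scale = 1.0
    se = se_fe * scale
    return MRResult(
        method="ivw-re" if mode == "random" else "ivw-fe",
        nsnp=J,
        estimate=estimate,
        se=se,
        ci_low=estimate - Z95 * se,
        ci_high=estimate + Z95 * se,
        pval=_normal_p(estimate / se),
    )


def mr_egger(
    beta_exp: Sequence[float],
    beta_out: Sequence[float],
    se_out: Sequence[float],
) -> tuple[MRResult, PleiotropyResult]:
    """MR-Egger regression: slope (causal estimate) and intercept
    (average directional pleiotropy) with t(J−2) p-values."""
    bx, by, sy = _as_arrays(beta_exp, beta_out, se_out)
    J = bx.size
    if J < 3:
        raise ValueError("Egger requires >= 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    intercept, slope = fit.params
    # statsmodels' bse already include sqrt(scale); refloor at 1
    resid_scale = float(fit.scale)  # Q_reg / (J - 2)
    floor = max(1.0, math.sqrt(resid_scale))
    se_unscaled = fit.bse / math.sqrt(resid_scale)
    se_int, se_slope = (float(s) * floor for s in se_unscaled)
    df = J - 2
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), df))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), df))
    slope_res = MRResult(
        method="mr-egger",
        nsnp=J,
        estimate=float(slope),
        se=se_slope,
        ci_low=float(slope) - Z95 * se_slope,
        ci_high=float(slope) + Z95 * se_slope,
        pval=max(p_slope, 5e-324),
    )
    return slope_res, PleiotropyResult(float(intercept), se_int, max(p_int, 5e-324))


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median by linear interpolation of the cumulative
    midpoint mass s_j = (Σ_{k<=j} w_k − w_j/2) / Σ w at s = 0.5."""
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    cum = np.cumsum(w, axis=1)
    total = cum[:, -1:]
    s = (cum - w / 2.0) / total
    n, J = r.shape
    k = np.argmax(s >= 0.5, axis=1)
    est = np.empty(n)
    rows = np.arange(n)
    at_zero = k == 0
    est[at_zero] = r[at_zero, 0]
    m = ~at_zero
    k_m = k[m]
    s0 = s[rows[m], k_m - 1]
    s1 = s[rows[m], k_m]
    r0 = r[rows[m], k_m - 1]
    r1 = r[rows[m], k_m]
    est[m] = r0 + (0.5 - s0) * (r1 - r0) / (s1 - s0)
    return est


def weighted_median_estimate(
    beta_exp: Sequence[float],
    se_exp: Sequence[float],
    beta_out: Sequence[float],
    se_out: Sequence[float],
) -> float:
    """Point estimate only (no bootstrap)."""
    bx, sx, by, sy = _as_arrays(beta_exp, se_exp, beta_out, se_out)
    ratios = (by / bx)[None, :]
    weights = ((bx / sy) ** 2)[None, :]  # 1 / ratio_se²
    return float(_weighted_median_rows(ratios, weights)[0])


def weighted_median(
    beta_exp: Sequence[float],
    se_exp: Sequence[float],
    beta_out: Sequence[float],
    se_out: Sequence[float],
    n_boot: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap SE.

    Bootstrap replicates redraw beta_exp and beta_out from normals
    centred at the observed values with their reported SEs and recompute
    the weighted median; the SE is the SD over replicates. Deterministic
    given ``seed`` (or a caller-supplied ``rng``).
    """
    bx, sx, by, sy = _as_arrays(beta_exp, se_exp, beta_out, se_out)
    J = bx.size
    if J < 3:
        raise ValueError("weighted median requires >= 3 instruments")
    estimate = weighted_median_estimate(bx, sx, by, sy)
    if rng is None:
        rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, J))
    by_star = rng.normal(by, sy, size=(n_boot, J))
    ratios = by_star / bx_star
    weights = (bx_star / sy) ** 2
    boots = _weighted_median_rows(ratios, weights)
    se = float(np.std(boots, ddof=1))
    if se > 0:
        pval = _normal_p(estimate / se)
    else:
        pval = 1.0 if estimate == 0 else 5e-324
    return MRResult(
        method="weighted-median",
        nsnp=J,
        estimate=estimate,
        se=se if se > 0 else 5e-324,
        ci_low=estimate - Z95 * se,
        ci_high=estimate + Z95 * se,
        pval=pval,
    )


def to_or_scale(result: MRResult) -> MRResult:
    """Populate the odds-ratio fields by exponentiating the linear-scale
    estimate and CI (binary outcomes only; linear fields unchanged)."""
    return replace(
        result,
        or_=math.exp(result.estimate),
        or_ci_low=math.exp(result.ci_low),
        or_ci_high=math.exp(result.ci_high),
    )
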