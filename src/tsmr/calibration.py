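"""Seeded simulation studies that score the estimators against the
generator's known truth.

These routines drive both the test suite and the reproduction script:
each one repeatedly draws two-sample summary statistics from
:func:`tsmr.simulate.simulate_effect_arrays` under a stated scenario and
measures a calibration property of an estimator — coverage of the IVW
random-effects interval, the type-I error of the Egger intercept test,
pleiotropy-parameter recovery, the weighted median's robustness to
invalid instruments, the null distribution of Cochran's Q, and the
family-wise error of the Bonferroni-tiered study pipeline.

All scenario parameters default to the emulated study's conditions
(J = 65 instruments, exposure n = 451,486, outcome n = 218,792).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from . import estimators
from .diagnostics import cochrans_q
from .simulate import SyntheticConfig, simulate_effect_arrays
from .study import bonferroni_threshold, classify_association

__all__ = [
    "ivw_null_bias",
    "ivw_coverage",
    "egger_type1_error",
    "egger_intercept_recovery",
    "wm_vs_ivw_bias",
    "q_calibration",
    "familywise_error",
]


def _rng_stream(seed: int, n_reps: int):
    root = np.random.default_rng(seed)
    return [np.random.default_rng(s) for s in root.integers(0, 2**31 - 1, size=n_reps)]


def ivw_null_bias(
    n_reps: int = 500,
    seed: int = 1,
    config: SyntheticConfig | None = None,
) -> dict[str, float]:
    """Mean IVW estimate under a zero causal effect.

    Returns the Monte-Carlo mean, its standard error, and the
    z-statistic of the departure from 0.
    """
    cfg = config or SyntheticConfig(theta=0.0, invalid_fraction=0.0)
    ests = np.empty(n_reps)
    for i, rng in enumerate(_rng_stream(seed, n_reps)):
        d = simulate_effect_arrays(cfg, rng)
        ests[i] = estimators.ivw(d["beta_x"], d["beta_y"], d["se_y"]).estimate
    mc_se = float(np.std(ests, ddof=1) / np.sqrt(n_reps))
    mean = float(np.mean(ests))
    return {"mean": mean, "mc_se": mc_se, "z": mean / mc_se}


def ivw_coverage(
    theta: float = -0.43,
    n_reps: int = 1000,
    seed: int = 2,
    config: SyntheticConfig | None = None,
) -> dict[str, float]:
    """Fraction of replicates whose IVW-RE 95% CI contains the true θ."""
    cfg = replace(config or SyntheticConfig(), theta=theta, invalid_fraction=0.0)
    hits = 0
    for rng in _rng_stream(seed, n_reps):
        d = simulate_effect_arrays(cfg, rng)
        r = estimators.ivw(d["beta_x"], d["beta_y"], d["se_y"])
        hits += r.ci_low <= theta <= r.ci_high
    return {"coverage": hits / n_reps, "n_reps": n_reps}


def _egger_scenario(**overrides) -> SyntheticConfig:
    base = dict(
        theta=0.0,
        invalid_fraction=1.0,
        pleiotropy_mode="balanced",
        pleiotropy_sd=0.002,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def egger_type1_error(
    n_reps: int = 2000,
    seed: int = 3,
    alpha: float = 0.05,
    config: SyntheticConfig | None = None,
) -> dict[str, float]:
    """Rejection rate of the Egger intercept test under balanced
    pleiotropy (every instrument pleiotropic, α_j ~ N(0, 0.002))."""
    cfg = config or _egger_scenario()
    rejections = 0
    for rng in _rng_stream(seed, n_reps):
        d = simulate_effect_arrays(cfg, rng)
        _, pleio = estimators.mr_egger(d["beta_x"], d["beta_y"], d["se_y"])
        rejections += pleio.intercept_pval < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def egger_intercept_recovery(
    pleiotropy_mean: float = 0.02,
    n_reps: int = 1000,
    seed: int = 4,
    config: SyntheticConfig | None = None,
) -> dict[str, float]:
    """Mean Egger intercept under directional pleiotropy of known mean."""
    cfg = config or _egger_scenario(
        pleiotropy_mode="directional",
        pleiotropy_mean=pleiotropy_mean,
        pleiotropy_sd=0.005,
    )
    ints = np.empty(n_reps)
    for i, rng in enumerate(_rng_stream(seed, n_reps)):
        d = simulate_effect_arrays(cfg, rng)
        _, pleio = estimators.mr_egger(d["beta_x"], d["beta_y"], d["se_y"])
        ints[i] = pleio.intercept
    mean = float(np.mean(ints))
    mc_se = float(np.std(ints, ddof=1) / np.sqrt(n_reps))
    return {
        "mean_intercept": mean,
        "mc_se": mc_se,
        "true_mean": pleiotropy_mean,
        "z": (mean - pleiotropy_mean) / mc_se,
    }


def wm_vs_ivw_bias(
    theta: float = 0.5,
    n_reps: int = 500,
    seed: int = 5,
    config: SyntheticConfig | None = None,
) -> dict[str, float]:
    """Bias of the weighted median vs IVW when 40% of instruments carry
    large directional pleiotropy (the >50%-valid guarantee)."""
    cfg = config or SyntheticConfig(
        theta=theta,
        invalid_fraction=0.4,
        pleiotropy_mode="directional",
        pleiotropy_mean=0.05,
        pleiotropy_sd=0.01,
    )
    wm = np.empty(n_reps)
    iv = np.empty(n_reps)
    for i, rng in enumerate(_rng_stream(seed, n_reps)):
        d = simulate_effect_arrays(cfg, rng)
        wm[i] = estimators.weighted_median_estimate(
            d["beta_x"], d["se_x"], d["beta_y"], d["se_y"]
        )
        iv[i] = estimators.ivw(d["beta_x"], d["beta_y"], d["se_y"]).estimate
    return {
        "wm_bias": float(np.mean(wm) - cfg.theta),
        "ivw_bias": float(np.mean(iv) - cfg.theta),
        "n_reps": n_reps,
    }


def q_calibration(
    n_variants: int = 30,
    n_reps: int = 1000,
    seed: int = 6,
) -> dict[str, float]:
    """Mean Cochran Q under the exact homogeneous null (θ = 0, no
    pleiotropy), where Q | beta_x ~ χ²(J−1)."""
    cfg = SyntheticConfig(n_variants=n_variants, theta=0.0, invalid_fraction=0.0)
    qs = np.empty(n_reps)
    for i, rng in enumerate(_rng_stream(seed, n_reps)):
        d = simulate_effect_arrays(cfg, rng)
        est = estimators.ivw(d["beta_x"], d["beta_y"], d["se_y"]).estimate
        qs[i] = cochrans_q(d["beta_x"], d["beta_y"], d["se_y"], est).Q
    df = n_variants - 1
    return {
        "mean_q": float(np.mean(qs)),
        "expected": float(df),
        "band_half_width": 3 * np.sqrt(2 * df / n_reps),
        "n_reps": n_reps,
    }


def familywise_error(
    n_outcomes: int = 10,
    n_reps: int = 200,
    seed: int = 7,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Fraction of replicate studies (all outcomes θ = 0) with at least
    one 'significant'-tier outcome under the family Bonferroni
    threshold."""
    cfg = SyntheticConfig(theta=0.0, invalid_fraction=0.0)
    threshold = bonferroni_threshold(alpha, n_outcomes)
    any_sig = 0
    for rng in _rng_stream(seed, n_reps):
        d_exp = simulate_effect_arrays(cfg, rng)
        sig = False
        for _ in range(n_outcomes):
            se_y = d_exp["se_y"]
            beta_y = rng.normal(0.0, se_y)  # θ = 0, shared instruments
            r = estimators.ivw(d_exp["beta_x"], beta_y, se_y)
            if classify_association(r.pval, threshold, alpha) == "significant":
                sig = True
        any_sig += sig
    return {"familywise_rate": any_sig / n_reps, "n_reps": n_reps}
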