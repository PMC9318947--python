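"""Heterogeneity, leave-one-out and per-SNP plot-data diagnostics.

Cochran's Q measures dispersion of the per-SNP Wald ratios around the
pooled IVW estimate under inverse-variance weights; excess Q signals
heterogeneity, a possible footprint of horizontal pleiotropy.  The
ratio-form Q computed here, Σ v_j (r_j − b)² with v_j = 1/ratio_se_j²,
is algebraically identical to the regression residual sum
Σ w_j (βY_j − b βX_j)² that drives the IVW random-effects inflation, so
the two modules agree by construction (asserted in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MRResult, Z95, ivw
from .harmonize import HarmonizedInstrument

__all__ = [
    "HeterogeneityResult",
    "LeaveOneOutResult",
    "cochrans_q",
    "leave_one_out",
    "single_snp_forest",
    "funnel_data",
]


@dataclass(slots=True)
class HeterogeneityResult:
    Q: float
    df: int
    pval: float


@dataclass
class LeaveOneOutResult:
    """IVW-RE re-fits excluding one SNP at a time.

    ``rows`` holds (excluded snp_id, MRResult on the remaining J−1);
    ``flagged`` lists exclusions that change the estimate's sign or move
    it outside the all-SNP 95% CI.
    """

    full: MRResult
    rows: list[tuple[str, MRResult]]
    max_abs_shift: float
    argmax_snp: str
    flagged: list[str]


def cochrans_q(
    beta_exp: Sequence[float],
    beta_out: Sequence[float],
    se_out: Sequence[float],
    ivw_estimate: float,
) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios around the pooled IVW estimate,
    with ratio-form weights v_j = 1/ratio_se_j²; df = J − 1."""
    bx, by, sy = (np.asarray(a, dtype=float) for a in (beta_exp, beta_out, se_out))
    J = bx.size
    if J < 2:
        raise ValueError("Cochran's Q requires >= 2 instruments")
    ratios = by / bx
    v = (bx / sy) ** 2
    q = float(np.sum(v * (ratios - ivw_estimate) ** 2))
    df = J - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))


def leave_one_out(
    beta_exp: Sequence[float],
    beta_out: Sequence[float],
    se_out: Sequence[float],
    snp_ids: Sequence[str],
) -> LeaveOneOutResult:
    """Re-run the primary IVW-RE estimator J times, excluding one SNP
    each time."""
    bx, by, sy = (np.asarray(a, dtype=float) for a in (beta_exp, beta_out, se_out))
    J = bx.size
    if J < 3:
        raise ValueError("leave-one-out requires >= 3 instruments")
    full = ivw(bx, by, sy, mode="random")
    rows: list[tuple[str, MRResult]] = []
    flagged: list[str] = []
    shifts = np.empty(J)
    mask = np.ones(J, dtype=bool)
    for j in range(J):
        mask[j] = False
        sub = ivw(bx[mask], by[mask], sy[mask], mode="random")
        mask[j] = True
        rows.append((snp_ids[j], sub))
        shifts[j] = abs(sub.estimate - full.estimate)
        sign_change = np.sign(sub.estimate) != np.sign(full.estimate) and sub.estimate != 0
        outside_ci = not (full.ci_low <= sub.estimate <= full.ci_high)
        if sign_change or outside_ci:
            flagged.append(snp_ids[j])
    k = int(np.argmax(shifts))
    return LeaveOneOutResult(
        full=full,
        rows=rows,
        max_abs_shift=float(shifts[k]),
        argmax_snp=snp_ids[k],
        flagged=flagged,
    )


def single_snp_forest(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Per-SNP Wald ratios with 95% CIs — the forest-plot table."""
    if not instruments:
        raise ValueError("no instruments")
    return pd.DataFrame(
        {
            "snp_id": [h.snp_id for h in instruments],
            "ratio": [h.ratio for h in instruments],
            "ci_low": [h.ratio - Z95 * h.ratio_se for h in instruments],
            "ci_high": [h.ratio + Z95 * h.ratio_se for h in instruments],
        }
    )


def funnel_data(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Per-SNP (ratio, precision = 1/ratio_se) — the funnel-plot table."""
    if not instruments:
        raise ValueError("no instruments")
    return pd.DataFrame(
        {
            "snp_id": [h.snp_id for h in instruments],
            "ratio": [h.ratio for h in instruments],
            "precision": [1.0 / h.ratio_se for h in instruments],
        }
    )
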