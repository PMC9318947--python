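"""Model/Results front end for a single exposure-outcome MR analysis.

`MendelianRandomization` is built from harmonized instruments (or
directly from two summary-statistic tables via
:meth:`MendelianRandomization.from_summary_stats`, which runs instrument
selection and harmonization); :meth:`~MendelianRandomization.fit` returns
an :class:`MRResults` carrying the IVW (random- and fixed-effect),
weighted-median and MR-Egger estimates, the Egger intercept pleiotropy
test, Cochran's Q, and a leave-one-out analysis, with ``summary()``
rendering the familiar study table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import diagnostics, estimators
from .harmonize import HarmonizedInstrument, harmonize, to_arrays
from .io import LDMatrix, SummaryStatRecord
from .select import SelectionConfig, SelectionResult, select_instruments

__all__ = ["MendelianRandomization", "MRResults"]


class MendelianRandomization:
    """Two-sample summary-data MR model for one exposure-outcome pair.

    Parameters
    ----------
    instruments :
        Harmonized instruments (aligned exposure/outcome effects).
    binary_outcome :
        When True, fitted results also carry the odds-ratio scale.

    Examples
    --------
    >>> model = MendelianRandomization.from_summary_stats(exp, out, ld=ld)
    >>> res = model.fit(seed=7)
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(
        self,
        instruments: Sequence[HarmonizedInstrument],
        binary_outcome: bool = False,
    ) -> None:
        if len(instruments) == 0:
            raise ValueError("no harmonized instruments")
        self.instruments = list(instruments)
        self.binary_outcome = binary_outcome
        self.selection: SelectionResult | None = None
        self.harmonization_audit = None

    @classmethod
    def from_summary_stats(
        cls,
        exposure_records: Sequence[SummaryStatRecord],
        outcome_records: Sequence[SummaryStatRecord],
        ld: LDMatrix | None = None,
        selection: SelectionConfig | None = None,
        maf_ambiguity_threshold: float = 0.42,
        palindromic_mode: str = "infer",
        binary_outcome: bool = False,
    ) -> "MendelianRandomization":
        """Select instruments from the exposure GWAS (significance,
        clumping against ``ld``, F filter) and harmonize them against the
        outcome GWAS.  With ``ld=None`` the variants are assumed
        independent and clumping is skipped."""
        sel = None
        if ld is not None:
            sel = select_instruments(exposure_records, ld, selection)
            exposure_records = sel.instruments
        kept, audit = harmonize(
            exposure_records,
            outcome_records,
            maf_ambiguity_threshold=maf_ambiguity_threshold,
            palindromic_mode=palindromic_mode,
        )
        model = cls(kept, binary_outcome=binary_outcome)
        model.selection = sel
        model.harmonization_audit = audit
        return model

    @property
    def nsnp(self) -> int:
        return len(self.instruments)

    def fit(self, n_boot: int = 5000, seed: int | None = None) -> "MRResults":
        """Compute all estimators and diagnostics.

        ``seed`` drives the weighted-median bootstrap; everything else is
        deterministic.
        """
        arr = to_arrays(self.instruments)
        bx, sx, by, sy = arr["beta_exp"], arr["se_exp"], arr["beta_out"], arr["se_out"]
        ivw_re = estimators.ivw(bx, by, sy, mode="random")
        ivw_fe = estimators.ivw(bx, by, sy, mode="fixed")
        results = {"ivw-re": ivw_re, "ivw-fe": ivw_fe}
        pleiotropy = None
        loo = None
        wm = None
        if self.nsnp >= 3:
            egger, pleiotropy = estimators.mr_egger(bx, by, sy)
            wm = estimators.weighted_median(bx, sx, by, sy, n_boot=n_boot, seed=seed)
            results["mr-egger"] = egger
            results["weighted-median"] = wm
            loo = diagnostics.leave_one_out(bx, by, sy, list(arr["snp_ids"]))
        het = diagnostics.cochrans_q(bx, by, sy, ivw_re.estimate)
        if self.binary_outcome:
            results = {k: estimators.to_or_scale(v) for k, v in results.items()}
        return MRResults(
            model=self,
            results=results,
            heterogeneity=het,
            pleiotropy=pleiotropy,
            leave_one_out=loo,
        )


@dataclass
class MRResults:
    """Fitted estimates, diagnostics and report tables for one outcome."""

    model: MendelianRandomization
    results: dict[str, estimators.MRResult]
    heterogeneity: diagnostics.HeterogeneityResult
    pleiotropy: estimators.PleiotropyResult | None
    leave_one_out: diagnostics.LeaveOneOutResult | None

    @property
    def primary(self) -> estimators.MRResult:
        """The random-effects IVW estimate (the primary analysis)."""
        return self.results["ivw-re"]

    def forest_data(self) -> pd.DataFrame:
        return diagnostics.single_snp_forest(self.model.instruments)

    def funnel_data(self) -> pd.DataFrame:
        return diagnostics.funnel_data(self.model.instruments)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, r in self.results.items():
            rows.append(
                {
                    "method": name,
                    "nsnp": r.nsnp,
                    "estimate": r.estimate,
                    "se": r.se,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "pval": r.pval,
                    "or": r.or_,
                    "or_ci_low": r.or_ci_low,
                    "or_ci_high": r.or_ci_high,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = []
        lines.append("Two-sample Mendelian randomization")
        lines.append("=" * 74)
        lines.append(f"Instruments: {self.model.nsnp}")
        frame = self.to_frame()
        cols = ["method", "nsnp", "estimate", "se", "ci_low", "ci_high", "pval"]
        if self.model.binary_outcome:
            cols += ["or", "or_ci_low", "or_ci_high"]
        lines.append(
            frame[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}")
        )
        lines.append("-" * 74)
        h = self.heterogeneity
        lines.append(f"Heterogeneity: Cochran Q = {h.Q:.3f}, df = {h.df}, p = {h.pval:.3g}")
        if self.pleiotropy is not None:
            p = self.pleiotropy
            lines.append(
                "Pleiotropy (Egger intercept): "
                f"{p.intercept:.5f} (se {p.intercept_se:.5f}), p = {p.intercept_pval:.3g}"
            )
        if self.leave_one_out is not None:
            lines.append(
                f"Leave-one-out: max |shift| = {self.leave_one_out.max_abs_shift:.4g} "
                f"(excluding {self.leave_one_out.argmax_snp}); "
                f"flagged: {len(self.leave_one_out.flagged)}"
            )
        return "\n".join(lines)
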