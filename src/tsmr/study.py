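"""Multi-outcome study orchestration, Bonferroni families and tiers.

One exposure GWAS is instrumented once; every outcome GWAS is harmonized
against that instrument set and fitted with all estimators.  Outcomes
belong to one of two multiple-testing families (``disease`` or
``biomarker``); each family's Bonferroni threshold is alpha divided by
the family size, and the primary (IVW random-effects) p-value is
classified into three tiers:

* ``significant`` — p < alpha/m,
* ``suggestive``  — alpha/m <= p < alpha,
* ``null``        — p >= alpha.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnostics import HeterogeneityResult, LeaveOneOutResult
from .estimators import MRResult, PleiotropyResult
from .harmonize import AuditEntry
from .io import LDMatrix, SummaryStatRecord, read_ld_matrix, read_summary_stats
from .model import MendelianRandomization, MRResults
from .select import SelectionConfig, SelectionResult, select_instruments

__all__ = [
    "OutcomeSpec",
    "StudyConfig",
    "OutcomeReport",
    "StudyReport",
    "bonferroni_threshold",
    "display_threshold",
    "classify_association",
    "run_study",
    "run_mr_study",
    "report_frame",
    "estimates_frame",
    "write_report",
]

TIERS = ("significant", "suggestive", "null")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Exact family-wise threshold alpha/m."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m

def display_threshold(threshold: float) -> str:
    """Render a threshold to 4 decimal places (the reporting convention)."""
    return f"{threshold:.4f}".rstrip("0").rstrip(".") if threshold >= 1e-4 else f"{threshold:g}"


def classify_association(pval: float, threshold: float, alpha: float = 0.05) -> str:
    """Three-tier label for the primary p-value (see module docstring)."""
    if threshold > alpha:
        raise ValueError("Bonferroni threshold cannot exceed alpha")
    if pval < threshold:
        return "significant"
    if pval < alpha:
        return "suggestive"
    return "null"


@dataclass
class OutcomeSpec:
    name: str
    path: str | Path = ""
    column_map: Mapping[str, str] | None = None
    binary: bool = True
    family: str = "disease"  # disease | biomarker

    def __post_init__(self) -> None:
        if self.family not in ("disease", "biomarker"):
            raise ValueError("family must be 'disease' or 'biomarker'")


@dataclass
class StudyConfig:
    exposure_path: str | Path
    outcomes: list[OutcomeSpec]
    ld_path: str | Path
    exposure_column_map: Mapping[str, str] | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    alpha: float = 0.05
    n_boot: int = 5000
    seed: int = 0
    palindromic_mode: str = "infer"

    def __post_init__(self) -> None:
        names = [o.name for o in self.outcomes]
        if len(set(names)) != len(names):
            raise ValueError("outcome names must be unique")


@dataclass
class OutcomeReport:
    name: str
    family: str
    binary: bool
    nsnp: int
    results: dict[str, MRResult] | None
    heterogeneity: HeterogeneityResult | None
    pleiotropy: PleiotropyResult | None
    loo_max_abs_shift: float | None
    loo_flagged: list[str]
    tier: str | None
    threshold: float | None
    forest: pd.DataFrame | None = None
    funnel: pd.DataFrame | None = None
    harmonization_audit: list[AuditEntry] | None = None
    error: str | None = None


@dataclass
class StudyReport:
    outcomes: list[OutcomeReport]
    selection: SelectionResult
    family_sizes: dict[str, int]
    thresholds: dict[str, float]
    alpha: float


def _fit_outcome(
    spec: OutcomeSpec,
    instruments: Sequence[SummaryStatRecord],
    outcome_records: Sequence[SummaryStatRecord],
    threshold: float,
    alpha: float,
    n_boot: int,
    seed: int,
    palindromic_mode: str,
) -> OutcomeReport:
    from .harmonize import harmonize

    kept, audit = harmonize(instruments, outcome_records, palindromic_mode=palindromic_mode)
    if len(kept) == 0:
        return OutcomeReport(
            name=spec.name, family=spec.family, binary=spec.binary, nsnp=0,
            results=None, heterogeneity=None, pleiotropy=None,
            loo_max_abs_shift=None, loo_flagged=[], tier=None,
            threshold=threshold, harmonization_audit=audit,
            error="no instruments kept at harmonization",
        )
    model = MendelianRandomization(kept, binary_outcome=spec.binary)
    res: MRResults = model.fit(n_boot=n_boot, seed=seed)
    tier = classify_association(res.primary.pval, threshold, alpha)
    return OutcomeReport(
        name=spec.name, family=spec.family, binary=spec.binary, nsnp=model.nsnp,
        results=res.results, heterogeneity=res.heterogeneity,
        pleiotropy=res.pleiotropy,
        loo_max_abs_shift=(res.leave_one_out.max_abs_shift if res.leave_one_out else None),
        loo_flagged=(res.leave_one_out.flagged if res.leave_one_out else []),
        tier=tier, threshold=threshold,
        forest=res.forest_data(), funnel=res.funnel_data(),
        harmonization_audit=audit,
    )


def run_study(
    exposure_records: Sequence[SummaryStatRecord],
    outcome_tables: Sequence[tuple[OutcomeSpec, Sequence[SummaryStatRecord]]],
    ld: LDMatrix,
    selection: SelectionConfig | None = None,
    alpha: float = 0.05,
    n_boot: int = 5000,
    seed: int = 0,
    palindromic_mode: str = "infer",
) -> StudyReport:
    """In-memory study: select instruments once from the exposure, then
    harmonize and fit every outcome independently.

    A per-outcome failure (no SNPs kept at harmonization) is recorded on
    that outcome's report row; the run continues.
    """
    sel = select_instruments(exposure_records, ld, selection)
    family_sizes: dict[str, int] = {}
    for spec, _ in outcome_tables:
        family_sizes[spec.family] = family_sizes.get(spec.family, 0) + 1
    thresholds = {fam: bonferroni_threshold(alpha, m) for fam, m in family_sizes.items()}
    reports = []
    for k, (spec, records) in enumerate(outcome_tables):
        reports.append(
            _fit_outcome(
                spec, sel.instruments, records, thresholds[spec.family],
                alpha, n_boot, seed + k, palindromic_mode,
            )
        )
    return StudyReport(
        outcomes=reports, selection=sel,
        family_sizes=family_sizes, thresholds=thresholds, alpha=alpha,
    )


def run_mr_study(config: StudyConfig) -> StudyReport:
    """File-based entry point: read exposure, LD and every outcome table
    per ``config``, then delegate to :func:`run_study`."""
    exposure, issues = read_summary_stats(config.exposure_path, config.exposure_column_map)
    if not exposure:
        raise ValueError("exposure table has no valid rows")
    ld = read_ld_matrix(config.ld_path)
    tables = []
    for spec in config.outcomes:
        recs, _ = read_summary_stats(spec.path, spec.column_map)
        tables.append((spec, recs))
    return run_study(
        exposure, tables, ld,
        selection=config.selection, alpha=config.alpha,
        n_boot=config.n_boot, seed=config.seed,
        palindromic_mode=config.palindromic_mode,
    )


def report_frame(report: StudyReport, family: str | None = None) -> pd.DataFrame:
    """One row per outcome: the primary estimate plus diagnostics columns
    (method, nsnp, estimate, se, OR, CI, p, Q, Q_df, Q_p, Egger
    intercept and its p, tier)."""
    rows = []
    for oc in report.outcomes:
        if family is not None and oc.family != family:
            continue
        if oc.error is not None or oc.results is None:
            rows.append({"outcome": oc.name, "family": oc.family, "method": "ivw-re",
                         "nsnp": oc.nsnp, "tier": None, "error": oc.error})
            continue
        r = oc.results["ivw-re"]
        rows.append(
            {
                "outcome": oc.name,
                "family": oc.family,
                "method": "ivw-re",
                "nsnp": r.nsnp,
                "estimate": r.estimate,
                "se": r.se,
                "OR": r.or_,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "or_ci_low": r.or_ci_low,
                "or_ci_high": r.or_ci_high,
                "p": r.pval,
                "Q": oc.heterogeneity.Q if oc.heterogeneity else None,
                "Q_df": oc.heterogeneity.df if oc.heterogeneity else None,
                "Q_p": oc.heterogeneity.pval if oc.heterogeneity else None,
                "egger_intercept": oc.pleiotropy.intercept if oc.pleiotropy else None,
                "intercept_p": oc.pleiotropy.intercept_pval if oc.pleiotropy else None,
                "tier": oc.tier,
                "error": None,
            }
        )
    return pd.DataFrame(rows)


def estimates_frame(report: StudyReport) -> pd.DataFrame:
    """Long table: one row per (outcome, method)."""
    rows = []
    for oc in report.outcomes:
        if oc.results is None:
            continue
        for method, r in oc.results.items():
            rows.append(
                {
                    "outcome": oc.name, "family": oc.family, "method": method,
                    "nsnp": r.nsnp, "estimate": r.estimate, "se": r.se,
                    "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.pval,
                    "OR": r.or_, "or_ci_low": r.or_ci_low, "or_ci_high": r.or_ci_high,
                }
            )
    return pd.DataFrame(rows)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def report_to_json(report: StudyReport) -> str:
    payload = _jsonable(report)
    # SelectionResult carries full record objects; keep only ids + log
    payload["selection"] = {
        "instrument_ids": [r.snp_id for r in report.selection.instruments],
        "stage_counts": report.selection.stage_counts,
        "removal_log": _jsonable(report.selection.removal_log),
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Emit the report bundle: per-family main tables, the long estimate
    table, heterogeneity / leave-one-out / forest / funnel TSVs, the
    selection removal log, and a machine-readable JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for fam in sorted(report.family_sizes):
        frame = report_frame(report, family=fam)
        frame.to_csv(outdir / f"report_{fam}.tsv", sep="\t", index=False)
    estimates_frame(report).to_csv(outdir / "estimates.tsv", sep="\t", index=False)

    het_rows, loo_rows, forest_rows, funnel_rows = [], [], [], []
    for oc in report.outcomes:
        if oc.heterogeneity is not None:
            het_rows.append(
                {"outcome": oc.name, "Q": oc.heterogeneity.Q,
                 "df": oc.heterogeneity.df, "p": oc.heterogeneity.pval}
            )
        if oc.forest is not None:
            f = oc.forest.copy()
            f.insert(0, "outcome", oc.name)
            forest_rows.append(f)
        if oc.funnel is not None:
            f = oc.funnel.copy()
            f.insert(0, "outcome", oc.name)
            funnel_rows.append(f)
        loo_rows.append(
            {"outcome": oc.name, "max_abs_shift": oc.loo_max_abs_shift,
             "flagged": ",".join(oc.loo_flagged)}
        )
    pd.DataFrame(het_rows).to_csv(outdir / "heterogeneity.tsv", sep="\t", index=False)
    pd.DataFrame(loo_rows).to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)
    if forest_rows:
        pd.concat(forest_rows).to_csv(outdir / "forest.tsv", sep="\t", index=False)
    if funnel_rows:
        pd.concat(funnel_rows).to_csv(outdir / "funnel.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"snp": e.snp_id, "stage": e.stage, "reason": e.reason}
         for e in report.selection.removal_log]
    ).to_csv(outdir / "removal_log.tsv", sep="\t", index=False)
    (outdir / "report.json").write_text(report_to_json(report))
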