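"""Align exposure and outcome effects to the same effect allele.

Two GWASs may report the same biallelic SNP with the alleles in either
order and on either strand.  Harmonization rewrites every outcome row
onto the exposure's effect allele:

* same allele pair, same orientation — keep as is;
* same pair, effect/other swapped — negate the outcome beta and
  complement its allele frequency;
* pair matching only under strand complement (non-palindromic) — relabel
  to the exposure strand, then apply the two cases above;
* palindromic pair (A/T or C/G) — allele labels carry no strand
  information, so orientation is inferred from allele frequencies: both
  frequencies must be present, both minor-allele frequencies below the
  ambiguity threshold (default 0.42), and the frequency comparison fixes
  the orientation; otherwise the SNP is dropped;
* anything else — allele mismatch, dropped.

Kept rows carry the per-SNP Wald ratio beta_out/beta_exp with its
first-order standard error se_out/|beta_exp| (exposure uncertainty is
second-order for instruments passing F > 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import SummaryStatRecord

__all__ = [
    "HarmonizedInstrument",
    "AuditEntry",
    "harmonize",
    "wald_ratio",
    "to_arrays",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


@dataclass(slots=True)
class HarmonizedInstrument:
    """One variant with exposure and outcome effects on the same allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None
    eaf_out: float | None
    ratio: float
    ratio_se: float
    action: str  # kept-as-is | flipped | palindromic-inferred


@dataclass(slots=True)
class AuditEntry:
    snp_id: str
    action: str  # kept-as-is | flipped | palindromic-inferred | dropped
    reason: str


def wald_ratio(
    beta_exp: float, se_exp: float, beta_out: float, se_out: float
) -> tuple[float, float]:
    """Per-SNP causal estimate beta_out/beta_exp and its first-order SE.

    Raises ZeroDivisionError upstream concerns: callers must not pass
    beta_exp == 0 (harmonize drops such rows instead).
    """
    if beta_exp == 0:
        raise ValueError("beta_exp must be nonzero for a Wald ratio")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def _check_unique(records: Sequence[SummaryStatRecord], label: str) -> dict[str, SummaryStatRecord]:
    out: dict[str, SummaryStatRecord] = {}
    for r in records:
        if r.snp_id in out:
            raise ValueError(f"duplicate snp_id in {label} table: {r.snp_id}")
        out[r.snp_id] = r
    return out


def harmonize(
    exposure_records: Sequence[SummaryStatRecord],
    outcome_records: Sequence[SummaryStatRecord],
    maf_ambiguity_threshold: float = 0.42,
    palindromic_mode: str = "infer",
) -> tuple[list[HarmonizedInstrument], list[AuditEntry]]:
    """Join on snp_id and align outcome effects to the exposure allele.

    Returns kept instruments and an audit log with one entry per exposure
    row (kept + dropped = joined row count).
    """
    if palindromic_mode not in ("infer", "drop"):
        raise ValueError("palindromic_mode must be 'infer' or 'drop'")
    _check_unique(exposure_records, "exposure")
    out_by_id = _check_unique(outcome_records, "outcome")

    kept: list[HarmonizedInstrument] = []
    audit: list[AuditEntry] = []

    for ex in exposure_records:
        oc = out_by_id.get(ex.snp_id)
        if oc is None:
            audit.append(AuditEntry(ex.snp_id, "dropped", "missing-in-outcome"))
            continue

        e1, o1 = ex.effect_allele, ex.other_allele
        e2, o2 = oc.effect_allele, oc.other_allele
        beta_out, eaf_out = oc.beta, oc.eaf
        action = "kept-as-is"

        if _is_palindromic(e1, o1):
            if palindromic_mode == "drop":
                audit.append(AuditEntry(ex.snp_id, "dropped", "palindromic"))
                continue
            if {e2, o2} != {e1, o1}:
                audit.append(AuditEntry(ex.snp_id, "dropped", "allele-mismatch"))
                continue
            if ex.eaf is None or eaf_out is None:
                audit.append(AuditEntry(ex.snp_id, "dropped", "palindromic-ambiguous"))
                continue
            # align labels first; for a palindromic pair this cannot tell
            # strand, frequency concordance decides below
            if e2 == o1:
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
            maf_e = min(ex.eaf, 1 - ex.eaf)
            maf_o = min(eaf_out, 1 - eaf_out)
            if maf_e >= maf_ambiguity_threshold or maf_o >= maf_ambiguity_threshold:
                audit.append(AuditEntry(ex.snp_id, "dropped", "palindromic-ambiguous"))
                continue
            if (ex.eaf - 0.5) * (eaf_out - 0.5) < 0:
                # frequencies disagree on which allele is minor: the outcome
                # row is on the opposite strand; flip it
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
            action = "palindromic-inferred"
        else:
            if {e2, o2} == {e1, o1}:
                pass
            elif {_COMPLEMENT[e2], _COMPLEMENT[o2]} == {e1, o1}:
                # reported on the opposite strand: relabel (frequencies and
                # effects are strand-invariant for non-palindromic pairs)
                e2, o2 = _COMPLEMENT[e2], _COMPLEMENT[o2]
            else:
                audit.append(AuditEntry(ex.snp_id, "dropped", "allele-mismatch"))
                continue
            if e2 == o1:
                beta_out = -beta_out
                if eaf_out is not None:
                    eaf_out = 1.0 - eaf_out
                action = "flipped"

        if ex.beta == 0:
            audit.append(AuditEntry(ex.snp_id, "dropped", "zero-exposure-effect"))
            continue

        ratio, ratio_se = wald_ratio(ex.beta, ex.se, beta_out, oc.se)
        kept.append(
            HarmonizedInstrument(
                snp_id=ex.snp_id,
                beta_exp=ex.beta, se_exp=ex.se,
                beta_out=beta_out, se_out=oc.se,
                eaf_exp=ex.eaf, eaf_out=eaf_out,
                ratio=ratio, ratio_se=ratio_se,
                action=action,
            )
        )
        audit.append(AuditEntry(ex.snp_id, action, "kept"))

    return kept, audit


def to_arrays(instruments: Sequence[HarmonizedInstrument]) -> dict[str, np.ndarray]:
    """Column arrays (beta_exp, se_exp, beta_out, se_out, snp_ids) for the
    estimators."""
    return {
        "snp_ids": np.array([h.snp_id for h in instruments]),
        "beta_exp": np.array([h.beta_exp for h in instruments]),
        "se_exp": np.array([h.se_exp for h in instruments]),
        "beta_out": np.array([h.beta_out for h in instruments]),
        "se_out": np.array([h.se_out for h in instruments]),
    }
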