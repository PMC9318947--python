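"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the study design the package targets: one large
exposure GWAS (a food-intake trait measured per standard deviation) whose
genome-wide-significant, mutually independent variants instrument a set of
outcome GWASs.  Every nuisance the real pipeline must survive is
configurable — horizontal pleiotropy on a chosen fraction of instruments
(balanced or directional), palindromic A/T and C/G allele pairs, outcome
rows emitted on the opposite allele orientation, and block LD structure —
and the hidden truth (causal effect θ, per-SNP effects γ_j, pleiotropy
α_j) is returned alongside the tables so estimators can be scored against
it.

Model
-----
For variant j with minor-allele frequency p_j ~ Uniform(maf_range), under
standardized traits the per-allele standard errors are

    se_X,j = 1 / sqrt(2 p_j (1 - p_j) n_exposure)     (outcome analogous)

and the observed effects are

    beta_X,j ~ Normal(γ_j, se_X,j²)
    beta_Y,j ~ Normal(θ·γ_j + α_j, se_Y,j²)

with α_j = 0 for valid instruments.  P-values are two-sided normal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .io import LDMatrix, SummaryStatRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SimulatedStudy",
    "generate_two_sample_dataset",
    "generate_study_dataset",
    "generate_ld_matrix",
    "simulate_effect_arrays",
    "write_truth",
]

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

#: gap between LD blocks (bp); larger than the 10,000 kb clumping window so
#: distinct blocks can never conflict by distance alone.
_BLOCK_GAP_BP = 20_000_000
_WITHIN_BLOCK_STEP_BP = 10_000

# smallest positive double: p-values stay in (0, 1] even when z is extreme
_TINY_P = 5e-324


@dataclass
class SyntheticConfig:
    """Generator settings.  Defaults are the emulated study's conditions:

    65 independent instruments from an exposure GWAS of n = 451,486,
    outcome GWASs of n = 218,792, per-SNP exposure effects strong enough
    that every instrument reaches genome-wide significance with F > 10.
    """

    n_variants: int = 65
    n_exposure: int = 451_486
    n_outcome: int = 218_792
    theta: float = 0.0
    maf_range: tuple[float, float] = (0.10, 0.40)
    effect_mean: float = 0.035
    effect_sd: float = 0.003
    invalid_fraction: float = 0.0
    pleiotropy_mode: str = "balanced"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    palindromic_fraction: float = 0.2
    allele_scramble_fraction: float = 0.0
    n_ld_blocks: int | None = None  # None -> one block per variant (no LD)
    within_block_r2_range: tuple[float, float] = (0.1, 0.8)
    ambiguous_palindromes: bool = False  # draw palindromic eaf near 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 2:
            raise ValueError("n_variants must be >= 2")
        for name in ("invalid_fraction", "palindromic_fraction", "allele_scramble_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("maf_range must lie within (0, 0.5)")
        if self.pleiotropy_mode not in ("balanced", "directional"):
            raise ValueError("pleiotropy_mode must be 'balanced' or 'directional'")
        if self.pleiotropy_mode == "balanced":
            self.pleiotropy_mean = 0.0
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not math.isfinite(v):
                raise ValueError(f"non-finite config value: {f.name}")
        if self.n_ld_blocks is not None and not (1 <= self.n_ld_blocks <= self.n_variants):
            raise ValueError("n_ld_blocks must lie in [1, n_variants]")
        rlo, rhi = self.within_block_r2_range
        if not (0 <= rlo <= rhi <= 1):
            raise ValueError("within_block_r2_range must lie within [0, 1]")


@dataclass
class SyntheticTruth:
    """The generator's hidden parameters, for estimator-recovery scoring."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    valid_mask: np.ndarray
    ld_block_id: np.ndarray


class SimulatedStudy(NamedTuple):
    exposure: list[SummaryStatRecord]
    outcome: list[SummaryStatRecord]
    ld: LDMatrix
    truth: SyntheticTruth


def _block_ids(n_variants: int, n_blocks: int) -> np.ndarray:
    ids = np.empty(n_variants, dtype=int)
    for b, idx in enumerate(np.array_split(np.arange(n_variants), n_blocks)):
        ids[idx] = b
    return ids


def simulate_effect_arrays(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    theta: float | None = None,
) -> dict[str, np.ndarray]:
    """Draw the numeric core of one replicate (no allele bookkeeping).

    Returns arrays ``maf, gamma, alpha, valid_mask, se_x, beta_x, se_y,
    beta_y``.  This is the fast path used by Monte-Carlo calibration
    studies; :func:`generate_two_sample_dataset` builds on the same draws.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    th = config.theta if theta is None else theta
    J = config.n_variants
    maf = rng.uniform(*config.maf_range, size=J)
    gamma = rng.normal(config.effect_mean, config.effect_sd, size=J)
    n_invalid = round(config.invalid_fraction * J)
    invalid = rng.permutation(J)[:n_invalid]
    alpha = np.zeros(J)
    alpha[invalid] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_invalid)
    valid_mask = np.ones(J, dtype=bool)
    valid_mask[invalid] = False
    se_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_exposure)
    se_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_outcome)
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(th * gamma + alpha, se_y)
    return {
        "maf": maf,
        "gamma": gamma,
        "alpha": alpha,
        "valid_mask": valid_mask,
        "se_x": se_x,
        "beta_x": beta_x,
        "se_y": se_y,
        "beta_y": beta_y,
    }


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, _TINY_P)


def generate_ld_matrix(
    config: SyntheticConfig,
    positions: Sequence[int],
    rng: np.random.Generator | None = None,
    snp_ids: Sequence[str] | None = None,
) -> LDMatrix:
    """Block-diagonal r² matrix: unit diagonal, within-block off-diagonals
    drawn from ``within_block_r2_range``, zero between blocks."""
    positions = np.asarray(positions)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    J = len(positions)
    n_blocks = config.n_ld_blocks if config.n_ld_blocks is not None else J
    block = _block_ids(J, n_blocks)
    r2 = np.eye(J)
    lo, hi = config.within_block_r2_range
    for i in range(J):
        for k in range(i + 1, J):
            if block[i] == block[k]:
                r2[i, k] = r2[k, i] = rng.uniform(lo, hi)
    ids = list(snp_ids) if snp_ids is not None else [f"snp{j:04d}" for j in range(J)]
    return LDMatrix(ids, r2)


def _draw_alleles(config: SyntheticConfig, rng: np.random.Generator):
    J = config.n_variants
    n_pal = round(config.palindromic_fraction * J)
    pal_idx = set(rng.permutation(J)[:n_pal].tolist())
    ea, oa = [], []
    for j in range(J):
        pool = _PALINDROMIC_PAIRS if j in pal_idx else _NONPALINDROMIC_PAIRS
        e, o = pool[rng.integers(len(pool))]
        ea.append(e)
        oa.append(o)
    return ea, oa, pal_idx


def generate_two_sample_dataset(config: SyntheticConfig) -> SimulatedStudy:
    """Generate one exposure table, one outcome table, an LD matrix and
    the hidden truth.  Bit-identical output for a fixed seed.

    Outcome rows selected by ``allele_scramble_fraction`` (exactly
    ``round(f·J)`` of them) are emitted with effect/other alleles swapped,
    beta negated and eaf complemented; harmonization must undo this.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_variants
    core = simulate_effect_arrays(config, rng)
    ea, oa, pal_idx = _draw_alleles(config, rng)

    maf = core["maf"].copy()
    if config.ambiguous_palindromes and pal_idx:
        idx = sorted(pal_idx)
        maf[idx] = rng.uniform(0.47, 0.4999, size=len(idx))
        # recompute SEs/draws? no: SEs were computed from the original maf;
        # keep the statistical core unchanged and only move the reported
        # frequencies toward 0.5 (what strand ambiguity looks like on disk).
    eaf_exp = maf
    eaf_noise = rng.normal(0.0, np.sqrt(maf * (1 - maf) / (2 * config.n_outcome)))
    eaf_out = np.clip(maf + eaf_noise, 1e-4, 1 - 1e-4)

    n_blocks = config.n_ld_blocks if config.n_ld_blocks is not None else J
    block = _block_ids(J, n_blocks)
    pos = np.empty(J, dtype=int)
    within = np.zeros(J, dtype=int)
    for b in range(n_blocks):
        members = np.where(block == b)[0]
        within[members] = np.arange(len(members))
    pos = 1 + block * _BLOCK_GAP_BP + within * _WITHIN_BLOCK_STEP_BP

    snp_ids = [f"snp{j:04d}" for j in range(J)]
    p_x = _two_sided_p(core["beta_x"], core["se_x"])
    p_y = _two_sided_p(core["beta_y"], core["se_y"])

    # scramble indices drawn unconditionally so the pre-scramble tables are
    # identical across allele_scramble_fraction values at the same seed
    scramble_perm = rng.permutation(J)
    n_scramble = round(config.allele_scramble_fraction * J)
    scrambled = set(scramble_perm[:n_scramble].tolist())

    exposure, outcome = [], []
    for j in range(J):
        exposure.append(
            SummaryStatRecord(
                snp_id=snp_ids[j], chrom="1", pos=int(pos[j]),
                effect_allele=ea[j], other_allele=oa[j],
                eaf=float(eaf_exp[j]), beta=float(core["beta_x"][j]),
                se=float(core["se_x"][j]), pval=float(p_x[j]),
                n=float(config.n_exposure),
            )
        )
        if j in scrambled:
            o_ea, o_oa = oa[j], ea[j]
            o_beta = -float(core["beta_y"][j])
            o_eaf = 1.0 - float(eaf_out[j])
        else:
            o_ea, o_oa = ea[j], oa[j]
            o_beta = float(core["beta_y"][j])
            o_eaf = float(eaf_out[j])
        outcome.append(
            SummaryStatRecord(
                snp_id=snp_ids[j], chrom="1", pos=int(pos[j]),
                effect_allele=o_ea, other_allele=o_oa,
                eaf=o_eaf, beta=o_beta,
                se=float(core["se_y"][j]), pval=float(p_y[j]),
                n=float(config.n_outcome),
            )
        )

    ld = generate_ld_matrix(config, pos, rng, snp_ids)
    truth = SyntheticTruth(
        theta=config.theta,
        gamma=core["gamma"],
        alpha=core["alpha"],
        valid_mask=core["valid_mask"],
        ld_block_id=block,
    )
    return SimulatedStudy(exposure, outcome, ld, truth)


class StudyDataset(NamedTuple):
    exposure: list[SummaryStatRecord]
    outcomes: dict[str, list[SummaryStatRecord]]
    ld: LDMatrix
    truths: dict[str, SyntheticTruth]


def generate_study_dataset(
    config: SyntheticConfig, outcome_thetas: Mapping[str, float]
) -> StudyDataset:
    """One shared exposure GWAS against several outcome GWASs.

    Each outcome reuses the exposure draw (γ_j, α_j, frequencies, alleles)
    with its own causal effect θ and independent outcome sampling noise —
    the multi-outcome design of a summary-data MR study.
    """
    base = generate_two_sample_dataset(config)
    outcomes: dict[str, list[SummaryStatRecord]] = {}
    truths: dict[str, SyntheticTruth] = {}
    for k, (name, th) in enumerate(outcome_thetas.items()):
        sub = replace(config, theta=th, seed=config.seed + 100_003 * (k + 1))
        # redraw only the outcome side: same exposure randomness by reusing
        # the base exposure; regenerate a full dataset and keep its outcome
        ds = _regenerate_outcome(config, sub, base)
        outcomes[name] = ds.outcome
        truths[name] = ds.truth
    return StudyDataset(base.exposure, outcomes, base.ld, truths)


def _regenerate_outcome(
    base_config: SyntheticConfig, sub: SyntheticConfig, base: SimulatedStudy
) -> SimulatedStudy:
    rng = np.random.default_rng(sub.seed)
    J = base_config.n_variants
    truth = base.truth
    maf = np.array([r.eaf for r in base.exposure])
    se_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * base_config.n_outcome)
    beta_y = rng.normal(sub.theta * truth.gamma + truth.alpha, se_y)
    p_y = _two_sided_p(beta_y, se_y)
    eaf_noise = rng.normal(0.0, np.sqrt(maf * (1 - maf) / (2 * base_config.n_outcome)))
    eaf_out = np.clip(maf + eaf_noise, 1e-4, 1 - 1e-4)
    scramble_perm = rng.permutation(J)
    n_scramble = round(base_config.allele_scramble_fraction * J)
    scrambled = set(scramble_perm[:n_scramble].tolist())
    outcome = []
    for j, ex in enumerate(base.exposure):
        if j in scrambled:
            o_ea, o_oa = ex.other_allele, ex.effect_allele
            o_beta, o_eaf = -float(beta_y[j]), 1.0 - float(eaf_out[j])
        else:
            o_ea, o_oa = ex.effect_allele, ex.other_allele
            o_beta, o_eaf = float(beta_y[j]), float(eaf_out[j])
        outcome.append(
            SummaryStatRecord(
                snp_id=ex.snp_id, chrom=ex.chrom, pos=ex.pos,
                effect_allele=o_ea, other_allele=o_oa, eaf=o_eaf,
                beta=o_beta, se=float(se_y[j]), pval=float(p_y[j]),
                n=float(base_config.n_outcome),
            )
        )
    new_truth = SyntheticTruth(
        theta=sub.theta, gamma=truth.gamma, alpha=truth.alpha,
        valid_mask=truth.valid_mask, ld_block_id=truth.ld_block_id,
    )
    return SimulatedStudy(base.exposure, outcome, base.ld, new_truth)


def write_truth(truth: SyntheticTruth, dest) -> None:
    """Sidecar JSON with the generator's hidden parameters."""
    payload = {
        "theta": truth.theta,
        "gamma": truth.gamma.tolist(),
        "alpha": truth.alpha.tolist(),
        "valid_mask": truth.valid_mask.astype(bool).tolist(),
        "ld_block_id": truth.ld_block_id.tolist(),
    }
    text = json.dumps(payload, indent=1, sort_keys=True)
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
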