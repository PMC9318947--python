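"""Harmonization: orientation cases, palindromic frequency inference,
Wald ratios, and the scramble-invariance law."""

import dataclasses

import numpy as np
import pytest

from tsmr.estimators import ivw, mr_egger, weighted_median
from tsmr.harmonize import harmonize, to_arrays, wald_ratio
from tsmr.io import SummaryStatRecord
from tsmr.simulate import SyntheticConfig, generate_two_sample_dataset


def _rec(snp, ea, oa, beta, eaf=0.2, se=0.01, pos=100):
    return SummaryStatRecord(snp, "1", pos, ea, oa, eaf, beta, se, 1e-9, 1e5)


def _one(exposure, outcome, **kw):
    kept, audit = harmonize([exposure], [outcome], **kw)
    return kept, audit


class TestOrientationCases:
    def test_same_orientation_kept_as_is(self):
        kept, audit = _one(_rec("s", "A", "G", 0.1), _rec("s", "A", "G", 0.03))
        assert kept[0].beta_out == 0.03
        assert kept[0].action == "kept-as-is"

    def test_swapped_alleles_negate_outcome_beta(self):
        kept, _ = _one(_rec("s", "A", "G", 0.1), _rec("s", "G", "A", 0.03, eaf=0.8))
        assert kept[0].beta_out == -0.03
        assert kept[0].eaf_out == pytest.approx(0.2)
        assert kept[0].action == "flipped"

    def test_strand_complement_resolved_for_non_palindromic(self):
        # exposure A/G; outcome reported as T/C (same variant, other strand)
        kept, _ = _one(_rec("s", "A", "G", 0.1), _rec("s", "T", "C", 0.03))
        assert kept[0].beta_out == 0.03
        assert kept[0].action == "kept-as-is"

    def test_strand_complement_plus_swap_flips_sign(self):
        kept, _ = _one(_rec("s", "A", "G", 0.1), _rec("s", "C", "T", 0.03, eaf=0.8))
        assert kept[0].beta_out == -0.03
        assert kept[0].action == "flipped"

    def test_incompatible_alleles_dropped(self):
        kept, audit = _one(_rec("s", "A", "G", 0.1), _rec("s", "A", "C", 0.03))
        assert kept == []
        assert audit[0].reason == "allele-mismatch"

    def test_missing_in_outcome_dropped(self):
        kept, audit = harmonize([_rec("s", "A", "G", 0.1)], [])
        assert kept == []
        assert audit[0].reason == "missing-in-outcome"

    def test_zero_exposure_beta_dropped_not_divided(self):
        kept, audit = _one(_rec("s", "A", "G", 0.0), _rec("s", "A", "G", 0.03))
        assert kept == []
        assert audit[0].reason == "zero-exposure-effect"

    def test_duplicate_snp_is_hard_error(self):
        recs = [_rec("s", "A", "G", 0.1), _rec("s", "A", "G", 0.2)]
        with pytest.raises(ValueError, match="duplicate"):
            harmonize(recs, [])


class TestPalindromic:
    def test_concordant_minor_allele_frequencies_inferred(self):
        kept, _ = _one(
            _rec("s", "A", "T", 0.1, eaf=0.10),
            _rec("s", "A", "T", 0.03, eaf=0.12),
        )
        assert kept and kept[0].action == "palindromic-inferred"
        assert kept[0].beta_out == 0.03

    def test_discordant_frequencies_imply_opposite_strand_flip(self):
        kept, _ = _one(
            _rec("s", "C", "G", 0.1, eaf=0.10),
            _rec("s", "C", "G", 0.03, eaf=0.88),
        )
        assert kept and kept[0].action == "palindromic-inferred"
        assert kept[0].beta_out == -0.03

    def test_eaf_half_is_ambiguous(self):
        kept, audit = _one(
            _rec("s", "A", "T", 0.1, eaf=0.10),
            _rec("s", "A", "T", 0.03, eaf=0.50),
        )
        assert kept == []
        assert audit[0].reason == "palindromic-ambiguous"

    def test_maf_above_threshold_is_ambiguous(self):
        kept, audit = _one(
            _rec("s", "A", "T", 0.1, eaf=0.45),
            _rec("s", "A", "T", 0.03, eaf=0.44),
        )
        assert audit[0].reason == "palindromic-ambiguous"

    def test_missing_eaf_is_ambiguous(self):
        kept, audit = _one(
            _rec("s", "A", "T", 0.1, eaf=None),
            _rec("s", "A", "T", 0.03, eaf=0.2),
        )
        assert audit[0].reason == "palindromic-ambiguous"

    def test_drop_mode_drops_all_palindromic(self):
        kept, audit = _one(
            _rec("s", "A", "T", 0.1, eaf=0.10),
            _rec("s", "A", "T", 0.03, eaf=0.12),
            palindromic_mode="drop",
        )
        assert kept == []
        assert audit[0].reason == "palindromic"


class TestWaldRatio:
    def test_arithmetic(self):
        ratio, ratio_se = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert ratio == pytest.approx(0.5)
        assert ratio_se == pytest.approx(0.2)

    def test_zero_outcome_beta(self):
        ratio, ratio_se = wald_ratio(0.1, 0.01, 0.0, 0.02)
        assert ratio == 0.0
        assert ratio_se == pytest.approx(0.2)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)

    def test_first_order_se_close_to_second_order_for_strong_instruments(self, rng):
        """With |beta_exp/se_exp| > 10 the first-order SE is within 5% of
        the second-order delta-method SE sqrt(se_y²/bx² + by²se_x²/bx⁴)."""
        for _ in range(100):
            bx = rng.uniform(0.02, 0.05) * rng.choice([-1, 1])
            sx = abs(bx) / rng.uniform(10.001, 40)
            by = rng.normal(0, abs(bx))  # |ratio| mostly <= ~2
            sy = rng.uniform(0.5, 2) * sx
            first = sy / abs(bx)
            second = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
            if abs(by / bx) * sx / sy <= 0.3:  # regime where 5% is guaranteed
                assert abs(first - second) / second < 0.05


class TestInvarianceLaws:
    def test_double_flip_is_identity(self):
        """Scrambling outcome alleles (swap + negate + complement eaf) and
        harmonizing reproduces the unscrambled harmonized table."""
        exposure = [
            _rec("a", "A", "G", 0.1, eaf=0.2),
            _rec("b", "C", "G", -0.05, eaf=0.1),
            _rec("c", "T", "C", 0.07, eaf=0.3),
        ]
        outcome = [
            _rec("a", "A", "G", 0.02, eaf=0.21),
            _rec("b", "C", "G", 0.01, eaf=0.11),
            _rec("c", "T", "C", -0.03, eaf=0.31),
        ]
        scrambled = [
            dataclasses.replace(
                r,
                effect_allele=r.other_allele,
                other_allele=r.effect_allele,
                beta=-r.beta,
                eaf=1 - r.eaf,
            )
            for r in outcome
        ]
        plain, _ = harmonize(exposure, outcome)
        scr, _ = harmonize(exposure, scrambled)
        assert [h.snp_id for h in plain] == [h.snp_id for h in scr]
        for p, s in zip(plain, scr):
            assert p.beta_out == s.beta_out
            assert p.ratio == s.ratio

    def test_estimates_invariant_under_full_allele_scramble(self):
        """End-to-end: a dataset emitted with 100% of outcome rows on the
        opposite orientation yields identical estimator output."""
        base_cfg = SyntheticConfig(
            n_variants=40, theta=-0.3, palindromic_fraction=0.25, seed=21
        )
        plain = generate_two_sample_dataset(base_cfg)
        scrambled = generate_two_sample_dataset(
            dataclasses.replace(base_cfg, allele_scramble_fraction=1.0)
        )
        h1, _ = harmonize(plain.exposure, plain.outcome)
        h2, _ = harmonize(scrambled.exposure, scrambled.outcome)
        a1, a2 = to_arrays(h1), to_arrays(h2)
        np.testing.assert_array_equal(a1["beta_out"], a2["beta_out"])
        for f in (
            lambda a: ivw(a["beta_exp"], a["beta_out"], a["se_out"]).estimate,
            lambda a: mr_egger(a["beta_exp"], a["beta_out"], a["se_out"])[0].estimate,
            lambda a: weighted_median(
                a["beta_exp"], a["se_exp"], a["beta_out"], a["se_out"], n_boot=200, seed=5
            ).estimate,
        ):
            assert f(a1) == f(a2)

    def test_kept_plus_dropped_equals_join_count(self, small_dataset):
        kept, audit = harmonize(small_dataset.exposure, small_dataset.outcome)
        dropped = [e for e in audit if e.action == "dropped"]
        assert len(kept) + len(dropped) == len(audit) == len(small_dataset.exposure)
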