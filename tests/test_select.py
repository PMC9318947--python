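"""Instrument selection: significance boundary, F arithmetic, greedy
clumping against a naive oracle, and the three-stage composition."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tsmr.io import LDMatrix, SummaryStatRecord
from tsmr.select import (
    EmptySelectionError,
    SelectionConfig,
    clump,
    compute_f_statistic,
    filter_significant,
    select_instruments,
)


def _rec(snp, pval=1e-9, beta=0.03, se=0.003, pos=None, chrom="1"):
    if pos is None:
        pos = 1000 * (abs(hash(snp)) % 1000 + 1)
    return SummaryStatRecord(snp, chrom, pos, "A", "G", 0.2, beta, se, pval, 1e5)


def _ld(records, pairs):
    """Identity LD matrix with r2 set for the given (i, j, r2) pairs."""
    ids = [r.snp_id for r in records]
    m = np.eye(len(ids))
    for i, j, v in pairs:
        m[i, j] = m[j, i] = v
    return LDMatrix(ids, m)


class TestSignificanceFilter:
    def test_strict_inequality_at_genome_wide_threshold(self):
        records = [
            _rec("a", pval=1e-9),
            _rec("b", pval=5e-8),  # boundary: excluded, filter is strict
            _rec("c", pval=1e-7),
        ]
        kept = filter_significant(records, 5e-8)
        assert [r.snp_id for r in kept] == ["a"]

    def test_threshold_one_keeps_everything(self):
        records = [_rec(f"s{i}", pval=p) for i, p in enumerate([0.2, 0.9, 1e-30])]
        assert filter_significant(records, 1.0) == records

    def test_kept_count_matches_brute_force_scan(self, rng):
        pvals = rng.uniform(0, 1, size=100)
        records = [_rec(f"s{i}", pval=p) for i, p in enumerate(pvals)]
        kept = filter_significant(records, 0.3)
        assert len(kept) == int(np.sum(pvals < 0.3))


class TestFStatistic:
    def test_arithmetic(self):
        assert compute_f_statistic(_rec("a", beta=0.02, se=0.005)) == pytest.approx(16.0)
        assert compute_f_statistic(_rec("a", beta=0.0, se=0.005)) == 0.0

    def test_f_threshold_matches_normal_pvalue_threshold(self, rng):
        """F > 10 iff |beta/se| > sqrt(10) iff two-sided normal p < 0.0015654..."""
        p_cut = 2 * stats.norm.sf(np.sqrt(10))
        assert p_cut == pytest.approx(0.001565402, abs=1e-9)
        for _ in range(200):
            beta, se = rng.normal(0, 0.01), rng.uniform(1e-4, 0.01)
            rec = _rec("x", beta=beta, se=se)
            p = 2 * stats.norm.sf(abs(beta / se))
            assert (compute_f_statistic(rec) > 10) == (p < p_cut)


def _naive_clump(records, ld, r2_threshold, window_kb):
    """Independent restatement of the deletion rule: rebuild the conflict
    graph each round, delete the max-degree node (ties: larger p, then
    lexicographically larger ID) until no edges remain."""
    alive = {r.snp_id: r for r in records}
    while True:
        edges = {}
        for a, b in itertools.combinations(alive.values(), 2):
            close = a.chrom == b.chrom and abs(a.pos - b.pos) <= window_kb * 1000
            if close and ld.value(a.snp_id, b.snp_id) > r2_threshold:
                edges.setdefault(a.snp_id, set()).add(b.snp_id)
                edges.setdefault(b.snp_id, set()).add(a.snp_id)
        if not edges:
            return set(alive)
        victim = max(edges, key=lambda s: (len(edges[s]), alive[s].pval, s))
        del alive[victim]


class TestClump:
    def test_identity_ld_retains_everything(self):
        records = [_rec(f"s{i}", pos=1000 + i) for i in range(5)]
        kept, removed = clump(records, _ld(records, []))
        assert kept == records and removed == []

    def test_higher_pvalue_snp_deleted_on_equal_degree(self):
        records = [
            _rec("a", pval=1e-9, pos=1000),
            _rec("b", pval=1e-8, pos=2000),
        ]
        kept, removed = clump(records, _ld(records, [(0, 1, 0.5)]))
        assert [r.snp_id for r in kept] == ["a"]
        assert removed[0].snp_id == "b"

    def test_path_graph_hub_deleted_first_regardless_of_p(self):
        """A-B-C with B correlated to both: B has max degree and is
        removed even though its p-value is the best; A and C survive."""
        records = [
            _rec("A", pval=1e-8, pos=1000),
            _rec("B", pval=1e-20, pos=2000),
            _rec("C", pval=1e-8, pos=3000),
        ]
        kept, removed = clump(records, _ld(records, [(0, 1, 0.9), (1, 2, 0.9)]))
        assert [r.snp_id for r in kept] == ["A", "C"]
        assert removed[0].snp_id == "B"

    def test_window_excludes_distant_pairs_and_is_inclusive_at_boundary(self):
        records = [
            _rec("a", pos=1_000),
            _rec("b", pos=1_000 + 10_000_000),      # exactly window apart
            _rec("c", pos=1_000 + 10_000_001 * 2),  # beyond the window from both
        ]
        ld = _ld(records, [(0, 1, 0.9), (0, 2, 0.9), (1, 2, 0.9)])
        kept, removed = clump(records, ld)
        # only a-b conflict (inclusive boundary); c always retained
        assert "c" in {r.snp_id for r in kept}
        assert len(removed) == 1

    def test_missing_snp_in_ld_is_hard_error(self):
        records = [_rec("a"), _rec("b")]
        ld = LDMatrix(["a"], np.eye(1))
        with pytest.raises(KeyError, match="b"):
            clump(records, ld)

    def test_matches_naive_oracle_on_all_three_node_graphs(self):
        pvals = [1e-10, 1e-9, 1e-8]
        for edge_set in itertools.chain.from_iterable(
            itertools.combinations([(0, 1), (0, 2), (1, 2)], k) for k in range(4)
        ):
            for perm in itertools.permutations(pvals):
                records = [
                    _rec(s, pval=p, pos=1000 * (i + 1))
                    for i, (s, p) in enumerate(zip("abc", perm))
                ]
                ld = _ld(records, [(i, j, 0.9) for i, j in edge_set])
                kept, _ = clump(records, ld)
                assert {r.snp_id for r in kept} == _naive_clump(records, ld, 0.001, 10_000)

    def test_matches_naive_oracle_on_random_20_node_graphs(self, rng):
        for _ in range(50):
            n = 20
            records = [
                _rec(f"s{i:02d}", pval=rng.uniform(), pos=1000 + 1000 * i)
                for i in range(n)
            ]
            m = np.eye(n)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.uniform() < 0.15:
                        m[i, j] = m[j, i] = rng.uniform(0.1, 1.0)
            ld = LDMatrix([r.snp_id for r in records], m)
            kept, _ = clump(records, ld)
            assert {r.snp_id for r in kept} == _naive_clump(records, ld, 0.001, 10_000)

    def test_retained_set_is_conflict_free_and_order_invariant(self, rng):
        n = 15
        records = [
            _rec(f"s{i:02d}", pval=rng.uniform(), pos=1000 * (i + 1)) for i in range(n)
        ]
        m = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.uniform() < 0.3:
                    m[i, j] = m[j, i] = rng.uniform(0.002, 1.0)
        ld = LDMatrix([r.snp_id for r in records], m)
        kept, _ = clump(records, ld)
        for a in kept:
            for b in kept:
                if a.snp_id < b.snp_id:
                    assert ld.value(a.snp_id, b.snp_id) <= 0.001
        shuffled = list(records)
        rng.shuffle(shuffled)
        kept2, _ = clump(shuffled, ld)
        assert {r.snp_id for r in kept} == {r.snp_id for r in kept2}

    def test_relaxing_r2_threshold_never_reduces_retained_count(self, rng):
        n = 12
        records = [_rec(f"s{i:02d}", pval=rng.uniform(), pos=1000 * (i + 1)) for i in range(n)]
        m = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = rng.uniform(0, 1)
        ld = LDMatrix([r.snp_id for r in records], m)
        counts = [
            len(clump(records, ld, r2_threshold=t)[0]) for t in (0.001, 0.1, 0.5, 0.9, 1.0)
        ]
        assert counts == sorted(counts)


class TestSelectInstruments:
    def test_constructed_sixty_five_instrument_gwas_passes_intact(self, default_dataset):
        """A synthetic exposure GWAS built so all 65 variants are
        genome-wide significant, independent and strong must come
        through the three stages with exactly 65 instruments."""
        res = select_instruments(default_dataset.exposure, default_dataset.ld)
        assert len(res.instruments) == 65
        assert res.stage_counts == {
            "input": 65, "significant": 65, "clumped": 65, "strong": 65
        }

    def test_all_weak_instruments_is_a_named_error(self):
        records = [_rec(f"s{i}", beta=0.001, se=0.01, pval=1e-9, pos=1000 * (i + 1)) for i in range(3)]
        ld = _ld(records, [])
        with pytest.raises(EmptySelectionError, match="F filter"):
            select_instruments(records, ld)

    def test_nothing_significant_is_a_named_error(self):
        records = [_rec(f"s{i}", pval=0.5, pos=1000 * (i + 1)) for i in range(3)]
        with pytest.raises(EmptySelectionError, match="significance"):
            select_instruments(records, _ld(records, []))

    def test_stage_counts_form_a_bookkeeping_identity(self, rng):
        records = []
        for i in range(40):
            records.append(
                _rec(
                    f"s{i:02d}",
                    pval=10.0 ** rng.uniform(-12, -4),
                    beta=rng.uniform(0.001, 0.05),
                    se=0.003,
                    pos=1000 + 1000 * i,
                )
            )
        m = np.eye(40)
        for i in range(40):
            for j in range(i + 1, 40):
                if rng.uniform() < 0.1:
                    m[i, j] = m[j, i] = rng.uniform(0.002, 1)
        ld = LDMatrix([r.snp_id for r in records], m)
        res = select_instruments(records, ld)
        by_stage = {"significance": 0, "clump": 0, "f-statistic": 0}
        for entry in res.removal_log:
            by_stage[entry.stage] += 1
        assert len(records) - sum(by_stage.values()) == len(res.instruments)
        assert res.stage_counts["significant"] == len(records) - by_stage["significance"]


def test_selection_config_validation():
    with pytest.raises(ValueError):
        SelectionConfig(r2_threshold=0.0)
    with pytest.raises(ValueError):
        SelectionConfig(p_threshold=-1)
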