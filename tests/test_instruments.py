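"""Instrument selection: p filter, greedy LD clumping, F and R² grading."""

import numpy as np
import pytest
from scipy import stats

from mrmediate.instruments import (
    LDMatrix,
    f_statistic,
    filter_by_f,
    filter_by_pvalue,
    ld_clump,
    read_ld_matrix,
    total_variance_explained,
    write_ld_matrix,
)
from mrmediate.sumstats import SumStatsError

from conftest import make_record, make_set


def _set_with_pvals(pvals):
    return make_set(
        [make_record(f"rs{i}", beta=0.1, se=0.01, pval=p) for i, p in enumerate(pvals)]
    )


class TestPvalueFilter:
    def test_strict_inequality_at_threshold(self):
        s = _set_with_pvals([1e-9, 1e-7, 4.9e-8, 5e-8])
        out = filter_by_pvalue(s, 5e-8)
        assert [r.pval for r in out] == [1e-9, 4.9e-8]

    def test_threshold_one_keeps_all(self):
        s = _set_with_pvals([0.2, 0.9, 1.0])
        assert len(filter_by_pvalue(s, 1.0)) == 3

    def test_matches_brute_force_on_random_pvals(self, rng):
        pvals = rng.uniform(0, 1, 1000)
        pvals[pvals == 0] = 0.5
        s = _set_with_pvals(pvals)
        out = filter_by_pvalue(s, 0.05)
        assert len(out) == int(np.sum(pvals < 0.05))

    def test_idempotent(self):
        s = _set_with_pvals([1e-9, 0.2, 0.04])
        once = filter_by_pvalue(s, 0.05)
        twice = filter_by_pvalue(once, 0.05)
        assert once.snp_ids() == twice.snp_ids()


class TestLDClump:
    def test_independent_snps_all_retained(self):
        s = _set_with_pvals([1e-9, 1e-8, 1e-7])
        ld = LDMatrix.identity(s.snp_ids())
        assert len(ld_clump(s, ld, 0.001, 10000)) == 3

    def test_correlated_pair_keeps_best_p(self):
        s = make_set([
            make_record("rsA", pval=1e-10),
            make_record("rsB", pval=1e-9),
        ])
        r2 = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = ld_clump(s, LDMatrix(["rsA", "rsB"], r2), 0.001, 10000)
        assert out.snp_ids() == ["rsA"]

    def test_missing_snp_is_fatal(self):
        s = _set_with_pvals([1e-9])
        ld = LDMatrix.identity(["other"])
        with pytest.raises(SumStatsError, match="rs0"):
            ld_clump(s, ld, 0.001, 10000)

    def test_distance_window_limits_discards(self):
        # r2 above threshold but SNPs 20 Mb apart: both kept at 10 Mb window
        s = make_set([make_record("rsA", pval=1e-10), make_record("rsB", pval=1e-9)])
        r2 = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = LDMatrix(["rsA", "rsB"], r2, positions={"rsA": 1e6, "rsB": 21e6})
        assert len(ld_clump(s, ld, 0.001, 10000)) == 2
        ld_near = LDMatrix(["rsA", "rsB"], r2, positions={"rsA": 1e6, "rsB": 2e6})
        assert ld_clump(s, ld_near, 0.001, 10000).snp_ids() == ["rsA"]

    def test_block_structure_against_pairwise_oracle(self, rng):
        # 20 SNPs in 4 blocks of 5 with high within-block r2
        j, bs = 20, 5
        ids = [f"rs{i:02d}" for i in range(j)]
        r2 = np.eye(j)
        for s0 in range(0, j, bs):
            r2[s0:s0 + bs, s0:s0 + bs] = 0.6
        np.fill_diagonal(r2, 1.0)
        pvals = rng.uniform(1e-12, 1e-6, j)
        s = make_set([make_record(ids[i], pval=pvals[i]) for i in range(j)])
        kept = ld_clump(s, LDMatrix(ids, r2), 0.001, 10000)
        kept_ids = set(kept.snp_ids())
        idx = {sid: i for i, sid in enumerate(ids)}
        # every retained pair independent
        for a in kept_ids:
            for b in kept_ids:
                if a != b:
                    assert r2[idx[a], idx[b]] < 0.001
        # every discarded SNP conflicts with a retained SNP of better p
        pv = {ids[i]: pvals[i] for i in range(j)}
        for sid in set(ids) - kept_ids:
            assert any(
                r2[idx[sid], idx[k]] >= 0.001 and (pv[k], k) < (pv[sid], sid)
                for k in kept_ids
            )

    def test_invariant_to_input_order(self, rng):
        ids = [f"rs{i}" for i in range(10)]
        r2 = np.eye(10)
        r2[0, 1] = r2[1, 0] = 0.9
        r2[3, 7] = r2[7, 3] = 0.9
        pvals = rng.uniform(1e-10, 1e-7, 10)
        recs = [make_record(ids[i], pval=pvals[i]) for i in range(10)]
        ld = LDMatrix(ids, r2)
        a = ld_clump(make_set(recs), ld, 0.001, 10000)
        perm = [recs[i] for i in rng.permutation(10)]
        b = ld_clump(make_set(perm), ld, 0.001, 10000)
        assert a.snp_ids() == b.snp_ids()


class TestStrength:
    def test_f_statistic_direct(self):
        assert f_statistic(0.05, 0.01) == pytest.approx(25.0)
        assert f_statistic(0.0, 0.3) == 0.0

    def test_f_equals_z_squared(self, rng):
        for _ in range(50):
            beta = rng.normal(0, 0.1)
            se = rng.uniform(0.001, 0.05)
            assert f_statistic(beta, se) == pytest.approx((beta / se) ** 2, rel=1e-12)

    def test_f_requires_positive_se(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)

    def test_filter_by_f_boundary(self):
        weak = make_record("rsW", beta=0.03, se=0.01)   # F = 9
        strong = make_record("rsS", beta=0.05, se=0.01)  # F = 25
        out = filter_by_f(make_set([weak, strong]), 10.0)
        assert out.snp_ids() == ["rsS"]

    def test_filter_by_f_matches_brute_force(self, rng):
        recs = [
            make_record(f"rs{i}", beta=rng.normal(0, 0.05), se=rng.uniform(0.005, 0.02))
            for i in range(100)
        ]
        out = filter_by_f(make_set(recs), 10.0)
        expected = [r.snp_id for r in recs if (r.beta / r.se) ** 2 > 10.0]
        assert out.snp_ids() == expected


class TestVarianceExplained:
    def test_single_snp(self):
        s = make_set([make_record("rs1", beta=0.1, eaf=0.5)])
        assert total_variance_explained(s) == pytest.approx(0.005)

    def test_empty_set_is_zero(self):
        assert total_variance_explained(make_set([])) == 0.0

    def test_additive_and_permutation_invariant(self, rng):
        recs = [
            make_record(f"rs{i}", beta=rng.normal(0, 0.1), eaf=rng.uniform(0.01, 0.5))
            for i in range(20)
        ]
        total = total_variance_explained(make_set(recs))
        half = total_variance_explained(make_set(recs[:10])) + total_variance_explained(
            make_set(recs[10:])
        )
        assert total == pytest.approx(half, rel=1e-12)
        perm = [recs[i] for i in rng.permutation(20)]
        assert total_variance_explained(make_set(perm)) == pytest.approx(total, rel=1e-12)

    def test_missing_eaf_fatal(self):
        rec = make_record("rs1", eaf=None)
        with pytest.raises(SumStatsError, match="rs1"):
            total_variance_explained(make_set([rec]))


class TestLDMatrixIO:
    def test_square_roundtrip(self, tmp_path):
        ids = ["rs1", "rs2", "rs3"]
        r2 = np.array([[1, 0.2, 0], [0.2, 1, 0.1], [0, 0.1, 1]], float)
        ld = LDMatrix(ids, r2)
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, path)
        back = read_ld_matrix(path)
        assert back.snp_ids == ids
        assert np.allclose(back.r2, r2)

    def test_long_format(self, tmp_path):
        path = tmp_path / "long.tsv"
        path.write_text("snp_a\tsnp_b\tr2\nrs1\trs2\t0.4\n")
        ld = read_ld_matrix(path)
        assert ld.lookup("rs1", "rs2") == pytest.approx(0.4)
        assert ld.lookup("rs1", "rs1") == 1.0

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 0.9]]))  # diag != 1


def test_pvalue_z_consistency_of_generated_stats():
    """Generated p-values equal the two-sided normal p of beta/se."""
    from mrmediate.simulate import SimConfig, simulate_sumstats

    exp, med, out, _, _ = simulate_sumstats(SimConfig(seed=3, n_snps=50, n_med_snps=10))
    for sset in (exp, med, out):
        for r in sset.records:
            assert r.pval == pytest.approx(2 * stats.norm.sf(abs(r.beta / r.se)), abs=1e-10)
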