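"""Positional bound-vs-unbound statistics and preference calls."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from motifenv.envstats import (
    call_preference,
    compare_position,
    delta_profile,
    delta_profile_from_matrices,
    fdr_qvalues,
    position_feature_matrix,
)
from motifenv.pfm import Background
from motifenv.scan import align_best_hit, match_sizes
from motifenv.simulate import SyntheticConfig, generate_pools, random_pfm


def make_pools(seed, n, gc_bound, gc_unbound, pfm=None, probe_len=20, **kw):
    pfm = pfm or random_pfm(seed=11)
    bg = Background.uniform()
    cfg = SyntheticConfig(
        seed=seed, n_bound=n, n_unbound=n, probe_len=probe_len, motif=pfm,
        flank_gc_bound=gc_bound, flank_gc_unbound=gc_unbound, **kw,
    )
    b, u, _ = generate_pools(cfg)
    pb, _ = align_best_hit(b, pfm, bg, strands="both", flank_up=10,
                           flank_down=10, min_pool_size=1, pad_incomplete=True)
    pu, _ = align_best_hit(u, pfm, bg, strands="both", flank_up=10,
                           flank_down=10, min_pool_size=1, pad_incomplete=True)
    return match_sizes(pb, pu, seed)


class TestFeatureMatrix:
    def test_column_means_match_counting_oracle(self, sharp_pfm):
        pb, _ = make_pools(2, 300, 0.55, 0.45, pfm=sharp_pfm)
        mat, positions = position_feature_matrix(pb, "GC")
        cols, _ = pb.flank_columns()
        for j, c in enumerate(cols):
            column = pb.codes[:, c]
            defined = column < 4
            expected = np.mean(np.isin(column[defined], [1, 2]))
            assert np.nanmean(mat[:, j]) == pytest.approx(expected)

    def test_base_features_sum_to_one(self, sharp_pfm):
        pb, _ = make_pools(3, 100, 0.5, 0.5, pfm=sharp_pfm)
        mats = [position_feature_matrix(pb, f)[0] for f in "ACGT"]
        total = np.nansum(mats, axis=0)
        defined = ~np.isnan(mats[0])
        assert np.all(total[defined] == 1.0)

    def test_core_and_exclusion_positions_absent(self, sharp_pfm):
        pb, _ = make_pools(4, 50, 0.5, 0.5, pfm=sharp_pfm)
        _, positions = position_feature_matrix(pb, "GC")
        assert np.all(np.abs(positions) >= pb.core_exclusion + 1)


class TestComparePosition:
    def test_identical_columns_no_signal(self):
        col = np.array([1.0, 0.0] * 8)
        pg, pl = compare_position(col, col.copy())
        assert pg >= 0.5 and pl >= 0.5

    def test_rank_sum_equals_permutation_enumeration(self):
        b = np.array([1.0] * 8 + [0.0] * 2)
        u = np.array([1.0] * 2 + [0.0] * 8)
        pg, pl = compare_position(b, u, test="rank_sum")
        pooled = np.concatenate([b, u])
        ranks = sstats.rankdata(pooled)
        obs = ranks[:10].sum()
        stats_all = [
            ranks[list(c)].sum() for c in combinations(range(20), 10)
        ]
        expected_g = np.mean([s >= obs - 1e-9 for s in stats_all])
        expected_l = np.mean([s <= obs + 1e-9 for s in stats_all])
        assert pg == pytest.approx(expected_g)
        assert pl == pytest.approx(expected_l)

    def test_swapping_columns_swaps_sides(self):
        rng = np.random.default_rng(0)
        b, u = rng.random(40), rng.random(40) + 0.2
        pg, pl = compare_position(b, u)
        pg2, pl2 = compare_position(u, b)
        assert pg == pytest.approx(pl2) and pl == pytest.approx(pg2)

    def test_signed_rank_requires_equal_sizes(self):
        with pytest.raises(ValueError):
            compare_position(np.ones(5), np.zeros(4), test="signed_rank")

    def test_all_tied_gives_one(self):
        pg, pl = compare_position(np.ones(30), np.ones(30))
        assert pg == 1.0 and pl == 1.0
        pg, pl = compare_position(np.ones(30), np.ones(30), test="signed_rank")
        assert pg == 1.0 and pl == 1.0

    def test_empty_columns_error(self):
        with pytest.raises(ValueError):
            compare_position(np.array([]), np.ones(3))


class TestFdr:
    def test_all_ones(self):
        np.testing.assert_allclose(fdr_qvalues(np.ones(6), "BH"), 1.0)
        np.testing.assert_allclose(fdr_qvalues(np.ones(6), "storey"), 1.0)

    def test_bh_step_up_hand_example(self):
        q = fdr_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), "BH")
        np.testing.assert_allclose(q, 0.04)

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(0, 0.01, 20), rng.uniform(0, 1, 80)])
        assert np.all(fdr_qvalues(p, "storey") <= fdr_qvalues(p, "BH") + 1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1, 30)
        perm = rng.permutation(30)
        q = fdr_qvalues(p, "storey")
        q_perm = fdr_qvalues(p[perm], "storey")
        np.testing.assert_allclose(q_perm, q[perm])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_qvalues(np.array([0.0, 0.5]))
        assert fdr_qvalues(np.array([])).size == 0


class TestDeltaProfile:
    def test_planted_gc_shift_all_positive(self, sharp_pfm):
        pb, pu = make_pools(7, 2000, 0.60, 0.50, pfm=sharp_pfm)
        stats = delta_profile(pb, pu, "GC")
        assert np.all(stats["delta"] > 0)

    def test_label_exchange_negates_delta(self, sharp_pfm):
        pb, pu = make_pools(8, 400, 0.56, 0.50, pfm=sharp_pfm)
        fwd = delta_profile(pb, pu, "GC")
        rev = delta_profile(pu, pb, "GC")
        np.testing.assert_allclose(rev["delta"], -fwd["delta"], atol=1e-9)

    def test_frame_mismatch_rejected(self, sharp_pfm):
        pb, pu = make_pools(9, 50, 0.5, 0.5, pfm=sharp_pfm)
        mat_b, pos = position_feature_matrix(pb, "GC")
        with pytest.raises(ValueError):
            delta_profile_from_matrices(mat_b, mat_b[:, :-1], pos, "GC")

    def test_rank_invariance_to_positive_scaling(self):
        rng = np.random.default_rng(3)
        mat_b = rng.random((60, 6))
        mat_u = rng.random((60, 6)) * 0.8
        pos = np.arange(3, 9)
        s1 = delta_profile_from_matrices(mat_b, mat_u, pos, "x")
        s2 = delta_profile_from_matrices(5.0 * mat_b, 5.0 * mat_u, pos, "x")
        np.testing.assert_allclose(s1["p_greater"], s2["p_greater"])
        np.testing.assert_allclose(s1["delta"], s2["delta"])

    def test_null_positions_rarely_significant(self, sharp_pfm):
        hits = 0
        total = 0
        for rep in range(10):
            pb, pu = make_pools(100 + rep, 400, 0.5, 0.5, pfm=sharp_pfm)
            stats = delta_profile(pb, pu, "GC")
            hits += int(np.sum((stats["q_greater"] <= 0.05) | (stats["q_less"] <= 0.05)))
            total += len(stats)
        assert hits / total <= 0.05


class TestCallPreference:
    def _stats(self, n_sig_hi, n_sig_lo, n_total=16):
        qg = np.ones(n_total)
        ql = np.ones(n_total)
        qg[:n_sig_hi] = 0.01
        ql[n_total - n_sig_lo:] = 0.01
        mean_b = np.where(qg < 1, 0.6, 0.5)
        mean_b = np.where(ql < 1, 0.4, mean_b)
        return pd.DataFrame(
            {
                "position": np.arange(n_total),
                "mean_bound": mean_b,
                "mean_unbound": 0.5,
                "q_greater": qg,
                "q_less": ql,
            }
        )

    def test_threshold_boundary(self):
        assert call_preference(self._stats(4, 0)).call == "none"
        assert call_preference(self._stats(5, 0)).call == "high-GC"
        assert call_preference(self._stats(0, 5)).call == "high-AT"

    def test_planted_at_preference_called(self, sharp_pfm):
        pb, pu = make_pools(12, 2000, 0.47, 0.53, pfm=sharp_pfm)
        stats = delta_profile(pb, pu, "GC")
        call = call_preference(stats)
        assert call.call == "high-AT"
        assert call.mean_delta_gc < 0
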