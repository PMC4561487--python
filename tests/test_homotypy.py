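"""Homotypic cluster counting, environment similarity, masking controls."""

import numpy as np
import pytest

from motifenv import seqcodec
from motifenv.homotypy import (
    cluster_sum_scores,
    count_clusters,
    drop_motif_sequences,
    env_scores,
    mask_motif_matches,
    offcore_window_starts,
)
from motifenv.pfm import PFM, Background, Scorer
from motifenv.scan import AlignedPool


def pool_from_sequences(seqs, core_start, core_len, label="bound"):
    codes = np.vstack([seqcodec.encode(s) for s in seqs])
    flank_up = core_start
    flank_down = codes.shape[1] - core_start - core_len
    return AlignedPool(
        label=label, codes=codes, seq_ids=[f"s{i}" for i in range(len(seqs))],
        core_start=core_start, core_len=core_len,
        flank_up=flank_up, flank_down=flank_down,
    )


@pytest.fixture(scope="module")
def bg():
    return Background.uniform()


class TestCountClusters:
    def test_two_planted_consensus_copies(self, sharp_pfm, bg):
        cons = sharp_pfm.consensus()
        seq = cons + "AT" + cons + "GC" + cons  # core in the middle
        pool = pool_from_sequences([seq], core_start=10, core_len=8)
        counts = count_clusters(pool, sharp_pfm, bg)
        assert counts.iloc[0, 0] == 2

    def test_hit_straddling_core_excluded(self, sharp_pfm, bg):
        cons = sharp_pfm.consensus()
        # consensus copy shifted to overlap the core block by one bp
        seq = "A" * 3 + cons + cons[:-1] + "G" * 8
        pool = pool_from_sequences([seq], core_start=3 + 7, core_len=8)
        starts = offcore_window_starts(pool, 8)
        assert all(s + 8 <= 10 or s >= 18 for s in starts)

    def test_bins_partition_hits(self, sharp_pfm, bg):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(40)]
        pool = pool_from_sequences(seqs, core_start=26, core_len=8)
        counts = count_clusters(pool, sharp_pfm, bg, bins=(0.001, 0.05, 0.1))
        scorer = Scorer(sharp_pfm, bg)
        starts = offcore_window_starts(pool, 8)
        for i in range(pool.n):
            total_le_01 = 0
            for strand in "+-":
                sc = scorer.window_int_scores(pool.codes[i][None, :], strand)[0][starts]
                p = scorer.pvalue(sc)
                total_le_01 += int(np.sum(p <= 0.1))
            assert counts.iloc[i].sum() == total_le_01

    def test_background_rate_of_significant_hits(self, sharp_pfm, bg):
        # random flanks: expected count in the <=0.001 bin is ~ 2*W*0.001
        rng = np.random.default_rng(6)
        n = 4000
        seqs = ["".join(rng.choice(list("ACGT"), 44)) for _ in range(n)]
        pool = pool_from_sequences(seqs, core_start=18, core_len=8)
        counts = count_clusters(pool, sharp_pfm, bg)
        W = offcore_window_starts(pool, 8).size
        observed = counts.iloc[:, 0].mean()
        # per-window tail probability is <= 0.001 but not exactly 0.001
        scorer = Scorer(sharp_pfm, bg)
        cut = scorer.int_cutoff(0.001)
        p_true = scorer.pvalue(np.array([cut]))[0]
        expected = 2 * W * p_true
        se = np.sqrt(expected / n)
        assert abs(observed - expected) <= 3 * se + 1e-9


class TestEnvScores:
    def test_uniform_pfm_scores_zero(self, bg):
        uni = PFM("u", np.full((4, 4), 0.25))
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(10)]
        pool = pool_from_sequences(seqs, core_start=13, core_len=4)
        np.testing.assert_allclose(env_scores(pool, uni, bg), 0.0, atol=1e-9)

    def test_window_set_matches_enumeration_oracle(self, sharp_pfm, bg):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), 50))
        pool = pool_from_sequences([seq], core_start=21, core_len=8)
        scorer = Scorer(sharp_pfm, bg)
        L = 8
        expected_windows = []
        for s in range(pool.frame_len - L + 1):
            if s + L <= pool.core_start or s >= pool.core_end:
                window = seqcodec.encode(seq)[s : s + L]
                f = scorer.score_kmer(window)
                r = scorer.score_kmer(seqcodec.revcomp_codes(window))
                expected_windows.append(max(f, r))
        got = env_scores(pool, sharp_pfm, bg, strands="both")[0]
        assert got == pytest.approx(np.mean(expected_windows), abs=1e-9)

    def test_revcomp_invariance_both_strands(self, sharp_pfm, bg):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 40))
        # a symmetric frame so the flipped record keeps the core centred
        pool = pool_from_sequences([seq], core_start=16, core_len=8)
        flipped = pool_from_sequences(
            [seqcodec.revcomp(seq)], core_start=16, core_len=8
        )
        s1 = env_scores(pool, sharp_pfm, bg, strands="both")[0]
        s2 = env_scores(flipped, sharp_pfm, bg, strands="both")[0]
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_homotypic_flanks_score_higher_than_random(self, sharp_pfm, bg):
        from scipy.stats import mannwhitneyu

        # the contrast needs a motif whose average composition deviates
        # from the background (a compositionally balanced motif has a
        # near-uniform column average, so iid draws from it carry no signal)
        from motifenv.simulate import random_pfm

        pfm = random_pfm(length=8, ic_per_column=1.5, gc_target=0.75, seed=21)
        rng = np.random.default_rng(10)
        avg = pfm.column_average().probs
        bases = np.array(list("ACGT"))
        homo = ["".join(rng.choice(bases, 40, p=avg)) for _ in range(300)]
        rand = ["".join(rng.choice(bases, 40)) for _ in range(300)]
        ph = pool_from_sequences(homo, core_start=16, core_len=8)
        pr = pool_from_sequences(rand, core_start=16, core_len=8)
        sh = env_scores(ph, pfm, bg)
        sr = env_scores(pr, pfm, bg)
        p = mannwhitneyu(sh, sr, alternative="greater").pvalue
        assert p < 1e-6

    def test_no_eligible_window_gives_nan(self, sharp_pfm, bg):
        seq = "AT" + sharp_pfm.consensus() + "GC"
        pool = pool_from_sequences([seq], core_start=2, core_len=8)
        assert np.isnan(env_scores(pool, sharp_pfm, bg)[0])


class TestMasking:
    def _planted_pool(self, sharp_pfm):
        cons = sharp_pfm.consensus()
        rng = np.random.default_rng(11)
        seqs = []
        for _ in range(20):
            flank1 = "".join(rng.choice(list("ACGT"), 12))
            flank2 = "".join(rng.choice(list("ACGT"), 4))
            seqs.append(flank1[:2] + cons + flank1[2:] + cons + flank2)
        # layout: 2 + 8(planted) + 10 + 8(core at 20? ) -- core is second copy
        return pool_from_sequences(seqs, core_start=20, core_len=8), cons

    def test_impossible_cutoff_masks_nothing(self, sharp_pfm, bg):
        pool, _ = self._planted_pool(sharp_pfm)
        masked = mask_motif_matches(pool, sharp_pfm, bg, p_cutoff=0.0)
        assert masked.mask.sum() == 0

    def test_masked_positions_cover_planted_copies(self, sharp_pfm, bg):
        pool, cons = self._planted_pool(sharp_pfm)
        masked = mask_motif_matches(pool, sharp_pfm, bg, p_cutoff=1e-4)
        assert np.all(masked.mask[:, 2:10])

    def test_looser_cutoff_masks_superset(self, sharp_pfm, bg):
        pool, _ = self._planted_pool(sharp_pfm)
        strict = mask_motif_matches(pool, sharp_pfm, bg, p_cutoff=1e-4)
        loose = mask_motif_matches(pool, sharp_pfm, bg, p_cutoff=0.05)
        assert np.all(loose.mask[strict.mask])

    def test_gc_difference_retained_after_masking(self, sharp_pfm, bg):
        # pools differing only in GC (no planted motifs): masking
        # motif-like windows must not remove the composition difference
        from motifenv.envstats import delta_profile
        from motifenv.scan import align_best_hit, match_sizes
        from motifenv.simulate import SyntheticConfig, generate_pools

        cfg = SyntheticConfig(
            seed=13, n_bound=1500, n_unbound=1500, probe_len=30,
            motif=sharp_pfm, flank_gc_bound=0.58, flank_gc_unbound=0.50,
        )
        b, u, _ = generate_pools(cfg)
        pb, _ = align_best_hit(b, sharp_pfm, bg, strands="both", flank_up=10,
                               flank_down=10, min_pool_size=1, pad_incomplete=True)
        pu, _ = align_best_hit(u, sharp_pfm, bg, strands="both", flank_up=10,
                               flank_down=10, min_pool_size=1, pad_incomplete=True)
        pb, pu = match_sizes(pb, pu, 13)
        before = delta_profile(pb, pu, "GC")
        mb = mask_motif_matches(pb, sharp_pfm, bg, p_cutoff=0.01)
        mu = mask_motif_matches(pu, sharp_pfm, bg, p_cutoff=0.01)
        after = delta_profile(mb, mu, "GC")
        gap_before = np.mean(before["mean_bound"] - before["mean_unbound"])
        gap_after = np.mean(after["mean_bound"] - after["mean_unbound"])
        assert gap_after == pytest.approx(gap_before, abs=0.02)
        assert np.sum(after["q_greater"] <= 0.05) >= 5

    def test_drop_sequences_filter(self, sharp_pfm, bg):
        pool, _ = self._planted_pool(sharp_pfm)
        kept, report = drop_motif_sequences(pool, sharp_pfm, bg, p_cutoff=1e-4)
        assert report["kept"] == 0 and report["dropped"] == pool.n
        rng = np.random.default_rng(12)
        clean = pool_from_sequences(
            ["".join(rng.choice(list("ACGT"), 36)) for _ in range(10)],
            core_start=14, core_len=8,
        )
        kept2, report2 = drop_motif_sequences(clean, sharp_pfm, bg, p_cutoff=1e-6)
        assert report2["dropped"] == 0 and kept2.n == clean.n


class TestClusterSum:
    def test_planted_copies_sum_matches_scan(self, sharp_pfm, bg):
        cons = sharp_pfm.consensus()
        seq = cons + "AT" + cons + "GC" + cons
        pool = pool_from_sequences([seq], core_start=10, core_len=8)
        scorer = Scorer(sharp_pfm, bg)
        got = cluster_sum_scores(pool, sharp_pfm, bg, p_cutoff=0.001)[0]
        starts = offcore_window_starts(pool, 8)
        expected = 0.0
        for st in "+-":
            sc = scorer.window_int_scores(pool.codes, strand=st)[0][starts]
            p = scorer.pvalue(sc)
            expected += scorer.to_bits(sc[p <= 0.001]).sum()
        assert got == pytest.approx(expected)
        assert got > 0

    def test_uniform_pfm_gives_zero(self, bg):
        uni = PFM("u", np.full((4, 4), 0.25))
        pool = pool_from_sequences(["ACGTACGTACGTACGTACGT"], core_start=8, core_len=4)
        assert cluster_sum_scores(pool, uni, bg)[0] == 0.0
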