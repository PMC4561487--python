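"""Block-HMM likelihoods, strand bias, and LLR-based discrimination."""

from itertools import product

import numpy as np
import pytest

from motifenv import seqcodec
from motifenv.hmm import (
    HMMSpec,
    background_for_mode,
    estimate_strand_bias,
    hmm_auroc,
    inversed_background,
    llr,
    sequence_loglik,
)
from motifenv.pfm import PFM, Background
from motifenv.simulate import SyntheticConfig, generate_pools, random_pfm

from oracles import hmm_brute_force


@pytest.fixture(scope="module")
def pfm2():
    rng = np.random.default_rng(51)
    return PFM("L2", rng.dirichlet(np.ones(4), size=2))


@pytest.fixture(scope="module")
def beta():
    return Background(np.array([0.3, 0.2, 0.2, 0.3]))


class TestLoglik:
    def test_exhaustive_tiling_oracle(self, pfm2, beta):
        rng = np.random.default_rng(52)
        spec = HMMSpec(pfm=pfm2, beta=beta, t_bg=0.99, strand_bias=0.7)
        for n in range(1, 9):
            for _ in range(5):
                codes = rng.integers(0, 4, size=n).astype(np.uint8)
                expected = hmm_brute_force(pfm2.freq, beta.probs, 0.99, 0.7, codes)
                got = sequence_loglik(spec, codes)
                assert got == pytest.approx(np.log(expected), rel=1e-9)

    def test_sequence_shorter_than_motif(self, beta):
        pfm = PFM("L5", np.full((5, 4), 0.25))
        spec = HMMSpec(pfm=pfm, beta=beta, t_bg=0.99, strand_bias=0.5)
        codes = seqcodec.encode("ACG")
        expected = 3 * np.log(0.99) + np.log(beta.probs[[0, 1, 2]]).sum()
        assert sequence_loglik(spec, codes) == pytest.approx(expected)

    def test_empty_sequence(self, pfm2, beta):
        spec = HMMSpec(pfm=pfm2, beta=beta)
        assert sequence_loglik(spec, "") == 0.0

    def test_n_rejected(self, pfm2, beta):
        spec = HMMSpec(pfm=pfm2, beta=beta)
        with pytest.raises(ValueError):
            sequence_loglik(spec, "ACNG")

    def test_total_probability_mass_bounded(self, pfm2, beta):
        spec = HMMSpec(pfm=pfm2, beta=beta, t_bg=0.99, strand_bias=0.5)
        for n in (1, 3, 6):
            total = 0.0
            for tup in product(range(4), repeat=n):
                total += np.exp(
                    sequence_loglik(spec, np.array(tup, dtype=np.uint8))
                )
            assert total <= 1.0 + 1e-9

    def test_revcomp_invariance_with_symmetric_parameters(self, pfm2):
        sym_beta = Background.uniform()
        spec = HMMSpec(pfm=pfm2, beta=sym_beta, t_bg=0.99, strand_bias=0.5)
        rng = np.random.default_rng(53)
        for _ in range(10):
            codes = rng.integers(0, 4, size=12).astype(np.uint8)
            a = sequence_loglik(spec, codes)
            b = sequence_loglik(spec, seqcodec.revcomp_codes(codes))
            assert a == pytest.approx(b, rel=1e-12)


class TestLlr:
    def test_background_only_algebra(self, beta):
        # motif longer than the sequence: only the background parse exists
        pfm = PFM("L9", np.full((9, 4), 0.25))
        spec = HMMSpec(pfm=pfm, beta=beta, mode="genomic")
        seq = "ACGTAC"
        got = llr(spec, seq, genomic_beta=beta)
        assert got == pytest.approx(6 * np.log(0.99))
        assert got <= 0

    def test_additive_over_junction_free_concatenation(self):
        # hard-zero PFM: blocks have zero probability except on the consensus
        freq = np.zeros((3, 4))
        freq[0, 0] = freq[1, 1] = freq[2, 2] = 1.0  # consensus ACG
        pfm = PFM("hard", freq)
        beta = Background.uniform()
        spec = HMMSpec(pfm=pfm, beta=beta, strand_bias=1.0)
        u, v = "TTATT", "TTTAT"  # no ACG window anywhere, incl. the junction
        lu = llr(spec, u, beta)
        lv = llr(spec, v, beta)
        luv = llr(spec, u + v, beta)
        assert luv == pytest.approx(lu + lv, rel=1e-9)

    def test_planted_site_scores_higher(self, sharp_pfm):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(54)
        bases = np.array(list("ACGT"))
        cons = sharp_pfm.consensus()
        with_site = []
        without = []
        for _ in range(300):
            s = "".join(rng.choice(bases, 40))
            without.append(s)
            pos = int(rng.integers(0, 40 - 8))
            with_site.append(s[:pos] + cons + s[pos + 8:])
        beta = Background.uniform()
        spec = HMMSpec(pfm=sharp_pfm, beta=beta, strand_bias=0.5)
        s1 = np.array([llr(spec, s, beta) for s in with_site])
        s0 = np.array([llr(spec, s, beta) for s in without])
        assert mannwhitneyu(s1, s0, alternative="greater").pvalue < 1e-6

    def test_inserting_consensus_never_decreases_llr(self, sharp_pfm):
        rng = np.random.default_rng(55)
        beta = Background.uniform()
        spec = HMMSpec(pfm=sharp_pfm, beta=beta, strand_bias=0.6)
        cons = sharp_pfm.consensus()
        for _ in range(10):
            s = "".join(rng.choice(list("ACGT"), 30))
            base = llr(spec, s, beta)
            with_block = llr(spec, s[:15] + cons + s[15:], beta)
            extra = llr(spec, cons, beta)
            assert with_block >= base - 1e-9


class TestStrandBias:
    def test_all_forward_plants(self, sharp_pfm, uniform_bg):
        seqs = ["AATT" + sharp_pfm.consensus() + "GGCC"] * 50
        assert estimate_strand_bias(seqs, sharp_pfm, uniform_bg) == 1.0

    def test_seventy_thirty_mix(self, sharp_pfm, uniform_bg):
        cfg = SyntheticConfig(seed=57, n_bound=2000, n_unbound=1, probe_len=24,
                              motif=sharp_pfm, orientation_mix=0.7)
        bound, _, _ = generate_pools(cfg)
        s = estimate_strand_bias(bound, sharp_pfm, uniform_bg)
        assert s == pytest.approx(0.70, abs=0.03)

    def test_palindrome_near_half(self, palindromic_pfm, uniform_bg):
        cfg = SyntheticConfig(seed=58, n_bound=2000, n_unbound=1, probe_len=24,
                              motif=palindromic_pfm, orientation_mix=1.0)
        bound, _, _ = generate_pools(cfg)
        s = estimate_strand_bias(bound, palindromic_pfm, uniform_bg)
        assert s == pytest.approx(0.5, abs=0.05)

    def test_no_hits_gives_half(self, sharp_pfm, uniform_bg):
        assert estimate_strand_bias(["AAAA"], sharp_pfm, uniform_bg) == 0.5


class TestModesAndAuroc:
    def test_inversed_background_swaps_at_gc_mass(self):
        bg = Background(np.array([0.1, 0.2, 0.3, 0.4]))
        inv = inversed_background(bg)
        np.testing.assert_allclose(inv.probs, [0.3, 0.4, 0.1, 0.2])
        assert inv.gc == pytest.approx(1.0 - bg.gc)

    def test_mode_backgrounds(self, sharp_pfm):
        genomic = Background(np.array([0.3, 0.2, 0.2, 0.3]))
        assert background_for_mode("genomic", sharp_pfm, genomic) is genomic
        avg = background_for_mode("pfm_average", sharp_pfm, genomic)
        np.testing.assert_allclose(avg.probs, sharp_pfm.freq.mean(axis=0))
        with pytest.raises(ValueError):
            background_for_mode("bogus", sharp_pfm, genomic)

    def test_identical_pools_auroc_half(self, sharp_pfm):
        rng = np.random.default_rng(59)
        codes = rng.integers(0, 4, size=(50, 30)).astype(np.uint8)
        assert hmm_auroc(codes, codes, sharp_pfm) == pytest.approx(0.5)

    def test_homotypic_pools_mode_ordering(self):
        # bound flanks from the motif-average composition: the
        # motif-average background should beat genomic, genomic beat the
        # inverted composition
        pfm = random_pfm(length=8, ic_per_column=1.5, gc_target=0.72, seed=61)
        cfg = SyntheticConfig(
            seed=62, n_bound=300, n_unbound=300, probe_len=60, motif=pfm,
            homotypic_flank_fraction=0.6, weak_motif_rate=1.0,
        )
        bound, unbound, _ = generate_pools(cfg)
        bc = np.vstack([seqcodec.encode(s) for _, s in bound])
        uc = np.vstack([seqcodec.encode(s) for _, s in unbound])
        aucs = {m: hmm_auroc(bc, uc, pfm, mode=m) for m in
                ("pfm_average", "genomic", "pfm_inversed")}
        assert aucs["pfm_average"] > aucs["genomic"] > aucs["pfm_inversed"]
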