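"""Two-state block HMM scoring of sequences (motif block + background).

The generative model emits, at every step, either one background base
(probability ``t_bg``, default 0.99) or a whole motif block of length L
(probability 1 − t_bg), the block being forward-oriented with the
precalculated strand bias ``s``.  A sequence is scored by the log
likelihood ratio of this model against a fixed genomic background, so
sequences whose environment looks like the motif — strong sites, weak
sites, or merely motif-like composition — score high.  Three choices
of the background-state emission are supported: the genomic
(unbound-pool) frequencies, the column-average of the PFM, and the
latter with its AT and GC mass swapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import seqcodec
from .mlr import auroc
from .pfm import _INVALID_CUTOFF, PFM, Background, Scorer

MODES = ("genomic", "pfm_average", "pfm_inversed")


def inversed_background(bg: Background) -> Background:
    """Swap A<->G and T<->C probability mass (exchanges total AT and GC
    content while preserving purine/pyrimidine pairing)."""
    a, c, g, t = bg.probs
    return Background(np.array([g, t, a, c]))


def background_for_mode(
    mode: str, pfm: PFM, genomic: Background
) -> Background:
    if mode == "genomic":
        return genomic
    if mode == "pfm_average":
        return pfm.column_average()
    if mode == "pfm_inversed":
        return inversed_background(pfm.column_average())
    raise ValueError(f"unknown background mode {mode!r}")


@dataclass(frozen=True)
class HMMSpec:
    pfm: PFM
    beta: Background          # background-state emission
    t_bg: float = 0.99        # probability of emitting a background base
    strand_bias: float = 0.5  # probability a motif block is forward
    mode: str = "genomic"

    def __post_init__(self):
        if not 0.0 < self.t_bg < 1.0:
            raise ValueError("t_bg must be in (0, 1)")
        if not 0.0 <= self.strand_bias <= 1.0:
            raise ValueError("strand bias must be in [0, 1]")


def estimate_strand_bias(
    sequences,
    pfm: PFM,
    bg: Background,
    p_cutoff: float = 0.001,
    scorer: Scorer | None = None,
) -> float:
    """Fraction of motif hits (p <= cutoff) in the forward orientation
    over a pool of raw sequences; 0.5 when there are no hits."""
    scorer = scorer or Scorer(pfm, bg)
    cut = scorer.int_cutoff(p_cutoff)
    n_fwd = n_rev = 0
    for item in sequences:
        seq = item[1] if isinstance(item, tuple) else item
        codes = seqcodec.encode(seq) if isinstance(seq, str) else np.asarray(seq)
        if codes.size < pfm.length:
            continue
        f = scorer.window_int_scores(codes, strand="+")[0]
        r = scorer.window_int_scores(codes, strand="-")[0]
        n_fwd += int(np.sum((f > _INVALID_CUTOFF) & (f >= cut)))
        n_rev += int(np.sum((r > _INVALID_CUTOFF) & (r >= cut)))
    if n_fwd + n_rev == 0:
        return 0.5
    return n_fwd / (n_fwd + n_rev)


def _block_logprobs(hmm: HMMSpec, codes: np.ndarray) -> np.ndarray:
    """log P(motif block at each window), mixing both orientations.

    codes: (n, slen); returns (n, slen - L + 1); -inf where the window
    has zero probability (or contains N).
    """
    L = hmm.pfm.length
    n, slen = codes.shape
    W = slen - L + 1
    if W <= 0:
        return np.zeros((n, 0))
    freq = hmm.pfm.freq
    rc = freq[::-1, ::-1]
    pf = np.ones((n, W))
    pr = np.ones((n, W))
    bad = np.zeros((n, W), dtype=bool)
    for j in range(L):
        sub = codes[:, j : j + W]
        bad |= sub >= 4
        safe = np.minimum(sub, 3)
        pf *= freq[j, safe]
        pr *= rc[j, safe]
    mix = hmm.strand_bias * pf + (1.0 - hmm.strand_bias) * pr
    mix[bad] = 0.0
    with np.errstate(divide="ignore"):
        return np.log(mix)


def pool_loglik(hmm: HMMSpec, codes: np.ndarray) -> np.ndarray:
    """log P(seq | hmm) for equal-length sequences (natural log).

    Forward recursion over emission boundaries:
    F(i) = t_bg * beta(x_i) * F(i-1)
         + (1 - t_bg) * [i >= L] * block(x_{i-L+1..i}) * F(i-L).
    """
    codes = np.atleast_2d(np.asarray(codes))
    if np.any(codes >= 4):
        raise ValueError("sequence contains N; mask or drop it first")
    n, slen = codes.shape
    L = hmm.pfm.length
    log_tbg = np.log(hmm.t_bg)
    log_switch = np.log1p(-hmm.t_bg)
    log_beta = np.log(hmm.beta.probs)[codes]          # (n, slen)
    log_block = _block_logprobs(hmm, codes)           # (n, slen - L + 1)

    F = np.zeros((slen + 1, n))
    for i in range(1, slen + 1):
        val = log_tbg + log_beta[:, i - 1] + F[i - 1]
        if i >= L:
            alt = log_switch + log_block[:, i - L] + F[i - L]
            val = np.logaddexp(val, alt)
        F[i] = val
    return F[slen]


def sequence_loglik(hmm: HMMSpec, seq: str | np.ndarray) -> float:
    codes = seqcodec.encode(seq) if isinstance(seq, str) else np.asarray(seq)
    if codes.size == 0:
        return 0.0
    return float(pool_loglik(hmm, codes[None, :])[0])


def llr(
    hmm: HMMSpec, seq: str | np.ndarray, genomic_beta: Background
) -> float:
    """Log likelihood ratio of the block HMM against a pure genomic
    background parse of the same sequence."""
    codes = seqcodec.encode(seq) if isinstance(seq, str) else np.asarray(seq)
    if codes.size == 0:
        return 0.0
    return float(pool_llr(hmm, codes[None, :], genomic_beta)[0])


def pool_llr(
    hmm: HMMSpec, codes: np.ndarray, genomic_beta: Background
) -> np.ndarray:
    codes = np.atleast_2d(np.asarray(codes))
    ll = pool_loglik(hmm, codes)
    base = np.log(genomic_beta.probs)[codes].sum(axis=1)
    return ll - base


def hmm_auroc(
    bound_codes: np.ndarray,
    unbound_codes: np.ndarray,
    pfm: PFM,
    mode: str = "pfm_average",
    t_bg: float = 0.99,
    strand_bias: float | None = None,
    scan_bg: Background | None = None,
    genomic_beta: Background | None = None,
) -> float:
    """AUROC of the log-likelihood-ratio score, bound vs unbound pools.

    The genomic background is estimated from the unbound pool unless
    given; the strand bias from the bound pool unless given.
    """
    bound_codes = np.atleast_2d(bound_codes)
    unbound_codes = np.atleast_2d(unbound_codes)
    genomic_beta = genomic_beta or Background.from_codes(unbound_codes)
    if strand_bias is None:
        strand_bias = estimate_strand_bias(
            list(bound_codes), pfm, scan_bg or Background.uniform()
        )
    beta = background_for_mode(mode, pfm, genomic_beta)
    spec = HMMSpec(pfm=pfm, beta=beta, t_bg=t_bg, strand_bias=strand_bias, mode=mode)
    s_b = pool_llr(spec, bound_codes, genomic_beta)
    s_u = pool_llr(spec, unbound_codes, genomic_beta)
    scores = np.concatenate([s_b, s_u])
    labels = np.concatenate([np.ones(s_b.size), np.zeros(s_u.size)])
    return auroc(scores, labels)
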