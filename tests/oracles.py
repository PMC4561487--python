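"""Independent brute-force oracles used to pin down expected values.

Everything here recomputes quantities by direct enumeration (k-mer
tables, window loops, exhaustive parse sums) and is deliberately
separate from the library's DP/vectorized code paths.
"""

from itertools import product

import numpy as np

from motifenv import seqcodec

GRAN = 1e-3


def quantized_cell_matrix(pfm, bg, granularity=GRAN):
    """Per-cell quantized integer log-odds, derived directly."""
    lo = np.log2(pfm.freq) - np.log2(bg.probs)[None, :]
    return np.rint(lo / granularity).astype(np.int64)


def enumerate_kmer_scores(pfm, bg, granularity=GRAN):
    """{int score: null prob} plus per-kmer scores, by full enumeration."""
    ints = quantized_cell_matrix(pfm, bg, granularity)
    L = pfm.length
    kmer_score = {}
    score_prob = {}
    for kmer in product(range(4), repeat=L):
        s = int(sum(ints[i, b] for i, b in enumerate(kmer)))
        p = float(np.prod([bg.probs[b] for b in kmer]))
        kmer_score[kmer] = s
        score_prob[s] = score_prob.get(s, 0.0) + p
    return kmer_score, score_prob


def enumeration_tail(score_prob):
    """score -> P(S >= score) from an enumerated score distribution."""
    scores = sorted(score_prob)
    tail = {}
    acc = 0.0
    for s in reversed(scores):
        acc += score_prob[s]
        tail[s] = acc
    return tail


def scan_oracle(pfm, bg, seq, p_cutoff, strands="both", granularity=GRAN):
    """Window-loop scan with enumeration-derived exact p-values.

    Returns a set of (offset, strand, int_score) for hits with
    p <= cutoff."""
    kmer_score, score_prob = enumerate_kmer_scores(pfm, bg, granularity)
    tail = enumeration_tail(score_prob)
    codes = seqcodec.encode(seq)
    L = pfm.length
    hits = set()
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    for off in range(len(seq) - L + 1):
        window = codes[off : off + L]
        if np.any(window >= 4):
            continue
        for st in strand_list:
            w = window if st == "+" else seqcodec.revcomp_codes(window)
            s = kmer_score[tuple(int(x) for x in w)]
            if tail[s] <= p_cutoff:
                hits.add((off, st, s))
    return hits, tail


def hmm_brute_force(freq, beta, t_bg, s, codes):
    """P(seq) as the exhaustive sum over all tilings of the sequence
    into single background characters and non-overlapping motif blocks
    in either orientation."""
    L = freq.shape[0]
    rc = freq[::-1, ::-1]

    def block_prob(window):
        pf = np.prod([freq[j, b] for j, b in enumerate(window)])
        pr = np.prod([rc[j, b] for j, b in enumerate(window)])
        return s * pf + (1.0 - s) * pr

    def rec(x):
        if len(x) == 0:
            return 1.0
        total = t_bg * beta[x[0]] * rec(x[1:])
        if len(x) >= L:
            total += (1.0 - t_bg) * block_prob(x[:L]) * rec(x[L:])
        return total

    return rec(list(codes))
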