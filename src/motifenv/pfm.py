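"""Position frequency matrices, log-odds scoring, and exact score p-values.

A :class:`PFM` stores per-position nucleotide probabilities of a core
binding motif (alphabet order A, C, G, T).  Scoring is done in log-odds
(base 2) against a mononucleotide :class:`Background`.  To make score
ties and p-values well defined, all scanning goes through a
:class:`Scorer`, which quantizes the per-cell log-odds to a fixed
granularity (default 1/1000 of a bit) and computes the exact null
distribution of window scores by dynamic programming over positions.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .seqcodec import ALPHABET

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_GRANULARITY = 1e-3  # bits per score bin

# sentinel per-cell value marking an N inside a window; any window sum
# containing one of these is far below every real score
_N_PENALTY = -(10**9)
_INVALID_CUTOFF = -(10**8)


class MotifFormatError(ValueError):
    """Raised when a motif file cannot be parsed."""


@dataclass(frozen=True)
class Background:
    """Mononucleotide background distribution over A, C, G, T."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise ValueError("background needs exactly 4 probabilities")
        if np.any(p <= 0):
            raise ValueError("background probabilities must be > 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_codes(cls, codes: np.ndarray, pseudocount: float = 1.0) -> "Background":
        """Estimate from encoded sequences; N codes are ignored."""
        flat = np.asarray(codes).ravel()
        counts = np.bincount(flat[flat < 4], minlength=4).astype(float)
        counts += pseudocount
        return cls(counts / counts.sum())

    @property
    def gc(self) -> float:
        return float(self.probs[1] + self.probs[2])

    def log2(self) -> np.ndarray:
        return np.log2(self.probs)


@dataclass(frozen=True)
class PFM:
    """Core-motif position frequency matrix.

    ``freq`` rows are probabilities over A, C, G, T after the pseudocount
    has been added and the row renormalized; they sum to 1 within 1e-9.
    """

    name: str
    freq: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self):
        f = np.asarray(self.freq, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
            raise ValueError("PFM frequency matrix must be L x 4 with L >= 1")
        if np.any(f < 0):
            raise ValueError("PFM frequencies must be >= 0")
        if np.any(np.abs(f.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("PFM rows must sum to 1")
        object.__setattr__(self, "freq", f)

    @classmethod
    def from_counts_or_freq(
        cls, name: str, raw: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT
    ) -> "PFM":
        """Build from a raw L x 4 nonnegative matrix: add the pseudocount to
        every cell, then renormalize each row."""
        raw = np.asarray(raw, dtype=float)
        if raw.ndim != 2 or raw.shape[1] != 4:
            raise MotifFormatError("matrix must have 4 columns (A, C, G, T)")
        sums = raw.sum(axis=1)
        if np.any(sums <= 0):
            bad = int(np.nonzero(sums <= 0)[0][0])
            raise MotifFormatError(f"row {bad} has non-positive sum")
        # interpret rows as probabilities regardless of scale, then smooth
        probs = raw / sums[:, None]
        probs = probs + pseudocount
        probs = probs / probs.sum(axis=1, keepdims=True)
        return cls(name=name, freq=probs, pseudocount=pseudocount)

    def __len__(self) -> int:
        return self.freq.shape[0]

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in np.argmax(self.freq, axis=1))

    def reverse_complement(self) -> "PFM":
        return PFM(self.name + "_rc", self.freq[::-1, ::-1], self.pseudocount)

    def column_average(self) -> Background:
        """Average nucleotide frequencies over motif positions."""
        return Background(self.freq.mean(axis=0))

    def information_content(self, bg: Background | None = None) -> np.ndarray:
        """Per-column information content in bits (relative entropy to bg)."""
        bg = bg or Background.uniform()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.freq * np.log2(self.freq / bg.probs)
        return np.nansum(terms, axis=1)

    @property
    def gc(self) -> float:
        return float(self.freq[:, 1:3].sum(axis=1).mean())

    def is_palindromic(self, tol: float = 0.05) -> bool:
        """A motif counts as palindromic when the per-cell RMS distance to
        its own reverse complement is below ``tol``."""
        rc = self.freq[::-1, ::-1]
        rms = math.sqrt(float(np.mean((self.freq - rc) ** 2)))
        return rms < tol


def log_odds(pfm: PFM, kmer_codes: np.ndarray, bg: Background) -> float:
    """Unquantized log-odds score (bits) of one k-mer against ``bg``."""
    codes = np.asarray(kmer_codes)
    if codes.shape != (pfm.length,):
        raise ValueError(f"k-mer length {codes.shape} != motif length {pfm.length}")
    if np.any(codes >= 4):
        raise ValueError("k-mer contains a non-ACGT character")
    idx = np.arange(pfm.length)
    return float(np.sum(np.log2(pfm.freq[idx, codes]) - np.log2(bg.probs[codes])))


@dataclass
class Scorer:
    """Quantized log-odds scorer with an exact window-score null distribution.

    Per-cell log-odds values are rounded to multiples of ``granularity``
    bits; a window score is the sum of its quantized cells.  The null
    distribution of this (discrete) score under ``bg`` is computed by
    convolving the per-position score distributions, so reported
    p-values P(score >= s) are exact for the quantized matrix.
    """

    pfm: PFM
    bg: Background
    granularity: float = DEFAULT_GRANULARITY

    int_matrix: np.ndarray = field(init=False)       # (L, 5) int64; col 4 = N penalty
    rc_int_matrix: np.ndarray = field(init=False)
    _min_score: int = field(init=False)
    _tail: np.ndarray = field(init=False)            # P(score >= min_score + k)

    def __post_init__(self):
        if self.granularity <= 0:
            raise ValueError("granularity must be > 0")
        lo = np.log2(self.pfm.freq) - np.log2(self.bg.probs)[None, :]
        ints = np.rint(lo / self.granularity).astype(np.int64)
        L = self.pfm.length
        self.int_matrix = np.full((L, 5), _N_PENALTY, dtype=np.int64)
        self.int_matrix[:, :4] = ints
        # reverse-complement scoring matrix: rc[j, b] = fwd[L-1-j, 3-b]
        self.rc_int_matrix = np.full((L, 5), _N_PENALTY, dtype=np.int64)
        self.rc_int_matrix[:, :4] = ints[::-1, ::-1]
        self._build_distribution(ints)

    def _build_distribution(self, ints: np.ndarray) -> None:
        lo_min = int(ints.min(axis=1).sum())
        lo_max = int(ints.max(axis=1).sum())
        pmf = np.zeros(lo_max - lo_min + 1)
        # DP over positions: offset tracks the running minimum achievable sum
        cur = np.array([1.0])
        cur_min = 0
        for j in range(ints.shape[0]):
            row = ints[j]
            rmin, rmax = int(row.min()), int(row.max())
            nxt = np.zeros(cur.size + rmax - rmin)
            for b in range(4):
                off = int(row[b]) - rmin
                nxt[off : off + cur.size] += cur * self.bg.probs[b]
            cur = nxt
            cur_min += rmin
        assert cur_min == lo_min and cur.size == pmf.size
        pmf[:] = cur
        self._min_score = lo_min
        self._tail = np.cumsum(pmf[::-1])[::-1]
        # guard against fp round-off above 1
        np.clip(self._tail, 0.0, 1.0, out=self._tail)
        self._tail[self._tail <= 0] = np.finfo(float).tiny

    # -- scoring -------------------------------------------------------

    def window_int_scores(self, codes: np.ndarray, strand: str = "+") -> np.ndarray:
        """Quantized integer scores of every window.

        ``codes``: (..., seqlen) uint8.  Returns (..., seqlen - L + 1)
        int64; windows containing N come out below any valid score.
        ``strand='-'`` scores the reverse complement of each window at
        the same forward offset.
        """
        codes = np.atleast_2d(np.asarray(codes))
        L = self.pfm.length
        n, slen = codes.shape
        W = slen - L + 1
        if W <= 0:
            return np.zeros(codes.shape[:-1] + (0,), dtype=np.int64)
        mat = self.int_matrix if strand == "+" else self.rc_int_matrix
        out = np.zeros((n, W), dtype=np.int64)
        for j in range(L):
            out += mat[j, codes[:, j : j + W]]
        return out

    def to_bits(self, int_scores: np.ndarray) -> np.ndarray:
        return np.asarray(int_scores, dtype=float) * self.granularity

    def score_kmer(self, codes: np.ndarray, strand: str = "+") -> float:
        s = self.window_int_scores(np.atleast_2d(codes), strand)[0]
        if s.size != 1:
            raise ValueError("score_kmer expects a k-mer of the motif length")
        return float(self.to_bits(s[0]))

    def pvalue(self, int_scores: np.ndarray) -> np.ndarray:
        """Exact P(score >= s) for quantized integer scores."""
        idx = np.asarray(int_scores) - self._min_score
        idx = np.clip(idx, None, self._tail.size)  # above max -> 0 prob bucket
        out = np.where(idx >= self._tail.size, np.finfo(float).tiny, 0.0)
        inside = idx < self._tail.size
        low = idx < 0
        out = np.where(inside, self._tail[np.clip(idx, 0, self._tail.size - 1)], out)
        out = np.where(low, 1.0, out)
        return out

    def int_cutoff(self, p_cutoff: float) -> int:
        """Smallest quantized score whose exact p-value is <= p_cutoff."""
        # tail is non-increasing; find first index with tail <= p_cutoff
        idx = np.searchsorted(-self._tail, -p_cutoff, side="left")
        if idx >= self._tail.size:
            return self._min_score + self._tail.size  # unreachable score
        return self._min_score + int(idx)

    def tail_function(self) -> tuple[np.ndarray, np.ndarray]:
        """(scores in bits ascending, exact tail probabilities P(S >= s))."""
        scores = (self._min_score + np.arange(self._tail.size)) * self.granularity
        return scores, self._tail.copy()


def exact_pvalues(
    pfm: PFM, bg: Background, granularity: float = DEFAULT_GRANULARITY
) -> tuple[np.ndarray, np.ndarray]:
    """Exact tail distribution of quantized window scores under ``bg``.

    Returns (scores_bits, tail) with tail monotone non-increasing.
    """
    return Scorer(pfm, bg, granularity).tail_function()


# -- MEME motif format ----------------------------------------------------


def read_pfm(
    path_or_handle,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    name: str | None = None,
) -> PFM:
    """Read one motif from a MEME-motif-format file.

    Returns the first motif, or the one called ``name``.  The pseudocount
    is added per cell and rows renormalized.
    """
    motifs = read_all_pfms(path_or_handle, pseudocount=pseudocount)
    if not motifs:
        raise MotifFormatError("no motif block found in file")
    if name is None:
        return motifs[0]
    for m in motifs:
        if m.name == name:
            return m
    raise MotifFormatError(f"motif {name!r} not found in file")


def read_all_pfms(path_or_handle, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PFM]:
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
    else:
        with open(path_or_handle) as fh:
            lines = fh.read().splitlines()

    motifs: list[PFM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_name = parts[1] if len(parts) > 1 else f"motif_{len(motifs) + 1}"
            i += 1
            # skip to the letter-probability header (or straight to rows)
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise MotifFormatError(
                        f"motif {motif_name!r} has no letter-probability matrix "
                        f"(line {i + 1})"
                    )
                i += 1
            if i >= len(lines):
                raise MotifFormatError(
                    f"motif {motif_name!r} has no letter-probability matrix"
                )
            i += 1
            rows = []
            while i < len(lines):
                row_line = lines[i].strip()
                if not row_line or row_line.startswith(("MOTIF", "URL")):
                    break
                fields = row_line.split()
                try:
                    vals = [float(x) for x in fields]
                except ValueError as exc:
                    raise MotifFormatError(
                        f"malformed matrix row at line {i + 1}: {row_line!r}"
                    ) from exc
                if len(vals) != 4:
                    raise MotifFormatError(
                        f"expected 4 columns at line {i + 1}, got {len(vals)}"
                    )
                rows.append(vals)
                i += 1
            if not rows:
                raise MotifFormatError(f"motif {motif_name!r} has an empty matrix")
            motifs.append(
                PFM.from_counts_or_freq(motif_name, np.array(rows), pseudocount)
            )
        else:
            i += 1
    return motifs


def write_pfm(path_or_handle, pfms: PFM | list[PFM], bg: Background | None = None):
    """Write motifs in minimal MEME motif format."""
    if isinstance(pfms, PFM):
        pfms = [pfms]
    bg = bg or Background.uniform()
    buf = io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    buf.write("Background letter frequencies\n")
    buf.write(
        "A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*bg.probs)
    )
    for pfm in pfms:
        buf.write(f"MOTIF {pfm.name}\n")
        buf.write(
            f"letter-probability matrix: alength= 4 w= {pfm.length} "
            f"nsites= 20 E= 0\n"
        )
        for row in pfm.freq:
            buf.write(" {0:9.6f} {1:9.6f} {2:9.6f} {3:9.6f}\n".format(*row))
        buf.write("\n")
    text = buf.getvalue()
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)
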