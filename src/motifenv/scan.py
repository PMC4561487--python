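"""FIMO-style motif scanning and best-hit alignment of probe pools.

Scanning reports every window whose exact p-value passes the cutoff;
with ``strands='both'`` each window is additionally scored on its
reverse complement and reported at the same forward-strand offset.

Best-hit alignment mirrors the selection applied to HT-SELEX probes and
genomic motif matches: each sequence keeps its unique highest-scoring
hit, sequences with no passing hit or a tied top score are discarded,
and reverse-strand best hits are reverse-complemented into a common
frame in which the core motif occupies a fixed coordinate block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import seqcodec
from .pfm import _INVALID_CUTOFF, PFM, Background, Scorer

DEFAULT_CORE_EXCLUSION = 2
DEFAULT_MIN_POOL_SIZE = 1000


class PoolTooSmallError(ValueError):
    """Fewer sequences survived alignment than the required minimum."""


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int          # 0-based start on the forward sequence
    strand: str          # '+' or '-'
    score: float         # quantized log-odds, bits
    pvalue: float        # exact tail probability under the background


def scan(
    pfm: PFM,
    seq: str | np.ndarray,
    bg: Background,
    p_cutoff: float = 1e-4,
    strands: str = "both",
    seq_id: str = "seq",
    scorer: Scorer | None = None,
) -> list[MotifHit]:
    """All motif hits with exact p-value <= ``p_cutoff``.

    Windows containing N are skipped.  Returns hits sorted by offset,
    forward strand first at equal offsets.
    """
    codes = seqcodec.encode(seq) if isinstance(seq, str) else np.asarray(seq)
    scorer = scorer or Scorer(pfm, bg)
    if codes.size < pfm.length:
        return []
    cutoff = scorer.int_cutoff(p_cutoff)
    hits: list[MotifHit] = []
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    per_strand = {}
    for st in strand_list:
        per_strand[st] = scorer.window_int_scores(codes, strand=st)[0]
    n_win = codes.size - pfm.length + 1
    for off in range(n_win):
        for st in strand_list:
            s = per_strand[st][off]
            if s <= _INVALID_CUTOFF:
                continue
            if s >= cutoff:
                hits.append(
                    MotifHit(
                        seq_id=seq_id,
                        offset=off,
                        strand=st,
                        score=float(scorer.to_bits(s)),
                        pvalue=float(scorer.pvalue(np.array([s]))[0]),
                    )
                )
    return hits


def write_hits_tsv(path, hits: list[MotifHit]) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\toffset\tstrand\tscore\tpvalue\n")
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.offset}\t{h.strand}\t{h.score:.6g}\t{h.pvalue:.6g}\n")


@dataclass
class AlignedPool:
    """Equal-length sequences aligned so the core motif occupies
    ``[core_start, core_start + core_len)`` of the frame.

    ``codes`` is an (n, frame_len) uint8 matrix; code 4 marks positions
    the original probe did not cover (padded frames).  ``mask`` is an
    optional boolean matrix flagging positions excluded from downstream
    statistics (set by motif masking).
    """

    label: str
    codes: np.ndarray
    seq_ids: list[str]
    core_start: int
    core_len: int
    flank_up: int
    flank_down: int
    core_exclusion: int = DEFAULT_CORE_EXCLUSION
    motif_scores: np.ndarray | None = None   # core-window score per record, bits
    motif_strands: np.ndarray | None = None  # original strand of the best hit
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        if self.flank_up < 0 or self.flank_down < 0:
            raise ValueError("flank extents must be >= 0")
        if self.codes.shape[1] != self.flank_up + self.core_len + self.flank_down:
            raise ValueError("frame width inconsistent with flanks and core length")
        if self.core_start != self.flank_up:
            raise ValueError("core must start right after the upstream flank")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def frame_len(self) -> int:
        return self.codes.shape[1]

    @property
    def core_end(self) -> int:
        return self.core_start + self.core_len

    def flank_columns(self) -> tuple[np.ndarray, np.ndarray]:
        """Frame columns usable for environment statistics.

        Returns (columns, positions): relative positions are negative
        upstream (-1 adjacent to the core) and positive downstream,
        with the core block and ``core_exclusion`` bp each side omitted.
        """
        cols, pos = [], []
        for c in range(self.core_start):
            rel = c - self.core_start            # -flank_up .. -1
            if rel <= -(self.core_exclusion + 1):
                cols.append(c)
                pos.append(rel)
        for c in range(self.core_end, self.frame_len):
            rel = c - self.core_end + 1          # 1 .. flank_down
            if rel >= self.core_exclusion + 1:
                cols.append(c)
                pos.append(rel)
        return np.array(cols, dtype=int), np.array(pos, dtype=int)

    def subset(self, idx: np.ndarray) -> "AlignedPool":
        idx = np.asarray(idx)
        return replace(
            self,
            codes=self.codes[idx],
            seq_ids=[self.seq_ids[i] for i in np.atleast_1d(idx)],
            motif_scores=None if self.motif_scores is None else self.motif_scores[idx],
            motif_strands=None if self.motif_strands is None else self.motif_strands[idx],
            mask=None if self.mask is None else self.mask[idx],
        )

    def sequences(self) -> list[str]:
        return [seqcodec.decode(row) for row in self.codes]

    def dense_codes(self, min_keep: int | None = None) -> np.ndarray:
        """Frames without undefined positions (for whole-sequence models).

        Records containing any undefined base are dropped; if too few
        records span the full frame, the widest core-centred column
        span covered by every record is used instead.
        """
        min_keep = max(20, self.n // 10) if min_keep is None else min_keep
        full_ok = ~(self.codes >= seqcodec.N_CODE).any(axis=1)
        if full_ok.sum() >= min_keep:
            return self.codes[full_ok]
        col_ok = (~(self.codes >= seqcodec.N_CODE)).all(axis=0)
        lo, hi = self.core_start, self.core_end
        while lo > 0 and col_ok[lo - 1]:
            lo -= 1
        while hi < self.frame_len and col_ok[hi]:
            hi += 1
        return self.codes[:, lo:hi]

    # -- persistence ---------------------------------------------------

    def to_fasta(self, fasta_path, sidecar_path=None) -> None:
        with open(fasta_path, "w") as fh:
            for sid, row in zip(self.seq_ids, self.codes):
                fh.write(f">{sid}\n{seqcodec.decode(row)}\n")
        if sidecar_path is not None:
            side = {
                "label": self.label,
                "core_start": self.core_start,
                "core_len": self.core_len,
                "flank_up": self.flank_up,
                "flank_down": self.flank_down,
                "core_exclusion": self.core_exclusion,
                "motif_scores": None
                if self.motif_scores is None
                else [round(float(x), 6) for x in self.motif_scores],
            }
            with open(sidecar_path, "w") as fh:
                json.dump(side, fh, indent=1, sort_keys=True)
                fh.write("\n")

    @classmethod
    def from_fasta(cls, fasta_path, sidecar_path) -> "AlignedPool":
        with open(sidecar_path) as fh:
            side = json.load(fh)
        ids, rows = [], []
        for sid, seq in iter_fasta(fasta_path):
            ids.append(sid)
            rows.append(seqcodec.encode(seq))
        scores = side.get("motif_scores")
        return cls(
            label=side["label"],
            codes=np.vstack(rows),
            seq_ids=ids,
            core_start=side["core_start"],
            core_len=side["core_len"],
            flank_up=side["flank_up"],
            flank_down=side["flank_down"],
            core_exclusion=side["core_exclusion"],
            motif_scores=None if scores is None else np.asarray(scores, dtype=float),
        )


def iter_fasta(path):
    """Yield (id, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    for record in SeqIO.parse(path, "fasta"):
        yield record.id, str(record.seq)


@dataclass
class AlignmentReport:
    kept: int = 0
    no_hit: int = 0
    tie: int = 0
    short_flank: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.no_hit + self.tie + self.short_flank

    def as_dict(self) -> dict:
        return {
            "kept": self.kept,
            "no_hit": self.no_hit,
            "tie": self.tie,
            "short_flank": self.short_flank,
        }


def align_best_hit(
    seqs,
    pfm: PFM,
    bg: Background,
    p_cutoff: float = 1e-4,
    strands: str = "both",
    flank_up: int = 10,
    flank_down: int = 10,
    label: str = "pool",
    core_exclusion: int = DEFAULT_CORE_EXCLUSION,
    min_pool_size: int = DEFAULT_MIN_POOL_SIZE,
    pad_incomplete: bool = False,
    scorer: Scorer | None = None,
) -> tuple[AlignedPool, AlignmentReport]:
    """Align a pool of probes on each sequence's unique best motif hit.

    ``seqs`` is an iterable of (seq_id, sequence).  Per sequence, the
    highest-scoring window with exact p-value <= ``p_cutoff`` is kept;
    a tied top score at two or more distinct offsets (scores compared on
    the quantized grid) discards the sequence, as does the absence of
    any passing hit.  Reverse-strand best hits are reverse-complemented
    into the common frame.  Records whose flanks do not cover the
    requested window are discarded unless ``pad_incomplete`` is set, in
    which case missing positions are padded as undefined (N).
    """
    scorer = scorer or Scorer(pfm, bg)
    L = pfm.length
    cutoff = scorer.int_cutoff(p_cutoff)
    strand_list = ["+"] if strands == "forward" else ["+", "-"]

    report = AlignmentReport()
    rows, ids, scores, hit_strands = [], [], [], []
    frame_len = flank_up + L + flank_down

    for sid, seq in seqs:
        codes = seqcodec.encode(seq) if isinstance(seq, str) else np.asarray(seq)
        if codes.size < L:
            report.no_hit += 1
            continue
        best_score = None
        best: list[tuple[int, str]] = []  # (offset, strand) at the top score
        for st in strand_list:
            win = scorer.window_int_scores(codes, strand=st)[0]
            valid = win > _INVALID_CUTOFF
            win = np.where(valid, win, np.iinfo(np.int64).min)
            top = int(win.max()) if win.size else np.iinfo(np.int64).min
            if top < cutoff:
                continue
            if best_score is None or top > best_score:
                best_score = top
                best = [(int(o), st) for o in np.nonzero(win == top)[0]]
            elif top == best_score:
                best.extend((int(o), st) for o in np.nonzero(win == top)[0])
        if best_score is None:
            report.no_hit += 1
            continue
        offsets = {o for o, _ in best}
        if len(offsets) > 1:
            report.tie += 1
            continue
        offset = best[0][0]
        # same offset on both strands (palindrome): prefer forward
        strand = "+" if any(st == "+" for _, st in best) else "-"
        if strand == "-":
            codes = seqcodec.revcomp_codes(codes)
            offset = codes.size - (offset + L)
        lo = offset - flank_up
        hi = offset + L + flank_down
        if lo < 0 or hi > codes.size:
            if not pad_incomplete:
                report.short_flank += 1
                continue
            frame = np.full(frame_len, seqcodec.N_CODE, dtype=np.uint8)
            src_lo, src_hi = max(lo, 0), min(hi, codes.size)
            frame[src_lo - lo : src_hi - lo] = codes[src_lo:src_hi]
        else:
            frame = codes[lo:hi]
        rows.append(frame)
        ids.append(sid)
        scores.append(scorer.to_bits(best_score))
        hit_strands.append(strand)
        report.kept += 1

    if report.kept < max(min_pool_size, 1):
        raise PoolTooSmallError(
            f"pool {label!r}: {report.kept} sequences after alignment "
            f"(minimum {min_pool_size})"
        )
    pool = AlignedPool(
        label=label,
        codes=np.vstack(rows),
        seq_ids=ids,
        core_start=flank_up,
        core_len=L,
        flank_up=flank_up,
        flank_down=flank_down,
        core_exclusion=core_exclusion,
        motif_scores=np.asarray(scores, dtype=float),
        motif_strands=np.asarray(hit_strands),
    )
    return pool, report


def match_sizes(
    a: AlignedPool, b: AlignedPool, seed: int
) -> tuple[AlignedPool, AlignedPool]:
    """Subsample the larger pool (without replacement) to the smaller's
    size; deterministic for a given seed."""
    if a.n == 0 or b.n == 0:
        raise ValueError("cannot size-match an empty pool")
    rng = np.random.default_rng(seed)
    if a.n == b.n:
        return a, b
    if a.n > b.n:
        idx = np.sort(rng.choice(a.n, size=b.n, replace=False))
        return a.subset(idx), b
    idx = np.sort(rng.choice(b.n, size=a.n, replace=False))
    return a, b.subset(idx)
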