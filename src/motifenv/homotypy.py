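"""Homotypic clusters and the homotypic-environment similarity score.

Bound motifs tend to sit among additional, mostly weak, occurrences of
the same motif.  Two quantifications are implemented on aligned pools:

* cluster counting — off-core motif hits on both strands binned by
  exact p-value (<= 0.001, 0.001-0.05, 0.05-0.1);
* environment similarity — the mean log-odds of *all* motif-length
  windows in the flanks (no threshold), taking the better strand per
  window, which captures overall resemblance of the environment to the
  motif.

Motif-masking controls (mask matched positions, or drop sequences with
off-core matches) let nucleotide-content comparisons be re-run with the
discrete motif occurrences removed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .pfm import _INVALID_CUTOFF, PFM, Background, Scorer
from .scan import AlignedPool

DEFAULT_BINS = (0.001, 0.05, 0.1)


def offcore_window_starts(pool: AlignedPool, L: int, exclusion: int = 0) -> np.ndarray:
    """Window start offsets fully inside the frame that do not overlap
    the core block (extended by ``exclusion`` bp on each side)."""
    lo_block = pool.core_start - exclusion
    hi_block = pool.core_end + exclusion
    starts = np.arange(pool.frame_len - L + 1)
    ok = (starts + L <= lo_block) | (starts >= hi_block)
    return starts[ok]


def _window_scores(
    pool: AlignedPool, scorer: Scorer, strands: str, exclusion: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(int scores fwd, int scores rev or None, eligible starts)."""
    starts = offcore_window_starts(pool, scorer.pfm.length, exclusion)
    fwd = scorer.window_int_scores(pool.codes, strand="+")[:, starts]
    rev = None
    if strands == "both":
        rev = scorer.window_int_scores(pool.codes, strand="-")[:, starts]
    return fwd, rev, starts


def count_clusters(
    pool: AlignedPool,
    pfm: PFM,
    bg: Background,
    bins: tuple[float, float, float] = DEFAULT_BINS,
    strands: str = "both",
    scorer: Scorer | None = None,
) -> pd.DataFrame:
    """Per-sequence off-core hit counts in the three p-value bins.

    Hits on both strands are counted (a window can contribute once per
    strand); windows overlapping the core block contribute to nothing.
    Sequences with no eligible window get NaN counts.
    """
    scorer = scorer or Scorer(pfm, bg)
    fwd, rev, starts = _window_scores(pool, scorer, strands)
    cut = [scorer.int_cutoff(b) for b in bins]
    cols = {}
    labels = [f"n_p_le_{bins[0]:g}", f"n_p_{bins[0]:g}_{bins[1]:g}", f"n_p_{bins[1]:g}_{bins[2]:g}"]
    mats = [fwd] if rev is None else [fwd, rev]
    for k, lab in enumerate(labels):
        # p <= bins[k] corresponds to score >= cut[k]; the previous,
        # stricter bin's score cutoff is the exclusive upper bound
        lo_score = cut[k]
        hi_score = cut[k - 1] if k > 0 else None
        total = np.zeros(pool.n, dtype=int)
        for m in mats:
            in_bin = (m > _INVALID_CUTOFF) & (m >= lo_score)
            if hi_score is not None:
                in_bin &= m < hi_score
            total += in_bin.sum(axis=1)
        cols[lab] = total
    out = pd.DataFrame(cols, index=pd.Index(pool.seq_ids, name="seq_id"))
    out.attrs["n_windows"] = int(starts.size)
    if starts.size == 0:
        out[:] = np.nan
    return out


def compare_clusters(
    pool_b: AlignedPool,
    pool_u: AlignedPool,
    pfm: PFM,
    bg: Background,
    bins=DEFAULT_BINS,
    strands: str = "both",
    scorer: Scorer | None = None,
) -> pd.DataFrame:
    """Rank-test comparison of bound vs unbound cluster counts per bin."""
    scorer = scorer or Scorer(pfm, bg)
    cb = count_clusters(pool_b, pfm, bg, bins, strands, scorer)
    cu = count_clusters(pool_u, pfm, bg, bins, strands, scorer)
    rows = []
    for col in cb.columns:
        b, u = cb[col].to_numpy(float), cu[col].to_numpy(float)
        b, u = b[~np.isnan(b)], u[~np.isnan(u)]
        if b.size == 0 or u.size == 0 or (b.max(initial=0) == 0 and u.max(initial=0) == 0):
            pg = pl = 1.0
        else:
            pg = float(sstats.mannwhitneyu(b, u, alternative="greater").pvalue)
            pl = float(sstats.mannwhitneyu(b, u, alternative="less").pvalue)
        rows.append(
            {
                "bin": col,
                "mean_bound": float(np.mean(b)) if b.size else np.nan,
                "mean_unbound": float(np.mean(u)) if u.size else np.nan,
                "p_greater": pg,
                "p_less": pl,
            }
        )
    return pd.DataFrame(rows)


def env_scores(
    pool: AlignedPool,
    pfm: PFM,
    bg: Background,
    strands: str = "both",
    exclusion: int = 0,
    scorer: Scorer | None = None,
) -> np.ndarray:
    """Homotypic-environment score per sequence: mean log-odds (bits)
    over all eligible off-core windows, best strand per window when
    ``strands='both'``.  NaN where a sequence has no eligible window."""
    scorer = scorer or Scorer(pfm, bg)
    fwd, rev, starts = _window_scores(pool, scorer, strands, exclusion)
    if starts.size == 0:
        return np.full(pool.n, np.nan)
    valid = fwd > _INVALID_CUTOFF
    sc = scorer.to_bits(fwd)
    if rev is not None:
        sc = np.maximum(sc, scorer.to_bits(rev))
        valid &= rev > _INVALID_CUTOFF
    sc = np.where(valid, sc, np.nan)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(sc, axis=1)
    return out


def env_similarity(
    record_codes: np.ndarray,
    pool_like: AlignedPool,
    pfm: PFM,
    bg: Background,
    strands: str = "both",
) -> float:
    """Environment score of a single aligned record (frame of
    ``pool_like``)."""
    tmp = replace(
        pool_like,
        codes=np.atleast_2d(record_codes),
        seq_ids=["record"],
        motif_scores=None,
        motif_strands=None,
        mask=None,
    )
    return float(env_scores(tmp, pfm, bg, strands)[0])


def cluster_sum_scores(
    pool: AlignedPool,
    pfm: PFM,
    bg: Background,
    p_cutoff: float = 0.001,
    strands: str = "both",
    exclusion: int = 0,
    scorer: Scorer | None = None,
) -> np.ndarray:
    """Per-sequence sum of off-core window log-odds scores (bits) with
    exact p-value <= ``p_cutoff`` (the homotypic-cluster model feature);
    0 when no window qualifies."""
    scorer = scorer or Scorer(pfm, bg)
    fwd, rev, starts = _window_scores(pool, scorer, strands, exclusion)
    if starts.size == 0:
        return np.zeros(pool.n)
    cut = scorer.int_cutoff(p_cutoff)
    total = np.zeros(pool.n)
    mats = [fwd] if rev is None else [fwd, rev]
    for m in mats:
        qual = (m > _INVALID_CUTOFF) & (m >= cut)
        total += np.where(qual, scorer.to_bits(m), 0.0).sum(axis=1)
    return total


def _hit_position_mask(
    pool: AlignedPool, scorer: Scorer, p_cutoff: float, strands: str
) -> np.ndarray:
    """Boolean (n, frame_len): positions covered by any off-core hit
    with p <= cutoff."""
    fwd, rev, starts = _window_scores(pool, scorer, strands)
    L = scorer.pfm.length
    cut = scorer.int_cutoff(p_cutoff)
    mask = np.zeros(pool.codes.shape, dtype=bool)
    if starts.size == 0:
        return mask
    mats = [fwd] if rev is None else [fwd, rev]
    hit_any = np.zeros((pool.n, starts.size), dtype=bool)
    for m in mats:
        hit_any |= (m > _INVALID_CUTOFF) & (m >= cut)
    rows, wins = np.nonzero(hit_any)
    for r, w in zip(rows, wins):
        s = starts[w]
        mask[r, s : s + L] = True
    return mask


def mask_motif_matches(
    pool: AlignedPool,
    pfm: PFM,
    bg: Background,
    p_cutoff: float = 0.001,
    strands: str = "both",
    scorer: Scorer | None = None,
) -> AlignedPool:
    """Flag positions covered by significant off-core motif matches as
    excluded; positional statistics then skip them per sequence."""
    scorer = scorer or Scorer(pfm, bg)
    new_mask = _hit_position_mask(pool, scorer, p_cutoff, strands)
    if pool.mask is not None:
        new_mask |= pool.mask
    return replace(pool, mask=new_mask)


def drop_motif_sequences(
    pool: AlignedPool,
    pfm: PFM,
    bg: Background,
    p_cutoff: float = 0.001,
    strands: str = "both",
    scorer: Scorer | None = None,
) -> tuple[AlignedPool, dict]:
    """Remove every sequence with at least one significant off-core
    motif match; returns (subset pool, report)."""
    scorer = scorer or Scorer(pfm, bg)
    fwd, rev, starts = _window_scores(pool, scorer, strands)
    cut = scorer.int_cutoff(p_cutoff)
    has_hit = np.zeros(pool.n, dtype=bool)
    if starts.size:
        mats = [fwd] if rev is None else [fwd, rev]
        for m in mats:
            has_hit |= ((m > _INVALID_CUTOFF) & (m >= cut)).any(axis=1)
    keep = np.nonzero(~has_hit)[0]
    report = {"kept": int(keep.size), "dropped": int(pool.n - keep.size)}
    return pool.subset(keep), report
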