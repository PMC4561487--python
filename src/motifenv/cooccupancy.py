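"""TF-pair co-occupancy of motif sites and GC-preference similarity.

Co-occupancy of a TF pair (A, B) is the fraction of A's motif sites
that lie within a proximity window (default 300 bp) of some B site;
site pairs that overlap by at least one bp are discarded first, since
related TFs often share near-identical motifs.  The similarity of two
TFs' GC-environment preferences is summarized as a signed, normalized
ratio of their average positional significance scores.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based half-open
    end: int
    tf: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("interval start must be < end")


@dataclass
class CooccupancyRecord:
    tf_a: str
    tf_b: str
    frac_a_near_b: float
    n_a_used: int
    n_discarded_overlap: int
    gc_similarity: float | None = None


def _to_frame(sites) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        df = sites[["chrom", "start", "end"]].copy()
    else:
        df = pd.DataFrame(
            [(s.chrom, s.start, s.end) for s in sites],
            columns=["chrom", "start", "end"],
        )
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def proximity_fraction(
    sites_a,
    sites_b,
    window: int = 300,
    mode: str = "edge",
    tf_a: str = "A",
    tf_b: str = "B",
) -> CooccupancyRecord:
    """Fraction of A sites within ``window`` bp of a B site.

    Overlapping (>= 1 shared bp) A/B pairs remove the A site from both
    numerator and denominator.  ``mode='edge'`` measures the gap between
    the closest interval edges; ``mode='midpoint'`` the distance between
    midpoints.  An empty denominator yields a NaN fraction.
    """
    a = _to_frame(sites_a)
    b = _to_frame(sites_b)
    n_near = 0
    n_used = 0
    n_drop = 0
    for chrom, agrp in a.groupby("chrom", sort=False):
        bgrp = b[b["chrom"] == chrom]
        if bgrp.empty:
            n_used += len(agrp)
            continue
        bs = bgrp["start"].to_numpy()
        be = bgrp["end"].to_numpy()
        for s, e in zip(agrp["start"].to_numpy(), agrp["end"].to_numpy()):
            overlap = np.any((bs < e) & (be > s))
            if overlap:
                n_drop += 1
                continue
            n_used += 1
            if mode == "edge":
                gap = np.minimum(np.abs(bs - e), np.abs(s - be)).min()
            elif mode == "midpoint":
                gap = np.abs((bs + be) / 2.0 - (s + e) / 2.0).min()
            else:
                raise ValueError(f"unknown distance mode {mode!r}")
            if gap <= window:
                n_near += 1
    frac = n_near / n_used if n_used else float("nan")
    return CooccupancyRecord(tf_a, tf_b, frac, n_used, n_drop)


def gc_similarity(stats_a: pd.DataFrame, stats_b: pd.DataFrame) -> tuple[float, bool]:
    """Signed similarity of two GC PositionStats profiles in [-1, 1].

    Each profile is summarized by the mean signed Δ[−log10 q] over
    positions; the ratio puts the larger-magnitude summary in the
    denominator, so 1 means equal direction and strength and negative
    values mean opposite preferences.  Returns (ratio, degenerate):
    degenerate is True when both profiles are null (ratio defined as 1).
    """
    sa = float(np.mean(stats_a["delta"]))
    sb = float(np.mean(stats_b["delta"]))
    if sa == 0.0 and sb == 0.0:
        return 1.0, True
    num, den = (sa, sb) if abs(sa) <= abs(sb) else (sb, sa)
    return num / den, False


def cooccupancy_matrix(
    sites_by_tf: dict[str, list],
    window: int = 300,
    mode: str = "edge",
    gc_stats_by_tf: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Long-format co-occupancy records for every ordered TF pair."""
    rows = []
    for tf_a in sites_by_tf:
        for tf_b in sites_by_tf:
            if tf_a == tf_b:
                continue
            rec = proximity_fraction(
                sites_by_tf[tf_a], sites_by_tf[tf_b], window, mode, tf_a, tf_b
            )
            sim = np.nan
            if gc_stats_by_tf is not None:
                sim, _ = gc_similarity(gc_stats_by_tf[tf_a], gc_stats_by_tf[tf_b])
            rows.append(
                {
                    "tf_a": tf_a,
                    "tf_b": tf_b,
                    "frac_a_near_b": rec.frac_a_near_b,
                    "n_a_used": rec.n_a_used,
                    "n_discarded_overlap": rec.n_discarded_overlap,
                    "gc_similarity": sim,
                }
            )
    return pd.DataFrame(rows)


def family_partition(
    records: pd.DataFrame, family_map: dict[str, str]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Split pairwise fractions into within- vs between-family pairs.

    ``records`` is the long-format table from
    :func:`cooccupancy_matrix`; unordered pairs are averaged over both
    directions.  Returns (within, between, two-sided rank-test p)."""
    frac = {}
    for _, r in records.iterrows():
        key = tuple(sorted((r["tf_a"], r["tf_b"])))
        frac.setdefault(key, []).append(r["frac_a_near_b"])
    within, between = [], []
    for (ta, tb), vals in frac.items():
        v = float(np.nanmean(vals))
        if np.isnan(v):
            continue
        if family_map[ta] == family_map[tb]:
            within.append(v)
        else:
            between.append(v)
    within = np.asarray(within)
    between = np.asarray(between)
    if within.size == 0 or between.size == 0:
        return within, between, float("nan")
    p = float(sstats.mannwhitneyu(within, between, alternative="two-sided").pvalue)
    return within, between, p


def read_sites_bed(path) -> dict[str, list[GenomicInterval]]:
    """Read motif sites from BED (chrom, start, end, tf_name)."""
    out: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"BED line {ln}: need 4 columns (chrom start end tf)")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[3])
            out.setdefault(iv.tf, []).append(iv)
    return out
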