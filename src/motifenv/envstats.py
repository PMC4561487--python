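"""Per-position comparison of bound vs unbound motif environments.

For every flank position (core block and two adjacent bp excluded) a
one-sided rank test compares the feature values of the bound and
unbound pools in both directions; the two one-sided p-value families
are FDR-corrected separately and combined into a signed significance
score delta = Δ[−log10 q], positive where the bound pool is higher.
A TF is called as preferring a high-GC (or high-AT) environment when at
least ``min_positions`` positions are significant with a consistent
sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .scan import AlignedPool
from .seqcodec import N_CODE

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
NUCLEOTIDE_FEATURES = ("GC", "A", "C", "G", "T")


def position_feature_matrix(
    pool: AlignedPool, feature: str = "GC"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence, per-flank-position indicator matrix for a base class.

    GC is the indicator of base in {G, C}; single-base features the
    indicator of that base.  Undefined (N/padded) and masked cells are
    NaN.  Returns (matrix [n x P], relative positions [P]).
    """
    cols, positions = pool.flank_columns()
    if cols.size == 0:
        raise ValueError("pool has no usable flank positions")
    sub = pool.codes[:, cols]
    if feature == "GC":
        vals = np.where((sub == 1) | (sub == 2), 1.0, 0.0)
    elif feature in _BASE_CODE:
        vals = np.where(sub == _BASE_CODE[feature], 1.0, 0.0)
    else:
        raise ValueError(f"unknown nucleotide feature {feature!r}")
    vals = np.where(sub == N_CODE, np.nan, vals)
    if pool.mask is not None:
        vals = np.where(pool.mask[:, cols], np.nan, vals)
    return vals, positions


def compare_position(
    bound_col: np.ndarray,
    unbound_col: np.ndarray,
    test: str = "rank_sum",
) -> tuple[float, float]:
    """One-sided p-values (bound > unbound, bound < unbound) at one position.

    ``rank_sum`` is the unpaired Mann-Whitney test; ``signed_rank`` pairs
    sequences by index (requires size-matched pools).  All-tied columns
    give p = 1 on both sides.
    """
    b = np.asarray(bound_col, dtype=float)
    u = np.asarray(unbound_col, dtype=float)
    b, u = b[~np.isnan(b)], u[~np.isnan(u)]
    if b.size == 0 or u.size == 0:
        raise ValueError("empty column")
    if test == "rank_sum":
        if np.all(b == b[0]) and np.all(u == b[0]):
            return 1.0, 1.0
        if b.size + u.size <= 20:
            return _exact_ranksum(b, u)
        g = sstats.mannwhitneyu(b, u, alternative="greater").pvalue
        l = sstats.mannwhitneyu(b, u, alternative="less").pvalue
        return float(g), float(l)
    if test == "signed_rank":
        if b.size != u.size:
            raise ValueError("signed_rank requires size-matched pools")
        d = b - u
        if np.all(d == 0):
            return 1.0, 1.0
        g = sstats.wilcoxon(d, alternative="greater").pvalue
        l = sstats.wilcoxon(d, alternative="less").pvalue
        return float(g), float(l)
    raise ValueError(f"unknown test {test!r}")


def _exact_ranksum(b: np.ndarray, u: np.ndarray) -> tuple[float, float]:
    """Exact one-sided rank-sum p-values by enumerating every label
    permutation (mid-ranks, so ties are handled exactly)."""
    from itertools import combinations

    pooled = np.concatenate([b, u])
    ranks = sstats.rankdata(pooled)
    obs = ranks[: b.size].sum()
    n = pooled.size
    stats_all = np.array(
        [ranks[list(c)].sum() for c in combinations(range(n), b.size)]
    )
    eps = 1e-9
    p_greater = float(np.mean(stats_all >= obs - eps))
    p_less = float(np.mean(stats_all <= obs + eps))
    return p_greater, p_less


def fdr_qvalues(pvalues: np.ndarray, method: str = "storey") -> np.ndarray:
    """FDR q-values: Benjamini-Hochberg step-up, or Storey with pi0
    estimated at lambda = 0.5 (q = pi0 * BH, clipped to (0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    if method == "BH":
        return bh
    if method == "storey":
        lam = 0.5
        pi0 = np.mean(p > lam) / (1.0 - lam)
        pi0 = min(1.0, max(pi0, 1.0 / p.size))
        return np.clip(pi0 * bh, np.finfo(float).tiny, 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def delta_from_q(mean_b, mean_u, q_greater, q_less):
    """Signed Δ[−log10 q]: positive where the bound pool is higher."""
    delta = np.zeros_like(np.asarray(q_greater, dtype=float))
    hi = np.asarray(mean_b) > np.asarray(mean_u)
    lo = np.asarray(mean_b) < np.asarray(mean_u)
    delta[hi] = -np.log10(np.asarray(q_greater)[hi])
    delta[lo] = np.log10(np.asarray(q_less)[lo])
    return delta


def delta_profile_from_matrices(
    mat_b: np.ndarray,
    mat_u: np.ndarray,
    positions: np.ndarray,
    feature: str,
    test: str = "rank_sum",
    fdr_method: str = "storey",
    min_n: int = 10,
) -> pd.DataFrame:
    """Positional bound-vs-unbound comparison of two [n x P] feature
    matrices (NaN = undefined); the engine behind all profile features."""
    if mat_b.shape[1] != mat_u.shape[1] or mat_b.shape[1] != positions.size:
        raise ValueError("bound/unbound matrices have mismatched frames")
    n_b = np.sum(~np.isnan(mat_b), axis=0)
    n_u = np.sum(~np.isnan(mat_u), axis=0)
    usable = (n_b >= min_n) & (n_u >= min_n)
    if not np.any(usable):
        raise ValueError("no position has enough defined values in both pools")

    mb = mat_b[:, usable]
    mu = mat_u[:, usable]
    if test == "rank_sum":
        with np.errstate(invalid="ignore"):
            pg = sstats.mannwhitneyu(
                mb, mu, axis=0, nan_policy="omit", alternative="greater"
            ).pvalue
            pl = sstats.mannwhitneyu(
                mb, mu, axis=0, nan_policy="omit", alternative="less"
            ).pvalue
        pg = np.asarray(pg, dtype=float)
        pl = np.asarray(pl, dtype=float)
        # columns with all values tied across both pools carry no evidence
        allsame = np.array(
            [
                np.nanmax(np.concatenate([mb[:, j], mu[:, j]]))
                == np.nanmin(np.concatenate([mb[:, j], mu[:, j]]))
                for j in range(mb.shape[1])
            ]
        )
        pg[allsame] = 1.0
        pl[allsame] = 1.0
    else:
        pg = np.empty(mb.shape[1])
        pl = np.empty(mb.shape[1])
        for j in range(mb.shape[1]):
            pg[j], pl[j] = compare_position(mb[:, j], mu[:, j], test=test)

    pg = np.clip(pg, np.finfo(float).tiny, 1.0)
    pl = np.clip(pl, np.finfo(float).tiny, 1.0)
    qg = fdr_qvalues(pg, method=fdr_method)
    ql = fdr_qvalues(pl, method=fdr_method)
    mean_b = np.nanmean(mb, axis=0)
    mean_u = np.nanmean(mu, axis=0)
    out = pd.DataFrame(
        {
            "position": positions[usable],
            "mean_bound": mean_b,
            "mean_unbound": mean_u,
            "n_bound": n_b[usable],
            "n_unbound": n_u[usable],
            "p_greater": pg,
            "p_less": pl,
            "q_greater": qg,
            "q_less": ql,
            "delta": delta_from_q(mean_b, mean_u, qg, ql),
        }
    )
    out.attrs["feature"] = feature
    out.attrs["test"] = test
    out.attrs["fdr_method"] = fdr_method
    return out


def delta_profile(
    pool_b: AlignedPool,
    pool_u: AlignedPool,
    feature: str = "GC",
    test: str = "rank_sum",
    fdr_method: str = "storey",
    min_n: int = 10,
) -> pd.DataFrame:
    """PositionStats table for a nucleotide-content feature."""
    mat_b, pos_b = position_feature_matrix(pool_b, feature)
    mat_u, pos_u = position_feature_matrix(pool_u, feature)
    if pos_b.size != pos_u.size or np.any(pos_b != pos_u):
        raise ValueError("pools have incompatible alignment frames")
    return delta_profile_from_matrices(
        mat_b, mat_u, pos_b, feature, test=test, fdr_method=fdr_method, min_n=min_n
    )


@dataclass(frozen=True)
class PreferenceCall:
    tf: str
    call: str                    # 'high-GC', 'high-AT', or 'none'
    n_significant_positions: int
    mean_delta_gc: float         # bound - unbound, percentage points


def call_preference(
    stats: pd.DataFrame,
    tf: str = "TF",
    min_positions: int = 5,
    q_threshold: float = 0.05,
) -> PreferenceCall:
    """GC-environment preference call from a GC PositionStats table.

    high-GC when >= ``min_positions`` positions are significantly
    bound-higher (q_greater <= threshold); high-AT analogously from the
    other one-sided family; whichever side has more significant
    positions wins if both qualify.
    """
    n_hi = int(np.sum(stats["q_greater"] <= q_threshold))
    n_lo = int(np.sum(stats["q_less"] <= q_threshold))
    mean_delta = 100.0 * float(
        np.mean(stats["mean_bound"]) - np.mean(stats["mean_unbound"])
    )
    if n_hi >= min_positions and n_hi >= n_lo:
        return PreferenceCall(tf, "high-GC", n_hi, mean_delta)
    if n_lo >= min_positions:
        return PreferenceCall(tf, "high-AT", n_lo, mean_delta)
    return PreferenceCall(tf, "none", max(n_hi, n_lo), mean_delta)


def write_position_stats(path, stats: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# feature={stats.attrs.get('feature', '?')} "
            f"test={stats.attrs.get('test', '?')} "
            f"fdr={stats.attrs.get('fdr_method', '?')}\n"
        )
        stats.to_csv(fh, sep="\t", index=False, float_format="%.6g")
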