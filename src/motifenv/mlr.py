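"""Environment-feature regression models for bound/unbound discrimination.

Four features are extracted from the flanks of each aligned sequence
(core motif and two adjacent bp excluded): mean GC fraction, mean
propeller twist, mean motif-similarity of flank windows (homotypic
environment), and the summed log-odds of significant flank hits
(homotypic clusters).  An L2-regularized *linear* regression on 0/1
labels — multiple linear regression as named, not logistic — is scored
by AUROC under nested stratified cross-validation; the ridge penalty is
picked per outer fold by an inner CV.  Motif-strength matching equates
the core-motif score distributions of the two pools first, so the
models see only the environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.linear_model import Ridge
from sklearn.model_selection import StratifiedKFold

from .homotypy import cluster_sum_scores, env_scores
from .envstats import position_feature_matrix
from .pfm import PFM, Background, Scorer
from .scan import AlignedPool
from .shape import ShapeTable, pool_profile_matrix

FEATURES = ("gc", "prot", "env", "clusters")
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 3, 13))

MODEL_SUBSETS = {
    "gc": ("gc",),
    "prot": ("prot",),
    "env": ("env",),
    "clusters": ("clusters",),
    "gc+prot": ("gc", "prot"),
    "gc+env": ("gc", "env"),
    "gc+clusters": ("gc", "clusters"),
    "combined": ("gc", "prot", "env"),
}


def extract_features(
    pool: AlignedPool,
    pfm: PFM,
    bg: Background,
    shape_table: ShapeTable,
    strands: str = "both",
    p_sig: float = 0.001,
    scorer: Scorer | None = None,
) -> pd.DataFrame:
    """Per-sequence environment feature vectors.

    Columns: gc, prot, env, clusters, motif_score (the core score, kept
    for strength matching only, never used as a model feature).
    """
    scorer = scorer or Scorer(pfm, bg)
    excl = pool.core_exclusion
    gc_mat, _ = position_feature_matrix(pool, "GC")
    prot_mat, _ = pool_profile_matrix(pool, shape_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gc = np.nanmean(gc_mat, axis=1)
        prot = np.nanmean(prot_mat, axis=1)
    env = env_scores(pool, pfm, bg, strands=strands, exclusion=excl, scorer=scorer)
    clusters = cluster_sum_scores(
        pool, pfm, bg, p_cutoff=p_sig, strands=strands, exclusion=excl, scorer=scorer
    )
    motif_score = (
        pool.motif_scores
        if pool.motif_scores is not None
        else np.full(pool.n, np.nan)
    )
    return pd.DataFrame(
        {
            "seq_id": pool.seq_ids,
            "gc": gc,
            "prot": prot,
            "env": env,
            "clusters": clusters,
            "motif_score": motif_score,
        }
    )


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outscores a random negative,
    ties counted 1/2 (Mann-Whitney form)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = sstats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def match_motif_strength(
    pool_b: AlignedPool,
    pool_u: AlignedPool,
    n_bins: int = 10,
    seed: int = 0,
) -> tuple[AlignedPool, AlignedPool, dict]:
    """Subsample both pools so their core-motif score distributions match.

    Scores are cut into quantile bins of the pooled distribution;
    within each bin both groups are subsampled to the common minimum.
    Bins empty in one group are dropped and reported.
    """
    if pool_b.motif_scores is None or pool_u.motif_scores is None:
        raise ValueError("pools need motif scores for strength matching")
    rng = np.random.default_rng(seed)
    all_scores = np.concatenate([pool_b.motif_scores, pool_u.motif_scores])
    edges = np.unique(np.quantile(all_scores, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:
        # degenerate score distribution: plain size matching
        m = min(pool_b.n, pool_u.n)
        idx = np.arange(m)
        return (
            pool_b.subset(idx),
            pool_u.subset(idx),
            {"n_matched": int(m), "dropped_bins": 0, "balance_p": 1.0},
        )
    # digitize into len(edges)-1 bins; rightmost edge inclusive
    bin_b = np.clip(np.searchsorted(edges, pool_b.motif_scores, side="right") - 1, 0, len(edges) - 2)
    bin_u = np.clip(np.searchsorted(edges, pool_u.motif_scores, side="right") - 1, 0, len(edges) - 2)
    keep_b, keep_u = [], []
    dropped_bins = 0
    for k in range(len(edges) - 1):
        ib = np.nonzero(bin_b == k)[0]
        iu = np.nonzero(bin_u == k)[0]
        if ib.size == 0 or iu.size == 0:
            dropped_bins += 1
            continue
        m = min(ib.size, iu.size)
        if ib.size == iu.size:
            sel_b, sel_u = ib, iu
        else:
            # greedy nearest-score pairing within the bin keeps the
            # retained score distributions tight, not just same-sized
            small, large, small_scores, large_scores = (
                (ib, iu, pool_b.motif_scores[ib], pool_u.motif_scores[iu])
                if ib.size <= iu.size
                else (iu, ib, pool_u.motif_scores[iu], pool_b.motif_scores[ib])
            )
            order_s = np.argsort(small_scores, kind="mergesort")
            order_l = np.argsort(large_scores, kind="mergesort")
            picked = []
            j = 0
            for pos in order_s:
                target = small_scores[pos]
                while (
                    j + 1 < order_l.size
                    and abs(large_scores[order_l[j + 1]] - target)
                    <= abs(large_scores[order_l[j]] - target)
                ):
                    j += 1
                picked.append(order_l[j])
                if j + 1 < order_l.size:
                    j += 1
            matched_large = large[np.array(picked[:m])]
            if ib.size <= iu.size:
                sel_b, sel_u = small[order_s[:m]], matched_large
            else:
                sel_b, sel_u = matched_large, small[order_s[:m]]
        keep_b.append(sel_b)
        keep_u.append(sel_u)
    if not keep_b:
        raise ValueError("no motif-strength bin is populated in both pools")
    idx_b = np.sort(np.concatenate(keep_b))
    idx_u = np.sort(np.concatenate(keep_u))
    out_b, out_u = pool_b.subset(idx_b), pool_u.subset(idx_u)
    if out_b.n > 1 and np.ptp(np.concatenate([out_b.motif_scores, out_u.motif_scores])) > 0:
        p_balance = float(
            sstats.mannwhitneyu(
                out_b.motif_scores, out_u.motif_scores, alternative="two-sided"
            ).pvalue
        )
    else:
        p_balance = 1.0
    report = {
        "n_matched": int(out_b.n),
        "dropped_bins": dropped_bins,
        "balance_p": p_balance,
    }
    return out_b, out_u, report


@dataclass
class CVResult:
    model_name: str
    features: tuple[str, ...]
    auroc_per_fold: list[float]
    lambda_per_fold: list[float]
    null_cutoff: float | None = None

    @property
    def auroc_mean(self) -> float:
        return float(np.mean(self.auroc_per_fold))

    def as_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "features": list(self.features),
            "auroc_per_fold": [round(a, 6) for a in self.auroc_per_fold],
            "auroc_mean": round(self.auroc_mean, 6),
            "lambda_per_fold": self.lambda_per_fold,
            "null_cutoff": self.null_cutoff,
        }


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    zero = sd == 0
    if np.any(zero):
        warnings.warn("constant feature column; it carries no information")
        sd = np.where(zero, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd


def _fit_predict(X_tr, y_tr, X_te, lam: float) -> np.ndarray:
    Xs, Xt = _standardize(X_tr, X_te)
    model = Ridge(alpha=lam, fit_intercept=True)
    model.fit(Xs, y_tr)
    return model.predict(Xt)


def _inner_select_lambda(X, y, lambda_grid, inner_folds, rng_seed) -> float:
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=rng_seed)
    mean_auc = []
    splits = list(skf.split(X, y))
    for lam in lambda_grid:
        aucs = []
        for tr, te in splits:
            pred = _fit_predict(X[tr], y[tr], X[te], lam)
            aucs.append(auroc(pred, y[te]))
        mean_auc.append(np.mean(aucs))
    return float(lambda_grid[int(np.argmax(mean_auc))])


def ridge_cv(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    feature_subset: tuple[str, ...] = FEATURES,
    folds: int = 10,
    inner_folds: int = 10,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    model_name: str | None = None,
) -> CVResult:
    """Nested stratified CV of the ridge model on a feature subset.

    Outer folds give held-out AUROCs; the penalty is chosen per outer
    fold by an inner CV on the training part.  Deterministic for a
    given (seed, folds, grid).
    """
    X = _as_matrix(features, feature_subset)
    y = np.asarray(labels, dtype=float)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs, lams = [], []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        lam = _inner_select_lambda(X[tr], y[tr], lambda_grid, inner_folds, seed + 1000 + k)
        pred = _fit_predict(X[tr], y[tr], X[te], lam)
        aucs.append(auroc(pred, y[te]))
        lams.append(lam)
    return CVResult(
        model_name=model_name or "+".join(feature_subset),
        features=tuple(feature_subset),
        auroc_per_fold=[float(a) for a in aucs],
        lambda_per_fold=lams,
    )


def _as_matrix(features, feature_subset) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        X = features[list(feature_subset)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if np.any(np.isnan(X)):
        raise ValueError("feature matrix contains NaN; drop incomplete records first")
    return X


def shuffled_null(
    features,
    labels,
    feature_subset: tuple[str, ...] = FEATURES,
    n_shuffles: int = 5,
    seed: int = 0,
    folds: int = 10,
    inner_folds: int = 10,
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> float:
    """Empirical significance cutoff: the maximum CV AUROC over
    label-shuffled refits of the same model."""
    y = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(seed)
    best = 0.0
    for s in range(n_shuffles):
        perm = rng.permutation(y.size)
        res = ridge_cv(
            features,
            y[perm],
            feature_subset,
            folds=folds,
            inner_folds=inner_folds,
            lambda_grid=lambda_grid,
            seed=seed + 7919 * (s + 1),
            model_name="shuffled",
        )
        best = max(best, res.auroc_mean)
    return best


def transfer_predict(
    train_features,
    train_labels,
    test_features,
    test_labels,
    feature_subset: tuple[str, ...] = ("gc", "prot", "env"),
    inner_folds: int = 10,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
) -> float:
    """Fit on one domain (penalty by CV on the training data only,
    standardization learned on train) and report AUROC on the other."""
    X_tr = _as_matrix(train_features, feature_subset)
    X_te = _as_matrix(test_features, feature_subset)
    y_tr = np.asarray(train_labels, dtype=float)
    y_te = np.asarray(test_labels, dtype=float)
    lam = _inner_select_lambda(X_tr, y_tr, np.asarray(lambda_grid), inner_folds, seed)
    pred = _fit_predict(X_tr, y_tr, X_te, lam)
    return auroc(pred, y_te)
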