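"""End-to-end orchestration: probe-pool and genomic flows.

The in vitro flow aligns bound/unbound probe pools on the core motif
and runs the positional, homotypic, shape and prediction analyses.
The genomic flow additionally refines an IUPAC seed into a PFM, splits
genome-wide motif hits into bound (inside ChIP peaks) and unbound
(outside), restricted to open chromatin, and can drop hits in
GC-extreme promoters before the same downstream analyses.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import seqcodec
from .envstats import (
    call_preference,
    delta_profile,
    write_position_stats,
)
from .hmm import MODES, hmm_auroc
from .homotypy import compare_clusters, env_scores
from .mlr import (
    MODEL_SUBSETS,
    extract_features,
    match_motif_strength,
    ridge_cv,
    shuffled_null,
)
from .pfm import PFM, Background, Scorer, read_pfm
from .scan import AlignedPool, align_best_hit, match_sizes, iter_fasta
from .shape import compare_shape, load_shape_table, synthetic_table
from .simulate import SyntheticConfig, generate_genome, generate_pools, write_truth_json

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def refine_iupac_to_pfm(
    peak_seqs,
    iupac_seed: str,
    max_mismatch: int = 1,
    pseudocount: float = 0.01,
    name: str | None = None,
) -> PFM:
    """Refine an IUPAC seed into a PFM from its occurrences in peaks.

    All occurrences with at most ``max_mismatch`` mismatches on either
    strand are stacked (reverse-strand occurrences as their reverse
    complement) and column frequencies taken.  Degenerate codes match
    every encoded base with zero mismatches.
    """
    seed = iupac_seed.upper()
    try:
        allowed = [IUPAC[c] for c in seed]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r} in seed") from exc
    L = len(seed)
    match = np.zeros((L, 5), dtype=np.int64)
    for j, bases in enumerate(allowed):
        for b in bases:
            match[j, seqcodec.encode(b)[0]] = 1
    rc_match = match[::-1, [3, 2, 1, 0, 4]]

    counts = np.zeros((L, 4), dtype=np.int64)
    n_occ = 0
    for item in peak_seqs:
        seq = item[1] if isinstance(item, tuple) else item
        codes = seqcodec.encode(seq) if isinstance(seq, str) else np.asarray(seq)
        if codes.size < L:
            continue
        W = codes.size - L + 1
        for mat, rc in ((match, False), (rc_match, True)):
            hits = np.zeros(W, dtype=np.int64)
            ok = np.ones(W, dtype=bool)
            for j in range(L):
                sub = codes[j : j + W]
                hits += mat[j, sub]
                ok &= sub < 4
            for t in np.nonzero(ok & (hits >= L - max_mismatch))[0]:
                window = codes[t : t + L]
                if rc:
                    window = seqcodec.revcomp_codes(window)
                counts[np.arange(L), window] += 1
                n_occ += 1
    if n_occ == 0:
        raise ValueError(f"IUPAC seed {seed!r} has no occurrence in the peaks")
    return PFM.from_counts_or_freq(name or f"refined_{seed}", counts.astype(float), pseudocount)


def split_bound_unbound(
    genome: dict[str, str],
    pfm: PFM,
    peaks,
    dnase,
    bg: Background | None = None,
    p_cutoff: float = 1e-4,
    flank: int = 300,
    core_exclusion: int = 2,
    min_pool_size: int = 1,
    seed: int = 0,
    size_match: bool = True,
) -> tuple[AlignedPool, AlignedPool, dict]:
    """Genome-wide motif hits split into bound/unbound aligned pools.

    A hit must lie fully inside an open-chromatin (DNase) interval; it
    is bound iff its midpoint falls inside a ChIP peak.  Flanks of
    ±``flank`` bp are extracted regardless of the open-chromatin
    boundary; hits whose flanks cross a chromosome end (or contain N)
    are excluded.  Pools are size-matched by default.
    """
    chrom_codes = {c: seqcodec.encode(s) for c, s in genome.items()}
    bg = bg or Background.from_codes(
        np.concatenate([v for v in chrom_codes.values()])
    )
    scorer = Scorer(pfm, bg)
    L = pfm.length
    cutoff = scorer.int_cutoff(p_cutoff)

    dnase_by = _by_chrom(dnase)
    peaks_by = _by_chrom(peaks)

    frames = {"bound": [], "unbound": []}
    ids = {"bound": [], "unbound": []}
    scores = {"bound": [], "unbound": []}
    meta = {"bound": [], "unbound": []}
    n_edge = 0
    for chrom, codes in chrom_codes.items():
        dn = dnase_by.get(chrom, np.empty((0, 2), dtype=int))
        pk = peaks_by.get(chrom, np.empty((0, 2), dtype=int))
        for strand in ("+", "-"):
            win = scorer.window_int_scores(codes, strand=strand)[0]
            for start in np.nonzero(win >= cutoff)[0]:
                start = int(start)
                end = start + L
                if not _inside_any(dn, start, end):
                    continue
                mid = (start + end) / 2.0
                bound = _contains_point(pk, mid)
                lo, hi = start - flank, end + flank
                if lo < 0 or hi > codes.size:
                    n_edge += 1
                    continue
                frame = codes[lo:hi]
                if np.any(frame >= 4):
                    n_edge += 1
                    continue
                if strand == "-":
                    frame = seqcodec.revcomp_codes(frame)
                lab = "bound" if bound else "unbound"
                frames[lab].append(frame)
                ids[lab].append(f"{chrom}:{start}-{end}({strand})")
                scores[lab].append(scorer.to_bits(win[start]))
                meta[lab].append((chrom, start, end, strand))

    if not frames["unbound"]:
        raise ValueError("no unbound motif hits in open chromatin")
    if not frames["bound"]:
        raise ValueError("no bound motif hits in open chromatin")
    pools = {}
    for lab in ("bound", "unbound"):
        pools[lab] = AlignedPool(
            label=lab,
            codes=np.vstack(frames[lab]),
            seq_ids=ids[lab],
            core_start=flank,
            core_len=L,
            flank_up=flank,
            flank_down=flank,
            core_exclusion=core_exclusion,
            motif_scores=np.asarray(scores[lab], dtype=float),
            meta={"hits": meta[lab]},
        )
    report = {
        "bound": pools["bound"].n,
        "unbound": pools["unbound"].n,
        "excluded_edge_or_N": n_edge,
    }
    if size_match:
        b, u = match_sizes(pools["bound"], pools["unbound"], seed)
        _subset_meta(pools["bound"], b)
        _subset_meta(pools["unbound"], u)
        pools["bound"], pools["unbound"] = b, u
    if pools["bound"].n < min_pool_size or pools["unbound"].n < min_pool_size:
        raise ValueError("pools smaller than the configured minimum")
    return pools["bound"], pools["unbound"], report


def _subset_meta(original: AlignedPool, subset: AlignedPool) -> None:
    if "hits" not in original.meta:
        return
    lookup = dict(zip(original.seq_ids, original.meta["hits"]))
    subset.meta = {"hits": [lookup[sid] for sid in subset.seq_ids]}


def _by_chrom(intervals) -> dict[str, np.ndarray]:
    out: dict[str, list] = {}
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        out.setdefault(chrom, []).append((start, end))
    return {c: np.array(sorted(v)) for c, v in out.items()}


def _inside_any(ivs: np.ndarray, start: int, end: int) -> bool:
    if ivs.size == 0:
        return False
    return bool(np.any((ivs[:, 0] <= start) & (ivs[:, 1] >= end)))


def _contains_point(ivs: np.ndarray, x: float) -> bool:
    if ivs.size == 0:
        return False
    return bool(np.any((ivs[:, 0] <= x) & (x < ivs[:, 1])))


def filter_promoter_gc_extremes(
    pool: AlignedPool,
    promoters: pd.DataFrame | None,
    drop_fraction: float = 0.10,
) -> tuple[AlignedPool, dict]:
    """Drop records whose core midpoint lies in a promoter whose GC is
    in the top or bottom ``drop_fraction`` of all promoters.

    ``promoters`` needs columns chrom, start, end, gc; with no
    promoters supplied the pool passes through unchanged.
    """
    if promoters is None or len(promoters) == 0:
        return pool, {"dropped": 0, "kept": pool.n}
    if "hits" not in pool.meta:
        raise ValueError("pool lacks genomic hit coordinates")
    gc = promoters["gc"].to_numpy(dtype=float)
    lo, hi = np.quantile(gc, [drop_fraction, 1.0 - drop_fraction])
    extreme = promoters[(gc <= lo) | (gc >= hi)]
    ext_by = _by_chrom(extreme[["chrom", "start", "end"]].itertuples(index=False))
    keep = []
    for i, (chrom, start, end, _) in enumerate(pool.meta["hits"]):
        mid = (start + end) / 2.0
        if not _contains_point(ext_by.get(chrom, np.empty((0, 2))), mid):
            keep.append(i)
    sub = pool.subset(np.array(keep, dtype=int))
    _subset_meta(pool, sub)
    return sub, {"dropped": pool.n - len(keep), "kept": len(keep)}


# -- full runs ------------------------------------------------------------

DEFAULT_CONFIG = {
    "mode": "invitro",
    "seed": 0,
    "p_align": 1e-4,
    "p_cluster": 1e-3,
    "q_threshold": 0.05,
    "min_positions": 5,
    "min_pool_size": 50,
    "flank_up": 10,
    "flank_down": 10,
    "core_exclusion": 2,
    "pad_incomplete": True,
    "strands": "both",
    "test": "rank_sum",
    "fdr_method": "storey",
    "models": ["gc", "prot", "env", "clusters", "gc+prot", "gc+env", "gc+clusters", "combined"],
    "n_shuffles": 2,
    "folds": 10,
    "inner_folds": 10,
    "hmm_modes": list(MODES),
    "generator": {},
    "shape_table": None,        # path to a pentamer TSV; None -> synthetic
    "run_mlr": True,
    "run_hmm": True,
}


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    gen = dict(cfg["generator"])
    gen.update(user.pop("generator", {}) or {})
    cfg.update(user)
    cfg["generator"] = gen
    return cfg


def run_all(cfg: dict, out_dir: str) -> dict:
    """Execute the full flow for one TF and write numeric outputs.

    Returns a summary dict (also written as summary.json).  All outputs
    are stamped with a hash of the configuration and the master seed,
    and identical (config, seed) reproduce them bit-identically.
    """
    full = dict(DEFAULT_CONFIG)
    gen_cfg = dict(full["generator"])
    gen_cfg.update(cfg.get("generator", {}) or {})
    full.update({k: v for k, v in cfg.items() if k != "generator"})
    full["generator"] = gen_cfg
    os.makedirs(out_dir, exist_ok=True)
    seed = int(full["seed"])
    log: list[str] = []
    summary: dict = {"config_hash": _config_hash(full), "seed": seed, "mode": full["mode"]}

    if full.get("shape_table"):
        table = load_shape_table(full["shape_table"])
    else:
        table = synthetic_table(seed=0)

    # ---- inputs: generate or load -------------------------------------
    if full["mode"] == "invitro":
        if "inputs" in full and full["inputs"]:
            inp = full["inputs"]
            bound = list(iter_fasta(inp["bound_fasta"]))
            unbound = list(iter_fasta(inp["unbound_fasta"]))
            pfm = read_pfm(inp["pfm_meme"])
            truth = None
        else:
            scfg = SyntheticConfig(seed=seed, **gen_cfg)
            bound, unbound, truth = generate_pools(scfg)
            pfm = scfg.resolved_motif()
            write_truth_json(os.path.join(out_dir, "truth.json"), truth)
        bg = Background.uniform()
        strands = full["strands"]
        if strands == "auto":
            strands = "both" if pfm.is_palindromic() else "forward"
        scorer = Scorer(pfm, bg)
        pool_b, rep_b = align_best_hit(
            bound, pfm, bg, p_cutoff=full["p_align"], strands=strands,
            flank_up=full["flank_up"], flank_down=full["flank_down"],
            label="bound", core_exclusion=full["core_exclusion"],
            min_pool_size=full["min_pool_size"],
            pad_incomplete=full["pad_incomplete"], scorer=scorer,
        )
        pool_u, rep_u = align_best_hit(
            unbound, pfm, bg, p_cutoff=full["p_align"], strands=strands,
            flank_up=full["flank_up"], flank_down=full["flank_down"],
            label="unbound", core_exclusion=full["core_exclusion"],
            min_pool_size=full["min_pool_size"],
            pad_incomplete=full["pad_incomplete"], scorer=scorer,
        )
        log.append(f"align bound: {json.dumps(rep_b.as_dict(), sort_keys=True)}")
        log.append(f"align unbound: {json.dumps(rep_u.as_dict(), sort_keys=True)}")
        summary["alignment"] = {"bound": rep_b.as_dict(), "unbound": rep_u.as_dict()}
        raw_bound_codes = [seqcodec.encode(s) for _, s in bound]
    else:
        scfg = SyntheticConfig(seed=seed, **gen_cfg)
        genome, peaks, dnase, sites = generate_genome(scfg)
        pfm = scfg.resolved_motif()
        bg = Background.from_codes(
            np.concatenate([seqcodec.encode(s) for s in genome.values()])
        )
        scorer = Scorer(pfm, bg)
        flank = int(full.get("flank_up", 300))
        pool_b, pool_u, rep = split_bound_unbound(
            genome, pfm, peaks, dnase, bg=bg,
            p_cutoff=full["p_align"], flank=flank,
            core_exclusion=full["core_exclusion"], seed=seed,
        )
        log.append(f"split: {json.dumps(rep, sort_keys=True)}")
        summary["split"] = rep
        raw_bound_codes = list(pool_b.codes)

    pool_b, pool_u = match_sizes(pool_b, pool_u, seed)
    log.append(f"size-matched pools: n={pool_b.n}")
    summary["n_matched"] = pool_b.n

    # ---- positional nucleotide content --------------------------------
    gc_stats = delta_profile(
        pool_b, pool_u, "GC", test=full["test"], fdr_method=full["fdr_method"]
    )
    write_position_stats(os.path.join(out_dir, "gc_position_stats.tsv"), gc_stats)
    pref = call_preference(
        gc_stats, tf=pfm.name,
        min_positions=full["min_positions"], q_threshold=full["q_threshold"],
    )
    summary["gc_preference"] = {
        "call": pref.call,
        "n_significant_positions": pref.n_significant_positions,
        "mean_delta_gc_pp": round(pref.mean_delta_gc, 4),
    }

    # ---- DNA shape -----------------------------------------------------
    shape_stats = compare_shape(
        pool_b, pool_u, table, test=full["test"], fdr_method=full["fdr_method"]
    )
    write_position_stats(os.path.join(out_dir, "propeller_twist_stats.tsv"), shape_stats)
    summary["shape_n_significant"] = int(
        np.sum((shape_stats["q_greater"] <= full["q_threshold"])
               | (shape_stats["q_less"] <= full["q_threshold"]))
    )

    # ---- homotypic clusters and environment ---------------------------
    clusters = compare_clusters(pool_b, pool_u, pfm, bg, strands="both", scorer=scorer)
    clusters.to_csv(
        os.path.join(out_dir, "homotypic_clusters.tsv"), sep="\t",
        index=False, float_format="%.6g",
    )
    env_b = env_scores(pool_b, pfm, bg, strands="both", scorer=scorer)
    env_u = env_scores(pool_u, pfm, bg, strands="both", scorer=scorer)
    eb, eu = env_b[~np.isnan(env_b)], env_u[~np.isnan(env_u)]
    if eb.size and eu.size:
        env_p = float(sstats.mannwhitneyu(eb, eu, alternative="greater").pvalue)
    else:
        env_p = float("nan")
    summary["homotypy"] = {
        "mean_hits_le_0.001_bound": round(float(clusters.iloc[0]["mean_bound"]), 4),
        "mean_hits_le_0.001_unbound": round(float(clusters.iloc[0]["mean_unbound"]), 4),
        "env_mean_bound": round(float(np.mean(eb)), 4) if eb.size else None,
        "env_mean_unbound": round(float(np.mean(eu)), 4) if eu.size else None,
        "env_p_greater": env_p,
    }

    # ---- MLR predictions ----------------------------------------------
    if full["run_mlr"]:
        mb, mu, match_rep = match_motif_strength(pool_b, pool_u, seed=seed)
        log.append(f"motif-strength matching: {json.dumps(match_rep, sort_keys=True)}")
        fb = extract_features(mb, pfm, bg, table, scorer=scorer)
        fu = extract_features(mu, pfm, bg, table, scorer=scorer)
        feats = pd.concat([fb, fu], ignore_index=True)
        labels = np.concatenate([np.ones(len(fb)), np.zeros(len(fu))])
        mlr_out = {}
        min_per_class = 2 * full["folds"]

        def _usable(subset):
            ok = ~feats[list(subset)].isna().any(axis=1)
            y = labels[ok.to_numpy()]
            if min(np.sum(y == 1), np.sum(y == 0)) < min_per_class:
                return None, None
            return feats[ok].reset_index(drop=True), y

        for name in full["models"]:
            sub_feats, sub_labels = _usable(MODEL_SUBSETS[name])
            if sub_feats is None:
                # flanks too short for this model's features (e.g. no
                # off-core window of motif length): skipped, as with the
                # probe-length subset used for homotypy analyses
                log.append(f"mlr model {name}: skipped, too few usable records")
                continue
            res = ridge_cv(
                sub_feats, sub_labels, MODEL_SUBSETS[name],
                folds=full["folds"], inner_folds=full["inner_folds"],
                seed=seed, model_name=name,
            )
            mlr_out[name] = res.as_dict()
        null_feats, null_labels = _usable(MODEL_SUBSETS["combined"])
        if full["n_shuffles"] and null_feats is not None:
            mlr_out["null_cutoff"] = round(
                shuffled_null(
                    null_feats, null_labels, MODEL_SUBSETS["combined"],
                    n_shuffles=full["n_shuffles"], seed=seed,
                    folds=full["folds"], inner_folds=full["inner_folds"],
                ), 6,
            )
        with open(os.path.join(out_dir, "mlr_results.json"), "w") as fh:
            json.dump(mlr_out, fh, indent=1, sort_keys=True)
            fh.write("\n")
        summary["mlr_auroc"] = {
            k: v["auroc_mean"] for k, v in mlr_out.items() if isinstance(v, dict)
        }

    # ---- HMM predictions ----------------------------------------------
    if full["run_hmm"]:
        genomic_beta = Background.from_codes(pool_u.codes)
        bc = pool_b.dense_codes()
        uc = pool_u.dense_codes()
        hmm_out = {}
        for mode in full["hmm_modes"]:
            hmm_out[mode] = round(
                hmm_auroc(bc, uc, pfm, mode=mode, genomic_beta=genomic_beta,
                          scan_bg=bg), 6,
            )
        with open(os.path.join(out_dir, "hmm_results.json"), "w") as fh:
            json.dump(hmm_out, fh, indent=1, sort_keys=True)
            fh.write("\n")
        summary["hmm_auroc"] = hmm_out

    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
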