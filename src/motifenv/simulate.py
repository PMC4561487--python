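"""Synthetic probe pools and toy genomes with planted, recoverable effects.

The generators emulate the statistical structure of the real inputs:

* in vitro — fixed-length probe pools in which every sequence carries
  one core-motif plant at a recorded offset/orientation; bound flanks
  can differ from unbound flanks in GC content (a tunable Δ), carry
  planted weak motifs (homotypic clusters, expected count per
  sequence), and/or have a fraction of positions sampled from the
  motif's average base composition (homotypic environment);
* in vivo — a toy genome with open-chromatin and peak tracks, motif
  instances planted inside peaks (bound, with environment effects) and
  in open chromatin outside peaks (unbound), all coordinates recorded.

Identical (config, seed) gives bit-identical output; every planted
coordinate is returned as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import seqcodec
from .pfm import PFM, Background, Scorer
from .scan import DEFAULT_CORE_EXCLUSION


def random_pfm(
    length: int = 10,
    ic_per_column: float = 1.5,
    gc_target: float = 0.5,
    seed: int = 0,
) -> PFM:
    """Random single-peak PFM hitting a mean per-column information
    content (within 0.1 bits) and column-average GC (within 0.05).

    Each column puts mass 1 - eps on a consensus base and eps/3 on the
    others, with eps solved so the column information content equals
    the target; the number of G/C consensus columns is chosen to hit
    the GC target and their placement randomized.
    """
    if not 0.0 <= ic_per_column <= 2.0:
        raise ValueError("information content per column must be in [0, 2]")
    rng = np.random.default_rng(seed)
    eps = _solve_eps(ic_per_column)
    gc_hi = 1.0 - 2.0 * eps / 3.0   # column GC when consensus is G or C
    gc_lo = 2.0 * eps / 3.0
    if abs(gc_hi - gc_lo) < 1e-9:
        n_gc = length // 2
    else:
        n_gc = int(round(length * (gc_target - gc_lo) / (gc_hi - gc_lo)))
        n_gc = min(max(n_gc, 0), length)
    is_gc = np.zeros(length, dtype=bool)
    is_gc[rng.choice(length, size=n_gc, replace=False)] = True
    freq = np.empty((length, 4))
    for i in range(length):
        cons = rng.choice([1, 2]) if is_gc[i] else rng.choice([0, 3])
        col = np.full(4, eps / 3.0)
        col[cons] = 1.0 - eps
        freq[i] = col
    return PFM(name=f"synthetic_L{length}", freq=freq)


def _solve_eps(ic: float) -> float:
    """Solve 2 - H(eps) = ic for the single-peak column entropy H."""

    def column_ic(eps):
        if eps <= 0:
            return 2.0
        if eps >= 0.75:
            return 0.0
        h = -(1 - eps) * np.log2(1 - eps) - eps * np.log2(eps / 3.0)
        return 2.0 - h

    lo, hi = 0.0, 0.75
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if column_ic(mid) > ic:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class SyntheticConfig:
    """Study conditions for the in vitro pool generator (and the toy
    genome, for the fields prefixed ``genome``/``peak``/``open``)."""

    seed: int = 0
    n_bound: int = 2000
    n_unbound: int = 2000
    probe_len: int = 20                    # dominant HT-SELEX probe length
    motif: PFM | None = None               # default: random_pfm(10, 1.5, 0.5)
    flank_gc_bound: float = 0.5
    flank_gc_unbound: float = 0.5
    weak_motif_rate: float = 0.0           # expected planted off-core sites
    homotypic_flank_fraction: float = 0.0  # bound flank positions from PFM average
    orientation_mix: float = 0.5           # probability a plant is forward
    core_temperature: float = 1.0          # PFM sampling temperature for cores
    weak_temperature: float = 1.0
    weak_p_cutoff: float = 1e-3            # plants conditioned to pass this
    # in vivo mode
    genome_len: int = 50_000
    genome_gc: float = 0.41
    n_peaks: int = 40
    peak_len: int = 200
    open_fraction: float = 0.5
    n_unbound_sites: int = 40
    env_halfwidth: int = 60                # bp around a bound plant carrying effects

    def resolved_motif(self) -> PFM:
        return self.motif if self.motif is not None else random_pfm(seed=self.seed)

    def validate(self) -> None:
        L = self.resolved_motif().length
        if self.probe_len < L + 2 * (DEFAULT_CORE_EXCLUSION + 1):
            raise ValueError("probe too short for the motif plus usable flanks")
        for name in (
            "flank_gc_bound",
            "flank_gc_unbound",
            "homotypic_flank_fraction",
            "orientation_mix",
            "open_fraction",
            "genome_gc",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _gc_base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _soften(freq: np.ndarray, temperature: float) -> np.ndarray:
    if temperature == 1.0:
        return freq
    if temperature <= 0:
        out = np.zeros_like(freq)
        out[np.arange(freq.shape[0]), np.argmax(freq, axis=1)] = 1.0
        return out
    p = freq ** (1.0 / temperature)
    return p / p.sum(axis=1, keepdims=True)


def _sample_kmer(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    u = rng.random(probs.shape[0])
    return (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1).astype(np.uint8)


def _sample_passing_kmer(
    rng: np.random.Generator,
    probs: np.ndarray,
    scorer: Scorer,
    p_cutoff: float,
    max_tries: int = 100,
) -> np.ndarray:
    cut = scorer.int_cutoff(p_cutoff)
    for _ in range(max_tries):
        kmer = _sample_kmer(rng, probs)
        if scorer.window_int_scores(kmer[None, :])[0][0] >= cut:
            return kmer
    # fall back to the consensus, which always passes for a cutoff the
    # motif can reach at all
    return np.argmax(probs, axis=1).astype(np.uint8)


def generate_pools(cfg: SyntheticConfig):
    """(bound records, unbound records, truth dict).

    Records are (seq_id, sequence) pairs; the truth dict maps seq_id to
    the planted core offset/strand and any weak-motif plants.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pfm = cfg.resolved_motif()
    scorer = Scorer(pfm, Background.uniform())
    core_probs = _soften(pfm.freq, cfg.core_temperature)
    weak_probs = _soften(pfm.freq, cfg.weak_temperature)
    pfm_avg = pfm.column_average().probs

    truth: dict[str, dict] = {}
    pools = {}
    for label, n, gc in (
        ("bound", cfg.n_bound, cfg.flank_gc_bound),
        ("unbound", cfg.n_unbound, cfg.flank_gc_unbound),
    ):
        records = []
        base_probs = _gc_base_probs(gc)
        for i in range(n):
            sid = f"{label}_{i}"
            codes = _sample_kmer(
                rng, np.tile(base_probs, (cfg.probe_len, 1))
            )
            if label == "bound" and cfg.homotypic_flank_fraction > 0:
                swap = rng.random(cfg.probe_len) < cfg.homotypic_flank_fraction
                if np.any(swap):
                    repl = _sample_kmer(rng, np.tile(pfm_avg, (int(swap.sum()), 1)))
                    codes[swap] = repl
            offset = int(rng.integers(0, cfg.probe_len - pfm.length + 1))
            strand = "+" if rng.random() < cfg.orientation_mix else "-"
            core = _sample_kmer(rng, core_probs)
            if strand == "-":
                core = seqcodec.revcomp_codes(core)
            codes[offset : offset + pfm.length] = core
            weak = []
            if label == "bound" and cfg.weak_motif_rate > 0:
                k = int(rng.poisson(cfg.weak_motif_rate))
                starts = _pick_weak_slots(rng, cfg.probe_len, pfm.length, offset, k)
                for s in starts:
                    w_strand = "+" if rng.random() < cfg.orientation_mix else "-"
                    kmer = _sample_passing_kmer(
                        rng, weak_probs, scorer, cfg.weak_p_cutoff
                    )
                    if w_strand == "-":
                        kmer = seqcodec.revcomp_codes(kmer)
                    codes[s : s + pfm.length] = kmer
                    weak.append({"start": int(s), "strand": w_strand})
            records.append((sid, seqcodec.decode(codes)))
            truth[sid] = {
                "label": label,
                "core_offset": offset,
                "core_strand": strand,
                "weak": weak,
            }
        pools[label] = records
    truth_meta = {
        "config": _config_dict(cfg),
        "motif_consensus": pfm.consensus(),
        "sequences": truth,
    }
    return pools["bound"], pools["unbound"], truth_meta


def _pick_weak_slots(rng, probe_len, L, core_offset, k) -> list[int]:
    """Up to k non-overlapping window starts avoiding the core plant."""
    cand = [
        s
        for s in range(probe_len - L + 1)
        if s + L <= core_offset or s >= core_offset + L
    ]
    rng.shuffle(cand)
    chosen: list[int] = []
    for s in cand:
        if len(chosen) >= k:
            break
        if all(abs(s - c) >= L for c in chosen):
            chosen.append(s)
    return sorted(chosen)


def _config_dict(cfg: SyntheticConfig) -> dict:
    d = asdict(cfg)
    if cfg.motif is not None:
        d["motif"] = {
            "name": cfg.motif.name,
            "freq": [[round(float(x), 6) for x in row] for row in cfg.motif.freq],
        }
    return d


# -- in vivo toy genome ---------------------------------------------------


def generate_genome(cfg: SyntheticConfig):
    """(genome dict chrom->sequence, peaks, dnase, truth sites).

    Peaks sit fully inside open-chromatin intervals; one bound motif is
    planted at each peak center with the configured environment effects,
    and unbound motifs are planted in open chromatin outside peaks.
    Interval lists are sorted 0-based half-open (chrom, start, end)
    tuples; truth sites carry (chrom, start, end, label, strand).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    pfm = cfg.resolved_motif()
    L = pfm.length
    chrom = "chr1"
    codes = _sample_kmer(
        rng, np.tile(_gc_base_probs(cfg.genome_gc), (cfg.genome_len, 1))
    )

    # open chromatin: non-overlapping intervals until coverage reached
    if cfg.open_fraction >= 1.0:
        dnase = [(chrom, 0, cfg.genome_len)]
    else:
        open_len = max(4 * cfg.peak_len, 800)
        target = int(cfg.open_fraction * cfg.genome_len)
        taken = np.zeros(cfg.genome_len, dtype=bool)
        dnase = []
        tries = 0
        while taken.sum() < target and tries < 10_000:
            tries += 1
            s = int(rng.integers(0, cfg.genome_len - open_len))
            if taken[s : s + open_len].any():
                continue
            taken[s : s + open_len] = True
            dnase.append((chrom, s, s + open_len))
        dnase.sort(key=lambda iv: iv[1])

    # peaks inside open regions
    peaks = []
    used = []
    tries = 0
    while len(peaks) < cfg.n_peaks and tries < 20_000:
        tries += 1
        _, os_, oe = dnase[int(rng.integers(0, len(dnase)))]
        if oe - os_ < cfg.peak_len + 2:
            continue
        s = int(rng.integers(os_, oe - cfg.peak_len))
        if any(s < e and s + cfg.peak_len > b for b, e in used):
            continue
        used.append((s, s + cfg.peak_len))
        peaks.append((chrom, s, s + cfg.peak_len))
    peaks.sort(key=lambda iv: iv[1])

    core_probs = _soften(pfm.freq, cfg.core_temperature)
    pfm_avg = pfm.column_average().probs
    sites = []

    def plant(pos: int, bound: bool):
        strand = "+" if rng.random() < cfg.orientation_mix else "-"
        core = _sample_kmer(rng, core_probs)
        if strand == "-":
            core = seqcodec.revcomp_codes(core)
        if bound:
            lo = max(0, pos - cfg.env_halfwidth)
            hi = min(cfg.genome_len, pos + L + cfg.env_halfwidth)
            env = _sample_kmer(
                rng, np.tile(_gc_base_probs(cfg.flank_gc_bound), (hi - lo, 1))
            )
            if cfg.homotypic_flank_fraction > 0:
                swap = rng.random(hi - lo) < cfg.homotypic_flank_fraction
                if np.any(swap):
                    env[swap] = _sample_kmer(
                        rng, np.tile(pfm_avg, (int(swap.sum()), 1))
                    )
            codes[lo:hi] = env
        codes[pos : pos + L] = core
        sites.append((chrom, pos, pos + L, "bound" if bound else "unbound", strand))

    for _, ps, pe in peaks:
        plant((ps + pe) // 2 - L // 2, bound=True)

    peak_arr = np.array([(b, e) for _, b, e in peaks]) if peaks else np.empty((0, 2))
    placed = 0
    tries = 0
    while placed < cfg.n_unbound_sites and tries < 50_000:
        tries += 1
        _, os_, oe = dnase[int(rng.integers(0, len(dnase)))]
        if oe - os_ <= L:
            continue
        s = int(rng.integers(os_, oe - L))
        if peak_arr.size and np.any((s < peak_arr[:, 1]) & (s + L > peak_arr[:, 0])):
            continue
        if any(s < e and s + L > b for _, b, e, _, _ in sites):
            continue
        plant(s, bound=False)
        placed += 1

    sites.sort(key=lambda t: t[1])
    genome = {chrom: seqcodec.decode(codes)}
    return genome, peaks, dnase, sites


def generate_cooccupancy_sites(
    n_families: int = 3,
    tfs_per_family: int = 3,
    sites_per_tf: int = 60,
    chrom_len: int = 500_000,
    site_len: int = 8,
    coupling: float = 0.7,
    anchor_spread: int = 120,
    seed: int = 0,
):
    """Motif-site sets for several TFs with family-coupled placement.

    A fraction ``coupling`` of each TF's sites is placed near shared
    per-family anchor loci (within ``anchor_spread`` bp, non-
    overlapping); the rest are uniform.  Returns (sites_by_tf,
    family_map)."""
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    sites_by_tf: dict[str, list] = {}
    family_map: dict[str, str] = {}
    n_anchors = max(sites_per_tf, 20)
    for f in range(n_families):
        fam = f"fam{f}"
        anchors = rng.integers(1000, chrom_len - 1000, size=n_anchors)
        for t in range(tfs_per_family):
            tf = f"{fam}_tf{t}"
            family_map[tf] = fam
            placed = []
            for i in range(sites_per_tf):
                if rng.random() < coupling:
                    a = int(anchors[int(rng.integers(0, n_anchors))])
                    s = a + int(rng.integers(-anchor_spread, anchor_spread))
                else:
                    s = int(rng.integers(0, chrom_len - site_len))
                s = min(max(s, 0), chrom_len - site_len)
                # avoid overlap within the TF's own site set
                if any(s < e and s + site_len > b for b, e in placed):
                    continue
                placed.append((s, s + site_len))
            from .cooccupancy import GenomicInterval

            sites_by_tf[tf] = [
                GenomicInterval(chrom, b, e, tf) for b, e in sorted(placed)
            ]
    return sites_by_tf, family_map


# -- writers --------------------------------------------------------------


def write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")


def write_bed(path, intervals) -> None:
    """Write sorted 0-based half-open intervals; extra tuple fields
    become extra BED columns."""
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda t: (t[0], t[1])):
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_truth_json(path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
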