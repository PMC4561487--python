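# motifenv

Only a small fraction of the genomic (or in vitro) occurrences of a
transcription factor's (TF's) consensus motif are actually bound by the
protein. `motifenv` implements a pipeline for asking what distinguishes the
*environment* of bound motifs from that of unbound ones: it aligns bound and
unbound motif-containing sequences on the core motif, compares the flanking
regions position by position (nucleotide content and DNA shape), quantifies
homotypic structure (weak motif copies and overall motif-likeness of the
flanks), relates environment preferences to TF co-occupancy, and tests how
far the environment alone predicts binding with regularized regression and a
block hidden Markov model. It is aimed at regulatory-genomics researchers
working with HT-SELEX-style probe pools or ChIP-seq/DNase data.

## The statistics at its core

Given a position frequency matrix (PFM) `f` and background `b`, windows are
scored by log-odds `S = Σᵢ log₂ f_i(x_i)/b(x_i)` with *exact* p-values from a
dynamic program over the discretized score distribution. After best-hit
alignment and size matching, each flank position (core ± 2 bp excluded) is
compared between pools with one-sided rank tests; the two one-sided p-value
families are FDR-corrected (Storey q-values) and summarized as the signed
significance

    Δ[−log₁₀ q]  — positive where the bound pool is higher,

with a preference call when ≥ 5 positions reach q ≤ 0.05 with a consistent
sign. Prediction uses (a) L2-regularized linear regression on environment
features (GC, propeller twist, homotypic environment, homotypic clusters)
under nested 10-fold cross-validation scored by AUROC, and (b) a two-state
block HMM — background base vs whole motif block (switch probability 0.01,
orientation by a precalculated strand bias) — scoring each sequence by its
log-likelihood ratio against a pure genomic background.

## Worked example

Generate a synthetic probe experiment with a planted 4-percentage-point GC
elevation around bound motifs, align both pools, and compare the flanks:

```sh
motifenv simulate --seed 7 --n-bound 2000 --n-unbound 2000 --probe-len 30 \
    --gc-bound 0.54 --gc-unbound 0.50 --out-dir sim
motifenv align --bound sim/bound.fasta --unbound sim/unbound.fasta \
    --pfm sim/motif.meme --flank 10 --min-pool-size 100 --out-dir aligned
motifenv env-compare --aligned-dir aligned --out gc_stats.tsv
```

which prints

```
bound: {"kept": 1668, "no_hit": 329, "short_flank": 0, "tie": 3}
unbound: {"kept": 1673, "no_hit": 326, "short_flank": 0, "tie": 1}
size-matched to n=1668
call=high-GC significant_positions=15 mean_delta_gc=4.96pp
```

Reading this: of 2000 probes per pool, ~1670 carried a unique significant
motif match and were aligned (the rest had no passing window or a tied top
score); the TF is called as preferring a high-GC environment, 15 of the 16
usable flank positions differ significantly, and the bound pool's flanks are
on average 4.96 percentage points more GC-rich — recovering the planted 4-pp
shift (plus sampling noise). The per-position table lands in
`gc_stats.tsv`:

```
position  mean_bound  mean_unbound  n_bound  n_unbound  p_greater   ...  delta
-10       0.561692    0.459906     851      848        1.363e-05        4.56447
-9        0.546326    0.498382     939      927        0.0191094        2.45912
-8        0.5345      0.478692     1029     1009       0.00588692       2.70723
```

`delta` is the signed Δ[−log₁₀ q]; positive values mean GC is higher around
bound motifs at that position. A single-feature regression on mean flank GC
separates the pools well above chance:

```sh
$ motifenv predict-mlr --aligned-dir aligned --pfm sim/motif.meme --model gc --seed 0 --out mlr.json
gc: AUROC 0.594
```

The same flow runs end to end — alignment, nucleotide and shape profiles,
homotypic clusters/environment, regression and HMM scoring — with
`motifenv run-all --seed 9 --out-dir results/`, and on a toy genome with
peak and open-chromatin tracks via `--mode invivo` configs. The library API
(`motifenv.scan`, `envstats`, `homotypy`, `shape`, `cooccupancy`, `mlr`,
`hmm`, `simulate`, `pipeline`) exposes every step individually.

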