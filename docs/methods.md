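# Methods

`motifenv` compares the sequence and structural environment around a
transcription factor's (TF's) core binding motif between sequences the TF
binds and sequences that contain the same motif but are not bound, and asks
how far that environment alone predicts binding. This note records the
models, the parameter choices that matter, and what the synthetic benchmarks
do and do not establish.

## Motif model and scanning

A motif is a position frequency matrix (PFM): per-position probabilities
over A, C, G, T. On reading, a pseudocount (default 0.01 per cell) is added
and rows renormalized, so log-odds scores are finite everywhere. A window of
motif length L is scored as

    S = sum_i log2( f_i(x_i) / b(x_i) )

against a mononucleotide background b (uniform 0.25 for in vitro probes;
genome-wide frequencies for genomic scans — the natural nulls for each data
type). To make p-values exact and score ties well defined, per-cell
log-odds are quantized to multiples of 1/1000 bit and the null distribution
of the quantized window score is computed by exact dynamic programming over
positions (a convolution of the four-point per-position score
distributions). Reported p-values P(S >= s) are therefore exact for the
scores reported; the quantization error on a score is at most L/2000 bits.
Windows containing an undefined base (N) are skipped. Reverse-strand
windows are scored on the reverse complement and reported at the forward
offset.

### Best-hit alignment

Each probe keeps its unique highest-scoring window with p <= p_align
(default 1e-4, the conventional scanning threshold; the source analyses do
not state the value used for alignment, only for cluster counting).
Sequences with no passing window, or with the same top score at two or more
distinct offsets, are discarded and counted by reason. A palindromic motif
scoring equally on both strands of the same window is not a tie; the
forward orientation is kept. Reverse-strand best hits are
reverse-complemented into the common frame.

The analysis frame spans `flank_up + L + flank_down` positions (±10 bp in
vitro, ±300 bp for genomic hits). Because short probes cannot cover the
full window at every motif offset, the pipeline pads missing frame
positions as undefined rather than discarding the record; every
per-position statistic then uses exactly the records that cover that
position (reported as n_bound/n_unbound per position). Strict discarding is
available (`pad_incomplete=False`) and is the library default for the bare
alignment function. Pools are size-matched by seeded subsampling without
replacement before any comparison.

## Positional comparison and preference calls

For each usable flank position — the core block plus 2 bp on each side is
always excluded — the feature values (GC indicator, single-base indicators,
or propeller twist) of the bound and unbound pools are compared with the
one-sided Mann–Whitney rank-sum test in both directions. The pools are
unpaired samples, so the unpaired test is the default; an index-paired
signed-rank variant is provided. For tiny columns (n1 + n2 <= 20) p-values
are computed by exact enumeration of all label permutations with mid-ranks,
otherwise by the tie-corrected normal approximation with continuity
correction. Positions covered in fewer than `min_n` (default 10) records in
either pool are dropped.

Each one-sided p-value family is FDR-corrected separately (Storey q-values
with pi0 estimated at lambda = 0.5, floored at 1/m; Benjamini–Hochberg
available) and combined into the signed score

    delta = -log10(q_greater)  if the bound mean is higher,
    delta = +log10(q_less)     if the unbound mean is higher,

so positive delta means the bound pool is higher. A TF is called as
preferring a high-GC (high-AT) environment when at least `min_positions`
(default 5) positions are significant (q <= 0.05) with the bound-higher
(bound-lower) sign.

## Homotypic clusters and homotypic environment

Off-core windows (no shared position with the core block) on both strands
are binned by exact p-value into <= 0.001, 0.001–0.05 and 0.05–0.1; the
per-sequence counts are compared between pools by rank test per bin. The
homotypic-environment score of a sequence is the mean log-odds over all
off-core windows — no threshold — taking the better strand per window (a
site is a site on either strand; forward-only mode exists). The masking
controls either flag all positions covered by off-core hits at a chosen
cutoff as excluded from positional statistics, or drop such sequences
entirely; a looser cutoff always masks a superset of a stricter one.

Note a structural fact that the simulations expose: for iid-generated
flanks, the expected window log-odds depends only on the mononucleotide
composition of the flank. A homotypic-environment signal therefore exists
only when the motif's average composition deviates from the background
(e.g. GC- or purine-skewed motifs), which is exactly the compositional
dependency the analysis is designed to detect.

## DNA shape

Propeller twist (degrees; a base-pair parameter, hence strand-symmetric) is
predicted per position by looking up the pentamer centered there in a
user-supplied table; the first and last two positions, and positions whose
pentamer crosses an undefined base, are left undefined rather than imputed.
Tables with 512 reverse-complement-reduced rows are expanded on load;
asymmetric duplicates and missing pentamers are errors. The package ships a
*synthetic* RC-symmetric table — value = −11.0 + 1.1 × (pentamer GC count)
+ pair-shared Gaussian noise (sd 0.3) — which reproduces the qualitative
trend that GC-rich DNA has less pronounced propeller twist. It is a test
fixture, not a physical model; real analyses should supply a table derived
from structural predictions.

## Co-occupancy

For a TF pair (A, B), site pairs overlapping by >= 1 bp are discarded
(related TFs share similar motifs), and the co-occupancy fraction is the
share of A's remaining sites whose edge-to-edge gap to the nearest B site
is <= 300 bp (midpoint distance available). GC-preference similarity of two
TFs is the ratio of their mean positional delta scores, oriented so the
larger magnitude is the denominator: the ratio lies in [−1, 1], 1 meaning
identical direction and strength, negative meaning opposite preferences;
two null profiles are defined as similarity 1 with a degeneracy flag.

## Regression models (MLR)

Per aligned sequence, four environment features are extracted, always
excluding the core and 2 bp each side: mean GC fraction, mean propeller
twist, mean window similarity (homotypic environment), and the summed
log-odds of off-core hits with p <= 0.001 (homotypic clusters). Sequences
whose flanks cannot host a motif-length off-core window have no defined
environment score and are excluded from models that need it — the same
probe-length restriction the homotypy analyses impose. The core motif score
is carried only for strength matching and never enters a model.

Before modeling, the two pools are subsampled so their core-score
distributions match: scores are cut into 10 pooled-quantile bins and within
each bin the groups are paired greedily by nearest score. The classifier is
ridge regression in the literal sense — least squares on 0/1 labels with an
L2 penalty, not logistic — scored by AUROC (Mann–Whitney form, ties ½) on
held-out folds of a stratified 10-fold cross-validation; the penalty is
chosen per outer fold by an inner 10-fold CV over a 13-point grid
log-spaced from 1e−3 to 1e3. Features are standardized on each training
fold only. The empirical significance cutoff is the maximum CV AUROC over
label-shuffled refits. Transfer between domains fits on one pool pair
(penalty by CV on it alone) and scores the other.

## Block HMM

The generative model emits, at each step, one background base with
probability t_bg = 0.99 or a whole motif block with probability 0.01, the
block forward-oriented with probability s (the strand bias, estimated as
the forward fraction of motif hits at p <= 0.001 in the bound pool; 0.5
with no hits). The forward recursion over emission boundaries

    F(i) = t_bg · beta(x_i) · F(i−1)
         + (1 − t_bg) · [i >= L] · (s·P_fwd + (1−s)·P_rev) · F(i−L)

is evaluated in log space; a sequence is scored by the log-likelihood ratio
of log F(n) against a pure genomic-background parse. The step-wise choice
(state-independent, 0.99 background) is the single well-defined semantics
consistent with the stated dominance of the background state; there is no
end state, which is immaterial because likelihoods are only compared
between equal-length sequences. Three background-state emissions are
supported: the genomic (unbound-pool) frequencies; the motif's column
average; and the column average with its A↔G and T↔C mass swapped
(exchanging total AT and GC content). No training is involved.

## Synthetic data

The generator produces the study conditions: fixed-length probe pools
(default 20 bp, the dominant HT-SELEX probe class) in which every sequence
carries one core plant sampled from the PFM (temperature-adjustable;
temperature 0 plants the consensus) at a uniform random offset and
orientation (default forward probability 0.5). Bound flanks may differ from
unbound in GC (the planted Δ; pool averages realize the target within 0.01
for n >= 2000), carry Poisson-distributed weak-motif plants in
non-overlapping off-core slots (each plant rejection-sampled from a
temperature-softened PFM until it passes p <= 0.001, so planting and
recovery thresholds coincide), and/or have a fraction of positions drawn
from the motif's average composition. The default motif is a random
single-peak PFM of length 10 at 1.5 bits/column — the sharpness regime of
selection-derived PFMs, and the shortest length at which sub-consensus
matches can still pass a 1e-4 scanning threshold, giving a non-degenerate
motif-strength distribution. The toy genome plants bound motifs at peak
centers (peaks inside open-chromatin intervals) with environment effects in
a ±60 bp neighborhood, and unbound motifs in open chromatin outside peaks;
all coordinates are recorded as ground truth, and identical (config, seed)
reproduce every output bit for bit.

What the generator does **not** emulate: selection-cycle amplification
biases, position-dependent flank composition, dinucleotide structure,
nucleosome or co-factor effects, real open-chromatin GC elevation, or
correlated motif families. Passing recovery tests therefore shows the
pipeline detects the effects it models at realistic magnitudes — a 4
percentage-point GC shift (the in vivo average reported for such data),
about three weak sites per bound sequence — not that real data meet its
assumptions.

## Benchmark problem sizes and numerical choices

The validation suite uses: 100 probe-pool replicates of n = 500 per pool
for null calibration (call rate <= 5%); 20 replicates of n = 5000 for
GC-shift recovery; 20 replicates of n = 300 for the HMM background-mode
ordering; three replicate data sets of n = 2500 for the regression-model
structure (60-bp probes so environment windows exist; the homotypic motif
is purine-skewed so its signal is not reducible to GC); n = 2000 100-bp
probes for weak-site recovery (shorter probes would truncate the Poisson(3)
plant count for lack of non-overlapping slots); and a full duplicate run
for bit-level determinism. `scripts/acceptance.py` reruns the same studies
at moderately reduced replicate counts and writes every measured number to
JSON.

Degenerate inputs are handled explicitly: all-tied test columns give p = 1
on both sides; a pool with no eligible environment window yields an
undefined (not zero) score; a constant feature column gets a zero
coefficient with a warning; a degenerate motif-score distribution reduces
strength matching to plain size matching; empty interval sets give NaN
co-occupancy fractions with counts reported.

## Known limitations

Only mononucleotide backgrounds and ungapped, fixed-length motifs are
supported; motif discovery is limited to IUPAC-seed refinement; only
propeller twist among shape features is implemented (tables for other
parameters would slot into the same interface); the co-occupancy null is
label permutation, not a genome-composition model; and the HMM assigns
probability mass across sequence lengths without an explicit end state, so
its absolute likelihoods are not comparable across lengths — only its
equal-length ratios are used.
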