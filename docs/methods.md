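# Methods

## Background and model

Nucleosomes — ~147 bp of DNA wrapped around a histone octamer — are the
repeating unit of chromatin; where they sit controls the accessibility of
regulatory sequence. Beyond base composition, the *physicochemical
structure* of DNA (flexibility, curvature, duplex energetics) carries
positioning information. `nucstruct` operationalises that idea: it turns
genomic sequence into smoothed profiles of twelve structural scales and
predicts nucleosome occupancy and discrete positions from those profiles
alone.

### Structural scales

A structural scale assigns a real value to every dinucleotide (or, for
bendability, trinucleotide) step: propeller-twist angle, duplex melting
temperature, bending stiffness, base-stacking energy, B→Z or B→A
transition energy, nearest-neighbour free energy, protein-induced
deformability, and so on. Scales split into two sign classes by the sign
of their genome-wide correlation with nucleosome occupancy:

* positive — propeller twist, DNA denaturation, DNA-bending stiffness,
  bendability, duplex disrupt energy;
* negative — stacking energy, Z-DNA, duplex free energy, A-philicity,
  protein–DNA twist, B-DNA twist, protein-induced deformation.

The numeric tables ship as TSV assets (`src/nucstruct/data/scales.tsv`
with `scales_meta.tsv`); values were compiled from the dinucleotide- and
trinucleotide-property literature and are reverse-complement symmetric,
as step parameters physically must be. The tables are data, not code:
point `load_scales` at a different TSV to swap models. Note a structural
consequence of that symmetry: any strand-symmetric dinucleotide scale is
a linear functional of the ten symmetrised dinucleotide frequencies of a
window, so eleven such scales are *necessarily* collinear — see the LARS
section.

### Structural profiles

A sequence is converted to a raw vector by substituting each k-mer with
its scale value, then smoothed with a moving average: window 100 bp, step
10 bp (defaults; the window is large enough to suppress k-mer noise and
smaller than a nucleosome so positional contrast survives). Coordinates
are 0-based half-open; a bin's representative coordinate is its window
centre. Only complete windows are emitted, and non-ACGT positions are
masked (NaN) and excluded from window means — real assemblies contain N
runs and masking must not crash the pipeline.

## Locating nucleosomes by peak detection (DLaNe)

Nucleosome-occupied sequence shows up as peaks of positively correlated
profiles and valleys of negatively correlated ones, so negative-class
profiles are negated ("oriented") and a single peak detector serves both.
Per chromosome:

1. **Median filtering** (window = the smoothing window, 100 bp; nearest
   odd bin count) removes narrow spikes while preserving edges.
2. **Adaptive threshold.** The filtered profile is partitioned into
   non-overlapping 165-bp scan windows — one nucleosome plus a typical
   yeast linker (the 165 bp is rounded to 17 bins at 10-bp resolution).
   Each window's peak intensity is `Pi = max − min`; the per-chromosome
   average `APi` times the peak-significance parameter `Ps ∈ (0, 1]`
   gives the acceptance threshold. `Ps` defaults to 0.45, the midpoint
   of the empirically best range [0.3, 0.6]; larger values call fewer,
   more intense peaks.
3. **Scan with steric exclusion.** A 165-bp window slides bin by bin.
   When its intensity reaches the threshold, the leftmost position of the
   window maximum becomes the peak centre `Pc`, implying the 147-bp call
   `[Pc−73, Pc+74)`; scanning resumes just past `Pr = Pc+73`, so calls
   never overlap.

Three rules cover cases the procedure itself leaves open, all chosen for
determinism and tested against a literal re-implementation:

* a window qualifies only when `Pi > 0`, so flat profiles produce no
  calls even at threshold zero;
* while the window maximum sits on the trailing edge, the profile is
  still rising into the window and acceptance is deferred one bin at a
  time until the apex is interior — without this the first qualifying
  window places `Pc` on a peak's rising flank, tens of bp left of the
  apex;
* candidate calls that would cross the covered span or overlap the
  previous call are skipped (the resume rule alone cannot guarantee
  non-overlap, since a fresh window's maximum may fall within 73 bp of
  the previous centre).

## Meta-prediction

Each feature's call set is a weak predictor; the meta-predictor pools
them. Every individual call becomes a candidate described by its support
count (features with a call centre within 73 bp — half a nucleosome),
the distance to the closest other pooled candidate, and one indicator per
feature. A Random Forest (100 trees, fixed seed recorded with the model)
is trained on one chromosome, labelling candidates positive when they lie
within 35 bp of a reference centre; training refuses single-class labels.
Accepted candidates are clustered by single linkage at 73 bp (the
"within 73 bp of each other" rule read transitively); each cluster emits
its median-centre candidate (lower median on ties). Clustering does not
by itself forbid overlapping survivors, so residual overlaps are resolved
greedily by descending support count — an implementation choice,
documented so it can be swapped. By default the six top-performing
features are combined (DNA denaturation, propeller twist, bending
stiffness, Z-DNA, stacking energy, duplex free energy); all twelve are a
configuration away.

## HMM positioning

The hidden Markov model has 16 states: linker `L0` plus nucleosome states
`N1..N15` — at 10-bp resolution a 147-bp core spans ~15 bins, so a
complete `N1→…→N15` pass traces one nucleosome. Legal transitions are
`L0→{L0, N1}`, `Nk→Nk+1`, and `N15→{L0, N1}`; the direct `N15→N1` edge
represents zero-linker abutment and is removable. Emissions are
independent Gaussians per state and channel over the six top-feature
profiles (diagonal covariance keeps the parameter count trainable from a
single chromosome). Training is supervised: a reference map is converted
to a state path — each reference centre claims exactly the 15 bins of the
15-bin window centred on it, which keeps every transition legal (a naive
"bins inside the 147-bp core" rule yields 14 bins half the time and an
illegal skip) — then transitions are estimated by add-one-smoothed counts
restricted to the legal set, and emissions by per-state means/variances
(variance floor 1e-6). Decoding is exact log-domain Viterbi with
leftmost tie-breaking; masked channels drop out of a bin's emission term,
and a fully masked bin is uninformative. Complete `N1..N15` runs become
147-bp calls centred at the run midpoint; truncated runs at sequence ends
are discarded.

## Predicting continuous occupancy (LARS)

The twelve profiles, aligned on shared unmasked bins with an occupancy
track, feed least angle regression. Features are centred and scaled
internally; coefficients are reported on the original scale. The model
is the Mallows'-Cp-minimising point on the LARS path (the conventional
default of the reference LARS implementation; the full-path OLS endpoint
is available via `stop="full"`). Because the strand-symmetric scales are
collinear (see above), the design matrix is rank-deficient by
construction; the fitter warns and lets the path stop at the rank, and
the Cp noise scale is estimated from the least-squares residual at that
rank rather than from the (numerically unstable) final path point.
Training and evaluation chromosomes are aligned separately, so fitting
never sees held-out bins.

## Evaluation

A prediction is correct when its centre lies within `L` bp of a reference
centre. Matching is one-to-one and greedy in increasing distance (ties
broken by position), so duplicate predictions of one nucleosome are
penalised; sensitivity `Se = TP/n_reference`, specificity
`Sp = TP/n_predicted`, and `F = 2·Se·Sp/(Se+Sp)` (zero when both rates
are zero). The default cutoff sweep is L ∈ {10,…,60} with 35 bp as the
single-point operating cutoff. The random baseline draws, per
chromosome, the reference's number of non-overlapping 147-bp calls
uniformly among all legal configurations via the gap-collapse
construction (n sorted draws from `[0, length − n·147]` expanded by one
core width each); naive rejection sampling was rejected because reference
maps cover ~85% of the chromosome and rejection stalls there.

## Synthetic data: what it emulates and what it does not

The generator plants alternating 147-bp cores and 10–20-bp linkers
(uniform lengths), with occasional 300–800-bp nucleosome-free regions
(10% of sequence by default, promoter/NDR-like). Cores and linkers are
drawn i.i.d. from different base compositions: GC-rich cores (GC = 0.85
at the default contrast) versus poly(dA:dT)-like linkers (GC = 0.02).
The composition route — rather than writing structural values directly —
exercises the full code path sequence → k-mer lookup → smoothing. The
`contrast` knob scales the divergence linearly; at 0 the planted signal
vanishes, which the null tests rely on. The defaults deliberately model
the *strongly positioned* regime (clear structural contrast between
occupied and free sequence) rather than average yeast chromatin: they are
the conditions under which the recovery guarantees in the test suite
(best-feature Se ≥ 0.8 / Sp ≥ 0.6 at 35 bp, ≥ 80% HMM recovery) hold.
The companion occupancy track is the boxcar-smoothed core indicator plus
Gaussian noise (sd 0.5, chosen to land held-out model correlations near
0.5 — the qualitative in-vivo regime). All randomness flows from one
seed through a counter-based stream per chromosome, so outputs are
byte-identical per configuration.

Not emulated: real k-mer statistics, MNase sequence bias, the ~10-bp
rotational periodicity of nucleosomal DNA, remodeler- or TF-driven
positioning, and linker-length heterogeneity beyond the uniform range.
Passing recovery tests therefore demonstrates algorithmic correctness on
the intended signal, not genome-scale accuracy on real chromatin. One
deliberate realism echo: protein-induced deformability rises with GC and
is classed negative, so on synthetic genomes its oriented profile is
anti-correlated with the planted signal and it ranks last among the
single features — matching its near-zero correlation and last-place rank
on real data.

### Benchmark problem sizes

The packaged benchmark (`nucstruct.benchmark.synthetic_benchmark`) uses
two 50-kb chromosomes — one for training the meta-predictor and HMM, one
held out for every reported metric — and the test suite averages 20
seeded replicates; the acceptance script averages 10. These sizes give
±0.02-level stability of the seed-averaged rates while keeping a full
run in seconds.

## Numerical and degenerate-input choices

* Masked data: NaN throughout; window means/medians ignore NaN, fully
  masked windows stay masked, fully masked emission vectors contribute 0.
* Ties: leftmost argmax everywhere (peak centres, Viterbi backtraces);
  lower median for even meta clusters.
* The 165-bp scan window becomes `round(165/step)` bins (17 at 10 bp).
* bedGraph intervals have width `step` centred on each bin; masked bins
  are omitted on write and reappear as masked on read.
* HMM variance floor 1e-6; transition smoothing add-one on legal edges.

## Known limitations

* Single-strand profiles only: scales are applied to the sequence as
  written (symmetric tables make this a no-op; asymmetric custom tables
  would see strand effects).
* The peak caller's localisation is limited by median-filter plateau
  formation plus the leftmost tie-break; centres can sit half a plateau
  left of the true apex.
* Supervised HMM training only (no Baum–Welch), matching the intended
  use with a reference map in hand.
* `Ps` is a global configuration value; no per-chromosome auto-tuning is
  attempted beyond the per-chromosome `APi` threshold itself.
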