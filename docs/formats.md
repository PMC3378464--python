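# File formats

All coordinates are 0-based, half-open (BED convention). Writers emit a
first line `# nucstruct v<version> <key=value ...>` recording provenance;
readers skip `#` comments and `track` lines.

## FASTA
Multi-record, wrapped lines, case-insensitive on read (sequences are
uppercased).

## Scale tables (TSV)
`scales.tsv`: columns `feature`, `kmer`, `value` — one row per k-mer,
complete over {A,C,G,T}^k per feature (16 dinucleotide or 64
trinucleotide rows). `scales_meta.tsv`: columns `feature`, `k`,
`sign_class` (`positive`/`negative`), `units`.

## Nucleosome calls (BED6)
`chrom  start  end  name  score  strand` — every interval spans exactly
147 bp; `name` is the source feature (or `meta`/`hmm`/`random`); `score`
is the call score scaled into [0, 1000]; strand is `.`. Reference maps
use the same layout (intervals of any width; the centre is the interval
midpoint). `--one-based` on readers shifts starts by −1 for 1-based
inclusive inputs.

## Tracks (bedGraph)
`chrom  start  end  value` — intervals of width `step_bp` (10 by
default), centred on each profile bin; masked bins are omitted and
reappear as masked on read. Overlapping or off-grid intervals are
rejected. Profile files are named `<chrom>.<feature>.bedGraph`,
occupancy tracks `<chrom>.occupancy.bedGraph`.

## Chromosome sizes (TSV)
`chrom  length`, one row per chromosome, order preserved.

## Anchors (TSV)
Header `class  chrom  position  strand`; one anchor per row, classes are
free-form labels (the simulator emits `depleted` and `enriched`).

## Evaluation output (TSV)
Header `calls  cutoff_bp  tp  n_reference  n_predicted  se  sp  f`; one
row per call file and distance cutoff.

## Model files
LARS: TSV `term  coefficient` with an `intercept` row, coefficients on
the original profile scale. HMM: key–value TSV blocks (`features`,
`start`, `trans0..15`, `mean0..15`, `var0..15`, comma-separated).
Meta-predictor: Python pickle containing the fitted model and its
feature list (regenerate rather than share across versions).
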