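# Methods

## The model

A split-pool experiment tags each cell with a combinatorial barcode over
three in-cell rounds (48 × 96 × 96 well barcodes) plus a PCR-indexed
sub-library (3 indices, represented downstream as one character appended
to the cell barcode), for 1,327,104 combinations. The simulator, the
demultiplexer and the QC modules all share one read-2 anatomy
(`BarcodeLayout.default()`): UMI at [0, 10), BC3 at [10, 18), a 30 nt
linker, BC2 at [48, 56), a second 30 nt linker, and BC1 at [86, 94), all
0-based half-open. The 94 nt minimum span is the constraint the length
filter enforces; the exact interior offsets are a package choice, since
they depend on oligo lengths that are plate-specific — the layout object
is the single source of truth and can be reconfigured. Linker fillers
are fixed arbitrary strings for the same reason.

Whitelists are drawn by rejection sampling with a pairwise Hamming floor
of 3 per round, which makes radius-1 correction of any single
substitution provably unambiguous. Real plates carry no such guarantee;
the floor is a simulator idealisation and can be disabled
(`enforce_min_dist=False`), in which case ambiguous corrections appear
and are dropped, exercising the AMBIGUOUS path.

## Synthetic data generator

Per-cell expression is gamma(shape 0.3, row-normalised) per gene; depth
is negative-binomial (dispersion 2) per cell; molecule counts follow
from depth via a mean-reads-per-UMI of 1.8 (each molecule gets at least
one read, extras spread multinomially), so UMI deduplication and
saturation analysis have real duplication to remove. The default depth
(1600 reads/cell, ≈ 890 UMIs/cell) matches the ~900 UMIs-per-cell regime
of a shallow split-pool experiment; tests and the acceptance script use
explicitly smaller depths (80–120 reads/cell) and cell counts
(30–20,000) as their stated problem sizes.

Doublets: a fraction (default 0.05) of barcode-bearing units merge two
cells drawn uniformly without replacement from the pooled mix, so
cross-species doublets arise at 2·p_A·p_B among doublets. Barcode
combinations are sampled uniformly *with replacement* from the product
space, so distinct units share a combination at the birthday-problem
rate — the tests check the closed form 1 − (1 − 1/C)^(U−1). Ambient
reads (default 2% of output) draw a transcript from the pooled
transcriptome but carry the valid barcode of a real unit, modelling
soup that is counted into cells; they trace to a reserved `AMBIENT`
truth id. Corruption modes: per-base substitutions (0.5%), read-2
truncation to 40–93 nt (1%), and adapter insertion into read 1 (0.5%).
Per-round cell retention (0.43³ ≈ 8% overall) is bookkeeping that sizes
the implied input pool; the configured `n_cells_per_species` counts
cells surviving to the last barcoding step.

What the generator does **not** model: splice structure and intronic
reads, quality-score profiles beyond flat Phred (so quality trimming is
exercised only by explicitly constructed tests), PCR chimeras between
cells' barcodes, and barcode-specific error hotspots. Passing tests
therefore demonstrate the pipeline's contracts (accounting identities,
correction radii, recovery of simulated parameters), not performance on
the artefact spectrum of any particular sequencer.

## Read curation

Checks run in a fixed order — 3′ quality trim (maximal suffix below
Phred 10), terminal-N strip on read 2, adapter trim (exact hit anywhere,
else a ≥ 6 nt 3′ suffix-prefix overlap), length floors (60 / 94 nt),
phase, pairing — with first-failure attribution, so the report buckets
partition the input exactly. A pair whose read is adapter from position
0 is charged to the adapter bucket; a pair merely left short is charged
to the length bucket. The phase check compares each fixed linker to its
expected offset with ≤ 1 substitution tolerated; indels shift all later
segments and fail it. Out-of-phase reads are dropped, not repaired —
retention is deliberately conservative, and no dephasing rescue is
attempted.

## Demultiplexing and quantification

Barcode correction: exact match wins immediately; otherwise the unique
whitelist entry at Hamming distance 1 (N counts as a mismatch); two or
more distance-1 candidates → AMBIGUOUS (dropped — assigning a tie would
fabricate a cell); none → NO_MATCH. UMIs containing N are dropped at
tagging because N corrupts the collapse distance logic.

Gene assignment replaces splice-aware genome alignment with a unique
k-mer vote (k = 31, odd, over both species' gene sets concatenated —
joint indexing is what makes cross-species collisions measurable): one
gene hit → assigned, two or more → multimapped (dropped), none →
unassigned. This is the package's one intentional departure from an
alignment-based toolchain, adequate because the references are
transcript-level and synthetic.

UMI collapse follows the standard digital-expression greedy rule:
descending read count, ties lexicographic, absorb anything within
Hamming distance 1 of an accepted UMI. A connected-components variant is
available (`method="components"`) for sensitivity analysis; greedy is
the default. All orderings (genes, barcodes, tie-breaks) are
lexicographic, so matrices are invariant to read and sub-library order
without any seed.

## Species QC and doublet calibration

A barcode's minority fraction is min(UMIs_A, UMIs_B)/total; "sharing
over 10%" is implemented as strictly greater-than, so a barcode at
exactly 0.10 is not a collision (configurable θ). Cell calling keeps
barcodes with ≥ 125 detected genes; of those, barcodes with > 5000 UMIs
or a collision flag are excluded, and the ledger stores the combined
exclusion count (mirroring the published accounting convention) plus the
two sub-counts for diagnostics. `n_retained` is a derived property, so
the identity retained = passed − excluded cannot be violated by
construction. Species assignment is majority-by-UMIs with ties toward
the first species column (vanishingly rare at realistic depth).

Doublet calibration treats observed cross-species collisions as a
sample of all doublets: estimate = n_cross / (2·p_A·p_B), with
proportions taken from the majority-species assignment of non-collision
barcodes and a Clopper-Pearson 95% interval propagated from the
collision count. Two opposing biases are worth knowing: natural barcode
collisions (not true doublets) inflate the cross-species count, while
strongly imbalanced doublets (minority below θ) escape detection. At
20,000 cells in a 1.3 M barcode space these nearly cancel; the recovery
test bounds the net error at 20% relative. Within-species doublets are
only *estimated* here, never removed — deconvolution-based removal is a
different problem.

## Saturation and label transfer

Saturation downsamples the read-level assignment table (equivalent to
resampling the alignment file, and far cheaper) under a single seeded
permutation, taking nested prefixes at 10/25/50/75/100%. Nesting makes
the subset property exact per cell, not just in medians. The cell set is
frozen at full depth, so curves measure molecules-per-called-cell, not
cell discovery. UMIs are re-collapsed at each fraction.

Label transfer normalises both matrices to counts-per-10k + log1p
(the transform ahead of the correlation is a package choice), selects
the top-variance reference features, and scores each query cell by the
mean of its top-k (default 20, matching a typical cell-graph
neighbourhood size) Pearson correlations to reference cells versus to
other query cells. The assignment rule — reference score minus self
score must exceed a margin — keeps cells that resemble the reference
more than their own dataset. The margin defaults to 0 (strictly
greater); because correlations are bounded by 1, any published
"difference > 1"-style cutoff cannot be read literally on this scale,
so the margin is an explicit parameter rather than a guessed constant.
Note the top-k order statistics depend on pool size: comparing a
reference pool much larger than the query pool biases the reference
score upward under the null, which is why the null-rejection test uses
matched pool sizes.

## RIN inference

The ribosomal fraction of a trace is the trapezoidal area of all
annotated non-marker windows over the total trace area minus the lower
marker window, after subtracting a flat baseline (the global fluorescence
minimum). Window areas use the sample points falling inside the window;
with the default 2000-point grid the discretisation error is far below
the 1% the tests allow. A trace that is entirely baseline has no
defined fraction; it is reported as 0 with a warning rather than an
exception, since a flat trace genuinely contains no ribosomal signal.
Band windows are caller-supplied intervals, not auto-detected peaks —
peak calling belongs to the instrument software. The hidden-break case
is handled by annotation: if the two 28S fragments are given their own
windows, both count as ribosomal signal, which is exactly the rationale
for preferring this statistic over the instrument's RIN on invertebrate
samples. Calibration is ordinary least squares of known RIN on fraction
(≥ 3 points, non-degenerate design required) and predictions are clamped
to [1, 10]. The synthetic trace generator places marker/18S/28S
Gaussians plus a degradation smear whose area grows as intactness falls;
it exists to test invariances (scaling, monotonicity, hidden-break
neutrality), not to imitate a specific instrument.

## Pipeline

`run_pipeline` executes simulate → curate/demux (per sub-library) →
quant → species QC → saturation. Per-stage seeds derive from the global
seed by hashing the stage name, so stages re-run in isolation reproduce
their outputs; FASTQ gzip members are written with zeroed mtime so equal
seeds give byte-identical files. The manifest records parameter echo,
per-stage reports and SHA-256 checksums of every output. Validation is
collect-all rather than fail-fast. Exit codes in the CLI: 0 success, 2
validation failure, 3 stage failure.

## Known limitations

- The k-mer assigner has no error model; a substitution that destroys
  every unique k-mer of a short read leaves it unassigned (conservative,
  never wrong-gene at realistic error rates, as the oracle test shows).
- The greedy UMI collapse count can in principle depend on which side of
  a distance-1 tie is processed first; determinism is guaranteed by the
  lexicographic tie-break, not by uniqueness of the optimum.
- The doublet estimator assumes doublet species-pairing is independent
  of depth; simulated depths satisfy this by construction.
- Saturation's subset property relies on nested sampling; independent
  per-fraction samples (as a file-level downsampler would produce) only
  satisfy it in expectation.
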