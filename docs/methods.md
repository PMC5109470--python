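# Methods

This note records the models implemented in `tnpool`, the defaults and why,
what the synthetic-data generator does and does not emulate, and the design
choices made where the problem left room.

## Pooling geometry and address arithmetic

A collection of `P` plates of `R × C` wells (defaults 8 × 12, two sterile
control wells per plate at the last row-major positions) is assigned
row-major, 1-based, onto a virtual plate grid of `PR × PC` positions
(default 20 × 21, holding up to 420 plates; the default collection uses 417).
Each well feeds four pools — row, column, plate-row, plate-column — so the
pool count is `R + C + PR + PC` (61 by default) and pooling costs `4P`
dispatch operations. Grid positions beyond `P` are *phantom plates*: the
inverse mapping rejects them, and the solver prunes candidate addresses that
would land on them.

Because every well contributes an equal aliquot and each pool is
mass-normalised before amplification, a mutant's expected template fraction
in a pool is `1 / (wells feeding that pool)`. The expected column:row
read-count ratio is therefore `C/R = 1.5` for 8 × 12 plates; for the
plate-grid axes the ratio depends on how full each plate-row/column is, and
`expected_template_ratio` averages it over all wells.

## Collection-size models

The Poisson model assumes insertions are uniform, independent, one per
mutant, over `N` equally receptive non-essential genes: the represented-gene
count is `n(k) = N(1 − e^(−k/N))` and the size needed to leave `u` genes
uncovered is `k = N ln(N/u)` (rounded). The Monte Carlo model draws
insertion sites uniformly with replacement from the AT/TA dinucleotides of
eligible loci; non-coding sites consume picks without representing a gene,
so the curve is bounded above by the Poisson curve and plateaus at the count
of genes that actually carry eligible sites. Essentiality is expressed as
label sets (`Dispensable`, `SurpriseDispensable`, `GuessDispensable`,
`DispensableUnclearInEcoli`, `ExpectedEssential`, `NewEssential`, `Unknown`,
plus `NonCoding` for intergenic sites): a "low" non-essential scenario uses
the four Dispensable labels, a "high" scenario adds `Unknown`. Rarefaction
from an observed catalogue shuffles the located-mutant list (sampling
without replacement), so its final value equals the distinct locus count
exactly.

Sites covered by overlapping genes are assigned to the gene whose
translation start lies nearest upstream (strand-aware). This is a modelling
choice — annotation formats do not say how shared sites should be attributed
— and the count of such resolutions is reported on the index.

## Sequencing-read reduction

Reads are accepted when the main read carries the transposon tag at a
configurable offset (a window of offsets is supported for libraries with
variable-length spacers) and the index read matches a pool barcode, both
under a Hamming allowance of 2 mismatches (no indels). Barcode tables are
validated at load: pairwise distance must exceed twice the allowance, which
makes fuzzy assignment provably unambiguous.

Junction coordinates are 1-based and always denote the first genomic base of
the flank 3′ of the transposon. The built-in locator indexes forward-strand
10-mers and queries three seeds per flank (disjoint for flanks ≥ 30 bases, so
by pigeonhole at least one seed is uncontaminated at ≤ 2 substitutions);
candidates are Hamming-verified on both orientations and multi-hit flanks
are discarded, mirroring unique-alignment filtering. Alternatively a SAM
file from an external end-to-end aligner is ingested: plus-strand primary
alignments report POS, minus-strand ones report the rightmost aligned base.

## Pool presence table and thresholding

One table line per unique coordinate accumulates read counts per pool.
Thresholding at `t` removes pool coordinates with fewer than `t` reads; the
surviving pattern classifies the line (single address / multiple on one
axis / ambiguous on several axes / three axes with sub-threshold fourth /
unmappable). The threshold scan (1–30 by default) reports all counts and
chooses the `t` maximising single-address lines, smaller `t` on ties; the
report is emitted so a user can override the choice after inspection, which
formalises an otherwise judgement-based step while keeping it auditable.

## Ratio model and address solving

The six log-ratio histograms are built from single-address lines
(≥ 200 required by default) and each is fitted with
`A · V(x − x0; σ, γ)`, `V` the Voigt profile evaluated through the Faddeeva
function. Fits initialise at (median, IQR/1.349, IQR/10) — robust whether
the data are Gaussian-like or heavy-tailed — with non-negative bounds, and
fall back to a pure Gaussian if the Voigt fit does not converge. Dropping
`A` leaves a density integrating to one; each of the six is normalised
independently (any joint scaling would cancel in ranking). Densities are
floored at 1e−9 outside the fitted support so one out-of-range ratio cannot
zero an otherwise consistent candidate.

Candidates are the Cartesian product of surviving coordinates (phantom
plates pruned); each is scored by the product of the six densities at its
log count ratios, and the top `m` are kept, `m` being the deepest axis's
coordinate count. Ties break by total read count, then address order, so
catalogues are byte-reproducible. Lines with three axes above threshold
borrow the highest sub-threshold fourth-axis coordinate and are flagged as
fill-ins. Runs of consecutive coordinates (gap ≤ 1) mapping to identical
address sets collapse to the A of an AT/TA dinucleotide inside the run, or
to the read-weighted median position when the run contains none; larger gaps
are treated as distinct insertions.

### What ambiguity resolution can and cannot do

An ambiguous line arises when one clone occupies two wells sharing fewer
than three coordinates. Its combinations are separable exactly when the two
wells' template abundances differ: the pure-high and pure-low candidates
then score above every mixed one. When the two colonies happen to grow to
similar abundance the sixteen combinations are statistically exchangeable
and no scoring rule can rank the true pair first — under the default
abundance spread (σ = 1.0 in log units) roughly a quarter of duplicated
clones fall in this regime, so per-line resolution of ambiguous entries
should be expected in the 60–75% range at the top rank and much lower for
exact recovery of both wells. Planted high/low pairs (abundance ratio ≈ 8)
resolve at ≥ 95%. Downstream condensation is largely insulated from this:
it prefers representatives from unambiguously mapped, singly occupied
wells, and verification of the condensed collection is an independent
check.

## Synthetic data generator

The generator emulates, in order: a replicon of genes tiled with intergenic
gaps (every ordinary gene guaranteed ≥ 1 AT/TA site; an optional fraction
built without any site, emulating undisruptable genes); colony picking in
plate order, each well receiving a fresh clone at a distinct site, and with
probability `duplicate_rate` (default per run; 0.15 in the large test
collection) the clone also lands in a second, already occupied well —
biased 50:50 between a same-plate-row well (decodes as an unambiguous
multiple) and a random well (decodes as ambiguous); per-placement template
abundance λ ~ LogNormal(0, σ_a = 1.0), independent per colony because each
grows separately; per-pool expected counts
`D · λ_i / Σ_{j∈pool} λ_j` (depth `D` = 50,000 per pool by default,
reflecting mass-normalised libraries), multiplied by per-(template, pool)
LogNormal(0, σ_p = 0.35) amplification noise — chosen to give log-ratio
histogram widths around 0.5, typical of arbitrary-primed amplicon data —
and Poisson-sampled; a crosstalk fraction (0.5% of depth) routed to pools a
clone does not occupy, emulating index hopping and making read-count
thresholding meaningful; and finally reads: transposon tag + genomic flank
(reverse-complemented for minus-orientation insertions), barcode index
reads, constant 'I' qualities, per-base substitution errors at 0.001.
A deterministic mode turns all noise off and rounds expected counts, for
exact end-to-end tests.

Not emulated: PCR chimeras, indels, quality degradation, amplification bias
by fragment length or GC, replication-origin-proximal insertion bias, and
correlated pool failures. Passing tests on this generator therefore
demonstrate the decoder's statistical machinery, not robustness to every
artefact of real libraries; the SAM ingestion path exists precisely so real
data can use a production aligner.

## Problem sizes and determinism

The test suite exercises a six-plate deterministic collection end-to-end
(~0.5M reads), a forty-plate stochastic collection (3,760 wells, ~1.6M
reads) through the full FASTQ → catalogue path, a 10,000-mutant count-level
simulation for the template-ratio property, and 10^5-sample fits for Voigt
parameter recovery — sizes chosen to make the statistics tight while a full
run stays in the minutes range on one core. Every stochastic component
takes an explicit seed (NumPy `default_rng`); identical inputs and seeds
give byte-identical TSV outputs. Statistical assertions use 3-standard-error
bands; the template-ratio check uses the geometric mean (the natural
location estimate under multiplicative noise) with cluster-robust standard
errors over row/column pool pairs, since mutants sharing a pool share its
normalisation.

## Known limitations

- Well occupancy `m` used by condensation counts *located* co-occupants
  only; unresolved residents are invisible, so `1/m` is optimistic.
- The condensation score's product form `(1/m)(1−d)` treats pick success
  and disruption success as independent; the linear `1−d` disruption model
  is a coarse surrogate for domain structure.
- The built-in locator is designed for synthetic fixtures: it is exact
  Hamming matching, not a gapped aligner.
- Verification tolerance (±2 bp) absorbs junction-calling off-by-ones but
  will also absorb genuinely distinct insertions closer than 2 bp — rare at
  AT/TA site densities, but possible.
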