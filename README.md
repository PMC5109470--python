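# tnpool

Deconvolution, condensation and verification of arrayed transposon mutant
collections from combinatorially pooled amplicon sequencing.

## The problem

A whole-genome knockout collection — one arrayed, clonally isolated disruption
mutant per non-essential gene — is one of the most useful genetic resources
for a microbe, but cataloguing a random transposon library plate by plate is
prohibitively slow. The alternative is combinatorial pooling: every well of
the arrayed progenitor collection is dispatched to four sample pools (its
plate **row**, its plate **column**, and the **plate-row** and
**plate-column** of its plate on a virtual grid), the pools are barcoded,
amplified across the transposon junction and sequenced in one run, and each
insertion's well address is reconstructed from the pools its reads appear in.
With 8 × 12 plates on a 20 × 21 grid this needs only 61 pools and 4 pooling
operations per plate for hundreds of plates.

The catch is that manual pooling carries no checksum: a clone that was picked
into two wells appears in up to eight pools, whose coordinates combine into
many artifactual addresses. `tnpool` implements the probabilistic decoder
that resolves these collisions, plus everything around it: collection-size
planning, a synthetic-data generator, read demultiplexing, pool-presence
tabulation, address solving, condensation to one mutant per gene, and
orthogonal verification of the condensed collection.

## The models

**Coverage.** With `N` non-essential genes and `k` mutants picked, Poisson
statistics give the represented-gene count
`n(k) = N · (1 − e^(−k/N))`, so covering all but one gene needs
`k = N ln N` picks (26,335 for N = 3,256). A Monte Carlo companion model
picks actual AT/TA mariner insertion sites from an annotated genome, so
intergenic hits and site-free genes slow and cap the curve realistically.

**Address solving.** For a mutant in one well, the read counts
`r_r, r_c, r_pr, r_pc` in its four pools all measure the same template, so
each of the six pairwise log-ratios `ln(r_a/r_b)` is drawn from a stable
distribution. These are learned from the unambiguously mapping lines by
fitting a Voigt profile (Gaussian ⊗ Lorentzian) to each log-ratio histogram
and normalising it into a density `f_ab`. A candidate address built from one
coordinate per axis is then scored

```
score = ∏ f_ab( ln(r_a / r_b) )       over the six axis pairs (a, b)
```

and a line with several coordinates per axis keeps its top-`m` candidates,
where `m` is the largest number of coordinates in any single axis.

**Condensation.** A representative for a gene is chosen by
`S = (1/m) · (1 − d)` — the probability that a colony struck from a well with
`m` located occupants is the right clone, times an insertion-position factor
that prefers disruptions near the translation start (`d` = fractional
distance into the gene). Representatives from shared wells get
`⌈ln(1 − 0.85)/ln(1 − 1/m)⌉` colonies picked (clamped to 2–10) for an 85%
chance of catching the right one.

## Worked example

`examples/` holds one short script per capability. Address arithmetic
(`examples/02_pooling_geometry.py`):

```
417 plates, 61 pools, 1,668 pooling operations
plate 394 sits at grid position (19, 16)
well P394_H06 feeds pools: row_H, col_6, pr_19, pc_16
...and those four pools decode back to P394_H06
a mutant's expected column:row template (and read-count) ratio is 1.50 -- column pools collect 8 wells per plate, row pools 12
```

The full decoding pipeline on a simulated six-plate collection
(`examples/03_locate_mutants.py`):

```
535,692 reads; 535,689 with valid tag+barcode; 535,667 located on the genome
564 pool presence lines; read-count threshold chosen: t=5
line classes: {'unambiguous_single': 479, 'unambiguous_multiple': 32, 'ambiguous_multi': 34, 'incomplete_3axis': 11, 'unmappable': 8}
singly placed mutants located at exactly their true well: 491/500 (98.2%)
```

Reads are parsed for the transposon tag and pool barcode (two mismatches
allowed each), located on the genome, tabulated per coordinate and pool,
thresholded (the scan picks the threshold that maximises single-address
lines), and solved; 98.2% of the singly placed mutants land on exactly their
true well. `examples/04_condense_and_verify.py` continues into condensation
and pool-set-intersection verification of the condensed plates.

A thin CLI mirrors the library (`tnpool simulate|fixtures|demux|tabulate|
solve|condense|verify|rarefy`); stages communicate through TSV/JSON files so
an external aligner's SAM output can replace the built-in locator between
`demux` and `tabulate`.

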