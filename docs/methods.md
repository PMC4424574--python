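# Methods

## The measurement model

A multiplex ligation-probe assay reads copy number through amplicon
abundance: probe pairs ligate only on their exact genomic target, ligated
products are amplified with universal primers, and the fluorescence of each
dye/size-resolved peak is proportional to the number of template copies.
`plexdose` operates entirely downstream of the instrument, on the tabular
peak export (sample, dye, apparent size, peak area or height).

The package's working assumption is multiplicative decomposition of the raw
signal:

```
A(s, p) = B · eff(p) · scale(s) · c(s, p) / 2 · exp(ε),   ε ~ N(0, σ²)
```

with `B` an arbitrary base level, `eff(p)` a fixed per-probe amplification
efficiency, `scale(s)` a per-sample factor (DNA input, ligation and PCR
yield), `c(s, p)` the integer copy number, and `ε` multiplicative
measurement noise. Both nuisance factors are removed by quotients, never
estimated: dividing by the sample's reference-probe median cancels
`scale(s)`, and dividing by the per-probe control-cohort median cancels
`eff(p)`. The resulting dosage ratio equals `c/2` exactly in the noiseless
limit, for any copy configuration — a property the test suite asserts.

Medians (not means) are used for both the reference factor and the baseline:
a CNV overlapping a reference probe, or a probe dropout, then perturbs
nothing as long as fewer than half the contributing values are affected.
Self-normalization (`controls="self"`, the default) additionally assumes
that fewer than half the batch is aberrant *at each probe*; it is refused
for batches under 8 samples, and an explicit control-sample set should be
passed whenever carriers dominate (as in a carrier-enriched classification
experiment).

## Fragment matching

Fragments are assigned to the unique same-dye probe within ±0.5 bp of its
expected amplicon size (tolerance configurable). Panels are validated for a
≥ 2 bp same-dye/same-PCR size separation, so under in-spec panels matching
is unambiguous. Two deliberate refusals guard ratio integrity: a fragment
within tolerance of two probes is dropped and flagged (never guessed), and
a second fragment landing on an occupied (sample, probe) cell marks the
cell missing and records a conflict (never overwrites). A sample matching
fewer than 80% of panel probes is flagged failed rather than raising — a
bad injection is data, not a crash. Missing cells stay missing through
normalization; a probe with no signal is reported as "no-signal" because a
homozygous loss and an assay failure are indistinguishable at ratio level.

## Calling and segmentation

Thresholds are fixed, not fitted: loss below 0.75 and gain above 1.25 for
the high-density four-dye mode, 0.70/1.30 for classic MLPA practice.
Values exactly at a threshold call normal in both modes — one inclusive
rule covering both the "between 0.75 and 1.25 is normal" and the strict
"< 0.70" / "> 1.30" conventions. Both pairs are symmetric about 1, so the
reflection `r -> 2 - r` exchanges gains and losses; every MLPA-mode
aberrant call is also aberrant in the tighter mode, never the reverse.

Segments are maximal runs of consecutive same-state aberrant probes on one
chromosome. Policy choices:

* `min_probes_per_segment = 2` — an isolated aberrant probe is emitted as a
  flag requiring confirmation, not a call; real single-probe events (e.g. a
  two-probe micro-duplication) still segment because the demo panel gives
  every named region at least two probes.
* Missing probes inside a run neither break nor extend it (configurable via
  `bridge_missing`); they are excluded from `n_probes` and the mean ratio.
* A direct loss→gain transition breaks the run — composite events such as a
  deletion immediately followed by a duplication on 8p23 yield two abutting
  segments, and the second segment's proximal-uncertainty interval spans
  from the last probe of the first event.

Segment coordinates are the anchor positions of the first and last aberrant
probe (1-based inclusive; BED export shifts to 0-based half-open). True
breakpoints are reported only as uncertainty intervals — the open gap
between the last non-member probe and the first member probe — which is the
tightest localization a probe assay can give.

## LCR classification

Recurrent 22q11.2 rearrangements are mediated by the low-copy repeats
LCR22A–H, which carry no unique probes; breakpoints therefore fall in
probe-free gaps. A segment is classified by matching each uncertainty
interval against the LCR map, each block widened by `tolerance_bp`
(default 200 kb). When several blocks overlap one interval the largest
overlap wins, ties going to the more proximal block. A class name
("A-D", "A-C", "E-H", ...) requires distinct proximal and distal blocks;
segments flanked by no block — or the same block twice, as for a small
interstitial variant — are "atypical", and segments outside the mapped
region (other chromosomes, 22q13) are "n/a".

The bundled LCR map is a schematic reconstruction, not measured
coordinates: blocks are placed in the demo panel's probe-free gaps so that
the published marker relations hold (proximal breakpoints between USP18
and DGCR6; LCR22B-flanked breakpoints between RTN4R and ZNF74; LCR22C
between MED15 and PI4KA). Users with real LCR coordinates supply their own
YAML map.

## The simulator

`simulate` draws directly from the measurement model above:
`eff(p) = exp(N(0, 0.25²))` frozen per (panel, seed); `scale(s) =
exp(N(0, 0.3²))` per sample; noise `σ = 0.04` by default; base area 1000
arbitrary units. Copy state 0 suppresses the fragment entirely rather than
emitting a zero-area peak, exercising the missing-cell path. Fragment sizes
are emitted exactly at the expected amplicon size; apparent-size error and
electrophoretic artifacts (stutter, pull-up, baseline drift) are not
modelled — size-tolerance behaviour is exercised by dedicated fixtures
instead. Cohorts are shuffled with a seeded generator and always accompanied
by a truth table, so scoring never infers truth from sample naming.

The default `σ = 0.04` keeps post-normalization per-probe CVs under the 0.1
QC bound with margin; it is a tunable describing a well-behaved run, not a
claim about any particular instrument. Consequences for interpretation:
passing tests demonstrate that the *analysis* recovers what the signal
model encodes — they do not validate ligation chemistry, probe specificity,
or real-world noise spectra, which can only come from instrument data.

## Statistics

Fisher's exact test computes the two-sided P by point-probability
summation: with margins fixed, the count `a` is hypergeometric, and all
tables with point probability at most `(1 + 1e-7)` times the observed one
are summed (the slack guards against floating-point ties; log-PMFs keep
cohort-scale tables, n ≈ 7,000, exact). The test suite checks the routine
against an independent exact-fraction enumeration oracle up to n = 200 and
against a second independent implementation. One-sided variants sum the
corresponding tail in `a`.

Frequency percentages round half away from zero to one decimal. The
2^−ΔΔCT converter assumes the calibrator is diploid at the target locus and
applies the cut-offs N < 1.5 (deletion) and N > 2.5 (duplication); note a
gain of one copy (N = 3) is a 50% increase over diploid. Sensitivity and
specificity are computed at carrier level: a sample is a predicted carrier
when at least one segment is called.

## Problem sizes and numerical choices

* The acceptance script runs 50 seeded 110-sample validation cohorts
  (~48 s total), a single 16-sample replicate study, and a single
  100-sample classification cohort — sizes chosen to mirror the validation
  designs the assay is judged on while remaining desk-scale.
* Per-probe CVs use the sample (n−1) standard deviation, chosen so the
  {0.9, 1.0, 1.1} fixture gives CV = 0.1 exactly; the pass comparison
  carries a 1e-9 relative slack so threshold-equal CVs pass despite float
  accumulation.
* CV grouping is by known copy state (mixing states would inflate CV
  mechanically); the grouping is a parameter for labs that pool.
* Peak-file round-trips parse floats with round-trip precision so simulated
  matrices survive write/read byte-exactly.
* Degenerate Fisher tables whose summation covers the full support snap to
  P = 1 (the exact value) instead of accumulating rounding error.

## Known limitations

* No statistical segmentation (CBS/HMM), mosaicism fractions, or
  parent-of-origin inference; calling is per-probe thresholding.
* No size/GC/slope signal corrections or plate-effect regression; the
  two-quotient normalization is the whole model.
* The demo panel's probe coordinates are schematic (anchored to published
  deletion endpoints with evenly spaced fillers); orderings are faithful,
  absolute positions are not.
* Proprietary binary chromatograms (.fsa) are out of scope; analysis starts
  at the tabular peak export.
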