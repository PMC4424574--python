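# plexdose

Targeted copy-number analysis for multiplex ligation-probe assays
(MLPA and its high-density four-dye variants), aimed at clinical and
research labs screening recurrent CNVs — in particular 22q11.2
deletions/duplications in congenital heart disease cohorts — from capillary
fragment-analysis peak tables.

In these assays each genomic locus is interrogated by a ligation probe pair;
after ligation and universal-primer PCR, the amount of each dye-labelled
amplicon is proportional to the target's copy number. Starting from a
GeneMapper-style peak export, `plexdose`:

1. **models and validates the probe panel** — dye channels, expected amplicon
   sizes, the 96-probes-per-PCR capacity, the 72 bp synthesis limit, and
   per-dye fragment-size separation;
2. **normalizes peak areas into dosage ratios**: each sample is scaled by the
   median area of its reference probes, then each probe is divided by its
   control-cohort median baseline, so the diploid expectation is

   `r(s, p) = [A(s, p) / med_ref A(s, ·)] / med_controls [A(·, p) / med_ref A(·, ·)] ≈ c(s, p) / 2`

   where `A` is peak area and `c` the copy number (1.0 diploid, ~0.5
   heterozygous deletion, ~1.5 single-copy gain);
3. **calls and segments CNVs** by fixed ratio thresholds — loss < 0.75,
   gain > 1.25 (or the classic MLPA window < 0.70 / > 1.30) — merging
   consecutive aberrant probes into segments with breakpoint-uncertainty
   intervals, and classifying 22q11.2 segments against the LCR22A–H
   low-copy-repeat map (typical A–D deletion, nested A–B / A–C, distal E–H
   duplication);
4. **reports assay QC** (per-probe CV = sd/mean within copy-state groups,
   pass at CV ≤ 0.1) and **cohort statistics**: Fisher's exact 2×2 tests,
   carrier-frequency tables, sensitivity/specificity scoring, and qPCR
   2^−ΔΔCT copy-number confirmation (N = 2·2^−ΔΔCT; N < 1.5 deletion,
   N > 2.5 duplication);
5. **simulates** whole cohorts with a seeded log-normal signal model, so the
   entire chain is testable without instrument data.

A bundled demo panel reproduces the geometry of a 189-probe 22q11.2 assay
(157 target + 32 reference probes in two 96/93 PCRs over four dyes), with
schematic coordinates anchored to published recurrent-deletion endpoints.

## Worked example

```python
from plexdose import *
from plexdose.simulate import known_cnv_specs

panel = build_demo_panel()
lcr = build_demo_lcr_map()
reg = known_cnv_specs()
peaks, truth = simulate_cohort(
    panel, {reg["normal"]: 10, reg["A-D"]: 1, reg["TOP3B-dup"]: 1},
    SimConfig(seed=7, noise_sigma=0.04))
result = run_calling(peaks, lcr_map=lcr)
for seg in result.segments:
    print(f"{seg.sample_id}  {seg.chrom}:{seg.start}-{seg.end}  {seg.state}"
          f"  n_probes={seg.n_probes}  mean_ratio={seg.mean_ratio:.2f}"
          f"  class={seg.lcr_class}  span={segment_length_mb(seg)} Mb")
sens, spec = sensitivity_specificity(result.predicted_carriers(),
                                     truth.set_index("sample_id")["carrier"])
print(f"sensitivity={sens:.0f}%  specificity={spec:.0f}%")
```

prints

```
S010  chr22:18893757-21464055  loss  n_probes=59  mean_ratio=0.49  class=A-D  span=2.57 Mb
S011  chr22:22312856-22330186  gain  n_probes=2  mean_ratio=1.46  class=atypical  span=0.02 Mb
sensitivity=100%  specificity=100%
```

The first call is the typical 2.57 Mb LCR22A–LCR22D deletion (59 probes at
mean ratio ≈ 0.5, one copy of two); the second is a two-probe TOP3B
micro-duplication, too small to be flanked by LCR blocks and therefore
reported "atypical". Both simulated carriers are recovered and none of the
ten diploid samples yields a call.

The same workflow is available from the shell:

```sh
plexdose demo --out-dir assets
plexdose simulate --panel assets/demo_panel.tsv --classes assets/classes.yaml \
    --seed 7 --out-peaks peaks.tsv --out-truth truth.tsv
plexdose call --peaks peaks.tsv --panel assets/demo_panel.tsv \
    --lcr-map assets/lcr_map.yaml --out-prefix run1
plexdose report --calls run1.calls.tsv --phenotypes pheno.tsv --out-prefix run1
```

## Layout

| module | purpose |
| --- | --- |
| `plexdose.panel` | probe/panel types, manifest I/O, design-rule validation, demo panel, LCR map |
| `plexdose.signals_io` | peak-table reading and dye+size fragment matching; calls/BED/ratio output |
| `plexdose.normalize` | reference-probe scaling and control-baseline dosage ratios |
| `plexdose.qc` | per-probe CV report within copy-state groups |
| `plexdose.caller` | threshold calling, segmentation, LCR classification |
| `plexdose.simulate` | seeded cohort simulator and named CNV profiles |
| `plexdose.stats` | Fisher exact, frequency tables, 2^−ΔΔCT, sensitivity/specificity |
| `plexdose.cli` | `plexdose` command: simulate / call / qc / report / demo |

See `docs/methods.md` for the modelling assumptions, parameter defaults, and
known limitations.
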