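# eccpipe

Detection and characterization of **extrachromosomal circular DNA
(eccDNA)** from circle-enriched paired-end sequencing (Circle-seq /
cirSeq-style libraries: exonuclease digestion of linear DNA, rolling-circle
amplification, 150-bp paired-end Illumina reads), for researchers who want
a tested, fully simulatable pipeline from alignments to cohort statistics.

A circle occupying `[s, e)` on the linear reference (0-based half-open, so
its length is `e − s`) betrays itself in three ways:

* **split reads** — a read crossing the circle junction aligns as a
  right-clipped segment ending exactly at `e` plus a left-clipped
  supplementary starting exactly at `s` (same chromosome and strand);
* **outward-facing (RF) discordant pairs** — mates of a junction-spanning
  fragment point away from each other, bounding the junction to within an
  insert length;
* **coverage enrichment** — rolling-circle amplification piles depth onto
  `[s, e)` relative to the genome-wide background.

Split junctions are clustered with a ±5 bp tolerance; a cluster becomes a
call with ≥2 split reads (or 1 split + ≥2 discordant pairs) and ≥2-fold
enrichment.  Catalogs are then characterized (200-bp length histograms,
the 400–6000 bp band fraction, chromosome of origin with a
length-proportionality χ² test, full-gene / partial-gene / intergenic
content with feature subtypes) and compared across samples (Student's *t*
/ one-way ANOVA, fold changes, median high/low stratification, Pearson
correlation with expression).  A seeded simulator generates the reference,
gene models, ground-truth circles and the entire read library — including
the truth alignments — so every stage is testable without downloads or an
external aligner.  See `docs/methods.md` for the model and its
assumptions.

## Worked example

The `analysis/` scripts run the whole study on synthetic data; computation
lives in the `eccpipe` package:

```sh
python analysis/01_build_reference.py   # 3 Mb genome, 40 genes
python analysis/02_simulate_cohort.py   # 6 samples: 3 low-, 3 high-burden
python analysis/03_call_circles.py
python analysis/04_characterize.py
python analysis/05_cohort_stats.py
```

which prints, among other lines:

```
high3: 57 circles called, recall 1.000, precision 1.000
...
high2: 50 circles, mean 1711 bp, 98.0% in 400-6000 bp, full-gene 0.0%, chrom chi2 p=0.920
...
burden high_burden vs low_burden: means {'high_burden': 50.666..., 'low_burden': 15.0},
  t=9.175, p=0.00078, fold change 3.38
median split at 31.5: 3 high / 3 low
marker1: r=0.992, R^2=0.983, p=0.00011
```

Reading: on error-free truth alignments every simulated circle is
recovered with breakpoints within ±5 bp (recall = precision = 1); circle
lengths concentrate in the 400–6000 bp band as configured; per-chromosome
circle counts are consistent with chromosome lengths (χ² p > 0.01); the
high-burden group carries 3.4× the circles of the low-burden group
(t test p < 0.001); and marker expression co-simulated from the called
burdens is recovered with r ≈ 0.99.  Tables land in `results/`,
intermediate SAM/FASTA in `scratch/`.

The same steps are available as a CLI for running on your own data
(`eccpipe fixtures`, `eccpipe simulate`, `eccpipe call --sam in.sam`,
`eccpipe annotate`, `eccpipe cohort`); real alignments must come from an
aligner that emits supplementary (SA-tagged) split alignments.

As a library:

```python
from eccpipe import (make_reference, make_annotation, SimConfig,
                     sample_circles, simulate_reads, write_truth_sam,
                     call_circles)

asm = make_reference(2, [1_000_000, 2_000_000], gc=0.42, seed=7)
ann = make_annotation(asm, 40, (2000, 10_000), (2, 5), seed=8)
cfg = SimConfig(n_circles=50, seed=11, n_read_pairs=12_000)
circles = sample_circles(asm, ann, cfg)
result = simulate_reads(asm, circles, cfg)
write_truth_sam(result, asm, "sample.sam")
catalog, qc = call_circles("sample.sam", asm.lengths, sample_id="s1")
print(catalog.n_eccDNA, catalog.mean_length)
```

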