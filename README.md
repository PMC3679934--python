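# amperr

Error profiling for 454-style amplicon sequencing.

High-coverage amplicon assays on flow-based pyrosequencers (HLA typing on
the GS Junior being the canonical case) need a quantitative error profile
before they can be trusted diagnostically: how many bases are wrong, of
which type, where in the read, in what sequence context, and how honestly
the instrument's quality scores describe them. `amperr` implements that
characterization as a reusable pipeline — reads plus references plus a
truth set of expected variants in, error rates and context/quality
analytics out — together with a synthetic read generator that reproduces
the statistical structure of such data with per-read ground truth, so the
whole pipeline is testable without access to any proprietary run data.

## What it computes

Given exon-annotated reference amplicons, quality-scored reads tagged by
run, and the expected variants per sample (plus known pseudogene
side-products, which are systematic differences, not errors):

- **Error rates** — total and per type (insertion / deletion /
  substitution), as erroneous bases over analyzed exon bases, where an
  event of length L counts L bases; per-read statistics (fraction of reads
  with errors, errors per erroneous read); mean error lengths.
- **Reproducibility** — event keys `(amplicon, left-aligned position,
  type, bases)` present in every run of the same library, and the base
  mass they carry.
- **Positional structure** — coverage-normalized error histograms over
  read positions and the median error position.
- **Homopolymer context** — background run-length composition of the
  references vs the run lengths associated with errors, a chi-square
  enrichment test, and the run-length/quality correlation.
- **Quality analytics** — phred scores averaged in error-rate space
  (Q = −10·log₁₀(p)); quality at error sites vs their 5-base
  neighborhoods; per-position quality curves; estimated-vs-empirical
  quality calibration tables.
- **Correction hook** — before/after erroneous-read fractions for any
  external read corrector (the corrector itself is out of scope).

Alignment is semi-global with affine gaps (match +2, mismatch −3, open −5,
extend −2) with indels left-aligned inside homopolymers, so recurrent
errors share one canonical coordinate. Only exon sequence is analyzed.

## Worked example

```python
from amperr.pipeline import PipelineConfig, run_pipeline
from amperr.simulate import SimulationConfig

config = PipelineConfig(
    simulation=SimulationConfig(n_runs=3, reads_per_amplicon=150, seed=11),
    seed=11,
)
summary = run_pipeline(config).summary
```

prints (via `examples/02_profile_errors.py`):

```
reads analyzed:        1350 (79.42% of raw bases kept after exon clipping)
events by class:       {'true_variant': 2436, 'pseudogene_product': 660, 'error': 539}
total error rate:      0.1486% of exon bases (ins 0.0875% / del 0.0417% / sub 0.0195%)
reads with >=1 error:  32.7%
mean error length:     1.01 bases
reproducible errors:   43.36% of erroneous bases recur at the same key in all 3 runs
median error position: 146.0 (read positions, 1-based)
```

Reading it: ~80% of raw bases survive primer trimming and exon clipping;
discrepancies split into expected allele variants, pseudogene
side-products and genuine sequencing errors; errors touch ~0.15% of exon
bases (indels dominating, as homopolymer miscalls should) yet a third of
reads carry at least one; and a large share of erroneous bases recur at
identical coordinates across independent runs — systematic, sequence-
driven errors, not random noise.

The `examples/` directory holds one short script per capability:
simulation to FASTQ/FASTA/TSV (`01`), end-to-end profiling (`02`),
quality-valley and calibration analytics (`03`), homopolymer context and
association (`04`). A thin CLI wraps the same stages:
`amperr simulate`, `amperr profile`, `amperr report`.

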