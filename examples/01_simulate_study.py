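"""Simulate a small multi-run amplicon study and write it to disk.

Generates reference amplicons (primer | flank | exon | flank | primer),
an allele carrying known true variants, a pseudogene co-amplified on one
locus, and two runs of quality-scored reads with homopolymer-aware
errors — everything the error-profiling pipeline needs, plus the ground
truth to check it against.
"""

from amperr import io as aio
from amperr.simulate import SimulationConfig, simulate_study

config = SimulationConfig(n_runs=2, reads_per_amplicon=100, seed=42)
study = simulate_study(config)

refs = study.references
print(f"amplicons: {[a.amplicon_id for a in refs.amplicons]}")
print(f"expected true-variant keys: {len(refs.truth_set.expected)}")
print(f"pseudogene loci: {list(refs.pseudogenes)} "
      f"(co-amplified at {config.pseudogene_fraction:.0%} of reads)")

n_reads = sum(len(r) for r in study.reads_by_run.values())
n_errors = sum(len(t.events) for t in study.all_truth)
print(f"simulated {n_reads} reads over {config.n_runs} runs; "
      f"{n_errors} error events injected (ground truth)")

outdir = "scratch/example_study"
aio.ensure_dir(outdir)
aio.write_fasta({a.amplicon_id: a.sequence for a in refs.amplicons},
                f"{outdir}/references.fasta")
aio.write_amplicon_table(refs.amplicons, f"{outdir}/amplicons.tsv")
aio.write_truth_set(refs.truth_set, f"{outdir}/truth_set.tsv")
for run_id, reads in study.reads_by_run.items():
    aio.write_fastq(reads, f"{outdir}/{run_id}.fastq")
print(f"wrote FASTA/TSV/FASTQ to {outdir}/")
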