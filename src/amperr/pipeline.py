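"""End-to-end orchestration: reads in, error profile and reports out.

A pipeline run takes either a simulation block (references, truth and reads
are generated) or paths to FASTA/TSV/FASTQ inputs, then trims primers,
aligns, clips to exons, extracts and classifies discrepancies, and produces
every headline statistic plus the context/quality analyses. Reruns with the
same configuration and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as aio
from .alignment import (
    AlignScores,
    ReadRejected,
    align_read,
    aligned_read_bases,
    clip_to_exon,
    make_aligner,
    trim_primers,
)
from .model import ERROR, AlignedRead, Read, ReferenceAmplicon, TruthRecord, TruthSet
from .profiling import (
    compute_error_rates,
    per_read_stats,
    positional_distribution,
    reproducible_errors,
    run_summary,
)
from .quality import (
    annotate_error_context,
    association_test,
    average_quality,
    background_distribution,
    calibration_curve,
    context_class_counts,
    error_neighborhood_quality,
    homopolymer_quality_table,
    per_position_quality,
    quality_homopolymer_correlation,
    scan_homopolymers,
)
from .simulate import SimulationConfig, SimulatedStudy, simulate_study
from .variants import (
    bidirectional_support,
    classify_variants,
    errors_only,
    events_to_dataframe,
    extract_variants,
)

log = logging.getLogger("amperr")


@dataclass
class InputPaths:
    references_fasta: str
    amplicon_tsv: str
    fastq_by_run: Mapping[str, str]  # run_id -> fastq path
    truth_tsv: str


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end analysis.

    Exactly one of ``simulation`` and ``inputs`` must be set.
    """

    simulation: Optional[SimulationConfig] = None
    inputs: Optional[InputPaths] = None
    scores: AlignScores = field(default_factory=AlignScores)
    min_alignment_score: Optional[float] = 0.0
    adjacency_window: int = 1
    n_neighbors: int = 5
    correction: object = "none"  # 'none' | ('drop_erroneous_fraction', f) | ('external', ids)
    output_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of simulation / inputs must be configured")
        if self.simulation is not None:
            self.simulation.validate()


@dataclass
class CorrectionResult:
    mode: str
    before_fraction: float
    after_fraction: float

    @property
    def recovered_fraction(self) -> float:
        return self.before_fraction - self.after_fraction


def correction_hook(
    read_ids: Sequence[str],
    erroneous_ids: Set[str],
    mode="none",
    rng: Optional[np.random.Generator] = None,
) -> CorrectionResult:
    """Report before/after erroneous-read fractions for a corrector.

    ``mode`` is ``'none'``, ``('drop_erroneous_fraction', f)`` (a stub
    corrector that fixes a fraction f of erroneous reads), or
    ``('external', corrected_ids)`` where an external tool claims to have
    corrected the given reads. The denominator is all analyzed reads in
    every fraction, so ``recovered = before - after`` is the share of total
    reads rescued by correction.
    """
    n = len(read_ids)
    if n == 0:
        raise ValueError("no reads")
    unknown = erroneous_ids - set(read_ids)
    if unknown:
        raise ValueError(f"erroneous ids not among reads: {sorted(unknown)[:3]}")
    before = len(erroneous_ids) / n
    if mode == "none":
        return CorrectionResult("none", before, before)
    kind, arg = mode
    if kind == "drop_erroneous_fraction":
        f = float(arg)
        if not 0.0 <= f <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        ordered = sorted(erroneous_ids)
        if rng is not None:
            ordered = [ordered[i] for i in rng.permutation(len(ordered))]
        n_fix = int(round(f * len(ordered)))
        remaining = len(ordered) - n_fix
        return CorrectionResult(f"drop_erroneous_fraction({f})", before, remaining / n)
    if kind == "external":
        corrected = set(arg)
        unknown = corrected - set(read_ids)
        if unknown:
            raise ValueError(f"external correction names unknown reads: {sorted(unknown)[:3]}")
        remaining = erroneous_ids - corrected
        return CorrectionResult("external", before, len(remaining) / n)
    raise ValueError(f"unknown correction mode {mode!r}")


@dataclass
class PipelineResult:
    config: PipelineConfig
    amplicons: List[ReferenceAmplicon]
    truth_set: TruthSet
    reads_by_run: Dict[str, List[Read]]
    alignments: List[AlignedRead]
    classified: list
    discard_tally: Dict[str, int]
    total_exon_bases: int
    raw_bases: int
    summary: Dict
    tables: Dict[str, pd.DataFrame]
    study: Optional[SimulatedStudy] = None

    def write_outputs(self, outdir: str) -> None:
        aio.ensure_dir(outdir)
        for name, table in self.tables.items():
            table.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=True)
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)


def _truth_error_masks(
    reads: Iterable[Read], truth: Iterable[TruthRecord]
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """(reported quality, per-base error flag) per read, from ground truth.

    Substituted and inserted read bases are labelled erroneous; deletions
    leave no read base to label.
    """
    by_id = {t.read_id: t for t in truth}
    out = []
    for r in reads:
        mask = np.zeros(len(r.sequence), dtype=bool)
        rec = by_id.get(r.read_id)
        if rec is not None:
            for ev in rec.events:
                if ev.kind in ("sub", "ins"):
                    mask[ev.read_pos - 1 : ev.read_pos - 1 + ev.length] = True
        out.append((r.quals, mask))
    return out


def _event_error_masks(
    trimmed_quals: Mapping[str, np.ndarray], errors
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Per-base error labels mapped back from classified error events."""
    masks = {rid: np.zeros(len(q), dtype=bool) for rid, q in trimmed_quals.items()}
    for ev in errors:
        if ev.kind == "del":
            continue
        m = masks.get(ev.read_id)
        if m is not None:
            m[ev.read_pos - 1 : ev.read_pos - 1 + ev.length] = True
    return [(trimmed_quals[rid], masks[rid]) for rid in sorted(trimmed_quals)]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and return every statistic plus report tables."""
    config.validate()
    study: Optional[SimulatedStudy] = None
    if config.simulation is not None:
        study = simulate_study(config.simulation)
        amplicons = study.references.amplicons
        truth_set = study.references.truth_set
        reads_by_run = study.reads_by_run
    else:
        paths = config.inputs
        seqs = aio.read_fasta(paths.references_fasta)
        amplicons = aio.read_amplicon_table(paths.amplicon_tsv, seqs)
        truth_set = aio.read_truth_set(paths.truth_tsv, [a.amplicon_id for a in amplicons])
        reads_by_run = {
            run_id: aio.read_fastq(path, run_id)
            for run_id, path in paths.fastq_by_run.items()
        }
    amp_by_id = {a.amplicon_id: a for a in amplicons}
    aligner = make_aligner(config.scores)

    alignments: List[AlignedRead] = []
    discard = {"primer_trim": 0, "unalignable": 0, "no_exon_overlap": 0}
    raw_bases = 0
    for run_id in sorted(reads_by_run):
        for read in reads_by_run[run_id]:
            raw_bases += len(read.sequence)
            amp = amp_by_id[read.amplicon_id]
            try:
                trimmed = trim_primers(read, amp)
            except ReadRejected:
                discard["primer_trim"] += 1
                continue
            try:
                ar = align_read(
                    trimmed, amp, config.scores, config.min_alignment_score, aligner
                )
            except ReadRejected:
                discard["unalignable"] += 1
                continue
            try:
                alignments.append(clip_to_exon(ar, amp))
            except ReadRejected:
                discard["no_exon_overlap"] += 1

    total_exon_bases = sum(aligned_read_bases(ar) for ar in alignments)
    if total_exon_bases == 0:
        raise ValueError("no exon bases survived trimming/alignment/clipping")

    classified = []
    for ar in alignments:
        classified.extend(classify_variants(extract_variants(ar, amp_by_id[ar.amplicon_id]), truth_set))
    errors = errors_only(classified)

    analyzed_ids = [ar.read_id for ar in alignments]
    rates = compute_error_rates(errors, total_exon_bases)
    reads_stats = per_read_stats(errors, analyzed_ids)

    errors_by_run: Dict[str, list] = {run_id: [] for run_id in reads_by_run}
    for ev in errors:
        errors_by_run[ev.run_id].append(ev)
    repro = (
        reproducible_errors(errors_by_run) if len(errors_by_run) >= 2 else None
    )

    # homopolymer context
    runs_by_amp = {a.amplicon_id: scan_homopolymers(a.sequence, a.amplicon_id) for a in amplicons}
    contexts = [
        annotate_error_context(ev, runs_by_amp[ev.amplicon_id], config.adjacency_window)
        for ev in errors
    ]
    background = background_distribution({a.amplicon_id: a.exon_sequence for a in amplicons})
    class_counts = context_class_counts(contexts)
    if errors:
        chi2, assoc_p, dof = association_test(class_counts, background)
    else:
        chi2 = assoc_p = dof = float("nan")

    # quality analyses
    read_lengths = [ar.read_length for ar in alignments]
    posdist = positional_distribution(errors, read_lengths, contexts)
    trimmed_quals = {
        ar.read_id: (ar.quals[::-1] if ar.strand == "-" else ar.quals) for ar in alignments
    }
    neigh = error_neighborhood_quality(errors, trimmed_quals, config.n_neighbors)
    all_reads = [r for run_id in sorted(reads_by_run) for r in reads_by_run[run_id]]
    ppq = per_position_quality(r.quals for r in all_reads)
    if study is not None:
        calib = calibration_curve(_truth_error_masks(all_reads, study.all_truth))
    else:
        calib = calibration_curve(_event_error_masks(trimmed_quals, errors))
    pairs = [
        (L, average_quality(ev.quals)) for L, ev in zip(contexts, errors) if ev.quals
    ]
    if len(pairs) >= 3:
        hp_r, hp_p = quality_homopolymer_correlation(pairs)
    else:
        hp_r = hp_p = float("nan")
    hp_q_table = homopolymer_quality_table(
        [ev for ev, _ in zip(errors, contexts)], contexts
    ) if errors else pd.DataFrame()

    both, both_frac, n_keys = bidirectional_support([cv.event for cv in classified])
    rsummary = run_summary(reads_by_run)

    err_ids = {ev.read_id for ev in errors}
    corr = correction_hook(
        analyzed_ids, err_ids, config.correction, np.random.default_rng(config.seed)
    )

    n_by_class = pd.Series([cv.cls for cv in classified]).value_counts().to_dict() if classified else {}
    mean_q_all = (
        average_quality(np.concatenate([r.quals for r in all_reads])) if all_reads else float("nan")
    )
    summary = {
        "seed": config.seed,
        "adjacency_window": config.adjacency_window,
        "n_neighbors": config.n_neighbors,
        "min_alignment_score": config.min_alignment_score,
        "reads_total": len(all_reads),
        "reads_analyzed": len(analyzed_ids),
        "reads_discarded": discard,
        "raw_bases": raw_bases,
        "total_exon_bases": total_exon_bases,
        "output_retention_percent": round(100.0 * total_exon_bases / raw_bases, 2),
        "events_total": len(classified),
        "events_by_class": {k: int(v) for k, v in n_by_class.items()},
        "erroneous_bases": rates.erroneous_bases,
        "total_error_rate_percent": round(100.0 * rates.total_rate, 4),
        "error_rate_percent_by_type": {
            k: round(100.0 * v, 4) for k, v in rates.rate_by_type.items()
        },
        "mean_error_length_by_type": {
            k: (round(v, 2) if np.isfinite(v) else None)
            for k, v in rates.mean_length_by_type.items()
        },
        "mean_error_length": round(rates.mean_event_length, 2)
        if np.isfinite(rates.mean_event_length)
        else None,
        "reads_with_errors_percent": round(100.0 * reads_stats.fraction_with_errors, 1),
        "mean_errors_per_erroneous_read": round(reads_stats.mean_errors_per_erroneous_read, 2)
        if np.isfinite(reads_stats.mean_errors_per_erroneous_read)
        else None,
        "reproducible_error_fraction_percent": round(
            100.0 * repro.fraction_of_erroneous_bases, 2
        )
        if repro
        else None,
        "reproducible_error_bases": repro.base_count if repro else None,
        "median_error_read_position": posdist.median_position
        if np.isfinite(posdist.median_position)
        else None,
        "mean_quality_all_bases": round(mean_q_all, 2) if np.isfinite(mean_q_all) else None,
        "mean_error_site_q": round(neigh.mean_error_q, 2)
        if np.isfinite(neigh.mean_error_q)
        else None,
        "mean_neighborhood_q": round(neigh.mean_neighborhood_q, 2)
        if np.isfinite(neigh.mean_neighborhood_q)
        else None,
        "homopolymer_association_chi2": round(chi2, 3) if np.isfinite(chi2) else None,
        "homopolymer_association_p": assoc_p if np.isfinite(assoc_p) else None,
        "homopolymer_quality_correlation_r": round(hp_r, 4) if np.isfinite(hp_r) else None,
        "homopolymer_quality_correlation_p": hp_p if np.isfinite(hp_p) else None,
        "bidirectional_keys": both,
        "bidirectional_fraction_percent": round(100.0 * both_frac, 1),
        "variant_keys_total": n_keys,
        "correction": {
            "mode": corr.mode,
            "before_percent": round(100.0 * corr.before_fraction, 1),
            "after_percent": round(100.0 * corr.after_fraction, 1),
            "recovered_percent": round(100.0 * corr.recovered_fraction, 1),
        },
        "mean_reads_per_run": rsummary.attrs["mean_reads_per_run"],
    }

    tables = {
        "events": events_to_dataframe(classified),
        "run_summary": rsummary,
        "positional_errors": posdist.table,
        "calibration": calib,
        "per_position_quality": ppq,
        "context_classes": pd.DataFrame(
            {"errors": class_counts, "background_fraction": background}
        ),
        "neighborhood_quality_per_run": neigh.per_run,
        "homopolymer_quality": hp_q_table,
    }

    result = PipelineResult(
        config=config,
        amplicons=list(amplicons),
        truth_set=truth_set,
        reads_by_run=dict(reads_by_run),
        alignments=alignments,
        classified=classified,
        discard_tally=discard,
        total_exon_bases=total_exon_bases,
        raw_bases=raw_bases,
        summary=summary,
        tables=tables,
        study=study,
    )
    if config.output_dir:
        result.write_outputs(config.output_dir)
    return result
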