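"""Aggregate error statistics: rates by type, per-read tallies, cross-run
reproducibility, and positional error distributions.

The headline quantity is the total error rate, defined as the fraction of
erroneous bases among all analyzed exon bases, where an event of length L
contributes L erroneous bases (for a deletion, the L deleted reference
bases). Rates are kept as exact fractions in machine output; report
rounding (percent to 2 decimals for rates, 1 decimal for read fractions)
happens only at the presentation layer.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .model import Read, VariantEvent

EVENT_KINDS = ("ins", "del", "sub")


@dataclass
class ErrorRates:
    """Per-type and total error rates over a base denominator."""

    total_bases: int
    bases_by_type: Dict[str, int]
    events_by_type: Dict[str, int]

    @property
    def erroneous_bases(self) -> int:
        return sum(self.bases_by_type.values())

    @property
    def rate_by_type(self) -> Dict[str, float]:
        return {k: self.bases_by_type[k] / self.total_bases for k in EVENT_KINDS}

    @property
    def total_rate(self) -> float:
        return self.erroneous_bases / self.total_bases

    @property
    def mean_length_by_type(self) -> Dict[str, float]:
        return {
            k: (self.bases_by_type[k] / self.events_by_type[k])
            if self.events_by_type[k]
            else float("nan")
            for k in EVENT_KINDS
        }

    @property
    def mean_event_length(self) -> float:
        n = sum(self.events_by_type.values())
        return self.erroneous_bases / n if n else float("nan")


def compute_error_rates(errors: Iterable[VariantEvent], total_bases: int) -> ErrorRates:
    """Per-type error rates: (sum of event lengths of a type) / total bases."""
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    bases = {k: 0 for k in EVENT_KINDS}
    events = {k: 0 for k in EVENT_KINDS}
    for ev in errors:
        bases[ev.kind] += ev.length
        events[ev.kind] += 1
    return ErrorRates(total_bases, bases, events)


@dataclass
class PerReadStats:
    reads_analyzed: int
    reads_with_errors: int
    mean_errors_per_erroneous_read: float  # per-occurrence tally
    mean_distinct_keys_per_erroneous_read: float
    errors_per_read: Counter = field(default_factory=Counter)  # occurrences -> n reads

    @property
    def fraction_with_errors(self) -> float:
        return self.reads_with_errors / self.reads_analyzed if self.reads_analyzed else 0.0

    @property
    def fraction_below(self) -> Mapping[int, float]:
        """Fraction of erroneous reads with fewer than k errors, for small k."""
        if not self.reads_with_errors:
            return {}
        out = {}
        for k in (2, 3, 4, 5):
            n = sum(c for e, c in self.errors_per_read.items() if 0 < e < k)
            out[k] = n / self.reads_with_errors
        return out


def per_read_stats(
    errors: Iterable[VariantEvent], read_ids: Sequence[str]
) -> PerReadStats:
    """Fraction of reads with >=1 error and errors-per-read distribution.

    Both the per-occurrence tally (every event counts) and the distinct-key
    tally (recurring identical events on one read count once) are reported.
    """
    ids = set(read_ids)
    occ: Counter = Counter()
    keys: Dict[str, Set] = defaultdict(set)
    for ev in errors:
        if ev.read_id not in ids:
            raise ValueError(f"error event for unknown read {ev.read_id!r}")
        occ[ev.read_id] += 1
        keys[ev.read_id].add(ev.key)
    n_err_reads = len(occ)
    dist = Counter(occ.values())
    dist[0] = len(ids) - n_err_reads
    mean_occ = sum(occ.values()) / n_err_reads if n_err_reads else float("nan")
    mean_keys = (
        sum(len(s) for s in keys.values()) / n_err_reads if n_err_reads else float("nan")
    )
    return PerReadStats(len(ids), n_err_reads, mean_occ, mean_keys, dist)


@dataclass
class ReproducibleErrors:
    keys: Set[Tuple]
    base_count: int  # bases of intersecting events summed over runs
    fraction_of_erroneous_bases: float
    n_runs: int


def reproducible_errors(errors_by_run: Mapping[str, Sequence[VariantEvent]]) -> ReproducibleErrors:
    """Error keys present in every run, and the base mass they carry.

    The fraction is (bases of intersecting events, summed over all runs) /
    (total erroneous bases over all runs); it is non-increasing in the
    number of runs intersected.
    """
    if len(errors_by_run) < 2:
        raise ValueError("reproducibility needs at least two runs")
    key_sets = [set(ev.key for ev in evs) for evs in errors_by_run.values()]
    common = set.intersection(*key_sets)
    total_bases = 0
    common_bases = 0
    for evs in errors_by_run.values():
        for ev in evs:
            total_bases += ev.length
            if ev.key in common:
                common_bases += ev.length
    frac = common_bases / total_bases if total_bases else 0.0
    return ReproducibleErrors(common, common_bases, frac, len(errors_by_run))


@dataclass
class PositionalDistribution:
    table: pd.DataFrame  # position, errors, errors_non_homopolymer, coverage, rate
    median_position: float  # weighted median over total error counts


def _weighted_median(positions: np.ndarray, counts: np.ndarray) -> float:
    if counts.sum() == 0:
        return float("nan")
    return float(np.median(np.repeat(positions, counts.astype(np.int64))))


def positional_distribution(
    errors: Sequence[VariantEvent],
    read_lengths: Sequence[int],
    homopolymer_lengths: Optional[Sequence[int]] = None,
) -> PositionalDistribution:
    """Errors per read position, coverage-normalized, plus the median position.

    ``read_lengths`` gives the length of every analyzed read (coverage of
    position p = number of reads at least p long). When
    ``homopolymer_lengths`` annotates each error with its associated
    homopolymer length, a second histogram restricted to
    non-homopolymer-associated errors (length 1) is included.
    """
    if homopolymer_lengths is not None and len(homopolymer_lengths) != len(errors):
        raise ValueError("one homopolymer length per error required")
    lengths = np.asarray(read_lengths, dtype=np.int64)
    if not errors:
        return PositionalDistribution(
            pd.DataFrame(
                columns=["position", "errors", "errors_non_homopolymer", "coverage", "rate"]
            ),
            float("nan"),
        )
    max_pos = max(ev.read_pos for ev in errors)
    max_len = int(lengths.max()) if lengths.size else max_pos
    n = max(max_pos, max_len)
    total = np.zeros(n + 1, dtype=np.int64)
    non_hp = np.zeros(n + 1, dtype=np.int64)
    for i, ev in enumerate(errors):
        total[ev.read_pos] += 1
        if homopolymer_lengths is not None and homopolymer_lengths[i] <= 1:
            non_hp[ev.read_pos] += 1
    coverage = np.zeros(n + 1, dtype=np.int64)
    if lengths.size:
        cnt = np.bincount(np.clip(lengths, 0, n), minlength=n + 1)
        coverage[1:] = cnt[::-1].cumsum()[::-1][1:]
    pos = np.arange(1, n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(coverage[1:] > 0, total[1:] / np.maximum(coverage[1:], 1), np.nan)
    table = pd.DataFrame(
        {
            "position": pos,
            "errors": total[1:],
            "errors_non_homopolymer": non_hp[1:]
            if homopolymer_lengths is not None
            else np.zeros(n, dtype=np.int64),
            "coverage": coverage[1:],
            "rate": rate,
        }
    )
    median = _weighted_median(pos.astype(float), total[1:].astype(float))
    return PositionalDistribution(table, median)


def run_summary(reads_by_run: Mapping[str, Sequence[Read]]) -> pd.DataFrame:
    """Table-1-style per-run metrics plus a grand-total row.

    Average read length is total bases / total reads, so the grand average
    equals the base-weighted mean over runs.
    """
    rows = []
    for run_id, reads in reads_by_run.items():
        lens = np.array([len(r.sequence) for r in reads], dtype=np.int64)
        rows.append(
            {
                "run_id": run_id,
                "reads": len(reads),
                "bases": int(lens.sum()),
                "median_read_length": float(np.median(lens)) if len(lens) else float("nan"),
                "avg_read_length": float(lens.mean()) if len(lens) else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    total_reads = int(df["reads"].sum())
    total_bases = int(df["bases"].sum())
    all_lens = np.concatenate(
        [[len(r.sequence) for r in reads] for reads in reads_by_run.values()]
    ) if reads_by_run else np.array([])
    grand = {
        "run_id": "all",
        "reads": total_reads,
        "bases": total_bases,
        "median_read_length": float(np.median(all_lens)) if all_lens.size else float("nan"),
        "avg_read_length": total_bases / total_reads if total_reads else float("nan"),
    }
    df = pd.concat([df, pd.DataFrame([grand])], ignore_index=True)
    df.attrs["mean_reads_per_run"] = total_reads / len(reads_by_run) if reads_by_run else 0.0
    return df
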