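"""Quality-score analytics and homopolymer context analysis.

Phred scores encode per-base error probability as Q = -10*log10(p). All
averaging of quality scores here happens in error-rate space: scores are
converted to probabilities, averaged, and converted back, so that a single
bad base dominates the mean the way it dominates the expected error count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import DNA, VariantEvent

__all__ = [
    "phred_to_error",
    "error_to_phred",
    "average_quality",
    "HomopolymerRun",
    "scan_homopolymers",
    "background_distribution",
    "annotate_error_context",
    "association_test",
    "error_neighborhood_quality",
    "calibration_curve",
    "per_position_quality",
    "quality_homopolymer_correlation",
]


def phred_to_error(q):
    """Error probability for a phred score; accuracy is ``1 - p``."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("phred scores must be >= 0")
    out = 10.0 ** (-q / 10.0)
    return float(out) if out.ndim == 0 else out


def error_to_phred(p):
    """Phred score for an error probability in (0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("error probability must be in (0, 1]")
    out = -10.0 * np.log10(p)
    return float(out) if out.ndim == 0 else out


def average_quality(quals: Sequence[float]) -> float:
    """Average phred scores in error-rate space.

    The result is bounded by the minimum and maximum of the inputs and is
    invariant under permutation.
    """
    quals = np.asarray(quals, dtype=float)
    if quals.size == 0:
        raise ValueError("cannot average an empty quality list")
    return float(error_to_phred(phred_to_error(quals).mean()))


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of identical nucleotides on a reference."""

    reference_id: str
    start: int  # 0-based
    length: int
    base: str


def scan_homopolymers(sequence: str, reference_id: str = "") -> List[HomopolymerRun]:
    """Tile a sequence into maximal homopolymer runs (length >= 1).

    The runs partition the sequence exactly: run lengths sum to the sequence
    length.
    """
    bad = set(sequence) - DNA
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    runs: List[HomopolymerRun] = []
    i, n = 0, len(sequence)
    while i < n:
        j = i + 1
        while j < n and sequence[j] == sequence[i]:
            j += 1
        runs.append(HomopolymerRun(reference_id, i, j - i, sequence[i]))
        i = j
    return runs


DEFAULT_CLASSES: Tuple[str, ...] = ("1", "2", "3", "4", "5", ">5")


def length_class(length: int, classes: Sequence[str] = DEFAULT_CLASSES) -> str:
    """Map a homopolymer length to its class label (last class is open-ended)."""
    for label in classes[:-1]:
        if length == int(label):
            return label
    return classes[-1]


def background_distribution(
    references: Mapping[str, str] | Iterable[str],
    classes: Sequence[str] = DEFAULT_CLASSES,
) -> pd.Series:
    """Fraction of reference bases lying in homopolymers of each length class.

    Every base is labelled with the length of the maximal run containing it,
    so the fractions sum to 1.
    """
    seqs = references.values() if isinstance(references, Mapping) else references
    counts = {c: 0 for c in classes}
    total = 0
    for seq in seqs:
        for run in scan_homopolymers(seq):
            counts[length_class(run.length, classes)] += run.length
            total += run.length
    if total == 0:
        raise ValueError("no reference bases")
    return pd.Series({c: counts[c] / total for c in classes}, name="background")


def annotate_error_context(
    event: VariantEvent,
    runs: Sequence[HomopolymerRun],
    adjacency_window: int = 1,
) -> int:
    """Homopolymer length associated with an error (1 if none).

    Returns the length of the longest maximal run overlapping the window
    ``[ref_pos - w, ref_pos + length + w)`` around the event. Insertions
    occupy no reference bases; their window is centred on the anchor
    position.
    """
    span_len = event.length if event.kind != "ins" else 0
    lo = event.ref_pos - adjacency_window
    hi = event.ref_pos + span_len + adjacency_window
    if event.kind == "ins" and adjacency_window == 0:
        # zero-width window: look at the anchor base itself
        hi = event.ref_pos + 1
    best = 1
    for run in runs:
        if run.start < hi and run.start + run.length > lo:
            best = max(best, run.length)
    return best


def context_class_counts(
    lengths: Iterable[int], classes: Sequence[str] = DEFAULT_CLASSES
) -> pd.Series:
    """Tally associated homopolymer lengths into length classes."""
    counts = {c: 0 for c in classes}
    for L in lengths:
        counts[length_class(L, classes)] += 1
    return pd.Series(counts, name="errors")


def association_test(
    error_class_counts: pd.Series | Mapping[str, int],
    background_fractions: pd.Series | Mapping[str, float],
    min_expected: float = 5.0,
) -> Tuple[float, float, int]:
    """Goodness-of-fit chi-square of error context classes vs background.

    Expected counts are background fraction x total errors; adjacent classes
    with expected counts below ``min_expected`` are pooled into their left
    neighbour (the first class pools rightward). Returns (statistic, p-value,
    degrees of freedom).
    """
    obs = pd.Series(error_class_counts, dtype=float)
    bg = pd.Series(background_fractions, dtype=float).reindex(obs.index)
    if obs.sum() < 1:
        raise ValueError("need at least one error")
    if not np.isclose(bg.sum(), 1.0, atol=1e-6):
        raise ValueError("background fractions must sum to 1")
    total = obs.sum()
    exp = bg.values * total
    o, e = list(obs.values), list(exp)
    # pool low-expectation classes into neighbours, right to left; always
    # keep at least two classes so the test remains defined
    i = len(e) - 1
    while i >= 0 and len(e) > 2:
        if e[i] < min_expected:
            j = i - 1 if i > 0 else 1
            e[j] += e[i]
            o[j] += o[i]
            del e[i], o[i]
        i -= 1
    if len(e) < 2:
        raise ValueError("fewer than two classes after pooling")
    stat, p = stats.chisquare(o, f_exp=e)
    return float(stat), float(p), len(e) - 1


@dataclass
class NeighborhoodQuality:
    """Quality at error positions vs their flanking neighborhoods."""

    per_event: pd.DataFrame  # read_id, run_id, error_q, neighborhood_q, truncated
    mean_error_q: float
    mean_neighborhood_q: float
    per_run: pd.DataFrame  # run_id, mean_error_q, mean_neighborhood_q, n


def _involved_read_positions(event: VariantEvent, read_length: int) -> List[int]:
    """0-based sequencing-orientation positions of the event's read bases.

    Substitutions/insertions: the event bases themselves. Deletions have no
    read bases; the two flanking bases (which carry the event's quality) are
    treated as involved so the neighborhood excludes them.
    """
    start = event.read_pos - 1
    if event.kind == "del":
        return [p for p in (start, start + 1) if 0 <= p < read_length]
    return list(range(start, min(start + event.length, read_length)))


def error_neighborhood_quality(
    events: Sequence[VariantEvent],
    read_quals: Mapping[str, np.ndarray],
    n_neighbors: int = 5,
) -> NeighborhoodQuality:
    """Compare quality at error positions with their flanking neighborhood.

    The neighborhood of an event is the ``n_neighbors`` read bases closest
    to it, excluding the event's own bases; distance ties are broken
    upstream (toward the read start). Events at read ends with fewer than
    ``n_neighbors`` available bases use what is there and are flagged
    truncated. Quality means are taken in error-rate space.
    """
    rows = []
    for ev in events:
        quals = np.asarray(read_quals[ev.read_id])
        n = len(quals)
        involved = set(_involved_read_positions(ev, n))
        if not involved:
            continue
        lo, hi = min(involved), max(involved)
        candidates = [p for p in range(n) if p not in involved]
        # distance to the event span; ties broken upstream (smaller index)
        candidates.sort(key=lambda p: (max(lo - p, p - hi, 0), p))
        chosen = candidates[:n_neighbors]
        if not chosen:
            continue
        rows.append(
            {
                "read_id": ev.read_id,
                "run_id": ev.run_id,
                "error_q": average_quality(quals[sorted(involved)]),
                "neighborhood_q": average_quality(quals[chosen]),
                "truncated": len(chosen) < n_neighbors,
            }
        )
    per_event = pd.DataFrame(
        rows, columns=["read_id", "run_id", "error_q", "neighborhood_q", "truncated"]
    )
    if per_event.empty:
        return NeighborhoodQuality(per_event, float("nan"), float("nan"), pd.DataFrame())
    per_run = (
        per_event.groupby("run_id")
        .agg(
            mean_error_q=("error_q", average_quality),
            mean_neighborhood_q=("neighborhood_q", average_quality),
            n=("error_q", "size"),
        )
        .reset_index()
    )
    return NeighborhoodQuality(
        per_event,
        average_quality(per_event["error_q"].values),
        average_quality(per_event["neighborhood_q"].values),
        per_run,
    )


def homopolymer_quality_table(
    events: Sequence[VariantEvent],
    context_lengths: Sequence[int],
    classes: Sequence[str] = ("1", "2", "3", "4", "5", "6", ">6"),
) -> pd.DataFrame:
    """Quartiles of event-site quality stratified by homopolymer length class."""
    qs = [average_quality(ev.quals) for ev in events]
    df = pd.DataFrame(
        {"length_class": [length_class(L, classes) for L in context_lengths], "q": qs}
    )
    out = (
        df.groupby("length_class")["q"]
        .describe(percentiles=[0.25, 0.5, 0.75])[["count", "min", "25%", "50%", "75%", "max"]]
        .reindex(classes)
    )
    return out.rename(columns={"25%": "q1", "50%": "median", "75%": "q3"})


def calibration_curve(
    labelled_reads: Iterable[Tuple[np.ndarray, np.ndarray]],
    max_q: int = 40,
) -> pd.DataFrame:
    """Estimated-vs-empirical quality calibration table.

    ``labelled_reads`` yields ``(reported quality array, boolean error mask)``
    pairs, one per read. Bases are binned by integer reported Q; for each bin
    the empirical quality is ``-10*log10(observed error fraction)``. Bins
    with zero observed errors get an NA empirical Q and are flagged.
    """
    n_bases = np.zeros(max_q + 1, dtype=np.int64)
    n_err = np.zeros(max_q + 1, dtype=np.int64)
    for quals, errs in labelled_reads:
        quals = np.asarray(quals, dtype=np.int64)
        errs = np.asarray(errs, dtype=bool)
        np.add.at(n_bases, quals, 1)
        np.add.at(n_err, quals[errs], 1)
    with np.errstate(divide="ignore"):
        rate = np.where(n_bases > 0, n_err / np.maximum(n_bases, 1), np.nan)
        empirical = np.where(n_err > 0, -10.0 * np.log10(np.where(rate > 0, rate, 1)), np.nan)
    df = pd.DataFrame(
        {
            "estimated_q": np.arange(max_q + 1),
            "n_bases": n_bases,
            "n_errors": n_err,
            "empirical_q": empirical,
            "no_errors_observed": (n_bases > 0) & (n_err == 0),
        }
    )
    df["deviation"] = df["estimated_q"] - df["empirical_q"]
    return df[df["n_bases"] > 0].reset_index(drop=True)


def per_position_quality(
    quals_iter: Iterable[np.ndarray], max_length: Optional[int] = None
) -> pd.DataFrame:
    """Mean quality per read position, averaged in error-rate space.

    Positions are 1-based sequencing-orientation read positions
    (the run-progress quality curve).
    """
    sum_p: np.ndarray = np.zeros(0)
    count: np.ndarray = np.zeros(0, dtype=np.int64)
    for quals in quals_iter:
        p = phred_to_error(np.asarray(quals, dtype=float))
        if len(p) > len(sum_p):
            sum_p = np.pad(sum_p, (0, len(p) - len(sum_p)))
            count = np.pad(count, (0, len(p) - len(count)))
        sum_p[: len(p)] += p
        count[: len(p)] += 1
    if max_length is not None:
        sum_p, count = sum_p[:max_length], count[:max_length]
    mask = count > 0
    mean_q = np.full(len(sum_p), np.nan)
    mean_q[mask] = -10.0 * np.log10(sum_p[mask] / count[mask])
    return pd.DataFrame(
        {"position": np.arange(1, len(sum_p) + 1), "coverage": count, "mean_q": mean_q}
    )


def quality_homopolymer_correlation(
    pairs: Sequence[Tuple[float, float]]
) -> Tuple[float, float]:
    """Pearson correlation of (homopolymer length, quality at error).

    Returns (r, two-sided p). With zero variance in either variable the
    correlation is undefined: returns (nan, nan) with a warning.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired observations")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in correlation input; returning NA")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
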