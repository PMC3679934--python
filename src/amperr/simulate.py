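"""Synthetic 454-style amplicon read simulator.

Generates reference amplicons (primer | flank | exon | flank | primer),
allele and pseudogene variant sequences, and multi-run FASTQ read sets with
the error structure characteristic of pyrosequencing: homopolymer-length-
dependent indels, a low flat substitution load, positional quality decay
with a drop late in the read, quality valleys at error positions, and a
configurable miscalibration between true and reported quality.

Every read carries a :class:`~amperr.model.TruthRecord` listing the injected
error events in reference coordinates, so downstream extraction and
classification can be checked against ground truth.

Design notes
------------
The per-base substitution probability is modulated along the read by the
quality profile but normalised so its mean over read positions equals the
configured ``substitution_rate``; the true quality of a base is defined as
the phred transform of that probability. Reported quality is the true
quality minus a penalty at error sites, passed through the configured
miscalibration and clamped to integer [0, 40].

Indels are drawn per traversed homopolymer base with probability
``indel_base_rate * indel_length_slope**(L-1)`` for a run of length ``L``;
successes within one run coalesce into a single over- or undercall placed at
the run's leftmost base, matching the extractor's left-alignment convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import (
    Read,
    ReferenceAmplicon,
    TruthEvent,
    TruthRecord,
    TruthSet,
    revcomp,
)

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class AmpliconSpec:
    """Layout of one simulated amplicon."""

    locus: str
    exon_length: int
    primer_lengths: Tuple[int, int] = (20, 20)
    homopolymer_weight: float = 1.0

    def validate(self) -> None:
        if self.exon_length < 50:
            raise ValueError(f"{self.locus}: exon length must be >= 50")
        if min(self.primer_lengths) < 10:
            raise ValueError(f"{self.locus}: primers must be >= 10 bp")
        if self.homopolymer_weight < 0:
            raise ValueError(f"{self.locus}: homopolymer weight must be >= 0")


def _default_amplicons() -> Tuple[AmpliconSpec, ...]:
    # Three loci standing in for the study's six-locus HLA panel; exon 2/3
    # of HLA class I genes is ~270 bp.
    return (
        AmpliconSpec("A", 270, (20, 20), 1.0),
        AmpliconSpec("B", 270, (20, 20), 1.0),
        AmpliconSpec("DRB1", 270, (20, 20), 1.2),
    )


@dataclass
class SimulationConfig:
    """Study design and error-model parameters for the simulator.

    Defaults emulate the characterised GS Junior assay: six runs of one
    pooled library, ~0.05% substitution load, indel load rising
    multiplicatively with homopolymer length (insertions outnumbering
    deletions ~2:1), a pseudogene co-amplified at 25% on one locus, mean
    base quality in the mid-30s with decay after ~300 bp, a 5-point quality
    valley at error sites, and an instrument that overestimates its quality
    above Q30 and underestimates it below.
    """

    n_runs: int = 6
    reads_per_amplicon: int = 300
    amplicon_specs: Tuple[AmpliconSpec, ...] = field(default_factory=_default_amplicons)
    flank_length: int = 15
    substitution_rate: float = 0.0005
    indel_base_rate: float = 0.00023
    indel_length_slope: float = 1.9
    indel_insertion_fraction: float = 0.69  # ins 0.09% vs del 0.04% of bases
    pseudogene_fraction: float = 0.25
    pseudogene_locus: Optional[str] = None  # default: first spec's locus
    n_pseudogene_diffs: int = 5
    true_variant_count: int = 2
    quality_profile: Tuple[float, float, float, float] = (33.0, 37.0, 300.0, 25.0)
    error_site_q_penalty: int = 5
    miscalibration: Mapping = field(
        default_factory=lambda: {"kind": "gs_junior", "threshold": 30, "above": 3, "below": -2}
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.amplicon_specs:
            raise ValueError("amplicon_specs must be nonempty")
        for spec in self.amplicon_specs:
            spec.validate()
        for name in ("substitution_rate", "indel_base_rate", "indel_insertion_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.pseudogene_fraction < 1.0:
            raise ValueError("pseudogene_fraction must be in [0, 1)")
        if self.indel_length_slope <= 0:
            raise ValueError("indel_length_slope must be positive")
        if self.n_runs < 1 or self.reads_per_amplicon < 1:
            raise ValueError("n_runs and reads_per_amplicon must be >= 1")
        if self.pseudogene_fraction > 0 and self.n_pseudogene_diffs < 3:
            raise ValueError("pseudogene must differ at >= 3 positions")

    def to_json(self) -> str:
        d = asdict(self)
        d["amplicon_specs"] = [asdict(s) for s in self.amplicon_specs]
        d["miscalibration"] = dict(self.miscalibration)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["amplicon_specs"] = tuple(
            AmpliconSpec(
                s["locus"],
                s["exon_length"],
                tuple(s.get("primer_lengths", (20, 20))),
                s.get("homopolymer_weight", 1.0),
            )
            for s in d["amplicon_specs"]
        )
        d["quality_profile"] = tuple(d["quality_profile"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# sequence generation


def _random_sequence(n: int, rng: np.random.Generator, weight: float) -> str:
    """Random DNA with homopolymer enrichment controlled by ``weight``.

    With weight > 0 the previous base repeats with elevated probability, so
    runs follow a geometric-like length law with a damped tail, capped at 7
    (longer runs are not seen in the amplicon targets this emulates); with
    weight == 0 repeats occur at the uniform 1/4 rate and runs of length
    >= 4 are forbidden.
    """
    p_repeat = min(0.45, 0.25 + 0.08 * weight)
    max_run = 3 if weight == 0 else 7
    out: List[str] = []
    run = 0
    for _ in range(n):
        p_eff = p_repeat * (0.7 ** max(run - 3, 0))
        if out and weight > 0 and rng.random() < p_eff:
            cand = out[-1]
        else:
            cand = str(rng.choice(_BASES))
        if run >= max_run and cand == out[-1]:
            others = [b for b in "ACGT" if b != out[-1]]
            cand = others[int(rng.integers(0, 3))]
        if out and cand == out[-1]:
            run += 1
        else:
            run = 1
        out.append(cand)
    return "".join(out)


def _max_run(seq: str) -> int:
    best = cur = 1
    for a, b in zip(seq, seq[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


def _away_from_runs(seq: str, p: int, max_run: int = 2, margin: int = 2) -> bool:
    """True when no homopolymer run of length > ``max_run`` comes within
    ``margin`` bases of position ``p`` (keeps a variant's alignment
    representation unambiguous next to indel-prone runs)."""
    lo = max(p - margin, 0)
    hi = min(p + margin + 1, len(seq))
    i = lo
    while i < hi:
        b = seq[i]
        j = i
        while j > 0 and seq[j - 1] == b:
            j -= 1
        k = i
        while k + 1 < len(seq) and seq[k + 1] == b:
            k += 1
        if k - j + 1 > max_run:
            return False
        i = k + 1
    return True


def _pick_spaced_positions(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    min_gap: int,
    avoid: Sequence[int] = (),
    seq: Optional[str] = None,
) -> List[int]:
    chosen: List[int] = []
    taken = list(avoid)
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 10000:
            raise ValueError("cannot place variant positions with required spacing")
        p = int(rng.integers(lo, hi))
        if any(abs(p - q) < min_gap for q in taken):
            continue
        if seq is not None and not _away_from_runs(seq, p):
            continue
        chosen.append(p)
        taken.append(p)
    return sorted(chosen)


def _substitute_isolated(seq: str, pos: int, rng: np.random.Generator) -> str:
    """Substitute base at ``pos`` avoiding both neighbours and the original.

    Keeps the new base from creating or extending a homopolymer run, so the
    difference stays a clean isolated substitution under any aligner.
    """
    excluded = {seq[pos]}
    if pos > 0:
        excluded.add(seq[pos - 1])
    if pos < len(seq) - 1:
        excluded.add(seq[pos + 1])
    choices = [b for b in "ACGT" if b not in excluded]
    return seq[:pos] + choices[int(rng.integers(0, len(choices)))] + seq[pos + 1:]


@dataclass
class SimulatedReferences:
    """References plus the variant sequences reads are drawn from."""

    amplicons: List[ReferenceAmplicon]
    alleles: Dict[str, str]  # amplicon_id -> allele sequence (true variants)
    pseudogenes: Dict[str, str]  # amplicon_id -> pseudogene sequence
    truth_set: TruthSet
    diff_positions: Dict[str, List[int]]  # all ref positions where any source differs


def generate_references(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedReferences:
    """Generate reference amplicons, allele/pseudogene variants and the truth set."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng((config.seed, 104729))
    pseudo_locus = config.pseudogene_locus or config.amplicon_specs[0].locus

    amplicons: List[ReferenceAmplicon] = []
    alleles: Dict[str, str] = {}
    pseudogenes: Dict[str, str] = {}
    expected = set()
    pseudo_keys: Dict[str, set] = {}
    diff_positions: Dict[str, List[int]] = {}

    for idx, spec in enumerate(config.amplicon_specs):
        amp_id = f"{spec.locus}_e{idx + 1}"
        pf = _random_sequence(spec.primer_lengths[0], rng, 0.0)
        pr = _random_sequence(spec.primer_lengths[1], rng, 0.0)
        flank5 = _random_sequence(config.flank_length, rng, 0.0)
        flank3 = _random_sequence(config.flank_length, rng, 0.0)
        exon = _random_sequence(spec.exon_length, rng, spec.homopolymer_weight)
        if spec.homopolymer_weight > 0 and _max_run(exon) < 4:
            p = int(rng.integers(1, spec.exon_length - 5))
            exon = exon[:p] + exon[p] * 4 + exon[p + 4:]
        seq = pf + flank5 + exon + flank3 + revcomp(pr)
        exon_start = len(pf) + config.flank_length
        amp = ReferenceAmplicon(
            amplicon_id=amp_id,
            locus=spec.locus,
            sequence=seq,
            exon=(exon_start, exon_start + spec.exon_length),
            primer_fwd=pf,
            primer_rev=pr,
        )
        amplicons.append(amp)

        # allele: isolated substitutions at the sample's true-variant sites
        var_pos = _pick_spaced_positions(
            rng, config.true_variant_count, exon_start + 2, amp.exon[1] - 2, 4, seq=seq
        )
        allele = seq
        for p in var_pos:
            allele = _substitute_isolated(allele, p, rng)
            expected.add((amp_id, p, "sub", allele[p]))
        alleles[amp_id] = allele
        diffs = list(var_pos)

        if spec.locus == pseudo_locus and config.pseudogene_fraction > 0:
            pg_pos = _pick_spaced_positions(
                rng,
                config.n_pseudogene_diffs,
                exon_start + 2,
                amp.exon[1] - 2,
                4,
                avoid=var_pos,
                seq=seq,
            )
            pg = seq
            keys = set()
            for p in pg_pos:
                pg = _substitute_isolated(pg, p, rng)
                keys.add((amp_id, p, "sub", pg[p]))
            pseudogenes[amp_id] = pg
            pseudo_keys[amp_id] = keys
            diffs.extend(pg_pos)
        diff_positions[amp_id] = sorted(diffs)

    truth = TruthSet(
        expected=expected,
        pseudogene=pseudo_keys,
        amplicons={a.amplicon_id for a in amplicons},
    )
    return SimulatedReferences(amplicons, alleles, pseudogenes, truth, diff_positions)


# ---------------------------------------------------------------------------
# quality model


def quality_profile_q(config: SimulationConfig, length: int) -> np.ndarray:
    """Piecewise-linear positional quality: start -> plateau -> decay -> end.

    Ramp-up over the first 20 bases, flat plateau until the decay onset,
    then linear decay to the end quality at ``length`` (or 100 bp past the
    onset, whichever is larger).
    """
    q_start, q_plateau, onset, q_end = config.quality_profile
    pos = np.arange(length, dtype=float)
    ramp_len = min(20.0, max(onset, 1.0))
    decay_end = max(float(length), onset + 100.0)
    q = np.full(length, q_plateau)
    ramp = pos < ramp_len
    q[ramp] = q_start + (q_plateau - q_start) * pos[ramp] / ramp_len
    decay = pos >= onset
    if decay_end > onset:
        q[decay] = q_plateau + (q_end - q_plateau) * (pos[decay] - onset) / (decay_end - onset)
    return np.maximum(q, 1.0)


def substitution_probability(config: SimulationConfig, length: int) -> np.ndarray:
    """Per-position substitution probability, mean-normalised to the configured rate."""
    q = quality_profile_q(config, length)
    p = 10.0 ** (-q / 10.0)
    if config.substitution_rate <= 0:
        return np.zeros(length)
    w = p / p.mean()
    return np.clip(config.substitution_rate * w, 0.0, 0.75)


def positional_error_probability(config: SimulationConfig, length: int) -> np.ndarray:
    """Positional component of the true per-base error probability."""
    if config.substitution_rate > 0:
        return substitution_probability(config, length)
    return 10.0 ** (-quality_profile_q(config, length) / 10.0)


def _run_length_per_base(seq: str) -> np.ndarray:
    """Length of the maximal homopolymer run containing each base."""
    n = len(seq)
    out = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        out[i:j] = j - i
        i = j
    return out


def true_read_quality(config: SimulationConfig, read_seq: str, p_pos: np.ndarray) -> np.ndarray:
    """True per-base quality of one read.

    Combines the positional substitution risk with the homopolymer indel
    risk of the run each base sits in (flow-based callers are less certain
    inside long runs, yielding the run-length/quality anticorrelation).
    """
    n = len(read_seq)
    p = p_pos[:n].copy()
    if config.indel_base_rate > 0:
        lengths = _run_length_per_base(read_seq)
        p = p + np.minimum(
            config.indel_base_rate
            * config.indel_length_slope ** (lengths - 1.0),
            0.9,
        )
    return -10.0 * np.log10(np.clip(p, 1e-9, 1.0))


def true_quality(config: SimulationConfig, length: int) -> np.ndarray:
    """True per-position quality implied by the substitution model alone."""
    p = substitution_probability(config, length)
    if config.substitution_rate <= 0:
        return quality_profile_q(config, length)
    return -10.0 * np.log10(p)


def apply_miscalibration(q_true: np.ndarray, spec: Mapping) -> np.ndarray:
    """Map true quality to instrument-reported quality."""
    kind = spec.get("kind", "identity")
    q = np.asarray(q_true, dtype=float)
    if kind == "identity":
        return q.copy()
    if kind == "offset":
        return q + float(spec["delta"])
    if kind == "gs_junior":
        thr = float(spec.get("threshold", 30))
        out = q.copy()
        out[q > thr] += float(spec.get("above", 3))
        out[q < thr] += float(spec.get("below", -2))
        return out
    raise ValueError(f"unknown miscalibration kind {kind!r}")


def reported_quality(
    config: SimulationConfig, q_true: np.ndarray, penalty_positions: Sequence[int]
) -> np.ndarray:
    q = q_true.copy()
    if penalty_positions:
        q[list(penalty_positions)] -= config.error_site_q_penalty
    q = apply_miscalibration(q, config.miscalibration)
    return np.clip(np.rint(q), 0, 40).astype(np.int64)


# ---------------------------------------------------------------------------
# read simulation


def _homopolymer_runs(seq: str, lo: int, hi: int) -> List[Tuple[int, int, str]]:
    """Maximal runs of ``seq`` fully contained in [lo, hi) as (start, length, base)."""
    runs = []
    i = lo
    # extend the first run leftward to check containment
    while i < hi:
        j = i + 1
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        start_ok = i == 0 or seq[i - 1] != seq[i]
        if start_ok and j <= hi:
            runs.append((i, j - i, seq[i]))
        i = j
    return runs


def _inject_errors(
    working: str,
    region: Tuple[int, int],
    diff_positions: Sequence[int],
    config: SimulationConfig,
    rng: np.random.Generator,
    p_sub: np.ndarray,
) -> Tuple[str, List[dict]]:
    """Inject substitution and homopolymer indel errors into ``working``.

    Returns the edited sequence and a list of event dicts with working-
    coordinate positions (pre-edit) plus final-read positions.
    """
    lo, hi = region
    n = len(working)
    # no injected event may come within 2 bases of an allele/pseudogene
    # difference: a sub+indel pair that close has co-optimal alignment
    # representations, which would make the ground truth ambiguous
    forbidden_sub = {q for p in diff_positions for q in (p - 1, p, p + 1)}

    # substitutions: per-base Bernoulli at the position-modulated rate
    draws = rng.random(hi - lo)
    hits = [lo + i for i in np.nonzero(draws < p_sub[lo:hi])[0] if (lo + i) not in forbidden_sub]

    sub_events: List[dict] = []
    i = 0
    while i < len(hits):
        j = i
        while j + 1 < len(hits) and hits[j + 1] == hits[j] + 1:
            j += 1
        start, end = hits[i], hits[j] + 1
        new = "".join(
            "ACGT".replace(working[p], "")[int(rng.integers(0, 3))] for p in range(start, end)
        )
        sub_events.append({"kind": "sub", "wstart": start, "wlen": end - start, "new": new})
        i = j + 1

    # indels at homopolymer runs fully inside the region; events keep at
    # least two matched anchor bases apart so the optimal alignment cannot
    # merge neighbouring events into a different representation
    taken_spans = [(e["wstart"], e["wstart"] + e["wlen"]) for e in sub_events]
    taken_spans += [(p, p + 1) for p in diff_positions]
    indel_events: List[dict] = []
    last_indel_run = -10
    for run_idx, (start, length, base) in enumerate(_homopolymer_runs(working, lo, hi)):
        p = min(config.indel_base_rate * config.indel_length_slope ** (length - 1), 0.9)
        if p <= 0:
            continue
        s = int(rng.binomial(length, p))
        if s == 0:
            continue
        if any(start < b + 2 and start + length > a - 2 for a, b in taken_spans):
            continue  # too close to a substitution: skip to keep truth unambiguous
        if run_idx - last_indel_run < 4:
            continue  # two indels with < 3 runs between them can re-align as
            # substitutions at run boundaries (454 frame shift); skip
        taken_spans.append((start, start + length))
        last_indel_run = run_idx
        if rng.random() < config.indel_insertion_fraction:
            indel_events.append(
                {"kind": "ins", "wstart": start, "wlen": s, "base": base, "runlen": length}
            )
        else:
            s = min(s, length)
            indel_events.append(
                {"kind": "del", "wstart": start, "wlen": s, "base": base, "runlen": length}
            )

    events = sorted(sub_events + indel_events, key=lambda e: e["wstart"])

    pieces: List[str] = []
    prev = 0
    delta = 0
    for ev in events:
        ws = ev["wstart"]
        pieces.append(working[prev:ws])
        if ev["kind"] == "sub":
            pieces.append(ev["new"])
            prev = ws + ev["wlen"]
            ev["read_start0"] = ws + delta
        elif ev["kind"] == "ins":
            pieces.append(ev["base"] * ev["wlen"])
            prev = ws
            ev["read_start0"] = ws + delta
            delta += ev["wlen"]
        else:  # del: drop the run's leftmost bases
            prev = ws + ev["wlen"]
            ev["read_start0"] = ws + delta - 1  # left flanking read base
            delta -= ev["wlen"]
    pieces.append(working[prev:])
    return "".join(pieces), events


def simulate_run(
    refs: SimulatedReferences,
    config: SimulationConfig,
    run_index: int,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[Read], List[TruthRecord]]:
    """Simulate one sequencing run over all amplicons.

    Each amplicon yields exactly ``reads_per_amplicon`` reads; each read
    covers the full amplicon. Errors are only injected between the primers
    (the primers themselves are trimmed before analysis).
    """
    config.validate()
    if run_index >= config.n_runs:
        raise ValueError(f"run_index {run_index} out of range for {config.n_runs} runs")
    if rng is None:
        rng = np.random.default_rng((config.seed, 7919, run_index))
    run_id = f"run{run_index + 1}"

    reads: List[Read] = []
    records: List[TruthRecord] = []
    for amp in refs.amplicons:
        L = len(amp.sequence)
        p_sub = substitution_probability(config, L + 64)
        p_pos = positional_error_probability(config, L + 64)
        ins_lo, ins_hi = amp.insert_interval
        diffs = refs.diff_positions.get(amp.amplicon_id, [])

        for ridx in range(config.reads_per_amplicon):
            use_pseudo = (
                amp.amplicon_id in refs.pseudogenes
                and rng.random() < config.pseudogene_fraction
            )
            source_label = "pseudogene" if use_pseudo else "allele"
            source = (
                refs.pseudogenes[amp.amplicon_id]
                if use_pseudo
                else refs.alleles[amp.amplicon_id]
            )
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                working = source
                region = (ins_lo, ins_hi)
                diffs_w = diffs
            else:
                working = revcomp(source)
                region = (L - ins_hi, L - ins_lo)
                diffs_w = [L - 1 - p for p in diffs]

            final, raw_events = _inject_errors(
                working, region, diffs_w, config, rng, p_sub
            )

            truth_events: List[TruthEvent] = []
            penalty_pos: List[int] = []
            for ev in raw_events:
                ws, wl = ev["wstart"], ev["wlen"]
                if ev["kind"] == "sub":
                    if strand == "+":
                        ref_pos, bases = ws, ev["new"]
                    else:
                        ref_pos, bases = L - ws - wl, revcomp(ev["new"])
                    read_pos = ev["read_start0"] + 1
                    penalty_pos.extend(range(ev["read_start0"], ev["read_start0"] + wl))
                    truth_events.append(TruthEvent(ref_pos, "sub", wl, bases, read_pos))
                else:
                    runlen, base = ev["runlen"], ev["base"]
                    # reference-orientation run start (left-aligned anchor)
                    if strand == "+":
                        ref_run_start = ws
                        ref_base = base
                    else:
                        ref_run_start = L - ws - runlen
                        ref_base = _COMP[base]
                    if ev["kind"] == "ins":
                        read_pos = ev["read_start0"] + 1
                        penalty_pos.extend(
                            range(ev["read_start0"], ev["read_start0"] + wl)
                        )
                        truth_events.append(
                            TruthEvent(ref_run_start, "ins", wl, ref_base * wl, read_pos)
                        )
                    else:
                        read_pos = ev["read_start0"] + 1
                        penalty_pos.extend(
                            p
                            for p in (ev["read_start0"], ev["read_start0"] + 1)
                            if 0 <= p < len(final)
                        )
                        truth_events.append(
                            TruthEvent(ref_run_start, "del", wl, ref_base * wl, read_pos)
                        )

            q_true = true_read_quality(config, final, p_pos)
            quals = reported_quality(config, q_true, penalty_pos)
            read_id = f"{run_id}:{amp.amplicon_id}:{ridx}/{'F' if strand == '+' else 'R'}"
            reads.append(Read(read_id, run_id, amp.amplicon_id, final, quals))
            records.append(
                TruthRecord(
                    read_id,
                    amp.amplicon_id,
                    run_id,
                    source_label,
                    strand,
                    tuple(sorted(truth_events, key=lambda e: e.ref_pos)),
                )
            )
    return reads, records


@dataclass
class SimulatedStudy:
    """A full multi-run simulated experiment."""

    config: SimulationConfig
    references: SimulatedReferences
    reads_by_run: Dict[str, List[Read]]
    truth_by_run: Dict[str, List[TruthRecord]]

    @property
    def all_reads(self) -> List[Read]:
        return [r for reads in self.reads_by_run.values() for r in reads]

    @property
    def all_truth(self) -> List[TruthRecord]:
        return [t for recs in self.truth_by_run.values() for t in recs]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate references and simulate all runs of the study."""
    refs = generate_references(config)
    reads_by_run: Dict[str, List[Read]] = {}
    truth_by_run: Dict[str, List[TruthRecord]] = {}
    for r in range(config.n_runs):
        reads, records = simulate_run(refs, config, r)
        reads_by_run[f"run{r + 1}"] = reads
        truth_by_run[f"run{r + 1}"] = records
    return SimulatedStudy(config, refs, reads_by_run, truth_by_run)
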