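"""Core data types shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; report writers
convert to 1-based closed intervals. Sequences are uppercase DNA over
{A, C, G, T}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

DNA = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A locus reference sequence with exon and primer annotations.

    The sequence layout is ``primer_fwd | 5' flank | exon | 3' flank |
    revcomp(primer_rev)``; ``exon`` is the 0-based half-open exon interval
    on the sequence. ``primer_rev`` is stored in its own (reverse-strand)
    orientation, as a wet lab would order it.
    """

    amplicon_id: str
    locus: str
    sequence: str
    exon: Tuple[int, int]
    primer_fwd: str
    primer_rev: str

    def __post_init__(self) -> None:
        if not set(self.sequence) <= DNA:
            raise ValueError(f"{self.amplicon_id}: sequence must be over ACGT")
        s, e = self.exon
        if not (0 <= s < e <= len(self.sequence)):
            raise ValueError(f"{self.amplicon_id}: exon {self.exon} out of bounds")
        for lo, hi in self.primer_intervals:
            if max(lo, s) < min(hi, e):
                raise ValueError(f"{self.amplicon_id}: primer overlaps exon")

    @property
    def primer_intervals(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        n = len(self.sequence)
        return (0, len(self.primer_fwd)), (n - len(self.primer_rev), n)

    @property
    def insert_interval(self) -> Tuple[int, int]:
        """Region between the primers (flanks + exon)."""
        return len(self.primer_fwd), len(self.sequence) - len(self.primer_rev)

    @property
    def exon_sequence(self) -> str:
        return self.sequence[self.exon[0]:self.exon[1]]


@dataclass
class Read:
    """A quality-scored read as it comes off the sequencer."""

    read_id: str
    run_id: str
    amplicon_id: str
    sequence: str
    quals: np.ndarray  # phred, one per base, sequencing orientation

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.sequence) != len(self.quals):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


# Alignment column: (reference position | None, read position | None).
# None on the reference side = insertion, None on the read side = deletion.
Column = Tuple[Optional[int], Optional[int]]


@dataclass
class AlignedRead:
    """A read's gapped alignment to one reference amplicon.

    ``sequence``/``quals`` are stored in reference (alignment) orientation;
    for a reverse-strand read they are the reverse complement of the
    sequenced bases. ``read_length`` is the length of the aligned (trimmed)
    read, used to map alignment coordinates back to sequencing orientation.
    """

    read_id: str
    run_id: str
    amplicon_id: str
    strand: str  # '+' or '-'
    columns: list
    sequence: str
    quals: np.ndarray
    score: float
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        last_r = last_q = -1
        for r, q in self.columns:
            if r is None and q is None:
                raise ValueError("column with gap on both sides")
            if r is not None:
                if r <= last_r:
                    raise ValueError("reference positions not increasing")
                last_r = r
            if q is not None:
                if q <= last_q:
                    raise ValueError("read positions not increasing")
                last_q = q

    @property
    def read_length(self) -> int:
        return len(self.sequence)

    def seq_position(self, aligned_pos: int) -> int:
        """Map an alignment-orientation read index to sequencing orientation."""
        if self.strand == "+":
            return aligned_pos
        return self.read_length - 1 - aligned_pos

    @property
    def ref_span(self) -> Tuple[int, int]:
        refs = [r for r, _ in self.columns if r is not None]
        if not refs:
            raise ValueError("alignment has no reference columns")
        return refs[0], refs[-1] + 1


@dataclass(frozen=True)
class VariantEvent:
    """One merged read/reference discrepancy.

    ``ref_pos`` is the 0-based reference start of the event; insertions are
    anchored at the reference base immediately following the (left-aligned)
    inserted segment, which for a homopolymer insertion is the run's first
    base. ``read_pos`` is the 1-based position of the first involved read
    base in sequencing orientation (for deletions, the left flanking base).
    ``quals`` holds the phred scores of the involved read bases; deletions
    carry the scores of the two flanking read bases.
    """

    amplicon_id: str
    ref_pos: int
    kind: str  # 'ins' | 'del' | 'sub'
    length: int
    ref_bases: str
    read_bases: str
    read_id: str
    run_id: str
    strand: str
    read_pos: int
    quals: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("ins", "del", "sub"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if self.kind == "sub" and len(self.ref_bases) != len(self.read_bases):
            raise ValueError("substitution ref/read base counts differ")
        if self.kind == "ins" and self.ref_bases:
            raise ValueError("insertion must have empty ref bases")
        if self.kind == "del" and self.read_bases:
            raise ValueError("deletion must have empty read bases")

    @property
    def key(self) -> Tuple:
        """Identity for cross-run / truth comparison.

        (amplicon, left-aligned ref position, kind, read bases) for
        insertions and substitutions; deletions use their length instead of
        bases (there are no read bases to carry).
        """
        detail = self.length if self.kind == "del" else self.read_bases
        return (self.amplicon_id, self.ref_pos, self.kind, detail)


TRUE_VARIANT = "true_variant"
PSEUDOGENE = "pseudogene_product"
ERROR = "error"


@dataclass(frozen=True)
class ClassifiedVariant:
    event: VariantEvent
    cls: str

    def __post_init__(self) -> None:
        if self.cls not in (TRUE_VARIANT, PSEUDOGENE, ERROR):
            raise ValueError(f"unknown class {self.cls!r}")


@dataclass
class TruthSet:
    """Expected variant keys per sample and known pseudogene side-products.

    ``expected`` and each per-amplicon pseudogene set hold event keys as
    produced by :attr:`VariantEvent.key`.
    """

    expected: set = field(default_factory=set)
    pseudogene: dict = field(default_factory=dict)  # amplicon_id -> set of keys
    amplicons: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for amp, keys in self.pseudogene.items():
            clash = keys & self.expected
            if clash:
                raise ValueError(f"pseudogene keys overlap expected variants: {clash}")

    def classify_key(self, key: Tuple) -> str:
        amp = key[0]
        if self.amplicons and amp not in self.amplicons:
            raise KeyError(f"event for unknown amplicon {amp!r}")
        if key in self.expected:
            return TRUE_VARIANT
        if key in self.pseudogene.get(amp, ()):
            return PSEUDOGENE
        return ERROR


@dataclass(frozen=True)
class TruthEvent:
    """A simulator-injected error event, in reference coordinates."""

    ref_pos: int
    kind: str
    length: int
    bases: str  # read bases for ins/sub, deleted reference bases for del
    read_pos: int  # 1-based, sequencing orientation


@dataclass
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    amplicon_id: str
    run_id: str
    source: str  # 'reference' | 'allele' | 'pseudogene'
    strand: str
    events: Sequence[TruthEvent] = ()

    def event_key(self, ev: TruthEvent) -> Tuple:
        detail = ev.length if ev.kind == "del" else ev.bases
        return (self.amplicon_id, ev.ref_pos, ev.kind, detail)
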