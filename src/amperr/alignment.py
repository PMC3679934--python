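"""Primer trimming, semi-global read alignment, and exon clipping.

Reads are aligned semi-globally to their amplicon reference: the full read
must align, but reference overhangs at either end are free, the natural
mode for a read contained within a longer amplicon. Scoring is affine
(match +2, mismatch -3, gap open -5, gap extend -2; a length-k gap costs
open + (k-1)*extend). The dynamic programming is Biopython's
:class:`Bio.Align.PairwiseAligner`; a post-pass left-aligns indels inside
homopolymers so that event coordinates are canonical.

Only exon sequence enters the downstream analysis: alignments are clipped
to the annotated exon interval after primer trimming.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from Bio import Align

from .model import AlignedRead, Column, Read, ReferenceAmplicon, revcomp


@dataclass(frozen=True)
class AlignScores:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


DEFAULT_SCORES = AlignScores()


class ReadRejected(Exception):
    """A read that cannot enter the analysis; ``reason`` says why."""

    def __init__(self, read_id: str, reason: str):
        super().__init__(f"{read_id}: {reason}")
        self.read_id = read_id
        self.reason = reason


def _hamming_at_most(a: str, b: str, k: int) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def trim_primers(read: Read, amplicon: ReferenceAmplicon, max_mismatch: int = 1) -> Read:
    """Strip the amplification primers off both read ends.

    Accepts up to ``max_mismatch`` mismatches per primer. Both sequencing
    orientations are tried: a forward read starts with the forward primer
    and ends with the reverse complement of the reverse primer; a reverse
    read is the mirror image. Raises :class:`ReadRejected` for reads shorter
    than the two primers combined or with no recognizable primer pair.
    """
    if not read.sequence:
        raise ReadRejected(read.read_id, "empty read")
    pf, pr = amplicon.primer_fwd, amplicon.primer_rev
    nf, nr = len(pf), len(pr)
    seq = read.sequence
    if len(seq) < nf + nr:
        raise ReadRejected(read.read_id, "shorter than combined primers")
    fwd = _hamming_at_most(seq[:nf], pf, max_mismatch) and _hamming_at_most(
        seq[-nr:], revcomp(pr), max_mismatch
    )
    rev = _hamming_at_most(seq[:nr], pr, max_mismatch) and _hamming_at_most(
        seq[-nf:], revcomp(pf), max_mismatch
    )
    if fwd:
        lo, hi = nf, len(seq) - nr
    elif rev:
        lo, hi = nr, len(seq) - nf
    else:
        raise ReadRejected(read.read_id, "primers not found at read ends")
    if hi <= lo:
        raise ReadRejected(read.read_id, "nothing left after primer trimming")
    return Read(read.read_id, read.run_id, read.amplicon_id, seq[lo:hi], read.quals[lo:hi])


def make_aligner(scores: AlignScores = DEFAULT_SCORES) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scores.match
    aligner.mismatch_score = scores.mismatch
    aligner.open_gap_score = scores.gap_open
    aligner.extend_gap_score = scores.gap_extend
    # free end gaps on the reference side (read contained within amplicon)
    aligner.end_deletion_score = 0.0
    return aligner


def _columns_from_alignment(aln) -> List[Column]:
    """Flatten a Biopython alignment into (ref_pos, read_pos) columns.

    Reference overhangs at the ends (free end gaps) are not columns; read
    overhangs, should they occur, become insertion columns so no read base
    is silently dropped.
    """
    tblocks, qblocks = aln.aligned
    cols: List[Column] = []
    prev_t: Optional[int] = None
    prev_q = 0
    first = True
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if first:
            for q in range(0, qs):  # leading read overhang
                cols.append((None, q))
            first = False
        else:
            for t in range(prev_t, ts):  # internal deletion
                cols.append((t, None))
            for q in range(prev_q, qs):  # internal insertion
                cols.append((None, q))
        for t, q in zip(range(ts, te), range(qs, qe)):
            cols.append((t, q))
        prev_t, prev_q = te, qe
    n_query = len(aln.query) if hasattr(aln, "query") else prev_q
    for q in range(prev_q, n_query):  # trailing read overhang
        cols.append((None, q))
    return cols


def left_align_indels(cols: List[Column], ref: str, query: str) -> List[Column]:
    """Shift gap segments left through identical bases (homopolymer canon).

    An insertion segment moves left while the read base entering it equals
    the base leaving it; deletions likewise on the reference. Produces the
    leftmost placement of each indel, the convention under which recurrent
    errors at a homopolymer share one coordinate.
    """
    cols = list(cols)
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(cols):
            r, q = cols[i]
            if r is not None and q is not None:
                i += 1
                continue
            j = i
            while j < len(cols) and (cols[j][0] is None) == (r is None) and (
                cols[j][1] is None
            ) == (q is None):
                j += 1
            # gap segment [i, j); try to swap with the aligned column at i-1
            if i > 0 and cols[i - 1][0] is not None and cols[i - 1][1] is not None:
                pr, pq = cols[i - 1]
                if r is None:  # insertion of read bases
                    last_q = cols[j - 1][1]
                    if query[pq] == query[last_q]:
                        seg = [(None, x) for x in range(pq, pq + (j - i))]
                        cols[i - 1:j] = seg + [(pr, pq + (j - i))]
                        # renumber read positions inside and after unchanged:
                        # bases are identical so only indices shift
                        changed = True
                        i = max(i - 2, 0)
                        continue
                else:  # deletion of reference bases
                    last_r = cols[j - 1][0]
                    if ref[pr] == ref[last_r]:
                        seg = [(x, None) for x in range(pr, pr + (j - i))]
                        cols[i - 1:j] = seg + [(pr + (j - i), pq)]
                        changed = True
                        i = max(i - 2, 0)
                        continue
            i = j
    return cols


def align_read(
    read: Read,
    amplicon: ReferenceAmplicon,
    scores: AlignScores = DEFAULT_SCORES,
    min_score: Optional[float] = None,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> AlignedRead:
    """Semi-globally align a (primer-trimmed) read to its reference.

    Both orientations are tried and the higher-scoring one kept (ties go to
    forward). Reads scoring below ``min_score`` are rejected as unalignable.
    """
    if not read.sequence:
        raise ReadRejected(read.read_id, "empty read")
    if aligner is None:
        aligner = make_aligner(scores)
    ref = amplicon.sequence
    fwd = aligner.align(ref, read.sequence)
    rc = revcomp(read.sequence)
    rev = aligner.align(ref, rc)
    if rev.score > fwd.score:
        best, strand, seq = rev[0], "-", rc
        quals = read.quals[::-1].copy()
    else:
        best, strand, seq = fwd[0], "+", read.sequence
        quals = read.quals.copy()
    if min_score is not None and best.score < min_score:
        raise ReadRejected(read.read_id, f"alignment score {best.score} below floor")
    cols = left_align_indels(_columns_from_alignment(best), ref, seq)
    return AlignedRead(
        read_id=read.read_id,
        run_id=read.run_id,
        amplicon_id=read.amplicon_id,
        strand=strand,
        columns=cols,
        sequence=seq,
        quals=quals,
        score=float(best.score),
    )


def clip_to_exon(aligned: AlignedRead, amplicon: ReferenceAmplicon) -> AlignedRead:
    """Restrict an alignment to the annotated exon interval.

    Columns whose reference position falls outside the exon are dropped.
    Insertion columns are kept iff their left reference neighbour lies in
    the exon (so an insertion right at the exon start, anchored in the
    intron, is dropped; one anchored at the last exon base is kept).
    Raises :class:`ReadRejected` if nothing overlaps the exon. Idempotent.
    """
    lo, hi = amplicon.exon
    kept: List[Column] = []
    last_ref = -1
    for r, q in aligned.columns:
        if r is not None:
            if lo <= r < hi:
                kept.append((r, q))
            last_ref = r
        else:
            if lo <= last_ref < hi:
                kept.append((r, q))
    if not any(r is not None for r, _ in kept):
        raise ReadRejected(aligned.read_id, "no overlap with exon")
    return AlignedRead(
        read_id=aligned.read_id,
        run_id=aligned.run_id,
        amplicon_id=aligned.amplicon_id,
        strand=aligned.strand,
        columns=kept,
        sequence=aligned.sequence,
        quals=aligned.quals,
        score=aligned.score,
        clipped=True,
    )


def aligned_read_bases(aligned: AlignedRead) -> int:
    """Number of read bases inside the alignment's columns."""
    return sum(1 for _, q in aligned.columns if q is not None)


def to_cigar(aligned: AlignedRead) -> Tuple[int, List[Tuple[int, int]]]:
    """(reference start, pysam-style CIGAR) for an alignment's columns.

    Read bases outside the columns (soft-clipped by exon clipping) are
    reported as soft clips. Operations: 0=M, 1=I, 2=D, 4=S.
    """
    cols = aligned.columns
    if not cols:
        raise ValueError("empty alignment")
    ref_start = next(r for r, _ in cols if r is not None)
    qpos = [q for _, q in cols if q is not None]
    lead = qpos[0] if qpos else 0
    trail = aligned.read_length - 1 - qpos[-1] if qpos else 0
    ops: List[Tuple[int, int]] = []
    if lead:
        ops.append((4, lead))
    for r, q in cols:
        if r is not None and q is not None:
            op = 0
        elif r is None:
            op = 1
        else:
            op = 2
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    if trail:
        ops.append((4, trail))
    return ref_start, ops


def write_sam(alignments: List[AlignedRead], amplicons: List[ReferenceAmplicon], path: str) -> None:
    """Export alignments as a SAM file via pysam."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": a.amplicon_id, "LN": len(a.sequence)} for a in amplicons],
    }
    order = {a.amplicon_id: i for i, a in enumerate(amplicons)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for ar in alignments:
            ref_start, cigar = to_cigar(ar)
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = ar.read_id
            seg.query_sequence = ar.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in ar.quals)
            )
            seg.flag = 16 if ar.strand == "-" else 0
            seg.reference_id = order[ar.amplicon_id]
            seg.reference_start = ref_start
            seg.mapping_quality = 60
            seg.cigar = cigar
            out.write(seg)
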