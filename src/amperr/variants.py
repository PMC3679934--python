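"""Discrepancy extraction and classification against a truth set.

Every maximal run of same-type discrepant alignment columns becomes one
:class:`~amperr.model.VariantEvent`; events are then partitioned into true
variants (expected from the sample's known genotype), pseudogene
side-products (systematic differences of a co-amplified homologous locus),
and sequencing errors. The partition is a total function of the event key
and the truth set, so classification is idempotent and order-independent.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pandas as pd

from .model import (
    ERROR,
    PSEUDOGENE,
    TRUE_VARIANT,
    AlignedRead,
    ClassifiedVariant,
    ReferenceAmplicon,
    TruthSet,
    VariantEvent,
)
from .quality import average_quality


def _column_state(ref: str, read: str, r, q) -> str:
    if r is None and q is None:
        raise ValueError("malformed alignment: column with gap on both sides")
    if r is None:
        return "ins"
    if q is None:
        return "del"
    return "sub" if ref[r] != read[q] else "match"


def _flank_quals(aligned: AlignedRead, left_q: int | None, right_q: int | None) -> Tuple[int, ...]:
    """Qualities of the read bases flanking a deletion (what exists of them)."""
    quals = []
    if left_q is not None and left_q >= 0:
        quals.append(int(aligned.quals[left_q]))
    if right_q is not None and right_q < aligned.read_length:
        quals.append(int(aligned.quals[right_q]))
    return tuple(quals)


def extract_variants(aligned: AlignedRead, amplicon: ReferenceAmplicon) -> List[VariantEvent]:
    """Extract merged discrepancy events from an exon-clipped alignment.

    Reference-adjacent same-type columns merge into one event (two adjacent
    mismatches are a single length-2 substitution); mixed-type adjacent
    discrepancies stay separate events. Insertions are anchored at the
    reference position following the (left-aligned) inserted segment.
    Returns an empty list iff the read matches the reference over its span.
    """
    ref = amplicon.sequence
    seq = aligned.sequence
    events: List[VariantEvent] = []
    cols = aligned.columns
    n = len(cols)
    i = 0
    while i < n:
        r, q = cols[i]
        state = _column_state(ref, seq, r, q)
        if state == "match":
            i += 1
            continue
        j = i + 1
        while j < n:
            r2, q2 = cols[j]
            if _column_state(ref, seq, r2, q2) != state:
                break
            # merge only reference-adjacent (or same-anchor) columns
            if state != "ins" and (r2 is None or cols[j - 1][0] is None or r2 != cols[j - 1][0] + 1):
                break
            if state == "ins" and q2 != cols[j - 1][1] + 1:
                break
            j += 1
        seg = cols[i:j]
        length = j - i
        if state == "sub":
            ref_pos = seg[0][0]
            ref_bases = "".join(ref[r2] for r2, _ in seg)
            read_bases = "".join(seq[q2] for _, q2 in seg)
            quals = tuple(int(aligned.quals[q2]) for _, q2 in seg)
            involved = [q2 for _, q2 in seg]
        elif state == "ins":
            # anchor: first reference column after the inserted segment
            nxt = next((r2 for r2, _ in cols[j:] if r2 is not None), None)
            if nxt is None:
                prev = next((r2 for r2, _ in reversed(cols[:i]) if r2 is not None), -1)
                nxt = prev + 1
            ref_pos = nxt
            ref_bases = ""
            read_bases = "".join(seq[q2] for _, q2 in seg)
            quals = tuple(int(aligned.quals[q2]) for _, q2 in seg)
            involved = [q2 for _, q2 in seg]
        else:  # del
            ref_pos = seg[0][0]
            ref_bases = "".join(ref[r2] for r2, _ in seg)
            read_bases = ""
            left_q = next((q2 for _, q2 in reversed(cols[:i]) if q2 is not None), None)
            right_q = next((q2 for _, q2 in cols[j:] if q2 is not None), None)
            if left_q is None and right_q is not None:
                left_q = right_q - 1
            if right_q is None and left_q is not None:
                right_q = left_q + 1
            quals = _flank_quals(aligned, left_q, right_q)
            involved = [p for p in (left_q,) if p is not None]
        if state == "del":
            base0 = involved[0] if involved else 0
            seq_positions = [aligned.seq_position(base0)]
            lq, rq = (left_q, right_q)
            flanks = [aligned.seq_position(p) for p in (lq, rq) if p is not None and 0 <= p < aligned.read_length]
            read_pos = (min(flanks) if flanks else 0) + 1
        else:
            seq_positions = [aligned.seq_position(p) for p in involved]
            read_pos = min(seq_positions) + 1
        events.append(
            VariantEvent(
                amplicon_id=aligned.amplicon_id,
                ref_pos=ref_pos,
                kind=state,
                length=length,
                ref_bases=ref_bases,
                read_bases=read_bases,
                read_id=aligned.read_id,
                run_id=aligned.run_id,
                strand=aligned.strand,
                read_pos=read_pos,
                quals=quals,
            )
        )
        i = j
    return events


def classify_variants(
    events: Iterable[VariantEvent], truth_set: TruthSet
) -> List[ClassifiedVariant]:
    """Partition events into true variants, pseudogene products and errors.

    The class depends only on the event key, so identical keys always get
    the same class and |true| + |pseudogene| + |error| = |events|.
    """
    return [ClassifiedVariant(ev, truth_set.classify_key(ev.key)) for ev in events]


def errors_only(classified: Iterable[ClassifiedVariant]) -> List[VariantEvent]:
    return [cv.event for cv in classified if cv.cls == ERROR]


def bidirectional_support(
    events: Iterable[VariantEvent],
) -> Tuple[int, float, int]:
    """Count variant keys observed on both strands.

    Returns (keys with >=1 forward and >=1 reverse observation, their
    fraction of all keys, total distinct keys).
    """
    strands: Dict[Tuple, Set[str]] = defaultdict(set)
    for ev in events:
        strands[ev.key].add(ev.strand)
    total = len(strands)
    both = sum(1 for s in strands.values() if {"+", "-"} <= s)
    return both, (both / total if total else 0.0), total


def events_to_dataframe(classified: Sequence[ClassifiedVariant]) -> pd.DataFrame:
    """Flat table of classified events (1-based positions for reporting)."""
    rows = []
    for cv in classified:
        ev = cv.event
        rows.append(
            {
                "amplicon_id": ev.amplicon_id,
                "ref_pos_1based": ev.ref_pos + 1,
                "type": ev.kind,
                "length": ev.length,
                "ref_bases": ev.ref_bases,
                "read_bases": ev.read_bases,
                "read_id": ev.read_id,
                "run_id": ev.run_id,
                "strand": ev.strand,
                "read_pos": ev.read_pos,
                "site_q": round(average_quality(ev.quals), 2) if ev.quals else float("nan"),
                "class": cv.cls,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "amplicon_id",
            "ref_pos_1based",
            "type",
            "length",
            "ref_bases",
            "read_bases",
            "read_id",
            "run_id",
            "strand",
            "read_pos",
            "site_q",
            "class",
        ],
    )


def write_vcf(
    classified: Sequence[ClassifiedVariant],
    amplicons: Sequence[ReferenceAmplicon],
    path: str,
) -> None:
    """Minimal VCFv4.2 export of classified events.

    Indels follow VCF convention: the record is anchored at the base before
    the inserted/deleted sequence, with that base prepended to REF and ALT.
    """
    by_id = {a.amplicon_id: a for a in amplicons}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Event class">\n')
        fh.write('##INFO=<ID=RUN,Number=1,Type=String,Description="Sequencing run">\n')
        fh.write('##INFO=<ID=STRAND,Number=1,Type=String,Description="Read strand">\n')
        for a in amplicons:
            fh.write(f"##contig=<ID={a.amplicon_id},length={len(a.sequence)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for cv in classified:
            ev = cv.event
            ref_seq = by_id[ev.amplicon_id].sequence
            if ev.kind == "sub":
                pos, ref_f, alt_f = ev.ref_pos + 1, ev.ref_bases, ev.read_bases
            elif ev.kind == "ins":
                anchor = max(ev.ref_pos - 1, 0)
                pos = anchor + 1
                ref_f = ref_seq[anchor]
                alt_f = ref_f + ev.read_bases
            else:
                anchor = max(ev.ref_pos - 1, 0)
                pos = anchor + 1
                ref_f = ref_seq[anchor] + ev.ref_bases
                alt_f = ref_seq[anchor]
            q = round(average_quality(ev.quals), 2) if ev.quals else "."
            fh.write(
                f"{ev.amplicon_id}\t{pos}\t.\t{ref_f}\t{alt_f}\t{q}\t.\t"
                f"CLASS={cv.cls};RUN={ev.run_id};STRAND={ev.strand}\n"
            )
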