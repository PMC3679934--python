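"""Readers and writers for the pipeline's interchange formats.

FASTA/FASTQ go through Bio.SeqIO (Sanger phred+33); tabular annotations and
truth sets are TSV via pandas; configuration is JSON. Amplicon annotation
columns: amplicon_id, locus, exon_start, exon_end (1-based closed in the
file, converted on read), primerF, primerR.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import Read, ReferenceAmplicon, TruthRecord, TruthSet


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fastq(reads: Iterable[Read], path: str) -> None:
    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
            yield rec

    SeqIO.write(records(), path, "fastq")


def read_fastq(path: str, run_id: str, amplicon_of: Mapping[str, str] | None = None) -> List[Read]:
    """Load a FASTQ; the amplicon tag is taken from the header convention
    ``run:amplicon:index/strand`` unless an explicit mapping is given."""
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        rid = rec.id
        if amplicon_of is not None:
            amp = amplicon_of[rid]
        else:
            parts = rid.split(":")
            if len(parts) < 3:
                raise ValueError(f"cannot infer amplicon from read id {rid!r}")
            amp = parts[1]
        reads.append(
            Read(
                rid,
                run_id,
                amp,
                str(rec.seq).upper(),
                np.array(rec.letter_annotations["phred_quality"], dtype=np.int64),
            )
        )
    return reads


def write_amplicon_table(amplicons: Sequence[ReferenceAmplicon], path: str) -> None:
    rows = [
        {
            "amplicon_id": a.amplicon_id,
            "locus": a.locus,
            "exon_start": a.exon[0] + 1,  # 1-based closed in the file
            "exon_end": a.exon[1],
            "primerF": a.primer_fwd,
            "primerR": a.primer_rev,
        }
        for a in amplicons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_amplicon_table(path: str, sequences: Mapping[str, str]) -> List[ReferenceAmplicon]:
    df = pd.read_csv(path, sep="\t", dtype={"amplicon_id": str, "locus": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            ReferenceAmplicon(
                amplicon_id=row["amplicon_id"],
                locus=row["locus"],
                sequence=sequences[row["amplicon_id"]],
                exon=(int(row["exon_start"]) - 1, int(row["exon_end"])),
                primer_fwd=row["primerF"],
                primer_rev=row["primerR"],
            )
        )
    return out


_TRUTH_COLS = ["read_id", "amplicon_id", "run_id", "event_pos", "event_type", "event_len", "bases"]


def write_truth_records(records: Iterable[TruthRecord], path: str) -> None:
    """Per-read injected-error table; error-free reads appear with type 'none'."""
    rows = []
    for rec in records:
        if not rec.events:
            rows.append(
                {
                    "read_id": rec.read_id,
                    "amplicon_id": rec.amplicon_id,
                    "run_id": rec.run_id,
                    "event_pos": 0,
                    "event_type": "none",
                    "event_len": 0,
                    "bases": "",
                }
            )
        for ev in rec.events:
            rows.append(
                {
                    "read_id": rec.read_id,
                    "amplicon_id": rec.amplicon_id,
                    "run_id": rec.run_id,
                    "event_pos": ev.ref_pos + 1,
                    "event_type": ev.kind,
                    "event_len": ev.length,
                    "bases": ev.bases,
                }
            )
    pd.DataFrame(rows, columns=_TRUTH_COLS).to_csv(path, sep="\t", index=False)


def write_truth_set(truth: TruthSet, path: str) -> None:
    rows = []
    for amp, pos, kind, detail in sorted(truth.expected):
        rows.append(
            {"amplicon_id": amp, "pos": pos + 1, "type": kind, "detail": detail, "kind": "expected"}
        )
    for amp_id, keys in sorted(truth.pseudogene.items()):
        for amp, pos, kind, detail in sorted(keys):
            rows.append(
                {"amplicon_id": amp, "pos": pos + 1, "type": kind, "detail": detail, "kind": "pseudogene"}
            )
    pd.DataFrame(rows, columns=["amplicon_id", "pos", "type", "detail", "kind"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth_set(path: str, amplicons: Iterable[str] = ()) -> TruthSet:
    df = pd.read_csv(path, sep="\t", dtype={"amplicon_id": str, "detail": str})
    expected = set()
    pseudo: Dict[str, set] = {}
    for _, row in df.iterrows():
        detail = row["detail"]
        if row["type"] == "del":
            detail = int(detail)
        key = (row["amplicon_id"], int(row["pos"]) - 1, row["type"], detail)
        if row["kind"] == "expected":
            expected.add(key)
        else:
            pseudo.setdefault(row["amplicon_id"], set()).add(key)
    return TruthSet(expected=expected, pseudogene=pseudo, amplicons=set(amplicons))


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
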