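"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython, SAM through pysam.  Internally reads are
plain :class:`FastqRead` tuples and alignments are :class:`~sedapop.align.AlignedRead`
records; these helpers are the only place format details live.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FastqRead", "read_fastq", "write_fastq", "read_fasta", "write_fasta",
    "read_sam", "write_sam",
]


class FastqRead(NamedTuple):
    name: str
    sequence: str
    quality: str  # Phred+33 encoded


def read_fastq(path: str | Path) -> list[FastqRead]:
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        seq = str(rec.seq).upper()
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        if len(seq) != len(qual):
            raise ValueError(f"record {i} ({rec.id}): sequence/quality length mismatch")
        out.append(FastqRead(rec.id, seq, qual))
    return out


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.name, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.quality]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_sam(reads, reference_name: str, reference_length: int,
              path: str | Path) -> None:
    """Write AlignedRead records as plain SAM (sequence in reference orientation)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference_name, "LN": reference_length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = r.name
            seg.flag = 16 if r.strand == "-" else 0
            seg.reference_id = 0
            seg.reference_start = r.ref_start
            seg.mapping_quality = 60
            seg.cigarstring = f"{len(r.sequence)}M"
            seg.query_sequence = r.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.qual))
            seg.set_tag("NM", int(r.n_mismatches))
            if r.sample_id:
                seg.set_tag("RG", r.sample_id)
            fh.write(seg)


def read_sam(path: str | Path, sample_id: str = "") -> list:
    """Ingest an external SAM file as AlignedRead records.

    Reads with indels, clips, or without a mapped position are skipped: the
    pipeline's internal model is ungapped.
    """
    from .align import AlignedRead

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            if any(op != 0 for op, _ in (seg.cigartuples or [])):
                continue
            quals = seg.query_qualities
            if quals is None:
                quals = [30] * len(seg.query_sequence)
            out.append(AlignedRead(
                name=seg.query_name,
                sequence=seg.query_sequence.upper(),
                qual=np.asarray(quals, dtype=np.uint8),
                ref_start=seg.reference_start,
                strand="-" if seg.is_reverse else "+",
                sample_id=sample_id or (seg.get_tag("RG") if seg.has_tag("RG") else ""),
                n_mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
            ))
    return out
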