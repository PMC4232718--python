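"""FASTA reading/writing (thin layer over Biopython SeqIO).

Sequences are stored as plain upper-case strings in an ordered mapping so
gapped alignment FASTA round-trips byte-exactly apart from documented case
normalization.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path: str | Path, upper: bool = True) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping.

    Raises on duplicate names and on empty records; ``upper`` controls the
    case normalization applied on input.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        seq = str(rec.seq)
        if upper:
            seq = seq.upper()
        if name in records:
            raise ValueError(f"duplicate FASTA record name {name!r} in {path}")
        if not seq:
            raise ValueError(f"empty FASTA record {name!r} in {path}")
        records[name] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    """Write an ordered name->sequence mapping as FASTA."""
    path = Path(path)
    seqrecs = []
    for name, seq in records.items():
        if not seq:
            raise ValueError(f"refusing to write empty record {name!r}")
        seqrecs.append(SeqRecord(Seq(seq), id=name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)
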