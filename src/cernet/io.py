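"""FASTA and table I/O helpers shared by the CLI."""

from __future__ import annotations

from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {id: uppercase RNA sequence} (T transcribed to U)."""
    return {rec.id: str(rec.seq).upper().replace("T", "U")
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
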