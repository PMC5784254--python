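"""Protein records and FASTA I/O.

Sequences are plain amino-acid strings. Record identifiers follow the
``species|protein_id`` header convention so that multi-proteome inventories
keep their provenance; a header without ``|`` gets the species tag
``unknown``. All residue coordinates in this package are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class ProteinRecord:
    """One amino-acid sequence with identity and provenance.

    Parameters
    ----------
    id : str
        Full identifier, conventionally ``species|protein_id``.
    seq : str
        Amino-acid sequence (uppercase, no stops).
    description : str
        Free-text remainder of the FASTA header.
    """

    id: str
    seq: str
    description: str = ""

    @property
    def species(self) -> str:
        """Species tag parsed from the ``species|protein_id`` convention."""
        if "|" in self.id:
            return self.id.split("|", 1)[0]
        return "unknown"

    @property
    def local_id(self) -> str:
        if "|" in self.id:
            return self.id.split("|", 1)[1]
        return self.id

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) FASTA file.

    Trailing ``*`` stop symbols are stripped; sequences are uppercased.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteinRecord(id=rec.id, seq=seq, description=rec.description))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def iter_windows(seq: str, size: int) -> Iterator[tuple[int, str]]:
    """Yield (1-based start, window) for every full-length window."""
    for i in range(len(seq) - size + 1):
        yield i + 1, seq[i : i + size]
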