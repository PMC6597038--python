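"""Sequence and structure file I/O.

FASTA reading/writing delegates to Biopython; structure files are plain
text with one dot-bracket string per line (blank lines and ``#``
comments ignored).  DNA-style input (T, lowercase) is normalized to the
RNA alphabet on read.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import dotbracket_to_pairmap, validate_sequence


def normalize_rna(seq: str) -> str:
    return validate_sequence(str(seq).upper().replace("T", "U"))


def read_fasta(path) -> dict[str, str]:
    """Read single- or multi-record FASTA into an ordered name->sequence map."""
    return {
        rec.id: normalize_rna(rec.seq)
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path, records: dict[str, str]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="")
         for name, seq in records.items()],
        str(path),
        "fasta",
    )


def read_structures(path) -> list[str]:
    """Read dot-bracket structures, one per line; each is validated."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        dotbracket_to_pairmap(line)
        out.append(line)
    return out


def write_structures(path, structures: list[str]) -> None:
    Path(path).write_text("\n".join(structures) + "\n")
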