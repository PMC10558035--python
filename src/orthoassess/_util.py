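"""Small shared helpers: FASTA IO, DNA translation, reverse complement."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, stops mapped to '*'
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    GENETIC_CODE[_stop] = "*"

#: amino acid -> sorted list of synonymous codons
SYNONYMOUS_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    SYNONYMOUS_CODONS.setdefault(_aa, []).append(_codon)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; anything ambiguous or short becomes X."""
    codon = codon.upper()
    if len(codon) != 3:
        return "X"
    return GENETIC_CODE.get(codon, "X")


def translate_cds(seq: str) -> str:
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3))


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (full header first word, sequence) records; gzip-transparent."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for name, seq in iter_fasta(path):
        seqs[name] = seq
    return seqs


def write_fasta(path: str | Path, records: Iterator[tuple[str, str]] | list[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
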