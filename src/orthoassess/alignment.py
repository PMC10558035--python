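"""Spliced protein-to-genome alignments in the miniprot PAF dialect.

The aligner maps an amino-acid query against nucleotide sequence, modelling
introns and frameshifts.  Its PAF output extends the CIGAR alphabet to eight
operations:

====  ==========================================  ===========  ============
op    meaning                                     query (aa)   target (nt)
====  ==========================================  ===========  ============
M     aligned codons (match or substitution)      len          3·len
I     insertion in the protein                    len          0
D     deletion from the protein (whole codons)    0            3·len
F     frameshift: nucleotides skipped             0            len
G     frameshift: codon aligned to len nt         1            len
N     phase-0 intron                              0            len
U     phase-1 intron incl. the split codon        1            len
V     phase-2 intron incl. the split codon        1            len
====  ==========================================  ===========  ============

``F`` and ``G`` both witness a reading-frame break (a 1–2 nt indel in the
assembly); their *count* — not their summed lengths — is the per-gene
frameshift-event statistic.  U/V op lengths include the split codon's
nucleotides on both sides of the intron (1+intron+2 for U, 2+intron+1 for V);
the rejoined codon contributes one amino acid.
"""

from __future__ import annotations

import logging
import os
import re
import shutil
import subprocess
from dataclasses import dataclass, field

from ._util import revcomp, translate_codon

logger = logging.getLogger(__name__)

CIGAR_OPS = frozenset("MIDFGNUV")
#: ops whose length is counted in nucleotides on the target
_NT_PER_LEN = {"F": 1, "G": 1, "N": 1, "U": 1, "V": 1}
_CIGAR_RE = re.compile(r"(\d+)([A-Za-z])")

DEFAULT_OUTS_RATIO = 0.97  # suppress alignments scoring below 97% of a query's best


class AlignmentError(ValueError):
    """Malformed alignment input."""


class AlignerNotFoundError(RuntimeError):
    pass


@dataclass(frozen=True)
class CigarOp:
    op: str
    length: int

    def __post_init__(self) -> None:
        if self.op not in CIGAR_OPS:
            raise AlignmentError(f"unknown CIGAR letter {self.op!r}")
        if self.length < 1:
            raise AlignmentError(f"non-positive CIGAR length {self.length} for op {self.op}")

    def __str__(self) -> str:
        return f"{self.length}{self.op}"


def parse_cigar(text: str) -> list[CigarOp]:
    if not text:
        raise AlignmentError("empty CIGAR string")
    ops: list[CigarOp] = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise AlignmentError(f"malformed CIGAR near {text[pos:pos+8]!r}")
        ops.append(CigarOp(m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(text):
        raise AlignmentError(f"trailing garbage in CIGAR: {text[pos:]!r}")
    return ops


def cigar_to_string(cigar: list[CigarOp]) -> str:
    return "".join(map(str, cigar))


def cigar_target_span(cigar: list[CigarOp]) -> int:
    """Nucleotides consumed on the genome: 3·M + 3·D + F + G + N + U + V."""
    span = 0
    for c in cigar:
        if c.op in "MD":
            span += 3 * c.length
        elif c.op in _NT_PER_LEN:
            span += c.length
    return span


def cigar_query_span(cigar: list[CigarOp]) -> int:
    """Amino acids consumed on the protein: ΣM + ΣI + #G + #U + #V."""
    span = 0
    for c in cigar:
        if c.op in "MI":
            span += c.length
        elif c.op in "GUV":
            span += 1
    return span


def count_frameshifts(cigar: list[CigarOp]) -> int:
    """Number of frameshift *events* (F or G operations), not summed lengths."""
    return sum(1 for c in cigar if c.op in "FG")


def aligned_aa_length(cigar: list[CigarOp]) -> int:
    """Amino acids aligned codon-to-codon (ΣM); the classifier's length measure."""
    return sum(c.length for c in cigar if c.op == "M")


@dataclass
class ProteinAlignment:
    """One spliced alignment of one member protein to the assembly."""

    protein_id: str
    group_id: str
    target: str
    target_start: int  # 0-based half-open, forward strand of the contig
    target_end: int
    strand: str
    query_start: int  # 0-based half-open, amino acids
    query_end: int
    query_length: int
    score: int
    cigar: list[CigarOp]
    cs: str | None = None
    identity: float | None = None
    translation: str | None = None
    line_number: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.target_start < self.target_end):
            raise AlignmentError(f"{self.protein_id}: bad target interval [{self.target_start},{self.target_end})")
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise AlignmentError(f"{self.protein_id}: bad query interval [{self.query_start},{self.query_end}) of {self.query_length}")
        if self.strand not in "+-":
            raise AlignmentError(f"{self.protein_id}: bad strand {self.strand!r}")
        nt = cigar_target_span(self.cigar)
        if nt != self.target_end - self.target_start:
            raise AlignmentError(
                f"{self.protein_id}: CIGAR consumes {nt} nt but target interval spans "
                f"{self.target_end - self.target_start}"
            )
        aa = cigar_query_span(self.cigar)
        if aa != self.query_end - self.query_start:
            raise AlignmentError(
                f"{self.protein_id}: CIGAR consumes {aa} aa but query interval spans "
                f"{self.query_end - self.query_start}"
            )

    @property
    def coverage(self) -> float:
        return (self.query_end - self.query_start) / self.query_length

    @property
    def frameshift_events(self) -> int:
        return count_frameshifts(self.cigar)

    @property
    def aligned_aa(self) -> int:
        return aligned_aa_length(self.cigar)

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def key(self) -> str:
        """Stable identifier of this aligned locus."""
        return f"{self.protein_id}|{self.target}:{self.target_start}-{self.target_end}{self.strand}"


def _parse_tags(fields: list[str]) -> dict[str, str]:
    tags: dict[str, str] = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return tags


def parse_alignment_line(line: str, line_number: int | None = None, header_sep: str = "_") -> ProteinAlignment:
    """Parse one PAF line (≥12 mandatory columns plus typed tags).

    Lines lacking a ``cg:Z`` extended CIGAR are rejected: every downstream
    statistic (frameshifts, translation, length class) derives from it.
    """
    fields = line.rstrip("\n").split("\t")
    where = f"line {line_number}" if line_number is not None else "PAF line"
    if len(fields) < 12:
        raise AlignmentError(f"{where}: expected ≥12 tab-separated columns, got {len(fields)}")
    tags = _parse_tags(fields[12:])
    if "cg" not in tags:
        raise AlignmentError(f"{where}: missing cg:Z CIGAR tag")
    cigar = parse_cigar(tags["cg"])
    score_text = tags.get("AS") or tags.get("ms") or fields[9]
    try:
        qlen, qstart, qend = int(fields[1]), int(fields[2]), int(fields[3])
        tstart, tend = int(fields[7]), int(fields[8])
        score = int(score_text)
    except ValueError as exc:
        raise AlignmentError(f"{where}: non-integer coordinate or score: {exc}") from exc
    protein_id = fields[0]
    from .lineage import group_id_from_header

    return ProteinAlignment(
        protein_id=protein_id,
        group_id=group_id_from_header(protein_id, header_sep),
        target=fields[5],
        target_start=tstart,
        target_end=tend,
        strand=fields[4],
        query_start=qstart,
        query_end=qend,
        query_length=qlen,
        score=score,
        cigar=cigar,
        cs=tags.get("cs"),
        line_number=line_number,
    )


def parse_paf(text_or_lines, header_sep: str = "_") -> list[ProteinAlignment]:
    """Parse a PAF stream; ``##``-prefixed comment lines are ignored."""
    if isinstance(text_or_lines, str):
        text_or_lines = text_or_lines.splitlines()
    out = []
    for lineno, line in enumerate(text_or_lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        out.append(parse_alignment_line(line, line_number=lineno, header_sep=header_sep))
    return out


# ---------------------------------------------------------------------------
# identity

_CS_TOKEN = re.compile(
    r":(?P<eq>\d+)"
    r"|\*(?P<sub_nt>[acgtn]{1,3})(?P<sub_aa>[A-Z*])"
    r"|\+(?P<ins>[A-Z*]+)"
    r"|-(?P<dele>[acgtn]+)"
    r"|~(?P<don>[acgtn]{2})(?P<ilen>\d+)(?P<acc>[acgtn]{2})"
)


def identity_from_cs(cs: str) -> float:
    """Identity over aligned residue columns encoded in a cs difference string.

    ``:n`` counts n identical columns; ``*<codon><aa>`` one substituted
    column (frameshifted codons appear with 1–2 nt and are never identical);
    insertions, deletions and introns contribute no columns.
    """
    identical = columns = 0
    pos = 0
    for m in _CS_TOKEN.finditer(cs):
        if m.start() != pos:
            raise AlignmentError(f"malformed cs string near {cs[pos:pos+10]!r}")
        pos = m.end()
        if m.group("eq"):
            n = int(m.group("eq"))
            identical += n
            columns += n
        elif m.group("sub_nt"):
            columns += 1
    if pos != len(cs):
        raise AlignmentError(f"trailing garbage in cs string: {cs[pos:]!r}")
    if columns == 0:
        return 0.0
    return identical / columns


def identity_from_translation(aln: ProteinAlignment, query_seq: str) -> float:
    """Identity by columnwise comparison of the reconstructed translation
    against the member protein.

    Walks the CIGAR: each M column pairs one translated codon with one query
    residue; U/V split codons pair likewise; G columns (frameshifted codons)
    count in the denominator but never as identical — a broken reading frame
    is evidence of assembly error, not conservation.
    """
    if aln.translation is None:
        raise AlignmentError("alignment has no reconstructed translation; call reconstruct_translation first")
    trans = aln.translation
    qseq = query_seq[aln.query_start : aln.query_end]
    ti = qi = 0
    identical = columns = 0
    for c in aln.cigar:
        if c.op == "M":
            for _ in range(c.length):
                columns += 1
                if trans[ti] == qseq[qi]:
                    identical += 1
                ti += 1
                qi += 1
        elif c.op == "I":
            qi += c.length
        elif c.op in "UV":
            columns += 1
            if trans[ti] == qseq[qi]:
                identical += 1
            ti += 1
            qi += 1
        elif c.op == "G":
            columns += 1  # translated as X; never identical to a real residue
            ti += 1
            qi += 1
        # D, F, N consume neither translation nor query residues
    if columns == 0:
        return 0.0
    return identical / columns


def compute_identity(aln: ProteinAlignment, query_seq: str | None = None) -> float:
    """Identity of an alignment, from its cs tag if present, else by
    reconstruction against the query protein sequence."""
    if aln.cs is not None:
        return identity_from_cs(aln.cs)
    if query_seq is not None and aln.translation is not None:
        return identity_from_translation(aln, query_seq)
    raise AlignmentError(f"{aln.protein_id}: no cs tag and no query sequence/translation to compute identity")


# ---------------------------------------------------------------------------
# translation reconstruction


def reconstruct_translation(aln: ProteinAlignment, genome: dict[str, str]) -> str:
    """Translate the aligned genomic region by walking the CIGAR.

    M consumes codons and translates them; D consumes codons silently;
    F skips frameshift nucleotides; G consumes 1–2 nt and emits ``X``
    (the frameshifted codon's residue is unknowable); N/U/V excise introns,
    with U/V rejoining the split codon across the junction.  Minus-strand
    alignments are reverse-complemented first.  Codons containing ambiguous
    bases translate to ``X``.
    """
    if aln.target not in genome:
        raise AlignmentError(f"contig {aln.target!r} absent from genome")
    region = genome[aln.target][aln.target_start : aln.target_end]
    if len(region) != aln.target_span:
        raise AlignmentError(
            f"{aln.protein_id}: target interval [{aln.target_start},{aln.target_end}) "
            f"exceeds contig {aln.target} length"
        )
    if aln.strand == "-":
        region = revcomp(region)
    out: list[str] = []
    pos = 0
    for c in aln.cigar:
        if c.op == "M":
            for _ in range(c.length):
                out.append(translate_codon(region[pos : pos + 3]))
                pos += 3
        elif c.op == "D":
            pos += 3 * c.length
        elif c.op in "FN":
            pos += c.length
        elif c.op == "G":
            out.append("X")
            pos += c.length
        elif c.op == "U":  # 1 nt + intron + 2 nt
            codon = region[pos] + region[pos + c.length - 2 : pos + c.length]
            out.append(translate_codon(codon))
            pos += c.length
        elif c.op == "V":  # 2 nt + intron + 1 nt
            codon = region[pos : pos + 2] + region[pos + c.length - 1]
            out.append(translate_codon(codon))
            pos += c.length
        # I consumes no genome
    translation = "".join(out)
    aln.translation = translation
    return translation


# ---------------------------------------------------------------------------
# external aligner


def run_aligner(
    genome: str | os.PathLike,
    proteins: str | os.PathLike,
    aligner_path: str = "miniprot",
    outs_ratio: float = DEFAULT_OUTS_RATIO,
    threads: int = 1,
    extra_args: tuple[str, ...] = (),
) -> str:
    """Run the external spliced aligner and return its PAF output.

    The secondary-suppression ratio (``--outs``) defaults to 0.97: alignments
    scoring below 97% of a query's best alignment are not reported.  The
    invocation, version and exit status are logged.  When the binary is
    unavailable, pre-computed PAF ingestion (:func:`parse_paf`) is the
    supported binary-free alternative.
    """
    for path, what in ((genome, "genome"), (proteins, "protein")):
        if not os.path.exists(path):
            raise FileNotFoundError(f"{what} file not found: {path}")
        if not os.access(path, os.R_OK):
            raise PermissionError(f"{what} file not readable: {path}")
    exe = shutil.which(aligner_path)
    if exe is None:
        raise AlignerNotFoundError(
            f"aligner binary {aligner_path!r} not found on PATH; either install it, pass "
            f"aligner_path=, or supply pre-computed alignments (paf=...) for binary-free operation"
        )
    try:
        version = subprocess.run([exe, "--version"], capture_output=True, text=True, check=False).stdout.strip()
    except OSError:
        version = "unknown"
    cmd = [exe, "-t", str(threads), f"--outs={outs_ratio}", *extra_args, str(genome), str(proteins)]
    logger.info("running aligner: %s (version %s)", " ".join(cmd), version)
    proc = subprocess.run(cmd, capture_output=True, text=True)
    logger.info("aligner exit status %d", proc.returncode)
    if proc.returncode != 0:
        raise RuntimeError(f"aligner failed with exit {proc.returncode}: {proc.stderr.strip()[:2000]}")
    return proc.stdout
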