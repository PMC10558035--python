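"""Four-way completeness classification and dataset-level summaries.

After alignment and HMM filtering, each ortholog group is assigned one of
four statuses:

* **Missing** — no alignment survived HMM filtration;
* **Fragmented** — alignments survive but *all* are shorter than the
  group's length threshold (mean expected length minus two sigmas);
* **Single** — exactly one surviving locus, full length;
* **Duplicated** — two or more surviving loci, at least one full length.

Aligned length is measured in amino acids actually aligned codon-to-codon
(ΣM over the CIGAR), not genomic span.  Near-identical overlapping
alignments on the same contig and strand are collapsed to one locus before
the single/duplicated decision so redundant secondary records cannot fake a
duplication.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from . import alignment as aln_mod
from .alignment import ProteinAlignment, compute_identity, parse_paf, reconstruct_translation, run_aligner
from .lineage import LineageDataset, OrthoGroup, load_lineage
from .orthology import (
    HmmHit,
    PyhmmerBackend,
    ScoringBackend,
    apply_cutoff,
    score_alignments,
    select_representative,
)
from ._util import read_fasta

logger = logging.getLogger(__name__)

DIVERGENCE_IDENTITY_FLOOR = 0.5  # mean identity below this triggers the warning
LOCUS_OVERLAP_FRACTION = 0.5  # same-contig/strand overlap beyond this fraction of the shorter span = one locus


class Status(str, Enum):
    SINGLE = "Single"
    DUPLICATED = "Duplicated"
    FRAGMENTED = "Fragmented"
    MISSING = "Missing"


@dataclass
class GeneAssessment:
    """Final status of one ortholog group plus its supporting alignments."""

    group_id: str
    status: Status
    alignments: list[ProteinAlignment] = field(default_factory=list)
    representative_protein: str | None = None
    frameshift_events: int = 0
    best_identity: float | None = None
    bit_scores: dict[str, float] = field(default_factory=dict)  # alignment key -> bits

    def __post_init__(self) -> None:
        if (self.status is Status.MISSING) != (len(self.alignments) == 0):
            raise ValueError(f"group {self.group_id}: Missing status must coincide with empty alignments")


@dataclass
class AssessmentReport:
    """Dataset-level S/D/F/M counts, percentages and quality summaries."""

    n: int
    counts: dict[Status, int]
    mean_identity: float | None  # over non-missing representatives; None if all missing
    frameshift_gene_fraction: float  # non-missing genes with ≥1 frameshift event
    divergence_warning: bool
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n:
            raise ValueError(f"status counts {self.counts} do not sum to n={self.n}")

    def percentage(self, status: Status) -> float:
        return 100.0 * self.counts[status] / self.n if self.n else 0.0

    @property
    def complete_pct(self) -> float:
        return self.percentage(Status.SINGLE) + self.percentage(Status.DUPLICATED)


def length_threshold(group: OrthoGroup) -> float:
    """Minimum aligned length (aa) for a hit to count as full length:
    max(0, mean − 2·sigma) over the lineage's length statistics."""
    return max(0.0, group.length_mean - 2.0 * group.length_sigma)


def _genomic_overlap(a: ProteinAlignment, b: ProteinAlignment) -> int:
    return max(0, min(a.target_end, b.target_end) - max(a.target_start, b.target_start))


def dedup_loci(alignments: list[ProteinAlignment]) -> list[ProteinAlignment]:
    """Collapse same-contig, same-strand alignments overlapping by more than
    half of the shorter genomic span; the higher-scoring record represents
    the locus."""
    kept: list[ProteinAlignment] = []
    for aln in sorted(alignments, key=lambda a: (-a.score, -a.aligned_aa, a.key)):
        redundant = False
        for other in kept:
            if aln.target != other.target or aln.strand != other.strand:
                continue
            shorter = min(aln.target_span, other.target_span)
            if _genomic_overlap(aln, other) > LOCUS_OVERLAP_FRACTION * shorter:
                redundant = True
                break
        if not redundant:
            kept.append(aln)
    return kept


def classify_group(
    group: OrthoGroup,
    survivors: list[ProteinAlignment],
    representative: str | None = None,
    bit_scores: dict[str, float] | None = None,
) -> GeneAssessment:
    """Assign one of the four statuses from the representative's surviving loci."""
    if not survivors:
        return GeneAssessment(group_id=group.group_id, status=Status.MISSING)
    loci = dedup_loci(survivors)
    threshold = length_threshold(group)
    full = [a for a in loci if a.aligned_aa >= threshold]
    if not full:
        status = Status.FRAGMENTED
    elif len(loci) == 1:
        status = Status.SINGLE
    else:
        status = Status.DUPLICATED
    identities = [a.identity for a in loci if a.identity is not None]
    return GeneAssessment(
        group_id=group.group_id,
        status=status,
        alignments=loci,
        representative_protein=representative or survivors[0].protein_id,
        frameshift_events=sum(a.frameshift_events for a in loci),
        best_identity=max(identities) if identities else None,
        bit_scores={k: v for k, v in (bit_scores or {}).items()},
    )


def frameshift_summary(assessments: list[GeneAssessment]) -> float:
    """Fraction of non-missing genes carrying at least one frameshift event
    (an F or G CIGAR operation in a reported alignment)."""
    present = [a for a in assessments if a.status is not Status.MISSING]
    if not present:
        return 0.0
    return sum(1 for a in present if a.frameshift_events >= 1) / len(present)


def summarize(assessments: list[GeneAssessment]) -> AssessmentReport:
    counts = {s: 0 for s in Status}
    for a in assessments:
        counts[a.status] += 1
    identities = [a.best_identity for a in assessments if a.status is not Status.MISSING and a.best_identity is not None]
    notes: list[str] = []
    if identities:
        mean_identity = sum(identities) / len(identities)
    else:
        mean_identity = None
        notes.append("no surviving alignments: mean identity undefined, divergence check skipped")
    report = AssessmentReport(
        n=len(assessments),
        counts=counts,
        mean_identity=mean_identity,
        frameshift_gene_fraction=frameshift_summary(assessments),
        divergence_warning=mean_identity is not None and mean_identity < DIVERGENCE_IDENTITY_FLOOR,
        notes=notes,
    )
    return report


def divergence_check(report: AssessmentReport, stream=None) -> bool:
    """Warn when mean alignment identity is below 50%.

    High divergence between the assembly and the lineage's proteins makes a
    one-round alignment assessment unreliable; the message recommends also
    running BUSCO.  Printed exactly once per report, on the diagnostic
    stream.  Undefined mean identity (everything missing) logs a note and
    does not warn.
    """
    stream = stream if stream is not None else sys.stderr
    if report.mean_identity is None:
        logger.info("no alignments survived; divergence check not applicable")
        return False
    if report.divergence_warning:
        print(
            f"WARNING: mean protein-alignment identity is "
            f"{report.mean_identity:.1%}, below 50%. The assembly may be highly "
            f"diverged from this lineage; additionally running BUSCO is recommended.",
            file=stream,
        )
        return True
    return False


# ---------------------------------------------------------------------------
# end-to-end pipeline


def assess(
    genome: str | Path | dict[str, str],
    lineage: str | Path | LineageDataset,
    paf: str | Path | None = None,
    backend: ScoringBackend | None = None,
    outs_ratio: float = aln_mod.DEFAULT_OUTS_RATIO,
    aligner_path: str = "miniprot",
    threads: int = 1,
    header_sep: str = "_",
    diagnostic_stream=None,
) -> tuple[AssessmentReport, list[GeneAssessment]]:
    """Run the full pipeline: align (or ingest), translate, HMM-filter,
    pick representatives, classify every group, and summarize.

    Parameters
    ----------
    genome:
        FASTA path (optionally gzipped) or an in-memory ``{contig: seq}`` dict.
    lineage:
        Lineage directory or an already-loaded :class:`LineageDataset`.
    paf:
        Pre-computed aligner PAF (path or literal text).  When given, no
        subprocess is launched — the binary-free mode.
    backend:
        HMM scoring backend; defaults to in-process pyhmmer.
    outs_ratio:
        Secondary-suppression ratio passed to the aligner (live mode only;
        pre-computed PAF is trusted to have been produced with it).
    """
    if not isinstance(lineage, LineageDataset):
        lineage = load_lineage(lineage, header_sep=header_sep)
    if lineage.n_groups == 0:
        raise ValueError("lineage has no ortholog groups")
    if not isinstance(genome, dict):
        genome = read_fasta(genome)

    if paf is not None:
        if isinstance(paf, Path) or (isinstance(paf, str) and paf and "\n" not in paf and "\t" not in paf and Path(paf).exists()):
            paf_text = Path(str(paf)).read_text()
        else:
            paf_text = str(paf)
        logger.info("ingesting pre-computed alignments (binary-free mode)")
    else:
        import tempfile

        from ._util import write_fasta

        with tempfile.TemporaryDirectory() as tmp:
            gpath = Path(tmp) / "genome.fa"
            ppath = Path(tmp) / "proteins.faa"
            write_fasta(gpath, [(n, s) for n, s in genome.items()])
            write_fasta(
                ppath,
                [(pid, seq) for g in lineage.groups.values() for pid, seq in g.proteins],
            )
            paf_text = run_aligner(gpath, ppath, aligner_path=aligner_path, outs_ratio=outs_ratio, threads=threads)
        logger.info("effective secondary-suppression ratio: %g", outs_ratio)

    alignments = [a for a in parse_paf(paf_text, header_sep=header_sep) if a.group_id in lineage.groups]
    dropped = len(parse_paf(paf_text, header_sep=header_sep)) - len(alignments)
    if dropped:
        logger.warning("%d alignment(s) referenced unknown ortholog groups and were ignored", dropped)

    for aln in alignments:
        reconstruct_translation(aln, genome)
        query_seq = lineage.groups[aln.group_id].protein_sequence(aln.protein_id)
        aln.identity = compute_identity(aln, query_seq)

    backend = backend or PyhmmerBackend()
    hits = score_alignments(alignments, lineage, backend)
    retained = apply_cutoff(hits, lineage)
    by_key = {a.key: a for a in alignments}
    by_group: dict[str, list[HmmHit]] = {}
    for h in retained:
        by_group.setdefault(h.group_id, []).append(h)

    assessments: list[GeneAssessment] = []
    for gid in sorted(lineage.groups):
        group = lineage.groups[gid]
        chosen = select_representative(by_group.get(gid, []))
        if chosen is None:
            assessments.append(GeneAssessment(group_id=gid, status=Status.MISSING))
            continue
        rep, rep_hits = chosen
        survivors = [by_key[h.alignment_ref] for h in rep_hits]
        assessments.append(
            classify_group(
                group,
                survivors,
                representative=rep,
                bit_scores={h.alignment_ref: h.bit_score for h in rep_hits},
            )
        )

    report = summarize(assessments)
    divergence_check(report, stream=diagnostic_stream)
    assert sum(report.counts.values()) == report.n
    return report, assessments
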