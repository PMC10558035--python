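"""Truth-labeled synthetic inputs: toy lineages, planted genomes, rendered PAF.

Everything the pipeline consumes can be generated here at toy scale with a
known ground truth and no external binaries:

* :func:`make_toy_lineage` writes a fully valid lineage directory whose
  profile HMMs are built from the member proteins themselves, with per-group
  bit-score cutoffs calibrated so that genuine members (and 30%-length
  fragments of them) pass while shuffled decoys fail.
* :func:`plant_genome` reverse-translates member peptides with randomized
  synonymous codons, inserts canonical GT–AG introns at requested phases,
  applies defects (extra copies, 3'-truncation, omission, 1–2 nt
  frameshifts, substitutions, diverged paralog copies) and embeds the genes
  in random intergenic sequence, recording the expected status of every
  group.
* :func:`render_paf_fixture` emits the alignments an ideal spliced aligner
  would report for the planted truth — exact extended CIGARs including
  N/U/V/F/G operations — applying the secondary-suppression score ratio
  across each query's loci, so the full parse → filter → classify pipeline
  runs without any aligner.

All generators are seed-reproducible byte-for-byte.  The emulation is
deliberately idealized: no repeats, no GC isochores, no alignment noise —
what passing tests show is the correctness of the bookkeeping downstream of
alignment, not aligner robustness on real genomes.
"""

from __future__ import annotations

import datetime
import random
from dataclasses import dataclass, field
from pathlib import Path

from ._util import AMINO_ACIDS, SYNONYMOUS_CODONS, revcomp, write_fasta
from .alignment import DEFAULT_OUTS_RATIO, CigarOp, cigar_to_string
from .classify import length_threshold
from .lineage import LineageDataset, OrthoGroup, load_lineage

_HMM_EPOCH = datetime.datetime(2024, 1, 1)
_LENGTH_SIGMA_FRACTION = 0.1  # sigma = 10% of mean -> full-length threshold at 80%


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# toy lineage


def _random_peptide(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _mutate_peptide(rng: random.Random, peptide: str, rate: float) -> tuple[str, list[int]]:
    out = list(peptide)
    positions = []
    for i, aa in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([x for x in AMINO_ACIDS if x != aa])
            positions.append(i)
    return "".join(out), positions


def _bit_score_of(pyhmmer, alphabet, background, hmm, sequence: str) -> float:
    pipeline = pyhmmer.plan7.Pipeline(alphabet, background=background, bias_filter=False, F1=1.0, F2=1.0, F3=1.0, E=1e6)
    seq = pyhmmer.easel.TextSequence(name=b"cal", sequence=sequence).digitize(alphabet)
    hits = pipeline.search_hmm(hmm, pyhmmer.easel.DigitalSequenceBlock(alphabet, [seq]))
    return float(hits[0].score) if hits else float("-inf")


def make_toy_lineage(
    out_dir: str | Path,
    n_groups: int = 5,
    proteins_per_group: int = 3,
    peptide_length_range: tuple[int, int] = (80, 120),
    seed: int = 0,
    member_divergence: float = 0.04,
) -> Path:
    """Write a complete toy lineage directory and return its path.

    Member proteins of a group are substitution-only variants of a common
    random peptide (so they form a trivial gap-free MSA); the group HMM is
    built from that MSA.  Cutoffs are the midpoint between the weakest
    genuine signal (members and a 30%-length fragment) and the strongest
    shuffled decoy, asserted to separate cleanly.  Deterministic and
    byte-identical under a fixed seed.
    """
    import pyhmmer

    if n_groups < 1:
        raise FixtureError("n_groups must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "hmms").mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    alphabet = pyhmmer.easel.Alphabet.amino()
    background = pyhmmer.plan7.Background(alphabet)
    builder = pyhmmer.plan7.Builder(alphabet, seed=seed + 1)

    fasta_records: list[tuple[str, str]] = []
    score_lines: list[str] = []
    length_lines: list[str] = []
    for i in range(n_groups):
        gid = f"{1000 + i}at0"
        length = rng.randint(*peptide_length_range)
        base = _random_peptide(rng, length)
        members = []
        for j in range(proteins_per_group):
            pep = base if j == 0 else _mutate_peptide(rng, base, member_divergence)[0]
            members.append((f"{gid}_{j}", pep))
        fasta_records.extend(members)

        msa = pyhmmer.easel.TextMSA(
            name=gid.encode(),
            sequences=[pyhmmer.easel.TextSequence(name=pid.encode(), sequence=pep) for pid, pep in members],
        )
        hmm, _, _ = builder.build_msa(msa.digitize(alphabet), background)
        hmm.creation_time = _HMM_EPOCH
        with open(out_dir / "hmms" / f"{gid}.hmm", "wb") as fh:
            hmm.write(fh)

        # calibrate: genuine signal = members plus a 30%-length fragment;
        # null = shuffled decoys of the same composition
        signal = [_bit_score_of(pyhmmer, alphabet, background, hmm, pep) for _, pep in members]
        fragment = members[0][1][: max(10, int(0.3 * length))]
        signal.append(_bit_score_of(pyhmmer, alphabet, background, hmm, fragment))
        decoy_scores = []
        for _ in range(3):
            shuffled = list(members[0][1])
            rng.shuffle(shuffled)
            decoy_scores.append(_bit_score_of(pyhmmer, alphabet, background, hmm, "".join(shuffled)))
        max_decoy = max(decoy_scores)
        min_signal = min(signal)
        if max_decoy == float("-inf"):
            cutoff = min_signal / 2.0
        else:
            if min_signal <= max_decoy + 2.0:
                raise FixtureError(
                    f"group {gid}: cannot calibrate cutoff (signal {min_signal:.1f} vs decoy {max_decoy:.1f})"
                )
            cutoff = (min_signal + max_decoy) / 2.0
        cutoff = max(cutoff, 0.0)
        score_lines.append(f"{gid}\t{cutoff:.2f}")
        length_lines.append(f"{gid}\t0\t{length * _LENGTH_SIGMA_FRACTION:.2f}\t{float(length):.1f}")

    write_fasta(out_dir / "refseq_db.faa", fasta_records)
    (out_dir / "scores_cutoff").write_text("\n".join(score_lines) + "\n")
    (out_dir / "lengths_cutoff").write_text("\n".join(length_lines) + "\n")
    (out_dir / "dataset.cfg").write_text(
        f"name={out_dir.name}\ncreation_date=2024-01-01\nnumber_of_BUSCOs={n_groups}\ndomain=toy\n"
    )
    return out_dir


# ---------------------------------------------------------------------------
# gene planting


@dataclass
class GeneSpec:
    """Requested planting of one ortholog group into the toy genome."""

    group_id: str
    contig: str = "chr1"
    strand: str = "+"
    member: int = 0
    introns: list[tuple[int, int, int]] = field(default_factory=list)  # (aa_pos, length_nt, phase 0/1/2)
    frameshifts: list[tuple[int, str]] = field(default_factory=list)  # (aa_pos, "del1" | "ins1")
    substitution_rate: float = 0.0
    truncation_fraction: float | None = None  # keep this fraction of the 5' peptide
    absent: bool = False
    extra_copies: list[tuple[str, str]] = field(default_factory=list)  # exact duplicates: (contig, strand)
    paralogs: list[tuple[str, str, float]] = field(default_factory=list)  # (contig, strand, substitution_rate)


@dataclass
class Locus:
    """One planted copy of a gene, with the alignment an ideal aligner reports."""

    contig: str
    strand: str
    role: str  # primary | duplicate | paralog
    gene_nt: str  # nucleotides in query orientation (revcomp'd on insertion for '-')
    cigar: list[CigarOp]
    cs: str
    qstart: int
    qend: int
    qlen: int
    identical: int  # identical aligned columns
    columns: int  # aligned columns (M + G + U + V)
    start: int = -1  # contig coordinates, filled at assembly time
    end: int = -1

    @property
    def score(self) -> int:
        return 2 * self.identical

    @property
    def identity(self) -> float:
        return self.identical / self.columns if self.columns else 0.0


@dataclass
class PlantedGene:
    group_id: str
    protein_id: str
    peptide: str  # the query member protein
    spec: GeneSpec
    loci: list[Locus]
    expected_status: str
    expected_frameshifts: int


@dataclass
class Scenario:
    """A planted toy genome with its lineage and per-gene ground truth."""

    lineage: LineageDataset
    lineage_dir: Path
    genes: list[PlantedGene]
    genome: dict[str, str]
    seed: int

    def truth(self) -> dict[str, str]:
        return {g.group_id: g.expected_status for g in self.genes}

    def write_genome(self, path: str | Path) -> Path:
        write_fasta(path, sorted(self.genome.items()))
        return Path(path)

    def write_truth(self, path: str | Path) -> Path:
        lines = ["group_id\texpected_status\texpected_frameshifts\tcontigs"]
        for g in self.genes:
            contigs = ",".join(sorted({l.contig for l in g.loci})) or "-"
            lines.append(f"{g.group_id}\t{g.expected_status}\t{g.expected_frameshifts}\t{contigs}")
        Path(path).write_text("\n".join(lines) + "\n")
        return Path(path)


def _reverse_translate(rng: random.Random, peptide: str) -> list[str]:
    return [rng.choice(SYNONYMOUS_CODONS[aa]) for aa in peptide]


def _random_dna(rng: random.Random, length: int, gc: float) -> str:
    weights = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=weights, k=length))


def _mutate_exact(rng: random.Random, peptide: str, n_subs: int) -> tuple[str, list[int]]:
    """Substitute exactly ``n_subs`` positions (paralog copies need their
    score ratio to the primary locus guaranteed, not merely expected)."""
    out = list(peptide)
    positions = sorted(rng.sample(range(len(peptide)), min(n_subs, len(peptide))))
    for i in positions:
        out[i] = rng.choice([x for x in AMINO_ACIDS if x != out[i]])
    return "".join(out), positions


def _build_locus(
    rng: random.Random,
    query: str,
    spec: GeneSpec,
    contig: str,
    strand: str,
    role: str,
    substitution_rate: float,
) -> Locus:
    """Construct the genomic nucleotides and the ideal alignment of one copy."""
    import math

    qlen = len(query)
    keep = qlen if spec.truncation_fraction is None else max(5, int(round(spec.truncation_fraction * qlen)))
    if role == "paralog":
        genomic_pep, mismatches = _mutate_exact(rng, query[:keep], max(1, math.ceil(substitution_rate * keep)))
    else:
        genomic_pep, mismatches = _mutate_peptide(rng, query[:keep], substitution_rate)
    mismatch_set = set(mismatches)
    introns = {pos: (length, phase) for pos, length, phase in spec.introns if pos < keep}
    shifts = {pos: kind for pos, kind in spec.frameshifts if pos < keep}
    for pos, (ilen, phase) in introns.items():
        if pos in shifts:
            raise FixtureError(f"{spec.group_id}: intron and frameshift collide at position {pos}")
        if ilen < 10:
            raise FixtureError(f"{spec.group_id}: intron at {pos} shorter than 10 nt")
        if phase not in (0, 1, 2):
            raise FixtureError(f"{spec.group_id}: bad intron phase {phase}")

    codons = _reverse_translate(rng, genomic_pep)
    ops: list[CigarOp] = []
    nt: list[str] = []
    cs: list[str] = []
    run = 0
    identical = columns = 0

    def flush() -> None:
        nonlocal run
        if run:
            cs.append(f":{run}")
            run = 0

    def push(op: str, length: int) -> None:
        if op == "M" and ops and ops[-1].op == "M":
            ops[-1] = CigarOp("M", ops[-1].length + length)
        else:
            ops.append(CigarOp(op, length))

    for i in range(keep):
        codon = codons[i]
        intron = introns.get(i)
        if intron and intron[1] == 0:  # phase-0: between codons, before this one
            ilen = intron[0]
            iseq = "gt" + _random_dna(rng, ilen - 4, 0.4).lower() + "ag"
            nt.append(iseq)
            push("N", ilen)
            flush()
            cs.append(f"~gt{ilen}ag")
            intron = None
        columns += 1
        match = i not in mismatch_set
        if intron:  # phase 1 or 2: split codon inside a U/V op
            ilen, phase = intron
            iseq = "gt" + _random_dna(rng, ilen - 4, 0.4).lower() + "ag"
            nt.append(codon[:phase] + iseq + codon[phase:])
            push("U" if phase == 1 else "V", ilen + 3)
            flush()
            cs.append(f"~gt{ilen}ag")
            if match:
                cs.append(":1")
                identical += 1
            else:
                cs.append(f"*{codon.lower()}{query[i]}")
        elif shifts.get(i) == "del1":  # codon lost one nucleotide: G op, residue unknowable
            short = codon[:2]
            nt.append(short)
            push("G", 2)
            flush()
            cs.append(f"*{short.lower()}{query[i]}")
        elif match:
            nt.append(codon)
            push("M", 1)
            run += 1
            identical += 1
        else:
            nt.append(codon)
            push("M", 1)
            flush()
            cs.append(f"*{codon.lower()}{query[i]}")
        if shifts.get(i) == "ins1":  # stray nucleotide after this codon: F op
            extra = rng.choice("ACGT")
            nt.append(extra)
            push("F", 1)
            flush()
            cs.append(f"-{extra.lower()}")
    flush()

    return Locus(
        contig=contig,
        strand=strand,
        role=role,
        gene_nt="".join(nt),
        cigar=ops,
        cs="".join(cs),
        qstart=0,
        qend=keep,
        qlen=qlen,
        identical=identical,
        columns=columns,
    )


def _expected_status(group: OrthoGroup, spec: GeneSpec, primary: Locus) -> str:
    """Truth rule: absent -> Missing; all loci sub-threshold -> Fragmented;
    >1 surviving full-length locus -> Duplicated; else Single."""
    if spec.absent:
        return "Missing"
    threshold = length_threshold(group)
    aligned = sum(c.length for c in primary.cigar if c.op == "M")
    if spec.truncation_fraction is not None:
        if aligned >= threshold:
            raise FixtureError(
                f"{spec.group_id}: truncated copy still reaches the length threshold "
                f"({aligned} >= {threshold:.1f}); lower truncation_fraction"
            )
        return "Fragmented"
    if aligned < threshold:
        raise FixtureError(f"{spec.group_id}: planted copy below length threshold ({aligned} < {threshold:.1f})")
    if spec.extra_copies:
        return "Duplicated"
    return "Single"


def plant_genome(
    lineage: LineageDataset | str | Path,
    specs: list[GeneSpec],
    intergenic_length: int = 200,
    gc: float = 0.4,
    seed: int = 0,
    outs_ratio: float = DEFAULT_OUTS_RATIO,
) -> Scenario:
    """Plant every requested gene into a toy genome and label the truth.

    Paralog copies are given enough substitutions that their ideal alignment
    scores fall below ``outs_ratio`` of the primary locus (asserted), so
    they stay suppressed while the primary contig is present — mirroring how
    secondary hits resurface only when their better locus is deleted.
    """
    lineage_dir = Path(lineage) if not isinstance(lineage, LineageDataset) else None
    if lineage_dir is not None:
        lineage = load_lineage(lineage_dir)
    genes: list[PlantedGene] = []
    contig_parts: dict[str, list[str]] = {}
    contig_loci: dict[str, list[Locus]] = {}

    for spec in specs:
        if spec.group_id not in lineage.groups:
            raise FixtureError(f"unknown group {spec.group_id}")
        group = lineage.groups[spec.group_id]
        protein_id, query = group.proteins[spec.member]
        rng = random.Random(f"{seed}:{spec.group_id}")
        loci: list[Locus] = []
        if not spec.absent:
            primary = _build_locus(rng, query, spec, spec.contig, spec.strand, "primary", spec.substitution_rate)
            loci.append(primary)
            for contig, strand in spec.extra_copies:
                dup = _build_locus(rng, query, spec, contig, strand, "duplicate", spec.substitution_rate)
                loci.append(dup)
            for contig, strand, par_rate in spec.paralogs:
                par = _build_locus(rng, query, spec, contig, strand, "paralog", par_rate)
                if par.score >= outs_ratio * primary.score:
                    raise FixtureError(
                        f"{spec.group_id}: paralog scores {par.score} vs primary {primary.score}; "
                        f"raise its substitution rate so the {outs_ratio:.2f} ratio suppresses it"
                    )
                loci.append(par)
            status = _expected_status(group, spec, primary)
        else:
            primary = None
            status = "Missing"
        genes.append(
            PlantedGene(
                group_id=spec.group_id,
                protein_id=protein_id,
                peptide=query,
                spec=spec,
                loci=loci,
                expected_status=status,
                expected_frameshifts=len(spec.frameshifts) if not spec.absent else 0,
            )
        )
        for locus in loci:
            contig_loci.setdefault(locus.contig, []).append(locus)

    genome: dict[str, str] = {}
    flank_rng = random.Random(f"{seed}:intergenic")
    for contig in sorted(contig_loci):
        parts: list[str] = []
        pos = 0
        for locus in contig_loci[contig]:
            flank = _random_dna(flank_rng, intergenic_length, gc)
            parts.append(flank)
            pos += len(flank)
            insert = locus.gene_nt if locus.strand == "+" else revcomp(locus.gene_nt)
            locus.start = pos
            locus.end = pos + len(insert)
            parts.append(insert)
            pos += len(insert)
        parts.append(_random_dna(flank_rng, intergenic_length, gc))
        genome[contig] = "".join(parts).upper()
    contig_parts.clear()

    return Scenario(lineage=lineage, lineage_dir=lineage_dir or Path("."), genes=genes, genome=genome, seed=seed)


# ---------------------------------------------------------------------------
# rendered aligner / scorer output


def render_paf_fixture(
    scenario: Scenario,
    include_contigs: set[str] | None = None,
    outs_ratio: float = DEFAULT_OUTS_RATIO,
) -> str:
    """Emit the PAF an ideal aligner would produce for the planted truth.

    Only loci on ``include_contigs`` (default: all planted contigs) are
    considered, and per query protein any locus scoring below
    ``outs_ratio`` times that query's best surviving locus is suppressed —
    the aligner's secondary-output contract.
    """
    lines = []
    for gene in scenario.genes:
        loci = [
            l
            for l in gene.loci
            if (include_contigs is None or l.contig in include_contigs) and l.contig in scenario.genome
        ]
        if not loci:
            continue
        best = max(l.score for l in loci)
        for locus in loci:
            if locus.score < outs_ratio * best:
                continue
            tlen = len(scenario.genome[locus.contig])
            fields = [
                gene.protein_id,
                str(locus.qlen),
                str(locus.qstart),
                str(locus.qend),
                locus.strand,
                locus.contig,
                str(tlen),
                str(locus.start),
                str(locus.end),
                str(locus.identical),
                str(locus.end - locus.start),
                "60",
                f"AS:i:{locus.score}",
                f"cg:Z:{cigar_to_string(locus.cigar)}",
                f"cs:Z:{locus.cs}",
            ]
            lines.append("\t".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")


def render_hmm_fixture(scenario: Scenario, pass_identity: float = 0.6) -> str:
    """Emit a synthetic bit-score table for every planted locus.

    Scores follow a documented labelling rule, not a real HMM: a locus
    passes (cutoff + 10 bits) iff its planted identity is at least
    ``pass_identity``, else it scores 10 bits under the cutoff.  Length
    handling is deliberately left to the classifier.  Feed the result to the
    stub scoring backend for fully HMM-free pipeline runs.
    """
    lines = ["# alignment_key\tbits (synthetic fixture scores)"]
    for gene in scenario.genes:
        cutoff = scenario.lineage.groups[gene.group_id].score_cutoff
        for locus in gene.loci:
            key = f"{gene.protein_id}|{locus.contig}:{locus.start}-{locus.end}{locus.strand}"
            bits = cutoff + 10.0 if locus.identity >= pass_identity else max(0.0, cutoff - 10.0)
            lines.append(f"{key}\t{bits:.1f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# canonical demo scenario


def standard_scenario(
    lineage: LineageDataset | str | Path,
    n_single: int = 23,
    n_duplicated: int = 7,
    n_fragmented: int = 5,
    n_missing: int = 5,
    seed: int = 0,
) -> Scenario:
    """A mixed scenario over the first S+D+F+M groups of a lineage.

    Single genes cycle through clean, intron-bearing, frameshifted and
    substituted variants across both strands; duplicated genes get one extra
    full copy on a separate contig; fragmented genes are truncated to 30% of
    their expected length; missing genes are omitted.
    """
    if not isinstance(lineage, LineageDataset):
        lineage = load_lineage(lineage)
    gids = sorted(lineage.groups)
    need = n_single + n_duplicated + n_fragmented + n_missing
    if len(gids) < need:
        raise FixtureError(f"lineage has {len(gids)} groups but the scenario needs {need}")
    specs: list[GeneSpec] = []
    k = 0
    for i in range(n_single):
        gid = gids[k]
        k += 1
        length = len(lineage.groups[gid].proteins[0][1])
        spec = GeneSpec(
            group_id=gid,
            contig=f"chr{1 + i % 4}",
            strand="+" if i % 2 == 0 else "-",
        )
        if i % 3 == 0:
            spec.introns = [(length // 3, 120, i % 3), (2 * length // 3, 90, (i + 1) % 3)]
        if i % 4 == 1:
            spec.frameshifts = [(length // 2, "del1" if i % 8 == 1 else "ins1")]
        if i % 5 == 2:
            spec.substitution_rate = 0.05
        specs.append(spec)
    for i in range(n_duplicated):
        gid = gids[k]
        k += 1
        specs.append(
            GeneSpec(
                group_id=gid,
                contig=f"chr{1 + i % 4}",
                strand="+",
                extra_copies=[(f"chr{5 + i % 2}", "-" if i % 2 else "+")],
            )
        )
    for i in range(n_fragmented):
        gid = gids[k]
        k += 1
        specs.append(GeneSpec(group_id=gid, contig=f"chr{1 + i % 4}", truncation_fraction=0.3))
    for _ in range(n_missing):
        gid = gids[k]
        k += 1
        specs.append(GeneSpec(group_id=gid, absent=True))
    return plant_genome(lineage, specs, seed=seed)
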