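"""PAF parsing, CIGAR accounting, identity and translation reconstruction."""

from __future__ import annotations

import pytest

from orthoassess.alignment import (
    AlignerNotFoundError,
    AlignmentError,
    CigarOp,
    ProteinAlignment,
    cigar_query_span,
    cigar_target_span,
    compute_identity,
    count_frameshifts,
    identity_from_cs,
    identity_from_translation,
    parse_alignment_line,
    parse_cigar,
    parse_paf,
    reconstruct_translation,
    run_aligner,
)
from orthoassess.fixtures import GeneSpec, plant_genome, render_paf_fixture


def _paf_line(cigar="10M", qlen=10, qstart=0, qend=10, tstart=100, tend=130, extra=()):
    fields = [
        "123at0_0", str(qlen), str(qstart), str(qend), "+", "chr1", "5000",
        str(tstart), str(tend), "9", str(tend - tstart), "60", "AS:i:20", f"cg:Z:{cigar}",
    ]
    fields.extend(extra)
    return "\t".join(fields)


class TestCigar:
    def test_parse_simple(self):
        assert parse_cigar("10M2I3D") == [CigarOp("M", 10), CigarOp("I", 2), CigarOp("D", 3)]

    @pytest.mark.parametrize("bad", ["10X", "M10", "10M-3I", "", "10M5"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(AlignmentError):
            parse_cigar(bad)

    def test_unknown_letter_named(self):
        with pytest.raises(AlignmentError, match="'S'"):
            parse_cigar("10M5S")

    @pytest.mark.parametrize(
        "cigar,events",
        [("100M", 0), ("10M1F20M", 1), ("10M1F20M2G5M", 2), ("1F1F2G", 3), ("10M200N10M", 0)],
    )
    def test_frameshift_event_count(self, cigar, events):
        """F and G operations each count once, whatever their length."""
        assert count_frameshifts(parse_cigar(cigar)) == events

    def test_frameshift_count_invariant_under_intron_insertion(self):
        base = parse_cigar("10M1F20M2G5M")
        with_introns = parse_cigar("10M150N1F5M300N15M2G5M")
        assert count_frameshifts(base) == count_frameshifts(with_introns) == 2

    def test_span_accounting(self):
        cigar = parse_cigar("10M2I3D1F2G200N95U5M")
        # nt: 3*10 + 3*3 + 1 + 2 + 200 + 95 + 3*5 = 352
        assert cigar_target_span(cigar) == 352
        # aa: 10 + 2 + 1(G) + 1(U) + 5 = 19
        assert cigar_query_span(cigar) == 19


class TestParsePafLine:
    def test_basic_fields(self):
        aln = parse_alignment_line(_paf_line())
        assert aln.protein_id == "123at0_0"
        assert aln.group_id == "123at0"
        assert (aln.target_start, aln.target_end, aln.strand) == (100, 130, "+")
        assert aln.score == 20
        assert aln.frameshift_events == 0
        assert aln.coverage == 1.0

    def test_frameshift_cigar_line(self):
        line = _paf_line(cigar="5M1F4M2G", qlen=10, qend=10, tend=100 + 15 + 1 + 12 + 2)
        aln = parse_alignment_line(line)
        assert aln.frameshift_events == 2
        assert aln.aligned_aa == 9

    def test_missing_cigar_rejected(self):
        fields = _paf_line().split("\t")
        line = "\t".join(f for f in fields if not f.startswith("cg:"))
        with pytest.raises(AlignmentError, match="cg"):
            parse_alignment_line(line)

    def test_too_few_columns_rejected_with_line_number(self):
        with pytest.raises(AlignmentError, match="line 7"):
            parse_alignment_line("a\tb\tc", line_number=7)

    def test_span_mismatch_rejected(self):
        with pytest.raises(AlignmentError, match="consumes"):
            parse_alignment_line(_paf_line(cigar="9M"))  # 27 nt != 30

    def test_parse_paf_skips_comments(self):
        text = "##PAF comment\n" + _paf_line() + "\n\n"
        assert len(parse_paf(text)) == 1


class TestIdentity:
    def test_all_identical(self):
        assert identity_from_cs(":15") == 1.0

    def test_nine_identical_one_substitution(self):
        assert identity_from_cs(":4*gcaA:5") == 0.9

    def test_indels_and_introns_are_not_columns(self):
        assert identity_from_cs(":5-acgtac:3~gt200ag:2+KL") == 1.0

    def test_frameshifted_codon_counts_against_identity(self):
        # a G-op column appears with a 1-2 nt codon and can never be identical
        assert identity_from_cs(":9*caQ") == 0.9

    def test_malformed_cs_rejected(self):
        with pytest.raises(AlignmentError):
            identity_from_cs(":5&oops")

    def test_no_cs_and_no_sequences_is_an_error(self):
        aln = parse_alignment_line(_paf_line())
        with pytest.raises(AlignmentError):
            compute_identity(aln)


@pytest.fixture(scope="module")
def planted(toy_lineage):
    gids = sorted(toy_lineage.groups)
    specs = [
        GeneSpec(group_id=gids[0]),  # clean, intronless, + strand
        GeneSpec(group_id=gids[1], strand="-"),
        GeneSpec(group_id=gids[2], introns=[(20, 120, 0)]),
        GeneSpec(group_id=gids[3], introns=[(15, 90, 1), (40, 60, 2)]),
        GeneSpec(group_id=gids[4], frameshifts=[(30, "del1"), (50, "ins1")]),
        GeneSpec(group_id=gids[5], substitution_rate=0.2),
    ]
    return plant_genome(toy_lineage, specs, seed=5)


class TestReconstruction:
    def _alignments(self, planted):
        return parse_paf(render_paf_fixture(planted))

    def test_intronless_gene_reconstructs_exact_peptide(self, planted):
        aln = self._alignments(planted)[0]
        gene = planted.genes[0]
        assert reconstruct_translation(aln, planted.genome) == gene.peptide

    def test_minus_strand_reconstructs_exact_peptide(self, planted):
        aln = next(a for a in self._alignments(planted) if a.strand == "-")
        gene = next(g for g in planted.genes if g.spec.strand == "-")
        assert reconstruct_translation(aln, planted.genome) == gene.peptide

    def test_intron_excised(self, planted):
        aln = next(a for a in self._alignments(planted) if any(c.op == "N" for c in a.cigar))
        gene = planted.genes[2]
        assert reconstruct_translation(aln, planted.genome) == gene.peptide

    def test_split_codons_rejoined_across_uv_introns(self, planted):
        aln = next(a for a in self._alignments(planted) if any(c.op in "UV" for c in a.cigar))
        gene = planted.genes[3]
        assert reconstruct_translation(aln, planted.genome) == gene.peptide

    def test_frameshifted_codons_translate_to_x(self, planted):
        aln = next(a for a in self._alignments(planted) if any(c.op == "G" for c in a.cigar))
        gene = planted.genes[4]
        trans = reconstruct_translation(aln, planted.genome)
        assert trans.count("X") == 1  # one del1 event; the ins1 F op emits nothing
        assert len(trans) == len(gene.peptide)
        # all non-frameshifted positions round-trip
        assert sum(a != b for a, b in zip(trans, gene.peptide)) == 1

    def test_identity_routes_agree(self, planted):
        """cs-tag identity equals the column-by-column reconstruction identity."""
        for aln in self._alignments(planted):
            gene = next(g for g in planted.genes if g.protein_id == aln.protein_id)
            reconstruct_translation(aln, planted.genome)
            assert identity_from_cs(aln.cs) == pytest.approx(
                identity_from_translation(aln, gene.peptide), abs=1e-12
            )

    def test_planted_substitution_rate_recovered(self, planted):
        gene = planted.genes[5]
        aln = next(a for a in self._alignments(planted) if a.protein_id == gene.protein_id)
        reconstruct_translation(aln, planted.genome)
        identity = compute_identity(aln, gene.peptide)
        assert identity == gene.loci[0].identity  # generator's own bookkeeping
        assert identity == pytest.approx(0.8, abs=0.1)

    def test_absent_contig_is_an_error(self, planted):
        aln = self._alignments(planted)[0]
        with pytest.raises(AlignmentError, match="contig"):
            reconstruct_translation(aln, {"other": "ACGT" * 100})


class TestRunAligner:
    def test_unreadable_genome_fails_before_subprocess(self, tmp_path):
        proteins = tmp_path / "p.faa"
        proteins.write_text(">p\nMKL\n")
        with pytest.raises(FileNotFoundError):
            run_aligner(tmp_path / "nope.fa", proteins, aligner_path="definitely_not_a_real_aligner")

    def test_missing_binary_names_the_alternative(self, tmp_path):
        genome = tmp_path / "g.fa"
        genome.write_text(">c\nACGT\n")
        proteins = tmp_path / "p.faa"
        proteins.write_text(">p\nMKL\n")
        with pytest.raises(AlignerNotFoundError, match="binary-free|pre-computed"):
            run_aligner(genome, proteins, aligner_path="definitely_not_a_real_aligner")
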