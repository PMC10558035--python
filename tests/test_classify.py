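"""Status classification, locus deduplication, summaries and the pipeline."""

from __future__ import annotations

import io

import pytest

from orthoassess.alignment import parse_cigar
from orthoassess.classify import (
    AssessmentReport,
    GeneAssessment,
    Status,
    assess,
    classify_group,
    dedup_loci,
    divergence_check,
    frameshift_summary,
    length_threshold,
    summarize,
)
from orthoassess.fixtures import GeneSpec, plant_genome, render_paf_fixture
from orthoassess.lineage import LineageDataset, OrthoGroup
from orthoassess.alignment import ProteinAlignment


def _group(mean=410.0, sigma=35.0, cutoff=50.0) -> OrthoGroup:
    return OrthoGroup(
        group_id="g1",
        proteins=(("g1_0", "M" * 10),),
        score_cutoff=cutoff,
        length_mean=mean,
        length_sigma=sigma,
    )


def _aln(aa=400, contig="chr1", start=0, strand="+", score=800, pid="g1_0", identity=1.0):
    return ProteinAlignment(
        protein_id=pid,
        group_id="g1",
        target=contig,
        target_start=start,
        target_end=start + 3 * aa,
        strand=strand,
        query_start=0,
        query_end=aa,
        query_length=aa,
        score=score,
        cigar=parse_cigar(f"{aa}M"),
        identity=identity,
    )


class TestLengthThreshold:
    @pytest.mark.parametrize("mean,sigma,expected", [(410, 35, 340), (100, 0, 100), (10, 50, 0)])
    def test_mean_minus_two_sigma_floored_at_zero(self, mean, sigma, expected):
        assert length_threshold(_group(mean=mean, sigma=sigma)) == expected


class TestClassifyGroup:
    def test_no_survivors_is_missing(self):
        a = classify_group(_group(), [])
        assert a.status is Status.MISSING and a.alignments == []

    def test_one_full_length_survivor_is_single(self):
        a = classify_group(_group(), [_aln(400)])
        assert a.status is Status.SINGLE

    def test_two_loci_on_different_contigs_is_duplicated(self):
        a = classify_group(_group(), [_aln(400, "chr1"), _aln(400, "chr2")])
        assert a.status is Status.DUPLICATED

    def test_all_below_threshold_is_fragmented(self):
        a = classify_group(_group(), [_aln(100, start=0), _aln(120, start=5000), _aln(90, "chr2")])
        assert a.status is Status.FRAGMENTED

    def test_one_full_plus_fragments_is_complete_not_fragmented(self):
        """One passing alignment makes the gene complete even when shorter
        fragments survive alongside it."""
        a = classify_group(_group(), [_aln(400, start=0), _aln(100, start=5000)])
        assert a.status is Status.DUPLICATED  # two loci survive, one full length

    def test_overlapping_records_collapse_to_one_locus(self):
        first = _aln(400, start=0, score=800)
        echo = _aln(395, start=30, score=790)  # >50% overlap on the same strand
        a = classify_group(_group(), [first, echo])
        assert a.status is Status.SINGLE
        assert len(a.alignments) == 1 and a.alignments[0].score == 800

    def test_opposite_strands_are_distinct_loci(self):
        a = classify_group(_group(), [_aln(400, start=0, strand="+"), _aln(400, start=30, strand="-")])
        assert a.status is Status.DUPLICATED

    def test_dedup_keeps_higher_scoring_record(self):
        worse = _aln(400, start=0, score=700)
        better = _aln(400, start=10, score=900)
        kept = dedup_loci([worse, better])
        assert [a.score for a in kept] == [900]


class TestSummaries:
    def _assessments(self):
        return [
            GeneAssessment("g1", Status.SINGLE, [_aln(400)], "g1_0", frameshift_events=2, best_identity=0.9),
            GeneAssessment("g2", Status.DUPLICATED, [_aln(400)], "g2_0", frameshift_events=0, best_identity=0.8),
            GeneAssessment("g3", Status.FRAGMENTED, [_aln(100)], "g3_0", frameshift_events=0, best_identity=0.7),
            GeneAssessment("g4", Status.MISSING),
        ]

    def test_partition_counts_sum_to_n(self):
        report = summarize(self._assessments())
        assert sum(report.counts.values()) == report.n == 4
        assert report.complete_pct == pytest.approx(50.0)

    def test_mean_identity_over_non_missing(self):
        report = summarize(self._assessments())
        assert report.mean_identity == pytest.approx((0.9 + 0.8 + 0.7) / 3)

    def test_frameshift_fraction_counts_genes_not_events(self):
        assert frameshift_summary(self._assessments()) == pytest.approx(1 / 3)

    def test_all_missing_fraction_is_zero(self):
        assert frameshift_summary([GeneAssessment("g", Status.MISSING)]) == 0.0


def _report(mean_identity, n=10):
    counts = {Status.SINGLE: n, Status.DUPLICATED: 0, Status.FRAGMENTED: 0, Status.MISSING: 0}
    if mean_identity is None:
        counts = {Status.SINGLE: 0, Status.DUPLICATED: 0, Status.FRAGMENTED: 0, Status.MISSING: n}
    return AssessmentReport(
        n=n,
        counts=counts,
        mean_identity=mean_identity,
        frameshift_gene_fraction=0.0,
        divergence_warning=mean_identity is not None and mean_identity < 0.5,
    )


class TestDivergenceCheck:
    def test_below_half_warns_and_recommends_busco(self):
        stream = io.StringIO()
        assert divergence_check(_report(0.49), stream=stream) is True
        assert "BUSCO" in stream.getvalue()

    def test_exactly_half_does_not_warn(self):
        stream = io.StringIO()
        assert divergence_check(_report(0.50), stream=stream) is False
        assert stream.getvalue() == ""

    def test_all_missing_no_warning_but_noted(self):
        stream = io.StringIO()
        report = _report(None)
        assert divergence_check(report, stream=stream) is False
        assert stream.getvalue() == ""
        assert any("identity undefined" in note for note in summarize(
            [GeneAssessment("g", Status.MISSING)]).notes)


class TestAssessPipeline:
    def test_truth_recovery_on_rendered_fixture(self, toy_lineage, scenario, scenario_paf, hmm_backend):
        report, assessments = assess(scenario.genome, toy_lineage, paf=scenario_paf, backend=hmm_backend)
        truth = scenario.truth()
        assert {a.group_id: a.status.value for a in assessments} == truth
        assert sum(report.counts.values()) == report.n == toy_lineage.n_groups

    def test_empty_genome_everything_missing(self, toy_lineage, hmm_backend):
        report, assessments = assess({}, toy_lineage, paf="", backend=hmm_backend)
        assert report.counts[Status.MISSING] == report.n == toy_lineage.n_groups

    def test_concatenated_clean_genes_all_single_identity_one(self, toy_lineage, hmm_backend):
        """A genome that is exactly the reverse-translated, intronless member
        proteins laid end to end recovers every group as Single with perfect
        identity."""
        specs = [GeneSpec(group_id=gid, contig="chr1") for gid in sorted(toy_lineage.groups)]
        scn = plant_genome(toy_lineage, specs, seed=2)
        report, assessments = assess(scn.genome, toy_lineage, paf=render_paf_fixture(scn), backend=hmm_backend)
        assert report.counts[Status.SINGLE] == report.n
        assert all(a.best_identity == 1.0 for a in assessments)
        assert report.mean_identity == 1.0

    def test_zero_group_lineage_rejected(self, hmm_backend):
        empty = LineageDataset(name="none", groups={})
        with pytest.raises(ValueError, match="no ortholog groups"):
            assess({}, empty, paf="", backend=hmm_backend)

    def test_planted_paralog_below_cutoff_never_contributes(self, toy_lineage, hmm_backend):
        """A diverged paralog locus whose translation cannot reach the group
        bit-score cutoff is filtered out even when the aligner reports it."""
        gid = sorted(toy_lineage.groups)[0]
        # heavily diverged second copy: survives outs only if primary absent
        specs = [GeneSpec(group_id=gid, contig="chrP", paralogs=[("chrQ", "+", 0.8)])]
        scn = plant_genome(toy_lineage, specs, seed=3)
        paf_without_primary = render_paf_fixture(scn, include_contigs={"chrQ"})
        report, assessments = assess(scn.genome, toy_lineage, paf=paf_without_primary, backend=hmm_backend)
        assert assessments[[a.group_id for a in assessments].index(gid)].status is Status.MISSING
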