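"""Orthology confirmation by profile-HMM bit score.

Paralogous loci can attract a group's member proteins at reduced identity
and inflate completeness.  Each candidate alignment's reconstructed
translation is therefore scored against the group's profile HMM and kept
only when its full-sequence bit score reaches the lineage-defined cutoff
(``≥``, matching the conventional use of BUSCO cutoff files; the boundary is
pinned by a test).  Bit scores — not E-values — are used because the cutoff
files are bit-score valued and bit scores do not depend on database size.

Three interchangeable scoring backends exist:

* :class:`PyhmmerBackend` — in-process HMMER via pyhmmer (default);
* :class:`HmmsearchBackend` — the external ``hmmsearch`` binary;
* :class:`TableBackend` — pre-computed scores (``hmmsearch --tblout`` output
  or a fixture score table), enabling fully offline runs.
"""

from __future__ import annotations

import logging
import math
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

from .alignment import ProteinAlignment
from .lineage import LineageDataset, OrthoGroup

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


@dataclass(frozen=True)
class HmmHit:
    """Bit score of one candidate translated locus against its group's HMM."""

    group_id: str
    protein_id: str
    alignment_ref: str  # ProteinAlignment.key of the locus scored
    bit_score: float
    passed: bool


class ScoringBackend(Protocol):
    def score(self, group: OrthoGroup, name: str, translation: str) -> float:
        """Full-sequence bit score of ``translation`` against the group HMM."""
        ...


class PyhmmerBackend:
    """In-process HMMER scoring via pyhmmer.

    The acceleration filters are disabled so that short but genuine
    fragments are still scored rather than dropped by heuristics; bit
    scores are deterministic for fixed inputs and backend version.
    """

    def __init__(self) -> None:
        import pyhmmer

        self._pyhmmer = pyhmmer
        self._alphabet = pyhmmer.easel.Alphabet.amino()
        self._background = pyhmmer.plan7.Background(self._alphabet)
        self._hmm_cache: dict[Path, object] = {}

    def _load_hmm(self, group: OrthoGroup):
        if group.hmm_path is None:
            raise FileNotFoundError(f"group {group.group_id}: no profile HMM available")
        path = Path(group.hmm_path)
        if path not in self._hmm_cache:
            try:
                with self._pyhmmer.plan7.HMMFile(path) as fh:
                    self._hmm_cache[path] = fh.read()
            except Exception as exc:
                raise RuntimeError(f"group {group.group_id}: unreadable HMM {path}: {exc}") from exc
        return self._hmm_cache[path]

    def score(self, group: OrthoGroup, name: str, translation: str) -> float:
        if not translation:
            return NEG_INF
        hmm = self._load_hmm(group)
        pipeline = self._pyhmmer.plan7.Pipeline(
            self._alphabet,
            background=self._background,
            bias_filter=False,
            F1=1.0,
            F2=1.0,
            F3=1.0,
            E=1e6,
        )
        seq = self._pyhmmer.easel.TextSequence(name=name.encode(), sequence=translation)
        block = self._pyhmmer.easel.DigitalSequenceBlock(self._alphabet, [seq.digitize(self._alphabet)])
        hits = pipeline.search_hmm(hmm, block)
        if not hits:
            return NEG_INF
        return float(hits[0].score)


class HmmsearchBackend:
    """Score by invoking the external ``hmmsearch`` binary per group."""

    def __init__(self, hmmsearch_path: str = "hmmsearch") -> None:
        self.hmmsearch_path = hmmsearch_path

    def score(self, group: OrthoGroup, name: str, translation: str) -> float:
        if not translation:
            return NEG_INF
        if group.hmm_path is None:
            raise FileNotFoundError(f"group {group.group_id}: no profile HMM available")
        with tempfile.TemporaryDirectory() as tmp:
            faa = Path(tmp) / "query.faa"
            faa.write_text(f">{name}\n{translation}\n")
            tbl = Path(tmp) / "scores.tbl"
            cmd = [
                self.hmmsearch_path,
                "--tblout", str(tbl),
                "--max",  # no heuristic filters, mirrors the in-process backend
                "-E", "1e6",
                str(group.hmm_path),
                str(faa),
            ]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(f"hmmsearch failed (exit {proc.returncode}): {proc.stderr.strip()[:2000]}")
            scores = parse_tblout(tbl)
        return scores.get(name, NEG_INF)


class TableBackend:
    """Pre-computed scores keyed by query sequence name (binary-free)."""

    def __init__(self, scores: dict[str, float]) -> None:
        self.scores = dict(scores)

    @classmethod
    def from_tblout(cls, path: str | Path) -> "TableBackend":
        return cls(parse_tblout(path))

    @classmethod
    def from_table(cls, path: str | Path) -> "TableBackend":
        """Load a two-column ``name<TAB>bits`` score table."""
        scores = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, bits = line.split("\t")[:2]
            scores[name] = float(bits)
        return cls(scores)

    def score(self, group: OrthoGroup, name: str, translation: str) -> float:
        if not translation:
            return NEG_INF
        return self.scores.get(name, NEG_INF)


#: spec'd stub backend: fixture-specified scores
StubBackend = TableBackend


def parse_tblout(path: str | Path) -> dict[str, float]:
    """Extract full-sequence bit scores from ``hmmsearch --tblout`` output."""
    scores: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            continue
        name, bits = fields[0], float(fields[5])
        scores[name] = max(scores.get(name, NEG_INF), bits)
    return scores


def make_backend(kind: str, hmmsearch_path: str = "hmmsearch", score_table: str | Path | None = None) -> ScoringBackend:
    if kind == "inprocess":
        return PyhmmerBackend()
    if kind == "external":
        return HmmsearchBackend(hmmsearch_path)
    if kind == "stub":
        if score_table is None:
            raise ValueError("stub backend requires a score table")
        return TableBackend.from_table(score_table)
    raise ValueError(f"unknown HMM backend {kind!r} (choose inprocess, external or stub)")


# ---------------------------------------------------------------------------


def score_translation(translation: str, group: OrthoGroup, backend: ScoringBackend, name: str = "query") -> float:
    """Bit score of one translated locus; empty translations score −∞."""
    if not translation:
        return NEG_INF
    return backend.score(group, name, translation)


def score_alignments(
    alignments: list[ProteinAlignment],
    lineage: LineageDataset,
    backend: ScoringBackend,
) -> list[HmmHit]:
    """Score every aligned locus independently against its group's HMM.

    Each locus yields its own translation and its own hit, so duplication
    decisions downstream rest only on loci that individually pass the HMM.
    """
    hits = []
    for aln in alignments:
        group = lineage.groups[aln.group_id]
        if aln.translation is None:
            raise ValueError(f"{aln.key}: translation not reconstructed before scoring")
        bits = score_translation(aln.translation, group, backend, name=aln.key)
        hits.append(
            HmmHit(
                group_id=aln.group_id,
                protein_id=aln.protein_id,
                alignment_ref=aln.key,
                bit_score=bits,
                passed=not math.isinf(bits) and bits >= group.score_cutoff,
            )
        )
    return hits


def apply_cutoff(hits: list[HmmHit], lineage: LineageDataset) -> list[HmmHit]:
    """Retain hits with bit score ≥ the group's cutoff; log per-group discards."""
    retained = []
    discarded: dict[str, int] = {}
    for hit in hits:
        cutoff = lineage.groups[hit.group_id].score_cutoff
        if hit.bit_score >= cutoff:
            retained.append(hit)
        else:
            discarded[hit.group_id] = discarded.get(hit.group_id, 0) + 1
    for gid, n in sorted(discarded.items()):
        logger.debug("group %s: %d sub-cutoff hit(s) discarded", gid, n)
    return retained


def select_representative(hits: list[HmmHit]) -> tuple[str, list[HmmHit]] | None:
    """Choose the member protein with the highest bit score to represent the group.

    Returns that protein's id and *all* of its retained hits (one per locus);
    exact score ties break to the lexicographically smallest protein id.
    Returns None for an empty hit set (the group will be Missing).
    """
    if not hits:
        return None
    best: dict[str, float] = {}
    for h in hits:
        best[h.protein_id] = max(best.get(h.protein_id, NEG_INF), h.bit_score)
    rep = min(best, key=lambda pid: (-best[pid], pid))
    tied = [pid for pid, s in best.items() if s == best[rep]]
    if len(tied) > 1:
        logger.debug("group %s: bit-score tie among %s; chose %s", hits[0].group_id, sorted(tied), rep)
    return rep, [h for h in hits if h.protein_id == rep]
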