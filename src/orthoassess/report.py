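"""Stable serialization of per-gene and summary results.

Output layout (one directory per run):

* ``summary.txt`` — the one-line ``C:x%[S:x%,D:x%],F:x%,M:x%,n:N`` summary
  plus a human-readable block;
* ``full_table.tsv`` — one row per reported alignment, plus one row per
  missing group (versioned, fixed header);
* ``report.json`` — machine-readable counts, percentages and summaries;
* ``run.log`` — tool/backend versions and invocation details.

Coordinates are stored internally as 0-based half-open and converted to
1-based inclusive only in the displayed table (genome-browser convention);
percentages are rounded to one decimal, half away from zero, only at
presentation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .classify import AssessmentReport, GeneAssessment, Status

FULL_TABLE_VERSION = "1"
FULL_TABLE_COLUMNS = [
    "group_id",
    "status",
    "contig",
    "start",  # 1-based inclusive (display convention)
    "end",
    "strand",
    "score",
    "bit_score",
    "aligned_length",
    "identity",
    "coverage",
    "frameshift_events",
    "representative_protein",
]

_SUMMARY_RE = re.compile(
    r"C:(?P<C>[\d.]+)%\[S:(?P<S>[\d.]+)%,D:(?P<D>[\d.]+)%\],F:(?P<F>[\d.]+)%,M:(?P<M>[\d.]+)%,n:(?P<n>\d+)"
)


def round_pct(value: float, places: int = 1) -> float:
    """Round half away from zero (so 0.05 % displays as 0.1 %)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summary_line(report: AssessmentReport) -> str:
    s = round_pct(report.percentage(Status.SINGLE))
    d = round_pct(report.percentage(Status.DUPLICATED))
    f = round_pct(report.percentage(Status.FRAGMENTED))
    m = round_pct(report.percentage(Status.MISSING))
    c = round_pct(report.complete_pct)
    return f"C:{c:.1f}%[S:{s:.1f}%,D:{d:.1f}%],F:{f:.1f}%,M:{m:.1f}%,n:{report.n}"


def parse_summary_line(line: str) -> dict[str, float]:
    """Parse a summary line back into its percentages and n (round-trip aid)."""
    m = _SUMMARY_RE.search(line)
    if m is None:
        raise ValueError(f"not a summary line: {line!r}")
    out = {k: float(v) for k, v in m.groupdict().items()}
    out["n"] = int(out["n"])
    return out


def write_summary(report: AssessmentReport) -> str:
    """Render the summary block; the first non-comment line is the parseable one."""
    lines = [summary_line(report)]
    lines.append("")
    lines.append(f"{report.counts[Status.SINGLE]}\tComplete and single-copy (S)")
    lines.append(f"{report.counts[Status.DUPLICATED]}\tComplete and duplicated (D)")
    lines.append(f"{report.counts[Status.FRAGMENTED]}\tFragmented (F)")
    lines.append(f"{report.counts[Status.MISSING]}\tMissing (M)")
    lines.append(f"{report.n}\tTotal ortholog groups searched (n)")
    if report.mean_identity is not None:
        lines.append(f"Mean alignment identity: {report.mean_identity:.4f}")
    lines.append(f"Genes with frameshifts: {report.frameshift_gene_fraction:.4f}")
    if report.divergence_warning:
        lines.append("Divergence warning: mean identity < 50%; consider also running BUSCO.")
    for note in report.notes:
        lines.append(f"Note: {note}")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class FullTableRow:
    group_id: str
    status: str
    contig: str = ""
    start: str = ""  # display strings; empty for Missing
    end: str = ""
    strand: str = ""
    score: str = ""
    bit_score: str = ""
    aligned_length: str = ""
    identity: str = ""
    coverage: str = ""
    frameshift_events: str = ""
    representative_protein: str = ""


def build_rows(assessments: list[GeneAssessment]) -> list[FullTableRow]:
    """One row per reported alignment; Missing groups get one positional-empty row."""
    rows: list[FullTableRow] = []
    for a in assessments:
        if a.status is Status.MISSING:
            rows.append(FullTableRow(group_id=a.group_id, status=a.status.value))
            continue
        for aln in a.alignments:
            rows.append(
                FullTableRow(
                    group_id=a.group_id,
                    status=a.status.value,
                    contig=aln.target,
                    start=str(aln.target_start + 1),  # 0-based half-open -> 1-based inclusive
                    end=str(aln.target_end),
                    strand=aln.strand,
                    score=str(aln.score),
                    bit_score=(f"{a.bit_scores[aln.key]:.1f}" if aln.key in a.bit_scores else ""),
                    aligned_length=str(aln.aligned_aa),
                    identity=f"{aln.identity:.4f}" if aln.identity is not None else "",
                    coverage=f"{aln.coverage:.4f}",
                    frameshift_events=str(aln.frameshift_events),
                    representative_protein=a.representative_protein or "",
                )
            )
    return rows


def write_full_table(rows: list[FullTableRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# full_table version {FULL_TABLE_VERSION}; coordinates 1-based inclusive\n")
        fh.write("\t".join(FULL_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(getattr(row, col) for col in FULL_TABLE_COLUMNS) + "\n")


def read_full_table(path: str | Path) -> pd.DataFrame:
    """Read a full table back; the provided round-trip reader for the TSV."""
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def report_to_dict(report: AssessmentReport) -> dict:
    return {
        "n": report.n,
        "counts": {s.value: report.counts[s] for s in Status},
        "percentages": {s.value: round_pct(report.percentage(s)) for s in Status},
        "complete_pct": round_pct(report.complete_pct),
        "mean_identity": report.mean_identity,
        "frameshift_gene_fraction": report.frameshift_gene_fraction,
        "divergence_warning": report.divergence_warning,
        "summary_line": summary_line(report),
        "notes": list(report.notes),
    }


def write_json(report: AssessmentReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2) + "\n")


def write_run_outputs(
    out_dir: str | Path,
    report: AssessmentReport,
    assessments: list[GeneAssessment],
    log_lines: list[str] | None = None,
) -> Path:
    """Write summary.txt, full_table.tsv, report.json and run.log into one directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "summary.txt").write_text(write_summary(report))
    write_full_table(build_rows(assessments), out_dir / "full_table.tsv")
    write_json(report, out_dir / "report.json")
    (out_dir / "run.log").write_text("\n".join(log_lines or []) + "\n")
    return out_dir
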