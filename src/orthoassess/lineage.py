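"""BUSCO odb10-style lineage datasets: download, unpack, parse.

A lineage dataset is a directory bundling, for every near-universal
single-copy ortholog group of a clade:

* member protein sequences (multi-protein FASTA, headers keyed by group id),
* a profile HMM (``hmms/<group_id>.hmm``),
* a bit-score cutoff separating orthologs from paralogs (``scores_cutoff``),
* expected protein length statistics (``lengths_cutoff``),
* dataset metadata (``dataset.cfg``).

This module turns such a directory into validated in-memory records and can
fetch official datasets from the BUSCO data server (or any mirror exposing
the same ``file_versions.tsv`` layout, including ``file://`` trees).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import tarfile
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

from ._util import iter_fasta

logger = logging.getLogger(__name__)

DEFAULT_BASE_URL = "https://busco-data.ezlab.org/v5/data"
DEFAULT_CACHE_DIR = Path.home() / ".cache" / "orthoassess" / "lineages"

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX*]+$")

#: protein FASTA filenames probed inside a lineage directory, in order
_FASTA_CANDIDATES = (
    "refseq_db.faa.gz",
    "refseq_db.faa",
    "ancestral_variants",
    "ancestral",
    "proteins.faa",
)


class LineageError(Exception):
    """Malformed or unusable lineage data."""


class UnknownLineageError(LineageError):
    def __init__(self, name: str, available: list[str]):
        self.name = name
        self.available = available
        preview = ", ".join(available[:15])
        more = "" if len(available) <= 15 else f", … ({len(available)} total)"
        super().__init__(f"unknown lineage {name!r}; available lineages include: {preview}{more}")


@dataclass(frozen=True)
class OrthoGroup:
    """One single-copy ortholog group of the lineage."""

    group_id: str
    proteins: tuple[tuple[str, str], ...]  # (protein_id, amino-acid sequence)
    score_cutoff: float  # bits; orthology confirmation threshold
    length_mean: float  # expected protein length, aa
    length_sigma: float  # spread of expected length, aa
    hmm_path: Path | None = None

    def __post_init__(self) -> None:
        if not self.proteins:
            raise LineageError(f"group {self.group_id}: no member proteins")
        for pid, seq in self.proteins:
            if not seq or not _AA_RE.match(seq.upper()):
                raise LineageError(f"group {self.group_id}: protein {pid} is not an amino-acid sequence")
        if self.score_cutoff < 0:
            raise LineageError(f"group {self.group_id}: negative score cutoff")
        if self.length_mean <= 0:
            raise LineageError(f"group {self.group_id}: non-positive length mean")
        if self.length_sigma < 0:
            raise LineageError(f"group {self.group_id}: negative length sigma")

    def protein_sequence(self, protein_id: str) -> str:
        for pid, seq in self.proteins:
            if pid == protein_id:
                return seq
        raise KeyError(protein_id)


@dataclass
class LineageDataset:
    name: str
    groups: dict[str, OrthoGroup]
    creation_date: str = ""
    issues: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _parse_two_column(path: str | Path, cast, what: str):
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                key, value = fields[0], cast(fields[1:])
            except (IndexError, ValueError) as exc:
                raise LineageError(f"{path}: line {lineno}: unparseable {what} entry: {line.rstrip()!r}") from exc
            if key in out:
                logger.warning("%s: duplicate entry for %s at line %d; last wins", path, key, lineno)
            out[key] = value
    if not out:
        logger.warning("%s: empty %s file", path, what)
    return out


def parse_scores_cutoff(path: str | Path) -> dict[str, float]:
    """Parse the per-group HMM bit-score cutoff table (``group<TAB>bits``)."""
    return _parse_two_column(path, lambda f: float(f[0]), "scores_cutoff")


def parse_lengths_cutoff(path: str | Path) -> dict[str, tuple[float, float]]:
    """Parse per-group length statistics.

    The BUSCO v5 file has four tab-separated columns
    ``group_id  0  sigma  mean_length``; columns two and three were verified
    against a real odb10 dataset before freezing this parser (a vendored
    excerpt is unit-tested).  Returns ``{group_id: (mean, sigma)}``.
    """
    return _parse_two_column(path, lambda f: (float(f[2]), float(f[1])), "lengths_cutoff")


def _find_protein_fasta(directory: Path) -> Path:
    for name in _FASTA_CANDIDATES:
        cand = directory / name
        if cand.exists():
            return cand
    faas = sorted(directory.glob("*.fa")) + sorted(directory.glob("*.faa"))
    if faas:
        return faas[0]
    raise LineageError(f"{directory}: no protein FASTA found (looked for {', '.join(_FASTA_CANDIDATES)})")


def parse_dataset_cfg(path: Path) -> dict[str, str]:
    cfg: dict[str, str] = {}
    if path.exists():
        for line in path.read_text().splitlines():
            if "=" in line:
                key, _, value = line.partition("=")
                cfg[key.strip()] = value.strip()
    return cfg


def group_id_from_header(header: str, sep: str = "_") -> str:
    """Group id = header token up to the first separator (header dialects vary)."""
    return header.split(sep, 1)[0] if sep and sep in header else header


def load_lineage(directory: str | Path, header_sep: str = "_") -> LineageDataset:
    """Load a lineage directory into one :class:`OrthoGroup` per group id.

    Groups missing a cutoff entry are loaded fail-open (cutoff 0 bits, length
    threshold degenerate) with a warning collected on the dataset's
    ``issues`` list rather than dropped.
    """
    directory = Path(directory)
    fasta = _find_protein_fasta(directory)
    scores_path = directory / "scores_cutoff"
    lengths_path = directory / "lengths_cutoff"
    scores = parse_scores_cutoff(scores_path) if scores_path.exists() else {}
    lengths = parse_lengths_cutoff(lengths_path) if lengths_path.exists() else {}
    cfg = parse_dataset_cfg(directory / "dataset.cfg")

    members: dict[str, list[tuple[str, str]]] = {}
    n_proteins = 0
    for header, seq in iter_fasta(fasta):
        gid = group_id_from_header(header, header_sep)
        members.setdefault(gid, []).append((header, seq.upper().rstrip("*")))
        n_proteins += 1
    if not members:
        raise LineageError(f"{fasta}: empty protein FASTA")

    issues: list[str] = []
    groups: dict[str, OrthoGroup] = {}
    hmm_dir = directory / "hmms"
    for gid in sorted(members):
        cutoff = scores.get(gid)
        if cutoff is None:
            issues.append(f"group {gid}: no scores_cutoff entry; defaulting to 0 bits (fail-open)")
            cutoff = 0.0
        mean_sigma = lengths.get(gid)
        if mean_sigma is None:
            issues.append(f"group {gid}: no lengths_cutoff entry; length threshold disabled")
            # mean must be positive; sigma large enough that mean - 2*sigma <= 0
            mean_sigma = (1.0, 1.0)
        hmm_path = hmm_dir / f"{gid}.hmm"
        groups[gid] = OrthoGroup(
            group_id=gid,
            proteins=tuple(members[gid]),
            score_cutoff=cutoff,
            length_mean=mean_sigma[0],
            length_sigma=mean_sigma[1],
            hmm_path=hmm_path if hmm_path.exists() else None,
        )
    for issue in issues:
        logger.warning("%s", issue)
    logger.info("loaded lineage %s: %d groups, %d proteins", directory.name, len(groups), n_proteins)
    return LineageDataset(
        name=cfg.get("name", directory.name),
        groups=groups,
        creation_date=cfg.get("creation_date", ""),
        issues=issues,
    )


# ---------------------------------------------------------------------------
# download


def _fetch_bytes(url: str) -> bytes:
    with urllib.request.urlopen(url) as resp:
        return resp.read()


def list_remote_lineages(base_url: str = DEFAULT_BASE_URL) -> dict[str, tuple[str, str]]:
    """Return ``{lineage_name: (date, md5)}`` from the server's file_versions.tsv."""
    text = _fetch_bytes(f"{base_url}/file_versions.tsv").decode()
    out: dict[str, tuple[str, str]] = {}
    for line in text.splitlines():
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            continue
        # official listing marks lineage rows in the last column; mirrors
        # without the marker column are accepted wholesale
        if len(fields) >= 5 and fields[-1] != "lineages":
            continue
        out[fields[0]] = (fields[1], fields[2])
    return out


def fetch_lineage(
    name: str,
    base_url: str = DEFAULT_BASE_URL,
    cache_dir: str | Path = DEFAULT_CACHE_DIR,
) -> Path:
    """Download and unpack a lineage dataset, or return the cached copy.

    A warm cache performs no network access.  The archive md5 from the remote
    listing is verified and recorded; a truncated download removes its cache
    entry and raises.
    """
    cache_dir = Path(cache_dir).expanduser()
    dest = cache_dir / name
    marker = dest / ".orthoassess.json"
    if marker.exists():
        logger.info("lineage %s: warm cache at %s", name, dest)
        return dest

    listing = list_remote_lineages(base_url)
    if name not in listing:
        raise UnknownLineageError(name, sorted(listing))
    date, md5_expect = listing[name]
    url = f"{base_url}/lineages/{name}.{date}.tar.gz"
    cache_dir.mkdir(parents=True, exist_ok=True)
    archive = cache_dir / f"{name}.{date}.tar.gz"
    logger.info("downloading %s", url)
    try:
        data = _fetch_bytes(url)
    except urllib.error.URLError as exc:
        raise LineageError(f"download of {url} failed: {exc}") from exc
    md5_got = hashlib.md5(data).hexdigest()
    if md5_expect and md5_got != md5_expect:
        raise LineageError(f"{url}: checksum mismatch (expected {md5_expect}, got {md5_got}); archive discarded")
    archive.write_bytes(data)
    try:
        with tarfile.open(archive) as tar:
            tar.extractall(cache_dir, filter="data")
    except (tarfile.TarError, EOFError) as exc:
        archive.unlink(missing_ok=True)
        raise LineageError(f"{archive}: truncated or corrupt archive: {exc}") from exc
    finally:
        archive.unlink(missing_ok=True)
    if not dest.is_dir():
        raise LineageError(f"{url}: archive did not contain a {name}/ directory")
    marker.write_text(json.dumps({"name": name, "date": date, "md5": md5_got, "url": url}) + "\n")
    return dest
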