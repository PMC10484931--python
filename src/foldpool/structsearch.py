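"""Structure-search hits: parsing, MSA augmentation and template curation.

A structure search (Foldseek-style) aligns a query *model* against a
structure database and reports gapped alignments with e-values.  Those
alignments can be converted into A3M rows and merged into the query's
MSA — structure search finds remote homologs and analogs that sequence
search misses, which is the engine behind the iterative refinement loop.

Also curates a non-redundant template database from per-chain metadata:
chains with resolution worse than 8 A, shorter than 30 residues, or more
than 90% sequence identity to an already-kept chain are removed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align

from .msa import Msa, filter_redundancy, merge_msas

logger = logging.getLogger(__name__)

__all__ = [
    "StructureHit",
    "TemplateRecord",
    "HitFormatError",
    "DEFAULT_HIT_COLUMNS",
    "parse_hits",
    "write_hits",
    "hit_to_msa_row",
    "augment_msa",
    "select_templates",
    "curate_templates",
    "read_templates",
    "write_templates",
    "template_identity",
]

# Default tab-separated column order of a structure-search hit table.
DEFAULT_HIT_COLUMNS = (
    "query_id", "hit_id", "evalue", "tm",
    "qstart", "qend", "tstart", "tend", "qaln", "taln",
)

RESOLUTION_CUTOFF = 8.0     # Angstrom; experimental chains worse than this are dropped
MIN_TEMPLATE_LENGTH = 30    # residues
TEMPLATE_IDENTITY_CUTOFF = 0.90


class HitFormatError(ValueError):
    """Raised for hit rows violating the alignment invariants."""


@dataclass(frozen=True)
class StructureHit:
    """One structure-search alignment between a query model and a database hit."""

    query_id: str
    hit_id: str
    evalue: float
    tm: Optional[float]
    qstart: int
    qend: int
    tstart: int
    tend: int
    qaln: str
    taln: str

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise HitFormatError("evalue must be non-negative")
        if self.tm is not None and not (0.0 < self.tm <= 1.0):
            raise HitFormatError("tm must lie in (0, 1]")
        if len(self.qaln) != len(self.taln):
            raise HitFormatError("qaln and taln must have equal length")
        if any(q == "-" and t == "-" for q, t in zip(self.qaln, self.taln)):
            raise HitFormatError("column gapped on both sides")
        q_res = sum(1 for c in self.qaln if c != "-")
        t_res = sum(1 for c in self.taln if c != "-")
        if q_res != self.qend - self.qstart + 1:
            raise HitFormatError(
                f"qaln residue count {q_res} != qend-qstart+1 "
                f"({self.qend - self.qstart + 1})"
            )
        if t_res != self.tend - self.tstart + 1:
            raise HitFormatError(
                f"taln residue count {t_res} != tend-tstart+1 "
                f"({self.tend - self.tstart + 1})"
            )


@dataclass(frozen=True)
class TemplateRecord:
    """Per-chain template metadata (id, sequence, resolution, length, source)."""

    template_id: str
    sequence: str
    resolution: Optional[float]  # None encodes "NA" (predicted structures)
    length: int
    source: str = "experimental"

    def __post_init__(self) -> None:
        if self.sequence and self.length != len(self.sequence):
            raise ValueError("length must equal len(sequence) when sequence present")
        if self.source not in ("experimental", "predicted"):
            raise ValueError(f"unknown template source {self.source!r}")


def parse_hits(
    path: str | Path,
    dialect: Optional[Mapping[str, int]] = None,
) -> list[StructureHit]:
    """Parse a tab-separated hit table into validated :class:`StructureHit` s.

    ``dialect`` maps field name to 0-based column index; the default is the
    common structure-search column order (:data:`DEFAULT_HIT_COLUMNS`).
    Rows that fail the alignment invariants are rejected with a logged
    per-row error and do not abort the parse.
    """
    if dialect is None:
        dialect = {name: i for i, name in enumerate(DEFAULT_HIT_COLUMNS)}
    unknown = set(dialect) - set(DEFAULT_HIT_COLUMNS)
    if unknown:
        raise KeyError(f"unknown dialect keys: {sorted(unknown)}")
    missing = set(DEFAULT_HIT_COLUMNS) - set(dialect)
    if missing:
        raise KeyError(f"dialect missing fields: {sorted(missing)}")

    hits: list[StructureHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            try:
                tm_cell = cells[dialect["tm"]]
                hit = StructureHit(
                    query_id=cells[dialect["query_id"]],
                    hit_id=cells[dialect["hit_id"]],
                    evalue=float(cells[dialect["evalue"]]),
                    tm=None if tm_cell in ("", "NA") else float(tm_cell),
                    qstart=int(cells[dialect["qstart"]]),
                    qend=int(cells[dialect["qend"]]),
                    tstart=int(cells[dialect["tstart"]]),
                    tend=int(cells[dialect["tend"]]),
                    qaln=cells[dialect["qaln"]],
                    taln=cells[dialect["taln"]],
                )
            except (IndexError, ValueError, HitFormatError) as exc:
                logger.warning("%s line %d rejected: %s", path, lineno, exc)
                continue
            hits.append(hit)
    return hits


def write_hits(hits: Iterable[StructureHit], path: str | Path) -> None:
    """Write hits in the default tab-separated column order."""
    with open(path, "w") as fh:
        for h in hits:
            tm = "NA" if h.tm is None else f"{h.tm:.4f}"
            fh.write(
                f"{h.query_id}\t{h.hit_id}\t{h.evalue:.3g}\t{tm}\t"
                f"{h.qstart}\t{h.qend}\t{h.tstart}\t{h.tend}\t{h.qaln}\t{h.taln}\n"
            )


def hit_to_msa_row(hit: StructureHit, query_length: int) -> tuple[str, str]:
    """Convert a structure alignment into an A3M row over the query columns.

    Query columns outside [qstart, qend] and columns where the hit is
    gapped become ``-``; hit residues opposite a query gap become
    lowercase insertions.
    """
    if hit.qend > query_length:
        raise ValueError(
            f"hit qend {hit.qend} exceeds query length {query_length}"
        )
    parts = ["-" * (hit.qstart - 1)]
    for q, t in zip(hit.qaln, hit.taln):
        if q != "-":
            parts.append("-" if t == "-" else t.upper())
        else:
            parts.append(t.lower())
    parts.append("-" * (query_length - hit.qend))
    return hit.hit_id, "".join(parts)


def _hit_sort_key(h: StructureHit):
    # ascending e-value, then descending TM-score, then id
    return (h.evalue, -(h.tm if h.tm is not None else 0.0), h.hit_id)


def augment_msa(
    msa: Msa,
    hits: Sequence[StructureHit],
    max_hits: int = 50,
    id_threshold: float = 0.90,
) -> Msa:
    """Deepen an MSA with rows derived from structure-search hits.

    Hits are converted in ascending e-value order (capped at ``max_hits``),
    merged after the existing rows, and the result is redundancy-filtered
    at ``id_threshold`` (query always kept).
    """
    usable = [h for h in hits if any(c != "-" for c in h.qaln)]
    usable.sort(key=_hit_sort_key)
    rows = []
    for h in usable[:max_hits]:
        rid, row = hit_to_msa_row(h, msa.n_columns)
        if all(c == "-" for c in row):
            continue
        rows.append((rid, row))
    merged = merge_msas(msa, rows)
    return filter_redundancy(merged, threshold=id_threshold)


def select_templates(hits: Sequence[StructureHit], k: int = 4) -> list[StructureHit]:
    """Top ``k`` hits by ascending e-value (ties: higher TM-score, then id)."""
    return sorted(hits, key=_hit_sort_key)[:k]


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -0.5
_aligner.extend_gap_score = -0.1
try:  # Biopython >= 1.88 naming
    _aligner.end_insertion_score = 0.0
    _aligner.end_deletion_score = 0.0
except AttributeError:
    _aligner.target_end_gap_score = 0.0
    _aligner.query_end_gap_score = 0.0


def template_identity(seq_a: str, seq_b: str) -> float:
    """Global sequence identity with free end gaps, over the shorter length."""
    if not seq_a or not seq_b:
        return 0.0
    aln = _aligner.align(seq_a, seq_b)[0]
    identities = aln.counts().identities
    return identities / min(len(seq_a), len(seq_b))


def curate_templates(records: Sequence[TemplateRecord]) -> list[TemplateRecord]:
    """Apply the template-database construction filters.

    Removes chains with resolution > 8 A (``NA`` resolution passes — the
    filter targets experimental quality), chains shorter than 30 residues,
    and then greedily (input order) any chain with more than 90% sequence
    identity to an already-kept chain.  All three boundaries are strict.
    """
    prefiltered = [
        r for r in records
        if (r.resolution is None or r.resolution <= RESOLUTION_CUTOFF)
        and r.length >= MIN_TEMPLATE_LENGTH
    ]
    kept: list[TemplateRecord] = []
    for rec in prefiltered:
        if any(
            template_identity(rec.sequence, k.sequence) > TEMPLATE_IDENTITY_CUTOFF
            for k in kept
        ):
            continue
        kept.append(rec)
    return kept


def read_templates(path: str | Path) -> list[TemplateRecord]:
    """Read template metadata TSV: template_id, resolution, length, sequence[, source]."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            tid, res, length, seq = cells[:4]
            source = cells[4] if len(cells) > 4 else "experimental"
            records.append(
                TemplateRecord(
                    template_id=tid,
                    sequence=seq,
                    resolution=None if res in ("NA", "") else float(res),
                    length=int(length),
                    source=source,
                )
            )
    return records


def write_templates(records: Iterable[TemplateRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            res = "NA" if r.resolution is None else f"{r.resolution:.2f}"
            fh.write(f"{r.template_id}\t{res}\t{r.length}\t{r.sequence}\t{r.source}\n")
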