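"""Query-anchored multiple sequence alignments in the A3M dialect.

In A3M, uppercase letters and ``-`` are match states aligned to the query
columns and lowercase letters are insertions relative to the query.  Plain
FASTA alignments (no lowercase) are a degenerate A3M and read by the same
parser.  Provides pairwise identity, HHfilter-style redundancy filtering,
depth/Neff statistics and alignment merging.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Msa",
    "MsaFormatError",
    "read_a3m",
    "write_a3m",
    "match_state_count",
    "pairwise_identity",
    "filter_redundancy",
    "depth",
    "neff",
    "merge_msas",
]


class MsaFormatError(ValueError):
    """Raised for malformed A3M/FASTA input or inconsistent row shapes."""


def match_state_count(row: str) -> int:
    """Number of match-state positions (uppercase or '-') in an aligned row."""
    return sum(1 for c in row if c == "-" or c.isupper())


def _match_string(row: str) -> str:
    """The row reduced to its match-state columns (insertions dropped)."""
    return "".join(c for c in row if c == "-" or c.isupper())


@dataclass(frozen=True)
class Msa:
    """An A3M alignment; row 0 is the query (no gaps, no insertions)."""

    query_id: str
    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        rows = tuple((str(i), str(s)) for i, s in self.rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise MsaFormatError("an Msa must contain at least the query row")
        qid, qseq = rows[0]
        if "-" in qseq or any(c.islower() for c in qseq):
            raise MsaFormatError("query row must contain no gaps or insertions")
        L = len(qseq)
        for rid, seq in rows:
            if match_state_count(seq) != L:
                raise MsaFormatError(
                    f"row {rid!r} has {match_state_count(seq)} match columns, "
                    f"expected {L}"
                )

    @property
    def query(self) -> str:
        return self.rows[0][1]

    @property
    def n_columns(self) -> int:
        return len(self.query)


def read_a3m(path: str | Path) -> Msa:
    """Parse an A3M (or degenerate FASTA) alignment file."""
    text = Path(path).read_text()
    entries: list[tuple[str, list[str]]] = []
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        if line.startswith(">"):
            entries.append((line[1:].split()[0] if line[1:].split() else "", []))
        else:
            if not entries:
                raise MsaFormatError(f"{path}: sequence data before first header")
            entries[-1][1].append(line.strip())
    if not entries:
        raise MsaFormatError(f"{path}: no alignment rows found")
    rows = tuple((rid, "".join(chunks)) for rid, chunks in entries)
    return Msa(query_id=rows[0][0], rows=rows)


def write_a3m(msa: Msa, path: str | Path) -> None:
    """Write an Msa in A3M; one unwrapped sequence line per row."""
    with open(path, "w") as fh:
        for rid, seq in msa.rows:
            fh.write(f">{rid}\n{seq}\n")


def pairwise_identity(a: str, b: str) -> float:
    """Sequence identity between two aligned rows.

    Counted over match columns where both rows carry the same uppercase
    letter, normalised by the smaller of the two rows' residue (uppercase)
    counts; 0 if either row is all-gap.  Insertions are ignored.
    """
    am = _match_string(a)
    bm = _match_string(b)
    if len(am) != len(bm):
        raise MsaFormatError(
            f"rows have different match-column counts: {len(am)} vs {len(bm)}"
        )
    na = sum(1 for c in am if c != "-")
    nb = sum(1 for c in bm if c != "-")
    denom = min(na, nb)
    if denom == 0:
        return 0.0
    matches = sum(1 for x, y in zip(am, bm) if x == y and x != "-")
    return matches / denom


def filter_redundancy(msa: Msa, threshold: float = 0.90) -> Msa:
    """Drop rows more than ``threshold`` identical to an already-kept row.

    Greedy scan in row order; the query is always kept; removal uses
    strict inequality, so a row at exactly the threshold survives.
    """
    kept: list[tuple[str, str]] = [msa.rows[0]]
    for rid, seq in msa.rows[1:]:
        if any(pairwise_identity(seq, kseq) > threshold for _, kseq in kept):
            continue
        kept.append((rid, seq))
    return Msa(query_id=msa.query_id, rows=tuple(kept))


def depth(msa: Msa) -> int:
    """Number of rows, query included."""
    return len(msa.rows)


def neff(msa: Msa, cluster_threshold: float = 0.80) -> float:
    """Number of effective sequences.

    ``Neff = sum_i 1/n_i`` where ``n_i`` counts the rows (self included)
    with pairwise identity >= ``cluster_threshold`` to row i.  A
    single-sequence alignment therefore has Neff = 1.
    """
    seqs = [s for _, s in msa.rows]
    n = len(seqs)
    if n == 1:
        return 1.0
    ident = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(seqs[i], seqs[j])
    cluster_sizes = np.sum(ident >= cluster_threshold, axis=1)
    return float(np.sum(1.0 / cluster_sizes))


def merge_msas(base: Msa, extra_rows: Iterable[tuple[str, str]]) -> Msa:
    """Append non-duplicate rows (exact aligned-string comparison) to ``base``."""
    L = base.n_columns
    seen = {seq for _, seq in base.rows}
    rows = list(base.rows)
    for rid, seq in extra_rows:
        if match_state_count(seq) != L:
            raise MsaFormatError(
                f"extra row {rid!r} has {match_state_count(seq)} match columns, "
                f"expected {L}"
            )
        if seq in seen:
            continue
        seen.add(seq)
        rows.append((rid, seq))
    return Msa(query_id=base.query_id, rows=tuple(rows))
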