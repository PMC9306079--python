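"""Marker-gene read recruitment at fixed identity/coverage thresholds.

Reads are aligned semi-globally against a marker reference set: the query is
aligned end to end while the reference is local (leading and trailing
reference columns are free), matching ``usearch_global`` semantics. A read
is recruited when its best hit reaches 85% identity and 90% query coverage
(both inclusive). Recruited counts are normalized to reads per million
(RPM).

Alignment dialect: the aligner minimizes unit-cost edits (mismatches and
internal gaps) and, among minimum-edit alignments, maximizes the number of
matched columns. Identity is matches over alignment columns, so the reported
identity is well-defined and independent of which co-optimal path a
traceback would pick. Both strands are searched and the better one kept —
shotgun reads are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReadHit",
    "DEFAULT_MIN_IDENTITY",
    "DEFAULT_MIN_COVERAGE",
    "DEFAULT_MIN_LENGTH",
    "semiglobal_identity",
    "align_read",
    "screen_reads",
    "rpm_summary",
    "read_fasta",
    "reverse_complement",
]

DEFAULT_MIN_IDENTITY = 0.85
DEFAULT_MIN_COVERAGE = 0.90
DEFAULT_MIN_LENGTH = 45  # matches the upstream read-trimming floor

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadHit:
    """Best alignment of one read against the reference set."""

    read_id: str
    ref_id: str
    identity: float  # matches / alignment columns, in [0, 1]
    query_coverage: float  # aligned query fraction, in [0, 1]
    aligned: bool
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.aligned and not (
            self.identity >= DEFAULT_MIN_IDENTITY
            and self.query_coverage >= DEFAULT_MIN_COVERAGE
        ):
            raise ValueError(
                "aligned hit below thresholds: "
                f"identity={self.identity}, coverage={self.query_coverage}"
            )


def semiglobal_identity(query: str, target: str) -> tuple[float, int, int]:
    """Align ``query`` end-to-end inside ``target`` and return
    ``(identity, matches, columns)``.

    Minimizes edits (mismatches + internal gaps; reference overhangs are
    free), then maximizes matches among minimum-edit alignments; columns =
    matches + edits, identity = matches / columns.
    """
    if not query:
        raise ValueError("empty query")
    if not target:
        raise ValueError("empty target")
    q = np.frombuffer(query.upper().encode(), dtype=np.uint8)
    t = np.frombuffer(target.upper().encode(), dtype=np.uint8)
    m, n = len(q), len(t)
    # Cell value = edits * BIG + (m - matches): lexicographic
    # (min edits, max matches) folded into one integer.
    big = np.int64(m + n + 2)
    idx = np.arange(n + 1, dtype=np.int64) * big
    row = np.full(n + 1, np.int64(m))  # free leading target columns
    for i in range(m):
        diag_step = np.where(t == q[i], np.int64(-1), big)
        cand = np.minimum(row[:-1] + diag_step, row[1:] + big)
        new = np.empty(n + 1, dtype=np.int64)
        new[0] = row[0] + big
        new[1:] = cand
        # propagate internal target-gap (left) moves: each adds one edit
        new = np.minimum.accumulate(new - idx) + idx
        row = new
    best = int(row.min())  # free trailing target columns
    edits = best // int(big)
    matches = m - (best % int(big))
    columns = matches + edits
    identity = matches / columns if columns else 0.0
    return identity, matches, columns


def align_read(
    read_id: str,
    read: str,
    refs: Sequence[tuple[str, str]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_length: int = DEFAULT_MIN_LENGTH,
    search_both_strands: bool = True,
) -> ReadHit | None:
    """Best recruiting hit of one read against the references, or ``None``.

    Thresholds are inclusive (identity exactly 0.85 and coverage exactly
    0.90 are accepted). Reads shorter than ``min_length`` are never
    recruited. Ties break toward the earlier reference and the forward
    strand. The query aligns end to end, so coverage is 1 by construction;
    the threshold still guards alternative dialects.
    """
    if not refs:
        raise ValueError("empty reference set")
    if len(read) < min_length:
        return None
    strands = [("+", read)]
    if search_both_strands:
        strands.append(("-", reverse_complement(read)))
    best: tuple[float, int, int, str] | None = None  # identity, -order, strand pref
    best_hit = None
    for order, (ref_id, ref_seq) in enumerate(refs):
        for strand, seq in strands:
            identity, _, _ = semiglobal_identity(seq, ref_seq)
            key = (identity, -order, 0 if strand == "+" else -1, strand)
            if best is None or key > best:
                best = key
                best_hit = (ref_id, identity, strand)
    assert best_hit is not None
    ref_id, identity, strand = best_hit
    coverage = 1.0
    if identity >= min_identity and coverage >= min_coverage:
        return ReadHit(
            read_id=read_id,
            ref_id=ref_id,
            identity=identity,
            query_coverage=coverage,
            aligned=True,
            strand=strand,
        )
    return None


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _read_sequences(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def screen_reads(
    reads_path: str | Path,
    refs_path: str | Path,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[list[ReadHit], int]:
    """Recruit every read in a FASTQ/FASTA file against a FASTA reference
    set; returns (recruiting hits, total read count)."""
    refs = read_fasta(refs_path)
    if not refs:
        raise ValueError(f"no references in {refs_path}")
    reads = _read_sequences(reads_path)
    hits = []
    for read_id, seq in reads:
        hit = align_read(
            read_id,
            seq,
            refs,
            min_identity=min_identity,
            min_coverage=min_coverage,
            min_length=min_length,
        )
        if hit is not None:
            hits.append(hit)
    return hits, len(reads)


def rpm_summary(
    hits: Iterable[ReadHit],
    groups: Mapping[str, str],
    total_reads: int,
) -> pd.DataFrame:
    """Aggregate recruiting hits to reads-per-million by reference group.

    Every group in the mapping is reported, including zero-hit groups
    (0 RPM). ``rpm = hit_count / total_reads * 1e6``.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    counts: dict[str, int] = {g: 0 for g in dict.fromkeys(groups.values())}
    for hit in hits:
        if not hit.aligned:
            continue
        group = groups.get(hit.ref_id)
        if group is None:
            raise KeyError(f"reference {hit.ref_id!r} missing from group map")
        counts[group] += 1
    rows = [
        {
            "group_id": group,
            "hit_count": count,
            "total_reads": total_reads,
            "rpm": count / total_reads * 1e6,
        }
        for group, count in counts.items()
    ]
    return pd.DataFrame(rows, columns=["group_id", "hit_count", "total_reads", "rpm"])
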