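"""Domain types, table I/O, annotation-hit filtering, MAG QC and dereplication.

The unit of analysis is the metagenome-assembled genome (MAG): a draft genome
binned from a community shotgun co-assembly, carrying CheckM-style quality
metrics (completeness, contamination), an optional relative-abundance
estimate, and the set of annotated genes that survived the homology-hit
filter. A :class:`Community` is an ordered collection of such genomes.

Gene identifiers are case-normalized on entry; both gene symbols (``nirK``)
and KEGG orthology identifiers (``K00368``) are accepted — KO-to-symbol
mapping is handled downstream by the marker and pathway definition files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GeneHit",
    "GenomeRecord",
    "Community",
    "FormatError",
    "read_annotation_table",
    "read_quality_table",
    "filter_hits",
    "qc_filter",
    "dereplicate",
    "build_community",
    "normalize_gene",
    "EVALUE_MAX",
    "BITSCORE_MIN",
    "IDENTITY_MIN",
]

# Annotation hit-retention thresholds (strict inequalities): best hits must
# satisfy E-value < 1e-5, bit score > 60 and percent identity > 30.
EVALUE_MAX = 1e-5
BITSCORE_MIN = 60.0
IDENTITY_MIN = 30.0

# Sentinel statistics assigned to presence-only tables so that rows lacking
# hit statistics pass the filter unconditionally.
_SENTINEL_EVALUE = 0.0
_SENTINEL_BITSCORE = float("inf")
_SENTINEL_IDENTITY = 100.0

# QC: keep a MAG if completeness >= 70%, or at any completeness when it has
# exactly zero contamination.
QC_COMPLETENESS_MIN = 70.0


class FormatError(ValueError):
    """Raised when an input table does not match the expected schema."""


def normalize_gene(gene: str) -> str:
    """Case-normalize a gene symbol or KO identifier."""
    return gene.strip().lower()


@dataclass(frozen=True)
class GeneHit:
    """One annotation hit: a gene observed in a genome with its statistics."""

    genome_id: str
    gene: str
    evalue: float = _SENTINEL_EVALUE
    bitscore: float = _SENTINEL_BITSCORE
    identity: float = _SENTINEL_IDENTITY

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene identifier must be non-empty")
        if self.evalue < 0:
            raise ValueError(f"negative E-value: {self.evalue}")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity out of [0, 100]: {self.identity}")

    @property
    def passes_filter(self) -> bool:
        return (
            self.evalue < EVALUE_MAX
            and self.bitscore > BITSCORE_MIN
            and self.identity > IDENTITY_MIN
        )


@dataclass
class GenomeRecord:
    """A MAG with quality metrics, abundance and its filtered gene set."""

    genome_id: str
    completeness: float = 100.0
    contamination: float = 0.0
    abundance: float | None = None
    genes: frozenset[str] = field(default_factory=frozenset)
    assembly_size: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"completeness out of [0, 100]: {self.completeness}")
        if self.contamination < 0:
            raise ValueError(f"negative contamination: {self.contamination}")
        self.genes = frozenset(normalize_gene(g) for g in self.genes)

    def has_gene(self, gene: str) -> bool:
        return normalize_gene(gene) in self.genes

    def with_genes(self, genes: Iterable[str]) -> "GenomeRecord":
        return GenomeRecord(
            genome_id=self.genome_id,
            completeness=self.completeness,
            contamination=self.contamination,
            abundance=self.abundance,
            genes=frozenset(genes),
            assembly_size=self.assembly_size,
        )


@dataclass
class Community:
    """Ordered collection of genomes with unique identifiers."""

    genomes: list[GenomeRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate genome ids: {dupes}")

    def __len__(self) -> int:
        return len(self.genomes)

    def __iter__(self):
        return iter(self.genomes)

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "provenance": self.provenance,
            "genomes": [
                {
                    "genome_id": g.genome_id,
                    "completeness": g.completeness,
                    "contamination": g.contamination,
                    "abundance": g.abundance,
                    "assembly_size": g.assembly_size,
                    "genes": sorted(g.genes),
                }
                for g in self.genomes
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Community":
        doc = json.loads(Path(path).read_text())
        genomes = [
            GenomeRecord(
                genome_id=g["genome_id"],
                completeness=g["completeness"],
                contamination=g["contamination"],
                abundance=g.get("abundance"),
                assembly_size=g.get("assembly_size"),
                genes=frozenset(g["genes"]),
            )
            for g in doc["genomes"]
        ]
        return cls(genomes=genomes, provenance=doc.get("provenance", ""))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_annotation_table(path: str | Path) -> list[GeneHit]:
    """Read a per-genome annotation table (TSV) into :class:`GeneHit` rows.

    Mandatory columns: ``genome_id``, ``gene``. Optional columns ``evalue``,
    ``bitscore``, ``identity``; rows lacking them receive pass-by-default
    sentinel values so that presence-only tables are accepted unchanged by
    :func:`filter_hits`.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "gene": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"annotation table {path} is empty", stacklevel=2)
        return []
    for col in ("genome_id", "gene"):
        if col not in table.columns:
            raise FormatError(f"annotation table {path} lacks mandatory column {col!r}")
    if table.empty:
        warnings.warn(f"annotation table {path} has no rows", stacklevel=2)
        return []
    hits = []
    has = {c: c in table.columns for c in ("evalue", "bitscore", "identity")}
    for row in table.itertuples(index=False):
        kwargs = {}
        for col, sentinel in (
            ("evalue", _SENTINEL_EVALUE),
            ("bitscore", _SENTINEL_BITSCORE),
            ("identity", _SENTINEL_IDENTITY),
        ):
            if has[col]:
                value = getattr(row, col)
                kwargs[col] = sentinel if pd.isna(value) else float(value)
        hits.append(GeneHit(genome_id=str(row.genome_id), gene=str(row.gene), **kwargs))
    return hits


def read_quality_table(path: str | Path) -> pd.DataFrame:
    """Read a MAG quality table (TSV: genome_id, completeness, contamination,
    optional abundance and assembly_size)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    for col in ("genome_id", "completeness", "contamination"):
        if col not in table.columns:
            raise FormatError(f"quality table {path} lacks mandatory column {col!r}")
    return table


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_hits(hits: Iterable[GeneHit]) -> list[GeneHit]:
    """Retain hits with E-value < 1e-5, bit score > 60 and identity > 30%.

    All three inequalities are strict; boundary values are rejected.
    Order-preserving and idempotent.
    """
    return [h for h in hits if h.passes_filter]


def qc_filter(community: Community) -> Community:
    """Retain genomes with completeness >= 70% or exactly zero contamination.

    The second clause admits less-complete but uncontaminated bins.
    """
    kept = [
        g
        for g in community.genomes
        if g.completeness >= QC_COMPLETENESS_MIN or g.contamination == 0.0
    ]
    return Community(genomes=kept, provenance=community.provenance)


def dereplicate(candidates: Sequence[GenomeRecord]) -> GenomeRecord:
    """Pick the best version among redundant bins of the same MAG.

    Ranking: higher completeness, then lower contamination, then larger
    assembly size (when recorded). Ties break deterministically by input
    order.
    """
    if not candidates:
        raise ValueError("dereplicate requires at least one candidate")
    best = candidates[0]
    for cand in candidates[1:]:
        if _derep_key(cand) > _derep_key(best):
            best = cand
    return best


def _derep_key(g: GenomeRecord) -> tuple[float, float, float]:
    size = g.assembly_size if g.assembly_size is not None else 0
    return (g.completeness, -g.contamination, size)


# ---------------------------------------------------------------------------
# Assembly of a Community from tables
# ---------------------------------------------------------------------------

def build_community(
    hits: Iterable[GeneHit],
    quality: pd.DataFrame,
    provenance: str = "",
    apply_hit_filter: bool = True,
) -> Community:
    """Join filtered annotation hits with the quality table into a Community.

    Genomes appear in quality-table order; genomes without any surviving hit
    get an empty gene set. Hits for genomes absent from the quality table
    raise a :class:`FormatError` (they indicate mismatched inputs).
    """
    if apply_hit_filter:
        hits = filter_hits(hits)
    genes_by_genome: dict[str, set[str]] = {}
    for h in hits:
        genes_by_genome.setdefault(h.genome_id, set()).add(normalize_gene(h.gene))
    known = set(quality["genome_id"])
    orphans = sorted(set(genes_by_genome) - known)
    if orphans:
        raise FormatError(
            f"annotation table mentions genomes absent from the quality table: {orphans}"
        )
    genomes = []
    for row in quality.itertuples(index=False):
        genomes.append(
            GenomeRecord(
                genome_id=str(row.genome_id),
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                abundance=float(row.abundance) if hasattr(row, "abundance") else None,
                assembly_size=int(row.assembly_size)
                if hasattr(row, "assembly_size")
                else None,
                genes=frozenset(genes_by_genome.get(str(row.genome_id), set())),
            )
        )
    return Community(genomes=genomes, provenance=provenance)
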