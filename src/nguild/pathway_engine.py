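"""Declarative pathway definitions and the pathway-completeness heuristic.

A pathway is an ordered list of reaction steps; each step lists the
alternative enzymes (gene symbols or KO ids) that can catalyze it, and the
step counts as present when the genome encodes any one of them. Pathway
presence follows a completeness heuristic tolerant of draft-genome gene
dropout: pathways longer than two steps may miss one step and still be
called present; pathways of one or two steps require every step (the
two-step case is a package decision, configurable via ``allowed_missing``).

Carbon-fixation pathways carry an additional ``key_genes`` set used for
autotrophy screening: a genome is classified autotrophic when all key genes
of at least one fixation pathway are present. Key-gene screening is
deliberately stricter than the one-missing-step rule — fixation marker genes
(e.g. RuBisCO) are diagnostic, the surrounding steps are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .core_model import Community, GenomeRecord, normalize_gene

__all__ = [
    "PathwayStep",
    "PathwayDef",
    "PathwayCall",
    "load_pathways",
    "default_pathways",
    "step_present",
    "call_pathway",
    "classify_trophy",
    "pathway_matrix",
    "matrix_to_frames",
]

AUTOTROPH = "autotroph"
NON_AUTOTROPH = "non_autotroph"


@dataclass(frozen=True)
class PathwayStep:
    step_id: str
    enzymes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.enzymes:
            raise ValueError(f"step {self.step_id}: empty enzyme set")
        object.__setattr__(
            self, "enzymes", frozenset(normalize_gene(e) for e in self.enzymes)
        )


@dataclass(frozen=True)
class PathwayDef:
    pathway_id: str
    category: str  # amino_acid | b_vitamin | carbon_fixation
    steps: tuple[PathwayStep, ...]
    key_genes: frozenset[str] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"pathway {self.pathway_id}: no steps")
        ids = [s.step_id for s in self.steps]
        if len(ids) != len(set(ids)):
            raise ValueError(f"pathway {self.pathway_id}: duplicate step ids")
        object.__setattr__(
            self, "key_genes", frozenset(normalize_gene(g) for g in self.key_genes)
        )

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def all_genes(self) -> frozenset[str]:
        genes: set[str] = set()
        for s in self.steps:
            genes |= s.enzymes
        return frozenset(genes)


@dataclass(frozen=True)
class PathwayCall:
    genome_id: str
    pathway_id: str
    n_steps: int
    n_present: int
    present: bool

    def __post_init__(self) -> None:
        if not 0 <= self.n_present <= self.n_steps:
            raise ValueError(
                f"{self.genome_id}/{self.pathway_id}: "
                f"n_present {self.n_present} out of [0, {self.n_steps}]"
            )


# ---------------------------------------------------------------------------
# Definition loading
# ---------------------------------------------------------------------------

def load_pathways(path: str | Path) -> list[PathwayDef]:
    """Load pathway definitions from a YAML file.

    Schema: top-level ``pathways:`` list; each entry has ``id``, ``category``,
    ``steps`` (a list of alternative-enzyme lists, or of ``{id, enzymes}``
    mappings) and optional ``key_genes`` and ``name``.
    """
    doc = yaml.safe_load(Path(path).read_text())
    return _parse_pathways(doc)


def default_pathways() -> list[PathwayDef]:
    """The packaged amino-acid, B-vitamin and carbon-fixation definitions."""
    text = resources.files("nguild.data").joinpath("pathways.yaml").read_text()
    return _parse_pathways(yaml.safe_load(text))


def _parse_pathways(doc: dict) -> list[PathwayDef]:
    defs = []
    for entry in doc["pathways"]:
        steps = []
        for i, step in enumerate(entry["steps"], start=1):
            if isinstance(step, dict):
                steps.append(
                    PathwayStep(step_id=str(step["id"]), enzymes=frozenset(step["enzymes"]))
                )
            else:
                steps.append(PathwayStep(step_id=f"s{i}", enzymes=frozenset(step)))
        defs.append(
            PathwayDef(
                pathway_id=str(entry["id"]),
                category=str(entry["category"]),
                steps=tuple(steps),
                key_genes=frozenset(entry.get("key_genes", [])),
                name=str(entry.get("name", "")),
            )
        )
    ids = [d.pathway_id for d in defs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate pathway ids in definition file")
    return defs


# ---------------------------------------------------------------------------
# Presence calls
# ---------------------------------------------------------------------------

def step_present(step: PathwayStep, genes: frozenset[str] | set[str]) -> bool:
    """A step is present when the genome encodes any of its alternative enzymes."""
    return not step.enzymes.isdisjoint(genes)


def call_pathway(
    pathway: PathwayDef,
    genes: frozenset[str] | set[str],
    allowed_missing: int = 1,
) -> PathwayCall:
    """Apply the completeness heuristic to one pathway in one genome.

    Pathways with more than two steps tolerate ``allowed_missing`` absent
    steps (default one); shorter pathways require every step.
    """
    n_present = sum(step_present(s, genes) for s in pathway.steps)
    n_steps = pathway.n_steps
    if n_steps > 2:
        present = (n_steps - n_present) <= allowed_missing
    else:
        present = n_present == n_steps
    return PathwayCall(
        genome_id="",
        pathway_id=pathway.pathway_id,
        n_steps=n_steps,
        n_present=n_present,
        present=present,
    )


def classify_trophy(
    genome: GenomeRecord, fixation_pathways: Iterable[PathwayDef]
) -> str:
    """Autotroph iff all key genes of at least one fixation pathway are present."""
    for pw in fixation_pathways:
        if pw.category != "carbon_fixation":
            continue
        key = pw.key_genes or pw.all_genes()
        if key and key <= genome.genes:
            return AUTOTROPH
    return NON_AUTOTROPH


def pathway_matrix(
    community: Community,
    defs: Sequence[PathwayDef],
    allowed_missing: int = 1,
) -> dict[str, dict[str, PathwayCall]]:
    """Complete genome x pathway matrix of presence calls.

    Returned as ``{genome_id: {pathway_id: PathwayCall}}`` preserving input
    order in both dimensions. Genes in the community that no definition
    mentions are simply ignored.
    """
    if not defs and len(community) > 0:
        raise ValueError("pathway_matrix requires at least one pathway definition")
    matrix: dict[str, dict[str, PathwayCall]] = {}
    for genome in community:
        row: dict[str, PathwayCall] = {}
        for pw in defs:
            call = call_pathway(pw, genome.genes, allowed_missing=allowed_missing)
            row[pw.pathway_id] = PathwayCall(
                genome_id=genome.genome_id,
                pathway_id=call.pathway_id,
                n_steps=call.n_steps,
                n_present=call.n_present,
                present=call.present,
            )
        matrix[genome.genome_id] = row
    return matrix


def matrix_to_frames(
    matrix: dict[str, dict[str, PathwayCall]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render a call matrix as (wide 0/1 frame, long frame with step counts)."""
    if not matrix:
        return (
            pd.DataFrame(index=pd.Index([], name="genome_id")),
            pd.DataFrame(
                columns=["genome_id", "pathway_id", "n_steps", "n_present", "present"]
            ),
        )
    genome_ids = list(matrix)
    pathway_ids = list(next(iter(matrix.values())))
    wide = pd.DataFrame(
        [[int(matrix[g][p].present) for p in pathway_ids] for g in genome_ids],
        index=pd.Index(genome_ids, name="genome_id"),
        columns=pathway_ids,
    )
    long = pd.DataFrame(
        [
            {
                "genome_id": g,
                "pathway_id": p,
                "n_steps": matrix[g][p].n_steps,
                "n_present": matrix[g][p].n_present,
                "present": matrix[g][p].present,
            }
            for g in genome_ids
            for p in pathway_ids
        ]
    )
    return wide, long
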