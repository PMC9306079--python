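"""Per-genome nitrogen-cycle gene census and guild assignment.

The census reduces a genome's filtered gene set to boolean flags over
nitrogen-cycle marker groups (amo, hao, hzs, hdh, nxr variants, nar/nap,
nirS/nirK, nirBD/nrfHA, nor variants, nosZ clades). Operon groups require
their catalytic-core subunits (configurable per group in the marker file);
accessory subunits are recorded but not required — the weakest assumption
consistent with flag-level reporting from draft genomes.

Guild logic:

* AOB — aerobic ammonia oxidizers: amoCABDE and hao.
* AnAOB — anammox: hzsABC and hdh.
* NOB_canonical — canonical nitrite oxidizers: an nxr of the canonical NOB
  clade plus autotrophy, without amo or hzs. nxr/nar homology cannot be
  resolved from gene symbols, so clade labels (canonical, anammox,
  periplasmic NOB/AnAOB-group) arrive as distinct symbols in the annotation
  table, assigned upstream from gene trees.
* comammox — amo together with any nxr.
* DNRA_complete — nitrate reductase (nar or nap) plus nrfHA or nirBD.
* denitrifier_complete — nitrate reductase, nitrite reductase (nirS/nirK),
  NO reductase (norBC/norZ) and nosZ of either clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .core_model import Community, GenomeRecord, normalize_gene
from .pathway_engine import AUTOTROPH

__all__ = [
    "MarkerMap",
    "NRepertoire",
    "GuildAssignment",
    "load_marker_map",
    "default_marker_map",
    "census",
    "census_community",
    "assign_guilds",
    "community_counts",
    "GUILDS",
]

GUILDS = (
    "AOB",
    "AnAOB",
    "NOB_canonical",
    "comammox",
    "DNRA_complete",
    "denitrifier_complete",
)

# Flag names, in reporting order.
MARKER_GROUPS = (
    "amoCABDE",
    "hao",
    "hzsABC",
    "hdh",
    "nxrAB_anammox",
    "nxr_like_periplasmic",
    "nxr_canonical",
    "narGHIJ",
    "napAB",
    "nirS",
    "nirK",
    "nirBD",
    "nrfHA",
    "norBC",
    "norZ",
    "nosZ_cladeI",
    "nosZ_cladeII",
)


@dataclass(frozen=True)
class MarkerMap:
    """Gene -> marker-group mapping with per-group subunit requirements."""

    groups: Mapping[str, frozenset[str]]  # group -> recorded genes
    required: Mapping[str, frozenset[str]]  # group -> required core subunits
    aliases: Mapping[str, str] = field(default_factory=dict)  # KO -> symbol
    hao_like_prefix: str = "haoa_like"

    def resolve(self, genes: Iterable[str]) -> frozenset[str]:
        """Apply KO aliases and case normalization to a gene set."""
        out = set()
        for g in genes:
            g = normalize_gene(g)
            out.add(self.aliases.get(g, g))
        return frozenset(out)


def load_marker_map(path: str | Path) -> MarkerMap:
    return _parse_marker_map(yaml.safe_load(Path(path).read_text()))


def default_marker_map() -> MarkerMap:
    text = resources.files("nguild.data").joinpath("markers.yaml").read_text()
    return _parse_marker_map(yaml.safe_load(text))


def _parse_marker_map(doc: dict) -> MarkerMap:
    groups: dict[str, frozenset[str]] = {}
    required: dict[str, frozenset[str]] = {}
    for name, spec in doc["groups"].items():
        genes = frozenset(normalize_gene(g) for g in spec["genes"])
        req = frozenset(normalize_gene(g) for g in spec.get("required", spec["genes"]))
        if not req <= genes:
            raise ValueError(f"marker group {name}: required genes not in gene list")
        groups[name] = genes
        required[name] = req
    missing = [g for g in MARKER_GROUPS if g not in groups]
    if missing:
        raise ValueError(f"marker map lacks groups: {missing}")
    aliases = {
        normalize_gene(k): normalize_gene(v) for k, v in doc.get("aliases", {}).items()
    }
    return MarkerMap(
        groups=groups,
        required=required,
        aliases=aliases,
        hao_like_prefix=normalize_gene(doc.get("hao_like_prefix", "haoA_like")),
    )


@dataclass(frozen=True)
class NRepertoire:
    """Boolean marker-group flags plus the hao-like paralog count."""

    genome_id: str
    flags: Mapping[str, bool]
    hao_like_count: int = 0

    def __post_init__(self) -> None:
        if self.hao_like_count < 0:
            raise ValueError("hao_like_count must be >= 0")

    def __getitem__(self, group: str) -> bool:
        return bool(self.flags[group])

    def any_of(self, *groups: str) -> bool:
        return any(self.flags[g] for g in groups)

    # Derived predicates used throughout reporting.
    @property
    def nitrate_reductase(self) -> bool:
        return self.any_of("narGHIJ", "napAB")

    @property
    def nitrite_reductase(self) -> bool:
        return self.any_of("nirS", "nirK")

    @property
    def no_reductase(self) -> bool:
        return self.any_of("norBC", "norZ")

    @property
    def nosZ(self) -> bool:
        return self.any_of("nosZ_cladeI", "nosZ_cladeII")

    @property
    def dnra_reductase(self) -> bool:
        return self.any_of("nrfHA", "nirBD")

    @property
    def any_nxr_nar_homolog(self) -> bool:
        return self.any_of(
            "narGHIJ", "napAB", "nxrAB_anammox", "nxr_like_periplasmic", "nxr_canonical"
        )


@dataclass(frozen=True)
class GuildAssignment:
    genome_id: str
    guilds: frozenset[str]
    denit_class: str
    trophy: str


def census(genome: GenomeRecord, marker_map: MarkerMap | None = None) -> NRepertoire:
    """Reduce a genome's gene set to marker-group flags.

    A group's flag is true iff all of its required core subunits are present
    (after KO-alias resolution and case normalization).
    """
    mm = marker_map or default_marker_map()
    genes = mm.resolve(genome.genes)
    flags = {
        group: mm.required[group] <= genes for group in mm.groups
    }
    hao_like = sum(1 for g in genes if g.startswith(mm.hao_like_prefix))
    return NRepertoire(genome_id=genome.genome_id, flags=flags, hao_like_count=hao_like)


def census_community(
    community: Community, marker_map: MarkerMap | None = None
) -> dict[str, NRepertoire]:
    mm = marker_map or default_marker_map()
    return {g.genome_id: census(g, mm) for g in community}


def assign_guilds(rep: NRepertoire, trophy: str, denit_class: str = "") -> GuildAssignment:
    """Derive guild membership from a censused repertoire and trophy label."""
    guilds = set()
    if rep["amoCABDE"] and rep["hao"]:
        guilds.add("AOB")
    if rep["hzsABC"] and rep["hdh"]:
        guilds.add("AnAOB")
    if (
        rep["nxr_canonical"]
        and trophy == AUTOTROPH
        and not rep["amoCABDE"]
        and not rep["hzsABC"]
    ):
        guilds.add("NOB_canonical")
    if rep["amoCABDE"] and rep.any_of(
        "nxr_canonical", "nxrAB_anammox", "nxr_like_periplasmic"
    ):
        guilds.add("comammox")
    if rep.nitrate_reductase and rep.dnra_reductase:
        guilds.add("DNRA_complete")
    if (
        rep.nitrate_reductase
        and rep.nitrite_reductase
        and rep.no_reductase
        and rep.nosZ
    ):
        guilds.add("denitrifier_complete")
    return GuildAssignment(
        genome_id=rep.genome_id,
        guilds=frozenset(guilds),
        denit_class=denit_class,
        trophy=trophy,
    )


def community_counts(
    reps: Mapping[str, NRepertoire] | Iterable[NRepertoire],
    nxr_as_nar: bool = False,
) -> dict[str, int]:
    """Community-level census summary: genomes per marker group, per derived
    respiratory capability, and per joint condition.

    With ``nxr_as_nar`` true, genomes whose only nitrate-reduction candidate
    is a periplasmic nxr-like gene are added to the nitrate-reducer count
    (their enzyme's direction is unresolved; this is the permissive reading).
    """
    if isinstance(reps, Mapping):
        reps = list(reps.values())
    else:
        reps = list(reps)

    counts: dict[str, int] = {"n_genomes": len(reps)}
    for group in MARKER_GROUPS:
        counts[group] = sum(r[group] for r in reps)

    def n(pred) -> int:
        return sum(1 for r in reps if pred(r))

    counts["nitrate_reducers"] = n(
        lambda r: r.nitrate_reductase
        or (nxr_as_nar and r["nxr_like_periplasmic"])
    )
    counts["nitrite_reducers"] = n(lambda r: r.nitrite_reductase)
    counts["no_reducers"] = n(lambda r: r.no_reductase)
    counts["n2o_reducers"] = n(lambda r: r.nosZ)
    counts["dnra_nitrite_reducers"] = n(lambda r: r.dnra_reductase)
    counts["nxr_nar_homolog_carriers"] = n(lambda r: r.any_nxr_nar_homolog)
    counts["nir_and_nar"] = n(lambda r: r.nitrite_reductase and r["narGHIJ"])
    counts["nor_and_nir"] = n(lambda r: r.no_reductase and r.nitrite_reductase)
    counts["nor_and_nir_and_nar"] = n(
        lambda r: r.no_reductase and r.nitrite_reductase and r["narGHIJ"]
    )
    counts["nosZII_and_nir"] = n(lambda r: r["nosZ_cladeII"] and r.nitrite_reductase)
    counts["nosZII_and_nar"] = n(lambda r: r["nosZ_cladeII"] and r["narGHIJ"])
    counts["nosZII_and_nor"] = n(lambda r: r["nosZ_cladeII"] and r.no_reductase)
    return counts


def repertoire_frame(reps: Mapping[str, NRepertoire]) -> pd.DataFrame:
    """Genome x marker-group 0/1 table (plus hao-like counts)."""
    rows = []
    for gid, rep in reps.items():
        row = {"genome_id": gid}
        row.update({g: int(rep[g]) for g in MARKER_GROUPS})
        row["hao_like_count"] = rep.hao_like_count
        rows.append(row)
    return pd.DataFrame(rows).set_index("genome_id")
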