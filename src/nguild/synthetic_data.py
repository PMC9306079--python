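"""Study fixture construction and synthetic-community / read simulation.

Three roles:

* :func:`build_fixture` materializes the packaged 55-MAG community from the
  declarative assignment in ``data/fixture.yaml`` and refuses to emit it if
  any embedded consistency constraint fails (the constraint set is evaluated
  directly on the declared marker tokens, before any gene set exists).
* :func:`validate_fixture` re-evaluates the same constraints through the
  full analysis pipeline (gene sets -> census -> guilds -> pathway calls),
  an independent code path; both passing is the fixture's consistency proof.
* :func:`simulate_community` and :func:`simulate_reads` generate random
  communities with known guild labels (gene dropout follows estimated
  completeness: each gene is retained with probability completeness/100,
  independently — no operon linkage) and substitution-mutated reads for
  exercising the read screen. Both are fully seeded.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .auxotrophy import community_profiles
from .core_model import Community, GenomeRecord, normalize_gene
from .nitrogen_census import (
    MarkerMap,
    assign_guilds,
    census_community,
    default_marker_map,
)
from .pathway_engine import (
    AUTOTROPH,
    PathwayDef,
    classify_trophy,
    default_pathways,
)

__all__ = [
    "FixtureError",
    "SimulationConfig",
    "build_fixture",
    "validate_fixture",
    "fixture_tables",
    "simulate_community",
    "guild_recovery",
    "simulate_reads",
]


class FixtureError(ValueError):
    """Raised when the fixture assignment violates its own constraints."""


# Marker tokens used in the fixture file -> (marker groups set true, genes emitted)
_TOKEN_MAP: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "amo": (("amoCABDE",), ("amoA", "amoB", "amoC", "amoD", "amoE")),
    "hao": (("hao",), ("haoA",)),
    "hzs": (("hzsABC",), ("hzsA", "hzsB", "hzsC")),
    "hdh": (("hdh",), ("hdh",)),
    "nxr_amx": (("nxrAB_anammox",), ("nxrA_anammox", "nxrB_anammox")),
    "nxr_peri": (("nxr_like_periplasmic",), ("nxrA_periplasmic",)),
    "nxr_canon": (("nxr_canonical",), ("nxrA_canonical", "nxrB_canonical")),
    "nar": (("narGHIJ",), ("narG", "narH", "narI", "narJ")),
    "nar_GHI": (("narGHIJ",), ("narG", "narH", "narI")),
    "nar_GH": (("narGHIJ",), ("narG", "narH")),
    "napAB": (("napAB",), ("napA", "napB")),
    "nirS": (("nirS",), ("nirS",)),
    "nirK": (("nirK",), ("nirK",)),
    "nirBD": (("nirBD",), ("nirB", "nirD")),
    "nrfHA": (("nrfHA",), ("nrfH", "nrfA")),
    "norBC": (("norBC",), ("norB", "norC")),
    "norZ": (("norZ",), ("norZ",)),
    "nosZ_I": (("nosZ_cladeI",), ("nosZ_cladeI",)),
    "nosZ_II": (("nosZ_cladeII",), ("nosZ_cladeII",)),
}

_VITAMIN_PANEL = (
    "vit_b1", "vit_b2", "vit_b3", "vit_b5", "vit_b6", "vit_b7", "vit_b9", "vit_b12",
)


def _load_fixture_doc(path: str | Path | None = None) -> dict:
    if path is None:
        text = resources.files("nguild.data").joinpath("fixture.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def _aa_ids(defs: Sequence[PathwayDef]) -> list[str]:
    return [d.pathway_id for d in defs if d.category == "amino_acid"]


def _pathway_fill_genes(defs: Sequence[PathwayDef]) -> dict[str, list[str]]:
    """Genes emitted for a pathway declared present: the last alternative of
    each step, so the alternative-enzyme rule is exercised on real data."""
    fill = {}
    for d in defs:
        if d.category == "carbon_fixation":
            fill[d.pathway_id] = sorted(d.all_genes() | d.key_genes)
        else:
            fill[d.pathway_id] = [sorted(s.enzymes)[-1] for s in d.steps]
    return fill


@dataclass
class _FixtureState:
    """Everything the constraint checker needs, however it was derived."""

    genome_ids: list[str]
    flags: dict[str, dict[str, bool]]
    hao_like: dict[str, int]
    guilds: dict[str, frozenset[str]]
    autotrophs: frozenset[str]
    aa_absent: dict[str, frozenset[str]]
    vit_present: dict[str, frozenset[str]]
    aa_panel: tuple[str, ...]


def _declared_state(doc: dict, defs: Sequence[PathwayDef]) -> _FixtureState:
    """Fixture state read straight off the declared tokens (builder side)."""
    comm = doc["community"]
    genome_ids = list(comm["genomes"])
    aa_panel = tuple(_aa_ids(defs))
    groups = list(default_marker_map().groups)

    flags = {}
    for gid in genome_ids:
        fl = {g: False for g in groups}
        for token in comm["nitrogen"].get(gid, []):
            if token not in _TOKEN_MAP:
                raise FixtureError(f"unknown nitrogen token {token!r} for {gid}")
            for group in _TOKEN_MAP[token][0]:
                fl[group] = True
        flags[gid] = fl

    hao_like = {gid: int(comm.get("hao_like", {}).get(gid, 0)) for gid in genome_ids}
    autotrophs = frozenset(comm.get("carbon_fixation", {}))

    aa_absent = {}
    default_absent = comm["aa_absent"].get("default", [])
    for gid in genome_ids:
        spec = comm["aa_absent"].get(gid, default_absent)
        aa_absent[gid] = (
            frozenset(aa_panel) if spec == "all" else frozenset(spec)
        )

    vits = comm["vitamins"]
    devoid = set(vits.get("devoid", []))
    b12 = set(vits.get("b12_providers", []))
    vit_present = {}
    for gid in genome_ids:
        if gid in devoid:
            present: set[str] = set()
        else:
            present = set(vits["default_present"])
            if gid in b12:
                present.add("vit_b12")
        vit_present[gid] = frozenset(present)

    guilds = {
        gid: _guilds_from_flags(flags[gid], gid in autotrophs)
        for gid in genome_ids
    }
    return _FixtureState(
        genome_ids=genome_ids,
        flags=flags,
        hao_like=hao_like,
        guilds=guilds,
        autotrophs=autotrophs,
        aa_absent=aa_absent,
        vit_present=vit_present,
        aa_panel=aa_panel,
    )


def _guilds_from_flags(fl: Mapping[str, bool], autotroph: bool) -> frozenset[str]:
    """Guild predicates restated over raw flags (builder-side duplicate of
    the census module's logic, kept separate on purpose)."""
    out = set()
    if fl["amoCABDE"] and fl["hao"]:
        out.add("AOB")
    if fl["hzsABC"] and fl["hdh"]:
        out.add("AnAOB")
    if fl["nxr_canonical"] and autotroph and not fl["amoCABDE"] and not fl["hzsABC"]:
        out.add("NOB_canonical")
    if fl["amoCABDE"] and (
        fl["nxr_canonical"] or fl["nxrAB_anammox"] or fl["nxr_like_periplasmic"]
    ):
        out.add("comammox")
    nar = fl["narGHIJ"] or fl["napAB"]
    if nar and (fl["nrfHA"] or fl["nirBD"]):
        out.add("DNRA_complete")
    if (
        nar
        and (fl["nirS"] or fl["nirK"])
        and (fl["norBC"] or fl["norZ"])
        and (fl["nosZ_cladeI"] or fl["nosZ_cladeII"])
    ):
        out.add("denitrifier_complete")
    return frozenset(out)


def _pipeline_state(community: Community, defs: Sequence[PathwayDef],
                    marker_map: MarkerMap) -> _FixtureState:
    """Fixture state recomputed through census/guild/pathway calls
    (validator side)."""
    cfix = [d for d in defs if d.category == "carbon_fixation"]
    reps = census_community(community, marker_map)
    aa_panel = tuple(_aa_ids(defs))
    profiles = community_profiles(community, defs)
    trophy = {g.genome_id: classify_trophy(g, cfix) for g in community}
    guilds = {
        gid: assign_guilds(rep, trophy[gid]).guilds for gid, rep in reps.items()
    }
    return _FixtureState(
        genome_ids=community.genome_ids(),
        flags={gid: dict(rep.flags) for gid, rep in reps.items()},
        hao_like={gid: rep.hao_like_count for gid, rep in reps.items()},
        guilds=guilds,
        autotrophs=frozenset(
            gid for gid, label in trophy.items() if label == AUTOTROPH
        ),
        aa_absent={
            gid: frozenset(a for a, ok in prof.aa_present.items() if not ok)
            for gid, prof in profiles.items()
        },
        vit_present={
            gid: frozenset(v for v, ok in prof.vit_present.items() if ok)
            for gid, prof in profiles.items()
        },
        aa_panel=aa_panel,
    )


# ---------------------------------------------------------------------------
# Constraint checking (shared semantics; state derivation differs by caller)
# ---------------------------------------------------------------------------

def _matches_cnf(fl: Mapping[str, bool], cnf: Sequence[Sequence[str]]) -> bool:
    return all(any(fl[g] for g in clause) for clause in cnf)


def _check_constraint(c: dict, st: _FixtureState) -> tuple[bool, str]:
    kind = c["kind"]
    if kind == "count":
        got = sum(_matches_cnf(st.flags[g], c["where"]) for g in st.genome_ids)
        return got == c["equals"], f"count {got} != {c['equals']}"
    if kind == "carriers":
        got = {g for g in st.genome_ids if _matches_cnf(st.flags[g], c["where"])}
        want = set(c["equals_set"])
        return got == want, f"carriers {sorted(got)} != {sorted(want)}"
    if kind == "members":
        got = {g for g in st.genome_ids if _matches_cnf(st.flags[g], c["where"])}
        missing = set(c["includes"]) - got
        return not missing, f"missing members {sorted(missing)}"
    if kind == "subset":
        inner = {g for g in st.genome_ids if _matches_cnf(st.flags[g], c["where"])}
        outer = {g for g in st.genome_ids if _matches_cnf(st.flags[g], c["of"])}
        stray = inner - outer
        return not stray, f"not a subset: {sorted(stray)}"
    if kind == "guild":
        got = {g for g in st.genome_ids if c["guild"] in st.guilds[g]}
        want = set(c["equals_set"])
        return got == want, f"guild {c['guild']}: {sorted(got)} != {sorted(want)}"
    if kind == "genome_has":
        bad = [
            (g, grp)
            for g in c["genomes"]
            for grp in c["groups"]
            if not st.flags[g][grp]
        ]
        return not bad, f"missing flags {bad}"
    if kind == "genome_lacks":
        bad = [
            (g, grp) for g in c["genomes"] for grp in c["groups"] if st.flags[g][grp]
        ]
        return not bad, f"unexpected flags {bad}"
    if kind == "genome_nox_exactly":
        nox = [g for g in st.flags[c["genome"]] if g not in ("amoCABDE", "hao")]
        got = {g for g in nox if st.flags[c["genome"]][g]}
        want = set(c["groups"])
        return got == want, f"{c['genome']} NOx flags {sorted(got)} != {sorted(want)}"
    if kind == "hao_like_counts":
        bad = {
            g: (st.hao_like.get(g, 0), n)
            for g, n in c["counts"].items()
            if st.hao_like.get(g, 0) != n
        }
        return not bad, f"hao-like counts off: {bad}"
    if kind == "autotrophs":
        want = set(c["equals_set"])
        got = set(st.autotrophs)
        return got == want, f"autotrophs {sorted(got)} != {sorted(want)}"
    if kind == "nxr_and_fixation":
        got = {
            g
            for g in st.genome_ids
            if g in st.autotrophs
            and (
                st.flags[g]["nxr_like_periplasmic"] or st.flags[g]["nxr_canonical"]
            )
        }
        want = set(c["equals_set"])
        return got == want, f"nxr+fixation {sorted(got)} != {sorted(want)}"
    if kind == "nitrate_reducers_nxr_as_nar":
        got = sum(
            st.flags[g]["narGHIJ"]
            or st.flags[g]["napAB"]
            or st.flags[g]["nxr_like_periplasmic"]
            for g in st.genome_ids
        )
        return got == c["equals"], f"nitrate reducers (nxr as nar) {got} != {c['equals']}"
    if kind == "full_aa_prototrophs":
        got = {g for g in st.genome_ids if not st.aa_absent[g]}
        want = set(c["equals_set"])
        return got == want, f"full AA prototrophs {sorted(got)} != {sorted(want)}"
    if kind == "aa_missing_exactly":
        want = (
            set(st.aa_panel) if c["pathways"] == "all" else set(c["pathways"])
        )
        got = set(st.aa_absent[c["genome"]])
        return got == want, f"{c['genome']} missing AA {sorted(got)} != {sorted(want)}"
    if kind == "vitamin_providers":
        got = {g for g in st.genome_ids if c["pathway"] in st.vit_present[g]}
        want = set(c["equals_set"])
        return got == want, f"{c['pathway']} providers {sorted(got)} != {sorted(want)}"
    if kind == "vitamin_devoid":
        bad = {g: sorted(st.vit_present[g]) for g in c["genomes"] if st.vit_present[g]}
        return not bad, f"vitamin potential in devoid genomes: {bad}"
    if kind == "full_vitamin_prototrophs":
        got = {
            g
            for g in st.genome_ids
            if set(_VITAMIN_PANEL) <= st.vit_present[g]
        }
        want = set(c["equals_set"])
        return got == want, f"full vitamin prototrophs {sorted(got)} != {sorted(want)}"
    raise FixtureError(f"unknown constraint kind {kind!r}")


def _run_constraints(doc: dict, st: _FixtureState) -> pd.DataFrame:
    rows = []
    for c in doc["constraints"]:
        ok, detail = _check_constraint(c, st)
        rows.append(
            {
                "constraint_id": c["id"],
                "passed": ok,
                "detail": "" if ok else detail,
                "note": c.get("note", ""),
            }
        )
    return pd.DataFrame(rows, columns=["constraint_id", "passed", "detail", "note"])


# ---------------------------------------------------------------------------
# Fixture construction
# ---------------------------------------------------------------------------

def build_fixture(
    constraints_path: str | Path | None = None,
    defs: Sequence[PathwayDef] | None = None,
) -> Community:
    """Materialize the packaged study community.

    Emits one :class:`GenomeRecord` per MAG with the full gene set implied by
    its declared markers, pathways and deterministic fills. Raises
    :class:`FixtureError` listing the violated constraint ids if the
    declared assignment is internally inconsistent.
    """
    doc = _load_fixture_doc(constraints_path)
    defs = list(defs) if defs is not None else default_pathways()
    st = _declared_state(doc, defs)
    report = _run_constraints(doc, st)
    failed = report.loc[~report.passed]
    if not failed.empty:
        details = "; ".join(
            f"{r.constraint_id} ({r.detail})" for r in failed.itertuples()
        )
        raise FixtureError(f"unsatisfiable constraint set: {details}")

    comm = doc["community"]
    defs_by_id = {d.pathway_id: d for d in defs}
    fill = _pathway_fill_genes(defs)
    aa_panel = st.aa_panel
    genomes = []
    for gid in st.genome_ids:
        genes: set[str] = set()
        for token in comm["nitrogen"].get(gid, []):
            genes.update(_TOKEN_MAP[token][1])
        for i in range(st.hao_like[gid]):
            genes.add(f"haoA_like_{i + 1:02d}")
        cfix = comm.get("carbon_fixation", {}).get(gid)
        if cfix:
            if cfix not in defs_by_id:
                raise FixtureError(f"{gid}: unknown fixation pathway {cfix!r}")
            genes.update(fill[cfix])
        for aa in aa_panel:
            if aa not in st.aa_absent[gid]:
                genes.update(fill[aa])
        for vit in st.vit_present[gid]:
            genes.update(fill[vit])
        genes.update(comm.get("extra_genes", {}).get(gid, []))
        completeness, contamination, abundance = comm["quality"][gid]
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                completeness=float(completeness),
                contamination=float(contamination),
                abundance=float(abundance),
                genes=frozenset(normalize_gene(g) for g in genes),
            )
        )
    return Community(genomes=genomes, provenance="packaged 55-MAG study fixture")


def validate_fixture(
    community: Community,
    constraints_path: str | Path | None = None,
    defs: Sequence[PathwayDef] | None = None,
    marker_map: MarkerMap | None = None,
) -> pd.DataFrame:
    """Re-evaluate every fixture constraint through the analysis pipeline.

    Independent of :func:`build_fixture`: flags, guilds, trophy labels and
    pathway calls are recomputed from the community's gene sets via the
    census and pathway modules. Returns a per-constraint pass/fail report.
    """
    doc = _load_fixture_doc(constraints_path)
    defs = list(defs) if defs is not None else default_pathways()
    mm = marker_map or default_marker_map()
    declared = set(doc["community"]["genomes"])
    present = set(community.genome_ids())
    if declared - present:
        # genome-scoped constraints cannot hold on a truncated community
        st = _pipeline_state(community, defs, mm)
        rows = []
        for c in doc["constraints"]:
            scoped = set(
                c.get("genomes", [])
                or ([c["genome"]] if "genome" in c else [])
            )
            if scoped - present:
                rows.append(
                    {
                        "constraint_id": c["id"],
                        "passed": False,
                        "detail": f"genomes absent: {sorted(scoped - present)}",
                        "note": c.get("note", ""),
                    }
                )
            else:
                ok, detail = _check_constraint(c, st)
                rows.append(
                    {
                        "constraint_id": c["id"],
                        "passed": ok,
                        "detail": "" if ok else detail,
                        "note": c.get("note", ""),
                    }
                )
        return pd.DataFrame(
            rows, columns=["constraint_id", "passed", "detail", "note"]
        )
    st = _pipeline_state(community, defs, mm)
    return _run_constraints(doc, st)


def fixture_tables(community: Community) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render a community as (annotation TSV frame, quality TSV frame) in the
    package's standard input formats, with deterministic hit statistics."""
    ann_rows = []
    for g in community:
        for gene in sorted(g.genes):
            ann_rows.append(
                {
                    "genome_id": g.genome_id,
                    "gene": gene,
                    # synthetic but filter-passing statistics
                    "evalue": 1e-20,
                    "bitscore": 150.0 + (zlib.crc32(gene.encode()) % 100),
                    "identity": 60.0 + (zlib.crc32(gene.encode()) % 35),
                }
            )
    annotations = pd.DataFrame(
        ann_rows, columns=["genome_id", "gene", "evalue", "bitscore", "identity"]
    )
    quality = pd.DataFrame(
        [
            {
                "genome_id": g.genome_id,
                "completeness": g.completeness,
                "contamination": g.contamination,
                "abundance": g.abundance,
            }
            for g in community
        ]
    )
    return annotations, quality


# ---------------------------------------------------------------------------
# Random-community simulation
# ---------------------------------------------------------------------------

# Guild-defining archetype gene sets. AOB and AnAOB carry their fixation key
# genes so trophy classification works on simulated genomes too.
GUILD_ARCHETYPES: dict[str, frozenset[str]] = {
    "AOB": frozenset(
        {"amoA", "amoB", "amoC", "amoD", "amoE", "haoA", "nirK", "norB", "norC",
         "rbcL", "rbcS", "prkB"}
    ),
    "AnAOB": frozenset(
        {"hzsA", "hzsB", "hzsC", "hdh", "nxrA_anammox", "nxrB_anammox",
         "acsA", "acsB", "acsE", "fhs"}
    ),
    "denitrifier": frozenset(
        {"narG", "narH", "narI", "narJ", "nirS", "norB", "norC", "nosZ_cladeI"}
    ),
    "DNRA": frozenset({"narG", "narH", "narI", "nrfH", "nrfA"}),
    "nosZII": frozenset({"nosZ_cladeII"}),
    "plain": frozenset(),
}

# Expected guild calls per archetype (the recovery ground truth).
ARCHETYPE_GUILDS: dict[str, frozenset[str]] = {
    "AOB": frozenset({"AOB"}),
    "AnAOB": frozenset({"AnAOB"}),
    "denitrifier": frozenset({"denitrifier_complete"}),
    "DNRA": frozenset({"DNRA_complete"}),
    "nosZII": frozenset(),
    "plain": frozenset(),
}

DEFAULT_GUILD_MIX: dict[str, float] = {
    "AOB": 0.05,
    "AnAOB": 0.05,
    "denitrifier": 0.20,
    "DNRA": 0.10,
    "nosZII": 0.20,
    "plain": 0.40,
}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic community draw.

    ``dropout`` follows the completeness model: every gene of a genome with
    estimated completeness *c* is observed with probability *c*/100,
    independently. The default guild mix mirrors a partial-nitritation/
    anammox reactor: a few autotrophic ammonia oxidizers on a heterotrophic
    background rich in truncated denitrifiers and clade II nosZ carriers.
    """

    n_genomes: int = 100
    guild_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GUILD_MIX)
    )
    completeness_range: tuple[float, float] = (70.0, 100.0)
    dropout: bool = True
    n_accessory: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.guild_mix.values()))
        if not np.isclose(total, 1.0):
            raise ValueError(f"guild_mix proportions sum to {total}, not 1")
        unknown = set(self.guild_mix) - set(GUILD_ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown guilds in mix: {sorted(unknown)}")
        lo, hi = self.completeness_range
        if not (0 <= lo <= hi <= 100):
            raise ValueError(f"bad completeness range {self.completeness_range}")


def simulate_community(
    config: SimulationConfig,
) -> tuple[Community, dict[str, dict]]:
    """Draw a random community with known guild labels.

    Returns ``(community, truth)`` where ``truth[genome_id]`` holds the
    archetype label, the expected guild set and the pre-dropout gene set.
    Identical configs (same seed) produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    labels = list(config.guild_mix)
    probs = np.array([config.guild_mix[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    picks = rng.choice(len(labels), size=config.n_genomes, p=probs)
    lo, hi = config.completeness_range
    genomes = []
    truth: dict[str, dict] = {}
    for i, pick in enumerate(picks):
        label = labels[int(pick)]
        gid = f"SIM{i + 1:04d}"
        completeness = float(rng.uniform(lo, hi))
        accessory = {
            f"acc_{int(k):04d}" for k in rng.integers(0, 5000, size=config.n_accessory)
        }
        true_genes = set(GUILD_ARCHETYPES[label]) | accessory
        if config.dropout:
            keep = rng.random(len(true_genes)) < completeness / 100.0
            observed = {g for g, k in zip(sorted(true_genes), keep) if k}
        else:
            observed = set(true_genes)
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                completeness=completeness,
                contamination=float(rng.uniform(0, 5)),
                genes=frozenset(observed),
            )
        )
        truth[gid] = {
            "label": label,
            "guilds": ARCHETYPE_GUILDS[label],
            "true_genes": frozenset(normalize_gene(g) for g in true_genes),
        }
    community = Community(
        genomes=genomes, provenance=f"simulated community (seed={config.seed})"
    )
    return community, truth


def guild_recovery(
    community: Community,
    truth: Mapping[str, dict],
    marker_map: MarkerMap | None = None,
    defs: Sequence[PathwayDef] | None = None,
) -> float:
    """Fraction of genomes whose predicted guild set equals the ground truth."""
    mm = marker_map or default_marker_map()
    defs = list(defs) if defs is not None else default_pathways()
    cfix = [d for d in defs if d.category == "carbon_fixation"]
    reps = census_community(community, mm)
    hits = 0
    for g in community:
        trophy = classify_trophy(g, cfix)
        predicted = assign_guilds(reps[g.genome_id], trophy).guilds
        if predicted == truth[g.genome_id]["guilds"]:
            hits += 1
    return hits / len(community) if len(community) else float("nan")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reads(
    refs: Sequence[tuple[str, str]],
    n_reads: int,
    read_length: int = 100,
    divergence: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Draw substitution-mutated read substrings from reference sequences.

    Each read is a uniformly placed ``read_length`` window of a uniformly
    chosen reference, mutated by independent substitutions at the given
    rate, and emitted from a random strand. Provenance (reference, start,
    strand) is recorded in the read id for recall computation. Returns
    ``(read_id, sequence)`` pairs; :func:`write_fastq` serializes them.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError(f"divergence {divergence} out of [0, 0.5]")
    if not refs:
        raise ValueError("empty reference set")
    short = [rid for rid, seq in refs if len(seq) < read_length]
    if short:
        raise ValueError(
            f"read length {read_length} exceeds reference length for: {short}"
        )
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        ref_idx = int(rng.integers(len(refs)))
        ref_id, ref_seq = refs[ref_idx]
        start = int(rng.integers(0, len(ref_seq) - read_length + 1))
        window = np.frombuffer(
            ref_seq[start : start + read_length].upper().encode(), dtype=np.uint8
        ).copy()
        if divergence > 0:
            mutate = rng.random(read_length) < divergence
            for j in np.nonzero(mutate)[0]:
                choices = _BASES[_BASES != window[j]]
                window[j] = choices[int(rng.integers(len(choices)))]
        seq = window.tobytes().decode()
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            from .read_screen import reverse_complement

            seq = reverse_complement(seq)
        reads.append((f"read{i + 1:06d}|{ref_id}|{start}|{strand}", seq))
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(seqs: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in seqs:
            fh.write(f">{seq_id}\n{seq}\n")
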