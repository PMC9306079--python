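"""The reticulated nitrogen cycle: per-genome transformation edges over NOx
intermediates, denitrification endpoint prediction, and community-level
exchange-candidate detection.

Each censused marker group licenses a substrate -> product conversion via a
declarative rule table (see ``data/ncycle_rules.yaml``). Anammox nxrAB is
emitted in both directions: its oxidative direction is the community's only
nitrate source, its reductive direction reflects the enzyme's nar homology.
Hydrazine synthase consumes both NO and ammonium, which keeps anammox
genomes visible as NO consumers even when they lack nirK — the genomic
signature behind community NO exchange.

An intermediate is an *exchange candidate* when some genome produces it
without being able to consume it and another consumes it without being able
to produce it. This is genomic potential only; no claim about in-situ flux.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .nitrogen_census import NRepertoire

__all__ = [
    "INTERMEDIATES",
    "DENIT_CHAIN",
    "NTransformation",
    "TransformationRule",
    "ExchangeNetwork",
    "load_rules",
    "default_rules",
    "derive_edges",
    "predict_endpoints",
    "build_exchange_network",
    "export_network",
    "read_edge_table",
]

INTERMEDIATES = frozenset(
    {"NH3", "NH2OH", "NO2-", "NO3-", "NO", "N2O", "N2", "NH4+", "N2H4"}
)

# The linear denitrification chain used for endpoint labelling. DNRA and
# anammox edges are reported but never folded into the chain label.
DENIT_CHAIN = ("NO3-", "NO2-", "NO", "N2O", "N2")
_CHAIN_SHORT = {"NO3-": "NO3", "NO2-": "NO2", "NO": "NO", "N2O": "N2O", "N2": "N2"}

# Marker groups whose edges count as respiratory denitrification steps.
_DENIT_GROUPS = frozenset(
    {
        "narGHIJ",
        "napAB",
        "nxr_like_periplasmic",
        "nirS",
        "nirK",
        "norBC",
        "norZ",
        "nosZ_cladeI",
        "nosZ_cladeII",
    }
)


@dataclass(frozen=True)
class NTransformation:
    """One genome-level conversion edge between nitrogen intermediates."""

    genome_id: str
    substrate: str
    product: str
    enzyme: str  # marker group licensing the edge

    def __post_init__(self) -> None:
        if self.substrate == self.product:
            raise ValueError(f"self-loop on {self.substrate}")
        for x in (self.substrate, self.product):
            if x not in INTERMEDIATES:
                raise ValueError(f"unknown intermediate {x!r}")


@dataclass(frozen=True)
class TransformationRule:
    group: str
    substrates: tuple[str, ...]
    product: str
    reversible: bool = False
    switch: str | None = None


def load_rules(path: str | Path) -> list[TransformationRule]:
    return _parse_rules(yaml.safe_load(Path(path).read_text()))


def default_rules() -> list[TransformationRule]:
    text = resources.files("nguild.data").joinpath("ncycle_rules.yaml").read_text()
    return _parse_rules(yaml.safe_load(text))


def _parse_rules(doc: dict) -> list[TransformationRule]:
    rules = []
    for entry in doc["rules"]:
        subs = entry["substrate"]
        if isinstance(subs, str):
            subs = [subs]
        rule = TransformationRule(
            group=str(entry["group"]),
            substrates=tuple(str(s) for s in subs),
            product=str(entry["product"]),
            reversible=bool(entry.get("reversible", False)),
            switch=entry.get("switch"),
        )
        for x in rule.substrates + (rule.product,):
            if x not in INTERMEDIATES:
                raise ValueError(f"rule for {rule.group}: unknown intermediate {x!r}")
        rules.append(rule)
    return rules


def derive_edges(
    rep: NRepertoire,
    rules: Sequence[TransformationRule] | None = None,
    switches: Mapping[str, bool] | None = None,
) -> list[NTransformation]:
    """Edges licensed by the genome's true marker flags.

    A pure function of the repertoire: community context never changes a
    genome's edges. ``switches`` enables rule-table options (``nxr_as_nar``,
    ``enable_hao_like_edges``); hao-like rules fire when the genome carries
    at least one hao-like paralog.
    """
    rules = default_rules() if rules is None else rules
    switches = dict(switches or {})
    edges: list[NTransformation] = []
    for rule in rules:
        if rule.switch and not switches.get(rule.switch, False):
            continue
        if rule.group == "hao_like":
            active = rep.hao_like_count > 0
        else:
            if rule.group not in rep.flags:
                raise ValueError(f"rule references unknown marker group {rule.group!r}")
            active = rep[rule.group]
        if not active:
            continue
        for sub in rule.substrates:
            edges.append(
                NTransformation(
                    genome_id=rep.genome_id,
                    substrate=sub,
                    product=rule.product,
                    enzyme=rule.group,
                )
            )
            if rule.reversible:
                edges.append(
                    NTransformation(
                        genome_id=rep.genome_id,
                        substrate=rule.product,
                        product=sub,
                        enzyme=rule.group,
                    )
                )
    return edges


def predict_endpoints(edges: Iterable[NTransformation]) -> str:
    """Denitrification-class label from a genome's respiratory chain edges.

    Follows NO3- -> NO2- -> NO -> N2O -> N2 and labels the maximal contiguous
    span(s) the genome can run, e.g. ``"NO3->NO2"``, ``"NO2->N2O"``,
    ``"full"``, ``"none"``; genomes with disjoint spans get a composite label
    such as ``"NO3->NO2+N2O->N2"``.
    """
    steps = [False] * (len(DENIT_CHAIN) - 1)
    for e in edges:
        if e.enzyme not in _DENIT_GROUPS:
            continue
        for i in range(len(DENIT_CHAIN) - 1):
            if e.substrate == DENIT_CHAIN[i] and e.product == DENIT_CHAIN[i + 1]:
                steps[i] = True
    if all(steps):
        return "full"
    if not any(steps):
        return "none"
    spans = []
    i = 0
    while i < len(steps):
        if steps[i]:
            j = i
            while j + 1 < len(steps) and steps[j + 1]:
                j += 1
            spans.append(
                f"{_CHAIN_SHORT[DENIT_CHAIN[i]]}->{_CHAIN_SHORT[DENIT_CHAIN[j + 1]]}"
            )
            i = j + 1
        i += 1
    return "+".join(spans)


@dataclass
class ExchangeNetwork:
    """Bipartite producer/consumer map over nitrogen intermediates."""

    graph: nx.DiGraph
    producers: dict[str, frozenset[str]]
    consumers: dict[str, frozenset[str]]
    donors: dict[str, tuple[str, ...]]  # produce but cannot consume
    acceptors: dict[str, tuple[str, ...]]  # consume but cannot produce
    exchange_candidates: tuple[str, ...]
    edges: list[NTransformation] = field(default_factory=list)

    def report(self) -> dict:
        return {
            "exchange_candidates": [
                {
                    "intermediate": x,
                    "donors": list(self.donors[x]),
                    "acceptors": list(self.acceptors[x]),
                }
                for x in self.exchange_candidates
            ],
            "anammox_attributed_no3_sources": sorted(
                {
                    e.genome_id
                    for e in self.edges
                    if e.enzyme == "nxrAB_anammox"
                    and e.substrate == "NO2-"
                    and e.product == "NO3-"
                }
            ),
        }


def build_exchange_network(edges: Iterable[NTransformation]) -> ExchangeNetwork:
    """Community exchange map from the pooled per-genome edges.

    Donor = genome producing an intermediate it cannot consume; acceptor =
    genome consuming an intermediate it cannot produce; an intermediate with
    at least one of each is an exchange candidate. A genome can never be
    both donor and acceptor for the same intermediate.
    """
    edges = list(edges)
    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    graph = nx.DiGraph()
    for e in edges:
        producers.setdefault(e.product, set()).add(e.genome_id)
        consumers.setdefault(e.substrate, set()).add(e.genome_id)
        graph.add_node(e.genome_id, kind="genome")
        for x in (e.substrate, e.product):
            graph.add_node(x, kind="intermediate")
        graph.add_edge(e.genome_id, e.product, role="produce", enzyme=e.enzyme)
        graph.add_edge(e.substrate, e.genome_id, role="consume", enzyme=e.enzyme)
    intermediates = sorted(set(producers) | set(consumers))
    donors = {}
    acceptors = {}
    candidates = []
    for x in intermediates:
        prod = producers.get(x, set())
        cons = consumers.get(x, set())
        donors[x] = tuple(sorted(prod - cons))
        acceptors[x] = tuple(sorted(cons - prod))
        if donors[x] and acceptors[x]:
            candidates.append(x)
    return ExchangeNetwork(
        graph=graph,
        producers={x: frozenset(producers.get(x, set())) for x in intermediates},
        consumers={x: frozenset(consumers.get(x, set())) for x in intermediates},
        donors=donors,
        acceptors=acceptors,
        exchange_candidates=tuple(candidates),
        edges=edges,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_network(
    net: ExchangeNetwork,
    edge_path: str | Path,
    dot_path: str | Path | None = None,
    report_path: str | Path | None = None,
) -> None:
    """Write the edge list (TSV), a DOT graph description and the JSON
    exchange-candidate report. Output ordering is deterministic."""
    rows = sorted(
        ({"genome_id": e.genome_id, "substrate": e.substrate, "product": e.product,
          "enzyme": e.enzyme} for e in net.edges),
        key=lambda r: (r["genome_id"], r["substrate"], r["product"], r["enzyme"]),
    )
    frame = pd.DataFrame(rows, columns=["genome_id", "substrate", "product", "enzyme"])
    try:
        frame.to_csv(edge_path, sep="\t", index=False)
    except OSError as err:
        raise OSError(f"cannot write edge list to {edge_path}: {err}") from err
    if dot_path is not None:
        Path(dot_path).write_text(_to_dot(net))
    if report_path is not None:
        Path(report_path).write_text(json.dumps(net.report(), indent=1) + "\n")


def _to_dot(net: ExchangeNetwork) -> str:
    """Minimal DOT rendering: genomes as boxes, intermediates as ellipses."""
    lines = ["digraph nox_exchange {"]
    for node in sorted(net.graph.nodes):
        kind = net.graph.nodes[node].get("kind", "genome")
        shape = "ellipse" if kind == "intermediate" else "box"
        lines.append(f'  "{node}" [shape={shape}];')
    for u, v, data in sorted(net.graph.edges(data=True)):
        lines.append(f'  "{u}" -> "{v}" [label="{data.get("enzyme", "")}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def read_edge_table(path: str | Path) -> list[NTransformation]:
    """Read an exported edge list back into transformations (round-trips)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.empty:
        return []
    return [
        NTransformation(
            genome_id=r.genome_id, substrate=r.substrate, product=r.product,
            enzyme=r.enzyme,
        )
        for r in frame.itertuples(index=False)
    ]
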