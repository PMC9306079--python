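"""NOx transformation edges, endpoint labels and the exchange network."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nguild.core_model import Community, GenomeRecord
from nguild.nitrogen_census import census, census_community
from nguild.nox_network import (
    build_exchange_network,
    default_rules,
    derive_edges,
    export_network,
    predict_endpoints,
    read_edge_table,
)


def _edges_for(genes, marker_map, genome_id="X", switches=None):
    rep = census(GenomeRecord(genome_id, genes=frozenset(genes)), marker_map)
    return derive_edges(rep, switches=switches)


class TestDeriveEdges:
    def test_cfx2_truncated_denitrifier(self, fixture_reps):
        edges = derive_edges(fixture_reps["CFX2"])
        pairs = {(e.substrate, e.product) for e in edges}
        assert pairs == {("NO3-", "NO2-"), ("NO2-", "NO")}

    def test_clb1_disjoint_edges(self, fixture_reps):
        edges = derive_edges(fixture_reps["CLB1"])
        pairs = {(e.substrate, e.product) for e in edges}
        assert pairs == {("NO3-", "NO2-"), ("N2O", "N2")}

    def test_empty_repertoire_no_edges(self, marker_map):
        assert _edges_for(set(), marker_map) == []

    def test_anammox_nxr_is_reversible(self, fixture_reps):
        pairs = {(e.substrate, e.product) for e in derive_edges(fixture_reps["AMX2"])}
        assert ("NO2-", "NO3-") in pairs  # the only NO3- source
        assert ("NO3-", "NO2-") in pairs

    def test_hao_like_edges_off_by_default(self, fixture_reps):
        default = {(e.substrate, e.product) for e in derive_edges(fixture_reps["AMX2"])}
        assert ("NH2OH", "NO") not in default
        enabled = {
            (e.substrate, e.product)
            for e in derive_edges(
                fixture_reps["AMX2"], switches={"enable_hao_like_edges": True}
            )
        }
        assert ("NH2OH", "NO") in enabled

    def test_pure_function_of_repertoire(self, fixture_community, fixture_reps):
        # permuting community order leaves per-genome edges unchanged
        reversed_comm = Community(list(fixture_community)[::-1])
        reps2 = census_community(reversed_comm)
        for gid in ("PRO3", "CFX2", "AMX1"):
            assert derive_edges(fixture_reps[gid]) == derive_edges(reps2[gid])


class TestPredictEndpoints:
    def test_aob_is_no2_to_n2o(self, fixture_reps):
        assert predict_endpoints(derive_edges(fixture_reps["AOB1"])) == "NO2->N2O"

    def test_pro3_full_chain(self, fixture_reps):
        assert predict_endpoints(derive_edges(fixture_reps["PRO3"])) == "full"

    def test_clb1_composite_label(self, fixture_reps):
        assert (
            predict_endpoints(derive_edges(fixture_reps["CLB1"]))
            == "NO3->NO2+N2O->N2"
        )

    def test_no_edges_labelled_none(self, marker_map):
        assert predict_endpoints([]) == "none"

    @given(st.lists(st.booleans(), min_size=4, max_size=4))
    @settings(max_examples=30, deadline=None)
    def test_matches_chain_following_oracle(self, marker_map, steps):
        step_genes = [
            {"narG", "narH"},
            {"nirS"},
            {"norB", "norC"},
            {"nosZ_cladeI"},
        ]
        genes = set()
        for on, g in zip(steps, step_genes):
            if on:
                genes |= g
        label = predict_endpoints(_edges_for(genes, marker_map))
        # oracle: walk the boolean chain directly
        chain = ["NO3", "NO2", "NO", "N2O", "N2"]
        spans, i = [], 0
        while i < 4:
            if steps[i]:
                j = i
                while j + 1 < 4 and steps[j + 1]:
                    j += 1
                spans.append(f"{chain[i]}->{chain[j + 1]}")
                i = j
            i += 1
        expected = "full" if all(steps) else ("+".join(spans) or "none")
        assert label == expected


class TestExchangeNetwork:
    def test_no_is_exchange_candidate_with_amx_acceptors(self, fixture_reps):
        edges = [e for rep in fixture_reps.values() for e in derive_edges(rep)]
        net = build_exchange_network(edges)
        assert "NO" in net.exchange_candidates
        assert {"AMX2", "AMX3"} <= set(net.acceptors["NO"])
        assert "AMX1" not in net.acceptors["NO"]  # nirK makes it a producer too

    def test_single_full_genome_has_no_candidates(self, marker_map):
        genes = {"narG", "narH", "nirS", "norB", "norC", "nosZ_cladeI"}
        net = build_exchange_network(_edges_for(genes, marker_map))
        assert net.exchange_candidates == ()

    def test_no_genome_is_both_donor_and_acceptor(self, fixture_reps):
        edges = [e for rep in fixture_reps.values() for e in derive_edges(rep)]
        net = build_exchange_network(edges)
        for x in net.donors:
            assert not set(net.donors[x]) & set(net.acceptors[x])

    def test_nosz_ii_carriers_have_no_no_reduction_edge(self, fixture_reps):
        carriers = [g for g, r in fixture_reps.items() if r["nosZ_cladeII"]]
        assert len(carriers) == 20
        for gid in carriers:
            pairs = {(e.substrate, e.product) for e in derive_edges(fixture_reps[gid])}
            assert ("NO", "N2O") not in pairs

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_flags_equal_brute_force_set_comparison(self, marker_map, data):
        pool = ["narG", "narH", "nirS", "nirK", "norB", "norC", "norZ",
                "nosZ_cladeII", "nrfA", "nrfH"]
        n = data.draw(st.integers(1, 8))
        all_edges = []
        for i in range(n):
            genes = data.draw(st.frozensets(st.sampled_from(pool)))
            all_edges += _edges_for(genes, marker_map, genome_id=f"G{i}")
        net = build_exchange_network(all_edges)
        for x in set(net.producers) | set(net.consumers):
            prod = {e.genome_id for e in all_edges if e.product == x}
            cons = {e.genome_id for e in all_edges if e.substrate == x}
            assert (x in net.exchange_candidates) == bool(prod - cons and cons - prod)


class TestExport:
    def test_roundtrip(self, fixture_reps, tmp_path):
        edges = [e for rep in fixture_reps.values() for e in derive_edges(rep)]
        net = build_exchange_network(edges)
        path = tmp_path / "edges.tsv"
        export_network(net, path, dot_path=tmp_path / "net.dot",
                       report_path=tmp_path / "report.json")
        back = build_exchange_network(read_edge_table(path))
        assert back.exchange_candidates == net.exchange_candidates
        assert back.donors == net.donors
        assert back.acceptors == net.acceptors
        assert (tmp_path / "net.dot").read_text().startswith("digraph")

    def test_empty_network_header_only(self, tmp_path):
        net = build_exchange_network([])
        path = tmp_path / "empty.tsv"
        export_network(net, path)
        lines = path.read_text().strip().splitlines()
        assert lines == ["genome_id\tsubstrate\tproduct\tenzyme"]
        assert read_edge_table(path) == []

    def test_unwritable_path_surfaces_context(self, fixture_reps, tmp_path):
        net = build_exchange_network(derive_edges(fixture_reps["PRO3"]))
        bad = tmp_path / "missing_dir" / "edges.tsv"
        with pytest.raises(OSError, match="edges.tsv"):
            export_network(net, bad)
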