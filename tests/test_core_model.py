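"""Annotation I/O, hit filtering, MAG QC and dereplication."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nguild.core_model import (
    Community,
    FormatError,
    GeneHit,
    GenomeRecord,
    build_community,
    dereplicate,
    filter_hits,
    qc_filter,
    read_annotation_table,
)


def _write_tsv(path, frame):
    frame.to_csv(path, sep="\t", index=False)
    return path


class TestReadAnnotationTable:
    def test_row_count_preserved(self, tmp_path):
        frame = pd.DataFrame(
            {
                "genome_id": ["G1", "G1", "G2"],
                "gene": ["nirK", "narG", "nosZ_cladeII"],
                "evalue": [1e-30, 1e-12, 1e-8],
                "bitscore": [200.0, 90.0, 75.0],
                "identity": [80.0, 55.0, 45.0],
            }
        )
        hits = read_annotation_table(_write_tsv(tmp_path / "a.tsv", frame))
        assert len(hits) == 3
        first = hits[0]
        assert (first.genome_id, first.gene) == ("G1", "nirK")
        assert first.evalue == pytest.approx(1e-30)
        assert (first.bitscore, first.identity) == (200.0, 80.0)

    def test_missing_gene_column_is_format_error(self, tmp_path):
        frame = pd.DataFrame({"genome_id": ["G1"], "symbol": ["nirK"]})
        with pytest.raises(FormatError, match="gene"):
            read_annotation_table(_write_tsv(tmp_path / "bad.tsv", frame))

    def test_presence_only_rows_pass_filter_unconditionally(self, tmp_path):
        frame = pd.DataFrame({"genome_id": ["G1", "G2"], "gene": ["nirK", "narG"]})
        hits = read_annotation_table(_write_tsv(tmp_path / "p.tsv", frame))
        assert filter_hits(hits) == hits

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert read_annotation_table(path) == []


class TestFilterHits:
    @pytest.mark.parametrize(
        "evalue,bitscore,identity,kept",
        [
            (1e-6, 61, 31, True),  # just inside all three thresholds
            (1e-5, 100, 90, False),  # E-value boundary: strict "<"
            (1e-9, 60, 90, False),  # bitscore boundary: strict ">"
            (1e-9, 100, 30, False),  # identity boundary: strict ">"
        ],
    )
    def test_threshold_boundaries(self, evalue, bitscore, identity, kept):
        hit = GeneHit("G1", "nirK", evalue, bitscore, identity)
        assert (filter_hits([hit]) == [hit]) is kept

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1e-3),
                st.floats(0, 200),
                st.floats(0, 100),
            ),
            max_size=100,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_rowwise_predicate_and_is_idempotent(self, rows):
        hits = [GeneHit("G", "x", e, b, i) for e, b, i in rows]
        kept = filter_hits(hits)
        # independent row-by-row re-check of the printed thresholds
        oracle = [h for h in hits if h.evalue < 1e-5 and h.bitscore > 60 and h.identity > 30]
        assert kept == oracle
        assert filter_hits(kept) == kept  # idempotent, order-preserving


class TestQcFilter:
    @pytest.mark.parametrize(
        "completeness,contamination,kept",
        [
            (72, 3, True),  # completeness clause
            (50, 0, True),  # uncontaminated clause
            (50, 1, False),  # fails both
            (70, 5, True),  # "at least 70" is inclusive
        ],
    )
    def test_clauses(self, completeness, contamination, kept):
        community = Community(
            [GenomeRecord("G1", completeness=completeness, contamination=contamination)]
        )
        assert (len(qc_filter(community)) == 1) is kept

    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 20)),
            max_size=50,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_equals_per_genome_predicate(self, rows):
        community = Community(
            [
                GenomeRecord(f"G{i}", completeness=c, contamination=x)
                for i, (c, x) in enumerate(rows)
            ]
        )
        kept = qc_filter(community)
        expected = [
            f"G{i}" for i, (c, x) in enumerate(rows) if c >= 70 or x == 0
        ]
        assert kept.genome_ids() == expected
        assert qc_filter(kept).genome_ids() == expected


class TestDereplicate:
    def test_completeness_ranks_before_contamination(self):
        a = GenomeRecord("G", completeness=90, contamination=2)
        b = GenomeRecord("G", completeness=85, contamination=0)
        # enumerated ranking: (90, -2) > (85, 0) on the first component
        assert dereplicate([a, b]) is a
        assert dereplicate([b, a]) is a

    def test_contamination_breaks_completeness_tie(self):
        a = GenomeRecord("G", completeness=90, contamination=2)
        b = GenomeRecord("G", completeness=90, contamination=1)
        assert dereplicate([a, b]) is b

    def test_single_candidate_and_empty(self):
        only = GenomeRecord("G", completeness=50, contamination=9)
        assert dereplicate([only]) is only
        with pytest.raises(ValueError):
            dereplicate([])

    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 10), st.integers(0, 10**7)),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_returns_an_input_element_that_no_candidate_beats(self, rows):
        cands = [
            GenomeRecord("G", completeness=c, contamination=x, assembly_size=s)
            for c, x, s in rows
        ]
        best = dereplicate(cands)
        assert best in cands
        key = lambda g: (g.completeness, -g.contamination, g.assembly_size)
        assert all(key(best) >= key(c) for c in cands)


class TestBuildCommunity:
    def test_gene_sets_joined_and_normalized(self):
        hits = [GeneHit("G1", "NirK"), GeneHit("G1", "nirk"), GeneHit("G2", "narG")]
        quality = pd.DataFrame(
            {"genome_id": ["G1", "G2"], "completeness": [90, 80], "contamination": [1, 0]}
        )
        community = build_community(hits, quality)
        assert community["G1"].genes == frozenset({"nirk"})  # deduplicated
        assert community["G2"].has_gene("NARG")

    def test_orphan_genomes_rejected(self):
        quality = pd.DataFrame(
            {"genome_id": ["G1"], "completeness": [90], "contamination": [1]}
        )
        with pytest.raises(FormatError, match="G9"):
            build_community([GeneHit("G9", "nirK")], quality)

    def test_duplicate_genome_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Community([GenomeRecord("G1"), GenomeRecord("G1")])

    def test_community_json_roundtrip(self, tmp_path, fixture_community):
        path = tmp_path / "community.json"
        fixture_community.to_json(path)
        back = Community.from_json(path)
        assert back.genome_ids() == fixture_community.genome_ids()
        assert all(
            back[g].genes == fixture_community[g].genes
            for g in back.genome_ids()
        )
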