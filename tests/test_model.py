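"""Readers/writers and domain-record invariants."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import random_network
from gametenet import (
    EvidenceRecord,
    FormatError,
    ProteinRecord,
    ValidationError,
    build_network,
    networks_equal,
    new_network,
    read_annotations,
    read_evidence,
    read_network,
    write_evidence,
    write_network,
)

ANNOT_HEADER = "accession\tgene_symbol\tsignal_peptide\ttransmembrane\tcompartments\n"
EVID_HEADER = (
    "protein_a\tprotein_b\tscore_exp\tscore_db\tmi_score\t"
    "n_publications\tis_physical\tn_conserved_species\n"
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestAnnotations:
    def test_empty_file_yields_empty_list(self, tmp_path):
        assert read_annotations(write(tmp_path, "a.tsv", ANNOT_HEADER)) == []

    def test_row_parsed_field_by_field(self, tmp_path):
        p = write(tmp_path, "a.tsv", ANNOT_HEADER + "P05556\tITGB1\t1\t1\tsperm;egg\n")
        (rec,) = read_annotations(p)
        assert rec == ProteinRecord(
            accession="P05556",
            gene_symbol="ITGB1",
            has_signal_peptide=True,
            has_transmembrane=True,
            compartments=frozenset({"sperm", "egg"}),
        )
        assert rec.is_membrane

    @pytest.mark.parametrize(
        "token,expected",
        [("0", False), ("FALSE", False), ("no", False),
         ("1", True), ("True", True), ("YES", True)],
    )
    def test_boolean_tokens(self, tmp_path, token, expected):
        p = write(tmp_path, "a.tsv", ANNOT_HEADER + f"P1\tG1\t{token}\t0\tsperm\n")
        assert read_annotations(p)[0].has_signal_peptide is expected

    def test_duplicate_accession_rejected(self, tmp_path):
        p = write(
            tmp_path, "a.tsv",
            ANNOT_HEADER + "P05556\tITGB1\t1\t0\tsperm\nP05556\tITGB1\t0\t1\tegg\n",
        )
        with pytest.raises(ValidationError, match="P05556"):
            read_annotations(p)

    def test_missing_column_named_in_error(self, tmp_path):
        p = write(tmp_path, "a.tsv", "accession\tgene_symbol\tsignal_peptide\tcompartments\nA\tg\t0\tsperm\n")
        with pytest.raises(FormatError, match="transmembrane"):
            read_annotations(p)


class TestEvidence:
    def test_header_only_yields_empty_list(self, tmp_path):
        assert read_evidence(write(tmp_path, "e.tsv", EVID_HEADER)) == []

    def test_duplicate_pair_merged_by_max_and_or(self, tmp_path):
        p = write(
            tmp_path, "e.tsv",
            EVID_HEADER
            + "A\tB\t0.5\t0.2\t0.3\t2\t0\t1\n"
            + "B\tA\t0.4\t0.6\t0.5\t5\t1\t0\n",
        )
        (rec,) = read_evidence(p)
        assert rec.pair == ("A", "B")
        assert rec.channel_scores == (0.5, 0.6)
        assert rec.mi_score == 0.5
        assert rec.n_publications == 5
        assert rec.is_physical is True
        assert rec.n_conserved_species == 1

    def test_score_out_of_bounds_reports_row(self, tmp_path):
        p = write(tmp_path, "e.tsv", EVID_HEADER + "A\tB\t1.3\t0.2\t0.3\t1\t0\t0\n")
        with pytest.raises(ValidationError, match=":2"):
            read_evidence(p)

    def test_self_pair_reports_row(self, tmp_path):
        p = write(tmp_path, "e.tsv", EVID_HEADER + "A\tA\t0.3\t0.2\t0.3\t1\t0\t0\n")
        with pytest.raises(ValidationError, match=":2"):
            read_evidence(p)

    def test_na_cells_are_unset(self, tmp_path):
        p = write(tmp_path, "e.tsv", EVID_HEADER + "A\tB\tNA\t0.2\t\t\t0\tNA\n")
        (rec,) = read_evidence(p)
        assert rec.channel_scores == (0.2,)
        assert rec.mi_score == 0.0
        assert rec.n_publications == 0

    def test_parsing_is_order_independent(self, tmp_path, rng):
        rows = [
            f"Q{i:02d}\tQ{j:02d}\t{rng.random():.3f}\t{rng.random():.3f}"
            f"\t{rng.random():.3f}\t{int(rng.integers(0, 9))}"
            f"\t{int(rng.integers(0, 2))}\t{int(rng.integers(0, 4))}\n"
            for i in range(8)
            for j in range(i + 1, 8)
        ]
        p1 = write(tmp_path, "e1.tsv", EVID_HEADER + "".join(rows))
        shuffled = list(rows)
        rng.shuffle(shuffled)
        p2 = write(tmp_path, "e2.tsv", EVID_HEADER + "".join(shuffled))
        assert read_evidence(p1) == read_evidence(p2)

    def test_record_pair_canonicalized(self):
        rec = EvidenceRecord(protein_a="Z", protein_b="A")
        assert rec.pair == ("A", "Z")
        with pytest.raises(ValidationError):
            EvidenceRecord(protein_a="A", protein_b="A")

    def test_write_read_evidence_round_trip_pairs(self, tmp_path, rng):
        records = [
            EvidenceRecord(
                protein_a=f"P{i}", protein_b=f"P{i + 1}",
                channel_scores=(round(float(rng.random()), 6),),
                mi_score=0.5, n_publications=3, is_physical=True,
                n_conserved_species=1,
            )
            for i in range(5)
        ]
        path = tmp_path / "out.tsv"
        write_evidence(records, path)
        back = read_evidence(path)
        assert [r.pair for r in back] == [r.pair for r in records]
        assert all(b.is_physical for b in back)


class TestNetworkIO:
    @pytest.mark.parametrize("fmt", ["sif", "edge-tsv"])
    def test_round_trip_reproduces_network(self, tmp_path, rng, fmt):
        for _ in range(10):
            net = random_network(rng, n_max=25)
            path = tmp_path / f"net.{fmt}"
            write_network(net, path, fmt)
            assert networks_equal(read_network(path, fmt), net)

    def test_isolated_node_survives_sif(self, tmp_path):
        net = new_network(["A", "B", "D"], [("A", "B")])
        path = tmp_path / "net.sif"
        write_network(net, path, "sif")
        assert "D" in path.read_text().splitlines()
        assert networks_equal(read_network(path, "sif"), net)

    def test_triangle_is_three_sif_lines(self, tmp_path):
        net = new_network(edges=[("A", "B"), ("B", "C"), ("A", "C")])
        path = tmp_path / "net.sif"
        write_network(net, path, "sif")
        assert len(path.read_text().splitlines()) == 3

    def test_empty_network_files(self, tmp_path):
        net = new_network()
        write_network(net, tmp_path / "e.sif", "sif")
        assert (tmp_path / "e.sif").read_text() == ""
        write_network(net, tmp_path / "e.tsv", "edge-tsv")
        assert (tmp_path / "e.tsv").read_text() == "protein_a\tprotein_b\n"

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(Exception, match="graphml"):
            write_network(new_network(), tmp_path / "x", "graphml")


class TestBuildNetwork:
    def test_empty_and_path(self):
        assert build_network([]).number_of_nodes() == 0
        net = build_network(
            [EvidenceRecord("A", "B"), EvidenceRecord("B", "C")]
        )
        assert net.number_of_nodes() == 3
        assert net.number_of_edges() == 2

    def test_counts_match_generator(self, rng):
        # 1484 distinct synthetic pairs over 106 proteins
        import networkx as nx

        g = nx.gnm_random_graph(106, 1484, seed=11)
        records = [
            EvidenceRecord(protein_a=f"P{a:03d}", protein_b=f"P{b:03d}")
            for a, b in g.edges
        ]
        net = build_network(records)
        assert net.number_of_nodes() == 106
        assert net.number_of_edges() == 1484

    def test_output_always_simple(self, rng):
        import networkx as nx

        for _ in range(20):
            n = int(rng.integers(2, 20))
            pairs = rng.integers(0, n, size=(30, 2))
            records = [
                EvidenceRecord(protein_a=f"P{a}", protein_b=f"P{b}")
                for a, b in pairs
                if a != b
            ]
            net = build_network(records)
            assert not list(nx.nodes_with_selfloops(net))
            assert net.number_of_edges() == len({frozenset(r.pair) for r in records})
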