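import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import gutmint as gm
from gutmint.reaction_net import (
    HOST,
    HOST_FAMILY,
    DirectionAnnotation,
    ReactionCatalog,
    import_edge_list,
    load_toy_catalog,
)


@pytest.fixture(scope="module")
def toy():
    catalog, annotations, families = load_toy_catalog()
    return catalog, annotations, families


@pytest.fixture(scope="module")
def toy_network(toy):
    catalog, annotations, families = toy
    return gm.build_network(catalog, families, annotations)


def brute_force_main_pair_edges(catalog, included):
    """Direct filter of catalog rows: the edge-inclusion oracle."""
    edges = set()
    for _, row in catalog.reactions.iterrows():
        if not int(row["main_pair"]):
            continue
        a, b = row["metabolite_a"], row["metabolite_b"]
        if a == b:
            continue
        fams = catalog.enzyme_families(row["enzyme_ec"])
        if HOST_FAMILY in fams or fams & included:
            edges.add(frozenset((a, b)))
    return edges


class TestLoadCatalog:
    def test_toy_catalog_has_seven_enzymes(self, toy):
        catalog, _, _ = toy
        assert len(catalog.enzymes) == 7

    def test_empty_reactions_allowed(self, tmp_path):
        (tmp_path / "r.tsv").write_text(
            "reaction_id\tmetabolite_a\tmetabolite_b\tmain_pair\tenzyme_ec\tenzyme_name\n"
        )
        (tmp_path / "l.tsv").write_text("enzyme_ec\torganism_id\n")
        (tmp_path / "f.tsv").write_text("organism_id\tfamily\n")
        catalog = gm.load_catalog(
            tmp_path / "r.tsv", tmp_path / "l.tsv", tmp_path / "f.tsv"
        )
        assert catalog.enzymes == []

    def test_unknown_organism_named_in_error(self, tmp_path, toy):
        catalog, _, _ = toy
        links = pd.concat(
            [
                catalog.enzyme_links,
                pd.DataFrame(
                    [{"enzyme_ec": "1.1.1.1", "organism_id": "mystery_bug"}]
                ),
            ]
        )
        with pytest.raises(ValueError, match="mystery_bug"):
            ReactionCatalog(
                catalog.reactions, links, catalog.organism_families
            )

    def test_duplicate_reactions_deduplicated(self, toy):
        catalog, _, _ = toy
        dup = pd.concat([catalog.reactions, catalog.reactions.iloc[:3]])
        cat2 = ReactionCatalog(
            dup, catalog.enzyme_links, catalog.organism_families
        )
        assert len(cat2.reactions) == len(catalog.reactions)


class TestBuildNetwork:
    def test_narrated_enzyme_linkages_present(self, toy_network):
        net = toy_network
        cases = {
            "2.8.3.1": {"acetate", "lactate", "propionate"},
            "3.5.1.8": {"L-aspartate", "formate"},
            "6.1.2.1": {"L-alanine", "lactate"},
            "1.13.12.4": {"lactate", "acetate"},
            "1.14.14.38": {"L-valine", "L-isoleucine"},
            "6.3.2.11": {"beta-alanine", "3-methylhistidine", "anserine"},
            "3.4.13.20": {"anserine", "beta-alanine", "3-methylhistidine"},
        }
        for ec, mets in cases.items():
            neighbors = {
                nb
                for nb in net.neighbors(ec)
                if net.nodes[nb]["node_type"] == "metabolite"
            }
            assert mets <= neighbors, ec

    def test_carnosine_forward_and_reverse_pairs(self, toy_network):
        net = toy_network
        for pair in [("beta-alanine", "anserine"), ("3-methylhistidine", "anserine")]:
            assert net.has_edge(*pair)
            enzymes = set(net.edges[pair]["enzymes"].split(";"))
            assert {"6.3.2.11", "3.4.13.20"} <= enzymes

    def test_host_only_mode(self, toy):
        catalog, annotations, _ = toy
        net = gm.build_network(catalog, set(), annotations)
        enzymes = {
            n for n, d in net.nodes(data=True) if d["node_type"] == "enzyme"
        }
        # only host-linked enzymes survive
        assert enzymes == {"3.5.1.8", "6.3.2.11", "3.4.13.20"}
        assert HOST in net
        assert not any(
            d["node_type"] == "family" for _, d in net.nodes(data=True)
        )

    def test_family_removal_monotone(self, toy):
        catalog, annotations, families = toy
        full = gm.build_network(catalog, families, annotations)
        smaller = gm.build_network(
            catalog, families - {"Mycobacteriaceae"}, annotations
        )
        assert set(smaller.edges) <= set(full.edges)

    def test_non_main_pair_gives_no_metabolite_edge(self, toy_network):
        assert not toy_network.has_edge("acetate", "CoA")
        assert toy_network.has_edge("2.8.3.1", "CoA")  # still participates

    def test_edge_rule_matches_oracle_on_random_catalogs(self, rng):
        mets = [f"m{i}" for i in range(8)]
        ecs = [f"1.1.1.{i}" for i in range(6)]
        orgs = {f"org{i}": f"fam{i % 5}" for i in range(10)}
        for trial in range(100):
            rows = []
            for j in range(int(rng.integers(1, 50))):
                a, b = rng.choice(mets, 2, replace=True)
                rows.append(
                    {
                        "reaction_id": f"R{j}",
                        "metabolite_a": a,
                        "metabolite_b": b,
                        "main_pair": int(rng.integers(0, 2)),
                        "enzyme_ec": str(rng.choice(ecs)),
                        "enzyme_name": "x",
                    }
                )
            links = []
            for ec in ecs:
                for o in rng.choice(
                    list(orgs) + [HOST], size=int(rng.integers(0, 4)),
                    replace=False,
                ):
                    links.append({"enzyme_ec": ec, "organism_id": o})
            if not links:
                links = [{"enzyme_ec": ecs[0], "organism_id": "org0"}]
            catalog = ReactionCatalog(
                pd.DataFrame(rows),
                pd.DataFrame(links),
                dict(orgs),
            )
            included = set(
                rng.choice(
                    sorted(set(orgs.values())),
                    size=int(rng.integers(0, 5)),
                    replace=False,
                )
            )
            net = gm.build_network(catalog, included)
            got = {
                frozenset((u, v))
                for u, v, d in net.edges(data=True)
                if d.get("kind") == "main_pair"
            }
            assert got == brute_force_main_pair_edges(catalog, included)


class TestFamiliesWithEnzyme:
    def test_formylaspartate_amidohydrolase_counts(self, toy_network, toy):
        _, annotations, _ = toy
        counts = gm.families_with_enzyme(toy_network, "3.5.1.8", annotations)
        assert counts == {"HC": 6, "IBS": 2, "unannotated": 0}

    def test_propionate_coa_transferase_counts(self, toy_network, toy):
        _, annotations, _ = toy
        counts = gm.families_with_enzyme(toy_network, "2.8.3.1", annotations)
        assert counts == {"HC": 13, "IBS": 14, "unannotated": 0}

    def test_counts_sum_to_family_degree(self, toy_network, toy):
        _, annotations, _ = toy
        for ec in ["2.8.3.1", "6.1.2.1", "1.14.14.38"]:
            counts = gm.families_with_enzyme(toy_network, ec, annotations)
            degree = sum(
                1
                for nb in toy_network.neighbors(ec)
                if toy_network.nodes[nb]["node_type"] == "family"
            )
            assert sum(counts.values()) == degree

    def test_host_only_enzyme_zero_counts(self, toy):
        catalog, annotations, _ = toy
        net = gm.build_network(catalog, set(), annotations)
        counts = gm.families_with_enzyme(net, "6.3.2.11", annotations)
        assert counts == {"IBS": 0, "HC": 0, "unannotated": 0}

    def test_absent_enzyme_raises(self, toy_network, toy):
        _, annotations, _ = toy
        with pytest.raises(KeyError):
            gm.families_with_enzyme(toy_network, "9.9.9.9", annotations)


class TestConcordance:
    def test_narrated_concordance_flags(self, toy_network, toy):
        _, annotations, _ = toy
        report = gm.concordance_report(toy_network, annotations).set_index(
            "enzyme_ec"
        )
        assert report.loc["1.13.12.4", "concordant"]  # lactate, acetate: HC
        assert not report.loc["6.1.2.1", "concordant"]  # alanine IBS vs lactate HC
        assert report.loc["1.14.14.38", "concordant"]  # valine+isoleucine IBS
        assert report.loc["6.3.2.11", "concordant"]

    def test_unannotated_network_empty_report(self, toy):
        catalog, _, families = toy
        net = gm.build_network(catalog, families, DirectionAnnotation())
        report = gm.concordance_report(net, DirectionAnnotation())
        assert report.empty


class TestExport:
    def test_edge_list_round_trip_isomorphic(self, toy_network, tmp_path):
        path = tmp_path / "edges.tsv"
        gm.export_network(toy_network, "edgelist", path)
        back = import_edge_list(path)
        assert nx.utils.graphs_equal(
            nx.Graph(
                (u, v) for u, v in toy_network.edges
            ),
            nx.Graph((u, v) for u, v in back.edges),
        )
        assert set(back.nodes) == set(toy_network.nodes)
        for n in back.nodes:
            assert (
                back.nodes[n]["node_type"]
                == toy_network.nodes[n]["node_type"]
            )

    def test_graphml_well_formed(self, toy_network, tmp_path):
        path = tmp_path / "net.graphml"
        gm.export_network(toy_network, "graphml", path)
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == toy_network.number_of_nodes()
        assert back.number_of_edges() == toy_network.number_of_edges()

    def test_tripartite_json_columns(self, toy_network, tmp_path):
        import json

        path = tmp_path / "net.json"
        gm.export_network(toy_network, "tripartite", path)
        payload = json.loads(path.read_text())
        assert list(payload) == ["families", "enzymes", "metabolites"]
        assert HOST in payload["families"]
        assert "acetate" in payload["metabolites"]

    def test_unknown_format_rejected(self, toy_network, tmp_path):
        with pytest.raises(ValueError):
            gm.export_network(toy_network, "dot", tmp_path / "x")
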