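"""Host + microbiome metabolic reaction network construction.

Two metabolites are associated ("main-pair" edge) when a catalog reaction
marks them as the main reactant pair *and* the mediating enzyme is linked
to a human gene or to a gene of an organism whose family is among the
included microbial families.  The resulting graph is tripartite --
families (plus the human host) | enzymes | metabolites -- with family and
metabolite nodes optionally annotated by the case/control direction in
which they are increased.

The catalog is a flat-file snapshot (three TSVs), mirroring KEGG-style
reaction / enzyme / gene-organism records; live database access is out of
scope.  A small hand-transcribed toy catalog ships with the package (see
:func:`load_toy_catalog`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import json

import networkx as nx
import pandas as pd

HOST = "Homo sapiens"
HOST_FAMILY = "host"

DIRECTIONS = ("IBS", "HC")

NODE_TYPES = ("family", "host", "enzyme", "metabolite")


@dataclass
class ReactionCatalog:
    """Flat reaction/enzyme/organism catalog.

    ``reactions`` columns: reaction_id, metabolite_a, metabolite_b,
    main_pair (0/1), enzyme_ec, enzyme_name.  ``enzyme_links`` columns:
    enzyme_ec, organism_id.  ``organism_families`` maps organism id ->
    family label; the human host maps to :data:`HOST_FAMILY`.
    """

    reactions: pd.DataFrame
    enzyme_links: pd.DataFrame
    organism_families: dict[str, str]

    def __post_init__(self) -> None:
        required = [
            "reaction_id",
            "metabolite_a",
            "metabolite_b",
            "main_pair",
            "enzyme_ec",
            "enzyme_name",
        ]
        missing = [c for c in required if c not in self.reactions.columns]
        if missing:
            raise ValueError(f"reactions table lacks columns: {missing}")
        if (self.reactions["enzyme_ec"].astype(str).str.len() == 0).any():
            raise ValueError("empty enzyme_ec in reactions")
        unknown = sorted(
            set(self.enzyme_links["organism_id"])
            - set(self.organism_families)
            - {HOST}
        )
        if unknown:
            raise ValueError(f"unknown organisms in enzyme_links: {unknown}")
        self.reactions = self.reactions.drop_duplicates(
            subset=["metabolite_a", "metabolite_b", "main_pair", "enzyme_ec"]
        ).reset_index(drop=True)

    @property
    def enzymes(self) -> list[str]:
        return sorted(self.reactions["enzyme_ec"].unique())

    def enzyme_families(self, ec: str) -> set[str]:
        """Families (and/or host) with a gene for the enzyme."""
        orgs = self.enzyme_links.loc[
            self.enzyme_links["enzyme_ec"] == ec, "organism_id"
        ]
        out = set()
        for o in orgs:
            out.add(HOST_FAMILY if o == HOST else self.organism_families[o])
        return out


@dataclass
class DirectionAnnotation:
    """Direction (increased-in IBS or HC) for families and metabolites."""

    family: dict[str, str] = field(default_factory=dict)
    metabolite: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping in (self.family, self.metabolite):
            bad = sorted(set(mapping.values()) - set(DIRECTIONS))
            if bad:
                raise ValueError(f"directions must be in {DIRECTIONS}: {bad}")


def load_catalog(
    reactions_path: str | Path,
    enzyme_links_path: str | Path,
    organism_families_path: str | Path,
) -> ReactionCatalog:
    """Load and validate a catalog from its three TSV files."""
    reactions = pd.read_csv(reactions_path, sep="\t", dtype=str)
    if len(reactions):
        reactions["main_pair"] = reactions["main_pair"].astype(int)
    else:
        reactions = pd.DataFrame(
            columns=[
                "reaction_id",
                "metabolite_a",
                "metabolite_b",
                "main_pair",
                "enzyme_ec",
                "enzyme_name",
            ]
        )
    links = pd.read_csv(enzyme_links_path, sep="\t", dtype=str)
    fam = pd.read_csv(organism_families_path, sep="\t", dtype=str)
    if fam.isna().any().any() or (fam["family"].str.len() == 0).any():
        raise ValueError("dangling family reference in organism_families")
    return ReactionCatalog(
        reactions=reactions,
        enzyme_links=links,
        organism_families=dict(zip(fam["organism_id"], fam["family"])),
    )


def load_annotations(path: str | Path) -> DirectionAnnotation:
    """Load a node-direction TSV (columns node_type, node, direction)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fam = {
        r["node"]: r["direction"]
        for _, r in df.iterrows()
        if r["node_type"] == "family"
    }
    met = {
        r["node"]: r["direction"]
        for _, r in df.iterrows()
        if r["node_type"] == "metabolite"
    }
    return DirectionAnnotation(family=fam, metabolite=met)


def _toy_path(name: str) -> Path:
    return Path(resources.files("gutmint").joinpath("data/toy_catalog", name))


def load_toy_catalog() -> tuple[ReactionCatalog, DirectionAnnotation, set[str]]:
    """Bundled toy catalog, its direction annotations and family set.

    Hand-transcribed from the narrated enzyme cases of the study this
    package reimplements (propionate CoA-transferase, N-formylaspartate
    amidohydrolase, alanine-lactate ligase, lactate 2-monooxygenase,
    valine N-monooxygenase, carnosine synthase, beta-alanine-histidine
    dipeptidase).  Families without a name in the narration are synthetic
    placeholders (``ToyHCxx`` / ``ToyIBSxx``) inserted only to reach the
    narrated family counts.
    """
    catalog = load_catalog(
        _toy_path("reactions.tsv"),
        _toy_path("enzyme_links.tsv"),
        _toy_path("organism_families.tsv"),
    )
    annotations = load_annotations(_toy_path("annotations.tsv"))
    families = set(annotations.family)
    return catalog, annotations, families


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def build_network(
    catalog: ReactionCatalog,
    included_families: set[str],
    annotations: DirectionAnnotation | None = None,
) -> nx.Graph:
    """Build the tripartite family-enzyme-metabolite network.

    An enzyme qualifies when it has at least one gene link to the host or
    to an organism whose family is in ``included_families``; enzymes
    without a qualifying link are excluded together with their edges.
    Metabolite-metabolite edges exist exactly for main-pair reactions of
    qualifying enzymes (no self-loops).  Unknown annotation targets are
    dropped.
    """
    annotations = annotations or DirectionAnnotation()
    included = set(included_families)
    net = nx.Graph()
    qualifying: dict[str, set[str]] = {}
    for ec in catalog.enzymes:
        fams = catalog.enzyme_families(ec)
        keep = {f for f in fams if f == HOST_FAMILY or f in included}
        if keep:
            qualifying[ec] = keep
    name_of = dict(
        zip(catalog.reactions["enzyme_ec"], catalog.reactions["enzyme_name"])
    )
    for ec, fams in qualifying.items():
        net.add_node(ec, node_type="enzyme", enzyme_name=name_of.get(ec, ""))
        for f in fams:
            if f == HOST_FAMILY:
                net.add_node(HOST, node_type="host")
                net.add_edge(HOST, ec, kind="has_gene")
            else:
                if f not in net:
                    net.add_node(
                        f,
                        node_type="family",
                        direction=annotations.family.get(f, ""),
                    )
                net.add_edge(f, ec, kind="has_gene")
    for _, row in catalog.reactions.iterrows():
        ec = row["enzyme_ec"]
        if ec not in qualifying:
            continue
        for met in (row["metabolite_a"], row["metabolite_b"]):
            if met not in net:
                net.add_node(
                    met,
                    node_type="metabolite",
                    direction=annotations.metabolite.get(met, ""),
                )
            net.add_edge(ec, met, kind="participates")
        a, b = row["metabolite_a"], row["metabolite_b"]
        if int(row["main_pair"]) and a != b:
            if net.has_edge(a, b):
                enzymes = set(net.edges[a, b].get("enzymes", "").split(";"))
                enzymes.discard("")
            else:
                enzymes = set()
            enzymes.add(ec)
            net.add_edge(
                a, b, kind="main_pair", enzymes=";".join(sorted(enzymes))
            )
    return net


def families_with_enzyme(
    network: nx.Graph, enzyme_ec: str, annotations: DirectionAnnotation
) -> dict[str, int]:
    """Count the enzyme's linked families per direction label.

    Returns ``{"IBS": ..., "HC": ..., "unannotated": ...}``; the host does
    not count as a family.
    """
    if enzyme_ec not in network:
        raise KeyError(f"enzyme {enzyme_ec!r} not in network")
    counts = {"IBS": 0, "HC": 0, "unannotated": 0}
    for nb in network.neighbors(enzyme_ec):
        if network.nodes[nb].get("node_type") != "family":
            continue
        direction = annotations.family.get(nb)
        counts[direction if direction in DIRECTIONS else "unannotated"] += 1
    return counts


def concordance_report(
    network: nx.Graph, annotations: DirectionAnnotation
) -> pd.DataFrame:
    """Per-enzyme direction labels of incident metabolites.

    An enzyme with at least two annotated incident metabolites is
    *concordant* when all share one direction and *discordant* otherwise;
    enzymes with fewer than two annotated metabolites are omitted.
    """
    rows = []
    for node, attrs in network.nodes(data=True):
        if attrs.get("node_type") != "enzyme":
            continue
        mets = [
            nb
            for nb in network.neighbors(node)
            if network.nodes[nb].get("node_type") == "metabolite"
        ]
        labels = sorted(
            annotations.metabolite[m]
            for m in mets
            if m in annotations.metabolite
        )
        if len(labels) < 2:
            continue
        rows.append(
            {
                "enzyme_ec": node,
                "enzyme_name": attrs.get("enzyme_name", ""),
                "n_metabolites": len(mets),
                "directions": ",".join(labels),
                "concordant": len(set(labels)) == 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "enzyme_ec",
            "enzyme_name",
            "n_metabolites",
            "directions",
            "concordant",
        ],
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_network(network: nx.Graph, fmt: str, path: str | Path) -> None:
    """Write the network as ``graphml``, ``edgelist`` TSV or tripartite JSON.

    The edge-list export also writes ``<path>.nodes.tsv`` so that
    :func:`import_edge_list` round-trips losslessly.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "edgelist":
        edges = pd.DataFrame(
            [
                {"source": u, "target": v, **data}
                for u, v, data in network.edges(data=True)
            ]
        )
        edges.to_csv(path, sep="\t", index=False)
        nodes = pd.DataFrame(
            [{"node": n, **data} for n, data in network.nodes(data=True)]
        )
        nodes.to_csv(f"{path}.nodes.tsv", sep="\t", index=False)
    elif fmt == "tripartite":
        cols = {
            "families": sorted(
                [
                    n
                    for n, d in network.nodes(data=True)
                    if d.get("node_type") in ("family", "host")
                ]
            ),
            "enzymes": sorted(
                n
                for n, d in network.nodes(data=True)
                if d.get("node_type") == "enzyme"
            ),
            "metabolites": sorted(
                n
                for n, d in network.nodes(data=True)
                if d.get("node_type") == "metabolite"
            ),
        }
        path.write_text(json.dumps(cols, indent=1))
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_edge_list(path: str | Path) -> nx.Graph:
    """Rebuild a network from an edge-list TSV and its nodes sidecar."""
    path = Path(path)
    edges = pd.read_csv(path, sep="\t", dtype=str)
    nodes = pd.read_csv(f"{path}.nodes.tsv", sep="\t", dtype=str)
    net = nx.Graph()
    for _, row in nodes.iterrows():
        attrs = {
            k: v for k, v in row.items() if k != "node" and pd.notna(v)
        }
        net.add_node(row["node"], **attrs)
    for _, row in edges.iterrows():
        attrs = {
            k: v
            for k, v in row.items()
            if k not in ("source", "target") and pd.notna(v)
        }
        net.add_edge(row["source"], row["target"], **attrs)
    return net
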