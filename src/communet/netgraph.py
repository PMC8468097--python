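"""Metabolite-graph construction.

Networks are compound projections of the reaction set: nodes are compounds,
and a directed edge runs from every substrate of a reaction to every product
(self-pairs skipped).  Each edge carries the set of (reaction_id, ec_id)
witnesses that justify it, so the underlying bipartite structure remains
recoverable.  Three scopes exist: the meta-network built from every EC in
the input table, and the two treatment sub-networks built from the
differentially abundant ECs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import networkx as nx

from .ingest import Association, DifferentialEnzymeTable
from .reactiondb import ReactionDatabase, ec_to_reactions

__all__ = ["MetabolicNetwork", "build_network", "scope_ec_sets", "export_network"]

SCOPES = ("meta", "treatment_1", "treatment_2")


@dataclass
class MetabolicNetwork:
    """Directed metabolite graph with per-edge reaction/EC witnesses."""

    graph: nx.DiGraph
    scope_label: str
    unmatched_ecs: set[str] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def witnesses(self, u: str, v: str) -> set[tuple[str, str]]:
        return self.graph.edges[u, v]["witnesses"]

    def is_empty(self) -> bool:
        return self.graph.number_of_nodes() == 0


def build_network(
    db: ReactionDatabase,
    ecs: Iterable[str],
    scope_label: str = "meta",
) -> MetabolicNetwork:
    """Build the metabolite graph for the reactions annotated with ``ecs``.

    For each matching reaction an edge is added from every substrate to
    every product (Cartesian product; self-pairs skipped); parallel
    witnesses are merged onto a single edge.  An EC set that maps to zero
    reactions yields an empty network with a warning record, not an error.
    """
    ec_set = set(ecs)
    reactions, unmatched = ec_to_reactions(db, ec_set)
    graph: nx.DiGraph = nx.DiGraph()
    for rxn in sorted(reactions, key=lambda r: r.reaction_id):
        witness_ecs = sorted(rxn.ec_ids & ec_set)
        for s in rxn.substrates:
            for p in rxn.products:
                if s == p:
                    continue
                if not graph.has_edge(s, p):
                    graph.add_edge(s, p, witnesses=set())
                graph.edges[s, p]["witnesses"].update(
                    (rxn.reaction_id, ec) for ec in witness_ecs
                )
    net = MetabolicNetwork(graph=graph, scope_label=scope_label, unmatched_ecs=unmatched)
    if not reactions:
        net.warnings.append(
            f"{scope_label}: no reaction matched any of the {len(ec_set)} query ECs"
        )
    return net


def scope_ec_sets(
    table: DifferentialEnzymeTable,
) -> tuple[set[str], set[str], set[str]]:
    """EC sets for the three scopes: (meta = all rows, treatment_1, treatment_2)."""
    meta: set[str] = set()
    t1: set[str] = set()
    t2: set[str] = set()
    for rec in table.records:
        meta.add(rec.ec_id)
        if rec.association is Association.TREATMENT_1:
            t1.add(rec.ec_id)
        elif rec.association is Association.TREATMENT_2:
            t2.add(rec.ec_id)
    return meta, t1, t2


def export_network(net: MetabolicNetwork, out_dir: Union[str, Path], prefix: str) -> list[Path]:
    """Write edge-list and node-list TSVs; deterministic row order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edge_path = out_dir / f"{prefix}_edges.tsv"
    node_path = out_dir / f"{prefix}_nodes.tsv"
    with edge_path.open("w", encoding="utf-8") as fh:
        fh.write("substrate\tproduct\treaction_ids\tec_ids\n")
        for u, v in sorted(net.graph.edges):
            wit = net.graph.edges[u, v]["witnesses"]
            rids = ";".join(sorted({r for r, _ in wit}))
            eids = ";".join(sorted({e for _, e in wit}))
            fh.write(f"{u}\t{v}\t{rids}\t{eids}\n")
    with node_path.open("w", encoding="utf-8") as fh:
        fh.write("compound\n")
        for node in sorted(net.graph.nodes):
            fh.write(f"{node}\n")
    return [edge_path, node_path]
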