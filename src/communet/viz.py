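"""Visualization of expanded treatment networks.

Rendering follows the conventions of the field's network figures: nodes are
metabolites positioned by the Fruchterman-Reingold force-directed layout,
edges carrying differentially abundant enzymes are colored, environmental
resources (seeds) are light-colored, treatment-unique compounds are dark,
and enriched-pathway membership is drawn as a wider background halo circle.
Very-high-degree nodes (currency metabolites such as water) are removed
before layout: a node with more than ``max_neighbors`` distinct neighbors
(direction ignored) is dropped in a single pass.

3-D interactivity is exported as a JSON coordinate/role file any plotting
front-end can consume, plus one sub-graph export per enriched pathway.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import networkx as nx

from .errors import ContractError
from .netgraph import MetabolicNetwork
from .seeds import EnvironmentalProxy

__all__ = [
    "NetworkLayout",
    "Palette",
    "filter_hubs",
    "layout_network",
    "assign_roles",
    "render",
]

logger = logging.getLogger(__name__)

NODE_ROLES = ("seed", "treatment_unique", "shared")
EDGE_ROLES = ("differential", "background")


@dataclass
class Palette:
    """Colors for node/edge roles; user-configurable."""

    seed: str = "#ffd92f"            # light: environmental resources
    treatment_unique: str = "#1f4e79"  # dark: treatment-unique compounds
    shared: str = "#bbbbbb"
    differential_edge: str = "#d95f02"
    background_edge: str = "#dddddd"
    halo: str = "#a6d854"

    def node_color(self, role: str) -> str:
        return {"seed": self.seed, "treatment_unique": self.treatment_unique,
                "shared": self.shared}[role]

    def edge_color(self, role: str) -> str:
        return {"differential": self.differential_edge,
                "background": self.background_edge}[role]


@dataclass
class NetworkLayout:
    """Node positions plus role and halo annotations for one network."""

    positions: dict[str, tuple[float, ...]]
    node_roles: dict[str, str]
    edge_roles: dict[tuple[str, str], str]
    halo_pathways: dict[str, set[str]] = field(default_factory=dict)
    rng_seed: int = 0
    iterations: int = 50
    edges: list[tuple[str, str]] = field(default_factory=list)
    scope_label: str = ""


def filter_hubs(net: MetabolicNetwork, max_neighbors: int = 25) -> MetabolicNetwork:
    """Drop nodes with more than ``max_neighbors`` distinct neighbors.

    Neighbors are counted ignoring edge direction and multiplicity, on the
    *input* graph; removal is single-pass (no cascade from recomputed
    degrees).  Default threshold 25 targets currency metabolites.
    """
    if max_neighbors < 1:
        raise ContractError("max_neighbors must be >= 1")
    undirected = net.graph.to_undirected(as_view=True)
    keep = [n for n in net.graph.nodes if undirected.degree(n) <= max_neighbors]
    sub = net.graph.subgraph(keep).copy()
    return MetabolicNetwork(
        graph=sub,
        scope_label=net.scope_label,
        unmatched_ecs=set(net.unmatched_ecs),
        warnings=list(net.warnings),
    )


def layout_network(
    net: MetabolicNetwork,
    dims: int = 2,
    iterations: int = 50,
    rng_seed: int = 0,
) -> dict[str, tuple[float, ...]]:
    """Fruchterman-Reingold force-directed positions, deterministic per seed.

    ``iterations=0`` returns the seeded initial placement untouched by
    forces.  Nodes are laid out in sorted order so the result depends only
    on the graph, not on insertion history.
    """
    if dims not in (2, 3):
        raise ContractError("dims must be 2 or 3")
    if iterations < 0:
        raise ContractError("iterations must be >= 0")
    if net.is_empty():
        return {}
    # rebuild with sorted node order: spring_layout's random init is
    # assigned in node order, so this makes positions insertion-invariant
    ordered = nx.DiGraph()
    ordered.add_nodes_from(sorted(net.graph.nodes))
    ordered.add_edges_from(sorted(net.graph.edges))
    pos = nx.spring_layout(ordered, dim=dims, iterations=iterations, seed=rng_seed)
    return {node: tuple(float(x) for x in xy) for node, xy in pos.items()}


def assign_roles(
    net: MetabolicNetwork,
    proxy: EnvironmentalProxy,
    unique: Iterable[str],
    differential_ecs: Iterable[str],
) -> tuple[dict[str, str], dict[tuple[str, str], str]]:
    """Classify nodes as seed/treatment_unique/shared and edges as
    differential/background.

    A compound in both the proxy and the unique set is classified as seed
    (and the overlap is logged); an edge is differential iff any of its
    witness ECs is differentially abundant.
    """
    unique_set = set(unique)
    diff_ecs = set(differential_ecs)
    overlap = proxy.compounds & unique_set
    if overlap:
        logger.info(
            "%d compounds in both proxy and unique set classified as seed: %s",
            len(overlap), sorted(overlap)[:5],
        )
    node_roles: dict[str, str] = {}
    for node in net.graph.nodes:
        if node in proxy.compounds:
            node_roles[node] = "seed"
        elif node in unique_set:
            node_roles[node] = "treatment_unique"
        else:
            node_roles[node] = "shared"
    edge_roles: dict[tuple[str, str], str] = {}
    for u, v in net.graph.edges:
        witness_ecs = {ec for _, ec in net.graph.edges[u, v]["witnesses"]}
        edge_roles[(u, v)] = "differential" if witness_ecs & diff_ecs else "background"
    return node_roles, edge_roles


def _safe_pathway_name(pathway: str) -> str:
    return re.sub(r"\s+", "_", pathway.strip())


def render(
    layout: NetworkLayout,
    out_dir: Union[str, Path],
    prefix: str,
    palette: Palette | None = None,
    enriched_pathways: Iterable[str] = (),
) -> list[Path]:
    """Write the 2-D raster, the 3-D-style coordinate/role JSON export, and
    one sub-graph JSON per enriched pathway (indexed 0..k-1).

    The JSON exports are a pure function of (layout, palette): identical
    inputs give byte-identical files.  An empty layout produces a
    placeholder image with a warning instead of crashing.
    """
    palette = palette or Palette()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    png_path = out_dir / f"{prefix}_network.png"
    fig, ax = plt.subplots(figsize=(7, 7))
    if not layout.positions:
        ax.text(0.5, 0.5, "empty network", ha="center", va="center", fontsize=14)
        ax.set_axis_off()
        logger.warning("rendering placeholder for empty network %s", prefix)
    else:
        xy = {n: p[:2] for n, p in layout.positions.items()}
        for (u, v) in layout.edges:
            if u in xy and v in xy:
                ax.plot(
                    [xy[u][0], xy[v][0]], [xy[u][1], xy[v][1]],
                    color=palette.edge_color(layout.edge_roles.get((u, v), "background")),
                    linewidth=0.6, zorder=1,
                )
        # halos first (wider background circles), then the nodes on top
        halo_nodes = [n for n in xy if layout.halo_pathways.get(n)]
        if halo_nodes:
            ax.scatter(
                [xy[n][0] for n in halo_nodes], [xy[n][1] for n in halo_nodes],
                s=160, color=palette.halo, zorder=2, linewidths=0,
            )
        for role in NODE_ROLES:
            nodes = [n for n in xy if layout.node_roles.get(n) == role]
            if nodes:
                ax.scatter(
                    [xy[n][0] for n in nodes], [xy[n][1] for n in nodes],
                    s=40, color=palette.node_color(role), label=role, zorder=3,
                    linewidths=0,
                )
        ax.legend(fontsize=8)
        ax.set_axis_off()
    fig.savefig(png_path, dpi=130)
    plt.close(fig)
    written.append(png_path)

    export = {
        "scope": layout.scope_label,
        "rng_seed": layout.rng_seed,
        "iterations": layout.iterations,
        "nodes": [
            {
                "id": n,
                "position": list(layout.positions[n]),
                "role": layout.node_roles.get(n, "shared"),
                "halo_pathways": sorted(layout.halo_pathways.get(n, ())),
            }
            for n in sorted(layout.positions)
        ],
        "edges": [
            {"source": u, "target": v,
             "role": layout.edge_roles.get((u, v), "background")}
            for u, v in sorted(layout.edges)
        ],
        "palette": vars(palette),
    }
    json_path = out_dir / f"3D_network_{prefix}.json"
    json_path.write_text(json.dumps(export, indent=1, sort_keys=True), encoding="utf-8")
    written.append(json_path)

    for i, pathway in enumerate(sorted(set(enriched_pathways))):
        member_nodes = sorted(
            n for n in layout.positions if pathway in layout.halo_pathways.get(n, ())
        )
        member_set = set(member_nodes)
        sub = {
            "scope": layout.scope_label,
            "pathway": pathway,
            "nodes": [
                {
                    "id": n,
                    "position": list(layout.positions[n]),
                    "role": layout.node_roles.get(n, "shared"),
                }
                for n in member_nodes
            ],
            "edges": [
                {"source": u, "target": v,
                 "role": layout.edge_roles.get((u, v), "background")}
                for u, v in sorted(layout.edges)
                if u in member_set and v in member_set
            ],
        }
        sub_path = out_dir / f"3D_network_{prefix}_{i}_{_safe_pathway_name(pathway)}.json"
        sub_path.write_text(json.dumps(sub, indent=1, sort_keys=True), encoding="utf-8")
        written.append(sub_path)
    return written
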