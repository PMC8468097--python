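"""Seed-set (environmental resource) prediction from network topology.

A compound that the community cannot synthesize internally must be taken up
from the environment.  Topologically these are the members of *source*
components of the strongly-connected-component condensation: SCCs with no
incoming edge from any other component.  All members of a multi-node source
SCC are reported, with the component id and size kept as provenance.

Treatment sub-networks are fragmented (they contain only the differentially
abundant reactions), which produces artificial sources; the meta filter
keeps only treatment seeds that are also seeds of the full meta-network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import networkx as nx

from .errors import ContractError
from .netgraph import MetabolicNetwork

__all__ = [
    "EnvironmentalProxy",
    "strongly_connected_components",
    "detect_seeds",
    "apply_meta_filter",
    "write_resources",
]

logger = logging.getLogger(__name__)


@dataclass
class EnvironmentalProxy:
    """Predicted externally consumed compounds for one network scope.

    ``provenance`` maps each compound to the id and size of the source SCC
    it belongs to.  ``filtered`` is True once the meta-network intersection
    filter has been applied.
    """

    compounds: set[str]
    provenance: dict[str, tuple[int, int]]
    scope_label: str
    filtered: bool = False

    def __post_init__(self) -> None:
        missing = self.compounds - set(self.provenance)
        if missing:
            raise ContractError(
                f"provenance missing for seed compounds: {sorted(missing)}"
            )


def strongly_connected_components(net: MetabolicNetwork) -> list[frozenset[str]]:
    """Partition the nodes into SCCs (two nodes share a component iff each
    reaches the other).  Deterministic order: by smallest member."""
    comps = [frozenset(c) for c in nx.strongly_connected_components(net.graph)]
    return sorted(comps, key=min)


def detect_seeds(net: MetabolicNetwork) -> EnvironmentalProxy:
    """Seeds = all members of condensation source components (in-degree 0).

    Empty networks yield an empty proxy.
    """
    comps = strongly_connected_components(net)
    membership = {node: i for i, comp in enumerate(comps) for node in comp}
    # condensation in-degree: does any edge enter the component from outside?
    has_external_in = [False] * len(comps)
    for u, v in net.graph.edges:
        cu, cv = membership[u], membership[v]
        if cu != cv:
            has_external_in[cv] = True
    compounds: set[str] = set()
    provenance: dict[str, tuple[int, int]] = {}
    for i, comp in enumerate(comps):
        if not has_external_in[i]:
            for node in comp:
                compounds.add(node)
                provenance[node] = (i, len(comp))
    return EnvironmentalProxy(
        compounds=compounds,
        provenance=provenance,
        scope_label=net.scope_label,
        filtered=False,
    )


def apply_meta_filter(
    treatment_proxy: EnvironmentalProxy, meta_proxy: EnvironmentalProxy
) -> EnvironmentalProxy:
    """Keep only treatment seeds that are also meta-network seeds.

    Provenance (component id/size) is retained from the treatment proxy.
    """
    if treatment_proxy.scope_label == "meta":
        raise ContractError("treatment proxy must not have scope 'meta'")
    if meta_proxy.scope_label != "meta":
        raise ContractError(
            f"meta proxy has scope {meta_proxy.scope_label!r}, expected 'meta'"
        )
    if treatment_proxy.filtered or meta_proxy.filtered:
        raise ContractError("apply_meta_filter expects unfiltered proxies")
    kept = treatment_proxy.compounds & meta_proxy.compounds
    if not kept and treatment_proxy.compounds:
        logger.warning(
            "meta filter removed every seed of %s (%d candidates)",
            treatment_proxy.scope_label,
            len(treatment_proxy.compounds),
        )
    return EnvironmentalProxy(
        compounds=kept,
        provenance={c: treatment_proxy.provenance[c] for c in kept},
        scope_label=treatment_proxy.scope_label,
        filtered=True,
    )


def write_resources(proxy: EnvironmentalProxy, path: Union[str, Path]) -> Path:
    """Write one compound id per line, sorted, to ``path``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{c}\n" for c in sorted(proxy.compounds)), encoding="utf-8")
    return path
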