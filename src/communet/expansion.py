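"""Network expansion: the producible-compound fixed point.

Starting from a set of precursor compounds (the environmental proxy), every
reaction whose full substrate set is available fires and contributes its
products; rounds repeat until no further reaction can fire.  The result is
the unique least fixed point — independent of reaction order — and models
what a community with a given reaction repertoire can synthesize in a given
environment.  Semantics are purely set-based: no stoichiometry, and a
compound once produced stays available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from .errors import ContractError
from .reactiondb import Reaction, ReactionDatabase, ec_to_reactions
from .seeds import EnvironmentalProxy

__all__ = [
    "ExpansionResult",
    "expand",
    "simulate_treatments",
    "unique_compounds",
    "write_compound_list",
]


@dataclass
class ExpansionResult:
    """Closure of producible compounds and fired reactions from a seed set."""

    producible: set[str]
    fired_reactions: set[str]
    iterations: list[tuple[set[str], set[str]]] = field(default_factory=list)
    scope_label: str = ""
    seeds: set[str] = field(default_factory=set)


def expand(
    reaction_bank: Iterable[Reaction],
    seeds: Iterable[str],
    scope_label: str = "",
) -> ExpansionResult:
    """Run the expansion to its fixed point.

    Each round fires *all* currently feasible unfired reactions (substrates
    fully contained in the pool) and then adds their products; the loop
    terminates when a round fires nothing.  Empty seeds or an empty bank are
    allowed and give the trivial closure.
    """
    bank = list(reaction_bank)
    pool: set[str] = set(seeds)
    pending = list(bank)
    fired: set[str] = set()
    layers: list[tuple[set[str], set[str]]] = []
    while True:
        feasible = [rxn for rxn in pending if rxn.substrates <= pool]
        if not feasible:
            break
        new_compounds: set[str] = set()
        for rxn in feasible:
            new_compounds |= rxn.products
        new_compounds -= pool
        layers.append(({r.reaction_id for r in feasible}, new_compounds))
        fired |= {r.reaction_id for r in feasible}
        pool |= new_compounds
        pending = [rxn for rxn in pending if rxn.reaction_id not in fired]
    return ExpansionResult(
        producible=pool,
        fired_reactions=fired,
        iterations=layers,
        scope_label=scope_label,
        seeds=set(seeds),
    )


def simulate_treatments(
    db: ReactionDatabase,
    meta_ecs: Iterable[str],
    proxy_1: EnvironmentalProxy,
    proxy_2: EnvironmentalProxy,
    auxiliary_seed_compounds: Iterable[str] = (),
) -> tuple[ExpansionResult, ExpansionResult]:
    """Expand the full meta reaction bank under each treatment's environment.

    Both expansions use the identical bank (every reaction reachable from
    ``meta_ecs``); only the seed sets differ.  ``auxiliary_seed_compounds``
    (default empty) are added to both environments, for sensitivity studies.
    """
    for proxy in (proxy_1, proxy_2):
        if not proxy.filtered:
            raise ContractError(
                f"proxy for {proxy.scope_label!r} must be meta-filtered before simulation"
            )
    bank, _ = ec_to_reactions(db, set(meta_ecs))
    bank_sorted = sorted(bank, key=lambda r: r.reaction_id)
    aux = set(auxiliary_seed_compounds)
    result_1 = expand(bank_sorted, proxy_1.compounds | aux, proxy_1.scope_label)
    result_2 = expand(bank_sorted, proxy_2.compounds | aux, proxy_2.scope_label)
    return result_1, result_2


def unique_compounds(
    result_1: ExpansionResult, result_2: ExpansionResult
) -> tuple[set[str], set[str]]:
    """Compounds producible in exactly one of the two expansions."""
    return (
        result_1.producible - result_2.producible,
        result_2.producible - result_1.producible,
    )


def write_compound_list(compounds: Iterable[str], path: Union[str, Path]) -> Path:
    """Write one compound id per line, sorted."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{c}\n" for c in sorted(compounds)), encoding="utf-8")
    return path
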