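"""Shared fixtures and independent oracles for the test-suite.

The oracles here deliberately use different algorithms from the package
(boolean-matrix transitive closure, sequential loop-until-stable expansion,
exact rational hypergeometric sums) so that agreement is meaningful.
"""

from __future__ import annotations

import random
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest

from communet.netgraph import MetabolicNetwork
from communet.reactiondb import Reaction


# ---------------------------------------------------------------------------
# random inputs
# ---------------------------------------------------------------------------


def random_digraph(rng: random.Random, n_max: int = 200) -> nx.DiGraph:
    """Random directed graph without self-loops; size and density vary."""
    n = rng.randint(2, n_max)
    g = nx.DiGraph()
    g.add_nodes_from(f"C{i}" for i in range(n))
    density = rng.choice([0.5, 1.0, 2.0, 3.0])
    m = int(n * density)
    for _ in range(m):
        u, v = rng.sample(range(n), 2)
        g.add_edge(f"C{u}", f"C{v}")
    return g


def as_network(g: nx.DiGraph, scope: str = "meta") -> MetabolicNetwork:
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    for u, v in g.edges:
        h.add_edge(u, v, witnesses={("R0", "1.1.1.1")})
    return MetabolicNetwork(graph=h, scope_label=scope)


def random_reaction_bank(
    rng: random.Random, n_compounds: int = 60, n_reactions: int = 300
) -> list[Reaction]:
    compounds = [f"C{i}" for i in range(n_compounds)]
    bank = []
    for i in range(rng.randint(1, n_reactions)):
        subs = set(rng.sample(compounds, rng.randint(1, 3)))
        prods = set(rng.sample([c for c in compounds if c not in subs], rng.randint(1, 3)))
        bank.append(
            Reaction(f"R{i}", frozenset({f"1.1.1.{i}"}), frozenset(subs), frozenset(prods))
        )
    return bank


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def reachability_matrix(g: nx.DiGraph) -> tuple[list[str], np.ndarray]:
    """Reflexive transitive closure via boolean matrix squaring."""
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for u, v in g.edges:
        reach[index[u], index[v]] = True
    while True:
        nxt = reach | (reach @ reach)
        if np.array_equal(nxt, reach):
            return nodes, reach
        reach = nxt


def brute_force_seeds(g: nx.DiGraph) -> set[str]:
    """A node s is a seed iff no node outside SCC(s) reaches s.

    SCC membership itself is derived from the closure: u ~ v iff each
    reaches the other.
    """
    nodes, reach = reachability_matrix(g)
    mutual = reach & reach.T
    seeds = set()
    for i, s in enumerate(nodes):
        reachers = reach[:, i]
        outside = reachers & ~mutual[:, i]
        if not outside.any():
            seeds.add(s)
    return seeds


def naive_expand(bank: list[Reaction], seeds: set[str]) -> tuple[set[str], set[str]]:
    """Sequential loop-until-stable expansion: sweep the bank in its given
    order, firing each feasible reaction immediately, until a full sweep
    changes nothing."""
    pool = set(seeds)
    fired: set[str] = set()
    changed = True
    while changed:
        changed = False
        for rxn in bank:
            if rxn.reaction_id in fired:
                continue
            if rxn.substrates <= pool:
                fired.add(rxn.reaction_id)
                before = len(pool)
                pool |= rxn.products
                changed = True
    return pool, fired


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n) as a rational number."""
    total = comb(N, n)
    return Fraction(
        sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)), total
    )


def bh_by_hand(ps: list[float]) -> list[float]:
    """Textbook BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * m / rank)
        q[i] = running
    return q


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20210830)


@pytest.fixture(scope="session")
def fixture_db():
    from communet.reactiondb import FixtureSpec, generate_fixture_database

    return generate_fixture_database(
        FixtureSpec(n_compounds=60, n_reactions=70, n_seeds=4, random_seed=7)
    )


@pytest.fixture(scope="session")
def pipeline_inputs(tmp_path_factory, fixture_db):
    """Fixture database + differential table written to disk once."""
    from communet.ingest import write_differential_table
    from communet.reactiondb import generate_fixture_table, write_reaction_database

    db, truth = fixture_db
    root = tmp_path_factory.mktemp("pipeline_inputs")
    write_reaction_database(db, root / "db")
    table = generate_fixture_table(db, random_seed=7)
    write_differential_table(table, root / "diff.csv")
    return root, db, truth, table
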