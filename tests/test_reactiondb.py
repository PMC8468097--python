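"""Reaction-database loading, reversibility split, and fixture generation."""

import random

import pytest

from communet.errors import ContractError, ValidationError
from communet.expansion import expand
from communet.netgraph import build_network
from communet.reactiondb import (
    DatabasePaths,
    FixtureSpec,
    Reaction,
    ec_to_reactions,
    generate_fixture_database,
    generate_fixture_table,
    load_reaction_database,
    write_reaction_database,
)
from communet.seeds import detect_seeds


def write_db_files(tmp_path, reactions, compounds, cpaths="", epaths=""):
    (tmp_path / "reactions.tsv").write_text(reactions)
    (tmp_path / "compounds.tsv").write_text(compounds)
    if cpaths:
        (tmp_path / "pathways_compounds.tsv").write_text(cpaths)
    if epaths:
        (tmp_path / "pathways_ecs.tsv").write_text(epaths)
    return DatabasePaths.in_dir(tmp_path)


class TestLoading:
    def test_single_forward_reaction(self, tmp_path):
        db = load_reaction_database(
            write_db_files(
                tmp_path,
                "R00001 | 1.1.1.1 | C00001 | C00002 | forward\n",
                "C00001\twater\nC00002\tethanol\n",
            )
        )
        assert set(db.reactions) == {"R00001"}
        rxn = db.reactions["R00001"]
        assert rxn.substrates == {"C00001"} and rxn.products == {"C00002"}
        assert not rxn.reversible

    def test_reversible_split_into_two_directed(self, tmp_path):
        db = load_reaction_database(
            write_db_files(
                tmp_path,
                "R00001 | 1.1.1.1 | C00001 | C00002 | reversible\n",
                "C00001\twater\nC00002\tethanol\n",
            )
        )
        assert set(db.reactions) == {"R00001_f", "R00001_r"}
        fwd, rev = db.reactions["R00001_f"], db.reactions["R00001_r"]
        assert fwd.substrates == rev.products == {"C00001"}
        assert fwd.products == rev.substrates == {"C00002"}
        # chemistry conserved: the two halves cover the bidirectional relation
        pairs = {(s, p) for r in (fwd, rev) for s in r.substrates for p in r.products}
        assert pairs == {("C00001", "C00002"), ("C00002", "C00001")}

    def test_dangling_compound_named_in_error(self, tmp_path):
        with pytest.raises(ValidationError, match="C00099"):
            load_reaction_database(
                write_db_files(
                    tmp_path,
                    "R00001 | 1.1.1.1 | C00001 | C00099 | forward\n",
                    "C00001\twater\n",
                )
            )

    def test_duplicate_reaction_id(self, tmp_path):
        with pytest.raises(ValidationError, match="duplicate reaction id"):
            load_reaction_database(
                write_db_files(
                    tmp_path,
                    "R1 | 1.1.1.1 | C1 | C2 | forward\n"
                    "R1 | 1.1.1.2 | C2 | C1 | forward\n",
                    "C1\ta\nC2\tb\n",
                )
            )

    def test_empty_substrate_list_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="non-empty"):
            load_reaction_database(
                write_db_files(
                    tmp_path,
                    "R1 | 1.1.1.1 |  | C2 | forward\n",
                    "C1\ta\nC2\tb\n",
                )
            )

    def test_bad_direction_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="direction"):
            load_reaction_database(
                write_db_files(
                    tmp_path,
                    "R1 | 1.1.1.1 | C1 | C2 | sideways\n",
                    "C1\ta\nC2\tb\n",
                )
            )


def test_reaction_self_conversion_needs_flag():
    with pytest.raises(ValidationError, match="both sides"):
        Reaction("R1", frozenset({"1.1.1.1"}), frozenset({"C1"}), frozenset({"C1", "C2"}))
    rxn = Reaction(
        "R1", frozenset({"1.1.1.1"}), frozenset({"C1"}), frozenset({"C1", "C2"}),
        allow_self_conversion=True,
    )
    assert "C1" in rxn.products


class TestEcToReactions:
    def test_simple_lookup(self, fixture_db):
        db, _ = fixture_db
        any_rxn = next(iter(db.reactions.values()))
        hits, unmatched = ec_to_reactions(db, set(any_rxn.ec_ids))
        assert any_rxn in hits
        assert not unmatched

    def test_empty_query(self, fixture_db):
        db, _ = fixture_db
        hits, unmatched = ec_to_reactions(db, set())
        assert hits == set() and unmatched == set()

    def test_unmatched_ecs_reported_not_raised(self, fixture_db):
        db, _ = fixture_db
        hits, unmatched = ec_to_reactions(db, {"9.9.9.9"})
        assert hits == set() and unmatched == {"9.9.9.9"}

    def test_matches_linear_scan_oracle_on_random_queries(self, fixture_db, rng):
        db, _ = fixture_db
        all_ecs = sorted(db.ecs)
        for _ in range(50):
            query = set(rng.sample(all_ecs, rng.randint(0, len(all_ecs)))) | (
                {"9.9.9.9"} if rng.random() < 0.3 else set()
            )
            expected = {r for r in db.reactions.values() if r.ec_ids & query}
            hits, unmatched = ec_to_reactions(db, query)
            assert hits == expected
            assert unmatched == query - {e for r in expected for e in r.ec_ids}


class TestRoundTrip:
    def test_load_write_load_identity(self, tmp_path, fixture_db):
        db, _ = fixture_db
        paths = write_reaction_database(db, tmp_path / "db")
        assert load_reaction_database(paths) == db


class TestFixtureGenerator:
    def test_chain_topology_plants_chain_head(self):
        db, truth = generate_fixture_database(
            FixtureSpec(n_compounds=5, n_reactions=4, n_seeds=1,
                        fraction_reversible=0.0, fraction_cycles=0.0,
                        random_seed=0)
        )
        assert truth.seed_compounds == {"C00001"}
        assert truth.closure == {f"C{i:05d}" for i in range(1, 6)}

    def test_same_seed_byte_identical_output(self, tmp_path):
        spec = FixtureSpec(n_compounds=40, n_reactions=40, random_seed=11)
        for d in ("a", "b"):
            db, _ = generate_fixture_database(spec)
            write_reaction_database(db, tmp_path / d)
        for name in ("reactions.tsv", "compounds.tsv",
                     "pathways_compounds.tsv", "pathways_ecs.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_infeasible_spec_raises(self):
        with pytest.raises(ContractError, match="infeasible"):
            generate_fixture_database(
                FixtureSpec(n_compounds=5, n_reactions=50, n_seeds=1,
                            fraction_cycles=0.0)
            )

    def test_planted_truth_consistent_with_detection_and_expansion(self, rng):
        for i in range(10):
            spec = FixtureSpec(
                n_compounds=rng.randint(10, 60),
                n_reactions=rng.randint(8, 60),
                n_seeds=rng.randint(1, 4),
                fraction_reversible=rng.choice([0.0, 0.3]),
                fraction_cycles=rng.choice([0.0, 0.2]),
                random_seed=1000 + i,
            )
            try:
                db, truth = generate_fixture_database(spec)
            except ContractError:
                continue
            net = build_network(db, db.ecs, "meta")
            assert detect_seeds(net).compounds == truth.seed_compounds
            result = expand(db.reactions.values(), truth.seed_compounds)
            assert result.producible == truth.closure


def test_fixture_table_covers_all_database_ecs(fixture_db):
    db, _ = fixture_db
    table = generate_fixture_table(db, random_seed=5)
    assert {r.ec_id for r in table.records} == db.ecs
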