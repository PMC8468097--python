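"""Reaction database: EC -> directed reactions, plus pathway annotations.

The database is the biochemical reference frame the tool operates in: every
enzyme (EC number) maps to one or more reactions, each converting a set of
substrate compounds into a set of product compounds.  Reversible reactions
are materialized as two directed reactions (suffixes ``_f``/``_r``) because
seed detection and expansion both need explicit direction.

A small pipe/tab-delimited flat dialect is defined so the database can live
in version-controlled text files:

* ``reactions.tsv``   — reaction_id | ECs (;-separated) | substrates (;) |
  products (;) | direction in {forward, reversible}
* ``compounds.tsv``   — compound_id | display name
* ``pathways_compounds.tsv`` — compound_id | pathway name
* ``pathways_ecs.tsv``       — ec | pathway name

Fields may be separated by tabs or by ``|`` (surrounding whitespace is
stripped); blank lines and ``#`` comments are ignored.

The module also provides a deterministic fixture generator that plants a
known seed set and expansion closure, used throughout the test-suite as
ground truth.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .errors import ContractError, ValidationError

__all__ = [
    "Reaction",
    "ReactionDatabase",
    "DatabasePaths",
    "FixtureSpec",
    "FixtureGroundTruth",
    "load_reaction_database",
    "write_reaction_database",
    "ec_to_reactions",
    "generate_fixture_database",
    "generate_fixture_table",
]


@dataclass(frozen=True)
class Reaction:
    """A directed reaction: all substrates are jointly converted to all products."""

    reaction_id: str
    ec_ids: frozenset[str]
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False
    allow_self_conversion: bool = False

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValidationError(
                f"reaction {self.reaction_id}: substrate and product sets must be non-empty"
            )
        overlap = self.substrates & self.products
        if overlap and not self.allow_self_conversion:
            raise ValidationError(
                f"reaction {self.reaction_id}: compounds {sorted(overlap)} appear "
                "on both sides (set allow_self_conversion to permit)"
            )


@dataclass
class ReactionDatabase:
    """Directed reactions keyed by id, with compound and pathway annotations."""

    reactions: dict[str, Reaction]
    compound_names: dict[str, str]
    compound_pathways: dict[str, set[str]] = field(default_factory=dict)
    ec_pathways: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dangling = sorted(
            {
                c
                for rxn in self.reactions.values()
                for c in rxn.substrates | rxn.products
                if c not in self.compound_names
            }
        )
        if dangling:
            raise ValidationError(
                "reactions reference compounds absent from the compound list: "
                + ", ".join(dangling)
            )

    @property
    def compounds(self) -> set[str]:
        return set(self.compound_names)

    @property
    def ecs(self) -> set[str]:
        return {ec for rxn in self.reactions.values() for ec in rxn.ec_ids}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionDatabase):
            return NotImplemented
        return (
            self.reactions == other.reactions
            and self.compound_names == other.compound_names
            and self.compound_pathways == other.compound_pathways
            and self.ec_pathways == other.ec_pathways
        )


@dataclass
class DatabasePaths:
    """Locations of the four flat files making up one database."""

    reactions: Path
    compounds: Path
    compound_pathways: Path | None = None
    ec_pathways: Path | None = None

    @classmethod
    def in_dir(cls, directory: Union[str, Path]) -> "DatabasePaths":
        d = Path(directory)
        cp = d / "pathways_compounds.tsv"
        ep = d / "pathways_ecs.tsv"
        return cls(
            reactions=d / "reactions.tsv",
            compounds=d / "compounds.tsv",
            compound_pathways=cp if cp.exists() else None,
            ec_pathways=ep if ep.exists() else None,
        )


_FIELD_SPLIT = re.compile(r"\t|\|")


def _rows(path: Path, n_fields: int) -> Iterable[list[str]]:
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in _FIELD_SPLIT.split(line)]
        if len(parts) != n_fields:
            raise ValidationError(
                f"{path.name}:{lineno}: expected {n_fields} fields, got {len(parts)}"
            )
        yield parts


def _split_ids(cell: str) -> frozenset[str]:
    return frozenset(x.strip() for x in cell.split(";") if x.strip())


def load_reaction_database(paths: DatabasePaths) -> ReactionDatabase:
    """Load the flat-file dialect, splitting reversible reactions into the
    two directed halves ``<id>_f`` and ``<id>_r``."""
    compound_names: dict[str, str] = {}
    for cid, name in _rows(paths.compounds, 2):
        compound_names[cid] = name

    reactions: dict[str, Reaction] = {}
    for rid, ecs, subs, prods, direction in _rows(paths.reactions, 5):
        if direction not in ("forward", "reversible"):
            raise ValidationError(
                f"reaction {rid}: direction must be 'forward' or 'reversible', "
                f"got {direction!r}"
            )
        ec_ids = _split_ids(ecs)
        substrates = _split_ids(subs)
        products = _split_ids(prods)
        if direction == "reversible":
            halves = [
                Reaction(f"{rid}_f", ec_ids, substrates, products, reversible=True),
                Reaction(f"{rid}_r", ec_ids, products, substrates, reversible=True),
            ]
        else:
            halves = [Reaction(rid, ec_ids, substrates, products, reversible=False)]
        for rxn in halves:
            if rxn.reaction_id in reactions:
                raise ValidationError(f"duplicate reaction id {rxn.reaction_id}")
            reactions[rxn.reaction_id] = rxn

    compound_pathways: dict[str, set[str]] = {}
    if paths.compound_pathways is not None:
        for cid, pathway in _rows(paths.compound_pathways, 2):
            compound_pathways.setdefault(cid, set()).add(pathway)
    ec_pathways: dict[str, set[str]] = {}
    if paths.ec_pathways is not None:
        for ec, pathway in _rows(paths.ec_pathways, 2):
            ec_pathways.setdefault(ec, set()).add(pathway)

    return ReactionDatabase(
        reactions=reactions,
        compound_names=compound_names,
        compound_pathways=compound_pathways,
        ec_pathways=ec_pathways,
    )


def write_reaction_database(db: ReactionDatabase, directory: Union[str, Path]) -> DatabasePaths:
    """Write the database back to the flat-file dialect (round-trip partner
    of :func:`load_reaction_database`).  Reversible halves are re-merged onto
    one line by their shared base id."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    lines = []
    emitted: set[str] = set()
    for rid in sorted(db.reactions):
        rxn = db.reactions[rid]
        if rxn.reversible:
            base = rid[:-2]  # strip _f / _r
            if base in emitted:
                continue
            emitted.add(base)
            fwd = db.reactions[f"{base}_f"]
            lines.append(
                "\t".join(
                    [
                        base,
                        ";".join(sorted(fwd.ec_ids)),
                        ";".join(sorted(fwd.substrates)),
                        ";".join(sorted(fwd.products)),
                        "reversible",
                    ]
                )
            )
        else:
            lines.append(
                "\t".join(
                    [
                        rid,
                        ";".join(sorted(rxn.ec_ids)),
                        ";".join(sorted(rxn.substrates)),
                        ";".join(sorted(rxn.products)),
                        "forward",
                    ]
                )
            )
    (directory / "reactions.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    (directory / "compounds.tsv").write_text(
        "\n".join(f"{cid}\t{db.compound_names[cid]}" for cid in sorted(db.compound_names))
        + "\n",
        encoding="utf-8",
    )
    (directory / "pathways_compounds.tsv").write_text(
        "".join(
            f"{cid}\t{pw}\n"
            for cid in sorted(db.compound_pathways)
            for pw in sorted(db.compound_pathways[cid])
        ),
        encoding="utf-8",
    )
    (directory / "pathways_ecs.tsv").write_text(
        "".join(
            f"{ec}\t{pw}\n"
            for ec in sorted(db.ec_pathways)
            for pw in sorted(db.ec_pathways[ec])
        ),
        encoding="utf-8",
    )
    return DatabasePaths.in_dir(directory)


def ec_to_reactions(
    db: ReactionDatabase, ecs: Iterable[str]
) -> tuple[set[Reaction], set[str]]:
    """Return every reaction whose EC annotation intersects ``ecs``, plus the
    set of query ECs that matched no reaction (reported, not an error)."""
    query = set(ecs)
    hits: set[Reaction] = set()
    matched: set[str] = set()
    for rxn in db.reactions.values():
        common = rxn.ec_ids & query
        if common:
            hits.add(rxn)
            matched |= common
    return hits, query - matched


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for a synthetic reaction database with planted structure."""

    n_compounds: int = 40
    n_reactions: int = 50
    n_seeds: int = 3
    fraction_reversible: float = 0.2
    fraction_cycles: float = 0.2
    n_pathways: int = 5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_compounds, self.n_reactions, self.n_pathways) < 1:
            raise ContractError("all fixture counts must be positive")
        if not 0 <= self.fraction_reversible <= 1:
            raise ContractError("fraction_reversible must lie in [0, 1]")
        if not 0 <= self.fraction_cycles < 1:
            raise ContractError("fraction_cycles must lie in [0, 1)")
        if self.n_seeds < 1 or self.n_seeds >= self.n_compounds:
            raise ContractError("need 1 <= n_seeds < n_compounds")


@dataclass
class FixtureGroundTruth:
    """What the generator planted: true seeds and true expansion closure."""

    seed_compounds: set[str]
    closure: set[str]
    ecs: set[str]


def generate_fixture_database(
    spec: FixtureSpec,
) -> tuple[ReactionDatabase, FixtureGroundTruth]:
    """Build a deterministic synthetic database with known topology.

    Construction invariants that make the ground truth exact:

    * the first ``n_seeds`` compounds are sources: they appear only as
      substrates, never as products, so each is a singleton source SCC and
      must be detected as a seed;
    * every other compound that enters the network is first introduced as the
      product of a reaction whose substrates are already producible, so the
      expansion closure from the planted seeds is exactly the set of
      compounds that occur in reactions;
    * cycle reactions and reversible flags are only added where they create
      no new incoming edge into a source and produce only already-producible
      compounds, leaving both ground truths intact.

    Raises :class:`ContractError` when more growth reactions are requested
    than there are compounds left to introduce.
    """
    rng = random.Random(spec.random_seed)
    compounds = [f"C{i + 1:05d}" for i in range(spec.n_compounds)]
    sources = compounds[: spec.n_seeds]
    pool = list(sources)  # producible so far, in introduction order
    unproduced = compounds[spec.n_seeds:]

    n_cycle = int(round(spec.n_reactions * spec.fraction_cycles))
    n_growth = spec.n_reactions - n_cycle
    if n_growth < spec.n_seeds:
        raise ContractError(
            "fixture needs at least one growth reaction per planted seed "
            f"({n_growth} growth reactions < {spec.n_seeds} seeds)"
        )
    if n_growth > len(unproduced):
        raise ContractError(
            f"infeasible spec: {n_growth} growth reactions but only "
            f"{len(unproduced)} compounds available to introduce"
        )

    reactions: dict[str, Reaction] = {}
    rxn_index = 0

    def add_reaction(subs: set[str], prods: set[str], reversible: bool) -> None:
        nonlocal rxn_index
        rxn_index += 1
        rid = f"R{rxn_index:05d}"
        ec = f"{1 + rxn_index % 6}.{1 + rxn_index % 9}.{1 + rxn_index % 9}.{rxn_index}"
        if reversible:
            reactions[f"{rid}_f"] = Reaction(
                f"{rid}_f", frozenset({ec}), frozenset(subs), frozenset(prods), True
            )
            reactions[f"{rid}_r"] = Reaction(
                f"{rid}_r", frozenset({ec}), frozenset(prods), frozenset(subs), True
            )
        else:
            reactions[rid] = Reaction(
                rid, frozenset({ec}), frozenset(subs), frozenset(prods), False
            )

    # Growth phase: each reaction introduces exactly one new compound from
    # substrates already in the pool.  The first reactions consume each
    # source in turn so every source actually appears in the network.
    for i in range(n_growth):
        new = unproduced.pop(0)
        if i < len(sources):
            subs = {sources[i]}
        else:
            k = min(len(pool), rng.choice([1, 1, 2]))
            subs = set(rng.sample(pool, k))
        # reversible only when no substrate is a source (the reverse half
        # would add an incoming edge to it, breaking its seed status)
        reversible = (
            not (subs & set(sources))
            and rng.random() < spec.fraction_reversible
        )
        add_reaction(subs, {new}, reversible)
        pool.append(new)

    # Cycle phase: back-edges among producible non-source compounds only.
    non_source_pool = [c for c in pool if c not in sources]
    for _ in range(n_cycle):
        if len(non_source_pool) < 2:
            break
        a, b = rng.sample(non_source_pool, 2)
        add_reaction({a}, {b}, rng.random() < spec.fraction_reversible)

    closure = set(pool)
    compound_names = {c: f"compound {c[1:].lstrip('0') or '0'}" for c in compounds}

    pathways = [f"pathway_{chr(ord('A') + i % 26)}{i // 26 or ''}" for i in range(spec.n_pathways)]
    compound_pathways: dict[str, set[str]] = {}
    for c in compounds:
        if rng.random() < 0.8:
            compound_pathways[c] = set(rng.sample(pathways, rng.choice([1, 1, 2]) if spec.n_pathways > 1 else 1))
    ecs = {ec for rxn in reactions.values() for ec in rxn.ec_ids}
    ec_pathways: dict[str, set[str]] = {}
    for ec in sorted(ecs):
        if rng.random() < 0.8:
            ec_pathways[ec] = set(rng.sample(pathways, rng.choice([1, 1, 2]) if spec.n_pathways > 1 else 1))

    db = ReactionDatabase(
        reactions=reactions,
        compound_names=compound_names,
        compound_pathways=compound_pathways,
        ec_pathways=ec_pathways,
    )
    truth = FixtureGroundTruth(
        seed_compounds=set(sources), closure=closure, ecs=ecs
    )
    return db, truth


def generate_fixture_table(
    db: ReactionDatabase,
    random_seed: int = 0,
    fractions: tuple[float, float] = (0.3, 0.3),
    treatment_labels: tuple[str, str] = ("treatment_1", "treatment_2"),
):
    """Synthesize a differential-abundance table over the database's ECs.

    Each EC is assigned to treatment_1 / treatment_2 / not_associated with
    probabilities (f1, f2, 1-f1-f2); associated ECs get a larger |logFC| and
    a small adjusted p-value, background ECs the reverse, so the table has
    the qualitative shape of a real differential contrast.
    """
    from .ingest import Association, DifferentialEnzymeRecord, DifferentialEnzymeTable

    f1, f2 = fractions
    if f1 < 0 or f2 < 0 or f1 + f2 > 1:
        raise ContractError("fractions must be non-negative and sum to <= 1")
    rng = random.Random(random_seed)
    records = []
    for ec in sorted(db.ecs):
        u = rng.random()
        if u < f1:
            assoc, sign = Association.TREATMENT_1, 1.0
        elif u < f1 + f2:
            assoc, sign = Association.TREATMENT_2, -1.0
        else:
            assoc, sign = Association.NOT_ASSOCIATED, rng.choice([1.0, -1.0])
        if assoc is Association.NOT_ASSOCIATED:
            log_fc = sign * rng.uniform(0.0, 1.0)
            p = rng.uniform(0.05, 1.0)
        else:
            log_fc = sign * rng.uniform(1.5, 6.0)
            p = rng.uniform(1e-8, 0.01)
        records.append(
            DifferentialEnzymeRecord(
                ec_id=ec,
                log_fc=round(log_fc, 4),
                p_value=round(p, 8),
                adj_p_value=round(min(1.0, p * 2), 8),
                association=assoc,
            )
        )
    return DifferentialEnzymeTable(records=records, treatment_labels=treatment_labels)
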