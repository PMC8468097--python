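"""End-to-end orchestration: input table -> full named output file set.

Stages: ingest -> networks (meta + two treatments) -> seed detection and
meta filtering -> expansion under each treatment environment -> treatment-
unique compounds -> pathway enrichment (enzymes, resources, compounds per
treatment) -> visualization.  Every run writes a JSON manifest recording
the configuration, package versions, RNG seed, universe definitions and a
checksum per text output, so identical inputs and config give byte-identical
text outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from . import __version__
from .enrichment import (
    EnrichmentQuery,
    fisher_pathway_enrichment,
    pathway_table,
    rows_to_frame,
)
from .errors import CommunetError, ValidationError
from .expansion import expand, simulate_treatments, unique_compounds, write_compound_list
from .ingest import TableDialect, parse_differential_table, plot_summary, summarize_table
from .netgraph import MetabolicNetwork, build_network, export_network, scope_ec_sets
from .reactiondb import DatabasePaths, ec_to_reactions, load_reaction_database
from .seeds import apply_meta_filter, detect_seeds, write_resources
from .viz import NetworkLayout, Palette, assign_roles, filter_hubs, layout_network, render

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineStageError(CommunetError):
    """An error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything a run needs; serialized verbatim into the manifest."""

    input_path: Path
    database_dir: Path
    output_dir: Path
    treatment_labels: tuple[str, str] = ("treatment_1", "treatment_2")
    min_pathway_size: int = 1
    max_pathway_size: int = 10_000
    excluded_pathways: set[str] = field(default_factory=set)
    alpha: float = 0.05
    hub_max_neighbors: int = 25
    layout_iterations: int = 50
    rng_seed: int = 0
    auxiliary_seed_compounds: set[str] = field(default_factory=set)
    palette: Palette = field(default_factory=Palette)
    dialect: TableDialect = field(default_factory=TableDialect)

    def __post_init__(self) -> None:
        self.input_path = Path(self.input_path)
        self.database_dir = Path(self.database_dir)
        self.output_dir = Path(self.output_dir)
        if self.min_pathway_size > self.max_pathway_size:
            raise ValidationError("min_pathway_size must be <= max_pathway_size")
        if not 0.0 < self.alpha <= 1.0:
            raise ValidationError("alpha must lie in (0, 1]")

    def to_jsonable(self) -> dict:
        return {
            "input_path": str(self.input_path),
            "database_dir": str(self.database_dir),
            "output_dir": str(self.output_dir),
            "treatment_labels": list(self.treatment_labels),
            "min_pathway_size": self.min_pathway_size,
            "max_pathway_size": self.max_pathway_size,
            "excluded_pathways": sorted(self.excluded_pathways),
            "alpha": self.alpha,
            "hub_max_neighbors": self.hub_max_neighbors,
            "layout_iterations": self.layout_iterations,
            "rng_seed": self.rng_seed,
            "auxiliary_seed_compounds": sorted(self.auxiliary_seed_compounds),
            "palette": vars(self.palette),
            "dialect": {
                k: v for k, v in dataclasses.asdict(self.dialect).items()
                if k != "association_synonyms"
            },
        }


_TEXT_SUFFIXES = {".txt", ".csv", ".tsv", ".json"}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the manifest (also written to
    ``manifest.json`` in the output directory)."""

    # --- validate inputs before touching the output directory
    if not config.input_path.exists():
        raise PipelineStageError("ingest", f"input file not found: {config.input_path}")
    db_paths = DatabasePaths.in_dir(config.database_dir)
    for name, p in (("reactions", db_paths.reactions), ("compounds", db_paths.compounds)):
        if not p.exists():
            raise PipelineStageError("reactiondb", f"{name} file not found: {p}")

    label_1, label_2 = config.treatment_labels

    # --- ingest
    try:
        table = parse_differential_table(
            config.input_path, config.dialect, config.treatment_labels
        )
        summary = summarize_table(table)
    except CommunetError as exc:
        raise PipelineStageError("ingest", str(exc)) from exc

    # --- reaction database
    try:
        db = load_reaction_database(db_paths)
    except CommunetError as exc:
        raise PipelineStageError("reactiondb", str(exc)) from exc

    # --- networks
    try:
        meta_ecs, t1_ecs, t2_ecs = scope_ec_sets(table)
        net_meta = build_network(db, meta_ecs, "meta")
        net_1 = build_network(db, t1_ecs, "treatment_1")
        net_2 = build_network(db, t2_ecs, "treatment_2")
    except CommunetError as exc:
        raise PipelineStageError("netgraph", str(exc)) from exc

    # --- seeds + meta filter
    try:
        proxy_meta = detect_seeds(net_meta)
        raw_1 = detect_seeds(net_1)
        raw_2 = detect_seeds(net_2)
        proxy_1 = apply_meta_filter(raw_1, proxy_meta)
        proxy_2 = apply_meta_filter(raw_2, proxy_meta)
    except CommunetError as exc:
        raise PipelineStageError("seeds", str(exc)) from exc

    # --- expansion
    try:
        result_1, result_2 = simulate_treatments(
            db, meta_ecs, proxy_1, proxy_2, config.auxiliary_seed_compounds
        )
        uniq_1, uniq_2 = unique_compounds(result_1, result_2)
        bank, _ = ec_to_reactions(db, meta_ecs)
        union_seeds = (
            proxy_1.compounds | proxy_2.compounds | config.auxiliary_seed_compounds
        )
        union_closure = expand(
            sorted(bank, key=lambda r: r.reaction_id), union_seeds, "union"
        ).producible
    except CommunetError as exc:
        raise PipelineStageError("expansion", str(exc)) from exc

    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    warnings = list(net_meta.warnings) + list(net_1.warnings) + list(net_2.warnings)

    (out / "input_summary.json").write_text(summary.to_json() + "\n", encoding="utf-8")
    written.append(out / "input_summary.json")
    written += plot_summary(summary, out, prefix="input")

    written.append(write_resources(proxy_1, out / f"{label_1}_resources.txt"))
    written.append(write_resources(proxy_2, out / f"{label_2}_resources.txt"))
    written.append(write_compound_list(uniq_1, out / f"{label_1}_compounds.txt"))
    written.append(write_compound_list(uniq_2, out / f"{label_2}_compounds.txt"))
    written += export_network(net_meta, out, "meta")
    written += export_network(net_1, out, label_1)
    written += export_network(net_2, out, label_2)

    # --- enrichment: universes per entity class (documented defaults)
    universes = {
        "enzyme": "all ECs in the input table",
        "resource": "all seed compounds of the meta-network",
        "compound": (
            "all compounds producible in the meta expansion seeded with the "
            "union of both treatment proxies"
        ),
    }
    enriched_compound_pathways: dict[str, list[str]] = {}
    try:
        jobs = [
            (label_1, "Enzymes", t1_ecs, meta_ecs, "enzyme", db.ec_pathways),
            (label_2, "Enzymes", t2_ecs, meta_ecs, "enzyme", db.ec_pathways),
            (label_1, "resources", proxy_1.compounds, proxy_meta.compounds,
             "resource", db.compound_pathways),
            (label_2, "resources", proxy_2.compounds, proxy_meta.compounds,
             "resource", db.compound_pathways),
            (label_1, "compounds", uniq_1, union_closure, "compound", db.compound_pathways),
            (label_2, "compounds", uniq_2, union_closure, "compound", db.compound_pathways),
        ]
        for label, kind, entities, universe, entity_class, pmap in jobs:
            if not universe:
                warnings.append(f"empty universe for {label} {kind}; enrichment skipped")
                rows = []
            else:
                query = EnrichmentQuery(
                    entities=set(entities), entity_class=entity_class,
                    universe=set(universe), scope_label=label,
                )
                rows = fisher_pathway_enrichment(
                    query,
                    pmap,
                    min_size=config.min_pathway_size,
                    max_size=config.max_pathway_size,
                    excluded=config.excluded_pathways,
                    alpha=config.alpha,
                )
            path = out / f"{label}_{kind}_pathway.csv"
            rows_to_frame(rows).to_csv(path, index=False)
            written.append(path)
            map_path = out / f"{label}_{kind}_pathway_map.csv"
            pathway_table(entities, pmap, entity_class, label).to_csv(map_path, index=False)
            written.append(map_path)
            if entity_class == "compound":
                enriched_compound_pathways[label] = [
                    r.pathway for r in rows if r.enriched
                ]
    except CommunetError as exc:
        raise PipelineStageError("enrichment", str(exc)) from exc

    # --- visualization: expansion-derived network per treatment
    try:
        for label, result, proxy, uniq in (
            (label_1, result_1, proxy_1, uniq_1),
            (label_2, result_2, proxy_2, uniq_2),
        ):
            diff_ecs = t1_ecs if label == label_1 else t2_ecs
            sub = MetabolicNetwork(
                graph=net_meta.graph.subgraph(result.producible).copy(),
                scope_label=label,
            )
            filtered = filter_hubs(sub, config.hub_max_neighbors)
            positions = layout_network(
                filtered, dims=2, iterations=config.layout_iterations,
                rng_seed=config.rng_seed,
            )
            node_roles, edge_roles = assign_roles(filtered, proxy, uniq, diff_ecs)
            enriched = enriched_compound_pathways.get(label, [])
            halos = {
                n: {pw for pw in db.compound_pathways.get(n, ()) if pw in enriched}
                for n in filtered.graph.nodes
            }
            layout = NetworkLayout(
                positions=positions,
                node_roles=node_roles,
                edge_roles=edge_roles,
                halo_pathways={n: s for n, s in halos.items() if s},
                rng_seed=config.rng_seed,
                iterations=config.layout_iterations,
                edges=sorted(filtered.graph.edges),
                scope_label=label,
            )
            written += render(
                layout, out, label, palette=config.palette,
                enriched_pathways=enriched,
            )
    except CommunetError as exc:
        raise PipelineStageError("viz", str(exc)) from exc

    manifest = {
        "tool": "communet",
        "version": __version__,
        "config": config.to_jsonable(),
        "rng_seed": config.rng_seed,
        "universe_definitions": universes,
        "universe_sizes": {
            "enzyme": len(meta_ecs),
            "resource": len(proxy_meta.compounds),
            "compound": len(union_closure),
        },
        "counts": {
            "input_records": summary.total,
            f"{label_1}_resources": len(proxy_1.compounds),
            f"{label_2}_resources": len(proxy_2.compounds),
            f"{label_1}_producible": len(result_1.producible),
            f"{label_2}_producible": len(result_2.producible),
            f"{label_1}_unique_compounds": len(uniq_1),
            f"{label_2}_unique_compounds": len(uniq_2),
        },
        "warnings": warnings,
        "files": {
            str(p.relative_to(out)): (
                _sha256(p) if p.suffix in _TEXT_SUFFIXES else f"size:{p.stat().st_size}"
            )
            for p in sorted(set(written))
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
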