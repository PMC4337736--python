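"""End-to-end orchestration from a single YAML configuration.

A run executes: read or simulate datasets -> per-dataset differential
expression -> gene-universe intersection -> GWRS/GWGS integration -> top-K
signature -> gene-set enrichment -> signature-induced network and hubs.
All stage tables are written under the output directory together with a
JSON manifest; identical config plus seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from gwsig import dataset_io, differential_expression as de
from gwsig import enrichment as enr
from gwsig import network_analysis as net
from gwsig import rank_integration as ri
from gwsig import synthetic_data as syn
from gwsig.errors import ConfigurationError, PipelineError

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the top-level seed."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1)[0])


@dataclass
class DatasetEntry:
    dataset_id: str
    matrix: str
    groups: str
    weight: float = 1.0


@dataclass
class GeneSetSimBlock:
    n_sets: int = 50
    set_size: int = 50
    signal_fraction: float = 0.8


@dataclass
class NetworkSimBlock:
    n_hubs: int = 5
    hub_degree: int = 15
    background_edge_prob: float = 0.01


@dataclass
class EnrichmentTask:
    profile: str = "go"
    gmt: Optional[str] = None  # None -> use the simulated collection


@dataclass
class NetworkBlock:
    edges: Optional[str] = None  # None -> use the simulated edge list
    min_score: float = net.DEFAULT_MIN_SCORE
    hub_threshold: int = net.DEFAULT_HUB_THRESHOLD


@dataclass
class PipelineConfig:
    """Validated pipeline parameters (see validate_config)."""

    output_dir: str
    seed: int = 0
    k: int = ri.DEFAULT_SIGNATURE_SIZE
    log_transform: bool = False
    apply_deg_filter: bool = False
    datasets: list[DatasetEntry] = field(default_factory=list)
    simulation: Optional[syn.SimulationConfig] = None
    gene_sets_sim: GeneSetSimBlock = field(default_factory=GeneSetSimBlock)
    network_sim: NetworkSimBlock = field(default_factory=NetworkSimBlock)
    enrichment: list[EnrichmentTask] = field(
        default_factory=lambda: [EnrichmentTask()]
    )
    network: NetworkBlock = field(default_factory=NetworkBlock)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")
        if bool(self.datasets) == bool(self.simulation is not None):
            raise ConfigurationError(
                "exactly one of 'datasets' and 'simulation' must be provided"
            )
        total = sum(d.weight for d in self.datasets)
        if self.datasets:
            if any(d.weight < 0 for d in self.datasets):
                raise ConfigurationError("dataset weights must be non-negative")
            if total <= 0:
                raise ConfigurationError("dataset weights must not all be zero")
            for d in self.datasets:
                d.weight = d.weight / total


_TOP_KEYS = {
    "seed", "output_dir", "k", "log_transform", "apply_deg_filter",
    "datasets", "simulation", "enrichment", "network",
}
_SIM_KEYS = {
    "n_datasets", "genes_per_dataset", "shared_gene_fraction", "n_cases",
    "n_controls", "n_de", "effect_size", "effect_sd", "noise_sd", "seed",
    "gene_sets", "network",
}
_DATASET_KEYS = {"id", "matrix", "groups", "weight"}
_GENESET_KEYS = {"n_sets", "set_size", "signal_fraction"}
_NETSIM_KEYS = {"n_hubs", "hub_degree", "background_edge_prob"}
_ENRICH_KEYS = {"profile", "gmt"}
_NETWORK_KEYS = {"edges", "min_score", "hub_threshold"}


def _check_keys(block: dict, allowed: set[str], where: str, errors: list[str]):
    unknown = sorted(set(block) - allowed)
    if unknown:
        errors.append(f"{where}: unknown key(s) {unknown!r}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default, and cross-check a YAML config.

    All problems are collected and reported in a single error message.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")

    errors: list[str] = []
    _check_keys(raw, _TOP_KEYS, "top level", errors)

    def get_typed(key: str, types: tuple, default: Any) -> Any:
        value = raw.get(key, default)
        if value is not None and not isinstance(value, types):
            errors.append(
                f"'{key}' must be of type {'/'.join(t.__name__ for t in types)}, "
                f"got {type(value).__name__}"
            )
            return default
        return value

    seed = get_typed("seed", (int,), 0)
    k = get_typed("k", (int,), ri.DEFAULT_SIGNATURE_SIZE)
    output_dir = get_typed("output_dir", (str,), "gwsig_output")
    log_transform = bool(get_typed("log_transform", (bool,), False))
    apply_deg_filter = bool(get_typed("apply_deg_filter", (bool,), False))

    datasets: list[DatasetEntry] = []
    for i, entry in enumerate(raw.get("datasets") or []):
        if not isinstance(entry, dict):
            errors.append(f"datasets[{i}]: must be a mapping")
            continue
        _check_keys(entry, _DATASET_KEYS, f"datasets[{i}]", errors)
        for req in ("id", "matrix", "groups"):
            if req not in entry:
                errors.append(f"datasets[{i}]: missing required key '{req}'")
        if all(r in entry for r in ("id", "matrix", "groups")):
            datasets.append(
                DatasetEntry(
                    dataset_id=str(entry["id"]),
                    matrix=str(entry["matrix"]),
                    groups=str(entry["groups"]),
                    weight=float(entry.get("weight", 1.0)),
                )
            )

    simulation: Optional[syn.SimulationConfig] = None
    gene_sets_sim, network_sim = GeneSetSimBlock(), NetworkSimBlock()
    sim_raw = raw.get("simulation")
    if sim_raw is not None:
        if not isinstance(sim_raw, dict):
            errors.append("'simulation' must be a mapping")
        else:
            _check_keys(sim_raw, _SIM_KEYS, "simulation", errors)
            gs_raw = sim_raw.get("gene_sets") or {}
            _check_keys(gs_raw, _GENESET_KEYS, "simulation.gene_sets", errors)
            ns_raw = sim_raw.get("network") or {}
            _check_keys(ns_raw, _NETSIM_KEYS, "simulation.network", errors)
            sim_fields = {
                key: value
                for key, value in sim_raw.items()
                if key in _SIM_KEYS - {"gene_sets", "network"}
            }
            sim_fields.setdefault("seed", derive_seed(seed, "simulation"))
            try:
                simulation = syn.SimulationConfig(**sim_fields)
                gene_sets_sim = GeneSetSimBlock(**gs_raw)
                network_sim = NetworkSimBlock(**ns_raw)
            except (ConfigurationError, TypeError) as exc:
                errors.append(f"simulation: {exc}")

    enrichment: list[EnrichmentTask] = []
    for i, entry in enumerate(raw.get("enrichment") or []):
        if not isinstance(entry, dict):
            errors.append(f"enrichment[{i}]: must be a mapping")
            continue
        _check_keys(entry, _ENRICH_KEYS, f"enrichment[{i}]", errors)
        profile = str(entry.get("profile", "go"))
        if profile not in enr.FILTER_PROFILES:
            errors.append(
                f"enrichment[{i}]: unknown profile '{profile}' "
                f"(choose from {sorted(enr.FILTER_PROFILES)})"
            )
        enrichment.append(EnrichmentTask(profile=profile, gmt=entry.get("gmt")))
    if not enrichment:
        enrichment = [EnrichmentTask()]

    net_raw = raw.get("network") or {}
    network = NetworkBlock()
    if not isinstance(net_raw, dict):
        errors.append("'network' must be a mapping")
    else:
        _check_keys(net_raw, _NETWORK_KEYS, "network", errors)
        network = NetworkBlock(
            edges=net_raw.get("edges"),
            min_score=float(net_raw.get("min_score", net.DEFAULT_MIN_SCORE)),
            hub_threshold=int(
                net_raw.get("hub_threshold", net.DEFAULT_HUB_THRESHOLD)
            ),
        )

    if errors:
        raise ConfigurationError(
            f"invalid configuration {path}:\n  - " + "\n  - ".join(errors)
        )
    try:
        return PipelineConfig(
            output_dir=output_dir,
            seed=seed,
            k=k,
            log_transform=log_transform,
            apply_deg_filter=apply_deg_filter,
            datasets=datasets,
            simulation=simulation,
            gene_sets_sim=gene_sets_sim,
            network_sim=network_sim,
            enrichment=enrichment,
            network=network,
        )
    except ConfigurationError as exc:
        raise ConfigurationError(f"invalid configuration {path}: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the output manifest (also written).

    On a stage failure the partial outputs are kept, the manifest records
    the failing stage, and a PipelineError naming the stage is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "parameters": {
            "k": config.k,
            "log_transform": config.log_transform,
            "apply_deg_filter": config.apply_deg_filter,
            "min_score": config.network.min_score,
            "hub_threshold": config.network.hub_threshold,
        },
        "stages": {},
        "outputs": [],
        "status": "running",
    }

    def record(path: Path) -> Path:
        manifest["outputs"].append(str(path.relative_to(out)))
        return path

    stage = "inputs"
    try:
        truth: Optional[syn.GroundTruth] = None
        sim_gmt_path: Optional[Path] = None
        sim_edges_path: Optional[Path] = None
        if config.simulation is not None:
            datasets, truth = syn.generate_multistudy_expression(config.simulation)
            sim_dir = out / "simulated"
            sim_dir.mkdir(exist_ok=True)
            for ds in datasets:
                dataset_io.write_expression_matrix(
                    ds,
                    record(sim_dir / f"{ds.dataset_id}_matrix.tsv"),
                    record(sim_dir / f"{ds.dataset_id}_groups.tsv"),
                )
        else:
            datasets = [
                dataset_io.read_expression_matrix(
                    d.matrix,
                    d.groups,
                    d.dataset_id,
                    weight=d.weight,
                    log2_transform=config.log_transform,
                )
                for d in config.datasets
            ]
        manifest["stages"]["inputs"] = {
            "n_datasets": len(datasets),
            "genes_per_dataset": {
                ds.dataset_id: len(ds.genes) for ds in datasets
            },
        }
        logger.info(
            "inputs: %d datasets (%s)",
            len(datasets),
            ", ".join(f"{ds.dataset_id}:{len(ds.genes)}" for ds in datasets),
        )

        stage = "differential_expression"
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        tables = {ds.dataset_id: de.compute_de_table(ds) for ds in datasets}

        stage = "intersection"
        common = ri.intersect_genes([ds.genes for ds in datasets])
        if config.apply_deg_filter:
            filtered = [
                set(t.index[t["passes_deg_filter"]]) for t in tables.values()
            ]
            common = ri.intersect_genes([set(common), *filtered])
        manifest["stages"]["intersection"] = {"n_common_genes": len(common)}
        logger.info("intersection: %d common genes", len(common))

        stage = "rank_integration"
        ranked = [
            de.rank_by_fold_change(tables[ds.dataset_id], restrict_to=common)
            for ds in datasets
        ]
        for ds, rl in zip(datasets, ranked):
            de.write_de_table(
                tables[ds.dataset_id], rl, record(de_dir / f"{ds.dataset_id}_de.tsv")
            )
        gwrs = ri.gwrs_matrix(ranked, genes=common)
        gwgs = ri.gwgs_scores(gwrs, weights=[ds.weight for ds in datasets])
        signature = ri.select_top_k(gwgs, config.k)
        integ_dir = out / "integration"
        integ_dir.mkdir(exist_ok=True)
        ri.write_gwgs_table(gwgs, record(integ_dir / "gwgs.tsv"))
        ri.write_signature(
            signature,
            record(integ_dir / "signature.txt"),
            scored_path=record(integ_dir / "signature_scored.tsv"),
        )
        manifest["stages"]["rank_integration"] = {"signature_size": len(signature)}
        logger.info("rank_integration: signature of %d genes", len(signature))

        if config.simulation is not None and truth is not None:
            stage = "simulated_annotations"
            gs = config.gene_sets_sim
            collection = syn.generate_gene_set_collection(
                truth,
                universe=common,
                n_sets=gs.n_sets,
                set_size=gs.set_size,
                signal_fraction=gs.signal_fraction,
                seed=derive_seed(config.seed, "gene_sets"),
            )
            sim_gmt_path = record(out / "simulated" / "gene_sets.gmt")
            enr.write_gmt(collection, sim_gmt_path)
            ns = config.network_sim
            edges, _hubs = syn.generate_interaction_network(
                signature_genes=sorted(truth.de_genes),
                background_genes=common,
                n_hubs=ns.n_hubs,
                hub_degree=ns.hub_degree,
                background_edge_prob=ns.background_edge_prob,
                seed=derive_seed(config.seed, "network"),
                truth=truth,
            )
            sim_edges_path = record(out / "simulated" / "network_edges.tsv")
            net.write_edge_list(edges, sim_edges_path)
            truth.to_json(record(out / "simulated" / "ground_truth.json"))

        stage = "enrichment"
        enr_dir = out / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        enr_counts = {}
        for task in config.enrichment:
            gmt_path = task.gmt or sim_gmt_path
            if gmt_path is None:
                raise ConfigurationError(
                    f"enrichment profile '{task.profile}' has no GMT file and "
                    "no simulated collection is available"
                )
            collection = enr.read_gmt(gmt_path)
            records = enr.enrich_signature(
                signature, collection, profile=task.profile, background=common
            )
            enr.write_enrichment_table(
                records, record(enr_dir / f"{task.profile}.tsv")
            )
            enr_counts[task.profile] = {
                "n_tested": len(records),
                "n_significant": sum(r.significant for r in records),
            }
        manifest["stages"]["enrichment"] = enr_counts

        stage = "network"
        net_dir = out / "network"
        net_dir.mkdir(exist_ok=True)
        edges_path = config.network.edges or sim_edges_path
        if edges_path is None:
            raise ConfigurationError(
                "no edge list configured and no simulated network is available"
            )
        edge_list = net.read_edge_list(edges_path, min_score=config.network.min_score)
        induced = net.induce_subnetwork(edge_list, signature)
        degrees = net.compute_degrees(induced)
        hubs = net.identify_hubs(degrees, threshold=config.network.hub_threshold)
        net.write_sif(induced, record(net_dir / "induced.sif"))
        net.write_node_attributes(
            induced,
            record(net_dir / "node_attributes.tsv"),
            threshold=config.network.hub_threshold,
        )
        net.write_hub_table(
            induced,
            record(net_dir / "hubs.tsv"),
            threshold=config.network.hub_threshold,
        )
        record(net_dir / "isolates.txt").write_text(
            "\n".join(induced.isolates) + ("\n" if induced.isolates else ""),
            encoding="utf-8",
        )
        manifest["stages"]["network"] = {
            "n_nodes": len(induced.nodes),
            "n_edges": induced.n_edges,
            "n_isolates": len(induced.isolates),
            "hubs": hubs,
        }
        logger.info(
            "network: %d nodes, %d edges, %d hub(s)",
            len(induced.nodes), induced.n_edges, len(hubs),
        )

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, out)
        raise PipelineError(stage, str(exc)) from exc

    manifest["outputs"].sort()
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
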