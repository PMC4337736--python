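"""Synthetic multi-study fixtures with planted ground truth.

Generates (a) several two-group log2 expression matrices sharing a common
gene core plus dataset-private noise genes, with a planted subset of
differentially expressed genes; (b) gene-set collections with one planted
enriched set; (c) scored interaction edge lists with planted high-degree
hubs.  Everything is a deterministic function of its configuration and
seed, so downstream stages can be validated against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from gwsig.dataset_io import ExpressionDataset
from gwsig.enrichment import GeneSet, GeneSetCollection
from gwsig.errors import ConfigurationError
from gwsig.network_analysis import Edge, EdgeList

BASELINE_LOW, BASELINE_HIGH = 4.0, 12.0
EDGE_SCORE_LOW = 0.4  # scores drawn uniform in (0.4, 1.0]


@dataclass
class SimulationConfig:
    """Parameters for the multi-study expression simulation.

    The shared gene core has ``round(shared_gene_fraction * min(genes_per_dataset))``
    genes and is present in every dataset; each dataset is padded with
    private pure-noise genes up to its configured size.  Planted genes are
    shifted in the case group by a signed log2 effect whose magnitude is
    ``|effect_size + effect_sd * z|`` with z standard normal, the sign up or
    down with equal probability.
    """

    n_datasets: int = 3
    genes_per_dataset: list[int] = field(default_factory=lambda: [3500, 3300, 3200])
    shared_gene_fraction: float = 0.9375
    n_cases: int = 10
    n_controls: int = 10
    n_de: int = 150
    effect_size: float = 2.0
    effect_sd: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ConfigurationError(f"n_datasets must be >= 1, got {self.n_datasets}")
        if len(self.genes_per_dataset) != self.n_datasets:
            raise ConfigurationError(
                f"genes_per_dataset has {len(self.genes_per_dataset)} entries "
                f"for n_datasets={self.n_datasets}"
            )
        if any(g < 1 for g in self.genes_per_dataset):
            raise ConfigurationError("genes_per_dataset entries must be >= 1")
        if not 0.0 < self.shared_gene_fraction <= 1.0:
            raise ConfigurationError(
                f"shared_gene_fraction must lie in (0, 1], got "
                f"{self.shared_gene_fraction}"
            )
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("n_cases and n_controls must be >= 1")
        if self.n_de < 0:
            raise ConfigurationError(f"n_de must be >= 0, got {self.n_de}")
        if self.noise_sd < 0 or self.effect_sd < 0:
            raise ConfigurationError("noise_sd and effect_sd must be >= 0")
        if self.n_de > self.n_shared:
            raise ConfigurationError(
                f"n_de={self.n_de} exceeds the shared gene universe size "
                f"{self.n_shared}"
            )

    @property
    def n_shared(self) -> int:
        return round(self.shared_gene_fraction * min(self.genes_per_dataset))


@dataclass
class GroundTruth:
    """Planted truth recorded by the generators."""

    de_genes: frozenset[str]
    effects: dict[str, float]  # gene -> signed log2 effect
    seed: int
    planted_set_id: Optional[str] = None
    planted_hubs: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": sorted(self.de_genes),
            "effects": {g: self.effects[g] for g in sorted(self.effects)},
            "planted_set_id": self.planted_set_id,
            "planted_hubs": sorted(self.planted_hubs),
            "seed": self.seed,
        }
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def _shared_gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_multistudy_expression(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Simulate the configured studies and return them with the planted truth.

    Every dataset contains the full shared core plus private genes; planted
    genes have their case-group mean shifted by the same signed effect in
    every dataset.  Identical config (including seed) gives bit-identical
    output.
    """
    root = np.random.SeedSequence(config.seed)
    effect_ss, *dataset_ss = root.spawn(1 + config.n_datasets)
    rng = np.random.default_rng(effect_ss)

    shared = _shared_gene_ids(config.n_shared)
    de_genes = sorted(rng.choice(shared, size=config.n_de, replace=False))
    signs = rng.choice([-1.0, 1.0], size=config.n_de)
    magnitudes = np.abs(
        config.effect_size + config.effect_sd * rng.standard_normal(config.n_de)
    )
    effects = {g: float(s * m) for g, s, m in zip(de_genes, signs, magnitudes)}

    datasets: list[ExpressionDataset] = []
    for j in range(config.n_datasets):
        ds_id = f"DS{j + 1}"
        size = config.genes_per_dataset[j]
        private = [f"{ds_id}_P{i:05d}" for i in range(size - config.n_shared)]
        genes = shared + private
        ds_rng = np.random.default_rng(dataset_ss[j])
        baseline = ds_rng.uniform(BASELINE_LOW, BASELINE_HIGH, size=len(genes))
        n_samples = config.n_cases + config.n_controls
        values = baseline[:, None] + config.noise_sd * ds_rng.standard_normal(
            (len(genes), n_samples)
        )
        gene_index = {g: i for i, g in enumerate(genes)}
        for g, eff in effects.items():
            values[gene_index[g], : config.n_cases] += eff
        samples = [f"{ds_id}_case_{i + 1}" for i in range(config.n_cases)] + [
            f"{ds_id}_ctrl_{i + 1}" for i in range(config.n_controls)
        ]
        group = ["case"] * config.n_cases + ["control"] * config.n_controls
        datasets.append(
            ExpressionDataset(
                dataset_id=ds_id,
                genes=genes,
                samples=samples,
                values=values,
                group=group,
            )
        )

    truth = GroundTruth(
        de_genes=frozenset(de_genes), effects=effects, seed=config.seed
    )
    return datasets, truth


def generate_gene_set_collection(
    truth: GroundTruth,
    universe: Sequence[str],
    n_sets: int,
    set_size: int,
    signal_fraction: float,
    seed: int,
) -> GeneSetCollection:
    """Generate n_sets gene sets over the universe, one enriched for truth.

    The planted set draws ``round(signal_fraction * set_size)`` members from
    the planted differentially expressed genes and the remainder from the
    non-planted universe; all other sets are uniform draws from the whole
    universe.  The planted set's id is recorded in ``truth.planted_set_id``.
    """
    universe = sorted(set(universe))
    if n_sets < 1:
        raise ConfigurationError(f"n_sets must be >= 1, got {n_sets}")
    if not 0 < set_size <= len(universe):
        raise ConfigurationError(
            f"set_size={set_size} must lie in 1..{len(universe)} (universe size)"
        )
    if not 0.0 <= signal_fraction <= 1.0:
        raise ConfigurationError(
            f"signal_fraction must lie in [0, 1], got {signal_fraction}"
        )
    de_in_universe = sorted(truth.de_genes & set(universe))
    n_signal = round(signal_fraction * set_size)
    if n_signal > len(de_in_universe):
        raise ConfigurationError(
            f"planted set needs {n_signal} differentially expressed members "
            f"but only {len(de_in_universe)} are available in the universe"
        )
    non_de = sorted(set(universe) - truth.de_genes)
    if set_size - n_signal > len(non_de):
        raise ConfigurationError(
            f"planted set needs {set_size - n_signal} background members but "
            f"only {len(non_de)} non-planted genes exist"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    planted_index = int(rng.integers(n_sets))
    sets: list[GeneSet] = []
    for i in range(n_sets):
        set_id = f"SET{i + 1:04d}"
        if i == planted_index:
            members = sorted(rng.choice(de_in_universe, n_signal, replace=False))
            members += sorted(
                rng.choice(non_de, set_size - n_signal, replace=False)
            )
            description = "planted"
        else:
            members = sorted(rng.choice(universe, set_size, replace=False))
            description = "background"
        sets.append(GeneSet(set_id, description, tuple(members)))
    truth.planted_set_id = f"SET{planted_index + 1:04d}"
    return GeneSetCollection(sets=sets, background=list(universe))


def generate_interaction_network(
    signature_genes: Sequence[str],
    background_genes: Sequence[str],
    n_hubs: int,
    hub_degree: int,
    background_edge_prob: float,
    seed: int,
    truth: Optional[GroundTruth] = None,
) -> tuple[EdgeList, list[str]]:
    """Generate a scored edge list with planted hubs among signature genes.

    Each planted hub gets edges to ``hub_degree`` distinct signature genes;
    further edges among all genes appear independently with
    ``background_edge_prob``.  Scores are uniform in (0.4, 1.0].  Returns
    the edge list and the planted hub ids; if ``truth`` is given the hubs
    are also recorded in ``truth.planted_hubs``.
    """
    signature_genes = sorted(set(signature_genes))
    background_genes = sorted(set(background_genes) - set(signature_genes))
    if n_hubs < 0:
        raise ConfigurationError(f"n_hubs must be >= 0, got {n_hubs}")
    if n_hubs > len(signature_genes):
        raise ConfigurationError(
            f"n_hubs={n_hubs} exceeds the {len(signature_genes)} signature genes"
        )
    if n_hubs > 0 and hub_degree > len(signature_genes) - 1:
        raise ConfigurationError(
            f"hub_degree={hub_degree} exceeds the {len(signature_genes) - 1} "
            "possible distinct signature partners"
        )
    if not 0.0 <= background_edge_prob <= 1.0:
        raise ConfigurationError(
            f"background_edge_prob must lie in [0, 1], got {background_edge_prob}"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    hubs = sorted(str(g) for g in rng.choice(signature_genes, size=n_hubs, replace=False))

    pairs: dict[tuple[str, str], float] = {}

    def add(a: str, b: str) -> None:
        key = (a, b) if a < b else (b, a)
        if key not in pairs:
            # uniform in (0.4, 1.0]
            pairs[key] = float(1.0 - rng.random() * (1.0 - EDGE_SCORE_LOW))

    for hub in hubs:
        partners = [g for g in signature_genes if g != hub]
        chosen = rng.choice(partners, size=hub_degree, replace=False)
        for p in chosen:
            add(hub, p)

    if background_edge_prob > 0:
        all_genes = signature_genes + background_genes
        idx_a, idx_b = np.triu_indices(len(all_genes), k=1)
        mask = rng.random(len(idx_a)) < background_edge_prob
        for ia, ib in zip(idx_a[mask], idx_b[mask]):
            add(all_genes[ia], all_genes[ib])

    edges = EdgeList(edges=[Edge(a, b, s) for (a, b), s in sorted(pairs.items())])
    if truth is not None:
        truth.planted_hubs = tuple(hubs)
    return edges, hubs
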