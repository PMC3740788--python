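"""Synthetic multi-dataset miRNA/mRNA studies with planted ground truth.

The generator emulates the statistical structure a heterogeneity-aware
discovery pipeline assumes: a shared core of truly active miRNAs planted in
every miRNA dataset, dataset-specific false signatures, tumour shifts carried
by only a fraction of tumour samples, missing values, and a bipartite target
network in which active miRNAs own exclusive deregulated targets.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, NORMAL, TUMOR
from .network import TargetNetwork

PREDICTION_SOURCES = ("targetscan", "pictar", "miranda")
EXPERIMENTAL_SOURCES = ("mirecords",)


@dataclass
class SimulationConfig:
    """Study-level parameters of the synthetic generator.

    Expression values live on a log2-like scale; the tumour shift for a
    planted feature is ``effect_size`` baseline standard deviations, applied
    to a random ``activation_fraction`` of the tumour samples only (the
    heterogeneous-activation regime outlier statistics are built for).
    """

    n_mirna_datasets: int = 5
    n_mrna_datasets: int = 4
    n_features_mirna: int = 800
    n_genes: int = 2000
    n_normal: int = 15
    n_tumor: int = 15
    n_true_active_mirna: int = 11
    activation_fraction: float = 0.3
    effect_size: float = 3.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    missing_rate: float = 0.02
    noise_signature_size: int = 15
    seed: int = 0
    # network shape: how many miRNAs have annotated targets and how many
    # targets / exclusive targets active vs decoy miRNAs carry
    # sized so the union of active-miRNA targets plus noise genes stays within
    # the top-5% detection capacity of the mRNA datasets (0.05 * n_genes), so
    # the planted premise "targets of active miRNAs are deregulated and
    # detectable" is coherent by construction
    n_network_mirnas: int = 150
    active_total_targets: int = 8
    active_exclusive_targets: int = 4
    decoy_total_targets: int = 8
    decoy_max_exclusive: int = 3
    n_noise_dereg_genes: int = 8

    def __post_init__(self) -> None:
        counts = {
            "n_mirna_datasets": self.n_mirna_datasets,
            "n_mrna_datasets": self.n_mrna_datasets,
            "n_features_mirna": self.n_features_mirna,
            "n_genes": self.n_genes,
            "n_normal": self.n_normal,
            "n_tumor": self.n_tumor,
            "n_true_active_mirna": self.n_true_active_mirna,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if not (0.0 < self.activation_fraction <= 1.0):
            raise ValueError("activation_fraction must be in (0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_true_active_mirna > self.n_features_mirna:
            raise ValueError("n_true_active_mirna exceeds n_features_mirna")
        if self.noise_signature_size < 0:
            raise ValueError("noise_signature_size must be >= 0")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be > 0")
        if self.n_network_mirnas > self.n_features_mirna:
            raise ValueError("n_network_mirnas exceeds n_features_mirna")
        if self.n_true_active_mirna > self.n_network_mirnas:
            raise ValueError("active miRNAs must fit in the network")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated study."""

    active_mirnas: set[str] = field(default_factory=set)
    planted_outlier_features: dict[str, set[str]] = field(default_factory=dict)
    planted_dereg_genes: dict[str, set[str]] = field(default_factory=dict)
    shift_signs: dict[str, dict[str, int]] = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "active_mirnas": sorted(self.active_mirnas),
            "planted_outlier_features": {k: sorted(v) for k, v in self.planted_outlier_features.items()},
            "planted_dereg_genes": {k: sorted(v) for k, v in self.planted_dereg_genes.items()},
            "shift_signs": {k: dict(sorted(v.items())) for k, v in self.shift_signs.items()},
            "seed": self.seed,
        }


def _child_seed(master: int, *key: int) -> int:
    """Independent substream seed: adding datasets never perturbs earlier ones."""
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_expression_dataset(
    config: SimulationConfig,
    planted: Iterable[str],
    seed: int,
    feature_ids: Sequence[str] | None = None,
    dataset_id: str = "sim",
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate one feature x sample matrix with heterogeneous planted outliers.

    Baseline entries are Normal(baseline_mean, baseline_sd^2).  Each planted
    feature receives an additive shift of ``effect_size * baseline_sd`` (sign
    Bernoulli(1/2) per feature) in a random subset of
    ``ceil(activation_fraction * n_tumor)`` tumour samples.  Entries are then
    set missing completely at random at ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    n_feat = config.n_features_mirna if feature_ids is None else len(feature_ids)
    if feature_ids is None:
        feature_ids = [f"mir-{i:04d}" for i in range(n_feat)]
    planted = sorted(set(planted))
    unknown = set(planted) - set(feature_ids)
    if unknown:
        raise ValueError(f"planted features outside the universe: {sorted(unknown)[:5]}")

    n_activated = math.ceil(config.activation_fraction * config.n_tumor)
    if config.activation_fraction * config.n_tumor < 1:
        raise ValueError("no activated samples: activation_fraction * n_tumor < 1")

    n_samples = config.n_normal + config.n_tumor
    sample_ids = [f"{dataset_id}-N{i:02d}" for i in range(config.n_normal)] + [
        f"{dataset_id}-T{i:02d}" for i in range(config.n_tumor)
    ]
    groups = pd.Series(
        [NORMAL] * config.n_normal + [TUMOR] * config.n_tumor, index=sample_ids
    )

    mat = rng.normal(config.baseline_mean, config.baseline_sd, size=(n_feat, n_samples))
    tumor_cols = np.arange(config.n_normal, n_samples)
    row_of = {f: i for i, f in enumerate(feature_ids)}
    signs: dict[str, int] = {}
    for f in planted:
        sign = 1 if rng.random() < 0.5 else -1
        signs[f] = sign
        cols = rng.choice(tumor_cols, size=n_activated, replace=False)
        mat[row_of[f], cols] += sign * config.effect_size * config.baseline_sd

    if config.missing_rate > 0:
        mask = rng.random(mat.shape) < config.missing_rate
        mat = np.where(mask, np.nan, mat)

    values = pd.DataFrame(mat, index=list(feature_ids), columns=sample_ids)
    ds = ExpressionDataset(values=values, groups=groups, dataset_id=dataset_id)
    truth = SyntheticTruth(
        planted_outlier_features={dataset_id: set(planted)},
        shift_signs={dataset_id: signs},
        seed=seed,
    )
    return ds, truth


def simulate_target_network(
    n_mirna: int,
    n_gene: int,
    exclusivity_profile: Mapping[str, tuple[int, int]],
    seed: int,
    gene_ids: Sequence[str] | None = None,
    sources: Sequence[str] = PREDICTION_SOURCES + EXPERIMENTAL_SOURCES,
) -> TargetNetwork:
    """Build a bipartite network matching a requested exclusivity profile.

    ``exclusivity_profile`` maps each miRNA id to ``(total_targets,
    exclusive_targets)``.  Exclusive targets end with miRNA-degree exactly 1;
    every non-exclusive target is shared by at least two miRNAs, so the
    realized exclusivity counts equal the request exactly.  Each edge gets a
    random non-empty evidence-source subset.
    """
    rng = np.random.default_rng(seed)
    profile = {m: (int(t), int(e)) for m, (t, e) in exclusivity_profile.items()}
    if len(profile) > n_mirna:
        raise ValueError("profile larger than n_mirna")
    for m, (t, e) in profile.items():
        if e > t:
            raise ValueError(f"{m}: exclusive targets ({e}) exceed total ({t})")
        if t > n_gene:
            raise ValueError(f"{m}: total targets ({t}) exceed n_gene")
    if sum(e for _, e in profile.values()) > n_gene:
        raise ValueError("infeasible exclusivity profile: exclusive targets exceed gene universe")

    if gene_ids is None:
        gene_ids = [f"gene-{i:04d}" for i in range(n_gene)]
    elif len(gene_ids) != n_gene:
        raise ValueError("gene_ids length must equal n_gene")
    pool = list(gene_ids)
    rng.shuffle(pool)
    pool_iter = iter(pool)

    net = TargetNetwork()

    def _edge_sources() -> set[str]:
        k = int(rng.integers(1, len(sources) + 1))
        idx = rng.choice(len(sources), size=k, replace=False)
        return {sources[i] for i in sorted(idx)}

    # exclusive genes: disjoint blocks, degree 1 by construction
    for m in sorted(profile):
        _, excl = profile[m]
        for _ in range(excl):
            net.add_edge(m, next(pool_iter), _edge_sources())

    # shared genes: pair remaining target slots so every shared gene has
    # degree >= 2 with all endpoints distinct
    slots = {m: t - e for m, (t, e) in profile.items() if t - e > 0}
    heap = [(-c, m) for m, c in sorted(slots.items())]
    heapq.heapify(heap)
    shared_members: list[tuple[str, set[str]]] = []  # (gene, mirnas on it)
    while len(heap) >= 2:
        c1, m1 = heapq.heappop(heap)
        c2, m2 = heapq.heappop(heap)
        try:
            g = next(pool_iter)
        except StopIteration:
            raise ValueError("infeasible profile: gene universe exhausted for shared targets")
        net.add_edge(m1, g, _edge_sources())
        net.add_edge(m2, g, _edge_sources())
        shared_members.append((g, {m1, m2}))
        if c1 + 1 < 0:
            heapq.heappush(heap, (c1 + 1, m1))
        if c2 + 1 < 0:
            heapq.heappush(heap, (c2 + 1, m2))
    if heap:
        c, m = heap[0]
        open_genes = [(g, on) for g, on in shared_members if m not in on]
        if len(open_genes) < -c:
            raise ValueError(
                f"infeasible profile: {m} has more shared-target slots than can be paired"
            )
        pick = rng.choice(len(open_genes), size=-c, replace=False)
        for i in pick:
            g, on = open_genes[int(i)]
            net.add_edge(m, g, _edge_sources())
            on.add(m)
    return net


def simulate_study(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], list[ExpressionDataset], TargetNetwork, SyntheticTruth]:
    """Simulate a full multi-dataset study.

    Returns ``n_mirna_datasets`` miRNA expression datasets sharing a planted
    core of active miRNAs (plus dataset-specific false signatures),
    ``n_mrna_datasets`` mRNA datasets in which the targets of the active
    miRNAs are deregulated (plus dataset-specific noise genes), the target
    network, and the full planted truth.
    """
    mirna_ids = [f"mir-{i:04d}" for i in range(config.n_features_mirna)]
    gene_ids = [f"gene-{i:04d}" for i in range(config.n_genes)]

    setup_rng = np.random.default_rng(_child_seed(config.seed, 0))
    active = sorted(
        str(m) for m in setup_rng.choice(mirna_ids, size=config.n_true_active_mirna, replace=False)
    )
    non_active = [m for m in mirna_ids if m not in set(active)]
    n_decoy = config.n_network_mirnas - config.n_true_active_mirna
    decoys = sorted(str(m) for m in setup_rng.choice(non_active, size=n_decoy, replace=False))

    profile: dict[str, tuple[int, int]] = {}
    for m in active:
        profile[m] = (config.active_total_targets, config.active_exclusive_targets)
    for m in decoys:
        excl = int(setup_rng.integers(0, config.decoy_max_exclusive + 1))
        profile[m] = (config.decoy_total_targets, excl)

    network = simulate_target_network(
        n_mirna=config.n_network_mirnas,
        n_gene=config.n_genes,
        exclusivity_profile=profile,
        seed=_child_seed(config.seed, 0, 1),
        gene_ids=gene_ids,
    )

    active_targets: set[str] = set()
    for m in active:
        active_targets.update(network.targets_of(m))
    non_target_genes = sorted(set(gene_ids) - active_targets)

    truth = SyntheticTruth(active_mirnas=set(active), seed=config.seed)

    mirna_datasets: list[ExpressionDataset] = []
    for i in range(config.n_mirna_datasets):
        ds_id = f"mirna-ds{i + 1}"
        noise_rng = np.random.default_rng(_child_seed(config.seed, 1, i, 0))
        candidates = [m for m in mirna_ids if m not in set(active)]
        noise = sorted(
            str(m) for m in noise_rng.choice(candidates, size=config.noise_signature_size, replace=False)
        ) if config.noise_signature_size else []
        planted = sorted(set(active) | set(noise))
        ds, t = simulate_expression_dataset(
            config, planted, seed=_child_seed(config.seed, 1, i, 1),
            feature_ids=mirna_ids, dataset_id=ds_id,
        )
        mirna_datasets.append(ds)
        truth.planted_outlier_features[ds_id] = set(planted)
        truth.shift_signs[ds_id] = t.shift_signs[ds_id]

    mrna_datasets: list[ExpressionDataset] = []
    for j in range(config.n_mrna_datasets):
        ds_id = f"mrna-ds{j + 1}"
        noise_rng = np.random.default_rng(_child_seed(config.seed, 2, j, 0))
        noise_genes = sorted(
            str(g) for g in noise_rng.choice(non_target_genes, size=config.n_noise_dereg_genes, replace=False)
        ) if config.n_noise_dereg_genes else []
        planted = sorted(active_targets | set(noise_genes))
        ds, t = simulate_expression_dataset(
            config, planted, seed=_child_seed(config.seed, 2, j, 1),
            feature_ids=gene_ids, dataset_id=ds_id,
        )
        mrna_datasets.append(ds)
        truth.planted_dereg_genes[ds_id] = set(planted)
        truth.shift_signs[ds_id] = t.shift_signs[ds_id]

    return mirna_datasets, mrna_datasets, network, truth
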