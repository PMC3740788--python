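"""POMA: regulatory-activity filtering of differential miRNAs.

The filter rests on two hypotheses: a miRNA's activity is reflected in the
deregulated expression of its target genes, and a miRNA that targets
deregulated genes *exclusively* (no other miRNA targets them) is more likely
to be genuinely regulatory.  Per miRNA, within the disease-specific
subnetwork restricted to deregulated genes,

    Z = alpha / beta

where beta counts all deregulated target genes of the miRNA and alpha those
targeted by no other miRNA.  A miRNA is *active* when alpha >= 2, beta >= 2
and Z >= 0.1 (inclusive threshold).  Active lists are computed per mRNA
dataset, combined by an at-least-``k``-datasets consensus, cross-matched
against each miRNA dataset's differential list, and the final signature is
the set of miRNAs supported by at least ``min_support`` filtered lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .datasets import ExpressionDataset
from .network import TargetNetwork
from .outliers import score_dataset

log = logging.getLogger(__name__)


@dataclass
class PomaConfig:
    z_threshold: float = 0.1
    active_min_datasets: int = 3
    relaxed_min_datasets: int = 2
    signature_min_support: int = 4
    selection_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.z_threshold <= 1.0):
            raise ValueError("z_threshold must be in (0, 1]")
        for name in ("active_min_datasets", "relaxed_min_datasets", "signature_min_support"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ZRecord:
    """Exclusivity score of one miRNA in the deregulated subnetwork."""

    mirna_id: str
    alpha: int
    beta: int
    z: float
    eligible: bool


def build_network(edge_tables: Iterable[pd.DataFrame]) -> TargetNetwork:
    """Union of (mirna, gene, source) edge tables; duplicate edges merge sources."""
    tables = list(edge_tables)
    if not tables or all(t.empty for t in tables):
        raise ValueError("no interaction edges supplied")
    net = TargetNetwork()
    n_rows = 0
    for t in tables:
        cols = {c.lower(): c for c in t.columns}
        for want in ("mirna", "gene", "source"):
            if want not in cols:
                raise ValueError(f"edge table missing column {want!r}")
        for i, row in enumerate(t.itertuples(index=False)):
            mirna = getattr(row, cols["mirna"])
            gene = getattr(row, cols["gene"])
            source = getattr(row, cols["source"])
            if not (isinstance(mirna, str) and mirna and isinstance(gene, str) and gene):
                raise ValueError(f"malformed edge at table row {i}: {row}")
            net.add_edge(mirna, gene, {str(source)})
            n_rows += 1
    log.info("build_network: %d rows -> %d edges, %d miRNAs, %d genes",
             n_rows, net.n_edges, len(net.mirnas), len(net.genes))
    return net


def dereg_genes(
    mrna_data: ExpressionDataset,
    selection_fraction: float = 0.05,
    method: str = "MOST",
) -> set[str]:
    """Deregulated genes of one mRNA dataset: the method's top-fraction outliers."""
    table = score_dataset(mrna_data, method, selection_fraction=selection_fraction)
    return table.selected


def build_subnetwork(network: TargetNetwork, dereg: set[str]) -> TargetNetwork:
    """Disease-specific subnetwork: edges restricted to deregulated genes."""
    sub = network.restrict_genes(set(dereg))
    if sub.n_edges == 0:
        log.warning("build_subnetwork: empty subnetwork")
    return sub


def compute_z(sub: TargetNetwork) -> list[ZRecord]:
    """Per-miRNA (alpha, beta, Z) from the deregulated subnetwork.

    beta = number of the miRNA's targets in the subnetwork; alpha = number of
    those whose subnetwork miRNA-degree is exactly 1.  Eligibility requires
    alpha >= 2 and beta >= 2.
    """
    degree = sub.gene_degree()
    records = []
    for m in sub.mirnas:
        targets = sub.targets_of(m)
        beta = len(targets)
        alpha = sum(1 for g in targets if degree[g] == 1)
        z = alpha / beta if beta > 0 else 0.0
        records.append(ZRecord(m, alpha, beta, z, eligible=(alpha >= 2 and beta >= 2)))
    return records


def active_mirnas(zrecords: Iterable[ZRecord], z_threshold: float = 0.1) -> set[str]:
    """Eligible miRNAs with Z at or above the threshold (inclusive)."""
    return {r.mirna_id for r in zrecords if r.eligible and r.z >= z_threshold}


def active_consensus(per_dataset_active: Sequence[set[str]], min_datasets: int = 3) -> set[str]:
    """miRNAs active in at least ``min_datasets`` of the mRNA datasets."""
    if len(per_dataset_active) < min_datasets:
        raise ValueError("fewer active lists than min_datasets")
    counts: dict[str, int] = {}
    for s in per_dataset_active:
        for m in s:
            counts[m] = counts.get(m, 0) + 1
    return {m for m, c in counts.items() if c >= min_datasets}


def cross_match(active: set[str], de_list: set[str]) -> set[str]:
    """Intersect the consensus active list with one dataset's differential list."""
    return set(active) & set(de_list)


def final_signature(
    filtered_lists: Sequence[set[str]],
    min_support: int = 4,
) -> pd.DataFrame:
    """Consensus signature: miRNAs in >= ``min_support`` filtered lists.

    Returns a frame indexed by miRNA with the support count, sorted by
    decreasing support then id.
    """
    if len(filtered_lists) < min_support:
        raise ValueError("fewer filtered lists than min_support")
    counts: dict[str, int] = {}
    for s in filtered_lists:
        for m in s:
            counts[m] = counts.get(m, 0) + 1
    kept = {m: c for m, c in counts.items() if c >= min_support}
    rows = sorted(kept.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {"support": [c for _, c in rows]},
        index=pd.Index([m for m, _ in rows], name="mirna_id"),
    )


def zrecords_frame(records: Iterable[ZRecord], z_threshold: float = 0.1) -> pd.DataFrame:
    rows = sorted(records, key=lambda r: (-r.z, r.mirna_id))
    return pd.DataFrame(
        {
            "alpha": [r.alpha for r in rows],
            "beta": [r.beta for r in rows],
            "z": [r.z for r in rows],
            "eligible": [r.eligible for r in rows],
            "active": [r.eligible and r.z >= z_threshold for r in rows],
        },
        index=pd.Index([r.mirna_id for r in rows], name="mirna_id"),
    )


def poma_filter(
    mirna_de_lists: dict[str, set[str]],
    mrna_datasets: Sequence[ExpressionDataset],
    network: TargetNetwork,
    config: PomaConfig | None = None,
) -> dict:
    """Run POMA steps end to end.

    Returns a dict with the per-mRNA-dataset active lists, consensus active
    set (strict and relaxed), per-miRNA-dataset filtered lists and the final
    signature frame.
    """
    config = config or PomaConfig()
    per_dataset_active: list[set[str]] = []
    z_tables: dict[str, pd.DataFrame] = {}
    for ds in mrna_datasets:
        dereg = dereg_genes(ds, selection_fraction=config.selection_fraction)
        sub = build_subnetwork(network, dereg)
        records = compute_z(sub)
        z_tables[ds.dataset_id] = zrecords_frame(records, config.z_threshold)
        per_dataset_active.append(active_mirnas(records, config.z_threshold))
    consensus = active_consensus(per_dataset_active, config.active_min_datasets)
    relaxed = active_consensus(per_dataset_active, config.relaxed_min_datasets)
    filtered = {k: cross_match(consensus, v) for k, v in mirna_de_lists.items()}
    signature = final_signature(list(filtered.values()), config.signature_min_support)
    return {
        "per_dataset_active": per_dataset_active,
        "consensus_active": consensus,
        "relaxed_active": relaxed,
        "z_tables": z_tables,
        "filtered_lists": filtered,
        "signature": signature,
    }
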