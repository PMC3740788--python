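"""Generate a synthetic multi-dataset miRNA/mRNA study with planted truth.

Five miRNA expression datasets share a core of 11 truly active miRNAs (each
also carries its own false dataset-specific signature); four mRNA datasets
carry deregulation in the targets of the active miRNAs; a bipartite target
network gives the active miRNAs exclusive deregulated targets.
"""

from mirsig.simulate import SimulationConfig, simulate_study

config = SimulationConfig(seed=42)
mirna_datasets, mrna_datasets, network, truth = simulate_study(config)

print(f"miRNA datasets : {len(mirna_datasets)} x "
      f"({mirna_datasets[0].n_features} features, {mirna_datasets[0].n_samples} samples)")
print(f"mRNA datasets  : {len(mrna_datasets)} x "
      f"({mrna_datasets[0].n_features} genes, {mrna_datasets[0].n_samples} samples)")
print(f"network        : {len(network.mirnas)} miRNAs, {len(network.genes)} genes, "
      f"{network.n_edges} edges")
print(f"planted actives: {sorted(truth.active_mirnas)[:4]} ... ({len(truth.active_mirnas)} total)")
ds1 = mirna_datasets[0].dataset_id
print(f"planted outliers in {ds1}: {len(truth.planted_outlier_features[ds1])} "
      "(the 11 shared actives + dataset-specific noise features)")
# Each planted feature is shifted by effect_size * baseline_sd in only
# ceil(activation_fraction * n_tumor) tumour samples -- the heterogeneous
# activation regime that motivates outlier statistics over the t-test.
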