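"""Run the whole discovery pipeline on a simulated study and measure how the
regulatory-activity filter changes cross-dataset consistency.

Differential miRNAs (MOST, top 5%) are called per dataset, active miRNAs are
identified from the four mRNA datasets (Z >= 0.1 in at least 3 of 4), the
differential lists are cross-matched against the consensus active set, and
the final signature keeps miRNAs supported by at least 4 of 5 filtered lists.
"""

from mirsig.pipeline import run_study
from mirsig.simulate import SimulationConfig

result = run_study(SimulationConfig(seed=4))

print(f"differential-list sizes : { {k: len(v) for k, v in result.de_lists.items()} }")
print(f"consensus active miRNAs : {len(result.poma['consensus_active'])}")
print(f"filtered-list sizes     : { {k: len(v) for k, v in result.poma['filtered_lists'].items()} }")
print(f"mean pairwise Jaccard   : {result.overlap_before.mean():.3f} before -> "
      f"{result.overlap_after.mean():.3f} after filtering "
      f"(paired t p = {result.p_value:.2g})")
print(f"signature ({len(result.signature)} miRNAs, support = datasets confirming):")
print(result.signature.to_string())
print(f"Jaccard vs planted truth: {result.signature_jaccard:.3f}")
# The filter removes dataset-specific false positives, so the surviving lists
# agree far better across datasets; the signature contains planted active
# miRNAs that were both detected as outliers and confirmed as regulators.
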