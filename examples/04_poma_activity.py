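"""Score miRNA regulatory activity with the exclusivity ratio Z = alpha/beta.

Within the subnetwork restricted to deregulated genes, beta counts all
deregulated targets of a miRNA and alpha those targeted by no other miRNA.
A miRNA is "active" when alpha >= 2, beta >= 2 and Z >= 0.1.
"""

from mirsig.network import TargetNetwork
from mirsig.poma import active_mirnas, build_subnetwork, compute_z, zrecords_frame

edges = [
    # miR-A: three targets, two exclusive
    ("miR-A", "g1", "db1"), ("miR-A", "g2", "db1"), ("miR-A", "g3", "db1"),
    # miR-B shares g3 and owns g4, g5
    ("miR-B", "g3", "db2"), ("miR-B", "g4", "db2"), ("miR-B", "g5", "db1"),
    # miR-C: one exclusive target only -> ineligible (alpha < 2)
    ("miR-C", "g6", "db1"),
]
network = TargetNetwork.from_edges(edges)

deregulated = {"g1", "g2", "g3", "g4", "g5", "g6"}
sub = build_subnetwork(network, deregulated)
records = compute_z(sub)

print(zrecords_frame(records, z_threshold=0.1))
print("\nactive:", sorted(active_mirnas(records, z_threshold=0.1)))
# miR-A: alpha=2 (g1, g2), beta=3 -> Z=0.67, active.  miR-B likewise.
# miR-C has Z=1.0 but only one deregulated target, so it fails the
# (alpha, beta > 1) eligibility rule and is excluded.
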