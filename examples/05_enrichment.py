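"""Consolidate predicted targets across sources and test gene-set enrichment.

Targets supported by fewer than two prediction programs are discarded
(experimentally validated interactions bypass the rule); the consolidated
set is then tested against a pathway collection with the exact hypergeometric
tail and BH-FDR, and screened at ratio > 0.15, p < 1e-4.
"""

from mirsig.enrichment import (
    GeneSetCollection, consolidate_targets, hypergeom_enrich, relevance_screen,
)

per_source = {
    "targetscan": {"miR-X": {"CCND1", "MYC", "BRCA1", "AXIN1"}},
    "miranda":    {"miR-X": {"CCND1", "MYC", "TP53"}},
    "pictar":     {"miR-X": {"MYC", "AXIN1"}},
    "mirecords":  {"miR-X": {"VEGFA"}},  # experimental evidence
}
targets = consolidate_targets(per_source, min_sources=2, experimental_sources=["mirecords"])
print("consolidated targets of miR-X:", sorted(targets["miR-X"]))

universe = {f"G{i}" for i in range(40)} | {"CCND1", "MYC", "AXIN1", "VEGFA", "TP53", "BRCA1"}
collection = GeneSetCollection(
    sets={
        "cell_cycle": {"CCND1", "MYC", "G1", "G2"},
        "wnt_signaling": {"AXIN1", "MYC", "CCND1", "G3", "G4", "G5"},
        "unrelated": {f"G{i}" for i in range(10, 25)},
    },
    universe=universe,
)
rows = hypergeom_enrich(targets["miR-X"], collection)
print("\n", rows[["k", "K", "n", "N", "p", "fdr", "ratio"]].round(5))

screen = relevance_screen(rows.rename(columns={"k": "hits", "K": "size"})[["hits", "size", "p"]],
                          ratio_min=0.15, p_max=1e-2)
print("\nflagged:", list(screen.index[screen["flagged"]]))
# k of K pathway members hit by the n consolidated targets in a universe of N
# genes; p is the exact upper hypergeometric tail, fdr its BH adjustment.
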