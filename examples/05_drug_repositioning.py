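"""Repurpose drugs by miRNA overlap with disease-associated miRNAs.

A drug's predicted miRNA partners are intersected with each disease's
curated miRNAs; the overlap is scored with a hypergeometric upper-tail
test over a shared miRNA universe, and Benjamini-Hochberg controls the
FDR at 0.1 across all candidate pairs.
"""

from mirlink import DiseaseMiRNAMap, run_repurposing

universe = {f"miR-{i:03d}" for i in range(50)}
drug_mirnas = {
    "valproate-like": {"miR-000", "miR-001", "miR-002", "miR-003", "miR-020"},
    "inert-drug": {"miR-030", "miR-045"},
}
disease_map = DiseaseMiRNAMap(
    {
        "breast-cancer-like": {"miR-000", "miR-001", "miR-002", "miR-003", "miR-010"},
        "unrelated-disease": {"miR-040", "miR-041"},
    },
    universe=universe,
)

result = run_repurposing(drug_mirnas, disease_map, fdr_cutoff=0.1, universe=universe)
print(result.table.to_string(index=False))
print()
hits = result.significant()
for _, row in hits.iterrows():
    print(
        f"{row['drug']} -> {row['disease']}: k={row['k']} shared miRNAs, "
        f"p={row['p']:.3g}, FDR={row['fdr']:.3g}"
    )
print("Pairs with FDR < 0.1 share more miRNAs than chance allows and are")
print("candidate new indications for the drug.")
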