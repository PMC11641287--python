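"""Pathway over-representation of miRNA target sets.

Uses the bundled target lists of the three worked-example miRNAs and the
bundled (synthetic stand-in) pathway collection, tests every
(miRNA, pathway) pair with the upper-tail hypergeometric test, and keeps
miRNAs enriched in whitelisted cancer-related pathways at FDR 0.05.
"""

from circaxis import cancer_pathway_filter, enrich_mirnas
from circaxis.worked_example import load_example_pathways, load_example_targets

results = enrich_mirnas(load_example_targets(), load_example_pathways())

print("top enrichment per miRNA (k/n targets in the K-gene set, universe N):")
for mirna, block in results.groupby("mirna_id"):
    best = block.sort_values("fdr").iloc[0]
    print(f"  {mirna:<15} {best['set_name']:<25} k={best['k']}/{best['n']} "
          f"K={best['K']} N={best['N']}  fdr={best['fdr']:.2e}")

retained = cancer_pathway_filter(results)
print(f"\nmiRNAs retained by the cancer-pathway filter: {sorted(retained)}")
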