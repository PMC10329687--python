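"""Contrast geographic clustering between functional gene groups.

Computes per-gene-tree PERMANOVA R² for 60 genes (30 under regional
selection, labeled membrane/metabolic; 30 neutral, labeled organelle), then
runs the Kruskal-Wallis omnibus test across the three groups and, where it
fires, pairwise Wilcoxon contrasts — the procedure that distinguishes local
selection from dispersal limitation. Covariate diagnostics check that R² is
not explained by gene length, diversity, tree size, or regional entropy.
"""

from phylogeostrat import SimulationParams, compare_groups, covariate_diagnostics, simulate_dataset
from phylogeostrat.workflows import gene_r2_records

bundle = simulate_dataset(SimulationParams(seed=5))
records = gene_r2_records(bundle, n_perm=99, seed=5)
comp = compare_groups(records, value="r2")

print(f"genes tested: {len(records)}")
for group, mean in sorted(comp.group_means.items()):
    print(f"  mean R^2 {group:10s} {mean:.3f}  (n={comp.group_ns[group]})")
print(f"Kruskal-Wallis H={comp.kruskal_h:.2f}, BH-adjusted p={comp.kruskal_p_adj:.2g}")
for (a, b), (stat, _p, p_adj) in sorted(comp.pairwise.items()):
    print(f"  Wilcoxon {a} vs {b}: U={stat:.0f}, BH-adjusted p={p_adj:.2g}")

table = covariate_diagnostics(records)
print("\ncovariate diagnostics (PCC of R^2 vs ...):")
print(table.round(3).to_string(index=False))
print("species flagged for covariate bias:", table.attrs["species_flagged"])
# A significantly lower organelle mean than membrane mean is the signature
# of regional selection acting on environment-facing genes. In this synthetic
# dataset the R^2-vs-mean_pi correlation is expected by construction (the
# selection overwrite adds region-correlated variation, raising both), and
# gene length / tip count / entropy are constant across genes, hence
# undefined; on real data a flagged species warrants closer inspection.
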