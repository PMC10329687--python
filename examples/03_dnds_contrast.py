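"""Per-gene dN/dS (Nei-Gojobori 1986) and its contrast between gene groups.

Selects genes with genuine nucleotide variation, enforces the framing rules
(ATG/TTG/GTG start, trailing stops trimmed), computes one NG86 dN/dS ratio
per gene under the bacterial code, and contrasts the ratios between
membrane (selected) and organelle (neutral) genes with the rank-based
pipeline. Elevated membrane dN/dS corroborates positive selection.
"""

import numpy as np

from phylogeostrat import SimulationParams, assign_groups, simulate_dataset
from phylogeostrat.dnds import dnds_group_contrast, frame_and_trim, ng86, select_variable_genes

bundle = simulate_dataset(SimulationParams(seed=5))
groups = assign_groups(bundle.annotations, gene_ids=list(bundle.gene_alignments))
variable = set(select_variable_genes(bundle.gene_alignments))

results = []
excluded = {"no_start": 0, "too_short": 0, "invariant": 0}
for gene_id, aln in bundle.gene_alignments.items():
    if gene_id not in variable:
        excluded["invariant"] += 1
        continue
    framed, reason = frame_and_trim(aln)
    if framed is None:
        excluded[reason] += 1
        continue
    results.append(ng86(framed, gene_id))

ratios = {}
for res in results:
    if res.defined:
        ratios.setdefault(groups[res.gene_id], []).append(res.ratio)
print(f"genes with a defined ratio: {sum(len(v) for v in ratios.values())}"
      f"  (excluded: {excluded})")
for group in sorted(ratios):
    print(f"  median dN/dS {group:10s} {np.median(ratios[group]):.3f}")

comp = dnds_group_contrast(results, groups)
print(f"Kruskal-Wallis BH-adjusted p = {comp.kruskal_p_adj:.2g}")
for (a, b), (stat, _p, p_adj) in sorted(comp.pairwise.items()):
    print(f"  Wilcoxon {a} vs {b}: U={stat:.0f}, BH-adjusted p={p_adj:.2g}")
# dN/dS > 1 indicates an excess of amino-acid-changing substitutions;
# the membrane-vs-organelle gap mirrors the geographic-clustering contrast.
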