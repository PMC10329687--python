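"""Genome-abundance normalization: coverage filter, rarefaction, TPM, diversity.

Builds a toy samples-by-genomes read-count matrix, filters cells whose
observed covered fraction falls short of half the expected coverage
c = 1 - (1 - l/g)^r, rarefies all samples to the minimum depth, converts to
TPM, and reports per-sample Shannon diversity plus a two-sample KS test
between two sample groups' composition.
"""

import numpy as np
import pandas as pd

from phylogeostrat.abundance import (
    CountMatrix,
    composition_ks,
    coverage_filter,
    expected_coverage,
    rarefy,
    shannon_diversity,
    tpm,
)

rng = np.random.default_rng(3)
genomes = [f"mag{j}" for j in range(8)]
counts = pd.DataFrame(
    rng.negative_binomial(5, 0.002, size=(6, 8)),
    index=[f"sample{i}" for i in range(6)],
    columns=genomes,
)
lengths = pd.Series(rng.uniform(1.5e6, 6e6, 8), index=genomes)
cm = CountMatrix(counts, lengths, read_length=150.0)

print(f"expected coverage of mag0 in sample0: "
      f"{expected_coverage(150, lengths['mag0'], counts.iloc[0, 0]):.4f}")

# observed covered fractions: mostly consistent, two cells suspiciously low
# (far below half the ~0.05-0.2 expected coverage at these depths)
observed = pd.DataFrame(0.9, index=counts.index, columns=genomes)
observed.iloc[0, 1] = 0.01
observed.iloc[3, 2] = 0.02
filtered = coverage_filter(cm, observed)
print(f"cells zeroed by coverage filter: "
      f"{int((filtered.counts == 0).sum().sum() - (cm.counts == 0).sum().sum())}")

depth = int(filtered.counts.sum(axis=1).min())
rare = rarefy(filtered, depth, seed=3)
print(f"rarefaction depth: {depth} reads/sample")

tpm_matrix = tpm(rare)
shannon = tpm_matrix.apply(shannon_diversity, axis=1)
print("per-sample Shannon diversity (nats):")
print(shannon.round(3).to_string())

d, p = composition_ks(tpm_matrix.iloc[:3].mean(), tpm_matrix.iloc[3:].mean())
print(f"KS test between sample-group compositions: D={d:.3f}, p={p:.3f}")
# TPM normalizes away genome length and sequencing depth, so diversity and
# composition comparisons are not driven by genome size or library size.
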