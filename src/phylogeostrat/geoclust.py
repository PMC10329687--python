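"""Geographic clustering of trees via PERMANOVA.

The headline statistic is the PERMANOVA R² of a tree's patristic distance
matrix against the region of origin of its tips: the fraction of
distance-matrix variation explained by geography. The implementation uses the
Gower-centered trace formulation. With squared distances ``D∘D``, set
``A = -½ D∘D`` and ``G = J A J`` (``J = I - 11ᵀ/n`` the centering projector).
Then ``SS_total = tr(G)`` and, with ``H`` the hat matrix of the one-factor
group design, ``SS_model = tr(H G H) = Σ_g (1_gᵀ G 1_g)/n_g`` and
``SS_resid = SS_total - SS_model``. The pseudo-F is
``[SS_model/(k-1)] / [SS_resid/(n-k)]`` and its null distribution is obtained
by permuting group labels. On non-Euclidean distance matrices ``G`` can be
indefinite, so R² may be negative — the model then fits worse than the grand
mean ("a horizontal line").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from statsmodels.stats.multitest import multipletests

from .phylo import FilterResult, ValidationError, filter_tips, patristic_distances

__all__ = [
    "PermanovaResult",
    "SpeciesClusteringReport",
    "permanova",
    "benjamini_hochberg",
    "test_species",
    "adjust_species_reports",
]

DEFAULT_N_PERM = 999  # vegan's adonis2 default


@dataclass
class PermanovaResult:
    """One PERMANOVA test of one grouping on one distance matrix.

    ``r2`` is SS_model/SS_total (may be negative on non-Euclidean matrices);
    ``p_value`` uses the permutation correction (1 + #{F* >= F}) / (1 + n_perm),
    so it is never exactly 0. ``status`` is "untestable" when the test could
    not run (degenerate matrix or filters left < 2 regions); numeric fields
    are then NaN.
    """

    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_tips: int
    n_regions: int
    status: str = "tested"

    @property
    def testable(self) -> bool:
        return self.status == "tested"


def _untestable(n_tips: int = 0, n_regions: int = 0) -> PermanovaResult:
    return PermanovaResult(
        np.nan, np.nan, np.nan, 0, n_tips, n_regions, status="untestable"
    )


def gower_center(dm_values: np.ndarray) -> np.ndarray:
    """Double-center -½ of the squared distances: G = J (-½ D∘D) J."""
    a = -0.5 * dm_values**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _ss_model(g: np.ndarray, codes: np.ndarray, k: int) -> float:
    # tr(HGH) = tr(HG) for the one-hot group design (H idempotent, symmetric);
    # reduces to sum over groups of 1_g' G 1_g / n_g.
    total = 0.0
    for gi in range(k):
        mask = codes == gi
        block = g[np.ix_(mask, mask)]
        total += block.sum() / mask.sum()
    return float(total)


def permanova(
    dm: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA of ``dm`` against ``groups`` (tip_id -> region)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = list(dm.ids)
    try:
        raw = [groups[t] for t in labels]
    except KeyError as exc:
        raise ValidationError(f"tip {exc} missing from grouping") from exc
    codes, uniques = pd.factorize(np.asarray(raw, dtype=object))
    n, k = len(labels), len(uniques)
    if k < 2:
        raise ValidationError("need >= 2 groups")
    if n - k < 1:
        raise ValidationError(
            f"singular design: {n} observations for {k} groups leaves no "
            "residual degrees of freedom"
        )

    g = gower_center(dm.data)
    ss_total = float(np.trace(g))
    if ss_total <= 1e-12:
        return _untestable(n, k)

    def f_stat(c: np.ndarray) -> tuple[float, float]:
        ss_m = _ss_model(g, c, k)
        ss_r = ss_total - ss_m
        if ss_r <= 1e-12 * abs(ss_total):
            # zero residual variation: perfect separation, F unbounded
            return ss_m, np.inf
        return ss_m, (ss_m / (k - 1)) / (ss_r / (n - k))

    ss_model, f_obs = f_stat(codes)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    exceed = 0
    for _ in range(n_perm):
        _, f_perm = f_stat(rng.permutation(codes))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(ss_model / ss_total, f_obs, p, n_perm, n, k)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass
class SpeciesClusteringReport:
    """All clustering tests for one species: the species tree plus gene trees.

    ``p_adjusted`` is the BH-adjusted species-tree p-value; the family is the
    set of species trees tested in one run (apply
    :func:`adjust_species_reports` across reports), never the gene trees —
    downstream group comparisons consume gene R² values, not gene p-values.
    """

    species_id: str
    species_tree_result: PermanovaResult
    gene_results: list[tuple[str, PermanovaResult]] = field(default_factory=list)
    p_adjusted: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "unit_id": self.species_id,
                "level": "species",
                "n_tips": self.species_tree_result.n_tips,
                "n_regions": self.species_tree_result.n_regions,
                "r2": self.species_tree_result.r2,
                "pseudo_f": self.species_tree_result.pseudo_f,
                "p": self.species_tree_result.p_value,
                "p_adj": self.p_adjusted,
                "status": self.species_tree_result.status,
            }
        ]
        for gene_id, res in self.gene_results:
            rows.append(
                {
                    "unit_id": gene_id,
                    "level": "gene",
                    "n_tips": res.n_tips,
                    "n_regions": res.n_regions,
                    "r2": res.r2,
                    "pseudo_f": res.pseudo_f,
                    "p": res.p_value,
                    "p_adj": np.nan,
                    "status": res.status,
                }
            )
        return pd.DataFrame(rows)


def _filtered_permanova(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    n_perm: int,
    rng: np.random.Generator,
) -> PermanovaResult:
    try:
        filt = filter_tips(dm, meta)
    except ValidationError:
        return _untestable(dm.shape[0])
    if not filt.testable or filt.matrix is None:
        return _untestable(len(filt.kept), filt.n_regions)
    regions = meta.set_index("tip_id")["region"]
    return permanova(filt.matrix, regions, n_perm=n_perm, seed=rng)


def test_species(
    species_tree: TreeNode,
    gene_trees: Mapping[str, TreeNode],
    meta: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    species_id: str = "species",
) -> SpeciesClusteringReport:
    """Run the filtered PERMANOVA on a species tree and each of its gene trees.

    Gene trees observed in fewer than three samples are reported untestable
    (too few tips for a meaningful tree). Untestable units are carried through
    with status flags, never dropped silently.
    """
    rng = np.random.default_rng(seed)
    sp_res = _filtered_permanova(patristic_distances(species_tree), meta, n_perm, rng)
    report = SpeciesClusteringReport(species_id, sp_res, p_adjusted=sp_res.p_value)
    for gene_id in gene_trees:
        tree = gene_trees[gene_id]
        n_tips = tree.count(tips=True)
        if n_tips < 3:
            warnings.warn(f"gene {gene_id} has {n_tips} tips; untestable")
            report.gene_results.append((gene_id, _untestable(n_tips)))
            continue
        res = _filtered_permanova(patristic_distances(tree), meta, n_perm, rng)
        report.gene_results.append((gene_id, res))
    return report


def adjust_species_reports(
    reports: Sequence[SpeciesClusteringReport],
) -> list[SpeciesClusteringReport]:
    """BH-adjust species-tree p-values across all species tested in one run."""
    tested = [r for r in reports if r.species_tree_result.testable]
    adjusted = benjamini_hochberg([r.species_tree_result.p_value for r in tested])
    for rep, adj in zip(tested, adjusted):
        rep.p_adjusted = adj
    return list(reports)
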