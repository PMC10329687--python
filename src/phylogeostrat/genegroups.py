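"""Gene functional groups and between-group contrasts of geographic clustering.

Genes are stratified by top-level GO cellular-component label into three
groups — membrane, organelle, and everything else pooled as "metabolic"
(including unannotated genes, whose biological-process terms are dominated by
metabolic pathways). Group differences in per-gene geographic R² (or dN/dS)
are tested with a Kruskal-Wallis rank test followed, when significant, by
pairwise two-sided Wilcoxon rank-sum tests, all BH-adjusted. Covariate
diagnostics check that R² is not driven by gene length, diversity, tree size,
or regional composition.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geoclust import benjamini_hochberg
from .phylo import CodonAlignment, VALID_BASES, ValidationError

__all__ = [
    "GROUPS",
    "GeneRecord",
    "GroupComparison",
    "assign_groups",
    "regional_entropy",
    "mean_pi",
    "compare_groups",
    "covariate_diagnostics",
    "read_annotations",
]

logger = logging.getLogger(__name__)

GROUPS = ("membrane", "organelle", "metabolic")

#: Exact Wilcoxon enumeration is used up to this per-group size (no ties).
EXACT_WILCOXON_MAX_N = 25


@dataclass
class GeneRecord:
    """Per-gene covariates and clustering outcome for one species."""

    gene_id: str
    group: str
    length: int
    mean_pi: float
    regional_entropy: float
    n_tips: int
    r2: float
    p_value: float
    dnds: float | None = None


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the annotation TSV: gene_id, cc_labels (semicolon-separated)."""
    ann = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("gene_id", "cc_labels"):
        if col not in ann.columns:
            raise ValidationError(f"annotation table missing column {col!r}")
    return ann


def assign_groups(
    annotations: Mapping[str, Iterable[str]] | pd.DataFrame,
    gene_ids: Iterable[str] | None = None,
) -> dict[str, str]:
    """Map genes to membrane / organelle / metabolic.

    Any label other than membrane or organelle — and any gene without an
    annotation row — falls into the pooled metabolic group. A gene carrying
    both membrane and organelle labels is assigned to membrane (surface
    exposure is what the selection hypothesis is about); such conflicts are
    counted and logged.
    """
    if isinstance(annotations, pd.DataFrame):
        mapping = {
            row["gene_id"]: [s for s in str(row["cc_labels"]).split(";") if s]
            for _, row in annotations.iterrows()
        }
    else:
        mapping = {g: list(labels) for g, labels in annotations.items()}
    genes = list(gene_ids) if gene_ids is not None else list(mapping)
    out: dict[str, str] = {}
    conflicts = 0
    for gene in genes:
        labels = {str(lab).strip().lower() for lab in mapping.get(gene, [])}
        has_mem = "membrane" in labels
        has_org = "organelle" in labels
        if has_mem and has_org:
            conflicts += 1
        if has_mem:
            out[gene] = "membrane"
        elif has_org:
            out[gene] = "organelle"
        else:
            out[gene] = "metabolic"
    if conflicts:
        logger.info(
            "%d gene(s) annotated both membrane and organelle; assigned membrane",
            conflicts,
        )
    return out


def regional_entropy(region_counts: Mapping[str, int]) -> float:
    """Shannon entropy (nats) of the regional composition of a tree's tips.

    Zero-count regions contribute nothing; a single represented region gives 0.
    """
    counts = np.asarray([c for c in region_counts.values()], dtype=float)
    if np.any(counts < 0):
        raise ValidationError("negative region count")
    total = counts.sum()
    if total <= 0:
        raise ValidationError("all region counts are zero")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def mean_pi(aln: CodonAlignment) -> float:
    """Mean over all sequence pairs of the fraction of differing sites.

    Gapped/ambiguous positions are excluded per pair (pairwise deletion);
    pairs with no comparable sites are excluded from the mean and logged.
    """
    if aln.n_seq < 2:
        raise ValidationError("mean_pi needs at least 2 sequences")
    valid = np.isin(aln.seqs, list(VALID_BASES))
    pis = []
    skipped = 0
    for i, j in itertools.combinations(range(aln.n_seq), 2):
        both = valid[i] & valid[j]
        compared = int(both.sum())
        if compared == 0:
            skipped += 1
            continue
        pis.append((aln.seqs[i][both] != aln.seqs[j][both]).sum() / compared)
    if skipped:
        logger.info("mean_pi: %d pair(s) with no comparable sites excluded", skipped)
    if not pis:
        raise ValidationError("no sequence pair had comparable sites")
    return float(np.mean(pis))


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus plus (gated) pairwise Wilcoxon contrasts.

    ``pairwise`` maps (groupA, groupB) to (U statistic of groupA, raw p,
    BH-adjusted p); it is populated only when the adjusted Kruskal-Wallis
    p-value is below ``alpha``. The U statistic is the Mann-Whitney count for
    the first-named group (0 when every groupA value is below every groupB
    value).
    """

    kruskal_h: float
    kruskal_p: float
    kruskal_p_adj: float
    pairwise: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=dict
    )
    group_means: dict[str, float] = field(default_factory=dict)
    group_ns: dict[str, int] = field(default_factory=dict)
    alpha: float = 0.05


def _wilcoxon_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < len(combined)
    exact = (
        not ties
        and len(x) <= EXACT_WILCOXON_MAX_N
        and len(y) <= EXACT_WILCOXON_MAX_N
    )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    records: Sequence[GeneRecord] | Mapping[str, Sequence[float]],
    value: str = "r2",
    alpha: float = 0.05,
) -> GroupComparison:
    """Contrast a per-gene value (r2 or dnds) between functional groups.

    Non-finite values (e.g. undefined dN/dS ratios) are excluded and counted
    in ``group_ns`` denominators' complement via logging; groups with fewer
    than two usable members are excluded from pairwise contrasts.
    """
    if isinstance(records, Mapping):
        by_group = {g: np.asarray(v, dtype=float) for g, v in records.items()}
    else:
        by_group = {}
        for rec in records:
            by_group.setdefault(rec.group, []).append(getattr(rec, value))
        by_group = {g: np.asarray(v, dtype=float) for g, v in by_group.items()}
    cleaned = {}
    for g, vals in by_group.items():
        finite = vals[np.isfinite(vals)]
        if len(finite) < len(vals):
            logger.info(
                "group %s: %d non-finite %s value(s) excluded",
                g, len(vals) - len(finite), value,
            )
        if len(finite) > 0:
            cleaned[g] = finite
    if len(cleaned) < 2:
        raise ValidationError("need >= 2 non-empty groups")

    samples = list(cleaned.values())
    if len(np.unique(np.concatenate(samples))) == 1:
        h, p = 0.0, 1.0  # every value identical: no group signal, no ranks
    else:
        h, p = stats.kruskal(*samples)
    p_adj = benjamini_hochberg([p])[0]
    comp = GroupComparison(
        kruskal_h=float(h),
        kruskal_p=float(p),
        kruskal_p_adj=float(p_adj),
        group_means={g: float(v.mean()) for g, v in cleaned.items()},
        group_ns={g: int(len(v)) for g, v in cleaned.items()},
        alpha=alpha,
    )
    if comp.kruskal_p_adj < alpha:
        eligible = {g: v for g, v in cleaned.items() if len(v) >= 2}
        for g in set(cleaned) - set(eligible):
            logger.info("group %s has < 2 members; excluded from pairwise", g)
        pairs = list(itertools.combinations(sorted(eligible), 2))
        raw = [_wilcoxon_pair(eligible[a], eligible[b]) for a, b in pairs]
        adjusted = benjamini_hochberg([p for _, p in raw])
        for (a, b), (stat, praw), padj in zip(pairs, raw, adjusted):
            comp.pairwise[(a, b)] = (stat, float(praw), float(padj))
    return comp


def covariate_diagnostics(records: Sequence[GeneRecord]) -> pd.DataFrame:
    """Pearson correlation of per-gene R² with each potential bias covariate.

    Returns one row per covariate (n_tips, mean_pi, length, regional_entropy)
    with the PCC, its two-sided p, the BH-adjusted p, and an ``undefined``
    flag for zero-variance covariates. The frame carries a ``species_flagged``
    attribute: True when any covariate correlates significantly (adjusted
    p < 0.05), the cue to exclude that species from group contrasts.
    """
    finite = [
        r
        for r in records
        if all(
            math.isfinite(v)
            for v in (r.r2, r.n_tips, r.mean_pi, r.length, r.regional_entropy)
        )
    ]
    if len(finite) < 3:
        raise ValidationError("need >= 3 records with finite values")
    r2 = np.array([r.r2 for r in finite], dtype=float)
    covariates = {
        "n_tips": np.array([r.n_tips for r in finite], dtype=float),
        "mean_pi": np.array([r.mean_pi for r in finite], dtype=float),
        "length": np.array([r.length for r in finite], dtype=float),
        "regional_entropy": np.array(
            [r.regional_entropy for r in finite], dtype=float
        ),
    }
    rows = []
    for name, x in covariates.items():
        if np.ptp(x) == 0 or np.ptp(r2) == 0:
            rows.append(
                {"covariate": name, "pcc": np.nan, "p": np.nan, "undefined": True}
            )
            continue
        pcc, p = stats.pearsonr(x, r2)
        rows.append(
            {"covariate": name, "pcc": float(pcc), "p": float(p), "undefined": False}
        )
    table = pd.DataFrame(rows)
    defined = table[~table["undefined"]]
    p_adj = pd.Series(np.nan, index=table.index, dtype=float)
    if len(defined):
        p_adj.loc[defined.index] = benjamini_hochberg(defined["p"].tolist())
    table["p_adj"] = p_adj
    table.attrs["species_flagged"] = bool((table["p_adj"] < 0.05).any())
    return table
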