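"""Region-structured synthetic datasets with known truth.

A dataset emulates one bacterial species sampled across several geographic
regions: a single shared genealogy drawn from an island-model structured
coalescent (within-region pairwise coalescence at rate 1 per pair in
coalescent units; per-lineage migration at total rate ``m`` to a uniformly
chosen other region), per-gene codon alignments evolved down that genealogy
under Jukes-Cantor mutation, and — for "selected" genes — regional
convergence: a fraction ``f`` of stop-safe amino-acid-changing sites
(first/second codon positions) gets a
per-region preferred base, and each tip's state there is overwritten with
probability ``s``. That overwrite creates exactly the signal the geographic
clustering statistic measures (region-correlated sequence variation) with
interpretable knobs, without a fitness-based forward simulation.

Functional labels are assigned so that the selection truth maps onto the
membrane / organelle / metabolic stratification: selected genes are labeled
membrane (half) and metabolic (half), neutral genes organelle. Duplicate-city
tips (with distinct dedup scores) are built in so the tip filters have work
to do.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd
from skbio import TreeNode

from .phylo import (
    CodonAlignment,
    ValidationError,
    neighbor_joining,
    p_distance_matrix,
    read_newick,
    write_newick,
)
from .dnds import STOP_CODONS

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "Bundle",
    "PRESETS",
    "simulate_genealogy",
    "simulate_alignment",
    "simulate_dataset",
    "write_bundle",
]

BASES = np.array(list("ACGT"))
_NON_STOP = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def _stop_safe_site(root_seq: np.ndarray, site: int) -> bool:
    """True when every base at ``site`` keeps the root codon stop-free."""
    start = site - site % 3
    codon = root_seq[start : start + 3].copy()
    for base in BASES:
        codon[site - start] = base
        if "".join(codon) in STOP_CODONS:
            return False
    return True


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study; defaults give the standard recovery regime.

    Rates are per coalescent-time unit; ``mutation_rate`` is per site per
    branch-length unit; ``gene_length`` is in codons. ``selection_fraction``
    is the fraction of stop-safe first/second codon positions constrained in selected
    genes and ``selection_strength`` the probability a constrained site is
    overwritten by its region's preferred base.
    """

    n_regions: int = 3
    samples_per_region: int = 8
    migration_rate: float = 0.1
    effective_size: float = 1.0
    n_genes_neutral: int = 30
    n_genes_selected: int = 30
    gene_length: int = 300
    mutation_rate: float = 0.05
    selection_fraction: float = 0.1
    selection_strength: float = 0.8
    cities_per_region: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 1:
            raise ValidationError("need n_regions >= 1")
        if min(self.migration_rate, self.mutation_rate, self.effective_size) < 0:
            raise ValidationError("rates must be >= 0")
        for name in ("selection_fraction", "selection_strength"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_regions > 1 and self.migration_rate == 0:
            raise ValidationError(
                "migration_rate = 0 with several regions: lineages could "
                "never share a region and the coalescent would not terminate"
            )


PRESETS: dict[str, SimulationParams] = {"fig3": SimulationParams()}


@dataclass
class SyntheticTruth:
    """What the generator knows and the pipeline must recover."""

    selected_gene_ids: set[str]
    params: SimulationParams
    preferred_states: dict[str, dict[str, dict[int, str]]] = field(
        default_factory=dict
    )  # gene -> region -> site index -> base

    def to_json(self) -> str:
        payload = {
            "selected_gene_ids": sorted(self.selected_gene_ids),
            "params": dataclasses.asdict(self.params),
            "preferred_states": {
                g: {r: {str(i): b for i, b in sites.items()} for r, sites in by_r.items()}
                for g, by_r in self.preferred_states.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _region_name(i: int) -> str:
    return f"R{i + 1}"


def simulate_genealogy(
    params: SimulationParams, seed: int | None = None
) -> tuple[TreeNode, pd.DataFrame]:
    """Draw one island-model structured-coalescent genealogy plus tip metadata.

    Branch lengths are in coalescent units (population size scaled by
    ``effective_size``). Tips are labeled ``R<r>_s<i>``; cities are assigned
    round-robin within each region, so with ``cities_per_region <
    samples_per_region`` some cities hold several tips and the city-dedup
    filter is exercised. Dedup scores are drawn uniformly on (0.5, 1).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    r = params.n_regions
    if r == 1:
        demography = msprime.Demography.isolated_model([params.effective_size])
    else:
        demography = msprime.Demography.island_model(
            [params.effective_size] * r,
            migration_rate=params.migration_rate / (r - 1),
        )
    samples = [
        msprime.SampleSet(params.samples_per_region, population=i, ploidy=1)
        for i in range(r)
    ]
    ts = msprime.sim_ancestry(
        samples=samples, demography=demography, ploidy=1, random_seed=ms_seed
    )
    rows = []
    node_labels = {}
    node = 0
    for i in range(r):
        region = _region_name(i)
        for j in range(params.samples_per_region):
            tip = f"{region}_s{j + 1:02d}"
            node_labels[node] = tip
            rows.append(
                {
                    "tip_id": tip,
                    "sample_id": tip,
                    "city": f"{region}_city{j % params.cities_per_region + 1}",
                    "region": region,
                    "dedup_score": round(float(rng.uniform(0.5, 1.0)), 6),
                }
            )
            node += 1
    newick = ts.first().as_newick(node_labels=node_labels)
    tree = read_newick(newick)
    return tree, pd.DataFrame(rows)


def _random_root(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    codons = ["ATG"] + [
        _NON_STOP[k] for k in rng.integers(0, len(_NON_STOP), size=n_codons - 1)
    ]
    return np.array(list("".join(codons)), dtype="U1")


def _creates_stop(seq: np.ndarray, site: int, base: str) -> bool:
    start = site - site % 3
    codon = seq[start : start + 3].copy()
    codon[site - start] = base
    return "".join(codon) in STOP_CODONS


def _mutate_branch(
    seq: np.ndarray, length: float, mu: float, rng: np.random.Generator
) -> np.ndarray:
    # the start codon (sites 0-2) is held invariant: losing a start is
    # lethal in a real gene, and downstream framing rules key on it
    out = seq.copy()
    n_target = out.size - 3
    n_mut = rng.poisson(mu * length * n_target)
    for _ in range(n_mut):
        for _attempt in range(100):
            site = int(rng.integers(3, out.size))
            current = out[site]
            base = BASES[BASES != current][rng.integers(3)]
            if not _creates_stop(out, site, base):
                out[site] = base
                break
    return out


def simulate_alignment(
    tree: TreeNode,
    params: SimulationParams,
    selected: bool,
    rng: np.random.Generator,
    region_of: dict[str, str] | None = None,
) -> tuple[CodonAlignment, dict[str, dict[int, str]]]:
    """Evolve one gene down ``tree`` under Jukes-Cantor mutation.

    Substitution counts per branch are Poisson(μ · branch length · sites)
    with uniform site choice and a uniform alternative base; mutations that
    would create an in-frame stop are resampled. For ``selected`` genes a
    fraction of stop-safe first/second codon positions receives per-region preferred
    bases, overwritten into each tip with probability ``selection_strength``.
    Returns the tip alignment and the region -> site -> preferred-base map
    (empty for neutral genes).
    """
    n_sites = 3 * params.gene_length
    root_seq = _random_root(params.gene_length, rng)

    seqs: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = _mutate_branch(seq, child.length or 0.0, params.mutation_rate, rng)
            if child.is_tip():
                seqs[child.name] = child_seq
            else:
                descend(child, child_seq)

    descend(tree, root_seq)

    preferred: dict[str, dict[int, str]] = {}
    if selected and params.selection_fraction > 0 and params.selection_strength > 0:
        if region_of is None:
            raise ValidationError("selected genes need a tip -> region map")
        # local adaptation is protein-level: constrained sites sit at first
        # and second codon positions (changes there are almost always
        # amino-acid changing), restricted to positions where any base keeps
        # the root codon stop-free
        eligible = [
            site
            for k in range(1, params.gene_length)
            for site in (3 * k, 3 * k + 1)
            if _stop_safe_site(root_seq, site)
        ]
        n_constrained = int(round(params.selection_fraction * len(eligible)))
        sites = sorted(
            rng.choice(eligible, size=n_constrained, replace=False).tolist()
        )
        regions = sorted(set(region_of.values()))
        # Regions adapt divergently: preferred states are distinct across
        # regions at each constrained site (possible for <= 4 regions; with
        # more regions than bases, draws are independent). Two regions
        # sharing a preferred state would experience no differential
        # selection at that site.
        per_site: dict[int, dict[str, str]] = {}
        for s in sites:
            if len(regions) <= 4:
                picks = rng.choice(4, size=len(regions), replace=False)
            else:
                picks = rng.integers(0, 4, size=len(regions))
            per_site[s] = {r: str(BASES[p]) for r, p in zip(regions, picks)}
        for region in regions:
            preferred[region] = {s: per_site[s][region] for s in sites}
        for tip, seq in seqs.items():
            prefs = preferred[region_of[tip]]
            for site, base in prefs.items():
                if rng.random() < params.selection_strength and not _creates_stop(
                    seq, site, base
                ):
                    seq[site] = base

    ids = sorted(seqs)
    return CodonAlignment(tuple(ids), np.vstack([seqs[t] for t in ids])), preferred


@dataclass
class Bundle:
    """One synthetic species dataset: inputs for every pipeline stage."""

    params: SimulationParams
    species_tree: TreeNode
    meta: pd.DataFrame
    gene_alignments: dict[str, CodonAlignment]
    gene_trees: dict[str, TreeNode]
    annotations: pd.DataFrame
    truth: SyntheticTruth


def _gene_labels(params: SimulationParams) -> list[tuple[str, bool, str]]:
    """(gene_id, selected, cc_label) triples; labels encode the truth mapping."""
    out = []
    n_sel = params.n_genes_selected
    for i in range(n_sel):
        if i < (n_sel + 1) // 2:
            cc = "membrane"
        else:
            # metabolic pool: alternate an explicit non-selected top-level
            # term with "unannotated" so both ingestion paths are exercised
            cc = "cytoplasm" if i % 2 else ""
        out.append((f"gene{i + 1:04d}", True, cc))
    for j in range(params.n_genes_neutral):
        out.append((f"gene{n_sel + j + 1:04d}", False, "organelle"))
    return out


def simulate_dataset(params: SimulationParams | None = None) -> Bundle:
    """Generate a full dataset: genealogy, gene alignments, NJ gene trees,
    metadata, annotations, and the truth record. Deterministic given the seed.

    Gene trees are rebuilt by neighbor joining from each gene's
    Jukes-Cantor-corrected p-distances rather than copied from the true
    genealogy, so tree-estimation noise is part of every recovery test.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    tree, meta = simulate_genealogy(params, seed=int(rng.integers(1, 2**31 - 1)))
    region_of = dict(zip(meta["tip_id"], meta["region"]))

    alignments: dict[str, CodonAlignment] = {}
    gene_trees: dict[str, TreeNode] = {}
    ann_rows = []
    truth = SyntheticTruth(set(), params)
    for gene_id, is_selected, cc in _gene_labels(params):
        aln, preferred = simulate_alignment(tree, params, is_selected, rng, region_of)
        alignments[gene_id] = aln
        with warnings.catch_warnings():
            # deep-divergence pairs may saturate; the cap is intentional here
            warnings.simplefilter("ignore")
            gene_trees[gene_id] = neighbor_joining(
                p_distance_matrix(aln, correction="jukes_cantor")
            )
        ann_rows.append({"gene_id": gene_id, "cc_labels": cc})
        if is_selected:
            truth.selected_gene_ids.add(gene_id)
            truth.preferred_states[gene_id] = preferred

    annotations = pd.DataFrame(ann_rows)
    # Truth / annotation consistency is structural; assert it on every bundle.
    organelle = set(annotations.loc[annotations.cc_labels == "organelle", "gene_id"])
    assert organelle.isdisjoint(truth.selected_gene_ids)
    membrane = set(annotations.loc[annotations.cc_labels == "membrane", "gene_id"])
    assert membrane <= truth.selected_gene_ids
    return Bundle(params, tree, meta, alignments, gene_trees, annotations, truth)


def write_bundle(bundle: Bundle, outdir: str | Path) -> None:
    """Write the bundle as plain-text files: species.nwk, genes/*.fasta,
    genes/*.nwk, meta.tsv, annotations.tsv, truth.json."""
    outdir = Path(outdir)
    (outdir / "genes").mkdir(parents=True, exist_ok=True)
    write_newick(bundle.species_tree, outdir / "species.nwk")
    bundle.meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    bundle.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    for gene_id, aln in bundle.gene_alignments.items():
        aln.to_fasta(outdir / "genes" / f"{gene_id}.fasta")
        write_newick(bundle.gene_trees[gene_id], outdir / "genes" / f"{gene_id}.nwk")
    (outdir / "truth.json").write_text(bundle.truth.to_json() + "\n")
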