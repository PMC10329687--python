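"""Per-gene dN/dS by the Nei-Gojobori (1986) counting method.

One ratio per gene, computed from the in-frame codon alignment under the
bacterial genetic code (translation table 11). Synonymous/nonsynonymous site
counts enumerate the three single-base mutations at each codon position,
excluding mutations to stop codons from the denominator; pairwise differences
are classified by averaging over all shortest substitution pathways with
equal weight, dropping pathways that pass through a stop codon. Proportions
are Jukes-Cantor corrected (d = -¾·ln(1 - 4p/3)). Genes enter the
calculation only if they show nucleotide variation, start with a valid
bacterial start codon (ATG, TTG, or GTG), and have trailing stop codons
trimmed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .genegroups import GeneRecord, GroupComparison, compare_groups
from .phylo import CodonAlignment, VALID_BASES, ValidationError

__all__ = [
    "DnDsResult",
    "select_variable_genes",
    "frame_and_trim",
    "ng86",
    "ng86_pair",
    "dnds_group_contrast",
    "BACTERIAL_TABLE",
    "STOP_CODONS",
    "START_CODONS",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"

# NCBI translation table 11 (bacterial/archaeal/plant plastid).
_T11_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
BACTERIAL_TABLE: dict[str, str] = {
    a + b + c: aa
    for (a, b, c), aa in zip(itertools.product("TCAG", repeat=3), _T11_AAS)
}
STOP_CODONS = frozenset(c for c, aa in BACTERIAL_TABLE.items() if aa == "*")
START_CODONS = frozenset({"ATG", "TTG", "GTG"})


def _translate(codon: str) -> str:
    return BACTERIAL_TABLE[codon]


def _is_clean(codon: str) -> bool:
    return all(b in VALID_BASES for b in codon)


@dataclass
class DnDsResult:
    """NG86 site and difference counts plus corrected rates for one gene.

    ``ratio`` is NaN (undefined) when dS = 0 or when either proportion is
    saturated (p >= 3/4, where the Jukes-Cantor correction diverges);
    ``status`` then says why.
    """

    gene_id: str
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    dn: float
    ds: float
    ratio: float
    status: str = "ok"

    @property
    def defined(self) -> bool:
        return math.isfinite(self.ratio)


def select_variable_genes(
    alns: Mapping[str, CodonAlignment]
) -> list[str]:
    """Genes with at least one column holding two distinct non-gap, non-N bases.

    Variation between a gap (or N) and a base does not count: only genuine
    nucleotide polymorphism qualifies a gene for dN/dS.
    """
    keep = []
    for gene_id, aln in alns.items():
        seqs = aln.seqs
        valid = np.isin(seqs, list(VALID_BASES))
        for col in range(aln.length):
            bases = set(seqs[valid[:, col], col].tolist())
            if len(bases) >= 2:
                keep.append(gene_id)
                break
    return keep


def _consensus_codon(aln: CodonAlignment, start: int) -> str:
    """Column-majority codon at positions [start, start+3); ties by base order."""
    out = []
    for col in range(start, start + 3):
        column = aln.seqs[:, col]
        counts = {b: int((column == b).sum()) for b in BASES}
        out.append(max(counts, key=lambda b: (counts[b], -BASES.index(b))))
    return "".join(out)


def frame_and_trim(
    aln: CodonAlignment,
) -> tuple[CodonAlignment | None, str | None]:
    """Enforce the gene-inclusion framing rules.

    Returns ``(framed_alignment, None)`` on success or ``(None, reason)`` when
    the gene is excluded: ``"too_short"`` (< 6 positions), ``"no_start"``
    (consensus first codon not ATG/TTG/GTG). The length is truncated to a
    multiple of 3 and trailing (consensus) stop codons are removed.
    """
    if aln.length < 6:
        return None, "too_short"
    length = aln.length - aln.length % 3
    seqs = aln.seqs[:, :length]
    framed = CodonAlignment(aln.ids, seqs)
    if _consensus_codon(framed, 0) not in START_CODONS:
        return None, "no_start"
    while framed.length >= 6 and _consensus_codon(
        framed, framed.length - 3
    ) in STOP_CODONS:
        framed = CodonAlignment(framed.ids, framed.seqs[:, : framed.length - 3])
    return framed, None


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions for one codon.

    Each position contributes its fraction of synonymous single-base changes
    among the non-stop alternatives; positions always sum to 1 site each, so
    s + n = 3 exactly.
    """
    if codon in STOP_CODONS or not _is_clean(codon):
        raise ValueError(f"cannot count sites for codon {codon!r}")
    aa = _translate(codon)
    syn = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            n_valid += 1
            if _translate(mutant) == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_diffs(c1: str, c2: str) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are dropped. Returns None when every pathway passes
    through a stop (the codon pair is then skipped).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            steps.append((current, nxt))
            current = nxt
        if not blocked:
            pathways.append(steps)
    if not pathways:
        return None
    syn = nonsyn = 0.0
    for steps in pathways:
        for a, b in steps:
            if _translate(a) == _translate(b):
                syn += 1
            else:
                nonsyn += 1
    k = len(pathways)
    return syn / k, nonsyn / k


def _jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction; NaN at saturation (p >= 3/4)."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _sequence_sites(codons: Sequence[str]) -> tuple[float, float]:
    syn = nonsyn = 0.0
    for codon in codons:
        if not _is_clean(codon) or codon in STOP_CODONS:
            continue
        s, n = _codon_sites(codon)
        syn += s
        nonsyn += n
    return syn, nonsyn


def _codons(seq_row: np.ndarray) -> list[str]:
    s = "".join(seq_row)
    return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


def ng86(aln: CodonAlignment, gene_id: str = "gene") -> DnDsResult:
    """NG86 dN/dS for one framed codon alignment (>= 2 sequences).

    S and N are averaged over sequences; Sd and Nd are averaged over all
    sequence pairs, skipping codons that contain a gap or N in either member
    of a pair and codon pairs whose every substitution pathway passes through
    a stop.
    """
    if aln.n_seq < 2:
        raise ValidationError("ng86 needs at least 2 sequences")
    if aln.length % 3 != 0:
        raise ValidationError("alignment length is not a multiple of 3")
    codon_rows = [_codons(row) for row in aln.seqs]

    per_seq = [_sequence_sites(row) for row in codon_rows]
    syn_sites = float(np.mean([s for s, _ in per_seq]))
    nonsyn_sites = float(np.mean([n for _, n in per_seq]))

    sd_list, nd_list = [], []
    for i, j in itertools.combinations(range(aln.n_seq), 2):
        sd = nd = 0.0
        for c1, c2 in zip(codon_rows[i], codon_rows[j]):
            if not (_is_clean(c1) and _is_clean(c2)):
                continue
            if c1 in STOP_CODONS or c2 in STOP_CODONS:
                continue
            diffs = _codon_diffs(c1, c2)
            if diffs is None:
                logger.info("%s: codon pair %s/%s stop-blocked; skipped", gene_id, c1, c2)
                continue
            sd += diffs[0]
            nd += diffs[1]
        sd_list.append(sd)
        nd_list.append(nd)
    syn_diffs = float(np.mean(sd_list))
    nonsyn_diffs = float(np.mean(nd_list))

    ps = syn_diffs / syn_sites if syn_sites > 0 else math.nan
    pn = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else math.nan
    ds = _jc_correct(ps) if math.isfinite(ps) else math.nan
    dn = _jc_correct(pn) if math.isfinite(pn) else math.nan

    status = "ok"
    if not (math.isfinite(dn) and math.isfinite(ds)):
        ratio = math.nan
        status = "saturated"
    elif ds == 0:
        ratio = math.nan
        status = "ds_zero"
    else:
        ratio = dn / ds
    return DnDsResult(
        gene_id, syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs, dn, ds, ratio,
        status,
    )


def ng86_pair(seq1: str, seq2: str) -> DnDsResult:
    """Convenience: NG86 on a single pair of equal-length in-frame sequences."""
    return ng86(CodonAlignment.from_dict({"seq1": seq1, "seq2": seq2}), "pair")


def dnds_group_contrast(
    results: Sequence[DnDsResult],
    groups: Mapping[str, str],
    alpha: float = 0.05,
) -> GroupComparison:
    """Contrast dN/dS ratios between functional gene groups.

    Undefined ratios (dS = 0 or saturated) are excluded; usable counts are
    reported per group in the returned comparison.
    """
    records = []
    excluded = 0
    for res in results:
        if not res.defined:
            excluded += 1
            continue
        records.append(
            GeneRecord(
                gene_id=res.gene_id,
                group=groups.get(res.gene_id, "metabolic"),
                length=0,
                mean_pi=math.nan,
                regional_entropy=math.nan,
                n_tips=0,
                r2=math.nan,
                p_value=math.nan,
                dnds=res.ratio,
            )
        )
    if excluded:
        logger.info("%d gene(s) with undefined dN/dS excluded from contrast", excluded)
    return compare_groups(records, value="dnds", alpha=alpha)
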