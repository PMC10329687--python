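"""Trees, alignments and distances.

Gene trees and species trees are handled as :class:`skbio.TreeNode` objects
with branch lengths in substitutions/site (or simulator time units), pairwise
tip distances as :class:`skbio.DistanceMatrix`. The module also implements the
tip-filtering rules applied before any geographic clustering test: city-level
deduplication by score and removal of sole regional representatives.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

__all__ = [
    "NewickFormatError",
    "ValidationError",
    "CodonAlignment",
    "FilterResult",
    "read_newick",
    "write_newick",
    "patristic_distances",
    "p_distance_matrix",
    "neighbor_joining",
    "filter_tips",
    "read_tip_metadata",
]

#: Distances are capped here when Jukes-Cantor correction diverges (p >= 3/4).
JC_SATURATION_CAP = 5.0

VALID_BASES = frozenset("ACGT")
VALID_ALPHABET = frozenset("ACGT-N")

METADATA_COLUMNS = ["tip_id", "sample_id", "city", "region", "dedup_score"]


class NewickFormatError(ValueError):
    """Malformed newick input; carries the byte offset of the first defect."""

    def __init__(self, message: str, byte_offset: int | None = None):
        if byte_offset is not None:
            message = f"{message} (byte offset {byte_offset})"
        super().__init__(message)
        self.byte_offset = byte_offset


class ValidationError(ValueError):
    """Input violates a documented invariant (duplicate labels, bad lengths...)."""


def _locate_newick_defect(text: str) -> int:
    """Best-effort byte offset of the first structural defect in a newick string."""
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
        elif ch == ";" and depth > 0:
            return i
    if depth > 0:
        return len(text)
    if ";" not in text:
        return len(text)
    return 0


def read_newick(source: str | Path | io.TextIOBase) -> TreeNode:
    """Read a single newick tree and validate it.

    Missing branch lengths are set to 0 with a warning; negative lengths and
    duplicate tip labels are rejected. The tree must have at least two tips.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = str(source)
        if "(" not in text:  # a path, not inline newick
            text = Path(source).read_text()
    try:
        with warnings.catch_warnings():
            # the registry's format sniffer re-warns on inputs we already
            # diagnose with a byte offset below
            warnings.simplefilter("ignore")
            tree = TreeNode.read(
                io.StringIO(text), format="newick", convert_underscores=False
            )
    except Exception as exc:  # skbio raises its own parse errors
        raise NewickFormatError(
            f"could not parse newick: {exc}", _locate_newick_defect(text)
        ) from exc
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    """Enforce the tree invariants: unique tips, finite lengths >= 0, >= 2 tips."""
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValidationError(f"tree has {len(tips)} tip(s); need at least 2")
    names = [t.name for t in tips]
    if any(n is None for n in names):
        raise ValidationError("unlabeled tip in tree")
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif not math.isfinite(node.length) or node.length < 0:
            raise ValidationError(
                f"branch length {node.length!r} on edge above "
                f"{node.name or 'internal node'} is not a finite value >= 0"
            )
    if n_missing:
        warnings.warn(
            f"{n_missing} edge(s) had no branch length; set to 0", stacklevel=2
        )
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Pairwise tip-to-tip path-length (patristic) distances."""
    validate_tree(tree)
    return tree.tip_tip_distances()


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame nucleotide multiple alignment.

    ``seqs`` is an (n_sequences, length) array of single characters drawn from
    {A, C, G, T, -, N}; rows are ordered as ``ids``.
    """

    ids: tuple[str, ...]
    seqs: np.ndarray

    def __post_init__(self):
        if self.seqs.ndim != 2 or len(self.ids) != self.seqs.shape[0]:
            raise ValidationError("ids and sequence rows disagree")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sequence ids")
        observed = set(np.unique(self.seqs).tolist())
        bad = observed - VALID_ALPHABET
        if bad:
            raise ValidationError(f"invalid alignment characters: {sorted(bad)}")

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str]) -> "CodonAlignment":
        ids = tuple(mapping)
        lengths = {len(s) for s in mapping.values()}
        if len(lengths) > 1:
            raise ValidationError(f"unequal sequence lengths: {sorted(lengths)}")
        arr = np.array([list(s.upper()) for s in mapping.values()], dtype="U1")
        return cls(ids, arr)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CodonAlignment":
        with open(path) as handle:
            records = {r.id: str(r.seq) for r in SeqIO.parse(handle, "fasta")}
        if len(records) < 1:
            raise ValidationError(f"no sequences in {path}")
        return cls.from_dict(records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq("".join(row)), id=name, description="")
            for name, row in zip(self.ids, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    @property
    def n_seq(self) -> int:
        return self.seqs.shape[0]

    def sequence(self, seq_id: str) -> str:
        return "".join(self.seqs[self.ids.index(seq_id)])


def jukes_cantor(p: float) -> float:
    """JC69 distance for proportion of differing sites ``p``; capped at saturation."""
    if p >= 0.75:
        return JC_SATURATION_CAP
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def p_distance_matrix(
    aln: CodonAlignment, correction: str = "none"
) -> DistanceMatrix:
    """Pairwise sequence distances with pairwise deletion of gaps/Ns.

    ``correction`` is ``"none"`` (raw p-distance) or ``"jukes_cantor"``.
    Saturated pairs (p >= 0.75 under JC) are set to :data:`JC_SATURATION_CAP`
    with a warning, keeping downstream neighbor joining finite.
    """
    if correction not in ("none", "jukes_cantor"):
        raise ValueError(f"unknown correction {correction!r}")
    if aln.n_seq < 2:
        raise ValidationError("need at least 2 sequences")
    valid = np.isin(aln.seqs, list(VALID_BASES))
    n = aln.n_seq
    out = np.zeros((n, n))
    saturated = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                warnings.warn(
                    f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}; "
                    "distance set to saturation cap",
                    stacklevel=2,
                )
                d = JC_SATURATION_CAP
            else:
                p = float((aln.seqs[i][both] != aln.seqs[j][both]).sum() / compared)
                if correction == "jukes_cantor":
                    if p >= 0.75:
                        saturated += 1
                    d = jukes_cantor(p)
                else:
                    d = p
            out[i, j] = out[j, i] = d
    if saturated:
        warnings.warn(
            f"{saturated} pair(s) saturated under Jukes-Cantor; "
            f"capped at {JC_SATURATION_CAP}",
            stacklevel=2,
        )
    return DistanceMatrix(out, ids=list(aln.ids))


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Negative branch length estimates are clamped to 0 (standard practice for
    noisy distance inputs).
    """
    if dm.shape[0] < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    return _skbio_nj(dm, neg_as_zero=True)


def read_tip_metadata(path: str | Path) -> pd.DataFrame:
    """Read the tip metadata TSV (tip_id, sample_id, city, region, dedup_score)."""
    meta = pd.read_csv(path, sep="\t", dtype={"tip_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    if meta["tip_id"].duplicated().any():
        raise ValidationError("duplicate tip_id in metadata")
    return meta


@dataclass
class FilterResult:
    """Outcome of the pre-test tip filters.

    ``status`` is ``"tested"`` when the filtered matrix is eligible for a
    geographic clustering test (>= 2 regions remain, each with >= 2 tips) and
    ``"untestable"`` otherwise. ``dropped`` maps removed tip ids to the rule
    that removed them (``"city_duplicate"`` or ``"sole_region_representative"``).
    """

    matrix: DistanceMatrix | None
    kept: tuple[str, ...]
    status: str
    n_regions: int
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def testable(self) -> bool:
        return self.status == "tested"


def filter_tips(dm: DistanceMatrix, meta: pd.DataFrame) -> FilterResult:
    """Apply the pre-test tip filters to a distance matrix.

    1. Among tips sharing a city, keep only the tip with the highest
       dedup_score (ties broken by lexicographically smallest tip_id).
    2. Drop any tip that is then the sole representative of its region.
    3. Declare the result testable only if >= 2 distinct regions remain
       (each necessarily with >= 2 tips after step 2).
    """
    labels = list(dm.ids)
    meta_idx = meta.set_index("tip_id")
    missing = [t for t in labels if t not in meta_idx.index]
    if missing:
        raise ValidationError(f"tips absent from metadata: {missing}")
    sub = meta_idx.loc[labels]

    dropped: dict[str, str] = {}
    kept: list[str] = []
    for _, group in sub.groupby("city", sort=False):
        ranked = group.assign(_tip=group.index).sort_values(
            ["dedup_score", "_tip"], ascending=[False, True], kind="mergesort"
        )
        winner = ranked.index[0]
        kept.append(winner)
        for loser in ranked.index[1:]:
            dropped[loser] = "city_duplicate"

    region_counts = sub.loc[kept, "region"].value_counts()
    final = []
    for tip in kept:
        if region_counts[sub.loc[tip, "region"]] < 2:
            dropped[tip] = "sole_region_representative"
        else:
            final.append(tip)
    if not final:
        raise ValidationError("no tips remain after filtering")
    final = [t for t in labels if t in set(final)]  # preserve input order
    n_regions = sub.loc[final, "region"].nunique()
    status = "tested" if n_regions >= 2 else "untestable"
    matrix = dm.filter(final) if len(final) >= 2 else None
    return FilterResult(matrix, tuple(final), status, int(n_regions), dropped)
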