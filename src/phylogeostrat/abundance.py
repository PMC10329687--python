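"""Genome-abundance normalization and diversity.

Read-count matrices (samples × genomes) are filtered by comparing the
observed covered fraction of each genome against its expected coverage
``c = 1 - (1 - l/g)^r`` (l mean read length, g genome length, r mapped
reads), rarefied to a common depth by sampling without replacement, and
converted to length-normalized TPM, from which Shannon diversity per sample
is computed. A two-sample Kolmogorov-Smirnov test compares per-phylum
composition between sample sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import ValidationError

__all__ = [
    "CountMatrix",
    "expected_coverage",
    "coverage_filter",
    "rarefy",
    "tpm",
    "shannon_diversity",
    "composition_ks",
]

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Integer read counts per sample (rows) × genome (columns).

    ``genome_lengths`` (bp) is indexed by genome; ``read_length`` is the mean
    mapped read length in bp.
    """

    counts: pd.DataFrame
    genome_lengths: pd.Series
    read_length: float

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64)
        if (self.counts.values < 0).any():
            raise ValidationError("negative read counts")
        self.genome_lengths = self.genome_lengths.astype(float)
        missing = [g for g in self.counts.columns if g not in self.genome_lengths.index]
        if missing:
            raise ValidationError(f"genomes without lengths: {missing}")
        self.genome_lengths = self.genome_lengths.loc[self.counts.columns]
        if (self.genome_lengths <= 0).any():
            raise ValidationError("genome lengths must be positive")
        if self.read_length <= 0:
            raise ValidationError("read length must be positive")

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, lengths_path: str | Path, read_length: float
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(counts, lengths, read_length)


def expected_coverage(l: float, g: float, r) -> float | np.ndarray:
    """Expected fraction of a genome covered by ``r`` reads of length ``l``.

    ``c = 1 - (1 - l/g)^r`` — each read independently covers a fraction l/g.
    Monotone nondecreasing in r; 0 at r = 0; exactly 1 when l = g, r >= 1.
    """
    if not 0 < l <= g:
        raise ValidationError(f"need 0 < read length ({l}) <= genome length ({g})")
    r_arr = np.asarray(r, dtype=float)
    if (r_arr < 0).any():
        raise ValidationError("read counts must be >= 0")
    c = -np.expm1(r_arr * np.log1p(-l / g)) if l < g else (r_arr > 0).astype(float)
    return c if c.ndim else float(c)


def coverage_filter(
    cm: CountMatrix,
    observed_covered_fraction: pd.DataFrame,
    min_ratio: float = 0.5,
    direction: str = "observed_over_expected",
) -> CountMatrix:
    """Zero out cells whose coverage ratio falls below ``min_ratio``.

    The expected coverage comes from the count matrix itself; the observed
    covered fraction (per sample × genome, in [0, 1]) is an input, since
    computing it needs per-base mapping depth. ``direction`` selects which
    way the ratio is formed; the default tests observed/expected >= 0.5.
    Cells with zero expected coverage (no reads) are already zero and stay so.
    """
    if direction not in ("observed_over_expected", "expected_over_observed"):
        raise ValueError(f"unknown direction {direction!r}")
    obs = observed_covered_fraction.reindex(
        index=cm.counts.index, columns=cm.counts.columns
    )
    if obs.isna().any().any():
        raise ValidationError("observed covered fraction missing cells")
    if ((obs.values < 0) | (obs.values > 1)).any():
        raise ValidationError("observed covered fraction outside [0, 1]")
    expected = np.vstack(
        [
            expected_coverage(cm.read_length, cm.genome_lengths[g], cm.counts[g].values)
            for g in cm.counts.columns
        ]
    ).T
    with np.errstate(divide="ignore", invalid="ignore"):
        if direction == "observed_over_expected":
            ratio = np.where(expected > 0, obs.values / np.where(expected > 0, expected, 1), np.inf)
        else:
            ratio = np.where(obs.values > 0, expected / np.where(obs.values > 0, obs.values, 1), np.inf)
    keep = ratio >= min_ratio
    filtered = cm.counts.where(keep, 0)
    return CountMatrix(filtered, cm.genome_lengths, cm.read_length)


def rarefy(cm: CountMatrix, depth: int, seed: int | np.random.Generator | None = None) -> CountMatrix:
    """Subsample each sample's reads to ``depth`` without replacement.

    One seeded multivariate-hypergeometric draw per sample (the behavior of
    vegan's ``rrarefy``); samples with fewer than ``depth`` total reads are
    dropped with a warning. Row sums of the result equal ``depth`` exactly.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = cm.counts.sum(axis=1)
    shallow = totals.index[totals < depth].tolist()
    if shallow:
        warnings.warn(
            f"samples below rarefaction depth {depth} dropped: {shallow}",
            stacklevel=2,
        )
    kept = cm.counts.loc[totals >= depth]
    if kept.empty:
        raise ValidationError("no samples reach the rarefaction depth")
    rows = [
        rng.multivariate_hypergeometric(row.values, depth)
        for _, row in kept.iterrows()
    ]
    out = pd.DataFrame(rows, index=kept.index, columns=kept.columns)
    return CountMatrix(out, cm.genome_lengths, cm.read_length)


def tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-kilobase-million normalization of the count matrix.

    Counts are divided by genome length in kb, then each sample row is scaled
    to sum to 1e6. All-zero rows stay zero (logged).
    """
    rate = cm.counts / (cm.genome_lengths / 1000.0)
    row_sums = rate.sum(axis=1)
    zero_rows = row_sums.index[row_sums == 0].tolist()
    if zero_rows:
        logger.info("all-zero TPM row(s): %s", zero_rows)
    scale = row_sums.replace(0, np.nan)
    out = rate.div(scale, axis=0) * 1e6
    return out.fillna(0.0)


def shannon_diversity(tpm_row) -> float:
    """Shannon index (nats) of one sample's abundance profile.

    Scale-invariant: raw counts, proportions, and TPM all give the same value.
    Returns NaN (undefined) for an all-zero row.
    """
    q = np.asarray(tpm_row, dtype=float)
    if (q < 0).any():
        raise ValidationError("abundances must be nonnegative")
    total = q.sum()
    if total <= 0:
        return float("nan")
    return float(stats.entropy(q / total))


def composition_ks(freq_a, freq_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on per-phylum frequency samples.

    Returns (D, p) with D the sup-distance between the two empirical CDFs and
    the asymptotic two-sided p-value.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty frequency vector")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
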