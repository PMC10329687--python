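import itertools
import math
import warnings

import numpy as np
import pytest

from phylogeostrat.dnds import (
    BACTERIAL_TABLE,
    STOP_CODONS,
    DnDsResult,
    dnds_group_contrast,
    frame_and_trim,
    ng86,
    ng86_pair,
    select_variable_genes,
)
from phylogeostrat.phylo import CodonAlignment
from phylogeostrat.synthetic import SimulationParams, simulate_alignment, simulate_genealogy


def aln(mapping):
    return CodonAlignment.from_dict(mapping)


# ---------------------------------------------------------------------------
# independent oracle: direct recursive enumeration of mutation pathways
# ---------------------------------------------------------------------------

def oracle_site_counts(codon):
    """Fraction of single-base changes (excluding to-stop) that are synonymous."""
    syn = 0.0
    for pos in range(3):
        alts = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in "ACGT"
            if b != codon[pos]
        ]
        alts = [a for a in alts if a not in STOP_CODONS]
        if alts:
            syn += sum(
                BACTERIAL_TABLE[a] == BACTERIAL_TABLE[codon] for a in alts
            ) / len(alts)
    return syn, 3 - syn


def oracle_pair_diffs(c1, c2):
    """Average syn/nonsyn steps over all stop-free orderings of the changes."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    results = []

    def walk(current, remaining, steps):
        if not remaining:
            results.append(steps)
            return
        for pos in remaining:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                continue
            syn = BACTERIAL_TABLE[current] == BACTERIAL_TABLE[nxt]
            walk(nxt, [p for p in remaining if p != pos], steps + [syn])

    walk(c1, positions, [])
    if not results:
        return None
    sd = sum(sum(r) for r in results) / len(results)
    nd = sum(len(r) - sum(r) for r in results) / len(results)
    return sd, nd


ALL_SENSE_CODONS = [c for c in BACTERIAL_TABLE if c not in STOP_CODONS]


class TestSelectVariableGenes:
    def test_invariant_alignment_excluded(self):
        alns = {"g": aln({"a": "ATGAAA", "b": "ATGAAA"})}
        assert select_variable_genes(alns) == []

    def test_single_snp_column_included(self):
        alns = {"g": aln({"a": "ATGAAA", "b": "ATGAAG"})}
        assert select_variable_genes(alns) == ["g"]

    def test_gap_versus_base_is_not_variation(self):
        alns = {"g": aln({"a": "ATGAAA", "b": "ATGAA-", "c": "ATGAAN"})}
        assert select_variable_genes(alns) == []


class TestFrameAndTrim:
    def test_trailing_stop_trimmed(self):
        framed, reason = frame_and_trim(aln({"a": "ATGAAATAA", "b": "ATGAAATAA"}))
        assert reason is None
        assert framed.length == 6
        assert framed.sequence("a") == "ATGAAA"

    def test_ttg_start_accepted(self):
        framed, reason = frame_and_trim(aln({"a": "TTGGCC", "b": "TTGGCC"}))
        assert reason is None and framed is not None

    def test_gtg_start_accepted(self):
        framed, reason = frame_and_trim(aln({"a": "GTGGCCAAA", "b": "GTGGCCAAA"}))
        assert reason is None

    def test_no_start_codon_rejected(self):
        framed, reason = frame_and_trim(aln({"a": "CCCAAA", "b": "CCCAAA"}))
        assert framed is None and reason == "no_start"

    def test_length_truncated_to_codon_multiple(self):
        framed, _ = frame_and_trim(aln({"a": "ATGAAAGG", "b": "ATGAAAGG"}))
        assert framed.length == 6

    def test_too_short_rejected(self):
        framed, reason = frame_and_trim(aln({"a": "ATG", "b": "ATG"}))
        assert framed is None and reason == "too_short"


class TestNg86:
    def test_identical_sequences_undefined_ratio(self):
        res = ng86_pair("ATGAAA", "ATGAAA")
        assert res.syn_diffs == 0 and res.nonsyn_diffs == 0
        assert not res.defined

    def test_single_synonymous_change(self):
        # TTT -> TTC is Phe -> Phe: one synonymous difference, dN = 0
        res = ng86_pair("ATGTTT", "ATGTTC")
        assert res.syn_diffs == pytest.approx(1.0)
        assert res.nonsyn_diffs == 0.0
        assert res.dn == 0.0
        # with only 1/3 synonymous site the toy pair saturates pS; add
        # synonymous capacity (CTN codons are 4-fold Leu) for a finite dS
        res2 = ng86_pair("ATGCTACTCCTGTTT", "ATGCTACTCCTGTTC")
        assert res2.syn_diffs == pytest.approx(1.0)
        assert res2.nonsyn_diffs == 0.0
        assert res2.dn == 0.0 and res2.ds > 0
        assert res2.ratio == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_site_counts_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        codons = [ALL_SENSE_CODONS[i] for i in rng.integers(0, 61, size=3)]
        seq = "".join(codons)
        res = ng86_pair(seq, seq)
        s_exp = sum(oracle_site_counts(c)[0] for c in codons)
        assert res.syn_sites == pytest.approx(s_exp, abs=1e-9)
        assert res.syn_sites + res.nonsyn_sites == pytest.approx(9.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_pathway_average_matches_oracle_on_multi_hit_codons(self, seed):
        rng = np.random.default_rng(100 + seed)
        c1, c2 = (ALL_SENSE_CODONS[i] for i in rng.integers(0, 61, size=2))
        expected = oracle_pair_diffs(c1, c2)
        res = ng86_pair("ATG" + c1, "ATG" + c2)
        if expected is None:
            assert res.syn_diffs == 0 and res.nonsyn_diffs == 0
        else:
            assert res.syn_diffs == pytest.approx(expected[0], abs=1e-12)
            assert res.nonsyn_diffs == pytest.approx(expected[1], abs=1e-12)

    def test_two_position_codon_explicit_orderings(self):
        # TTT -> GTA: pathways TTT->GTT->GTA (nonsyn Phe->Val, syn Val->Val)
        # and TTT->TTA->GTA (nonsyn Phe->Leu, nonsyn Leu->Val)
        expected = oracle_pair_diffs("TTT", "GTA")
        assert expected == (0.5, 1.5)
        res = ng86_pair("ATGTTT", "ATGGTA")
        assert (res.syn_diffs, res.nonsyn_diffs) == expected

    def test_symmetric_in_sequence_order(self):
        a, b = "ATGTTTACA", "ATGGTACCA"
        r1, r2 = ng86_pair(a, b), ng86_pair(b, a)
        assert r1.syn_diffs == r2.syn_diffs
        assert r1.nonsyn_diffs == r2.nonsyn_diffs
        assert r1.syn_sites == pytest.approx(r2.syn_sites)

    def test_gapped_codons_skipped_per_pair(self):
        res = ng86_pair("ATGTTTAAA", "ATGTT-AAG")
        # middle codon has a gap: only the AAA/AAG difference (syn) counts
        assert res.syn_diffs == pytest.approx(1.0)
        assert res.nonsyn_diffs == 0.0

    def test_site_count_conservation_on_bundle_genes(self, small_bundle):
        gene_id = sorted(small_bundle.gene_alignments)[0]
        a = small_bundle.gene_alignments[gene_id]
        res = ng86(a, gene_id)
        assert res.syn_sites + res.nonsyn_sites == pytest.approx(
            3 * (a.length // 3), abs=1e-6
        )

    def test_matches_biopython_reference_pairwise(self):
        Bio = pytest.importorskip("Bio.codonalign.codonseq")
        from Bio.Data import CodonTable

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t11 = CodonTable.unambiguous_dna_by_id[11]
            rng = np.random.default_rng(42)
            base = [ALL_SENSE_CODONS[i] for i in rng.integers(0, 61, size=30)]
            other = list(base)
            # a few scattered substitutions, keeping divergence moderate
            for k in (2, 7, 11, 19, 25):
                for _ in range(10):
                    cand = ALL_SENSE_CODONS[int(rng.integers(0, 61))]
                    if sum(x != y for x, y in zip(cand, other[k])) == 1:
                        other[k] = cand
                        break
            s1, s2 = "".join(base), "".join(other)
            dn_ref, ds_ref = Bio.cal_dn_ds(
                Bio.CodonSeq(s1), Bio.CodonSeq(s2), method="NG86", codon_table=t11
            )
        res = ng86_pair(s1, s2)
        # the reference counts mutations-to-stop as nonsynonymous sites while
        # this implementation excludes them from the site denominator; the
        # conventions differ by a few percent of the site totals at most
        assert res.dn == pytest.approx(dn_ref, rel=0.05, abs=1e-3)
        assert res.ds == pytest.approx(ds_ref, rel=0.05, abs=1e-3)

    def test_neutral_simulation_ratio_not_above_one(self):
        # without selection the NG86 ratio should scatter around 1: a sign
        # test across seeds must not show a significant excess of ratios > 1
        from scipy import stats

        params = SimulationParams(
            n_regions=2, samples_per_region=3, gene_length=120,
            cities_per_region=3, migration_rate=0.5, mutation_rate=0.02,
        )
        above = total = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            tree, meta = simulate_genealogy(params, seed=2000 + seed)
            a, _ = simulate_alignment(tree, params, False, rng)
            res = ng86(a)
            if res.defined:
                total += 1
                above += res.ratio > 1
        assert total >= 10
        p = stats.binomtest(above, total, 0.5, alternative="greater").pvalue
        assert p > 0.05


class TestGroupContrast:
    def _result(self, gene_id, ratio):
        return DnDsResult(gene_id, 10, 20, 1, 2, 0.1, 0.1, ratio)

    def test_equal_ratios_no_signal(self):
        results = [self._result(f"g{i}", 0.5) for i in range(6)]
        groups = {f"g{i}": "membrane" if i < 3 else "organelle" for i in range(6)}
        comp = dnds_group_contrast(results, groups)
        assert comp.kruskal_p == 1.0

    def test_undefined_ratios_excluded_with_n_reported(self):
        results = [self._result(f"g{i}", 0.5 + 0.1 * i) for i in range(4)]
        results.append(self._result("g4", float("nan")))
        groups = {f"g{i}": "membrane" if i % 2 else "organelle" for i in range(5)}
        comp = dnds_group_contrast(results, groups)
        assert sum(comp.group_ns.values()) == 4

    def test_selected_membrane_exceeds_neutral_organelle(self, small_bundle):
        # recovery: selection raises dN/dS for membrane-labeled (selected)
        # genes relative to organelle-labeled (neutral) ones
        from phylogeostrat.genegroups import assign_groups

        groups = assign_groups(
            small_bundle.annotations,
            gene_ids=list(small_bundle.gene_alignments),
        )
        results = []
        for gene_id, a in small_bundle.gene_alignments.items():
            framed, reason = frame_and_trim(a)
            if framed is None:
                continue
            results.append(ng86(framed, gene_id))
        by_group = {}
        for res in results:
            if res.defined:
                by_group.setdefault(groups[res.gene_id], []).append(res.ratio)
        assert np.median(by_group["membrane"]) > np.median(by_group["organelle"])
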