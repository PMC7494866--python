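"""Codon engine, McDonald-Kreitman test, and group-comparison machinery."""

from itertools import product

import numpy as np
import pytest
from scipy import stats

import porpopgen as pp
from porpopgen.coalsim import DemographyModel, synth_codon_alignment
from porpopgen.selection import (
    MKTable,
    MKResult,
    codon_site_fractions,
    g_test_2x2,
    mk_counts,
    _code,
)

ALL_CODONS = ["".join(c) for c in product("ACGT", repeat=3)]


# independent oracle: classify every one-step neighbor straight off the table
def oracle_site_fractions(codon, table_id=2):
    code = _code(table_id)
    if code.is_stop(codon):
        return 0.0, 0.0, 3.0
    n = s = excl = 0.0
    for pos in range(3):
        nbrs = [codon[:pos] + b + codon[pos + 1:]
                for b in "ACGT" if b != codon[pos]]
        stops = sum(code.is_stop(x) for x in nbrs)
        syn = sum((not code.is_stop(x)) and code.translate(x) == code.translate(codon)
                  for x in nbrs)
        non = 3 - stops - syn
        usable = syn + non
        weight = 1 - stops / 3
        if usable:
            s += syn / usable * weight
            n += non / usable * weight
        excl += stops / 3
    return n, s, excl


class TestCodonSites:
    def test_phe_third_position(self):
        # TTT (Phe): only TTT->TTC is silent among third-position changes
        n, s, _ = codon_site_fractions("TTT")
        assert s == pytest.approx(1 / 3)

    def test_gly_fourfold_third_position(self):
        # GGG (Gly) third position is 4-fold degenerate: a full syn site
        n, s, excl = codon_site_fractions("GGG")
        assert s == pytest.approx(1.0)
        assert n + s + excl == pytest.approx(3.0)

    def test_all_64_codons_match_enumeration(self):
        """Exhaustive check of the Nei-Gojobori site fractions under the
        vertebrate mitochondrial code, and the exact 3-site accounting."""
        for codon in ALL_CODONS:
            got = codon_site_fractions(codon)
            assert got == pytest.approx(oracle_site_fractions(codon))
            assert sum(got) == pytest.approx(3.0)

    def test_mito_code_assignments(self):
        code = _code(2)
        assert code.translate("ATA") == "M"  # Ile in the standard code
        assert code.translate("TGA") == "W"  # stop in the standard code
        assert code.is_stop("AGA") and code.is_stop("AGG")

    def test_sites_independent_of_n(self):
        genes = {"g": pp.GenomeAlignment(["a", "b", "c"], ["ATGAAA"] * 3)}
        ca3 = pp.CodonAlignment.from_gene_alignments(genes)
        genes2 = {"g": pp.GenomeAlignment(["a", "b"], ["ATGAAA"] * 2)}
        ca2 = pp.CodonAlignment.from_gene_alignments(genes2)
        assert pp.count_syn_nonsyn_sites(ca3) == pp.count_syn_nonsyn_sites(ca2)


class TestCodonDifferences:
    def test_single_synonymous(self):
        assert pp.count_codon_differences("ATT", "ATC") == (0.0, 1.0)

    def test_ata_atg_silent_under_mito_code(self):
        # both Met under the mitochondrial code; nonsynonymous under table 1
        assert pp.count_codon_differences("ATA", "ATG") == (0.0, 1.0)
        assert pp.count_codon_differences("ATA", "ATG", table_id=1) == (1.0, 0.0)

    def test_identical(self):
        assert pp.count_codon_differences("AAA", "AAA") == (0.0, 0.0)

    def test_symmetry(self, rng):
        for _ in range(60):
            a, b = rng.choice(ALL_CODONS, size=2)
            a, b = str(a), str(b)
            code = _code(2)
            if code.is_stop(a) or code.is_stop(b):
                continue
            assert pp.count_codon_differences(a, b) == \
                pp.count_codon_differences(b, a)

    def test_pathway_average_two_step(self):
        # TTT (F) vs GTA: pathways via GTT (V) and TTA (L); enumerate by hand
        nd, sd = pp.count_codon_differences("TTT", "GTA")
        # path1 TTT->GTT (F->V, nonsyn) ->GTA (V->V, syn): (1, 1)
        # path2 TTT->TTA (F->L, nonsyn) ->GTA (L->V, nonsyn): (2, 0)
        assert (nd, sd) == (1.5, 0.5)

    def test_total_diffs_conserved(self, rng):
        code = _code(2)
        for _ in range(60):
            a, b = (str(x) for x in rng.choice(ALL_CODONS, size=2))
            if code.is_stop(a) or code.is_stop(b):
                continue
            nd, sd = pp.count_codon_differences(a, b)
            n_diff = sum(x != y for x, y in zip(a, b))
            if nd + sd:  # pairs with all pathways blocked are skipped
                assert nd + sd == pytest.approx(n_diff)

    def test_unusable_codon_rejected(self):
        with pytest.raises(ValueError):
            pp.count_codon_differences("AN-", "AAA")


class TestPiNPiS:
    def test_only_synonymous_variation(self):
        genes = {"g": pp.GenomeAlignment(["a", "b"], ["ATTAAA", "ATCAAA"])}
        ca = pp.CodonAlignment.from_gene_alignments(genes)
        pin, pis, ratio = pp.pi_n_pi_s(ca)
        assert pin == 0.0 and pis > 0 and ratio == 0.0

    def test_pis_zero_flagged(self):
        seq_a = "ATG" + "AAA" * 299
        seq_b = "CTG" + "AAA" * 299  # one nonsynonymous change (M->L)
        genes = {"g": pp.GenomeAlignment(["a", "b"], [seq_a, seq_b])}
        ca = pp.CodonAlignment.from_gene_alignments(genes)
        pin, pis, ratio = pp.pi_n_pi_s(ca)
        assert pin > 0 and pis == 0.0 and ratio is None

    def test_pairwise_sum_consistency(self, rng):
        """For n=2, summing per-codon pathway counts reproduces the
        pi_n_pi_s numerators exactly."""
        ing, _ = synth_codon_alignment(
            150, 2, DemographyModel("constant", theta1=8.0), seed=rng
        )
        nd = sd = 0.0
        for ca, cb in zip(ing.codons[0], ing.codons[1]):
            d = pp.count_codon_differences(ca, cb)
            nd, sd = nd + d[0], sd + d[1]
        n_sites, s_sites = pp.count_syn_nonsyn_sites(ing)
        pin, pis, _ = pp.pi_n_pi_s(ing)
        assert pin == pytest.approx(nd / n_sites)
        assert pis == pytest.approx(sd / s_sites)

    def test_low_nonsyn_fraction_gives_small_ratio(self, rng):
        ing, _ = synth_codon_alignment(
            400, 6, DemographyModel("constant", theta1=20.0),
            nonsyn_fraction=0.1, seed=rng,
        )
        _, _, ratio = pp.pi_n_pi_s(ing)
        assert ratio is not None and ratio < 0.5

    def test_codon_column_with_gap_excluded(self):
        genes = {"g": pp.GenomeAlignment(["a", "b"], ["ATG-AA", "ATGCAA"])}
        ca = pp.CodonAlignment.from_gene_alignments(genes)
        assert ca.n_codons == 1 and ca.excluded_codons == 1


class TestMK:
    def test_ni_arithmetic(self):
        tab = MKTable(Dn=2, Ds=10, Pn=4, Ps=5)
        ni = (tab.Pn / tab.Ps) / (tab.Dn / tab.Ds)
        assert ni == pytest.approx(4.0)
        assert MKResult.interpret(ni) == "purifying"
        assert MKResult.interpret(0.2) == "positive"
        assert MKResult.interpret(1.0) == "neutral"

    def test_counts_on_constructed_alignment(self):
        # ingroup polymorphic at codon 1 (ATT/ATC syn), fixed vs outgroup at
        # codon 2 (AAA->AAG syn is Lys->Lys... use AAA->ACA nonsyn)
        ing = pp.CodonAlignment(
            ["i1", "i2"], [[ "ATT", "AAA"], ["ATC", "AAA"]], [("g", 2)]
        )
        out = pp.CodonAlignment(["o1"], [["ATT", "ACA"]], [("g", 2)])
        tab = mk_counts(ing, out)
        assert (tab.Pn, tab.Ps) == (0.0, 1.0)
        assert (tab.Dn, tab.Ds) == (1.0, 0.0)  # AAA vs ACA: Lys->Thr

    def test_polymorphic_and_divergent_counts_polymorphism_only(self):
        ing = pp.CodonAlignment(
            ["i1", "i2"], [["ATT"], ["ATC"]], [("g", 1)]
        )
        out = pp.CodonAlignment(["o1"], [["ATA"]], [("g", 1)])
        tab = mk_counts(ing, out)
        assert (tab.Dn, tab.Ds) == (0.0, 0.0)
        assert tab.Ps == 1.0

    def test_neutral_table_gives_g_near_zero(self):
        ing, out = synth_codon_alignment(
            600, 6, DemographyModel("constant", theta1=15.0),
            divergence=40.0, seed=5,
        )
        tab, res = pp.mk_test(ing, out)
        if res.NI is not None:
            assert res.NI == pytest.approx(
                (tab.Pn * tab.Ds) / (tab.Ps * tab.Dn)
            )

    def test_equal_ratios_mean_ni_one(self):
        tab = np.array([[4, 10], [8, 20]], dtype=float)
        g, p = g_test_2x2(tab)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_g_test_matches_scipy_power_divergence(self):
        obs = np.array([[12, 5], [7, 21]], dtype=float)
        g, p = g_test_2x2(obs)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        ref = stats.power_divergence(
            obs.ravel(), expected.ravel(), ddof=2, lambda_="log-likelihood"
        )
        assert g == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_zero_cells_flagged_not_raised(self):
        ing = pp.CodonAlignment(["i1", "i2"], [["ATT"], ["ATT"]], [("g", 1)])
        out = pp.CodonAlignment(["o1"], [["ATT"]], [("g", 1)])
        tab, res = pp.mk_test(ing, out)
        assert res.NI is None and res.interpretation == "undefined"


class TestPermutationTest:
    def test_cloned_groups_not_significant(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        labels = np.repeat(["a", "b", "c"], 4)
        _, p, _ = pp.permutation_group_test(vals, labels, n_perm=499, seed=0)
        assert p > 0.3

    def test_separated_groups_significant(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(10, 1, 10)  # 10 pooled SDs apart
        stat, p, pairwise = pp.permutation_group_test(
            np.concatenate([a, b]), ["a"] * 10 + ["b"] * 10,
            n_perm=9999, seed=1,
        )
        assert p <= 0.001
        assert pairwise["pvalue_fdr"].iloc[0] <= 0.001

    def test_null_pvalues_roughly_uniform(self, rng):
        """Calibration: with exchangeable labels, p < 0.05 about 5% of the
        time over 200 simulated datasets."""
        hits = 0
        for i in range(200):
            vals = rng.normal(size=16)
            labels = np.repeat(["a", "b", "c", "d"], 4)
            _, p, _ = pp.permutation_group_test(vals, labels, n_perm=199,
                                                seed=int(rng.integers(2**31)))
            hits += p < 0.05
        assert 0.01 <= hits / 200 <= 0.11

    def test_small_group_excluded_with_warning(self):
        vals = [1.0, 2.0, 3.0, 4.0, 99.0]
        labels = ["a", "a", "b", "b", "c"]
        with pytest.warns(UserWarning, match="excluding"):
            stat, p, pairwise = pp.permutation_group_test(vals, labels,
                                                          n_perm=99, seed=0)
        assert set(pairwise["group_a"]) | set(pairwise["group_b"]) == {"a", "b"}


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        assert pp.correlation_test(x, x)[0] == pytest.approx(1.0)
        assert pp.correlation_test(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        assert pp.correlation_test([1, 1, 1], [1, 2, 3]) == (None, None)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pp.correlation_test([1, 2, np.nan], [1, 2, 3])
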