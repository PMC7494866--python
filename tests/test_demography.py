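"""Neutrality statistics against independently coded oracles, coalescent
p-values, mismatch model closed forms, fitting, and unit conversions."""

import math
from fractions import Fraction

import numpy as np
import pytest

import porpopgen as pp
from porpopgen.demography import (
    fu_li_from_counts,
    tajimas_d_from_counts,
    _stats_from_counts,
)
from porpopgen.diversity import PreconditionError
from .conftest import random_alignment


# --- oracle implementations (exact-rational coefficients, separate code path)

def oracle_tajima_d(seqs):
    n = len(seqs)
    L = len(seqs[0])
    cols = [j for j in range(L) if all(s[j] in "ACGT" for s in seqs)]
    S = sum(len({s[j] for s in seqs}) > 1 for j in cols)
    if S == 0:
        return None
    k_tot = Fraction(0)
    for i in range(n):
        for j in range(i + 1, n):
            k_tot += sum(seqs[i][c] != seqs[j][c] for c in cols)
    k_mean = k_tot / (n * (n - 1) // 2)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, 1) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    num = k_mean - S / a1
    return float(num) / math.sqrt(float(e1 * S + e2 * S * (S - 1)))


def oracle_fu_li(seqs):
    n = len(seqs)
    L = len(seqs[0])
    cols = [j for j in range(L) if all(s[j] in "ACGT" for s in seqs)]
    eta = eta_s = 0
    for j in cols:
        counts = {}
        for s in seqs:
            counts[s[j]] = counts.get(s[j], 0) + 1
        if len(counts) < 2:
            continue
        eta += len(counts) - 1
        ones = sum(1 for v in counts.values() if v == 1)
        if n == 2:
            ones = min(ones, 1)
        eta_s += ones
    if eta == 0:
        return None, None
    k_tot = Fraction(0)
    for i in range(n):
        for j in range(i + 1, n):
            k_tot += sum(seqs[i][c] != seqs[j][c] for c in cols)
    pi = k_tot / (n * (n - 1) // 2)
    an = sum(Fraction(1, i) for i in range(1, n))
    bn = sum(Fraction(1, i * i) for i in range(1, n))
    an1 = an + Fraction(1, n)
    cn = Fraction(2 * n, (n - 1) * (n - 2)) * an - Fraction(4, n - 2)
    dn = (cn + Fraction(n - 2, (n - 1) ** 2)
          + Fraction(2, n - 1) * (Fraction(3, 2) - (2 * an1 - 3) / (n - 2)
                                  - Fraction(1, n)))
    denom = an * an + bn
    v_d = (Fraction(n * n, (n - 1) ** 2) * bn + an * an * dn
           - 2 * Fraction(n, (n - 1) ** 2) * an * (an + 1)) / denom
    u_d = Fraction(n, n - 1) * (an - Fraction(n, n - 1)) - v_d
    dstar = float(Fraction(n, n - 1) * eta - an * eta_s) / math.sqrt(
        float(u_d * eta + v_d * eta * eta)
    )
    v_f = (dn + Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
           - Fraction(2, n - 1) * (4 * bn - 6 + Fraction(8, n))) / denom
    u_f = (Fraction(n, n - 1) + Fraction(n + 1, 3 * (n - 1))
           - Fraction(4, n * (n - 1))
           + Fraction(2 * (n + 1), (n - 1) ** 2) * (an1 - Fraction(2 * n, n + 1))
           ) / an - v_f
    fstar = float(pi - Fraction(n - 1, n) * eta_s) / math.sqrt(
        float(u_f * eta + v_f * eta * eta)
    )
    return dstar, fstar


class TestTajimaD:
    def test_zero_numerator(self):
        # pi_total chosen exactly at S/a1
        n, S = 6, 10
        a1 = sum(1 / i for i in range(1, n))
        assert tajimas_d_from_counts(S / a1, S, n) == pytest.approx(0.0)

    def test_undefined_when_no_variation(self):
        assert tajimas_d_from_counts(0.0, 0, 10) is None

    def test_small_n_rejected(self):
        with pytest.raises(PreconditionError):
            tajimas_d_from_counts(1.0, 2, 3)

    def test_oracle_agreement_random_alignments(self, rng):
        """Agreement with the exact-rational reimplementation to 1e-10."""
        checked = 0
        for _ in range(200):
            aln = random_alignment(rng, n=int(rng.integers(4, 9)))
            expect = oracle_tajima_d(aln.sequences)
            got = pp.tajimas_d(aln)
            if expect is None:
                assert got is None
                continue
            assert got == pytest.approx(expect, abs=1e-10)
            checked += 1
        assert checked > 150


class TestFuLi:
    def test_oracle_agreement_random_alignments(self, rng):
        checked = 0
        for _ in range(200):
            aln = random_alignment(rng, n=int(rng.integers(4, 9)))
            ed, ef = oracle_fu_li(aln.sequences)
            gd, gf = pp.fu_li_tests(aln)
            if ed is None:
                assert gd is None and gf is None
                continue
            assert gd == pytest.approx(ed, abs=1e-10)
            assert gf == pytest.approx(ef, abs=1e-10)
            checked += 1
        assert checked > 150

    def test_excess_singletons_negative(self):
        # every mutation a singleton (eta_s = eta) forces both negative;
        # 8 singletons at n=8 give pi_total = 8 * 2*1*7/(8*7) = 2
        d, f = fu_li_from_counts(pi_total=2.0, eta=8, eta_s=8, n=8)
        assert d < 0 and f < 0

    def test_no_singletons_balanced_positive(self):
        # mid-frequency variants only: D* > 0
        n = 8
        counts = np.full(6, 4)  # 6 sites at derived count 4 of 8
        pi_total = float((2.0 * counts * (n - counts)).sum() / (n * (n - 1)))
        d, _ = fu_li_from_counts(pi_total, eta=6, eta_s=0, n=n)
        assert d > 0

    def test_undefined_when_no_mutations(self):
        assert fu_li_from_counts(0.0, 0, 0, 8) == (None, None)


class TestNeutralityPValue:
    def test_median_of_null_gives_p_near_one(self):
        from porpopgen.demography import _null_distribution
        n, S = 12, 10
        null = _null_distribution(n, S, 2000, 7)[0]
        p = pp.neutrality_pvalue("tajima_d", float(np.median(null)), n, S,
                                 n_sims=2000, seed=7)
        assert p > 0.9

    def test_extreme_observation_small_p(self):
        p = pp.neutrality_pvalue("fu_li_dstar", -6.0, 12, 10, n_sims=500, seed=3)
        assert p < 0.05

    def test_p_in_unit_interval(self):
        for stat in ("tajima_d", "fu_li_dstar", "fu_li_fstar"):
            p = pp.neutrality_pvalue(stat, 0.0, 10, 5, n_sims=200, seed=1)
            assert 0 < p <= 1

    def test_neutrality_stats_bundle(self, synth_bundle):
        aln = synth_bundle["aln"].subset(
            synth_bundle["lineages"].samples(lineage="L1"))
        ns = pp.neutrality_stats(aln, n_sims=300, seed=2)
        assert ns.S >= 1 and ns.eta >= ns.S
        assert set(ns.p_values) == {"tajima_d", "fu_li_dstar", "fu_li_fstar"}
        # sudden expansion: star-like genealogy, D expected negative
        assert ns.tajima_d < 0.5


class TestMismatchModel:
    def test_constant_closed_form(self):
        f = pp.mismatch_expected("constant", theta1=1.0, max_k=3)
        assert f[0] == pytest.approx(0.5)
        assert f[1] == pytest.approx(0.25)

    def test_constant_normalizes(self):
        f = pp.mismatch_expected("constant", theta1=3.0, max_k=3000)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_expansion_tau_zero_is_constant_at_theta0(self):
        e = pp.mismatch_expected("sudden_expansion", 2.0, 50.0, 0.0, 20)
        c = pp.mismatch_expected("constant", theta1=2.0, max_k=20)
        np.testing.assert_allclose(e, c, atol=1e-12)

    def test_expansion_large_tau_is_constant_at_theta1(self):
        e = pp.mismatch_expected("sudden_expansion", 1.0, 5.0, 400.0, 20)
        c = pp.mismatch_expected("constant", theta1=5.0, max_k=20)
        np.testing.assert_allclose(e, c, atol=1e-9)

    def test_expansion_sums_to_at_most_one(self):
        e = pp.mismatch_expected("sudden_expansion", 1.0, 30.0, 6.0, 500)
        assert e.sum() == pytest.approx(1.0, abs=1e-9)
        assert (e >= 0).all()

    def test_monte_carlo_agreement(self):
        """Simulated pairwise-difference distribution matches the closed
        form (independent route through the coalescent simulator)."""
        rng = np.random.default_rng(8)
        model = pp.DemographyModel("sudden_expansion", theta0=0.5,
                                   theta1=20.0, tau=3.0)
        acc = np.zeros(200)
        reps = 3000
        for _ in range(reps):
            g = pp.simulate_genealogy(2, model, rng)
            m = pp.drop_mutations(g, theta=20.0, seed=rng)
            k = m.shape[1]
            if k < 200:
                acc[k] += 1
        acc /= reps
        expect = pp.mismatch_expected("sudden_expansion", 0.5, 20.0, 3.0, 199)
        # compare the head of the distribution at Monte-Carlo resolution
        np.testing.assert_allclose(acc[:10], expect[:10], atol=0.02)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            pp.mismatch_expected("sudden_expansion", -1.0, 1.0, 1.0, 10)
        with pytest.raises(ValueError):
            pp.mismatch_expected("constant", theta1=np.inf, max_k=10)


class TestMismatchFit:
    def test_noiseless_recovery(self):
        exp = pp.mismatch_expected("sudden_expansion", 1.0, 100.0, 5.0, 40)
        hist = exp * 435.0  # C(30, 2) pairs
        fit = pp.fit_sudden_expansion(hist, n=30, bootstrap=False)
        assert fit.tau == pytest.approx(5.0, rel=1e-3)
        assert fit.theta0 == pytest.approx(1.0, rel=1e-2)
        assert fit.theta1 == pytest.approx(100.0, rel=1e-2)

    def test_constant_fit_recovers_theta(self):
        hist = pp.mismatch_expected("constant", theta1=4.0, max_k=60) * 100
        fit = pp.fit_constant(hist)
        assert fit.theta1 == pytest.approx(4.0, rel=1e-3)

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(3)
        model = pp.DemographyModel("sudden_expansion", theta0=1, theta1=50, tau=4)
        g = pp.simulate_genealogy(15, model, rng)
        hist = pp.pairwise_difference_histogram(
            pp.drop_mutations(g, theta=50, seed=rng))
        a = pp.fit_sudden_expansion(hist, n=15, B=40, seed=9)
        b = pp.fit_sudden_expansion(hist, n=15, B=40, seed=9)
        assert a.ci == b.ci and a.p_ssd == b.p_ssd
        for lo, hi in a.ci.values():
            assert lo <= hi

    def test_monomorphic_degenerate(self):
        hist = np.array([10])  # all pairs identical
        fit = pp.fit_sudden_expansion(hist, n=5, bootstrap=False)
        assert fit.tau == 0.0 and fit.ssd == 0.0

    def test_observed_mismatch_sums_to_pairs(self, synth_bundle):
        aln = synth_bundle["aln"].subset(
            synth_bundle["lineages"].samples(lineage="L1"))
        hist = pp.observed_mismatch(aln)
        assert hist.sum() == aln.n * (aln.n - 1) // 2


class TestConversions:
    def test_worked_example(self):
        # tau=4 at 5e-8 /site/yr, L=16302, 10-y generations -> ~2.45 kyr
        t_gen, t_years = pp.tau_to_time(4.0, 5e-8, 16302, 10.0)
        assert t_years == pytest.approx(4 / (2 * 5e-8 * 16302 * 10) * 10)
        assert t_years == pytest.approx(2453.7, abs=0.5)

    def test_tau_zero(self):
        assert pp.tau_to_time(0.0, 5e-8, 16302, 10.0) == (0.0, 0.0)

    def test_rate_doubling_halves_time(self):
        t1 = pp.tau_to_time(4.0, 5e-8, 16302, 10.0)[1]
        t2 = pp.tau_to_time(4.0, 1e-7, 16302, 10.0)[1]
        assert t1 == pytest.approx(2 * t2)

    def test_theta_to_ne(self):
        assert pp.theta_to_ne(2.0, 1e-3) == pytest.approx(1000.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pp.tau_to_time(1.0, 0.0, 100, 10.0)
        with pytest.raises(ValueError):
            pp.theta_to_ne(1.0, 0.0)
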