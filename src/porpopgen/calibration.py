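"""Simulation calibration experiments for the statistical machinery.

These are the package's own correctness experiments, run both by the test
suite and by ``scripts/acceptance.py``: under neutral constant-size
coalescent simulation the mean of Tajima's D should sit near zero and its
two-tailed simulation test should reject at close to the nominal rate; the
segregating-site count should average theta * a1 (Watterson); neutral
McDonald–Kreitman tables should give a mean neutrality index near 1 with a
nominal G-test rejection rate; and sudden-expansion mismatch fits should
recover the generating parameters with bootstrap intervals that cover the
truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coalsim import (
    DemographyModel,
    drop_mutations,
    pairwise_difference_histogram,
    simulate_genealogy,
    synth_codon_alignment,
)
from .demography import (
    _stats_from_counts,
    fit_sudden_expansion,
    neutrality_pvalue,
)
from .diversity import harmonic_number
from .selection import mk_test

__all__ = [
    "tajima_calibration",
    "watterson_calibration",
    "mk_neutral_calibration",
    "mismatch_recovery",
]


@dataclass
class TajimaCalibration:
    mean_d: float
    rejection_rate: float
    reps: int


def tajima_calibration(
    n: int = 20,
    theta: float = 10.0,
    reps: int = 2000,
    seed: int = 0,
    pvalue_sims: int = 600,
) -> TajimaCalibration:
    """Neutral constant-size calibration of Tajima's D and its test.

    Simulates ``reps`` neutral datasets, returning the mean D and the
    fraction rejected by the two-tailed fixed-S simulation p-value at 0.05.
    Null distributions are shared across replicates with equal S, so the
    p-value conditioning matches the test's own definition.
    """
    rng = np.random.default_rng(seed)
    model = DemographyModel(kind="constant", theta1=theta)
    ds = []
    rejected = 0
    tested = 0
    null_seed = int(rng.integers(2**31))
    for _ in range(reps):
        g = simulate_genealogy(n, model, rng)
        counts = drop_mutations(g, theta=theta, seed=rng).sum(axis=0)
        d, _, _ = _stats_from_counts(counts, n)
        if d is None:
            continue
        ds.append(d)
        S = int(((counts > 0) & (counts < n)).sum())
        p = neutrality_pvalue("tajima_d", d, n, S, n_sims=pvalue_sims,
                              seed=null_seed)
        tested += 1
        rejected += p < 0.05
    return TajimaCalibration(
        mean_d=float(np.mean(ds)), rejection_rate=rejected / tested, reps=tested
    )


@dataclass
class WattersonCalibration:
    mean_S: float
    expected_S: float
    reps: int

    @property
    def ratio(self) -> float:
        return self.mean_S / self.expected_S


def watterson_calibration(
    n: int = 20, theta: float = 10.0, reps: int = 2000, seed: int = 0
) -> WattersonCalibration:
    """Theta-mode simulation check of E[S] = theta * a1."""
    rng = np.random.default_rng(seed)
    model = DemographyModel(kind="constant", theta1=theta)
    s_vals = np.empty(reps)
    for i in range(reps):
        g = simulate_genealogy(n, model, rng)
        s_vals[i] = drop_mutations(g, theta=theta, seed=rng).shape[1]
    return WattersonCalibration(
        mean_S=float(s_vals.mean()),
        expected_S=theta * harmonic_number(n - 1),
        reps=reps,
    )


@dataclass
class MKCalibration:
    mean_ni: float
    g_rejection_rate: float
    reps: int
    undefined: int


def mk_neutral_calibration(
    reps: int = 500,
    n: int = 8,
    n_codons: int = 3000,
    theta: float = 30.0,
    divergence: float = 160.0,
    seed: int = 0,
) -> MKCalibration:
    """Neutral ingroup/outgroup MK simulation: E[NI] near 1, nominal G-test.

    Mutations are random non-stop substitutions (no forced syn/nonsyn
    composition), so polymorphism and divergence share the same expected
    nonsynonymous fraction and the neutrality index is 1 in expectation.
    Replicates with an undefined NI (a zero cell) are excluded from the mean
    but counted.
    """
    rng = np.random.default_rng(seed)
    model = DemographyModel(kind="constant", theta1=theta)
    nis = []
    rejected = 0
    tested = 0
    undefined = 0
    for _ in range(reps):
        ingroup, outgroup = synth_codon_alignment(
            n_codons, n, model, divergence=divergence,
            nonsyn_fraction=None, seed=rng,
        )
        _, res = mk_test(ingroup, outgroup)
        if res.NI is None:
            undefined += 1
        else:
            nis.append(res.NI)
        if res.g_pvalue is not None:
            tested += 1
            rejected += res.g_pvalue < 0.05
    return MKCalibration(
        mean_ni=float(np.mean(nis)), g_rejection_rate=rejected / tested,
        reps=reps, undefined=undefined,
    )


@dataclass
class MismatchRecovery:
    median_tau: float
    true_tau: float
    tau_ci_coverage: float | None
    reps: int


def mismatch_recovery(
    reps: int = 100,
    n: int = 30,
    theta0: float = 1.0,
    theta1: float = 100.0,
    tau: float = 5.0,
    B: int = 0,
    seed: int = 0,
) -> MismatchRecovery:
    """Simulation-recovery of the sudden-expansion parameters.

    Each replicate simulates a coalescent dataset under (theta0, theta1,
    tau), refits the model, and (with ``B`` > 0) checks whether the
    percentile bootstrap CI for tau covers the generating value.
    """
    rng = np.random.default_rng(seed)
    model = DemographyModel(
        kind="sudden_expansion", theta0=theta0, theta1=theta1, tau=tau
    )
    taus = np.empty(reps)
    covered = 0
    with_ci = 0
    for i in range(reps):
        g = simulate_genealogy(n, model, rng)
        mat = drop_mutations(g, theta=theta1, seed=rng)
        hist = pairwise_difference_histogram(mat)
        fit = fit_sudden_expansion(
            hist, n=n, B=B, seed=int(rng.integers(2**31)), bootstrap=B > 0
        )
        taus[i] = fit.tau
        if B > 0 and "tau" in fit.ci:
            with_ci += 1
            lo, hi = fit.ci["tau"]
            covered += lo <= tau <= hi
    return MismatchRecovery(
        median_tau=float(np.median(taus)), true_tau=tau,
        tau_ci_coverage=(covered / with_ci) if with_ci else None,
        reps=reps,
    )
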