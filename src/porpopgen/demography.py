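"""Site-frequency-spectrum neutrality tests and mismatch-distribution fits.

Tajima's D contrasts pi (pairwise diversity) with S/a1 (Watterson) using
the 1989 normalization; Fu & Li's D* and F* (the without-outgroup variants)
contrast total mutations eta with singletons eta_s.  Their two-tailed
p-values come from constant-size coalescent simulations conditioned on the
observed number of segregating sites (fixed-S mutation placement), the
standard desktop-tool convention.

The mismatch side implements the two-epoch ("sudden expansion") model of
pairwise difference counts: at equilibrium the difference count of a pair
is geometric with mean theta, and an instantaneous size change tau
mutational units ago mixes the recent-epoch geometric with a
Poisson-shifted ancient one.  The finite-sum closed form used here is the
exact two-epoch distribution (Rogers–Harpending transient expression).
Parameters (theta0, theta1, tau) are estimated by bounded least squares on
the mismatch frequencies from deterministic multi-starts, with percentile
confidence intervals and a goodness-of-fit p from a parametric coalescent
bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .coalsim import (
    DemographyModel,
    drop_mutations,
    pairwise_difference_histogram,
    simulate_genealogy,
)
from .diversity import (
    PreconditionError,
    harmonic_number,
    mean_pairwise_differences,
    site_summary,
    total_mutations,
)
from .seqio import GenomeAlignment

__all__ = [
    "NeutralityStats",
    "MismatchFit",
    "tajimas_d",
    "tajimas_d_from_counts",
    "fu_li_tests",
    "fu_li_from_counts",
    "neutrality_pvalue",
    "neutrality_stats",
    "observed_mismatch",
    "mismatch_expected",
    "fit_constant",
    "fit_sudden_expansion",
    "tau_to_time",
    "theta_to_ne",
]


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of the 1989 variance normalization."""
    a1 = harmonic_number(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return c1 / a1, c2 / (a1**2 + a2)


def tajimas_d_from_counts(pi_total: float, S: int, n: int) -> float | None:
    """D from the sufficient statistics; None when S = 0."""
    if n < 4:
        raise PreconditionError(f"Tajima's D needs n >= 4, got {n}")
    if S == 0:
        return None
    a1 = harmonic_number(n - 1)
    e1, e2 = _tajima_constants(n)
    return (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def tajimas_d(aln: GenomeAlignment) -> float | None:
    S = site_summary(aln)[0]
    return tajimas_d_from_counts(mean_pairwise_differences(aln), S, aln.n)


# ---------------------------------------------------------------------------
# Fu & Li D* / F*
# ---------------------------------------------------------------------------

def _fu_li_constants(n: int) -> tuple[float, float, float, float]:
    """(uD*, vD*, uF*, vF*) without-outgroup variance constants.

    Fu & Li (1993) as corrected by Simonsen, Churchill & Aquadro (1995);
    the originally printed constants contain typos.  (The uncorrected 1993
    forms give slightly different variances and are not offered.)
    """
    an = harmonic_number(n - 1)
    bn = float(np.sum(1.0 / np.arange(1, n) ** 2))
    an1 = an + 1.0 / n  # a_{n+1}
    cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n)
    )
    denom = an**2 + bn
    v_dstar = (
        (n / (n - 1.0)) ** 2 * bn
        + an**2 * dn
        - 2.0 * n * an * (an + 1) / (n - 1.0) ** 2
    ) / denom
    u_dstar = (n / (n - 1.0)) * (an - n / (n - 1.0)) - v_dstar
    v_fstar = (
        dn
        + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        - (2.0 / (n - 1)) * (4.0 * bn - 6.0 + 8.0 / n)
    ) / denom
    u_fstar = (
        n / (n - 1.0)
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 / (n * (n - 1))
        + 2.0 * (n + 1) / (n - 1.0) ** 2 * (an1 - 2.0 * n / (n + 1))
    ) / an - v_fstar
    return u_dstar, v_dstar, u_fstar, v_fstar


def fu_li_from_counts(
    pi_total: float, eta: int, eta_s: int, n: int
) -> tuple[float | None, float | None]:
    """(D*, F*) from total mutations, singletons and pi; None when eta = 0."""
    if n < 4:
        raise PreconditionError(f"Fu & Li tests need n >= 4, got {n}")
    if eta == 0:
        return None, None
    an = harmonic_number(n - 1)
    u_d, v_d, u_f, v_f = _fu_li_constants(n)
    dstar = (n / (n - 1.0) * eta - an * eta_s) / math.sqrt(
        u_d * eta + v_d * eta**2
    )
    fstar = (pi_total - (n - 1.0) / n * eta_s) / math.sqrt(
        u_f * eta + v_f * eta**2
    )
    return dstar, fstar


def fu_li_tests(aln: GenomeAlignment) -> tuple[float | None, float | None]:
    eta, eta_s = total_mutations(aln)
    return fu_li_from_counts(mean_pairwise_differences(aln), eta, eta_s, aln.n)


# ---------------------------------------------------------------------------
# coalescent-simulation p-values
# ---------------------------------------------------------------------------

def _stats_from_counts(counts: np.ndarray, n: int) -> tuple[float, float, float]:
    """(D, D*, F*) of a simulated dataset given derived allele counts."""
    counts = counts[(counts > 0) & (counts < n)]
    S = len(counts)
    pi_total = float((2.0 * counts * (n - counts)).sum() / (n * (n - 1)))
    eta_s = int(((counts == 1) | (counts == n - 1)).sum())
    d = tajimas_d_from_counts(pi_total, S, n)
    dstar, fstar = fu_li_from_counts(pi_total, S, eta_s, n)
    return d, dstar, fstar


@lru_cache(maxsize=512)
def _null_distribution(
    n: int, S: int, n_sims: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-S constant-size null of (D, D*, F*), cached per (n, S)."""
    rng = np.random.default_rng(seed)
    model = DemographyModel(kind="constant", theta1=1.0)
    d = np.empty(n_sims)
    ds = np.empty(n_sims)
    fs = np.empty(n_sims)
    for i in range(n_sims):
        g = simulate_genealogy(n, model, rng)
        mat = drop_mutations(g, fixed_S=S, seed=rng)
        d[i], ds[i], fs[i] = _stats_from_counts(mat.sum(axis=0), n)
    return d, ds, fs


_STAT_INDEX = {"tajima_d": 0, "fu_li_dstar": 1, "fu_li_fstar": 2}


def neutrality_pvalue(
    stat_name: str,
    observed: float,
    n: int,
    S: int,
    n_sims: int = 10000,
    seed: int = 0,
) -> float:
    """Two-tailed coalescent-simulation p-value for one SFS statistic.

    The null fixes n and the observed S (mutations placed uniformly on
    constant-size genealogies) and p = 2 min(P(stat <= obs), P(stat >= obs))
    capped at 1, with an add-one correction keeping p in (0, 1].
    """
    if stat_name not in _STAT_INDEX:
        raise ValueError(f"unknown statistic {stat_name!r}")
    if S < 1:
        raise ValueError("S must be >= 1 for a simulation p-value")
    null = _null_distribution(n, S, n_sims, seed)[_STAT_INDEX[stat_name]]
    p_lo = (1 + (null <= observed).sum()) / (n_sims + 1)
    p_hi = (1 + (null >= observed).sum()) / (n_sims + 1)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


@dataclass
class NeutralityStats:
    """SFS neutrality-test bundle for one group (a neutrality-table row)."""

    n: int
    S: int
    eta: int
    eta_s: int
    tajima_d: float | None
    fu_li_dstar: float | None
    fu_li_fstar: float | None
    p_values: dict = field(default_factory=dict)


def neutrality_stats(
    aln: GenomeAlignment, n_sims: int = 10000, seed: int = 0
) -> NeutralityStats:
    """D, D*, F* with simulation p-values for one group alignment."""
    S = site_summary(aln)[0]
    eta, eta_s = total_mutations(aln)
    pi_total = mean_pairwise_differences(aln)
    d = tajimas_d_from_counts(pi_total, S, aln.n)
    dstar, fstar = fu_li_from_counts(pi_total, eta, eta_s, aln.n)
    pvals = {}
    if S >= 1:
        for name, obs in (
            ("tajima_d", d), ("fu_li_dstar", dstar), ("fu_li_fstar", fstar)
        ):
            if obs is not None:
                pvals[name] = neutrality_pvalue(name, obs, aln.n, S, n_sims, seed)
    return NeutralityStats(aln.n, S, eta, eta_s, d, dstar, fstar, pvals)


# ---------------------------------------------------------------------------
# mismatch distributions
# ---------------------------------------------------------------------------

def observed_mismatch(aln: GenomeAlignment) -> np.ndarray:
    """Pairwise-difference histogram over usable columns (sums to C(n,2))."""
    from .diversity import _usable_matrix

    mat = _usable_matrix(aln)
    n = mat.shape[0]
    diffs = np.empty(n * (n - 1) // 2, dtype=np.int64)
    k = 0
    for i in range(n - 1):
        d = (mat[i + 1:] != mat[i]).sum(axis=1)
        diffs[k: k + len(d)] = d
        k += len(d)
    return np.bincount(diffs, minlength=int(diffs.max()) + 1)


def _constant_pmf(theta: float, max_k: int) -> np.ndarray:
    """Geometric equilibrium pmf F(k) = theta^k / (theta+1)^(k+1)."""
    k = np.arange(max_k + 1)
    if theta == 0:
        out = np.zeros(max_k + 1)
        out[0] = 1.0
        return out
    return np.exp(k * np.log(theta) - (k + 1) * np.log(theta + 1.0))


def mismatch_expected(
    model: str,
    theta0: float = 0.0,
    theta1: float = 0.0,
    tau: float = 0.0,
    max_k: int = 50,
) -> np.ndarray:
    """Expected pairwise-difference pmf over k = 0..max_k.

    ``constant`` uses theta1 only.  ``sudden_expansion`` evaluates the
    two-epoch transient: with lambda = (theta1+1)/theta1,

        F_k = Fhat_k(theta1) + exp(-lambda tau)
              * sum_{j<=k} tau^j/j! [Fhat_{k-j}(theta0) - Fhat_{k-j}(theta1)]

    which reduces to the constant model at theta0 when tau = 0 and to the
    constant model at theta1 as tau -> infinity.  The vector sums to <= 1;
    the tail mass beyond max_k is simply not represented.
    """
    for v in (theta0, theta1, tau):
        if not math.isfinite(v) or v < 0:
            raise ValueError("parameters must be finite and >= 0")
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    if model == "constant":
        return _constant_pmf(theta1, max_k)
    if model != "sudden_expansion":
        raise ValueError(f"unknown mismatch model {model!r}")
    if tau == 0:
        return _constant_pmf(theta0, max_k)
    if theta1 < 1e-12:
        # no recent diversity: all pairs coalesce instantly after the change
        lam_tau = np.inf
    else:
        lam_tau = tau * (theta1 + 1.0) / theta1
    f1 = _constant_pmf(theta1, max_k)
    if not np.isfinite(lam_tau):
        decay = 0.0
    else:
        decay = math.exp(-lam_tau)
    if decay == 0.0:
        return f1
    f0 = _constant_pmf(theta0, max_k)
    k = np.arange(max_k + 1)
    log_tau_pow = k * math.log(tau) - np.cumsum(
        np.concatenate(([0.0], np.log(np.maximum(k[1:], 1))))
    )
    tau_pow = np.exp(log_tau_pow)  # tau^j / j!
    conv = np.convolve(tau_pow, f0 - f1)[: max_k + 1]
    # cancellation in the far tail can leave values at -1e-22; keep a pmf
    return np.maximum(f1 + decay * conv, 0.0)


def _moment_start(hist: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments style start: tau near the mean, thetas around it."""
    k = np.arange(len(hist))
    total = hist.sum()
    mean = float((k * hist).sum() / total) if total else 1.0
    return max(mean, 0.1), max(10.0 * mean, 1.0), max(mean, 0.1)


@dataclass
class MismatchFit:
    """Least-squares mismatch fit with bootstrap uncertainty."""

    observed: np.ndarray
    model: str
    theta0: float
    theta1: float
    tau: float
    ssd: float
    ci: dict = field(default_factory=dict)  # param -> (low, high)
    p_ssd: float | None = None
    B: int = 0
    seed: int = 0
    converged: bool = True

    @property
    def n_pairs(self) -> int:
        return int(self.observed.sum())

    def expected(self, max_k: int | None = None) -> np.ndarray:
        return mismatch_expected(
            self.model, self.theta0, self.theta1, self.tau,
            max_k if max_k is not None else len(self.observed) - 1,
        )


def _fit_expansion_ls(
    freq: np.ndarray,
    starts: list[tuple[float, float, float]],
    bounds: tuple,
    constrain_growth: bool,
) -> tuple[np.ndarray, float, bool]:
    max_k = len(freq) - 1

    def residuals(p: np.ndarray) -> np.ndarray:
        t0, t1, tau = p
        if constrain_growth:
            t1 = max(t1, t0)
        return mismatch_expected("sudden_expansion", t0, t1, tau, max_k) - freq

    best = None
    ok = False
    lower = np.asarray(bounds[0], dtype=float)
    for s in starts:
        s = np.maximum(np.asarray(s, dtype=float), lower + 1e-9)
        try:
            res = least_squares(
                residuals, s,
                bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                max_nfev=400,
            )
        except Exception:
            continue
        ssd = float(np.sum(res.fun**2))
        ok = ok or res.success
        cand = (ssd, float(res.x[2]), res.x)
        if best is None or cand[:2] < best[:2]:  # lowest SSD, then lowest tau
            best = cand
    if best is None:
        raise RuntimeError("mismatch fit failed from every start")
    x = best[2].copy()
    if constrain_growth:
        x[1] = max(x[1], x[0])
    return x, best[0], ok


def _expansion_starts(freq: np.ndarray) -> list[tuple[float, float, float]]:
    """8 deterministic multi-starts spanning decades around a moment guess."""
    t0m, t1m, taum = _moment_start(freq * max(freq.sum(), 1))
    return [
        (0.5, 10.0, taum),
        (0.5, 100.0, taum),
        (5.0, 100.0, taum),
        (0.1, 1000.0, taum / 2.0),
        (t0m, t1m, taum),
        (0.01, 10.0 * t1m, taum),
        (1.0, 1.0, 0.5),
        (t0m / 10.0, t1m, 2.0 * taum),
    ]


def fit_constant(hist: np.ndarray) -> MismatchFit:
    """Least-squares fit of the one-parameter equilibrium model."""
    hist = np.asarray(hist, dtype=float)
    freq = hist / hist.sum()
    max_k = len(freq) - 1

    def residuals(p):
        return _constant_pmf(p[0], max_k) - freq

    k = np.arange(len(freq))
    start = max(float((k * freq).sum()), 1e-3)
    res = least_squares(residuals, [start], bounds=([0.0], [np.inf]),
                        xtol=1e-14, ftol=1e-14)
    theta = float(res.x[0])
    return MismatchFit(
        observed=hist.astype(np.int64), model="constant",
        theta0=theta, theta1=theta, tau=0.0,
        ssd=float(np.sum(res.fun**2)), converged=bool(res.success),
    )


def fit_sudden_expansion(
    hist: np.ndarray,
    n: int | None = None,
    B: int = 10000,
    seed: int = 0,
    constrain_growth: bool = False,
    bootstrap: bool = True,
) -> MismatchFit:
    """Fit (theta0, theta1, tau) of the sudden-expansion model by GLS.

    The sum of squared deviations between observed and expected mismatch
    frequencies is minimized with bounded least squares from 8 deterministic
    multi-starts (ties broken by lowest SSD then lowest tau).  With
    ``bootstrap=True``, B parametric replicates are simulated from the
    fitted model (coalescent genealogies of ``n`` tips under the fitted
    two-epoch demography, Poisson mutations), each refit, yielding 2.5/97.5
    percentile CIs per parameter and the goodness-of-fit
    p_ssd = fraction of bootstrap SSDs >= the observed SSD.

    ``n`` (the sample size behind the histogram) is recovered from
    sum(hist) = C(n,2) when omitted.  ``constrain_growth`` forces
    theta1 >= theta0 (growth-only fits).
    """
    hist = np.asarray(hist, dtype=float)
    n_pairs = float(hist.sum())
    if n_pairs < 3:
        raise ValueError("mismatch histogram needs >= 3 sequence pairs (n >= 3)")
    if n is None:
        # sum(hist) = C(n,2)  =>  n = (1 + sqrt(1 + 8 pairs)) / 2
        n = int(round((1.0 + math.sqrt(1.0 + 8.0 * n_pairs)) / 2.0))
    freq = hist / n_pairs
    # pad so the expected vector can place mass a little beyond the data
    max_k = max(len(freq) - 1, 5) + 5
    freq = np.pad(freq, (0, max_k + 1 - len(freq)))
    if len(hist) == 1 or np.flatnonzero(hist).max() == 0:
        # monomorphic data: tau pinned at the boundary, nothing to estimate
        return MismatchFit(
            observed=hist.astype(np.int64), model="sudden_expansion",
            theta0=0.0, theta1=0.0, tau=0.0, ssd=0.0, B=0, seed=seed,
            converged=True,
        )
    bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])
    x, ssd, ok = _fit_expansion_ls(
        freq, _expansion_starts(freq), bounds, constrain_growth
    )
    fit = MismatchFit(
        observed=hist.astype(np.int64), model="sudden_expansion",
        theta0=float(x[0]), theta1=float(x[1]), tau=float(x[2]),
        ssd=ssd, B=0, seed=seed, converged=ok,
    )
    if not bootstrap or B <= 0:
        return fit
    rng = np.random.default_rng(seed)
    model = DemographyModel(
        kind="sudden_expansion", theta0=fit.theta0, theta1=fit.theta1, tau=fit.tau
    )
    boot = np.full((B, 3), np.nan)
    boot_ssd = np.full(B, np.nan)
    start = (max(fit.theta0, 1e-3), max(fit.theta1, 1e-3), max(fit.tau, 1e-3))
    for b in range(B):
        g = simulate_genealogy(n, model, rng)
        mat = drop_mutations(g, theta=fit.theta1, seed=rng)
        h = pairwise_difference_histogram(mat)
        bk = max(len(h) - 1, 5) + 5
        f = np.pad(h / h.sum(), (0, bk + 1 - len(h)))
        try:
            xb, sb, _ = _fit_expansion_ls(f, [start], bounds, constrain_growth)
        except RuntimeError:
            continue
        boot[b] = xb
        boot_ssd[b] = sb
    valid = ~np.isnan(boot_ssd)
    if valid.sum():
        lo, hi = np.nanpercentile(boot[valid], [2.5, 97.5], axis=0)
        fit.ci = {name: (float(lo[i]), float(hi[i]))
                  for i, name in enumerate(("theta0", "theta1", "tau"))}
        fit.p_ssd = float((boot_ssd[valid] >= ssd).mean())
    fit.B = int(valid.sum())
    return fit


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def tau_to_time(
    tau: float,
    rate_per_site_per_year: float,
    L: int,
    generation_years: float,
) -> tuple[float, float]:
    """Convert an expansion age from mutational units to (generations, years).

    With tau = 2 mu t (mu the per-sequence per-generation mutation rate and
    t in generations), mu = rate * L * generation_years, so
    t_generations = tau / (2 mu) and t_years = t_generations * generation
    time.  tau = 0 maps to time 0; other inputs must be positive.
    """
    for name, v in (("rate", rate_per_site_per_year), ("L", L),
                    ("generation_years", generation_years)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    mu_seq = rate_per_site_per_year * L * generation_years
    t_gen = tau / (2.0 * mu_seq)
    return t_gen, t_gen * generation_years


def theta_to_ne(theta_total: float, mu_seq_per_gen: float) -> float:
    """Effective (female) population size from per-sequence theta.

    For a maternally inherited, effectively haploid locus theta = 2 Ne mu,
    so Ne = theta / (2 mu) with mu per sequence per generation.
    """
    if mu_seq_per_gen <= 0:
        raise ValueError("mutation rate must be > 0")
    if theta_total < 0:
        raise ValueError("theta must be >= 0")
    return theta_total / (2.0 * mu_seq_per_gen)
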