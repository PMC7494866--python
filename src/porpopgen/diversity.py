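"""Per-group, per-partition nucleotide and haplotype diversity statistics.

All statistics use *complete deletion*: an alignment column containing any
gap, N or IUPAC ambiguity in any sequence is excluded for every sequence.
This matches the default of the desktop tools these analyses are usually run
in and makes the segregating-site count S reproducible regardless of which
pair of sequences is being compared.

Definitions (L = usable sites, n = sequences):

* S — columns with >= 2 states among usable columns; a singleton is a
  segregating column whose minor state occurs in exactly one sequence.
* pi — mean number of pairwise differences across all C(n,2) pairs,
  divided by L for the per-site value; variance per Nei (1987) eq. 10.7.
* theta_W — S / (a1 L) with a1 = sum_{i=1}^{n-1} 1/i.
* H, Hd — distinct sequences over usable columns and
  Hd = n/(n-1) (1 - sum p_i^2), variance per Nei (1987) eq. 8.12.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .seqio import GenomeAlignment

__all__ = [
    "DiversityStats",
    "RarefactionResult",
    "usable_columns",
    "site_summary",
    "haplotype_summary",
    "nucleotide_diversity",
    "watterson_theta",
    "harmonic_number",
    "diversity_stats",
    "rarefied_pi",
    "region_diversity",
    "diversity_table",
]


class PreconditionError(ValueError):
    """Too few sequences (or subsample larger than the pool)."""


class DegenerateInputError(ValueError):
    """No usable columns survive complete deletion."""


def harmonic_number(m: int) -> float:
    """a_m = sum_{i=1}^{m} 1/i (a1 of Watterson/Tajima uses m = n-1)."""
    return float(np.sum(1.0 / np.arange(1, m + 1))) if m >= 1 else 0.0


def usable_columns(aln: GenomeAlignment) -> np.ndarray:
    """Boolean mask of columns where every sequence has an unambiguous base."""
    mat = aln.matrix()
    ok = np.zeros(aln.length, dtype=bool)
    if aln.length == 0:
        return ok
    acgt = (mat == b"A") | (mat == b"C") | (mat == b"G") | (mat == b"T")
    return acgt.all(axis=0)


def _usable_matrix(aln: GenomeAlignment) -> np.ndarray:
    if aln.n < 2:
        raise PreconditionError(f"need >= 2 sequences, got {aln.n}")
    mat = aln.matrix()[:, usable_columns(aln)]
    if mat.shape[1] == 0:
        raise DegenerateInputError("no usable columns after complete deletion")
    return mat


def _column_state_counts(mat: np.ndarray) -> np.ndarray:
    """(4, L) counts of A/C/G/T per column of a usable-only matrix."""
    return np.stack([(mat == b).sum(axis=0) for b in (b"A", b"C", b"G", b"T")])


def site_summary(aln: GenomeAlignment) -> tuple[int, int, int, int]:
    """(S, singletons, shared_polymorphisms, usable_sites)."""
    mat = _usable_matrix(aln)
    counts = _column_state_counts(mat)
    n_states = (counts > 0).sum(axis=0)
    seg = n_states >= 2
    # minor state occurs exactly once -> singleton; ties at 1-1 (n=2) count
    # as singleton columns as well (the minor state is carried by one seq).
    minor = np.where(counts == 0, np.iinfo(np.int64).max, counts).min(axis=0)
    singles = seg & (minor == 1)
    S = int(seg.sum())
    singletons = int(singles.sum())
    return S, singletons, S - singletons, mat.shape[1]


def total_mutations(aln: GenomeAlignment) -> tuple[int, int]:
    """(eta, eta_s): total mutations and singleton mutations.

    Per column, eta counts (number of distinct states - 1) so tri-allelic
    columns contribute two mutations; eta_s counts states carried by exactly
    one sequence (except when n = 2, where a polymorphic column is one
    mutation carried by 'one sequence' once, not twice).
    """
    mat = _usable_matrix(aln)
    counts = _column_state_counts(mat)
    n_states = (counts > 0).sum(axis=0)
    eta = int((n_states - 1).sum())
    ones = (counts == 1).sum(axis=0)
    if mat.shape[0] == 2:
        ones = np.minimum(ones, 1) * (n_states > 1)
    eta_s = int(ones[n_states > 1].sum())
    return eta, eta_s


def haplotype_summary(aln: GenomeAlignment) -> tuple[int, float, float]:
    """(H, Hd, sd_Hd) over usable columns.

    Hd = n/(n-1) (1 - sum p_i^2); its sampling variance follows Nei (1987)
    eq. 8.12.
    """
    mat = _usable_matrix(aln)
    n = mat.shape[0]
    _, counts = np.unique(mat, axis=0, return_counts=True)
    H = len(counts)
    p = counts / n
    sum2, sum3 = float(np.sum(p**2)), float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - sum2)
    var = (
        2.0 / (n * (n - 1))
        * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return H, hd, float(np.sqrt(max(var, 0.0)))


def mean_pairwise_differences(aln: GenomeAlignment) -> float:
    """pi_total: mean count of differing usable columns over all C(n,2) pairs."""
    mat = _usable_matrix(aln)
    n, L = mat.shape
    counts = _column_state_counts(mat)
    # per column: number of differing pairs = (C(n,2) - sum_b C(c_b,2))
    same = (counts * (counts - 1) // 2).sum(axis=0)
    pairs = n * (n - 1) // 2
    return float((pairs - same).sum() / pairs)


def nucleotide_diversity(aln: GenomeAlignment) -> tuple[float, float, float]:
    """(pi_per_site, sd_pi_per_site, pi_total).

    The stochastic variance of pi follows Nei (1987) eq. 10.7:
    V(pi) = (n+1) pi / (3 (n-1) L) + 2 (n^2+n+3) pi^2 / (9 n (n-1)).
    """
    mat = _usable_matrix(aln)
    n, L = mat.shape
    pi_total = mean_pairwise_differences(aln)
    pi = pi_total / L
    var = (n + 1) * pi / (3 * (n - 1) * L) + (
        2 * (n**2 + n + 3) * pi**2 / (9 * n * (n - 1))
    )
    return pi, float(np.sqrt(max(var, 0.0))), pi_total


def watterson_theta(S: int, n: int, usable_sites: int) -> float:
    """Watterson's estimator per site: S / (a1 L)."""
    if n < 2:
        raise PreconditionError(f"need n >= 2, got {n}")
    if usable_sites < 1:
        raise DegenerateInputError("usable_sites must be >= 1")
    return S / (harmonic_number(n - 1) * usable_sites)


@dataclass
class DiversityStats:
    """One diversity-table row: the statistics bundle for a group/partition."""

    n: int
    usable_sites: int
    S: int
    singletons: int
    shared_poly: int
    H: int
    Hd: float
    sd_Hd: float
    pi: float
    sd_pi: float
    theta_w: float

    def as_dict(self) -> dict:
        return asdict(self)


def diversity_stats(aln: GenomeAlignment) -> DiversityStats:
    """All per-partition statistics of one group in a single pass."""
    S, singl, shared, L = site_summary(aln)
    H, hd, sd_hd = haplotype_summary(aln)
    pi, sd_pi, _ = nucleotide_diversity(aln)
    return DiversityStats(
        n=aln.n, usable_sites=L, S=S, singletons=singl, shared_poly=shared,
        H=H, Hd=hd, sd_Hd=sd_hd, pi=pi, sd_pi=sd_pi,
        theta_w=watterson_theta(S, aln.n, L),
    )


@dataclass
class RarefactionResult:
    k: int
    B: int
    pi_values: np.ndarray
    median: float
    mean: float
    ci_low: float
    ci_high: float
    seed: int


def rarefied_pi(
    aln: GenomeAlignment, k: int = 3, B: int = 2500, seed: int = 0
) -> RarefactionResult:
    """Rarefaction of pi to a common sample size.

    Each of B replicates draws k distinct sequences without replacement and
    computes per-site pi; the summary is the median, mean and the 2.5/97.5
    percentile interval of the replicate distribution.  Groups of unequal
    size become comparable at the common size k (default 3, the smallest
    multi-sample lineage size in the study design).
    """
    if aln.n < k:
        raise PreconditionError(f"need n >= k ({k}), got {aln.n}")
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        idx = rng.choice(aln.n, size=k, replace=False)
        sub = GenomeAlignment(
            [aln.sample_ids[i] for i in idx],
            [aln.sequences[i] for i in idx],
        )
        vals[b] = nucleotide_diversity(sub)[0]
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return RarefactionResult(
        k=k, B=B, pi_values=vals,
        median=float(np.median(vals)), mean=float(vals.mean()),
        ci_low=float(lo), ci_high=float(hi), seed=seed,
    )


def region_diversity(aln: GenomeAlignment, ann) -> pd.DataFrame:
    """Per-feature-class pi over the union of that class's columns.

    Classes with no columns in the alignment are absent from the output.
    The 'noncoding' row covers columns outside every annotated feature.
    """
    from .seqio import FEATURE_CLASSES, _resolve_feature

    rows = []
    covered_any = np.zeros(aln.length, dtype=bool)
    class_cols: dict[str, np.ndarray] = {}
    for klass in FEATURE_CLASSES:
        cols = np.zeros(aln.length, dtype=bool)
        for feat in ann.by_class(klass):
            cols[_resolve_feature(aln, feat)] = True
        covered_any |= cols
        class_cols[klass] = cols
    class_cols["noncoding"] = class_cols["noncoding"] | ~covered_any
    for klass, cols in class_cols.items():
        if not cols.any():
            continue
        sub = aln.take_columns(np.flatnonzero(cols))
        try:
            pi, _, _ = nucleotide_diversity(sub)
            L = int(usable_columns(sub).sum())
        except DegenerateInputError:
            continue
        rows.append({"klass": klass, "usable_sites": L, "pi_per_site": pi})
    return pd.DataFrame(rows, columns=["klass", "usable_sites", "pi_per_site"])


def diversity_table(
    aln: GenomeAlignment,
    lineages,
    partitions: dict[str, GenomeAlignment],
    min_n: int = 2,
) -> pd.DataFrame:
    """Diversity-table: one row per (species, lineage, partition).

    ``partitions`` maps partition name -> the full partition alignment;
    groups smaller than ``min_n`` are skipped (single-sample lineages carry
    no within-group diversity).
    """
    rows = []
    group_defs = [("species", sp, lg_samples)
                  for sp, lg_samples in lineages.groups("species").items()]
    group_defs += [("lineage", lg, samples)
                   for lg, samples in lineages.groups("lineage").items()]
    for level, label, samples in group_defs:
        samples = [s for s in samples if s in set(aln.sample_ids)]
        if len(samples) < min_n:
            continue
        for part_name, part in partitions.items():
            sub = part.subset(samples)
            try:
                st = diversity_stats(sub)
            except DegenerateInputError:
                continue
            rows.append({"level": level, "group": label, "partition": part_name,
                         **st.as_dict()})
    return pd.DataFrame(rows)
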