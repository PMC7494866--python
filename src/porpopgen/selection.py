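"""Codon-level selection analyses under the vertebrate mitochondrial code.

Synonymous/nonsynonymous site and difference counting follows Nei & Gojobori
(1986): per-codon fractional synonymous sites are the fraction of one-step
changes that are silent (changes creating stop codons are excluded from the
denominator), and multi-step codon differences are averaged over all minimal
mutational pathways that avoid stop codons.  The genetic code defaults to
NCBI translation table 2 (vertebrate mitochondrial: ATA=Met, TGA=Trp,
AGA/AGG=Stop) — the only defensible choice for these genes; it is
configurable for nuclear data.

On top of the engine sit piN/piS, the McDonald–Kreitman 2x2 test with its
neutrality index NI = (Pn/Ps)/(Dn/Ds), a permutation one-way group
comparison with BH-FDR-adjusted pairwise tests, and Pearson correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations, product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from Bio.Data import CodonTable

from .seqio import GenomeAlignment, USABLE_BASES

__all__ = [
    "CodonAlignment",
    "MKTable",
    "MKResult",
    "GeneticCode",
    "VERTEBRATE_MITO",
    "count_syn_nonsyn_sites",
    "count_codon_differences",
    "pi_n_pi_s",
    "mk_test",
    "g_test_2x2",
    "permutation_group_test",
    "correlation_test",
]

BASES = "ACGT"


class GeneticCode:
    """Translation table wrapper with stop-aware one-step enumeration."""

    def __init__(self, table_id: int = 2):
        tab = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.stop_codons = frozenset(tab.stop_codons)
        self.forward = dict(tab.forward_table)

    def translate(self, codon: str) -> str:
        """One-letter amino acid, or '*' for stop."""
        if codon in self.stop_codons:
            return "*"
        return self.forward[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


@lru_cache(maxsize=None)
def _code(table_id: int) -> GeneticCode:
    return GeneticCode(table_id)


VERTEBRATE_MITO = 2


@lru_cache(maxsize=None)
def codon_site_fractions(codon: str, table_id: int = 2) -> tuple[float, float, float]:
    """(nonsyn_sites, syn_sites, stop_excluded) for one codon; sums to 3.

    Per position, one-step changes to a stop codon are removed from the
    denominator; the position contributes its stop fraction to the third
    component so the three parts account for exactly 3 sites.  A stop codon
    itself contributes (0, 0, 3).
    """
    code = _code(table_id)
    if code.is_stop(codon):
        return 0.0, 0.0, 3.0
    aa = code.translate(codon)
    n_sites = s_sites = stop_frac = 0.0
    for pos in range(3):
        syn = non = stop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if code.is_stop(mut):
                stop += 1
            elif code.translate(mut) == aa:
                syn += 1
            else:
                non += 1
        usable = syn + non
        if usable:
            s_sites += syn / usable * (1 - stop / 3)
            n_sites += non / usable * (1 - stop / 3)
        stop_frac += stop / 3
    return n_sites, s_sites, stop_frac


@lru_cache(maxsize=None)
def count_codon_differences(
    codon_a: str, codon_b: str, table_id: int = 2
) -> tuple[float, float]:
    """(nonsyn_diffs, syn_diffs) between two codons, pathway-averaged.

    Multi-step differences average the synonymous/nonsynonymous breakdown
    over all minimal mutational pathways, excluding pathways that pass
    through a stop codon.  If every pathway is blocked, stop-traversing
    pathways are used as a fallback (with a warning) so the pair still
    contributes its total number of differences.
    """
    code = _code(table_id)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    for c in (codon_a, codon_b):
        if set(c) - USABLE_BASES:
            raise ValueError(f"codon {c!r} contains unusable bases")

    def pathway_counts(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = codon_a
        nd = sd = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if code.is_stop(nxt) and nxt != codon_b:
                return None
            if code.is_stop(cur) or code.is_stop(nxt):
                # terminal stop codon in the data: count as nonsynonymous
                nd += 1
            elif code.translate(cur) == code.translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return nd, sd

    results = [r for r in map(pathway_counts, permutations(diff_pos)) if r is not None]
    if not results:
        warnings.warn(
            f"all minimal pathways {codon_a}->{codon_b} pass through a stop; "
            "codon pair skipped",
            stacklevel=2,
        )
        return 0.0, 0.0
    nd = float(np.mean([r[0] for r in results]))
    sd = float(np.mean([r[1] for r in results]))
    return nd, sd


@dataclass
class CodonAlignment:
    """Per-gene codon columns for n sequences.

    Built from strand-oriented, frame-trimmed CDS alignments; codon columns
    containing any gap/N/ambiguity in any sequence are excluded (complete
    deletion at codon granularity) and counted in ``excluded_codons``.
    """

    sample_ids: list[str]
    codons: list[list[str]]  # [seq][codon_column]
    genes: list[tuple[str, int]]  # (gene name, codon-column count), in order
    genetic_code: int = VERTEBRATE_MITO
    excluded_codons: int = 0

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_codons(self) -> int:
        return len(self.codons[0]) if self.codons else 0

    @classmethod
    def from_gene_alignments(
        cls,
        genes: dict[str, GenomeAlignment],
        genetic_code: int = VERTEBRATE_MITO,
    ) -> "CodonAlignment":
        ids: list[str] | None = None
        cols: list[list[str]] | None = None
        order: list[tuple[str, int]] = []
        excluded = 0
        for name, aln in genes.items():
            if aln.length % 3:
                raise ValueError(f"gene {name}: length {aln.length} not codon-aligned")
            if ids is None:
                ids = list(aln.sample_ids)
                cols = [[] for _ in ids]
            elif list(aln.sample_ids) != ids:
                raise ValueError(f"gene {name}: sample ids differ between genes")
            kept = 0
            for c in range(0, aln.length, 3):
                col = [s[c:c + 3] for s in aln.sequences]
                if any(set(codon) - USABLE_BASES for codon in col):
                    excluded += 1
                    continue
                for row, codon in zip(cols, col):
                    row.append(codon)
                kept += 1
            order.append((name, kept))
        if ids is None:
            raise ValueError("no genes supplied")
        return cls(ids, cols, order, genetic_code, excluded)

    def subset(self, ids) -> "CodonAlignment":
        wanted = set(ids)
        keep = [i for i, s in enumerate(self.sample_ids) if s in wanted]
        if len(keep) != len(wanted):
            raise ValueError("some requested sample ids absent from codon alignment")
        return CodonAlignment(
            [self.sample_ids[i] for i in keep],
            [self.codons[i] for i in keep],
            list(self.genes), self.genetic_code, self.excluded_codons,
        )

    def column(self, j: int) -> list[str]:
        return [row[j] for row in self.codons]


def count_syn_nonsyn_sites(codon_aln: CodonAlignment) -> tuple[float, float]:
    """(N_sites, S_sites): Nei–Gojobori site counts averaged over sequences."""
    n_tot = s_tot = 0.0
    for row in codon_aln.codons:
        for codon in row:
            n, s, _ = codon_site_fractions(codon, codon_aln.genetic_code)
            n_tot += n
            s_tot += s
    return n_tot / codon_aln.n, s_tot / codon_aln.n


def _pairwise_diff_totals(codon_aln: CodonAlignment) -> tuple[float, float]:
    """Sum over all sequence pairs of pathway-averaged (nonsyn, syn) diffs."""
    nd_tot = sd_tot = 0.0
    tid = codon_aln.genetic_code
    for a, b in combinations(range(codon_aln.n), 2):
        ra, rb = codon_aln.codons[a], codon_aln.codons[b]
        for ca, cb in zip(ra, rb):
            if ca != cb:
                nd, sd = count_codon_differences(ca, cb, tid)
                nd_tot += nd
                sd_tot += sd
    return nd_tot, sd_tot


def pi_n_pi_s(codon_aln: CodonAlignment) -> tuple[float, float, float | None]:
    """(piN, piS, piN/piS) — pairwise diversity at nonsyn and syn sites.

    Mean pairwise nonsynonymous (synonymous) differences divided by the
    nonsynonymous (synonymous) site count; the ratio is None when piS = 0.
    """
    if codon_aln.n < 2:
        raise ValueError(f"need >= 2 sequences, got {codon_aln.n}")
    n_sites, s_sites = count_syn_nonsyn_sites(codon_aln)
    nd_tot, sd_tot = _pairwise_diff_totals(codon_aln)
    pairs = codon_aln.n * (codon_aln.n - 1) / 2
    pi_n = nd_tot / pairs / n_sites if n_sites > 0 else 0.0
    pi_s = sd_tot / pairs / s_sites if s_sites > 0 else 0.0
    ratio = pi_n / pi_s if pi_s > 0 else None
    return pi_n, pi_s, ratio


@dataclass
class MKTable:
    """2x2 McDonald–Kreitman counts (pathway-averaged, hence fractional)."""

    Dn: float
    Ds: float
    Pn: float
    Ps: float

    def rounded(self) -> tuple[int, int, int, int]:
        """Half-to-even rounding, used only for the G / Fisher 2x2 tests."""
        r = lambda x: int(round(x))  # Python round is banker's rounding
        return r(self.Dn), r(self.Ds), r(self.Pn), r(self.Ps)


@dataclass
class MKResult:
    NI: float | None
    g_stat: float | None
    g_pvalue: float | None
    fisher_pvalue: float | None
    interpretation: str  # positive | neutral | purifying | undefined

    @staticmethod
    def interpret(ni: float | None) -> str:
        if ni is None or not math.isfinite(ni):
            return "undefined"
        if math.isclose(ni, 1.0, rel_tol=1e-9):
            return "neutral"
        return "purifying" if ni > 1 else "positive"


def g_test_2x2(
    table: np.ndarray, williams: bool = False
) -> tuple[float | None, float | None]:
    """G-test of independence on a 2x2 table; optional Williams correction.

    Returns (None, None) when a marginal total is zero (expected counts
    undefined).  Zero observed cells contribute 0 to G.
    """
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if total == 0 or (rows == 0).any() or (cols == 0).any():
        return None, None
    expected = np.outer(rows, cols) / total
    nz = obs > 0
    g = 2.0 * float((obs[nz] * np.log(obs[nz] / expected[nz])).sum())
    if williams:
        q = 1 + ((total / rows).sum() - 1) * ((total / cols).sum() - 1) / (6 * total)
        g /= q
    return g, float(stats.chi2.sf(g, df=1))


def _consensus_codon(codons: list[str]) -> str:
    vals, counts = np.unique(codons, return_counts=True)
    return str(vals[np.argmax(counts)])  # ties broken alphabetically


def mk_counts(
    ingroup: CodonAlignment, outgroup: CodonAlignment
) -> MKTable:
    """Pathway-averaged MK counts from aligned codon matrices.

    A codon column is *polymorphic* when the ingroup segregates there (its
    pathway-averaged differences against the ingroup consensus feed Pn/Ps);
    it is a *fixed difference* when the ingroup is monomorphic and differs
    from the outgroup consensus codon.  Columns both polymorphic and
    divergent count only as polymorphism (conservative choice).
    """
    if ingroup.n_codons != outgroup.n_codons:
        raise ValueError("ingroup/outgroup codon alignments differ in length")
    tid = ingroup.genetic_code
    in_mat = np.array(ingroup.codons)  # (n, n_codons) of '<U3'
    out_mat = np.array(outgroup.codons)
    poly = (in_mat != in_mat[0]).any(axis=0)
    out_differs = (out_mat != in_mat[0]).any(axis=0)
    Dn = Ds = Pn = Ps = 0.0
    for j in np.flatnonzero(poly):
        col = [str(c) for c in in_mat[:, j]]
        ref = _consensus_codon(col)
        for c in sorted(set(col)):
            if c != ref:
                nd, sd = count_codon_differences(ref, c, tid)
                Pn += nd
                Ps += sd
    for j in np.flatnonzero(~poly & out_differs):
        out = _consensus_codon([str(c) for c in out_mat[:, j]])
        ref = str(in_mat[0, j])
        if out != ref:
            nd, sd = count_codon_differences(ref, out, tid)
            Dn += nd
            Ds += sd
    return MKTable(Dn=Dn, Ds=Ds, Pn=Pn, Ps=Ps)


def mk_test(
    ingroup: CodonAlignment,
    outgroup: CodonAlignment,
    williams: bool = False,
    haldane: bool = False,
) -> tuple[MKTable, MKResult]:
    """McDonald–Kreitman test: NI = (Pn/Ps)/(Dn/Ds) with G and Fisher tests.

    NI is computed on raw (fractional) counts; the 2x2 significance tests
    use half-to-even rounded counts.  ``haldane`` adds 0.5 to every cell of
    the NI ratio when a cell is zero (off by default).
    """
    tab = mk_counts(ingroup, outgroup)
    Dn, Ds, Pn, Ps = tab.Dn, tab.Ds, tab.Pn, tab.Ps
    if haldane and min(Dn, Ds, Pn, Ps) == 0:
        Dn, Ds, Pn, Ps = Dn + 0.5, Ds + 0.5, Pn + 0.5, Ps + 0.5
    if Ps > 0 and Dn > 0 and Ds > 0:
        ni = (Pn / Ps) / (Dn / Ds)
    else:
        ni = None
    r = tab.rounded()
    table2x2 = np.array([[r[2], r[3]], [r[0], r[1]]], dtype=float)  # P row, D row
    if table2x2.sum() == 0:
        return tab, MKResult(None, None, None, None, "undefined")
    g, p_g = g_test_2x2(table2x2, williams=williams)
    fisher_p = float(stats.fisher_exact(table2x2.astype(int))[1])
    return tab, MKResult(ni, g, p_g, fisher_p, MKResult.interpret(ni))


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _f_stat(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Between/within sum-of-squares ratio (one-way F-type statistic)."""
    grand = values.mean()
    ss_between = ss_within = 0.0
    for g in range(k):
        v = values[codes == g]
        m = v.mean()
        ss_between += len(v) * (m - grand) ** 2
        ss_within += ((v - m) ** 2).sum()
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    n = len(values)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permutation_group_test(
    values, labels, n_perm: int = 9999, seed: int = 0
) -> tuple[float, float, pd.DataFrame]:
    """Permutation one-way comparison of a numeric value across groups.

    The statistic is the one-way F ratio; its null distribution comes from
    random label permutations and p = (1 + #{perm >= obs})/(n_perm + 1).
    Pairwise group contrasts use the same two-group permutation test and are
    Benjamini–Hochberg adjusted.  Groups with fewer than 2 observations are
    excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    uniq, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    small = uniq[sizes < 2]
    if len(small):
        warnings.warn(f"excluding groups with < 2 observations: {list(small)}",
                      stacklevel=2)
        keep = ~np.isin(labels, small)
        values, labels = values[keep], labels[keep]
        uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    rng = np.random.default_rng(seed)
    k = len(uniq)

    def perm_p(vals: np.ndarray, cds: np.ndarray, kk: int) -> tuple[float, float]:
        obs = _f_stat(vals, cds, kk)
        count = 0
        c = cds.copy()
        for _ in range(n_perm):
            rng.shuffle(c)
            if _f_stat(vals, c, kk) >= obs:
                count += 1
        return obs, (1 + count) / (n_perm + 1)

    stat, pvalue = perm_p(values, codes, k)
    rows = []
    for a, b in combinations(range(k), 2):
        sel = (codes == a) | (codes == b)
        sub_codes = (codes[sel] == b).astype(int)
        s_ab, p_ab = perm_p(values[sel], sub_codes, 2)
        rows.append({"group_a": str(uniq[a]), "group_b": str(uniq[b]),
                     "stat": s_ab, "pvalue": p_ab})
    pairwise = pd.DataFrame(rows)
    if not pairwise.empty:
        pairwise["pvalue_fdr"] = multipletests(
            pairwise["pvalue"].to_numpy(), method="fdr_bh"
        )[1]
    return stat, pvalue, pairwise


def correlation_test(x, y) -> tuple[float | None, float | None]:
    """Pearson correlation with its t-distribution p-value.

    Returns (None, None) when either input has zero variance.  Any log10
    transformation happens upstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with >= 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
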