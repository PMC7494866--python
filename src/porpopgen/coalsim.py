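"""Coalescent synthetic-data generator.

Simulates Kingman genealogies under a constant-size or sudden-expansion
demography, drops infinite-sites mutations on them (Poisson with scaled
diversity theta, or conditioned on an exact number of segregating sites),
and assembles annotated synthetic mitogenome alignments whose coding
mutations have a controllable synonymous/nonsynonymous composition.  Every
other module in the package is testable offline against this generator.

Time and units
--------------
Genealogies are simulated in coalescent units of the *recent* population
(one unit = the timescale on which a pair of lineages coalesces at rate 1
today).  The sudden-expansion model holds the recent scaled diversity
``theta1`` back to the change point and the ancient ``theta0`` before it;
the change time ``tau`` is given in mutational units (tau = 2 mu t, the
convention of mismatch-distribution analyses) and is converted once to
coalescent units as tau / theta1.  With mutations dropped at rate theta1/2
per branch per coalescent unit, a pair coalescing at mutational time x
carries Poisson(x) differences, so E[pi] = theta under the constant model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import (
    Feature,
    GeneAnnotation,
    GenomeAlignment,
    LineageTable,
    MaskSet,
    reverse_complement,
    write_alignment,
    write_annotation,
    write_lineage_table,
)

__all__ = [
    "DemographyModel",
    "Genealogy",
    "GroupConfig",
    "SynthConfig",
    "simulate_genealogy",
    "drop_mutations",
    "porpoise_like_annotation",
    "synth_mitogenome_set",
]


@dataclass(frozen=True)
class DemographyModel:
    """Piecewise-constant demography for the simulator and mismatch model.

    ``constant`` uses only ``theta1`` (the scaled diversity 2 Ne mu per
    sequence); ``sudden_expansion`` jumps from ``theta0`` (ancient) to
    ``theta1`` (recent) at ``tau`` mutational units before the present.
    """

    kind: str = "constant"  # constant | sudden_expansion
    theta1: float = 1.0
    theta0: float = 1.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sudden_expansion"):
            raise ValueError(f"unknown demography kind {self.kind!r}")
        if min(self.theta0, self.theta1, self.tau) < 0:
            raise ValueError("demography parameters must be >= 0")


@dataclass
class Genealogy:
    """Binary rooted coalescent tree over ``n`` tips.

    Nodes 0..n-1 are tips at time 0; internal nodes n..2n-2 appear in
    coalescence order; ``parent[root] = -1``.  Times are coalescent units.
    """

    n: int
    parent: np.ndarray  # (2n-1,)
    time: np.ndarray  # (2n-1,) node times

    @property
    def n_nodes(self) -> int:
        return 2 * self.n - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def t_mrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        out[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return out

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_sets(self) -> np.ndarray:
        """(2n-1, n) boolean: tips below each node (nodes are time-ordered)."""
        below = np.zeros((self.n_nodes, self.n), dtype=bool)
        below[np.arange(self.n), np.arange(self.n)] = True
        for child in np.argsort(self.time[: self.n_nodes - 1], kind="stable"):
            below[self.parent[child]] |= below[child]
        return below

    def external_branch_length(self) -> float:
        return float(self.branch_lengths()[: self.n].sum())


def _rate_scale(model: DemographyModel) -> tuple[float, float]:
    """(change time in coalescent units, ancient rate multiplier)."""
    if model.kind == "constant" or model.tau == 0:
        return np.inf, 1.0
    if model.theta1 <= 0:
        return np.inf, 1.0
    t_change = model.tau / model.theta1
    theta0 = max(model.theta0, 1e-12)  # theta0=0: effectively instant MRCA
    return t_change, model.theta1 / theta0


def simulate_genealogy(
    n: int, model: DemographyModel, seed: int | np.random.Generator = 0
) -> Genealogy:
    """Sample a coalescent genealogy of ``n`` tips under ``model``.

    Exponential waiting times with rate C(k,2) are rescaled by the
    population-size trajectory; crossing the size-change point re-draws the
    remaining waiting time at the ancient rate (valid by memorylessness).
    """
    if n < 2:
        raise ValueError(f"need n >= 2 tips, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_change, ancient_mult = _rate_scale(model)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        base = k * (k - 1) / 2.0
        rate = base * (ancient_mult if t >= t_change else 1.0)
        w = rng.exponential(1.0 / rate)
        if t < t_change < t + w:
            # cross into the ancient epoch and re-draw there
            t = t_change
            w = rng.exponential(1.0 / (base * ancient_mult))
        t += w
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Genealogy(n=n, parent=parent, time=time)


def drop_mutations(
    g: Genealogy,
    *,
    theta: float | None = None,
    fixed_S: int | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Infinite-sites mutations on a genealogy -> (n, S) 0/1 matrix.

    ``theta`` mode draws Poisson(theta/2 * total length) mutations placed
    uniformly on branches; ``fixed_S`` mode places exactly S mutations
    (the conditioning used for neutrality-test null distributions).  Each
    mutation is a new column whose derived state 1 marks the tips below the
    mutated branch.
    """
    if (theta is None) == (fixed_S is None):
        raise ValueError("give exactly one of theta / fixed_S")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = g.branch_lengths()
    total = lengths.sum()
    if fixed_S is not None:
        if fixed_S < 0:
            raise ValueError("fixed_S must be >= 0")
        S = int(fixed_S)
    else:
        if theta < 0:
            raise ValueError("theta must be >= 0")
        S = int(rng.poisson(theta / 2.0 * total))
    if S == 0:
        return np.zeros((g.n, 0), dtype=np.uint8)
    branches = rng.choice(g.n_nodes, size=S, p=lengths / total)
    below = g.leaf_sets()
    return below[branches].T.astype(np.uint8)


def pairwise_difference_histogram(matrix: np.ndarray) -> np.ndarray:
    """Histogram of pairwise difference counts from a 0/1 site matrix.

    Entry k is the number of sequence pairs differing at exactly k sites;
    the histogram sums to C(n,2).
    """
    m = np.asarray(matrix, dtype=np.int64)
    n = m.shape[0]
    if n < 2:
        raise ValueError("need >= 2 sequences")
    ones = m @ m.T
    tot = m.sum(axis=1)
    diffs = tot[:, None] + tot[None, :] - 2 * ones
    iu = np.triu_indices(n, k=1)
    d = diffs[iu]
    return np.bincount(d, minlength=int(d.max()) + 1 if len(d) else 1)


def synth_codon_alignment(
    n_codons: int,
    n: int,
    model: DemographyModel,
    *,
    divergence: float = 0.0,
    n_outgroup: int = 1,
    nonsyn_fraction: float | None = None,
    divergence_nonsyn_fraction: float | None = ...,
    genetic_code: int = 2,
    seed: int | np.random.Generator = 0,
):
    """Coalescent ingroup + diverged outgroup codon alignments for one gene.

    Mutations (coalescent within the ingroup, Poisson(``divergence``) on the
    outgroup stem) hit distinct random codon positions.  With
    ``nonsyn_fraction=None`` the change is any random non-stop substitution
    (neutral with respect to coding effect); otherwise the substitution
    class is forced to nonsynonymous with that probability by rejection
    sampling, as in :func:`synth_mitogenome_set`.
    ``divergence_nonsyn_fraction`` controls the stem mutations separately
    (default: same as ``nonsyn_fraction``), letting polymorphism and
    divergence carry different compositions — the contrast McDonald-
    Kreitman tests detect.  Returns a pair of
    :class:`~porpopgen.selection.CodonAlignment` objects (ingroup,
    outgroup).
    """
    from .selection import CodonAlignment, _code

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    code = _code(genetic_code)
    if divergence_nonsyn_fraction is ...:
        divergence_nonsyn_fraction = nonsyn_fraction
    anc_seq = _random_coding_codons(n_codons, code, rng)
    ancestral = [anc_seq[i: i + 3] for i in range(0, 3 * n_codons, 3)]
    used: set[tuple[int, int]] = set()

    def draw_change(fraction: float | None) -> tuple[int, int, str]:
        want = None
        if fraction is not None:
            want = "nonsyn" if rng.random() < fraction else "syn"
        for _ in range(20000):
            ci = int(rng.integers(0, n_codons))
            w = int(rng.integers(0, 3))
            if (ci, w) in used:
                continue
            codon = ancestral[ci]
            new = [b for b in "ACGT" if b != codon[w]][rng.integers(0, 3)]
            klass = _mutation_class(codon, w, new, code)
            if klass == "stop":
                continue
            if want is None or klass == want:
                used.add((ci, w))
                return ci, w, new
        raise RuntimeError("codon set saturated; increase n_codons")

    in_rows = [list(ancestral) for _ in range(n)]
    if n >= 2:
        g = simulate_genealogy(n, model, rng)
        mat = drop_mutations(g, theta=model.theta1, seed=rng)
        for j in range(mat.shape[1]):
            ci, w, new = draw_change(nonsyn_fraction)
            for i in np.flatnonzero(mat[:, j]):
                c = in_rows[i][ci]
                in_rows[i][ci] = c[:w] + new + c[w + 1:]
    out_row = list(ancestral)
    for _ in range(int(rng.poisson(divergence)) if divergence > 0 else 0):
        ci, w, new = draw_change(divergence_nonsyn_fraction)
        c = out_row[ci]
        out_row[ci] = c[:w] + new + c[w + 1:]
    genes = [("gene1", n_codons)]
    ingroup = CodonAlignment(
        [f"in_{i + 1:03d}" for i in range(n)], in_rows, list(genes), genetic_code
    )
    outgroup = CodonAlignment(
        [f"out_{i + 1:03d}" for i in range(n_outgroup)],
        [list(out_row) for _ in range(n_outgroup)], list(genes), genetic_code,
    )
    return ingroup, outgroup


# ---------------------------------------------------------------------------
# annotated synthetic mitogenomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupConfig:
    """One lineage in a synthetic study: sample size, demography, divergence.

    ``stem_mutations`` is the expected number of mutations on the group's
    stem branch (Poisson); these are fixed within the group and create the
    between-group divergence that McDonald–Kreitman tests consume.
    """

    species: str
    lineage: str
    n: int
    model: DemographyModel = field(default_factory=DemographyModel)
    stem_mutations: float = 0.0


@dataclass
class SynthConfig:
    genome_length: int = 16300
    groups: list[GroupConfig] = field(default_factory=list)
    cds_nonsyn_fraction: float = 0.3
    annotation: GeneAnnotation | None = None  # default: porpoise_like_annotation
    seed: int = 0


def porpoise_like_annotation(genome_length: int = 16300) -> GeneAnnotation:
    """A compact mitogenome-like annotation template.

    Lays out rRNAs, thirteen CDSs (the last one minus-strand, overlapping
    the previous gene by 17 bp, mirroring the ND5/ND6 arrangement), tRNA
    spacers, an origin of replication, and a terminal control region.  Sizes
    are scaled to the requested genome length; all CDS lengths are multiples
    of 3.
    """
    if genome_length < 4000:
        raise ValueError("genome_length too small for the mitogenome template")
    feats: list[Feature] = []
    pos = 1

    def add(name: str, length: int, klass: str, strand: str = "+") -> None:
        nonlocal pos
        feats.append(Feature(name, pos, pos + length - 1, strand, klass))
        pos += length

    scale = genome_length / 16300.0

    def trna(idx: int) -> None:
        add(f"trn{idx}", max(30, int(70 * scale)), "tRNA")
    cds_len = [int(round(s * scale / 3)) * 3 for s in
               (954, 1044, 351, 681, 1824, 684, 783, 201, 228, 780, 297, 1374, 1140)]
    trna_i = 0
    trna(trna_i := trna_i + 1)
    add("rrnS", int(960 * scale), "rRNA")
    trna(trna_i := trna_i + 1)
    add("rrnL", int(1570 * scale), "rRNA")
    trna(trna_i := trna_i + 1)
    for g in range(11):
        add(f"cds{g + 1:02d}", cds_len[g], "CDS")
        trna(trna_i := trna_i + 1)
        if g == 5:
            add("OL", 32, "origin")
    # ND5/ND6-like pair: the last gene is minus-strand and overlaps by 17 bp
    add("cds12", cds_len[11], "CDS")
    overlap = 17
    pos -= overlap
    add("cds13", cds_len[12], "CDS", strand="-")
    trna(trna_i := trna_i + 1)
    remaining = genome_length - pos + 1
    if remaining < 200:
        raise ValueError("template overflow: increase genome_length")
    add("CR", remaining, "noncoding")
    return GeneAnnotation(feats)


def _random_coding_codons(n_codons: int, code, rng: np.random.Generator) -> str:
    """Random sense codons (no stops) under the given genetic code."""
    sense = sorted(set(code.forward))  # forward table excludes stops
    idx = rng.integers(0, len(sense), size=n_codons)
    return "".join(sense[i] for i in idx)


def _build_ancestral_genome(
    L: int, ann: GeneAnnotation, code, rng: np.random.Generator
) -> np.ndarray:
    """Random genome with stop-free reading frames in every CDS.

    CDSs are written in annotation order; where two CDSs overlap the later
    write wins, so the earlier gene's overlapping codons are re-checked and
    the later gene's overlap region is resampled (bounded retries) until
    both frames are stop-free.
    """
    genome = np.frombuffer(
        "".join(np.random.default_rng(rng.integers(2**31)).choice(list("ACGT"), size=L)).encode(),
        dtype="S1",
    ).copy()

    def write_cds(feat: Feature) -> None:
        n_codons = feat.length // 3
        seq = _random_coding_codons(n_codons, code, rng)
        seq = seq + "A" * (feat.length - len(seq))  # incomplete terminal codon
        if feat.strand == "-":
            seq = reverse_complement(seq)
        genome[feat.start - 1: feat.end] = np.frombuffer(seq.encode(), dtype="S1")

    def frame_ok(feat: Feature) -> bool:
        raw = genome[feat.start - 1: feat.end].tobytes().decode()
        if feat.strand == "-":
            raw = reverse_complement(raw)
        usable = len(raw) - len(raw) % 3
        return not any(
            code.is_stop(raw[i: i + 3]) for i in range(0, usable, 3)
        )

    cds = ann.by_class("CDS")
    for feat in cds:
        write_cds(feat)
    for _ in range(500):
        bad = [f for f in cds if not frame_ok(f)]
        if not bad:
            break
        # resample every overlapping partner chain containing a bad frame
        for feat in cds:
            for other in bad:
                if feat is not other and not (
                    feat.end < other.start or other.end < feat.start
                ):
                    write_cds(feat)
        for f in bad:
            if all(f.end < o.start or o.end < f.start for o in cds if o is not f):
                write_cds(f)  # isolated bad frame: just regenerate it
    else:
        raise RuntimeError("could not build stop-free overlapping reading frames")
    return genome


def _cds_context(pos0: int, feat: Feature, genome: np.ndarray) -> tuple[str, int, int]:
    """(ancestral codon, offset of pos within codon, codon genome start).

    All in the gene's reading direction; ``pos0`` is 0-based genomic.
    """
    if feat.strand == "+":
        off_gene = pos0 - (feat.start - 1)
    else:
        off_gene = (feat.end - 1) - pos0
    codon_idx = off_gene // 3
    within = off_gene % 3
    if feat.strand == "+":
        start0 = (feat.start - 1) + codon_idx * 3
        codon = genome[start0: start0 + 3].tobytes().decode()
    else:
        end0 = (feat.end - 1) - codon_idx * 3
        codon = reverse_complement(genome[end0 - 2: end0 + 1].tobytes().decode())
        start0 = end0 - 2
    return codon, within, start0


def _mutation_class(codon: str, within: int, new_base: str, code) -> str:
    """'syn' | 'nonsyn' | 'stop' classification against the ancestral codon."""
    mut = codon[:within] + new_base + codon[within + 1:]
    if code.is_stop(mut) or code.is_stop(codon):
        return "stop"
    return "syn" if code.translate(mut) == code.translate(codon) else "nonsyn"


def synth_mitogenome_set(
    config: SynthConfig, out_dir: str | Path | None = None
) -> tuple[GenomeAlignment, GeneAnnotation, LineageTable]:
    """Generate an annotated multi-lineage synthetic mitogenome alignment.

    For each group a coalescent genealogy is simulated under its demography,
    mutations are dropped (theta mode, rate ``model.theta1``) plus Poisson
    stem mutations fixed in the group, and every mutation is mapped to a
    distinct genome position (infinite sites).  Mutations landing in a CDS
    are made synonymous or nonsynonymous with probability
    ``cds_nonsyn_fraction`` by rejection-sampling position/base pairs within
    the CDS; changes creating stop codons are rejected.  When ``out_dir`` is
    given, FASTA / GFF3 / lineage-TSV files are written there.
    """
    from .selection import _code  # genetic-code cache

    if not config.groups:
        raise ValueError("config.groups is empty")
    if not 0.0 <= config.cds_nonsyn_fraction <= 1.0:
        raise ValueError("cds_nonsyn_fraction must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    code = _code(2)
    ann = config.annotation or porpoise_like_annotation(config.genome_length)
    L = config.genome_length
    for f in ann:
        if f.end > L:
            raise ValueError(f"annotation feature {f.name} exceeds genome length")
    genome = _build_ancestral_genome(L, ann, code, rng)

    cds_feats = ann.by_class("CDS")
    in_cds = np.zeros(L, dtype=bool)
    for f in cds_feats:
        in_cds[f.start - 1: f.end] = True
    cds_positions = np.flatnonzero(in_cds)
    feat_at: dict[int, Feature] = {}
    for f in cds_feats:  # first (earlier) gene owns shared columns for framing
        for p in range(f.start - 1, f.end):
            feat_at.setdefault(p, f)

    used = np.zeros(L, dtype=bool)
    other_bases = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}

    def draw_noncds_position() -> int:
        while True:
            p = int(rng.integers(0, L))
            if not used[p] and not in_cds[p]:
                return p

    fallback_count = 0

    def draw_cds_mutation(want_nonsyn: bool) -> tuple[int, str]:
        nonlocal fallback_count
        target = "nonsyn" if want_nonsyn else "syn"
        for _ in range(2000):
            p = int(cds_positions[rng.integers(0, len(cds_positions))])
            if used[p]:
                continue
            feat = feat_at[p]
            codon, within, _ = _cds_context(p, feat, genome)
            base = codon[within]
            new = other_bases[base][rng.integers(0, 3)]
            if _mutation_class(codon, within, new, code) == target:
                return p, new if feat.strand == "+" else reverse_complement(new)
        # unsatisfiable in this codon context budget: any non-stop CDS change
        fallback_count += 1
        for _ in range(20000):
            p = int(cds_positions[rng.integers(0, len(cds_positions))])
            if used[p]:
                continue
            feat = feat_at[p]
            codon, within, _ = _cds_context(p, feat, genome)
            new = other_bases[codon[within]][rng.integers(0, 3)]
            if _mutation_class(codon, within, new, code) != "stop":
                return p, new if feat.strand == "+" else reverse_complement(new)
        raise RuntimeError("CDS saturated: cannot place further mutations")

    all_ids: list[str] = []
    all_seqs: list[list[bytes]] = []
    lin_rows = []
    for grp in config.groups:
        ids = [f"{grp.lineage}_{i + 1:03d}" for i in range(grp.n)]
        seqs = [genome.copy() for _ in ids]
        carriers_list: list[np.ndarray] = []
        if grp.n >= 2:
            g = simulate_genealogy(grp.n, grp.model, rng)
            mat = drop_mutations(g, theta=grp.model.theta1, seed=rng)
            carriers_list.extend(mat[:, j].astype(bool) for j in range(mat.shape[1]))
        n_stem = int(rng.poisson(grp.stem_mutations)) if grp.stem_mutations > 0 else 0
        carriers_list.extend(np.ones(grp.n, dtype=bool) for _ in range(n_stem))
        for carriers in carriers_list:
            if rng.random() < (in_cds.sum() / L):
                want_nonsyn = rng.random() < config.cds_nonsyn_fraction
                p, new = draw_cds_mutation(want_nonsyn)
            else:
                p = draw_noncds_position()
                anc = genome[p].decode()
                new = other_bases[anc][rng.integers(0, 3)]
            used[p] = True
            newb = new.encode()
            for i in np.flatnonzero(carriers):
                seqs[i][p] = newb
        all_ids.extend(ids)
        all_seqs.extend(seqs)
        lin_rows.extend(
            {"sample_id": s, "species": grp.species, "lineage": grp.lineage}
            for s in ids
        )
    if fallback_count:
        import warnings

        warnings.warn(
            f"{fallback_count} CDS mutation(s) fell back to any non-stop change",
            stacklevel=2,
        )
    import pandas as pd

    aln = GenomeAlignment(
        all_ids, [s.tobytes().decode() for s in all_seqs],
        np.arange(1, L + 1, dtype=np.int64),
    )
    lineages = LineageTable(pd.DataFrame(lin_rows))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_alignment(aln, out / "alignment.fasta")
        write_annotation(ann, out / "annotation.gff3")
        gff = (out / "annotation.gff3").read_text()
        (out / "annotation.gff3").write_text(
            gff.replace("##gff-version 3", f"##gff-version 3\n# seed={config.seed}")
        )
        (out / "lineages.tsv").write_text(
            f"# seed={config.seed}\n"
        )
        lineages.table.to_csv(out / "lineages.tsv", sep="\t", index=False, mode="a")
    return aln, ann, lineages
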