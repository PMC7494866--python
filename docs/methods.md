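# Methods

This note records the models, conventions and numerical choices behind
porpopgen, in the spirit of a statistical supplement: what each statistic
is, which variant of each published formula is used, what the simulator
does and does not emulate, and where the design was genuinely open.

## Data model and missing data

An alignment is a set of equal-length sequences over the IUPAC DNA
alphabet plus `-`, with a per-column map back to original 1-based
coordinates. Masks (e.g. the hypervariable control-region repeat) are
expressed in original coordinates, so masking commutes and annotations
remain resolvable afterwards; BED input is converted from 0-based
half-open to the internal 1-based inclusive convention on read. Where a
published exclusion interval is stated inclusively but its quoted width
disagrees by one (a classic off-by-one between conventions), the interval
is taken as configuration: both conventions are supported and the
inclusive reading is the default.

All statistics use **complete deletion**: any column containing a gap, N
or ambiguity code in any sequence is dropped for every sequence. This
matches the default of the desktop tools the package replaces and, unlike
pairwise deletion, makes *S* (and hence θ_W and the neutrality tests) a
property of the alignment rather than of a sequence pair. Haplotype
identity is likewise evaluated on usable columns only.

## Partitions

Three analysis partitions are built from the annotation: the whole
alignment; the non-coding partition (columns covered by no CDS, tRNA,
rRNA or replication-origin feature — columns inside features annotated as
non-coding, such as the control region, stay non-coding); and the
concatenated-CDS partition. CDS extraction is per gene in annotation
order: minus-strand genes (ND6 in vertebrate mitogenomes) are
reverse-complemented so each gene reads 5'→3' in its own frame, columns
shared by overlapping genes (the ND5/ND6 17-bp overlap) appear once per
gene — the concatenation length is the **sum** of gene lengths, not the
union — and a terminal incomplete codon is dropped with a warning rather
than an error, since mitochondrial CDSs with incomplete stop codons are
routine.

## Diversity statistics

With n sequences and L usable sites: S counts columns with ≥ 2 states; a
singleton is a segregating column whose minor state is carried by exactly
one sequence; π_total is the mean pairwise difference count over all
C(n,2) pairs (computed per column from state counts, which is exactly the
pairwise definition); θ_W = S/(a₁L) with a₁ = Σ_{i<n} 1/i. Variances
follow Nei (1987): eq. 10.7 for π (stochastic variance) and eq. 8.12 for
haplotype diversity, so parity with DnaSP output is checkable.
Rarefaction draws k distinct sequences without replacement (default
k = 3, B = 2,500, seeded) and summarizes the replicate π distribution by
median, mean and the 2.5/97.5 percentiles. That interval is the
subsample spread of one realized genealogy, not a confidence interval on
θ: for a single non-recombining locus the genealogy itself dominates, so
the tests of the generator assert the *rank* of rarefied medians between
contrasting lineages rather than strict interval separation.

## Codon-level selection

The genetic code defaults to NCBI translation table 2 (vertebrate
mitochondrial; ATA = Met, TGA = Trp, AGA/AGG = Stop) — the only
defensible choice for these genes; it is configurable for other
compartments. Site counting is Nei–Gojobori:
per codon position, the synonymous fraction of the three one-step changes,
with changes to stop codons removed from the denominator and their
fraction reported separately so nonsyn + syn + stop-excluded = 3 exactly.
Codon differences are pathway-averaged over all minimal mutational routes
that avoid stop codons; if every route is blocked the pair is skipped
with a warning. π_N/π_S divides mean pairwise nonsynonymous (synonymous)
differences by the corresponding site counts; π_S = 0 flags the ratio as
undefined rather than raising.

McDonald–Kreitman counting is conservative and DnaSP-compatible: a codon
column polymorphic within the ingroup contributes its pathway-averaged
differences against the ingroup consensus to P_n/P_s; a column
monomorphic in the ingroup but different from the outgroup consensus
contributes to D_n/D_s; a column both polymorphic and divergent counts
as polymorphism only. NI = (P_n/P_s)/(D_n/D_s) is computed on the raw
fractional counts (undefined when a needed cell is zero; an optional
Haldane +0.5 correction exists behind a flag and is off by default), while
the G-test (no Williams correction by default) and two-sided Fisher exact
test round the table half-to-even first. Group comparisons of NI-like
values use a one-way F-type statistic with a label-permutation null,
p = (1 + #{perm ≥ obs})/(n_perm + 1), 9,999 permutations by default, and
Benjamini–Hochberg adjustment of the pairwise permutation p-values.

## SFS neutrality tests

Tajima's D uses the 1989 normalization (coefficients a₁, a₂, b₁, b₂, c₁,
c₂, e₁, e₂). Fu & Li's D* and F* are the without-outgroup statistics on
total mutations η (states − 1 summed per column, so triallelic columns
count twice) and singleton mutations η_s; the variance constants follow
Fu & Li (1993) **as corrected by Simonsen, Churchill & Aquadro (1995)**
— the originally printed constants contain typos. As a literature
cross-check, the corrected constants reproduce published vaquita
mitogenome values (n = 12, η = 16, η_s = 13 gives D* = −1.90, matching
the reported −1.89 to printed precision, and the reported D = −1.44
back-solves to a π consistent with the same data); reported F* values in
that literature fall between the corrected and uncorrected variants, a
known ambiguity of legacy implementations, and the documented corrected
constants are used throughout here.

P-values are two-tailed simulation probabilities: constant-size Kingman
genealogies of the observed n with **exactly S mutations** placed on
branches proportionally to length (the fixed-S conditioning the desktop
tools use), p = 2·min(P(stat ≤ obs), P(stat ≥ obs)) with an add-one
correction, capped at 1. Null distributions are cached per (n, S), which
also makes large calibration runs feasible. Calibration under the null
(n = 20, θ = 10): mean D ≈ −0.07 (the statistic is slightly left-skewed
at finite n; this is a property of D, not an artifact) and a rejection
rate at the 0.05 level within [0.03, 0.07].

## Mismatch distributions

Under equilibrium the pairwise difference count is geometric,
F(k) = θᵏ/(θ+1)ᵏ⁺¹. The sudden-expansion model holds θ₀ before and θ₁
after an instantaneous size change τ = 2µt mutational units ago; the
implementation evaluates the exact two-epoch closed form

F_k = F̂_k(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_{j≤k} (τʲ/j!) [F̂_{k−j}(θ₀) − F̂_{k−j}(θ₁)],

which is derived directly from the piecewise-exponential coalescence
density of a pair (the Rogers–Harpending transient expression; the finite
sum is exact for this model, not an approximation). Limits are honored
and tested: τ = 0 reduces to the equilibrium model at θ₀, τ → ∞ to θ₁.

Fitting minimizes the sum of squared deviations between observed and
expected mismatch *frequencies* with bounded least squares
(θ₀, θ₁, τ ≥ 0; xtol = ftol = 1e−14) from eight deterministic multi-starts
spanning decades around a moment-based guess; ties are broken by lowest
SSD, then lowest τ. θ₁ ≥ θ₀ can optionally be enforced (growth-only);
both parameters are free by default. The parametric bootstrap simulates
B datasets under the fitted demography (genealogies in coalescent units
of the recent epoch, change point at τ/θ₁, mutations at rate θ₁/2 per
branch per unit), refits each from the parent estimate, and reports
2.5/97.5 percentile CIs plus p_SSD = fraction of bootstrap SSDs ≥ the
observed SSD. B defaults to 10,000 as in the published workflow; tests
and calibration use B = 200 (seeded) to keep runtimes in minutes — the
documented experiment sizes below. τ̂ is weakly biased upward at n = 30
(median ≈ 5.4–5.9 against a generating 5 over 100 replicates) because θ₁
is barely identified when few pairs coalesce in the ancient epoch; the
τ CI coverage stays ≥ 90%. Monomorphic input yields the boundary fit
(τ̂ = 0) flagged as degenerate, not an error.

Unit conversions: with µ_seq = rate·L·generation time per sequence per
generation, t = τ/(2µ_seq) generations, and N_e = θ/(2µ_seq) under the
maternally inherited, effectively haploid convention. Defaults follow the
cetacean mitogenome literature: 5 × 10⁻⁸ substitutions/site/yr and a
10-year generation time.

## The synthetic-data generator

The simulator is standard Kingman: exponential waiting times at rate
C(k,2), rescaled by the population-size trajectory (ancient multiplier
θ₁/θ₀ past the change point, re-drawing across the boundary by
memorylessness), in coalescent units of the recent epoch. Mutations are
infinite-sites: Poisson(θ/2 × total length) or exactly S, placed on
branches proportionally to length, each a new biallelic column. Checked
moments: E[T_MRCA] = 2(1 − 1/n), E[total length] = 2a₁, E[S] = θa₁,
E[π] = θ; genealogy moments are also cross-checked against msprime's
constant-size coalescent in the test suite.

`synth_mitogenome_set` produces a full annotated study: a random ancestral
genome whose thirteen CDSs (the last one minus-strand, overlapping its
neighbour by 17 bp, mirroring ND5/ND6) have stop-free frames under the
mitochondrial code (overlapping frames are resampled jointly, bounded
retries); per-lineage coalescent mutations mapped to distinct genome
positions (infinite sites at mito scale; collisions resample); CDS hits
made synonymous/nonsynonymous with a controllable probability by
rejection-sampling position/base pairs, never creating stops, with a
logged fallback when a context cannot satisfy the requested class; and
optional Poisson "stem" mutations fixed within a lineage, which is what
gives McDonald–Kreitman tables their divergence axis. Output is
FASTA/GFF3/TSV read back by the package's own readers, byte-identical
under a fixed seed.

What the generator does **not** emulate — and what passing tests
therefore cannot certify about real data: recombination (none; correct
for mitochondria), selection within the genealogy (mutations are placed
neutrally; composition is controlled only marginally), rate heterogeneity
along the genome, back-mutation/homoplasy, sequencing error and alignment
ambiguity (no gaps or Ns are generated; the missing-data path is
exercised by constructed fixtures instead), and between-species tree
structure beyond a star of independently coalescing lineages hanging off
one ancestral sequence.

## Calibration experiment sizes

The packaged experiments (also run by `scripts/acceptance.py`) use: 200
random alignments (n ≤ 6, L ≤ 60) for exact oracle equivalence; 2,000
neutral replicates at n = 20, θ = 10 for the D calibration (600 fixed-S
null simulations per distinct S, shared across replicates) and for the
Watterson check; 500 neutral MK replicates at n = 8 over 3,000 codons
with θ = 30 and stem divergence 160 — cell counts of ~25–160 keep the
Jensen bias of the ratio-of-ratios estimator near +0.05, small against
the ±0.15 acceptance band; and 100 mismatch-recovery replicates at
n = 30 under (θ₀, θ₁, τ) = (1, 100, 5) with B = 200 bootstrap replicates
each. These sizes hold the full suite to minutes on one core while
keeping Monte-Carlo error well inside each asserted tolerance.

## Known limitations

* Fu & Li's tests take η from multi-state columns but the simulator only
  produces biallelic sites, so the η > S path is exercised only by
  constructed fixtures.
* The MK outgroup consensus is a plain majority vote (alphabetic
  tie-break); no probabilistic ancestral reconstruction.
* θ₁ in the sudden-expansion fit is effectively unbounded above when the
  observed histogram carries no ancient-coalescence mass; its CI upper
  bound should be read as "unidentified", and inference should focus on
  τ and the θ₁/θ₀ ratio's order of magnitude.
* The permutation group test assumes exchangeability of observations
  under the null; NI values sharing an outgroup are not strictly
  independent, so its p-values are descriptive, as in the workflow it
  mirrors.
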