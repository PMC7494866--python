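# porpopgen

Population-genetic analysis of whole mitochondrial genomes for small
cetacean (or any small-sample vertebrate) datasets: the kind of study where
a handful of mitogenomes per lineage must be squeezed for diversity,
selection and demographic signal. The package reimplements, as a tested
and scriptable library, the desktop-tool workflow usually spread across
DnaSP and Arlequin:

* **Partition-aware diversity** — segregating sites *S* (split into
  singletons and shared polymorphisms), haplotype count *H* and diversity
  *H*<sub>d</sub> = *n*/(*n*−1)(1 − Σ*p*<sub>i</sub>²), nucleotide
  diversity π (mean pairwise differences per usable site) and Watterson's
  θ<sub>W</sub> = *S*/(*a*₁*L*), per lineage and per genome partition
  (whole genome, non-coding, concatenated CDS) with complete deletion of
  gapped/ambiguous columns.
* **Rarefaction** — π rarefied to a common sample size (*k* = 3 by
  default, 2,500 resamples) so unevenly sampled lineages compare fairly.
* **Selection** — Nei–Gojobori synonymous/nonsynonymous site and
  pathway-averaged difference counting under the vertebrate mitochondrial
  code (table 2: ATA=Met, TGA=Trp, AGA/AGG=Stop), π<sub>N</sub>/π<sub>S</sub>,
  and McDonald–Kreitman tests with the neutrality index
  *NI* = (*P*<sub>n</sub>/*P*<sub>s</sub>)/(*D*<sub>n</sub>/*D*<sub>s</sub>)
  (G and Fisher exact tests), plus permutation one-way group comparisons
  with BH-FDR-adjusted pairwise contrasts and Pearson correlations.
* **Demography** — Tajima's *D* and Fu & Li's *D**/*F** with two-tailed
  p-values from constant-size coalescent simulations conditioned on the
  observed *S*; mismatch distributions under the equilibrium model
  *F*(*k*) = θᵏ/(θ+1)ᵏ⁺¹ and the sudden-expansion model (θ₀, θ₁,
  τ = 2µ*t*), fitted by bounded least squares with parametric-bootstrap
  CIs and goodness-of-fit; conversions of τ to years and θ to *N*<sub>e</sub>.
* **Coalescent simulator** — Kingman genealogies under constant-size or
  sudden-expansion demographies with infinite-sites mutations (Poisson-θ
  or fixed-*S*), and a generator of complete annotated synthetic
  mitogenome studies (FASTA + GFF3 + lineage TSV, stop-free reading
  frames, ND5/ND6-style strand overlap, controllable nonsynonymous
  fraction) so every stage is testable without any download.

Inputs are plain files: an aligned FASTA (one record per individual), a
GFF3 or 5-column TSV gene annotation, an optional BED mask (e.g. the
hypervariable control-region repeat), and a TSV assigning samples to
species/lineages.

## Worked example

`examples/` holds one short script per capability. For instance,
`examples/04_neutrality_tests.py` simulates one recently expanded and one
stable lineage (15 mitogenomes each) and runs the SFS neutrality tests:

```
EXPANDED  n=15 S= 14 eta_s=  7  D=-1.334 (p=0.1694)  D*=-0.773 (p=0.5223)  F*=-0.915 (p=0.3470)
STABLE    n=15 S= 41 eta_s= 14  D=-0.536 (p=0.6513)  D*=-0.060 (p=0.9371)  F*=-0.202 (p=0.7789)
```

The expanded lineage's excess of low-frequency variants drives all three
statistics more negative than the stable lineage's; the p-values are
two-tailed coalescent-simulation probabilities at the observed *S*.
`examples/05_mismatch_demography.py` continues to the mismatch fit: for a
lineage generated under (θ₀ = 1, θ₁ = 100, τ = 5) it prints the fitted
parameters with bootstrap CIs — e.g. τ̂ = 8.4 (95% CI 5.3–12.0),
goodness-of-fit p = 0.61 — and dates the expansion via τ = 2µ*t* at the
mitogenome substitution rate 5 × 10⁻⁸ /site/yr and a 10-year generation
time. `examples/06_full_pipeline.py` runs every stage from a YAML config,
the same route as the CLI:

```bash
porpopgen simulate -c sim.yaml -o study/
porpopgen run -c config.yaml        # diversity/rarefaction/mk/neutrality/mismatch tables
porpopgen stats -a alignment.fasta  # single-stage shortcuts: stats | mk | mismatch
```

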