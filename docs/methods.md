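# Methods

`safbreed` simulates a recurrent genomic-selection (GS) breeding program for
two correlated quantitative traits — grain yield (GY) and seed oil content
(OL) — on a diverse crop founder panel, and compares four strategies for
choosing each cycle's crossing parents. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## The breeding scheme

Each replicate proceeds as follows. Fifty initial crossing parents are drawn
uniformly from the founder panel (cycle 1). Thirty biparental crosses are
made among them; 10 F1 are kept per cross; the F1s of each cross are selfed
round-robin into a 200-plant F2 bulk; F2→F4 advancement uses single-seed
descent (SSD): lineage founders are sampled from the bulk without
replacement and each lineage keeps one selfed seed per generation. The
selection candidates are the F4 pool plus the current parents (3000 + 50 at
full scale). Candidates' genomic estimated breeding values (GEBVs) are
`ĝ = X′β`, with `X′` the 0/1/2 dosage matrix and `β` per-marker effects
fitted once per replicate on the founder panel's phenotypes (two-step GS;
no retraining, since no new phenotypes accrue inside the scheme). The chosen
strategy then picks the next 50 parents and the next 30 crosses, and the
scheme repeats. `n_cycles` counts parent sets *including* the initial random
one, so the default 5 performs four selection rounds — which is why gain
tables have transitions c1..c4.

### Selection strategies

* **GY / OL** — truncation (independent culling) on one trait's GEBV; the
  30 crosses among the selected 50 are random distinct pairs.
* **GY+OL** — truncation on an equal-weight index of the two traits'
  GEBVs, each standardized over the current candidate set.
* **GY+OL+Rel** — parents and matings chosen jointly by a genetic
  algorithm (GA) maximizing the summed pair fitness
  `f(i,j) = (index_i + index_j)/2 − λ·G_ij`, with `λ = 0.5` and `G_ij` the
  genomic co-ancestry (the off-diagonal GRM entry, not halved: λ absorbs
  scale). No self-pairs or duplicate pairs; at most 50 distinct parents; a
  per-parent usage cap of 2 crosses (default) keeps the 30 crosses spread
  over ~50 parents rather than concentrating on a few elite individuals.
* **random** — a null strategy for testing: without a selection
  differential, expected gain is zero.

The GA encodes a plan as a fixed-length list of 30 parent pairs, with
tournament selection (k=3), one-point crossover at pair boundaries (rate
0.8), per-gene mutation (rate 0.02), elitism 2, and a repair operator that
enforces feasibility. Half of the initial population is seeded from
candidates with high row-mean fitness, which speeds convergence without
changing the objective; on small instances the GA attains the enumerated
optimum (tested).

## Meiosis

The count-location model without interference: per chromosome, crossover
count ~ Poisson(map length in Morgans), positions uniform, starting phase a
fair coin flip. The default map is 12 chromosomes (the safflower karyotype)
of 1 Morgan each with evenly spaced markers. No mutation, no obligate
chiasma, no sex-specific maps. Expected heterozygosity halves per selfing
generation, so F4s derived from a fully heterozygous F1 retain 1/8 of its
heterozygosity (three selfing meioses: F1→F2→F3→F4); this is tested against
the selfing recursion.

## Kinship and inbreeding

The genomic relationship matrix follows VanRaden's first method,
`G = ZZ′ / (2Σp(1−p))` with `Z` the dosage matrix centered at twice the base
allele frequencies; markers monomorphic under the base frequencies are
excluded from numerator and denominator. The population inbreeding
coefficient is `F = mean(diag G) − 1` and the rate of inbreeding between
consecutive cycles is `ΔF = F_{k+1} − F_k`. **Base frequencies are fixed at
the founder values across cycles** (configurable): F then measures loss of
the initial diversity, which is the quantity of interest for the rising
inbreeding trajectories; re-estimating frequencies each cycle would
re-center F toward zero. Because SSD delivers nearly homozygous F4s, the
first selected parent set already carries most of the attainable
homozygosity, so the first transition dominates ΔF and later increases —
driven by allele-frequency change under selection — are smaller. This also
means the co-ancestry penalty's imprint on *parental* F is modest (it acts
on pair relatedness, only indirectly on individual homozygosity).

## BayesR marker effects

Each trait is fitted separately by Gibbs sampling of the model
`y = Xβ + e`, where each `β_j` comes from a four-component normal mixture
`N(0, γ_k σ²_g)` with `γ = (0, 10⁻⁴, 10⁻³, 10⁻²)` and the component
variances re-scaled by the current `σ²_g` every iteration. Phenotypes are
standardized (effects back-transformed); genotype columns are centered
inside the sampler because the chain carries no explicit intercept.
Updates: class indicators and effects marker-wise with the effect
marginalized out of the class likelihood; mixture proportions from a
Dirichlet; `σ²_g` and `σ²_e` from scaled inverse chi-squares.

Numerical choices that matter:

* **Dirichlet prior (10, 1, 1, 1).** For markers without signal the null
  and the `γ = 10⁻⁴` component are essentially likelihood-equivalent, and
  under a flat prior the proportions can random-walk into states where
  hundreds of spare markers absorb residual noise. Ten pseudo-counts on the
  null break the degeneracy; pure-noise fits then put ≥ 80% of markers'
  modal class in the null component while single-QTL and polygenic recovery
  are unaffected (both tested).
* **σ²_g prior** scaled-inv-χ²(ν=4, S²=0.25 on the standardized scale), so
  the mixture scale stays identified when few markers carry effects; the
  σ²_e prior is weak (ν=4, S²=0.01).
* **Parsimony start**: chains start with all effects null and
  π = (0.95, 0.02, 0.02, 0.01).
* Reported `sigma_g2` is the realized genomic variance `var(Xβ)` averaged
  over kept samples, so `σ²_g + σ²_e ≈ var(y)` holds as an interpretable
  diagnostic.
* Defaults 10 000 iterations / 2 000 burn-in / thin 10; the desk preset
  uses 800/200/5, which the parameter-recovery tests show is sufficient at
  1000 markers. The chain is compiled with numba when available (a
  pure-numpy implementation of the same model is the fallback; the two use
  different random streams).

A GBLUP REML utility (`estimate_h2_gblup`) estimates narrow-sense
heritability under `y = μ + g + e`, `g ~ N(0, G σ²_g)` by profiling the
restricted likelihood over h² after an eigen-rotation of the GRM; used for
validating generator heritabilities, not for selection.

## Synthetic founders

Balding–Nichols structure: ancestral frequencies `p₀ ~ U(0.05, 0.95)`; each
of `n_subpops` subpopulations draws its frequency from
`Beta(p₀(1−d)/d, (1−p₀)(1−d)/d)` so that the expected between-subpopulation
frequency variance is `d·p₀(1−p₀)`; haplotype alleles are independent
Bernoulli draws. Defaults emulate a diverse safflower panel: 349
individuals, MAF ≥ 0.01 after redrawing failing markers, three
subpopulations with mild divergence d = 0.05 (the panel shows "a few
subgroups"; the value is the package's choice since only mild structure is
described). Founder linkage disequilibrium is deliberately absent — the
downstream analyses rest on relationship structure and trait architecture,
not on LD fine-structure — so nothing here speaks to LD-dependent behavior
of real panels (e.g., persistence of marker-QTL phase across cycles is
optimistic).

Trait architecture: `n_qtl` markers (default 200 at desk scale; the real
panel's QTL number is unknown, so this is a free synthetic parameter) get
iid normal effects per trait; the second trait's effect vector is rotated in
breeding-value space so the realized TBV correlation in the founder panel
equals the target rG = 0.19 exactly, and both are rescaled to unit genetic
variance. Phenotypes are TBV plus independent normal noise sized so the
generating h² (0.54 GY, 0.80 OL) is exact in expectation — one value per
individual per trait, emulating a trial-combined BLUE rather than raw plots.

## Problem sizes

The desk preset — used by the long-running tests and by
`scripts/acceptance.py` — runs 349 founders × 1000 markers, 200 QTL, 30
crosses × 20 F4 lineages from a 60-plant F2 bulk (the bulk is 3× the
sampled lineages, preserving the bulk-then-sample structure), 5 parent
sets, 10 replicates, BayesR 800/200/5 and GA 120 × 200. The four strategy
arms run under common random numbers (same initial parents and marker
effects per replicate), so strategy contrasts are paired. A full-scale run
(6911 markers, 200-plant bulks, 100 lineages/cross, 50 replicates) uses the
same code via `ProgramConfig` defaults.

## Known limitations

* No founder LD, no missing genotypes, no genotyping error.
* Additive genetics only: no dominance, epistasis, or genotype-by-
  environment interaction; BLUE-like phenotypes with independent noise.
* Marker effects are never retrained within a replicate (no new phenotypes
  are simulated for progeny), so prediction accuracy decays across cycles
  as recombination erodes marker-QTL associations — a real phenomenon, but
  quantitatively optimistic here because QTL are a subset of the genotyped
  markers.
* The GA is a heuristic; optimality is verified only on enumerable
  instances.
* Inbreeding is genomic (VanRaden diagonal), not pedigree-based; its
  absolute level depends strongly on the fixed founder base frequencies.
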