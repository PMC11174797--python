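# safbreed

Stochastic simulation of a recurrent genomic-selection (GS) breeding program
for two correlated traits — grain yield (GY, t/ha) and seed oil content
(OL, %) — in a diverse safflower-like panel. The package is aimed at
breeders and quantitative geneticists who want to compare parent-selection
strategies *before* committing field seasons to them: how much gain does
each strategy deliver per cycle, and how quickly does it burn through the
panel's genetic diversity?

## What it simulates

A breeding cycle crosses 50 parents in 30 biparental combinations, keeps 10
F1 per cross, bulks 200 F2, advances to F4 by single-seed descent, and
selects the next 50 parents from the 3000 F4 candidates plus the current
parents — using genomic estimated breeding values

    ĝ = X′β

where X′ is the 0/1/2 marker dosage matrix and β are per-marker effects
fitted by **BayesR** (a four-component normal mixture N(0, γ·σ²g),
γ = 0, 10⁻⁴, 10⁻³, 10⁻², Gibbs-sampled) on the founder panel's trait
values. Meiosis draws Poisson crossover counts per chromosome (map length
in Morgans). Four strategies are compared:

| strategy | rule |
|---|---|
| `GY`, `OL` | truncation on one trait's GEBV (independent culling) |
| `GY_plus_OL` | truncation on an equal-weight index of standardized GEBVs |
| `GY_plus_OL_Rel` | genetic-algorithm mate allocation maximizing mid-parent index − λ·co-ancestry (λ = 0.5), spreading 30 crosses over exactly 50 parents |

Outcomes per cycle: genetic gain ΔG = (mean GEBVₖ₊₁ − mean GEBVₖ)/σ_GEBV(cycle 1)
and inbreeding F = mean(diag GRM) − 1, with the VanRaden GRM centered at
*founder* allele frequencies so F tracks loss of initial diversity.

A synthetic-founders module generates panels with the real panel's
statistical shape (349 individuals, MAF-filtered SNPs, mild subpopulation
structure, h² = 0.54/0.80, genetic correlation 0.19), so everything runs
without any data download. See `docs/methods.md` for models, parameters
and limitations.

## Worked example

```python
import safbreed as sb

pop  = sb.simulate_founders(sb.FounderConfig(n_markers=1000, seed=11))
arch = sb.simulate_trait_architecture(pop, n_qtl=200, seed=11)
cfg  = sb.desk_scale(seed=11)                  # reduced-scale preset
res  = sb.compare_strategies(pop, arch, cfg)   # 4 arms, common random numbers

print(sb.gain_table(res).round(3))
```

prints per-cycle gains (cycle-1 GEBV-SD units; c1 is the transition from
the random initial parents into the first selected set):

```
                     GY     OL  GY_plus_OL  GY_plus_OL_Rel
trait transition
GY    c1          1.874  0.265       1.379           1.374
      c2          1.121  0.157       0.845           0.931
      c3          0.916  0.020       0.693           0.791
      c4          0.787  0.066       0.591           0.687
      Sum         4.698  0.508       3.508           3.783
OL    c1          0.240  2.092       1.584           1.542
      ...
```

Read it like a breeder: single-trait truncation wins its own trait (4.70
SD of GY over four rounds) but leaves the other trait nearly flat (0.51 SD
of OL, the small correlated response of rG ≈ 0.19); the equal-weight index
gains strongly on both; and per-cycle gains shrink as selection uses up the
variation — the first cycle is always the biggest. `inbreeding_trajectory`
shows the price: F jumps sharply into the first selected generation and the
co-ancestry-penalized arm stays below the unconstrained index.

The same engine is exposed on the command line:

```bash
safbreed run --strategy GY+OL --seed 11 --out results/gyol
safbreed report results/*/results.csv --out results/report --markdown
```

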