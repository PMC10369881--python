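# igeam

**Indirect genetic effects and heritability under assortative mating.**

Parental alleles shape offspring phenotypes through two routes: transmission
(direct genetic effects, DGEs) and the rearing environment (parental indirect
genetic effects, IGEs, or "genetic nurture"). Assortative mating (AM) —
non-random pairing that correlates spouses' phenotypes and therefore their
genotypes — distorts most of the statistics used to study both routes:
heritability estimates from twins, sib-regression and RDR; polygenic-index
(PGI) R²; and the "non-transmitted coefficient" (NTC) from regressions of
offspring phenotype on proband and parental PGIs, which is routinely read as
evidence for IGEs but also absorbs purely AM-induced correlation.

`igeam` is for quantitative and statistical geneticists who work with
family-based PGI analyses. It provides:

- **Equilibrium theory.** For the phenotype model
  `Y_ij = Δ_ij + η_p(i) + η_m(i) + ε_ij`, with random-mating variance
  components `vg, ve~g, cge, σ²ε`, the equilibrium decomposition

  ```
  vg_eq  = vg / (1 − rδ)
  ve~g_eq = ve~g (1 + rη)/(1 − rη)
  cge_eq = (rδη_c + rδη_τ) · sqrt( 2 vg ve~g / ((1 − rδ)(1 − rη)) )
  vy_eq  = vg_eq + ve~g_eq + cge_eq + σ²ε
  ```

  in terms of the correlations between parents' DGE and IGE components,
  plus sib-regression expectations and closed-form PGI regression
  coefficients (`δ_PGI`, `α_PGI`, `β_PGI`, `ρ_k = 1 − (1 − k) rδ`, ...).

- **Two-generation inference.** The estimating-equation pipeline mapping
  `(δ̂_k or δ̂/β̂, α̂_k, r̂_k, ĥ²_f)` to `(k, rδ, h²_eq, ρ_k, α_δ, v_η:δ)` with
  delta-method standard errors: `k = (1 − r_k) δ_k² / h²_f`,
  `rδ = r_k / (k + (1 − k) r_k)`, `h²_eq = h²_f / (1 − rδ)`, and two
  estimators of the IGE coefficient `α_δ` of the true-DGE PGI.

- **A forward simulator.** Diploid, bi-allelic, unlinked loci; rank-matching
  on a noisy phenotype to a target spousal correlation; frozen effect sizes
  with emergent variance growth; per-generation truth tracking — used to
  validate the pipeline by parameter recovery.

## Worked example

Reproduce the height-PGI analysis (RDR heritability input) from published
summary statistics — the within-family shrinkage ratio δ/β = 0.910, parental
PGI correlation r_k = 0.106, h²_f = 0.554, and k = 0.452:

```bash
igeam infer-summary --ratio 0.910 --ratio-se 0.009 --rk 0.106 --rk-se 0.020 \
    --h2f 0.554 --h2f-se 0.044 --k 0.452 --k-se 0.038
```

prints (abridged):

```json
{
  "r_delta": 0.2078, "r_delta_se": 0.0374,
  "h2_eq": 0.6993,   "h2_eq_se": 0.0646,
  "rho_k": 0.8861,   "rho_k_se": 0.0245,
  "alpha_delta": -0.0217, "alpha_delta_se": 0.0231,
  "v_eta_delta": -0.0359, "v_eta_delta_se": 0.0400
}
```

Read: parents' height DGE components correlate at rδ ≈ 0.21, so the
family-based heritability 0.554 corresponds to an equilibrium heritability of
0.70. The observed shrinkage 0.910 is statistically indistinguishable from
the AM-only expectation ρ_k = 0.886, so there is no evidence for IGEs on
height (α_δ and v_η:δ within one SE of zero).

The same pipeline runs on individual-level data (`igeam infer --data
families.tsv --h2f 0.554`) or end-to-end against the simulator:

```bash
igeam simulate --profile reduced --seed 1 --out run/
igeam infer --data run/dataset.tsv --h2f 0.29
```

The library API mirrors the CLI (`igeam.run_two_generation_inference`,
`igeam.run_simulation`, `igeam.equilibrium_decomposition`, ...); see
`docs/methods.md` for the model, assumptions and numerical choices.

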