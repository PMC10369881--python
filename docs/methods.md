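# Methods

## Model

The phenotype of sibling *j* in family *i* is

    Y_ij = Δ_ij + η_p(i) + η_m(i) + ε_ij

where Δ_ij = Σ_l δ_l (g_ijl − 2 f_l) is the direct-genetic-effect (DGE)
component, η_p and η_m are the paternal and maternal indirect-genetic-effect
(IGE) components built from the parents' genotypes with average parental
effects η_l, and ε is residual noise. Variants are bi-allelic with frequency
f_l, assumed constant across generations, and segregate independently (no
linkage disequilibrium). Maternal–paternal IGE asymmetry is not modelled:
only the average parental effect enters, and the asymmetric part behaves as
extra residual that assortative mating (AM) does not reshape. Sibling IGEs,
population stratification and dominance/epistasis are out of scope.

Under random mating,

    Var(Y) = vg + ve~g + cge + σ²ε,
    vg  = 2 Σ δ² f(1−f)       (DGE variance)
    ve~g = 4 Σ η² f(1−f)       (variance of η_p + η_m)
    cge = 4 Σ δη f(1−f)       (twice Cov(Δ, η_p + η_m))

and rδη0 = cge / √(2 vg ve~g) is the genome-wide correlation between
standardized DGEs and IGEs.

## Equilibrium decomposition

AM at equilibrium is summarized by four correlations among parents'
components: rδ (fathers' vs mothers' Δ), rη (their η), and the within- and
cross-parent DGE–IGE correlations rδη_c and rδη_τ. No particular mating model
is assumed; the decomposition is

    vg_eq  = vg / (1 − rδ)
    ve~g_eq = ve~g (1 + rη) / (1 − rη)
    cge_eq = (rδη_c + rδη_τ) √( 2 vg ve~g / ((1 − rδ)(1 − rη)) )
    vy_eq  = vg_eq + ve~g_eq + cge_eq + σ²ε

with equilibrium heritability h²_eq = vg_eq / vy_eq and the family-based
estimand h²_f = vg / vy_eq = (1 − rδ) h²_eq.

Two groupings in this algebra are genuinely ambiguous in print and were
resolved by derivation and pinned by simulation:

- **cge_eq.** The (1−rδ)(1−rη) factor sits *inside* the square root. This
  follows from the per-parent equilibrium standard deviations
  √(vg/(1−rδ)) and √(ve~g/(2(1−rη))) together with the per-generation
  recursion Cov_cis − Cov_trans = cge/2, which also yields the identity
  rδη_c − rδη_τ = rδη0 √((1−rδ)(1−rη)) and the equivalent form
  cge_eq = cge (1 + 2 rδη_τ / (rδη0 √((1−rδ)(1−rη)))) for rδη0 ≠ 0.
  Note the random-mating limit is (rδ, rη, rδη_c, rδη_τ) = (0, 0, rδη0, 0):
  the within-parent correlation does not vanish without AM.
- **rδ under primary phenotypic assortment.** With matching on the observed
  phenotype, rδ = rY · Corr(Δ, Y)² and Cov(Δ, Y) = vg_eq + cge_eq/2, giving
  rδ = h²_eq rY (1 + cge_eq/(2 vg_eq))², which reduces to the classic
  rδ = h²_eq rY without DGE–IGE covariance.

Both resolutions are tested against the forward simulator; at long-run
equilibrium (60 generations, strongest AM scenario) predicted and empirical
phenotypic variance agree within Monte-Carlo noise (<1%).

Sib-regression expectations follow the same bookkeeping: regressing the
scaled phenotype cross-product of a sibling pair on realized relatedness has
slope h²_f (realized-relatedness variation is a within-family quantity, blind
to AM) and intercept rδ h²_eq + (ve~g_eq + cge_eq + E[ε_ij ε_ik]) / vy_eq, so
AM masquerades as shared environment unless rδ/(1−rδ) · h²_f is subtracted.

## PGI theory and the estimating equations

PGIs are standardized weighted allele-count sums. For ideal weight vectors
(w = δ, η, or δ+η) the random-mating regression coefficients are exact
ratio-of-sums expressions (e.g. the DGE-weight PGI has direct effect √vg and
expected NTC rδη0 √(ve~g/2)). The incomplete-PGI theory is parameterized by
(k, rδ) only, where k is the fraction of heritability the PGI would explain
under random mating; its validity for realistic noisy-weight PGIs is
established by simulation rather than algebra, mirroring how the equal-effect
equal-frequency derivation model is meant to be used.

Key equilibrium identities (standardized phenotype and PGIs):

    β_k = δ_k + (1 + r_k) α_k                      (OLS identity)
    r_k = k rδ / (1 − (1−k) rδ)  ⇔  rδ = r_k / (k + (1−k) r_k)
    ρ_k = δ_k/β_k (no IGEs) = 1 − (1−k) rδ
    δ_k/β_k = ρ_k / (1 + (1+rδ) α_δ)
    α_k/δ_k = [(1+rδ) α_δ + (1−ρ_k)] / (ρ_k (1 + r_k))

where α_δ = cge_eq / (2 (1+rδ) vg_eq) is the NTC of the *true* DGE PGI and
v_η:δ = 2 (1+rδ) α_δ (1+α_δ) h²_eq is the phenotypic variance contributed by
the IGE component correlated with the DGE component. The α_k/δ_k expression
carries a ρ_k factor in its denominator that is required for exact mutual
consistency of the identities above (the two α_δ estimators below are then
exact algebraic inverses of one another's forward maps, which the test suite
asserts to machine precision, and the published EA chain reproduces to three
decimals through either route).

The inference pipeline composes:

1. k̂ = (1 − r̂_k)(1 − ẑ_f⁻²)(δ̂_k² − Var(δ̂_k)) / ĥ²_f, the bias-corrected
   estimator (ẑ_f = ĥ²_f / SE(ĥ²_f)); clipped to [0,1] with a warning.
2. r̂δ = r̂_k / (k̂ + (1−k̂) r̂_k); ĥ²_eq = ĥ²_f / (1 − r̂δ); ρ̂_k = 1 − (1−k̂) r̂δ.
3. α̂_δ, either from the δ/β ratio (estimator 1) or from α̂_k/δ̂_k
   (estimator 2, the default when both coefficients come from the same
   regression so their sampling covariance is known); then v̂_η:δ.

Standard errors come from the delta method with a numeric Jacobian (central
differences, step max(1e−6, 1e−4·|x|)). The regression-coefficient block,
r̂_k, and ĥ²_f are treated as mutually independent — h²_f originates from an
external study and r_k from the parents alone. The pipeline warns when
k̂ < 0.05 (or the rδ denominator is below 0.05): the equations are ratios of
near-zero quantities there and are documented to become unstable around
k ≈ 0.01. The warning threshold is this package's choice.

## Individual-level estimation

`FamilyPGIDataset` holds one row per phenotyped sibling with proband,
paternal and maternal PGIs. Standardization scales the phenotype to unit
variance and divides all three PGIs by the proband-PGI standard deviation —
one common scale, so the β = δ + (1+r_k) α identity is preserved
(per-column standardization would break it); the parental sum is not
re-standardized (its variance is 2(1+r_k) at equilibrium). OLS fits use
family-clustered covariance by default because simulator datasets carry two
siblings per family; a one-sib-per-family mode reproduces independent-trio
analysis. r̂_k is the Pearson correlation over deduplicated families with
SE (1−r²)/√(n−1). Missing rows are dropped listwise with counts logged.

## Simulator

Defaults mirror the validation study design: 30,000 families, 1,000 unlinked
causal SNPs with MAFs from a density ∝ 1/f on [0.05, 0.5] (inverse-CDF
sampling f = lo·(hi/lo)^u), per-variant (δ, η) bivariate standard normal with
correlation rδη0 ∈ {0, 0.5, 1}, DGE variance 0.5 and summed-IGE variance
0.125 (or 0) in the first generation, spousal correlation targets
r_y ∈ {0, 0.25, 0.5, 0.75}, and 20 generations of mating after the
random-mating founder generation. σ²ε = 1 − (vg0 + ve~g0 + rδη0√(2 vg0 ve~g0))
makes the first-generation phenotypic variance 1 (h² = 0.5 in every design).

Choices worth stating:

- **Frozen scaling.** Effect-size scaling constants are computed once in the
  founder-derived generation and never revisited, so variance growth under AM
  is emergent; this is the only reading consistent with constant per-variant
  effects.
- **Mate matching.** Males and females are rank-matched on Z = Y + u,
  u ~ N(0, (1/r_y − 1)·vy) with vy the *current parental generation's*
  empirical phenotypic variance; realized spousal correlations are logged.
  Continuous Z makes ties measure-zero; sorting is stable.
- **Meiosis.** Each offspring draws one allele per locus uniformly from each
  parent, independently across loci and siblings (no recombination map).
  One male and one female offspring per family keep the mating pools
  balanced.
- **Truth tracking.** Per generation: empirical vg, ve~g, cge, Var(Y), the
  four couple correlations, and the realized spousal correlation. "True"
  equilibrium correlations are sample correlations among the final
  generation's parents; no analytic recurrence is used. PGI centring uses
  founder frequencies (drift is negligible at these sizes and the model
  treats frequencies as constant).
- **PGIs.** DGE-weight PGIs add noise of variance ν·Var(δ) to the true
  effects (population-effect PGIs use δ+η and ν·Var(δ+η)), giving
  k ≈ 1/(1+ν); realized k is measured from the weight vector as the squared
  heterozygosity-weighted correlation with the true DGEs.

What the simulator does *not* emulate: linkage and LD, drift and selection,
population structure and stratification confounding, sibling IGEs,
parent-of-origin IGE asymmetry, and GWAS-estimation noise structure beyond
i.i.d. weight error. Passing recovery tests therefore show the estimating
equations are correct under the model's own assumptions — not that real-data
PGIs are free of the confounds (notably stratification correlated between
parents) that the empirical analyses themselves flag as caveats.

## Problem sizes and tolerances in the test suite

Simulation studies run at a reduced scale chosen for routine execution:
3,000 families (1,000 SNPs, 20 generations) for the 16-scenario grid, and
150 replicates of one scenario at 12 generations for standard-error
calibration. Monte-Carlo comparisons use 3× a combined SE: the
family-clustered SE of the empirical moment plus the prediction SE from
propagating correlation-measurement noise ((1−r²)/√n) through the theory.
Convergence caveat: under the strongest design (rδη0 = 1, r_y = 0.75) the
equilibrium phenotypic variance is ≈5× the initial variance and the approach
to equilibrium is geometric with rate ≈(1+rδ)/2 ≈ 0.86 per generation, so
even at generation 20 a few-percent shortfall of the empirical variance
against the equilibrium prediction remains; the long-run check (60
generations) closes it. Algebraic identities (round-trips between the
estimators and forward maps) are asserted to machine precision; the published
inference chains to the three printed decimals.

## Known limitations

- h²_f is an input, never estimated from data here (no RDR/twin/sib-regression
  estimation machinery).
- No estimation of rη, rδη_c, rδη_τ from real data — they are measured in
  simulation or supplied.
- Delta-method SEs assume precise inputs; with noisy h²_f or small k the
  point estimates themselves are biased (ratios of noisy quantities) and the
  SEs optimistic — the pipeline's instability warning marks the regime, it
  does not fix it.
- The finite-locus corrections to sib-regression and imputation of parental
  genotypes from relatives are out of scope.
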