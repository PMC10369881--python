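"""Forward-in-time simulation of phenotypes with direct and parental indirect
genetic effects under assortative mating.

Design
------
A founder cohort of ``2 * n_families`` diploid individuals is drawn at
``n_variants`` unlinked bi-allelic SNPs with minor-allele frequencies from a
density proportional to 1/f on ``maf_range`` (the expectation for a
random-mating population of constant effective size). Founders are randomly
paired and produce the first offspring generation (one male, one female per
family) through meiosis with independent segregation. Per-variant direct and
indirect effects are drawn bivariate standard normal with correlation
``r_dg_ig_0`` and rescaled ONCE in this first generation so that the DGE
component has variance ``vg0`` and the summed parental IGE component has
variance ``ve_g0``; the scaled effects are then frozen, so later variance
growth under assortative mating is emergent rather than imposed. The residual
variance is fixed at sigma_eps2 = 1 - (vg0 + ve_g0 + r_dg_ig_0 *
sqrt(2 vg0 ve_g0)), making the first-generation phenotypic variance 1.

Each subsequent generation, males and females are rank-matched on a noisy
phenotype Z = Y + u, u ~ N(0, (1/r_y - 1) * vy), with vy the empirical
phenotypic variance of the current (parental) generation — which yields a
realized spousal phenotypic correlation close to the target r_y — and produce
two full-sibling offspring. Per-generation summaries record the empirical
variance components and the correlations between parents' DGE and IGE
components; the genotypes of the final two generations are retained for PGI
analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .components import EquilibriumCorrelations, RandomMatingComponents
from .regression import FamilyPGIDataset

__all__ = [
    "SimConfig",
    "SimResult",
    "SimPGI",
    "REDUCED_PROFILE",
    "PROFILES",
    "draw_mafs",
    "draw_effects",
    "mate_assortative",
    "meiosis",
    "run_simulation",
    "build_pgi",
]

SUMMARY_COLUMNS = [
    "generation",
    "vg",
    "ve_g",
    "cge",
    "vy",
    "r_delta",
    "r_eta",
    "r_de_cis",
    "r_de_trans",
    "r_y_realized",
]


@dataclass
class SimConfig:
    """Simulation parameters.

    ``n_generations`` counts the generations of (possibly assortative) mating
    performed after the random-mating founder-derived generation; with the
    default 20 an approximate equilibrium is comfortably reached.
    """

    n_families: int = 30000
    n_variants: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    vg0: float = 0.5
    ve_g0: float = 0.125
    r_dg_ig_0: float = 0.5
    r_y: float = 0.5
    n_generations: int = 20
    seed: int | None = None

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not 0.0 < lo < hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if self.n_families < 2 or self.n_variants < 1 or self.n_generations < 0:
            raise ValueError("invalid sizes")
        if not 0.0 <= self.r_y < 1.0:
            raise ValueError("r_y must lie in [0, 1)")
        if not -1.0 <= self.r_dg_ig_0 <= 1.0:
            raise ValueError("r_dg_ig_0 must lie in [-1, 1]")
        cge0 = self.r_dg_ig_0 * math.sqrt(2.0 * self.vg0 * self.ve_g0)
        if self.vg0 + self.ve_g0 + cge0 >= 1.0:
            raise ValueError("vg0 + ve_g0 + cge0 must be < 1 (sigma_eps2 > 0)")

    def to_dict(self) -> dict:
        return asdict(self)


#: scaled-down profile for routine test runs; the full-scale profile is the default
REDUCED_PROFILE = {"n_families": 3000, "n_generations": 12}
PROFILES = {"full": {}, "reduced": REDUCED_PROFILE}


@dataclass
class SimPGI:
    """A simulated PGI weight vector and its realized properties.

    ``k`` is the fraction of heritability the PGI would explain in a
    random-mating population, measured from the weights as the squared
    heterozygosity-weighted correlation with the true direct effects;
    k ~= 1 / (1 + noise_multiple) for DGE-weight PGIs.
    """

    weight_kind: str
    noise_multiple: float
    k: float
    weights: np.ndarray


@dataclass
class SimResult:
    """State retained from a simulation run."""

    config: SimConfig
    freqs: np.ndarray
    delta: np.ndarray  # scaled per-variant direct effects (frozen)
    eta: np.ndarray  # scaled per-variant average parental indirect effects
    sigma_eps2: float
    summary: pd.DataFrame
    # final generation offspring
    offspring_genotypes: np.ndarray  # (n_families, 2, L) dosages
    offspring_dge: np.ndarray  # (n_families, 2)
    offspring_parental_ige: np.ndarray  # (n_families,)
    offspring_y: np.ndarray  # (n_families, 2)
    # their parents (couples)
    father_genotypes: np.ndarray  # (n_families, L)
    mother_genotypes: np.ndarray
    father_dge: np.ndarray
    mother_dge: np.ndarray
    father_ige: np.ndarray
    mother_ige: np.ndarray
    father_y: np.ndarray
    mother_y: np.ndarray

    def random_mating_components(self) -> RandomMatingComponents:
        """Model-true random-mating components implied by the frozen scaled
        effects and founder allele frequencies."""
        het = self.freqs * (1.0 - self.freqs)
        return RandomMatingComponents(
            vg=float(2.0 * np.sum(self.delta**2 * het)),
            ve_g=float(4.0 * np.sum(self.eta**2 * het)),
            cge=float(4.0 * np.sum(self.delta * self.eta * het)),
            sigma_eps2=self.sigma_eps2,
        )

    def equilibrium_correlations(self) -> EquilibriumCorrelations:
        """Sample correlations among the final generation's parents."""
        row = self.summary.iloc[-1]
        return EquilibriumCorrelations(
            r_delta=float(row["r_delta"]),
            r_eta=float(row["r_eta"]),
            r_de_cis=float(row["r_de_cis"]),
            r_de_trans=float(row["r_de_trans"]),
        )


def draw_mafs(n_variants: int, maf_range: tuple[float, float], rng) -> np.ndarray:
    """I.i.d. draws with density proportional to 1/f on [lo, hi], via the
    inverse CDF f = lo * (hi/lo)^u with u ~ Uniform(0, 1)."""
    lo, hi = maf_range
    if not 0.0 < lo < hi <= 0.5:
        raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
    u = rng.random(n_variants)
    return lo * (hi / lo) ** u


def draw_effects(n_variants: int, r_dg_ig_0: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate standard-normal per-variant (direct, indirect) effect pairs
    with correlation r_dg_ig_0 (at +-1 the pair is exactly proportional)."""
    if not -1.0 <= r_dg_ig_0 <= 1.0:
        raise ValueError("r_dg_ig_0 must lie in [-1, 1]")
    z1 = rng.standard_normal(n_variants)
    z2 = rng.standard_normal(n_variants)
    eta = r_dg_ig_0 * z1 + math.sqrt(max(0.0, 1.0 - r_dg_ig_0**2)) * z2
    return z1, eta


def mate_assortative(
    y_males: np.ndarray, y_females: np.ndarray, r_y: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-match males and females on a noisy phenotype.

    Z = Y + u with u ~ N(0, (1/r_y - 1) * vy); sorting each sex by Z and
    pairing by rank yields Corr(Y_father, Y_mother) ~= r_y. With r_y = 0 the
    pairing is uniformly random. Returns index arrays (males, females) such
    that couple i is (y_males[im[i]], y_females[if_[i]]).
    """
    n = y_males.size
    if y_females.size != n:
        raise ValueError("need equal numbers of males and females")
    if not 0.0 <= r_y < 1.0:
        raise ValueError("r_y must lie in [0, 1)")
    if r_y == 0.0:
        return rng.permutation(n), rng.permutation(n)
    vy = float(np.var(np.concatenate([y_males, y_females])))
    sd = math.sqrt((1.0 / r_y - 1.0) * vy)
    zm = y_males + rng.normal(0.0, sd, n)
    zf = y_females + rng.normal(0.0, sd, n)
    return np.argsort(zm, kind="stable"), np.argsort(zf, kind="stable")


def _transmit(g: np.ndarray, rng) -> np.ndarray:
    """One gamete per individual: per variant, a uniformly chosen parental
    allele (heterozygotes transmit Bernoulli(1/2))."""
    het_draw = rng.random(g.shape, dtype=np.float32) < 0.5
    return ((g == 2) | ((g == 1) & het_draw)).astype(np.int8)


def meiosis(
    father_genotypes: np.ndarray, mother_genotypes: np.ndarray, rng, n_offspring: int = 2
) -> np.ndarray:
    """Produce full-sibling offspring dosages, independent segregation across
    variants and offspring. Returns shape (n_families, n_offspring, L)."""
    off = [
        _transmit(father_genotypes, rng) + _transmit(mother_genotypes, rng)
        for _ in range(n_offspring)
    ]
    return np.stack(off, axis=1)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def run_simulation(cfg: SimConfig) -> SimResult:
    """Run the forward simulation; fully reproducible given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n_families, cfg.n_variants

    freqs = draw_mafs(L, cfg.maf_range, rng)
    r0 = cfg.r_dg_ig_0 if cfg.ve_g0 > 0.0 else 0.0
    d_raw, e_raw = draw_effects(L, r0, rng)
    c2 = 2.0 * freqs

    # founders: random pairing
    g0 = rng.binomial(2, freqs, size=(2 * n, L)).astype(np.int8)
    perm = rng.permutation(2 * n)
    gf, gm = g0[perm[:n]], g0[perm[n:]]
    g_off = meiosis(gf, gm, rng)

    # scaling constants from the first offspring generation, then frozen
    d_off_raw = (g_off.reshape(2 * n, L) - c2) @ d_raw
    s_d = math.sqrt(cfg.vg0 / float(np.var(d_off_raw)))
    if cfg.ve_g0 > 0.0:
        epar_raw = (gf - c2) @ e_raw + (gm - c2) @ e_raw
        s_e = math.sqrt(cfg.ve_g0 / float(np.var(epar_raw)))
    else:
        s_e = 0.0
    delta = s_d * d_raw
    eta = s_e * e_raw
    cge0 = r0 * math.sqrt(2.0 * cfg.vg0 * cfg.ve_g0)
    sigma_eps2 = 1.0 - (cfg.vg0 + cfg.ve_g0 + cge0)

    def indiv_components(g2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centred = g2d - c2
        return centred @ delta, centred @ eta

    parents = {
        "gf": gf,
        "gm": gm,
        "y_f": None,  # founders carry no phenotype
        "y_m": None,
    }
    parents["d_f"], parents["e_f"] = indiv_components(gf)
    parents["d_m"], parents["e_m"] = indiv_components(gm)

    rows = []
    for gen in range(1, cfg.n_generations + 2):
        if gen > 1:
            # current generation becomes parents: sib 0 male, sib 1 female
            im, if_ = mate_assortative(y[:, 0], y[:, 1], cfg.r_y, rng)
            gf = g_off[im, 0]
            gm = g_off[if_, 1]
            parents = {"gf": gf, "gm": gm, "y_f": y[im, 0], "y_m": y[if_, 1]}
            parents["d_f"], parents["e_f"] = indiv_components(gf)
            parents["d_m"], parents["e_m"] = indiv_components(gm)
            g_off = meiosis(gf, gm, rng)

        d_off = ((g_off.reshape(2 * n, L) - c2) @ delta).reshape(n, 2)
        par_ige = parents["e_f"] + parents["e_m"]
        eps = rng.normal(0.0, math.sqrt(sigma_eps2), size=(n, 2))
        y = d_off + par_ige[:, None] + eps

        has_ige = cfg.ve_g0 > 0.0
        rows.append(
            {
                "generation": gen,
                "vg": float(np.var(d_off)),
                "ve_g": float(np.var(par_ige)),
                "cge": 2.0
                * float(np.mean((d_off - d_off.mean()) * (par_ige - par_ige.mean())[:, None])),
                "vy": float(np.var(y)),
                "r_delta": _corr(parents["d_f"], parents["d_m"]),
                "r_eta": _corr(parents["e_f"], parents["e_m"]) if has_ige else 0.0,
                "r_de_cis": 0.5
                * (_corr(parents["d_f"], parents["e_f"]) + _corr(parents["d_m"], parents["e_m"]))
                if has_ige
                else 0.0,
                "r_de_trans": 0.5
                * (_corr(parents["d_f"], parents["e_m"]) + _corr(parents["d_m"], parents["e_f"]))
                if has_ige
                else 0.0,
                "r_y_realized": _corr(parents["y_f"], parents["y_m"])
                if parents["y_f"] is not None
                else float("nan"),
            }
        )

    return SimResult(
        config=cfg,
        freqs=freqs,
        delta=delta,
        eta=eta,
        sigma_eps2=sigma_eps2,
        summary=pd.DataFrame(rows, columns=SUMMARY_COLUMNS),
        offspring_genotypes=g_off,
        offspring_dge=d_off,
        offspring_parental_ige=par_ige,
        offspring_y=y,
        father_genotypes=parents["gf"],
        mother_genotypes=parents["gm"],
        father_dge=parents["d_f"],
        mother_dge=parents["d_m"],
        father_ige=parents["e_f"],
        mother_ige=parents["e_m"],
        father_y=parents["y_f"] if parents["y_f"] is not None else np.full(n, np.nan),
        mother_y=parents["y_m"] if parents["y_m"] is not None else np.full(n, np.nan),
    )


def build_pgi(
    result: SimResult,
    kind: str = "dge",
    noise_multiple: float = 0.0,
    rng=None,
    seed: int | None = None,
) -> tuple[SimPGI, FamilyPGIDataset]:
    """Construct a noisy PGI from the simulated truth and emit the family
    dataset for the final two generations.

    kind='dge': weights = scaled direct effects + noise with variance
    noise_multiple * Var(delta_l); kind='population': weights are the summed
    direct and indirect effects plus noise scaled to Var(delta_l + eta_l).
    PGIs (proband, paternal, maternal) are centred with founder frequencies
    and divided by the proband-PGI standard deviation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if kind == "dge":
        base = result.delta
    elif kind == "population":
        base = result.delta + result.eta
    else:
        raise ValueError(f"unknown PGI kind {kind!r}; expected 'dge' or 'population'")
    noise_sd = math.sqrt(noise_multiple * float(np.var(base)))
    w = base + rng.normal(0.0, noise_sd, base.size)

    c2 = 2.0 * result.freqs
    n, L = result.offspring_genotypes.shape[0], result.freqs.size
    p_off = ((result.offspring_genotypes.reshape(2 * n, L) - c2) @ w).reshape(n, 2)
    p_f = (result.father_genotypes - c2) @ w
    p_m = (result.mother_genotypes - c2) @ w
    norm = float(np.std(p_off))
    p_off, p_f, p_m = p_off / norm, p_f / norm, p_m / norm

    het = result.freqs * (1.0 - result.freqs)
    num = float(2.0 * np.sum(w * result.delta * het))
    vw = float(2.0 * np.sum(w**2 * het))
    vg = float(2.0 * np.sum(result.delta**2 * het))
    k = num**2 / (vw * vg) if vw > 0.0 and vg > 0.0 else 0.0

    df = pd.DataFrame(
        {
            "family_id": np.repeat(np.arange(n), 2),
            "sib_index": np.tile([0, 1], n),
            "phenotype": result.offspring_y.ravel(),
            "proband_pgi": p_off.ravel(),
            "paternal_pgi": np.repeat(p_f, 2),
            "maternal_pgi": np.repeat(p_m, 2),
            "sex": np.tile(["M", "F"], n),
        }
    )
    return (
        SimPGI(weight_kind=kind, noise_multiple=noise_multiple, k=k, weights=w),
        FamilyPGIDataset(df),
    )
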