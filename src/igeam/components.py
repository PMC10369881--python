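"""Phenotypic variance decompositions with direct and parental indirect
genetic effects (DGEs and IGEs), under random mating and under assortative
mating (AM) at equilibrium.

The phenotype of offspring j in family i is modelled as

    Y_ij = Delta_ij + eta_p(i) + eta_m(i) + eps_ij,

where ``Delta_ij = sum_l delta_l (g_ijl - 2 f_l)`` is the DGE component and
``eta_p, eta_m`` are the paternal and maternal IGE components built from the
same genotypes with (average parental) indirect effects ``eta_l``. Causal
variants are bi-allelic with frequency ``f_l`` and segregate independently.

Under random mating the phenotypic variance decomposes as

    Var(Y) = vg + ve_g + cge + sigma_eps2,

with ``vg = 2 sum delta^2 f(1-f)``, ``ve_g = 4 sum eta^2 f(1-f)`` the variance
of the summed parental IGE component, and ``cge = 4 sum delta eta f(1-f)``
twice the covariance of the DGE component with the summed parental IGE
component. AM at equilibrium inflates these components as a function of the
correlations between parents' DGE and IGE components (``EquilibriumCorrelations``).

Components are stored unstandardized; heritabilities are ratios computed on
demand (the equilibrium phenotypic variance drifts above 1 under AM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "RandomMatingComponents",
    "EquilibriumCorrelations",
    "EquilibriumComponents",
    "SibRegressionExpectation",
    "random_mating_components",
    "components_from_variances",
    "equilibrium_decomposition",
    "equilibrium_cge_via_cge0",
    "rdelta_under_phenotypic_assortment",
    "sib_regression_expectation",
    "h2eq_from_h2f",
]

_TOL = 1e-9


@dataclass(frozen=True)
class RandomMatingComponents:
    """Variance decomposition holding in a random-mating population.

    Attributes
    ----------
    vg : variance of the DGE component.
    ve_g : variance of the summed parental IGE component (eta_p + eta_m).
    cge : twice the covariance between the DGE component and the summed
        parental IGE component.
    sigma_eps2 : residual variance.
    """

    vg: float
    ve_g: float
    cge: float
    sigma_eps2: float

    def __post_init__(self) -> None:
        if self.vg < -_TOL or self.ve_g < -_TOL or self.sigma_eps2 < -_TOL:
            raise ValueError("variance components must be non-negative")
        # Cauchy-Schwarz on cge = r_dg_ig_0 * sqrt(2 vg ve_g)
        if self.cge**2 > 2.0 * self.vg * self.ve_g * (1.0 + 1e-6) + _TOL:
            raise ValueError("cge^2 exceeds the bound 2*vg*ve_g")

    @property
    def r_dg_ig_0(self) -> float:
        """Genome-wide correlation between standardized DGEs and IGEs."""
        denom2 = 2.0 * self.vg * self.ve_g
        if denom2 <= 0.0:
            return 0.0
        return float(np.clip(self.cge / math.sqrt(denom2), -1.0, 1.0))

    @property
    def vy(self) -> float:
        """Total phenotypic variance under random mating."""
        return self.vg + self.ve_g + self.cge + self.sigma_eps2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["r_dg_ig_0"] = self.r_dg_ig_0
        d["vy"] = self.vy
        return d


@dataclass(frozen=True)
class EquilibriumCorrelations:
    """Equilibrium correlations among parents' DGE and IGE components.

    ``r_delta`` couples fathers' and mothers' DGE components; ``r_eta`` their
    IGE components; ``r_de_cis`` is the within-parent DGE-IGE correlation and
    ``r_de_trans`` the cross-parent one. The implied 4x4 correlation matrix of
    (Delta_p, Delta_m, eta_p, eta_m) must be positive semi-definite.
    """

    r_delta: float
    r_eta: float
    r_de_cis: float = 0.0
    r_de_trans: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_delta", "r_eta", "r_de_cis", "r_de_trans"):
            v = getattr(self, name)
            if not -1.0 - _TOL <= v <= 1.0 + _TOL:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        if np.linalg.eigvalsh(self.matrix()).min() < -1e-6:
            raise ValueError(
                "implied correlation matrix of (Delta_p, Delta_m, eta_p, eta_m)"
                " is not positive semi-definite"
            )

    def matrix(self) -> np.ndarray:
        """4x4 correlation matrix of (Delta_p, Delta_m, eta_p, eta_m)."""
        rd, re = self.r_delta, self.r_eta
        c, t = self.r_de_cis, self.r_de_trans
        return np.array(
            [
                [1.0, rd, c, t],
                [rd, 1.0, t, c],
                [c, t, 1.0, re],
                [t, c, re, 1.0],
            ]
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EquilibriumComponents:
    """Equilibrium analogues of the random-mating components.

    ``h2_eq = vg_eq / vy_eq`` is the equilibrium heritability and
    ``h2_f = vg / vy_eq`` the family-based heritability estimand (what twin
    ACE, sib-regression and RDR estimate); ``h2_f = (1 - r_delta) * h2_eq``.
    """

    vg_eq: float
    ve_g_eq: float
    cge_eq: float
    sigma_eps2: float

    @property
    def vy_eq(self) -> float:
        return self.vg_eq + self.ve_g_eq + self.cge_eq + self.sigma_eps2

    @property
    def h2_eq(self) -> float:
        return self.vg_eq / self.vy_eq

    def h2_f(self, rm: RandomMatingComponents) -> float:
        return rm.vg / self.vy_eq

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vy_eq"] = self.vy_eq
        d["h2_eq"] = self.h2_eq
        return d


@dataclass(frozen=True)
class SibRegressionExpectation:
    """Expected slope/intercept of the sib-regression of the scaled phenotype
    cross-product on realized relatedness, under AM at equilibrium."""

    slope: float
    intercept: float
    resid_cov: float

    def to_dict(self) -> dict:
        return asdict(self)


def random_mating_components(
    dge_effects, ige_effects, freqs, sigma_eps2: float = 0.0
) -> RandomMatingComponents:
    """Random-mating variance components from per-variant effects.

    Parameters
    ----------
    dge_effects, ige_effects : array-like
        Per-variant direct effects ``delta_l`` and average parental indirect
        effects ``eta_l``.
    freqs : array-like
        Allele frequencies ``f_l``, each strictly inside (0, 1).
    sigma_eps2 : float
        Residual variance.
    """
    d = np.asarray(dge_effects, dtype=float)
    e = np.asarray(ige_effects, dtype=float)
    f = np.asarray(freqs, dtype=float)
    if not (d.shape == e.shape == f.shape):
        raise ValueError("effect and frequency vectors must have equal length")
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    het = f * (1.0 - f)
    vg = float(2.0 * np.sum(d * d * het))
    ve_g = float(4.0 * np.sum(e * e * het))
    cge = float(4.0 * np.sum(d * e * het))
    return RandomMatingComponents(vg=vg, ve_g=ve_g, cge=cge, sigma_eps2=sigma_eps2)


def components_from_variances(
    vg: float, ve_g: float, r_dg_ig_0: float, sigma_eps2: float | None = None
) -> RandomMatingComponents:
    """Build components from target variances and the DGE-IGE correlation.

    ``cge = r_dg_ig_0 * sqrt(2 vg ve_g)``. When ``sigma_eps2`` is None the
    residual is set so that the random-mating phenotypic variance is 1.
    """
    cge = r_dg_ig_0 * math.sqrt(2.0 * vg * ve_g)
    if sigma_eps2 is None:
        sigma_eps2 = 1.0 - (vg + ve_g + cge)
        if sigma_eps2 < 0.0:
            raise ValueError("vg + ve_g + cge exceeds 1; supply sigma_eps2")
    return RandomMatingComponents(vg=vg, ve_g=ve_g, cge=cge, sigma_eps2=sigma_eps2)


def equilibrium_decomposition(
    rm: RandomMatingComponents, corr: EquilibriumCorrelations
) -> EquilibriumComponents:
    """Equilibrium variance decomposition.

    vg_eq = vg / (1 - r_delta)                      (Crow-Felsenstein factor)
    ve_g_eq = ve_g (1 + r_eta) / (1 - r_eta)
    cge_eq = (r_de_cis + r_de_trans) * sqrt(2 vg ve_g / ((1-r_delta)(1-r_eta)))

    The cge_eq form follows from the equilibrium per-parent standard
    deviations sqrt(vg/(1-r_delta)) and sqrt(ve_g/(2(1-r_eta))); it is pinned
    against the forward simulator in the test suite.
    """
    rd, re = corr.r_delta, corr.r_eta
    if rd >= 1.0 or re >= 1.0:
        raise ValueError("r_delta and r_eta must be < 1")
    vg_eq = rm.vg / (1.0 - rd)
    ve_g_eq = rm.ve_g * (1.0 + re) / (1.0 - re)
    prod = 2.0 * rm.vg * rm.ve_g / ((1.0 - rd) * (1.0 - re))
    cge_eq = (corr.r_de_cis + corr.r_de_trans) * math.sqrt(prod)
    return EquilibriumComponents(
        vg_eq=vg_eq, ve_g_eq=ve_g_eq, cge_eq=cge_eq, sigma_eps2=rm.sigma_eps2
    )


def equilibrium_cge_via_cge0(
    rm: RandomMatingComponents, corr: EquilibriumCorrelations
) -> float:
    """Equilibrium DGE-IGE covariance term expressed via the random-mating cge.

    cge_eq = cge * (1 + 2 r_de_trans / (r_dg_ig_0 * sqrt((1-r_delta)(1-r_eta)))).

    Valid only when ``r_dg_ig_0 != 0``; agrees with
    :func:`equilibrium_decomposition` on dynamically consistent inputs, where
    r_de_cis - r_de_trans = r_dg_ig_0 * sqrt((1-r_delta)(1-r_eta)).
    """
    r0 = rm.r_dg_ig_0
    if r0 == 0.0:
        raise ValueError(
            "r_dg_ig_0 is 0; use equilibrium_decomposition for cge_eq"
        )
    rd, re = corr.r_delta, corr.r_eta
    if rd >= 1.0 or re >= 1.0:
        raise ValueError("r_delta and r_eta must be < 1")
    root = math.sqrt((1.0 - rd) * (1.0 - re))
    return rm.cge * (1.0 + 2.0 * corr.r_de_trans / (r0 * root))


def rdelta_under_phenotypic_assortment(
    h2_eq: float, r_y: float, cge_eq: float = 0.0, vg_eq: float = 1.0
) -> float:
    """Correlation between parents' DGE components under primary phenotypic
    assortment.

    r_delta = h2_eq * r_y * (1 + cge_eq / (2 vg_eq))^2,

    which follows from r_delta = r_y * Corr(Delta, Y)^2 with
    Cov(Delta, Y) = vg_eq + cge_eq / 2. Reduces to the classic
    ``r_delta = h2_eq * r_y`` when cge_eq = 0.
    """
    if cge_eq != 0.0 and vg_eq <= 0.0:
        raise ValueError("vg_eq must be positive when cge_eq is non-zero")
    if vg_eq <= 0.0:
        return h2_eq * r_y
    return h2_eq * r_y * (1.0 + cge_eq / (2.0 * vg_eq)) ** 2


def sib_regression_expectation(
    rm: RandomMatingComponents,
    eq: EquilibriumComponents,
    corr: EquilibriumCorrelations,
    resid_cov: float = 0.0,
) -> SibRegressionExpectation:
    """Expected sib-regression slope and intercept at equilibrium.

    Regressing Y_ij Y_ik / vy_eq on realized relatedness R_ijk gives slope
    h2_f = vg / vy_eq and intercept
    r_delta * h2_eq + (ve_g_eq + cge_eq + E[eps_ij eps_ik]) / vy_eq.
    The r_delta*h2_eq term biases 'shared environment' upward under AM; it can
    be removed by subtracting (r_delta/(1-r_delta)) * h2_f.
    """
    vy_eq = eq.vy_eq
    if vy_eq <= 0.0:
        raise ValueError("equilibrium phenotypic variance must be positive")
    slope = rm.vg / vy_eq
    intercept = corr.r_delta * eq.h2_eq + (eq.ve_g_eq + eq.cge_eq + resid_cov) / vy_eq
    return SibRegressionExpectation(slope=slope, intercept=intercept, resid_cov=resid_cov)


def h2eq_from_h2f(h2_f: float, r_delta: float) -> float:
    """Inflate a family-based heritability estimate to the equilibrium scale:
    h2_eq = h2_f / (1 - r_delta)."""
    if r_delta >= 1.0:
        raise ValueError("r_delta must be < 1")
    return h2_f / (1.0 - r_delta)
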