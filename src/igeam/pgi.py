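"""Closed-form expected regression coefficients for polygenic-index (PGI)
analysis: one-generation (population-effect) and two-generation (proband +
parental PGI) regressions, under random mating and under assortative mating
at equilibrium.

Conventions: PGIs are standardized to variance 1 (the raw weighted sum is
divided by its standard deviation); equilibrium coefficients are per
standardized phenotype. ``k`` denotes the fraction of heritability the PGI
would explain in a random-mating population, and ``r_k`` the correlation
between parents' PGIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np

from .components import (
    EquilibriumComponents,
    EquilibriumCorrelations,
    RandomMatingComponents,
)

__all__ = [
    "PGIWeights",
    "PGICoefficients",
    "random_mating_coefficients",
    "true_dge_ntc",
    "true_dge_variance_explained",
    "equilibrium_R2",
    "rho_k",
    "ratio_with_ige",
    "ntc_ratio",
    "rk_from_rdelta",
]


@dataclass(frozen=True)
class PGIWeights:
    """Per-variant PGI weights ``w_l`` with allele frequencies ``f_l``.

    ``norm`` is the random-mating standard deviation of the raw weighted sum,
    sqrt(sum w^2 2f(1-f)); the standardized PGI is the raw sum divided by it.
    """

    weights: np.ndarray
    freqs: np.ndarray
    kind: str = "custom"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "freqs", f)
        if w.shape != f.shape:
            raise ValueError("weights and freqs must have equal length")
        if np.any(f <= 0.0) or np.any(f >= 1.0):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if self.kind not in ("dge", "ige", "population", "custom"):
            raise ValueError(f"unknown PGI kind {self.kind!r}")
        if np.any(w != 0.0) and self.norm <= 0.0:
            raise ValueError("norm must be positive for non-zero weights")

    @property
    def norm(self) -> float:
        het = self.freqs * (1.0 - self.freqs)
        return math.sqrt(float(2.0 * np.sum(self.weights**2 * het)))


@dataclass(frozen=True)
class PGICoefficients:
    """Expected coefficients for a standardized PGI.

    delta_pgi: direct effect; alpha_pgi: average non-transmitted coefficient
    (coefficient on the summed parental PGI); beta_pgi: population effect.
    At equilibrium beta = delta + (1 + r_k) * alpha.
    """

    delta_pgi: float
    alpha_pgi: float
    beta_pgi: float
    r_k: float = 0.0
    k: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def random_mating_coefficients(
    w: PGIWeights, dge_effects, ige_effects
) -> PGICoefficients:
    """Expected regression coefficients for a standardized PGI under random
    mating.

    delta = sum(w delta 2f(1-f)) / norm, alpha analogous with eta, beta with
    beta_l = delta_l + eta_l. For the special weight vectors w = delta, eta,
    or delta+eta these reduce to simple functions of (vg, ve_g, cge): e.g.
    the DGE-weight PGI has delta = sqrt(vg) and alpha = r_dg_ig_0*sqrt(ve_g/2).
    """
    d = np.asarray(dge_effects, dtype=float)
    e = np.asarray(ige_effects, dtype=float)
    if d.shape != w.weights.shape or e.shape != w.weights.shape:
        raise ValueError("effect vectors must align with the weights")
    if not np.any(w.weights != 0.0):
        raise ValueError("all-zero weight vector")
    het = w.freqs * (1.0 - w.freqs)
    norm = w.norm
    delta_pgi = float(2.0 * np.sum(w.weights * d * het)) / norm
    alpha_pgi = float(2.0 * np.sum(w.weights * e * het)) / norm
    beta_pgi = delta_pgi + alpha_pgi
    vg = float(2.0 * np.sum(d * d * het))
    k = delta_pgi**2 / vg if vg > 0.0 else 0.0
    return PGICoefficients(
        delta_pgi=delta_pgi, alpha_pgi=alpha_pgi, beta_pgi=beta_pgi, r_k=0.0, k=k
    )


def true_dge_ntc(
    rm: RandomMatingComponents,
    corr: EquilibriumCorrelations,
    eq: EquilibriumComponents,
) -> tuple[float, float]:
    """Average non-transmitted coefficient of the true (complete) DGE PGI at
    equilibrium.

    Regressing Y on (Delta_ij, Delta_par) gives coefficient 1 on the proband
    component and alpha_delta = cge_eq / (2 (1 + r_delta) vg_eq) on the
    parental sum. Returns ``(alpha_delta, alpha_delta_std)`` where the second
    is the coefficient for the variance-1 standardized component,
    alpha_delta * sqrt(vg_eq). alpha_delta is non-zero only when IGEs are
    present and r_de_cis + r_de_trans != 0.
    """
    if eq.vg_eq <= 0.0:
        raise ValueError("vg_eq must be positive")
    alpha = eq.cge_eq / (2.0 * (1.0 + corr.r_delta) * eq.vg_eq)
    return alpha, alpha * math.sqrt(eq.vg_eq)


def true_dge_variance_explained(
    h2_eq: float, r_delta: float, alpha_delta: float
) -> tuple[float, float]:
    """Variance explained by the joint regression on proband and parental true
    DGE PGIs, and the IGE contribution.

    proportion = (1 + 2 (1 + r_delta) alpha_delta (1 + alpha_delta)) * h2_eq;
    v_eta_delta = proportion - h2_eq, the phenotypic variance contributed by
    the IGE component correlated with the DGE component (magnified when
    r_delta > 0).
    """
    if not -1.0 < r_delta < 1.0:
        raise ValueError("r_delta must lie in (-1, 1)")
    proportion = (
        1.0 + 2.0 * (1.0 + r_delta) * alpha_delta * (1.0 + alpha_delta)
    ) * h2_eq
    return proportion, proportion - h2_eq


def equilibrium_R2(k: float, r_delta: float, r_k: float, h2_eq: float) -> float:
    """Phenotypic variance explained by an incomplete DGE PGI at equilibrium
    (no IGEs): R2_eq = k * h2_eq * (1 + (1 - k) r_delta / (1 + r_k))."""
    if not 0.0 <= k <= 1.0:
        raise ValueError("k must lie in [0, 1]")
    if 1.0 + r_k <= 0.0:
        raise ValueError("1 + r_k must be positive")
    return k * h2_eq * (1.0 + (1.0 - k) * r_delta / (1.0 + r_k))


def rho_k(k: float, r_delta: float) -> float:
    """Direct-to-population-effect ratio of an incomplete DGE PGI under AM
    without IGEs: rho_k = 1 - (1 - k) r_delta. The single-variant limit
    (k -> 0) is the classic within-family shrinkage 1 - r_delta."""
    if not 0.0 <= k <= 1.0:
        raise ValueError("k must lie in [0, 1]")
    if not -1.0 <= r_delta <= 1.0:
        raise ValueError("r_delta must lie in [-1, 1]")
    return 1.0 - (1.0 - k) * r_delta


def ratio_with_ige(rho: float, r_delta: float, alpha_delta: float) -> float:
    """Direct-to-population-effect ratio in the presence of IGEs:
    delta/beta = rho_k / (1 + (1 + r_delta) alpha_delta)."""
    denom = 1.0 + (1.0 + r_delta) * alpha_delta
    if denom == 0.0:
        raise ValueError("1 + (1 + r_delta) * alpha_delta must be non-zero")
    return rho / denom


def ntc_ratio(alpha_delta: float, r_delta: float, rho: float, r_k: float) -> float:
    """Ratio of the average NTC to the direct effect of an incomplete DGE PGI:

    alpha/delta = [(1 + r_delta) alpha_delta + (1 - rho_k)] / (rho_k (1 + r_k)),

    the sum of an IGE part and an AM part (1 - rho_k)/(rho_k (1 + r_k)). This
    is the exact consequence of the direct-to-population-effect ratio
    delta/beta = rho_k/(1 + (1 + r_delta) alpha_delta) combined with the OLS
    identity beta = delta + (1 + r_k) alpha."""
    if 1.0 + r_k <= 0.0:
        raise ValueError("1 + r_k must be positive")
    if rho <= 0.0:
        raise ValueError("rho_k must be positive")
    return ((1.0 + r_delta) * alpha_delta + (1.0 - rho)) / (rho * (1.0 + r_k))


def rk_from_rdelta(k: float, r_delta: float) -> float:
    """Correlation between parents' incomplete DGE PGIs implied by the
    correlation between their full DGE components:
    r_k = k r_delta / (1 - (1 - k) r_delta). Inverse of the r_delta
    estimating equation; r_k <= r_delta with equality at k = 1."""
    denom = 1.0 - (1.0 - k) * r_delta
    if denom <= 0.0:
        raise ValueError("(1 - k) * r_delta must be < 1")
    return k * r_delta / denom
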