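"""Monte-Carlo tolerance helpers for simulator-oracle tests.

Comparisons between theory and simulation use 3x a combined standard error:
the family-clustered SE of the empirical moment plus the SE of the theoretical
prediction obtained by propagating the sampling error of the measured couple
correlations (SE(r) = (1 - r^2)/sqrt(n)) through the decomposition.
"""

from __future__ import annotations

import math

import numpy as np

from igeam.components import RandomMatingComponents


def clustered_var_se(values: np.ndarray) -> tuple[float, float]:
    """Sample variance of per-individual values grouped (n_families, k) and
    its family-clustered standard error."""
    centred = values - values.mean()
    per_family = (centred**2).mean(axis=1)
    n_fam = per_family.size
    return float(per_family.mean()), float(per_family.std(ddof=1) / math.sqrt(n_fam))


def corr_se(r: float, n: int) -> float:
    return (1.0 - r**2) / math.sqrt(n)


def _vy_eq(rm: RandomMatingComponents, rd: float, re: float, c: float, t: float) -> float:
    vg_eq = rm.vg / (1.0 - rd)
    ve_g_eq = rm.ve_g * (1.0 + re) / (1.0 - re)
    cge_eq = (c + t) * math.sqrt(2.0 * rm.vg * rm.ve_g / ((1.0 - rd) * (1.0 - re)))
    return vg_eq + ve_g_eq + cge_eq + rm.sigma_eps2


def predicted_vy_se(rm: RandomMatingComponents, corr, n_couples: int) -> float:
    """Delta-method SE of the predicted equilibrium Var(Y) from the sampling
    error of the four measured couple correlations."""
    x0 = np.array([corr.r_delta, corr.r_eta, corr.r_de_cis, corr.r_de_trans])
    ses = np.array([corr_se(r, n_couples) for r in x0])
    grad = np.zeros(4)
    for j in range(4):
        h = 1e-5
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        grad[j] = (_vy_eq(rm, *xp) - _vy_eq(rm, *xm)) / (2.0 * h)
    return float(math.sqrt(np.sum((grad * ses) ** 2)))
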