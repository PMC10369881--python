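"""Two-generation PGI inference accounting for assortative mating.

A series of non-linear estimating equations maps summary inputs — the
regression coefficients (or the direct-to-population-effect ratio) from
two-generation PGI analysis, the correlation between parents' PGIs r_k, and a
family-based heritability estimate h2_f — to estimates of:

    k        fraction of heritability the PGI would explain under random mating
    r_delta  correlation between parents' DGE components
    h2_eq    equilibrium heritability, h2_f / (1 - r_delta)
    rho_k    direct/population effect ratio expected from AM alone
    alpha_delta  average NTC of the true DGE PGI (an IGE signal)
    v_eta_delta  phenotypic variance from the DGE-correlated IGE component

Standard errors are propagated through the composed map with the delta
method, using a numeric Jacobian (central differences). The regression
coefficient block, r_k, and h2_f are treated as mutually independent: h2_f
comes from an external study and r_k from the parents alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TwoGenInputs",
    "TwoGenEstimates",
    "estimate_k",
    "estimate_rdelta",
    "estimate_alpha_delta_1",
    "estimate_alpha_delta_2",
    "estimate_v_eta_delta",
    "numeric_jacobian",
    "delta_method_se",
    "run_two_generation_inference",
    "infer_from_dataset",
]

#: below this value of k (or of the denominator k + (1-k) r_k) the ratio-based
#: estimating equations are documented to become unstable
STABILITY_THRESHOLD = 0.05

_OUTPUT_NAMES = ("k", "r_delta", "h2_eq", "rho_k", "alpha_delta", "v_eta_delta")


def estimate_k(
    delta_hat: float,
    r_k_hat: float,
    h2f_hat: float,
    delta_var: float = 0.0,
    h2f_var: float = 0.0,
    bias_correct: bool = True,
) -> tuple[float, bool]:
    """Fraction of heritability the PGI would explain under random mating.

    Plain estimator: k = (1 - r_k) * delta^2 / h2_f. With ``bias_correct``
    the squared coefficient is debiased by its sampling variance and the
    h2_f denominator by its noise, k_hat = (1 - r_k)(1 - z_f^-2)
    (delta^2 - Var(delta)) / h2_f with z_f = h2_f / SE(h2_f). The estimate is
    clipped to [0, 1]; the returned flag reports whether clipping occurred.
    """
    if h2f_hat <= 0.0:
        raise ValueError("h2f_hat must be positive")
    if bias_correct:
        zf_factor = 1.0 - h2f_var / h2f_hat**2 if h2f_var > 0.0 else 1.0
        num = delta_hat**2 - delta_var
    else:
        zf_factor = 1.0
        num = delta_hat**2
    k = (1.0 - r_k_hat) * zf_factor * num / h2f_hat
    clipped = not 0.0 <= k <= 1.0
    return float(min(max(k, 0.0), 1.0)), clipped


def estimate_rdelta(k_hat: float, r_k_hat: float) -> float:
    """Correlation between parents' DGE components from (k, r_k):
    r_delta = r_k / (k + (1 - k) r_k)."""
    denom = k_hat + (1.0 - k_hat) * r_k_hat
    if denom <= 0.0:
        raise ValueError("k + (1 - k) * r_k must be positive")
    return r_k_hat / denom


def estimate_alpha_delta_1(rho_hat: float, ratio_hat: float, r_delta_hat: float) -> float:
    """IGE coefficient of the true DGE PGI from the observed
    direct-to-population-effect ratio:
    alpha_delta = (rho_k - ratio) / (ratio * (1 + r_delta)). Positive when the
    observed within-family shrinkage exceeds the AM-only prediction."""
    if ratio_hat == 0.0:
        raise ValueError("ratio_hat must be non-zero")
    return (rho_hat - ratio_hat) / (ratio_hat * (1.0 + r_delta_hat))


def estimate_alpha_delta_2(
    rho_hat: float, k_hat: float, r_delta_hat: float, ntc_ratio_hat: float
) -> float:
    """IGE coefficient of the true DGE PGI from the NTC-to-direct-effect
    ratio alpha/delta (both from the same regression):
    alpha_delta = ([rho_k + k r_delta] * (alpha/delta) - (1 - rho_k))
                  / (1 + r_delta)."""
    return (
        (rho_hat + k_hat * r_delta_hat) * ntc_ratio_hat - (1.0 - rho_hat)
    ) / (1.0 + r_delta_hat)


def estimate_v_eta_delta(
    alpha_delta_hat: float, r_delta_hat: float, h2eq_hat: float
) -> float:
    """Phenotypic variance contributed by the IGE component correlated with
    the DGE component: v = 2 (1 + r_delta) alpha_delta (1 + alpha_delta) h2_eq."""
    return (
        2.0
        * (1.0 + r_delta_hat)
        * alpha_delta_hat
        * (1.0 + alpha_delta_hat)
        * h2eq_hat
    )


def numeric_jacobian(f: Callable[[np.ndarray], np.ndarray], x: Sequence[float]) -> np.ndarray:
    """Central-difference Jacobian with per-coordinate step
    max(1e-6, 1e-4 * |x_j|)."""
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(f(x), dtype=float)
    jac = np.zeros((f0.size, x.size))
    for j in range(x.size):
        h = max(1e-6, 1e-4 * abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        jac[:, j] = (np.asarray(f(xp), dtype=float) - np.asarray(f(xm), dtype=float)) / (
            2.0 * h
        )
    return jac


def delta_method_se(
    pipeline: Callable[[np.ndarray], np.ndarray],
    x: Sequence[float],
    input_cov: np.ndarray,
) -> np.ndarray:
    """Delta-method standard errors sqrt(diag(J Sigma J^T)) for the composed
    map ``pipeline`` evaluated at ``x`` with input covariance ``input_cov``."""
    cov = np.asarray(input_cov, dtype=float)
    if cov.shape != (len(x), len(x)):
        raise ValueError("input covariance has wrong shape")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("input covariance must be symmetric")
    if np.linalg.eigvalsh(cov).min() < -1e-10:
        raise ValueError("input covariance must be positive semi-definite")
    jac = numeric_jacobian(pipeline, x)
    return np.sqrt(np.clip(np.diag(jac @ cov @ jac.T), 0.0, None))


@dataclass
class TwoGenInputs:
    """Summary-level inputs to the inference pipeline.

    Either the regression coefficients (``delta_hat``, ``alpha_hat``) or the
    direct-to-population-effect ratio (``ratio_hat``, requiring ``k_override``)
    must be supplied, together with ``r_k_hat`` and ``h2f_hat``. When
    ``r_k_se`` is omitted it defaults to the standard correlation SE,
    Var(r_k) = (1 - r_k^2)^2 / n_families.
    """

    r_k_hat: float = 0.0
    h2f_hat: float = 0.0
    r_k_se: float | None = None
    h2f_se: float = 0.0
    delta_hat: float | None = None
    delta_se: float = 0.0
    alpha_hat: float | None = None
    alpha_se: float = 0.0
    delta_alpha_cov: float = 0.0
    ratio_hat: float | None = None
    ratio_se: float = 0.0
    k_override: float | None = None
    k_se: float = 0.0
    n_families: int | None = None
    bias_correct: bool = True

    def validate(self) -> None:
        if not -1.0 < self.r_k_hat < 1.0:
            raise ValueError("r_k_hat must lie in (-1, 1)")
        if self.h2f_hat <= 0.0:
            raise ValueError("h2f_hat must be positive")
        have_coef = self.delta_hat is not None and self.alpha_hat is not None
        have_ratio = self.ratio_hat is not None and (
            self.k_override is not None or self.delta_hat is not None
        )
        if not (have_coef or have_ratio):
            raise ValueError(
                "supply (delta_hat, alpha_hat), or ratio_hat with k_override"
            )
        for name in ("r_k_se", "h2f_se", "delta_se", "alpha_se", "ratio_se", "k_se"):
            v = getattr(self, name)
            if v is not None and v < 0.0:
                raise ValueError(f"{name} must be non-negative")

    def resolved_r_k_var(self) -> float:
        if self.r_k_se is not None:
            return self.r_k_se**2
        if self.n_families:
            return (1.0 - self.r_k_hat**2) ** 2 / self.n_families
        return 0.0


@dataclass
class TwoGenEstimates:
    """Outputs of the inference pipeline, each with a delta-method SE."""

    k: float
    k_se: float
    r_delta: float
    r_delta_se: float
    h2_eq: float
    h2_eq_se: float
    rho_k: float
    rho_k_se: float
    alpha_delta: float
    alpha_delta_se: float
    v_eta_delta: float
    v_eta_delta_se: float
    beta_hat: float | None = None
    method_alpha: int = 2
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _chain(v: dict, opts: dict) -> tuple[np.ndarray, list[str], bool]:
    """Evaluate the estimating-equation chain at named input values."""
    warn: list[str] = []
    rk, h2f = v["r_k"], v["h2f"]
    if "k" in v:
        k, clipped = float(min(max(v["k"], 0.0), 1.0)), not 0.0 <= v["k"] <= 1.0
    else:
        k, clipped = estimate_k(
            v["delta"], rk, h2f,
            delta_var=opts["delta_var"], h2f_var=opts["h2f_var"],
            bias_correct=opts["bias_correct"],
        )
    if clipped:
        warn.append("k estimate clipped to [0, 1]")
    denom = k + (1.0 - k) * rk
    if denom <= 0.0:
        raise ValueError("estimating equation for r_delta failed: "
                         "k + (1 - k) * r_k is not positive")
    if k < STABILITY_THRESHOLD or denom < STABILITY_THRESHOLD:
        warn.append(
            f"k = {k:.4g} (denominator {denom:.4g}) below stability threshold "
            f"{STABILITY_THRESHOLD}; ratio-based estimating equations are "
            "unstable for PGIs explaining this little heritability"
        )
    r_delta = rk / denom
    if r_delta >= 1.0:
        raise ValueError("estimating equation for h2_eq failed: r_delta >= 1")
    h2_eq = h2f / (1.0 - r_delta)
    rho = 1.0 - (1.0 - k) * r_delta
    if opts["method"] == 2:
        alpha_delta = estimate_alpha_delta_2(rho, k, r_delta, v["alpha"] / v["delta"])
    else:
        alpha_delta = estimate_alpha_delta_1(rho, v["ratio"], r_delta)
    v_eta = estimate_v_eta_delta(alpha_delta, r_delta, h2_eq)
    return np.array([k, r_delta, h2_eq, rho, alpha_delta, v_eta]), warn, clipped


def run_two_generation_inference(inputs: TwoGenInputs) -> TwoGenEstimates:
    """Run the full estimating-equation pipeline with delta-method SEs.

    The alpha_delta estimator based on the NTC/direct-effect ratio (method 2)
    is the default when delta and alpha coefficients are jointly available
    (their sampling covariance is then known from the same regression); the
    ratio-based estimator (method 1) is used otherwise.
    """
    inputs.validate()
    method = 2 if (inputs.delta_hat is not None and inputs.alpha_hat is not None) else 1

    if (
        inputs.ratio_hat is not None
        and inputs.delta_hat is not None
        and inputs.alpha_hat is not None
    ):
        beta_implied = inputs.delta_hat + (1.0 + inputs.r_k_hat) * inputs.alpha_hat
        if beta_implied != 0.0 and abs(
            inputs.delta_hat / beta_implied - inputs.ratio_hat
        ) > 1e-6:
            raise ValueError(
                "ratio_hat inconsistent with (delta_hat, alpha_hat, r_k_hat)"
            )

    names = []
    x0 = []
    variances = []
    if method == 2:
        names += ["delta", "alpha"]
        x0 += [inputs.delta_hat, inputs.alpha_hat]
        variances += [inputs.delta_se**2, inputs.alpha_se**2]
    else:
        names.append("ratio")
        x0.append(inputs.ratio_hat)
        variances.append(inputs.ratio_se**2)
    names += ["r_k", "h2f"]
    x0 += [inputs.r_k_hat, inputs.h2f_hat]
    variances += [inputs.resolved_r_k_var(), inputs.h2f_se**2]
    if inputs.k_override is not None:
        names.append("k")
        x0.append(inputs.k_override)
        variances.append(inputs.k_se**2)

    cov = np.diag(variances)
    if method == 2:
        cov[0, 1] = cov[1, 0] = inputs.delta_alpha_cov

    opts = {
        "method": method,
        "delta_var": inputs.delta_se**2,
        "h2f_var": inputs.h2f_se**2,
        "bias_correct": inputs.bias_correct,
    }

    est, warns, _ = _chain(dict(zip(names, x0)), opts)

    def fvec(x: np.ndarray) -> np.ndarray:
        return _chain(dict(zip(names, x)), opts)[0]

    ses = delta_method_se(fvec, x0, cov)

    beta_hat = None
    if method == 2:
        beta_hat = inputs.delta_hat + (1.0 + inputs.r_k_hat) * inputs.alpha_hat

    kwargs = {}
    for i, name in enumerate(_OUTPUT_NAMES):
        kwargs[name] = float(est[i])
        kwargs[name + "_se"] = float(ses[i])
    return TwoGenEstimates(
        beta_hat=beta_hat, method_alpha=method, warnings=warns, **kwargs
    )


def infer_from_dataset(
    dataset,
    h2f_hat: float,
    h2f_se: float = 0.0,
    one_sib_per_family: bool = False,
    bias_correct: bool = True,
) -> TwoGenEstimates:
    """Individual-level route: standardize a :class:`FamilyPGIDataset`, fit
    the two-generation regression with family-clustered SEs, estimate r_k from
    the parents, and run the summary pipeline."""
    from .regression import fit_two_gen, parental_pgi_correlation, standardize

    ds, _ = standardize(dataset)
    if one_sib_per_family:
        df = ds.df.sort_values(["family_id", "sib_index"]).groupby("family_id").head(1)
        ds = type(ds)(df.reset_index(drop=True))
    fit = fit_two_gen(ds)
    r_k, r_k_se = parental_pgi_correlation(ds)
    inputs = TwoGenInputs(
        delta_hat=fit.delta_hat,
        delta_se=math.sqrt(fit.cov[0, 0]),
        alpha_hat=fit.alpha_hat,
        alpha_se=math.sqrt(fit.cov[1, 1]),
        delta_alpha_cov=fit.cov[0, 1],
        r_k_hat=r_k,
        r_k_se=r_k_se,
        h2f_hat=h2f_hat,
        h2f_se=h2f_se,
        n_families=fit.n_families,
        bias_correct=bias_correct,
    )
    return run_two_generation_inference(inputs)
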