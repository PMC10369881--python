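"""Individual-level estimation from family PGI data.

The central container is :class:`FamilyPGIDataset`: one row per phenotyped
sibling with the proband, paternal and maternal PGIs on a common scale.
Standardization follows the two-generation regression convention: the
phenotype is scaled to unit variance, and all three PGIs are divided by the
proband-PGI standard deviation (a single common scale, so that the
beta = delta + (1 + r_k) alpha identity between one- and two-generation
coefficients is preserved; per-column standardization would distort it).

OLS fits use family-cluster-robust covariance by default, since datasets from
the simulator carry two siblings per family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyPGIDataset",
    "TwoGenFit",
    "PopulationFit",
    "standardize",
    "fit_two_gen",
    "fit_population",
    "parental_pgi_correlation",
    "pgi_from_genotypes",
    "load_pgi_weights",
]

CORE_COLUMNS = [
    "family_id",
    "sib_index",
    "phenotype",
    "proband_pgi",
    "paternal_pgi",
    "maternal_pgi",
]

# on-disk header (tab-separated, "NA" missing code)
_TSV_COLUMNS = ["FID", "IID", "phenotype", "pgi_proband", "pgi_father", "pgi_mother"]


@dataclass
class FamilyPGIDataset:
    """Per-family phenotype and PGI table.

    ``df`` must contain :data:`CORE_COLUMNS`; siblings share ``family_id``
    and parental PGIs. Rows with missing core values are dropped at
    construction (listwise deletion, counts logged).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        n0 = len(self.df)
        self.df = self.df.dropna(subset=CORE_COLUMNS[2:]).reset_index(drop=True)
        if len(self.df) < n0:
            logger.info("dropped %d rows with missing values", n0 - len(self.df))
        if self.df["family_id"].nunique() < 2:
            raise ValueError("need at least 2 distinct families")
        shared = self.df.groupby("family_id")[["paternal_pgi", "maternal_pgi"]].nunique()
        if (shared > 1).any().any():
            raise ValueError("siblings must share parental PGIs within a family")

    @property
    def n_families(self) -> int:
        return int(self.df["family_id"].nunique())

    def parental_sum(self) -> np.ndarray:
        return (self.df["paternal_pgi"] + self.df["maternal_pgi"]).to_numpy()

    @classmethod
    def from_tsv(cls, path) -> "FamilyPGIDataset":
        df = pd.read_csv(path, sep="\t", na_values="NA")
        missing = [c for c in _TSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"input table lacks columns: {missing}")
        out = pd.DataFrame(
            {
                "family_id": df["FID"],
                "sib_index": df.groupby("FID").cumcount(),
                "phenotype": df["phenotype"],
                "proband_pgi": df["pgi_proband"],
                "paternal_pgi": df["pgi_father"],
                "maternal_pgi": df["pgi_mother"],
            }
        )
        return cls(out)

    def to_tsv(self, path) -> None:
        out = pd.DataFrame(
            {
                "FID": self.df["family_id"],
                "IID": self.df["family_id"].astype(str)
                + "_"
                + self.df["sib_index"].astype(str),
                "phenotype": self.df["phenotype"],
                "pgi_proband": self.df["proband_pgi"],
                "pgi_father": self.df["paternal_pgi"],
                "pgi_mother": self.df["maternal_pgi"],
            }
        )
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_pgi_weights(path) -> pd.DataFrame:
    """Read a per-variant weight table with columns
    ``variant_id  weight  frequency`` (tab-separated)."""
    df = pd.read_csv(path, sep="\t", na_values="NA")
    missing = [c for c in ("variant_id", "weight", "frequency") if c not in df.columns]
    if missing:
        raise ValueError(f"weight file lacks columns: {missing}")
    return df


def pgi_from_genotypes(genotypes, weights, freqs) -> np.ndarray:
    """Standardized PGI values Sum_l w_l (g_l - 2 f_l) / sqrt(v) from an
    (individuals x variants) additive-dosage matrix; v is the sample variance
    of the raw weighted sum."""
    g = np.asarray(genotypes, dtype=float)
    w = np.asarray(weights, dtype=float)
    f = np.asarray(freqs, dtype=float)
    if g.ndim != 2 or g.shape[1] != w.size or w.size != f.size:
        raise ValueError("genotype matrix must be individuals x variants, "
                         "aligned with weights and frequencies")
    if np.any((g < 0) | (g > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    raw = (g - 2.0 * f) @ w
    sd = float(np.std(raw))
    if sd <= 0.0:
        raise ValueError("raw PGI has zero variance")
    return raw / sd


class TwoGenFit(NamedTuple):
    delta_hat: float
    alpha_hat: float
    cov: np.ndarray  # 2x2 sampling covariance of (delta_hat, alpha_hat)
    n_families: int
    n_individuals: int


class PopulationFit(NamedTuple):
    beta_hat: float
    se: float
    n_families: int
    n_individuals: int


def standardize(dataset: FamilyPGIDataset) -> tuple[FamilyPGIDataset, dict]:
    """Standardize phenotype to mean 0 / variance 1 and put all PGIs on the
    proband-PGI SD scale (mean-centred). The parental sum is NOT
    re-standardized: at equilibrium Var(paternal + maternal) = 2 (1 + r_k)."""
    df = dataset.df.copy()
    y_mean = float(df["phenotype"].mean())
    y_sd = float(df["phenotype"].std(ddof=0))
    pgi_sd = float(df["proband_pgi"].std(ddof=0))
    if y_sd <= 0.0 or pgi_sd <= 0.0:
        raise ValueError("phenotype and proband PGI must have non-zero variance")
    df["phenotype"] = (df["phenotype"] - y_mean) / y_sd
    for col in ("proband_pgi", "paternal_pgi", "maternal_pgi"):
        df[col] = (df[col] - df[col].mean()) / pgi_sd
    report = {"y_mean": y_mean, "y_sd": y_sd, "pgi_sd": pgi_sd}
    return FamilyPGIDataset(df), report


def _fit_ols(y, X, groups, cluster: bool):
    model = sm.OLS(y, sm.add_constant(X))
    if cluster:
        return model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    return model.fit()


def fit_two_gen(dataset: FamilyPGIDataset, cluster: bool = True) -> TwoGenFit:
    """OLS of phenotype on proband PGI and the summed parental PGI.

    Returns the direct effect delta_hat, the average non-transmitted
    coefficient alpha_hat, and their family-cluster-robust sampling
    covariance (siblings are correlated).
    """
    df = dataset.df
    X = np.column_stack([df["proband_pgi"].to_numpy(), dataset.parental_sum()])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(df)), X])) < 3:
        raise ValueError("design matrix is rank-deficient (degenerate PGIs)")
    res = _fit_ols(df["phenotype"].to_numpy(), X, df["family_id"].to_numpy(), cluster)
    cov = np.asarray(res.cov_params())[1:3, 1:3]
    return TwoGenFit(
        delta_hat=float(res.params[1]),
        alpha_hat=float(res.params[2]),
        cov=cov,
        n_families=dataset.n_families,
        n_individuals=len(df),
    )


def fit_population(dataset: FamilyPGIDataset, cluster: bool = True) -> PopulationFit:
    """OLS of phenotype on the proband PGI alone (the 'population effect')."""
    df = dataset.df
    res = _fit_ols(
        df["phenotype"].to_numpy(),
        df["proband_pgi"].to_numpy(),
        df["family_id"].to_numpy(),
        cluster,
    )
    return PopulationFit(
        beta_hat=float(res.params[1]),
        se=float(np.sqrt(np.asarray(res.cov_params())[1, 1])),
        n_families=dataset.n_families,
        n_individuals=len(df),
    )


def parental_pgi_correlation(dataset: FamilyPGIDataset) -> tuple[float, float]:
    """Pearson correlation between paternal and maternal PGIs over unique
    families (siblings deduplicated), with SE = (1 - r^2) / sqrt(n - 1)."""
    fam = dataset.df.drop_duplicates("family_id")
    n = len(fam)
    if n < 3:
        raise ValueError("need at least 3 unique families")
    r = float(
        np.corrcoef(fam["paternal_pgi"].to_numpy(), fam["maternal_pgi"].to_numpy())[0, 1]
    )
    se = (1.0 - r**2) / math.sqrt(n - 1)
    return r, se
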