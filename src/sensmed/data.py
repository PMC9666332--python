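"""Synthetic data generation for the parenting → rumination → depression study.

The raw longitudinal data behind the published moderated-mediation analysis
(N = 196 children; environmental sensitivity observed at age 3, parenting
styles reported at age 3, rumination at age 9, depressive symptoms at ages 9
and 12) are not publicly deposited.  This module therefore provides three
seeded generators that stand in for them:

``generate_mvn``
    Multivariate-normal draws around a :class:`MomentSummary`.  With
    ``exact=True`` a whiten-then-recolour transform makes the *sample*
    means/SDs/correlations equal the targets to numerical precision, so a
    dataset generated from :func:`study_moments` carries exactly the published
    moment structure.

``generate_structural``
    Forward simulation from the structural path model with known coefficients
    (including the parenting × sensitivity interaction), used for parameter
    recovery and model-selection experiments.

``generate_items``
    One-factor continuous item data with equal loadings, supporting the
    internal-consistency (Cronbach's alpha) computations.

All generators work on the raw scale; standardisation happens at fit time
(see :mod:`sensmed.models`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientSampleError,
    InvalidMomentsError,
    InvalidParameterError,
    InvalidScenarioError,
)

__all__ = [
    "MomentSummary",
    "Dataset",
    "SensitivitySpec",
    "StructuralScenario",
    "study_moments",
    "generate_mvn",
    "generate_structural",
    "generate_items",
    "population_alpha",
    "loading_for_alpha",
    "repair_correlation",
    "zscore",
]

STUDY_VARIABLES = (
    "es",
    "sex",
    "permissive",
    "authoritarian",
    "authoritative",
    "rumination",
    "depression_9",
    "depression_12",
)

# Published univariate statistics of the study variables (N = 196).  Sex is a
# 0/1 indicator with mean 0.43; no SD is printed for it, so it is carried as
# the Bernoulli value sqrt(p(1-p)).
_STUDY_MEANS = (4.00, 0.43, 10.75, 20.08, 60.69, 23.41, 4.53, 4.55)
_STUDY_SDS = (0.90, math.sqrt(0.43 * 0.57), 3.04, 4.18, 6.65, 7.02, 3.76, 5.39)
_STUDY_CORR_LOWER = {
    ("sex", "es"): 0.19,
    ("permissive", "es"): 0.01,
    ("permissive", "sex"): 0.05,
    ("authoritarian", "es"): -0.07,
    ("authoritarian", "sex"): -0.05,
    ("authoritarian", "permissive"): 0.36,
    ("authoritative", "es"): -0.07,
    ("authoritative", "sex"): 0.08,
    ("authoritative", "permissive"): -0.08,
    ("authoritative", "authoritarian"): -0.13,
    ("rumination", "es"): 0.10,
    ("rumination", "sex"): 0.00,
    ("rumination", "permissive"): 0.07,
    ("rumination", "authoritarian"): 0.08,
    ("rumination", "authoritative"): -0.14,
    ("depression_9", "es"): -0.21,
    ("depression_9", "sex"): -0.18,
    ("depression_9", "permissive"): 0.07,
    ("depression_9", "authoritarian"): 0.14,
    ("depression_9", "authoritative"): -0.15,
    ("depression_9", "rumination"): 0.35,
    ("depression_12", "es"): -0.01,
    ("depression_12", "sex"): 0.16,
    ("depression_12", "permissive"): -0.03,
    ("depression_12", "authoritarian"): 0.07,
    ("depression_12", "authoritative"): 0.01,
    ("depression_12", "rumination"): 0.14,
    ("depression_12", "depression_9"): 0.33,
}
STUDY_N = 196


def repair_correlation(corr: np.ndarray, min_eig: float = 1e-8,
                       max_perturbation: float = 0.01) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues below ``min_eig`` are clipped and the diagonal renormalised to
    one.  Printed two-decimal rounding can break positive semi-definiteness;
    the repair is expected to perturb entries by well under 0.005.  If the
    repair would move any entry by more than ``max_perturbation`` the matrix
    is considered genuinely invalid.
    """
    corr = np.asarray(corr, dtype=float)
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= min_eig:
        return corr
    clipped = np.clip(vals, min_eig, None)
    fixed = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    if np.max(np.abs(fixed - corr)) > max_perturbation:
        raise InvalidMomentsError(
            "correlation matrix is not PSD and cannot be repaired within "
            f"tolerance {max_perturbation}"
        )
    return fixed


@dataclass(frozen=True)
class MomentSummary:
    """Means, SDs and correlation matrix of a set of study variables."""

    variable_names: tuple
    means: np.ndarray
    sds: np.ndarray
    correlations: np.ndarray
    n: int

    def __post_init__(self):
        object.__setattr__(self, "variable_names", tuple(self.variable_names))
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        object.__setattr__(
            self, "correlations", np.asarray(self.correlations, dtype=float)
        )
        self.validate()

    @property
    def p(self) -> int:
        return len(self.variable_names)

    def validate(self) -> None:
        p = self.p
        if self.means.shape != (p,) or self.sds.shape != (p,):
            raise InvalidMomentsError("means/sds length mismatch")
        if self.correlations.shape != (p, p):
            raise InvalidMomentsError("correlation matrix shape mismatch")
        if not np.all(self.sds > 0):
            raise InvalidMomentsError("sds must be strictly positive")
        R = self.correlations
        if not np.allclose(R, R.T, atol=1e-12):
            raise InvalidMomentsError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise InvalidMomentsError("correlation diagonal must be exactly 1")
        off = R[~np.eye(p, dtype=bool)]
        if off.size and (off.min() < -1 or off.max() > 1):
            raise InvalidMomentsError("off-diagonal correlations must be in [-1, 1]")
        if self.n < p + 2:
            raise InvalidMomentsError("n must be >= number of variables + 2")

    def repaired(self) -> "MomentSummary":
        """Return a copy with a PSD-repaired correlation matrix."""
        return MomentSummary(
            self.variable_names,
            self.means,
            self.sds,
            repair_correlation(self.correlations),
            self.n,
        )

    def covariance(self) -> np.ndarray:
        return self.correlations * np.outer(self.sds, self.sds)

    def to_json(self) -> str:
        return json.dumps(
            {
                "variable_names": list(self.variable_names),
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "correlations": self.correlations.tolist(),
                "n": int(self.n),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MomentSummary":
        d = json.loads(text)
        return cls(
            tuple(d["variable_names"]),
            np.array(d["means"]),
            np.array(d["sds"]),
            np.array(d["correlations"]),
            int(d["n"]),
        )


def study_moments() -> MomentSummary:
    """Published sample moments of the seven study variables plus sex (N=196)."""
    p = len(STUDY_VARIABLES)
    idx = {name: i for i, name in enumerate(STUDY_VARIABLES)}
    R = np.eye(p)
    for (a, b), r in _STUDY_CORR_LOWER.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return MomentSummary(STUDY_VARIABLES, _STUDY_MEANS, _STUDY_SDS, R, STUDY_N)


@dataclass
class Dataset:
    """A rectangular dataset (one row per child) with provenance metadata."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.df.isna().any().any():
            raise InvalidScenarioError("datasets must not contain missing values")
        if len(self.df) < 3:
            raise InvalidScenarioError("datasets must have at least 3 rows")

    @property
    def variable_names(self) -> tuple:
        return tuple(self.df.columns)

    @property
    def n(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        """Write as UTF-8 CSV with a JSON provenance sidecar."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(df, meta)


def generate_mvn(moments: MomentSummary, n: int | None = None, seed: int = 0,
                 exact: bool = True, binarize_sex: bool = False) -> Dataset:
    """Draw an n × p multivariate-normal dataset around ``moments``.

    With ``exact=True`` the draws are whitened (empirical mean removed,
    empirical covariance factored out) and recoloured with the target
    correlation Cholesky factor, so the sample mean/SD/correlation of the
    result equal the targets to numerical precision (SDs with the n−1
    denominator).  Seeded runs are bit-for-bit reproducible.

    ``binarize_sex`` thresholds a generated ``sex`` column at its (1−mean)
    quantile, reproducing a 0/1 indicator at the cost of exactness for that
    column.
    """
    if n is None:
        n = moments.n
    p = moments.p
    if exact and n <= p + 1:
        raise InsufficientSampleError(
            f"exact moment matching needs n > p+1 (got n={n}, p={p})"
        )
    if n < 3:
        raise InsufficientSampleError("n must be at least 3")
    moments = moments.repaired()
    L = np.linalg.cholesky(moments.correlations)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p))
    if exact:
        Zc = Z - Z.mean(axis=0)
        S = np.cov(Zc, rowvar=False, ddof=1)
        Ls = np.linalg.cholesky(S)
        # whiten: sample covariance of Zw is exactly the identity
        Zw = np.linalg.solve(Ls, Zc.T).T
        core = Zw @ L.T
    else:
        core = Z @ L.T
    X = core * moments.sds + moments.means
    df = pd.DataFrame(X, columns=list(moments.variable_names))
    if binarize_sex and "sex" in df.columns:
        target = moments.means[list(moments.variable_names).index("sex")]
        cut = df["sex"].quantile(1.0 - target)
        df["sex"] = (df["sex"] > cut).astype(float)
    meta = {
        "generator": "generate_mvn",
        "seed": int(seed),
        "n": int(n),
        "exact": bool(exact),
        "binarize_sex": bool(binarize_sex),
    }
    return Dataset(df, meta)


@dataclass(frozen=True)
class SensitivitySpec:
    """Distribution family for the environmental-sensitivity moderator.

    ``family='normal'`` gives a standard normal (after loc/scale); ``'skew'``
    uses a skew-normal with shape ``alpha``, standardised to mean 0 / SD 1
    before loc/scale are applied, for scenarios where the observed trait
    distribution is asymmetric.
    """

    family: str = "normal"
    loc: float = 0.0
    scale: float = 1.0
    alpha: float = 0.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.scale <= 0:
            raise InvalidScenarioError("sensitivity scale must be positive")
        if self.family == "normal":
            z = rng.standard_normal(n)
        elif self.family == "skew":
            delta = self.alpha / math.sqrt(1 + self.alpha**2)
            mu = delta * math.sqrt(2 / math.pi)
            sd = math.sqrt(1 - mu**2)
            raw = stats.skewnorm.rvs(self.alpha, size=n, random_state=rng)
            z = (raw - mu) / sd
        else:
            raise InvalidScenarioError(f"unknown sensitivity family {self.family!r}")
        return self.loc + self.scale * z


@dataclass
class StructuralScenario:
    """Forward-simulation scenario for the moderated-mediation path system."""

    path_params: "PathParams"
    n: int = STUDY_N
    seed: int = 0
    sensitivity: SensitivitySpec = field(default_factory=SensitivitySpec)
    include_sex: bool = False
    parenting_name: str = "parenting"

    def __post_init__(self):
        if self.n < 10:
            raise InvalidScenarioError("structural scenarios need n >= 10")
        rv = self.path_params.resid_var
        if any(v <= 0 for v in rv.values()):
            raise InvalidScenarioError("residual variances must be positive")


def generate_structural(scenario: StructuralScenario) -> Dataset:
    """Simulate from the recursive path system with known coefficients.

    Standardised exogenous parenting P and sensitivity E are drawn
    independently; then

        rumination     = a·P + w·E + k·(P·E) + e1
        depression_9   = c1·P + b1·rumination + e2
        depression_12  = c2·P + b2·rumination + e3

    with independent normal residuals at the scenario's variances.
    """
    pp = scenario.path_params
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n
    P = rng.standard_normal(n)
    E = scenario.sensitivity.draw(n, rng)
    sd = {k: math.sqrt(v) for k, v in pp.resid_var.items()}
    M = pp.a * P + pp.w * E + pp.k * (P * E) + sd["rumination"] * rng.standard_normal(n)
    Y9 = pp.c1 * P + pp.b1 * M + sd["depression_9"] * rng.standard_normal(n)
    Y12 = pp.c2 * P + pp.b2 * M + sd["depression_12"] * rng.standard_normal(n)
    cols = {
        scenario.parenting_name: P,
        "es": E,
        "rumination": M,
        "depression_9": Y9,
        "depression_12": Y12,
    }
    if scenario.include_sex:
        # latent-normal threshold indicator, r ≈ 0.19 with ES, mean 0.43
        latent = 0.19 * E + math.sqrt(1 - 0.19**2) * rng.standard_normal(n)
        cols["sex"] = (latent > np.quantile(latent, 0.57)).astype(float)
    df = pd.DataFrame(cols)
    meta = {
        "generator": "generate_structural",
        "seed": int(scenario.seed),
        "n": int(n),
        "path_params": pp.to_dict(),
        "sensitivity": {
            "family": scenario.sensitivity.family,
            "loc": scenario.sensitivity.loc,
            "scale": scenario.sensitivity.scale,
            "alpha": scenario.sensitivity.alpha,
        },
    }
    return Dataset(df, meta)


def population_alpha(n_items: int, loading: float) -> float:
    """Population Cronbach's alpha of a one-factor model with equal loadings.

    For standardised items x_j = λ f + sqrt(1−λ²) e_j this is the
    Spearman-Brown value k·λ² / (1 + (k−1)·λ²).
    """
    lam2 = loading**2
    return n_items * lam2 / (1 + (n_items - 1) * lam2)


def loading_for_alpha(alpha: float, n_items: int) -> float:
    """Equal loading that yields population alpha ``alpha`` for ``n_items`` items."""
    if not 0 <= alpha < 1:
        raise InvalidParameterError("alpha must be in [0, 1)")
    lam2 = alpha / (n_items - alpha * (n_items - 1))
    return math.sqrt(lam2)


def generate_items(n_items: int, target_loading: float, n: int, seed: int = 0) -> Dataset:
    """One-factor continuous item data with equal loadings."""
    if n_items < 2:
        raise InvalidParameterError("need at least 2 items")
    if not 0 <= target_loading < 1:
        raise InvalidParameterError("loading must be in [0, 1)")
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    E = rng.standard_normal((n, n_items))
    X = target_loading * f[:, None] + math.sqrt(1 - target_loading**2) * E
    df = pd.DataFrame(X, columns=[f"item_{j+1}" for j in range(n_items)])
    meta = {
        "generator": "generate_items",
        "seed": int(seed),
        "n": int(n),
        "n_items": int(n_items),
        "loading": float(target_loading),
        "population_alpha": population_alpha(n_items, target_loading),
    }
    return Dataset(df, meta)


def zscore(x, ddof: int = 1) -> np.ndarray:
    """Standardise a vector with the sample SD (n−1 denominator by default)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        from .errors import DegenerateDataError

        raise DegenerateDataError("cannot z-score a constant column")
    return (x - x.mean()) / sd
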