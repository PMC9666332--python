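"""The four nested path-model variants and their likelihood/prior machinery.

The structural system under study is a recursive set of linear regressions
among observed, standardised variables:

    rumination     ~ a·parenting [+ w·ES] [+ k·(parenting × ES)]
    depression_9   ~ c1·parenting + b1·rumination
    depression_12  ~ c2·parenting + b2·rumination

with independent normal residuals.  Four nested variants are compared:

* ``null``        — no regression paths; variables modelled as independent
                    normals (variances only).
* ``mediation``   — paths a, b1, b2, c1, c2 (no sensitivity terms).
* ``additive``    — adds the main effect of sensitivity on rumination (w).
* ``interaction`` — adds the parenting × sensitivity product on rumination (k).

Each variant is estimated separately for one of three parenting styles
(permissive, authoritarian, authoritative).  All variables are z-scored with
the sample mean/SD before fitting and the interaction regressor is the product
of the two z-scores (mean-centred, which only absorbs the intercept), so
coefficients are on the standardised scale throughout.

Exogenous variables (parenting, sensitivity, their product) are conditioned
on, not modelled, except in the null model, whose variable scope is
configurable: ``endogenous_only`` matches the substantive models' likelihood
scope; ``all_variables`` additionally models the exogenous block, which
matters only for evidence/IC magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.special import gammaln

from .data import Dataset, zscore
from .errors import (
    InvalidParameterError,
    SchemaError,
    SingularDesignError,
)

__all__ = [
    "VARIANTS",
    "STYLES",
    "ENDOGENOUS",
    "PathModelSpec",
    "PathParams",
    "NormalPrior",
    "GammaPrior",
    "PriorSet",
    "default_priors",
    "build_design",
    "log_likelihood",
    "pointwise_log_likelihood",
    "log_prior",
    "fit_ml",
    "residuals_for_unit_variance",
    "spec_from_config",
]

VARIANTS = ("null", "mediation", "additive", "interaction")
STYLES = ("permissive", "authoritarian", "authoritative")
ENDOGENOUS = ("rumination", "depression_9", "depression_12")
PATH_NAMES = ("a", "w", "k", "c1", "b1", "c2", "b2")

# path -> (endogenous equation, predictor role)
_PATH_EQ = {
    "a": ("rumination", "parenting"),
    "w": ("rumination", "es"),
    "k": ("rumination", "product"),
    "c1": ("depression_9", "parenting"),
    "b1": ("depression_9", "rumination"),
    "c2": ("depression_12", "parenting"),
    "b2": ("depression_12", "rumination"),
}

_VARIANT_PATHS = {
    "null": (),
    "mediation": ("a", "c1", "b1", "c2", "b2"),
    "additive": ("a", "w", "c1", "b1", "c2", "b2"),
    "interaction": ("a", "w", "k", "c1", "b1", "c2", "b2"),
}


@dataclass(frozen=True)
class PathModelSpec:
    """Which arrows of the path diagram are active, and for which style."""

    variant: str = "interaction"
    parenting_style: str = "permissive"
    null_variable_scope: str = "endogenous_only"
    endogenous: tuple = ENDOGENOUS
    exogenous: tuple = ("parenting", "es")

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise InvalidParameterError(f"unknown variant {self.variant!r}")
        if self.parenting_style not in STYLES:
            raise InvalidParameterError(f"unknown style {self.parenting_style!r}")
        if self.null_variable_scope not in ("endogenous_only", "all_variables"):
            raise InvalidParameterError(
                f"unknown null scope {self.null_variable_scope!r}"
            )

    def active_paths(self) -> tuple:
        return _VARIANT_PATHS[self.variant]

    def variable_scope(self) -> tuple:
        """Names of the variables whose density the model evaluates."""
        if self.variant != "null" or self.null_variable_scope == "endogenous_only":
            return self.endogenous
        return ("parenting", "es", "product") + self.endogenous

    def sigma_names(self) -> tuple:
        return tuple(f"sigma_{v}" for v in self.variable_scope())

    def parameter_names(self) -> tuple:
        return self.active_paths() + self.sigma_names()

    def equations(self):
        """Per-endogenous-variable (response, [(predictor role, path)]) pairs."""
        eqs = {v: [] for v in self.endogenous}
        for path in self.active_paths():
            eq, role = _PATH_EQ[path]
            eqs[eq].append((role, path))
        return [(v, eqs[v]) for v in self.endogenous]


@dataclass
class PathParams:
    """Standardised path coefficients and residual variances.

    Paths excluded by a variant are structurally zero; ``resid_var`` is keyed
    by modelled variable name (the three endogenous variables, plus the
    exogenous block under the null model's ``all_variables`` scope).
    """

    a: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    w: float = 0.0
    k: float = 0.0
    resid_var: dict = field(
        default_factory=lambda: {v: 1.0 for v in ENDOGENOUS}
    )

    def path(self, name: str) -> float:
        return getattr(self, name)

    def to_dict(self) -> dict:
        d = {p: getattr(self, p) for p in PATH_NAMES}
        d["resid_var"] = dict(self.resid_var)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PathParams":
        kwargs = {p: d.get(p, 0.0) for p in PATH_NAMES}
        if "resid_var" in d:
            kwargs["resid_var"] = dict(d["resid_var"])
        return cls(**kwargs)


def residuals_for_unit_variance(params: PathParams) -> PathParams:
    """Residual variances that give each endogenous variable unit variance.

    Assumes independent standardised exogenous parenting and sensitivity, for
    which var(P·E) = 1.  Useful for building structural scenarios on the same
    standardised scale as the fitted models.
    """
    p = params
    v_m = p.a**2 + p.w**2 + p.k**2
    if v_m >= 1:
        raise InvalidParameterError("rumination paths imply variance >= 1")
    cov_pm = p.a  # cov(P, M)
    v9 = p.c1**2 + p.b1**2 + 2 * p.c1 * p.b1 * cov_pm
    v12 = p.c2**2 + p.b2**2 + 2 * p.c2 * p.b2 * cov_pm
    if v9 >= 1 or v12 >= 1:
        raise InvalidParameterError("depression paths imply variance >= 1")
    rv = {
        "rumination": 1 - v_m,
        "depression_9": 1 - v9,
        "depression_12": 1 - v12,
    }
    return replace(params, resid_var=rv)


@dataclass(frozen=True)
class NormalPrior:
    loc: float
    scale: float

    def logpdf(self, x: float) -> float:
        if self.scale <= 0:
            raise InvalidParameterError("prior scale must be positive")
        z = (x - self.loc) / self.scale
        return -0.5 * z * z - math.log(self.scale) - 0.5 * math.log(2 * math.pi)


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior for a positive residual-scale quantity."""

    shape: float = 1.0
    rate: float = 0.5

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        return (
            self.shape * math.log(self.rate)
            - gammaln(self.shape)
            + (self.shape - 1) * math.log(x)
            - self.rate * x
        )


@dataclass(frozen=True)
class PriorSet:
    """Per-path normal priors plus the residual prior and its parameterisation.

    ``resid_parameterization`` declares which positive quantity the gamma
    prior is placed on: the residual SD (default, the modern default of the
    Bayesian SEM software family this models), the variance, or the precision.
    ``log_prior`` and the sampler always operate on the residual SD, applying
    the change-of-variables Jacobian as needed.
    """

    paths: dict
    resid: GammaPrior = GammaPrior(1.0, 0.5)
    resid_parameterization: str = "sd"

    def __post_init__(self):
        if self.resid_parameterization not in ("sd", "variance", "precision"):
            raise InvalidParameterError(
                f"unknown residual parameterization {self.resid_parameterization!r}"
            )
        for name, pr in self.paths.items():
            if pr.scale <= 0:
                raise InvalidParameterError(f"prior scale for {name} must be positive")

    def scaled(self, factor: float) -> "PriorSet":
        """All path-prior scales multiplied by ``factor`` (sensitivity checks)."""
        return PriorSet(
            {n: NormalPrior(p.loc, p.scale * factor) for n, p in self.paths.items()},
            self.resid,
            self.resid_parameterization,
        )

    def log_prior_sigma(self, sigma: float) -> float:
        """Log prior density over the residual *SD*, whatever the parameterisation."""
        if sigma <= 0:
            return -math.inf
        if self.resid_parameterization == "sd":
            return self.resid.logpdf(sigma)
        if self.resid_parameterization == "variance":
            return self.resid.logpdf(sigma**2) + math.log(2 * sigma)
        # precision tau = sigma^-2, |d tau / d sigma| = 2 sigma^-3
        return self.resid.logpdf(sigma**-2) + math.log(2.0) - 3 * math.log(sigma)


def default_priors(style: str, variant: str,
                   resid_parameterization: str = "sd") -> PriorSet:
    """The study's informative priors for one parenting style and variant.

    Standardised-scale expectations: a small positive effect of permissive and
    authoritarian parenting (negative for authoritative) on rumination and
    depression; a strong rumination → depression link; a sceptical prior on
    the sensitivity main effect; and a focused positive prior on the
    permissive × sensitivity interaction (weakly informative for the other
    styles).  Residual scales get gamma(1, 0.5).
    """
    if style not in STYLES:
        raise InvalidParameterError(f"unknown style {style!r}")
    if variant not in VARIANTS:
        raise InvalidParameterError(f"unknown variant {variant!r}")
    sign = -1.0 if style == "authoritative" else 1.0
    full = {
        "a": NormalPrior(sign * 0.1, 0.1),
        "c1": NormalPrior(sign * 0.1, 0.1),
        "c2": NormalPrior(sign * 0.05, 0.1),
        "b1": NormalPrior(0.50, 0.10),
        "b2": NormalPrior(0.35, 0.10),
        "w": NormalPrior(0.0, 0.2),
        "k": NormalPrior(0.3, 0.1) if style == "permissive" else NormalPrior(0.0, 1.0),
    }
    active = {p: full[p] for p in _VARIANT_PATHS[variant]}
    return PriorSet(active, GammaPrior(1.0, 0.5), resid_parameterization)


# ---------------------------------------------------------------------------
# design construction


def _resolve_parenting_column(spec: PathModelSpec, df) -> str:
    if spec.parenting_style in df.columns:
        return spec.parenting_style
    if "parenting" in df.columns:
        return "parenting"
    raise SchemaError(
        f"no parenting column: expected {spec.parenting_style!r} or 'parenting'"
    )


class Design:
    """Standardised response/design matrices for one spec on one dataset.

    ``equations`` maps endogenous name -> (y, X, path_names); ``variables``
    maps each in-scope variable name to its standardised column (used by the
    null model and by pointwise likelihoods).
    """

    def __init__(self, spec: PathModelSpec, data: Dataset):
        df = data.df if isinstance(data, Dataset) else data
        self.spec = spec
        self.n = len(df)
        needed = {"rumination", "depression_9", "depression_12"}
        pcol = _resolve_parenting_column(spec, df)
        cols = {}
        for name in needed:
            if name not in df.columns:
                raise SchemaError(f"missing column {name!r}")
            cols[name] = zscore(df[name].to_numpy())
        cols["parenting"] = zscore(df[pcol].to_numpy())
        needs_es = spec.variant in ("additive", "interaction") or (
            spec.variant == "null" and spec.null_variable_scope == "all_variables"
        )
        if needs_es:
            if "es" not in df.columns:
                raise SchemaError("missing column 'es'")
            cols["es"] = zscore(df["es"].to_numpy())
            prod = cols["parenting"] * cols["es"]
            cols["product"] = prod - prod.mean()
        self.columns = cols
        self.equations = {}
        for endo, preds in spec.equations():
            names = [path for _, path in preds]
            X = (
                np.column_stack([cols[role] for role, _ in preds])
                if preds
                else np.empty((self.n, 0))
            )
            self.equations[endo] = (cols[endo], X, names)
        self.scope_vars = {v: cols[v] for v in spec.variable_scope()}

    def gram(self):
        """Sufficient statistics (XtX, Xty, yty, n) per modelled variable."""
        out = {}
        if self.spec.variant == "null":
            for name, z in self.scope_vars.items():
                out[name] = (np.empty((0, 0)), np.empty(0), float(z @ z), self.n, [])
        else:
            for endo, (y, X, names) in self.equations.items():
                out[endo] = (X.T @ X, X.T @ y, float(y @ y), self.n, names)
        return out


def build_design(spec: PathModelSpec, data: Dataset) -> Design:
    return Design(spec, data)


# ---------------------------------------------------------------------------
# likelihood / prior / ML


def _check_resid(params: PathParams, names: Iterable[str]):
    for name in names:
        v = params.resid_var.get(name)
        if v is None:
            raise SchemaError(f"missing residual variance for {name!r}")
        if v <= 0:
            raise ValueError(f"non-positive residual variance for {name!r}")


def log_likelihood(spec: PathModelSpec, params: PathParams, data: Dataset) -> float:
    """Sum of the conditional normal log-densities of the modelled variables."""
    design = data if isinstance(data, Design) else build_design(spec, data)
    _check_resid(params, spec.variable_scope())
    total = 0.0
    if spec.variant == "null":
        for name, z in design.scope_vars.items():
            v = params.resid_var[name]
            n = z.size
            total += -0.5 * n * math.log(2 * math.pi * v) - (z @ z) / (2 * v)
        return total
    for endo, (y, X, names) in design.equations.items():
        beta = np.array([params.path(p) for p in names])
        resid = y - X @ beta if names else y
        v = params.resid_var[endo]
        total += -0.5 * y.size * math.log(2 * math.pi * v) - (resid @ resid) / (2 * v)
    return total


def pointwise_log_likelihood(spec: PathModelSpec, draws: np.ndarray,
                             parameter_names: Iterable[str],
                             data: Dataset) -> np.ndarray:
    """Per-observation log-likelihood for every posterior draw.

    ``draws`` is an (S, P) array over ``parameter_names`` (paths followed by
    ``sigma_<variable>`` entries).  Returns an (S, n) matrix — the input to
    PSIS-LOO.
    """
    design = data if isinstance(data, Design) else build_design(spec, data)
    names = list(parameter_names)
    idx = {name: i for i, name in enumerate(names)}
    S = draws.shape[0]
    out = np.zeros((S, design.n))
    if spec.variant == "null":
        items = [(name, design.scope_vars[name], []) for name in design.scope_vars]
    else:
        items = [
            (endo, y, list(zip(pnames, X.T)))
            for endo, (y, X, pnames) in design.equations.items()
        ]
    for var, y, preds in items:
        sig = draws[:, idx[f"sigma_{var}"]]
        mu = np.zeros((S, design.n))
        for pname, xcol in preds:
            mu += draws[:, [idx[pname]]] * xcol[None, :]
        resid = y[None, :] - mu
        out += (
            -0.5 * np.log(2 * math.pi * sig**2)[:, None]
            - resid**2 / (2 * sig**2)[:, None]
        )
    return out


def log_prior(params: PathParams, priors: PriorSet) -> float:
    """Log prior density over the active paths and residual SDs.

    Returns −inf (not an exception) when any residual variance is outside the
    support.
    """
    total = 0.0
    for name, prior in priors.paths.items():
        total += prior.logpdf(params.path(name))
    for v in params.resid_var.values():
        if v <= 0:
            return -math.inf
        total += priors.log_prior_sigma(math.sqrt(v))
    return total


def fit_ml(spec: PathModelSpec, data: Dataset) -> PathParams:
    """Maximum-likelihood point estimates (per-equation least squares).

    Because the system is recursive with independent residuals, ML equals
    equation-by-equation OLS; residual variances are the ML (1/n) values.
    Serves as the frequentist oracle for the MCMC machinery.
    """
    design = data if isinstance(data, Design) else build_design(spec, data)
    params = PathParams(resid_var={})
    if spec.variant == "null":
        for name, z in design.scope_vars.items():
            params.resid_var[name] = float(z @ z) / z.size
        return params
    for endo, (y, X, names) in design.equations.items():
        if names:
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise SingularDesignError(f"collinear predictors in {endo} equation")
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            for p, b in zip(names, beta):
                setattr(params, p, float(b))
            resid = y - X @ beta
        else:
            resid = y
        params.resid_var[endo] = float(resid @ resid) / y.size
    return params


def spec_from_config(cfg: dict) -> tuple:
    """Build (PathModelSpec, PriorSet) from a plain config mapping.

    Recognised keys: ``style``, ``variant``, ``null_variable_scope``,
    ``resid_parameterization``, and ``priors`` — a mapping of path name to
    ``[loc, scale]`` overriding the defaults.
    """
    spec = PathModelSpec(
        variant=cfg.get("variant", "interaction"),
        parenting_style=cfg.get("style", "permissive"),
        null_variable_scope=cfg.get("null_variable_scope", "endogenous_only"),
    )
    priors = default_priors(
        spec.parenting_style,
        spec.variant,
        cfg.get("resid_parameterization", "sd"),
    )
    overrides = cfg.get("priors", {})
    if overrides:
        paths = dict(priors.paths)
        for name, (loc, scale) in overrides.items():
            if name not in paths:
                raise SchemaError(f"prior override for inactive path {name!r}")
            paths[name] = NormalPrior(float(loc), float(scale))
        priors = PriorSet(paths, priors.resid, priors.resid_parameterization)
    return spec, priors
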