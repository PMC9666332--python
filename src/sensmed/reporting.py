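"""Descriptives, reliability, and the end-to-end analysis pipeline.

``describe`` mirrors the study's descriptive table (means, SDs with the n−1
denominator, Pearson correlations); ``cronbach_alpha`` computes internal
consistency with a Feldt F-distribution confidence interval; ``run_pipeline``
composes simulate → fit → compare → effects for one or more parenting styles
and writes JSON/CSV reports with full provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import comparison, effects, inference
from .data import Dataset, MomentSummary, generate_mvn, study_moments
from .errors import (
    ConfigError,
    DegenerateDataError,
    InvalidParameterError,
    UndefinedReliabilityError,
)
from .models import (
    STYLES,
    VARIANTS,
    PathModelSpec,
    default_priors,
)

__all__ = [
    "ReliabilityResult",
    "RunConfig",
    "cronbach_alpha",
    "describe",
    "run_pipeline",
]


@dataclass
class ReliabilityResult:
    """Cronbach's alpha with a confidence interval."""

    alpha: float
    ci_low: float
    ci_high: float
    confidence: float
    n: int
    n_items: int

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "confidence": self.confidence,
            "n": self.n,
            "n_items": self.n_items,
        }


def cronbach_alpha(items, confidence: float = 0.95,
                   method: str = "feldt", n_boot: int = 2000,
                   seed: int = 0) -> ReliabilityResult:
    """Internal-consistency reliability of a multi-item scale.

    alpha = k/(k−1) · (1 − Σ item variances / total-score variance).  The
    default interval is the Feldt F-distribution interval; ``method='bootstrap'``
    resamples respondents instead.
    """
    df = items.df if isinstance(items, Dataset) else pd.DataFrame(items)
    X = df.to_numpy(dtype=float)
    n, k = X.shape
    if k < 2:
        raise InvalidParameterError("need at least 2 items")
    if n < 3:
        raise InvalidParameterError("need at least 3 respondents")
    if np.isnan(X).any():
        raise InvalidParameterError("missing values are not supported")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedReliabilityError("total-score variance is zero")
    item_var = X.var(axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1 - item_var / total_var)
    gamma = 1 - confidence
    if method == "feldt":
        df1, df2 = n - 1, (n - 1) * (k - 1)
        lo = 1 - (1 - alpha) * stats.f.ppf(1 - gamma / 2, df1, df2)
        hi = 1 - (1 - alpha) * stats.f.ppf(gamma / 2, df1, df2)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            Xb = X[idx]
            tv = Xb.sum(axis=1).var(ddof=1)
            boots[b] = (
                k / (k - 1) * (1 - Xb.var(axis=0, ddof=1).sum() / tv)
                if tv > 0 else np.nan
            )
        lo, hi = np.nanquantile(boots, [gamma / 2, 1 - gamma / 2])
    else:
        raise InvalidParameterError(f"unknown CI method {method!r}")
    return ReliabilityResult(float(alpha), float(lo), float(hi),
                             confidence, n, k)


def describe(data) -> MomentSummary:
    """Sample means, SDs (n−1 denominator) and Pearson correlations."""
    df = data.df if isinstance(data, Dataset) else pd.DataFrame(data)
    sds = df.std(ddof=1)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise DegenerateDataError(f"constant columns have undefined correlations: {bad}")
    return MomentSummary(
        tuple(df.columns),
        df.mean().to_numpy(),
        sds.to_numpy(),
        np.corrcoef(df.to_numpy(), rowvar=False),
        len(df),
    )


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    seed: int
    input_path: str | None = None
    styles: tuple = STYLES
    variants: tuple = ("null", "mediation", "additive", "interaction")
    chains: int = 4
    iterations: int = 8000
    null_variable_scope: str = "all_variables"
    weights_method: str = "pseudo_bma_plus"
    evidence_method: str = "laplace"
    n: int | None = None
    exact: bool = True
    output_dir: str | None = None
    verbosity: int = 1

    def __post_init__(self):
        if not self.styles:
            raise ConfigError("at least one style is required")
        if not self.variants:
            raise ConfigError("at least one variant is required")
        for s in self.styles:
            if s not in STYLES:
                raise ConfigError(f"unknown style {s!r}")
        for v in self.variants:
            if v not in VARIANTS:
                raise ConfigError(f"unknown variant {v!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "seed" not in raw:
            raise ConfigError("config must be a mapping with a 'seed' key")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("styles", "variants"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_or_generate(config: RunConfig) -> Dataset:
    if config.input_path is not None:
        return Dataset.from_csv(config.input_path)
    moments = study_moments()
    return generate_mvn(moments, n=config.n or moments.n, seed=config.seed,
                        exact=config.exact)


def _fit_style(style: str, config: RunConfig, data: Dataset) -> dict:
    entries = []
    fits = {}
    for variant in config.variants:
        spec = PathModelSpec(
            variant=variant,
            parenting_style=style,
            null_variable_scope=config.null_variable_scope,
        )
        priors = default_priors(style, variant)
        samples = inference.fit_mcmc(
            spec, priors, data, chains=config.chains,
            iterations=config.iterations, seed=config.seed,
        )
        fits[variant] = (spec, priors, samples)
        entries.append(
            {"label": variant, "spec": spec, "priors": priors, "samples": samples}
        )
    rows = comparison.compare_models(
        entries, data, weights_method=config.weights_method,
        evidence_method=config.evidence_method, seed=config.seed,
        allow_scope_mismatch=config.null_variable_scope == "all_variables",
    )
    substantive = [r for r in rows if r.model_id != "null"] or rows
    best_label = min(substantive, key=lambda r: r.loo_ic).model_id
    spec, priors, samples = fits[best_label]

    result = {
        "comparison": [r.to_dict() for r in rows],
        "best_model": best_label,
        "psrf": samples.sampler_meta.get("psrf", {}),
    }
    if spec.variant != "null":
        summaries = inference.summarize(samples)
        result["effects"] = [s.to_dict() for s in summaries]
        result["r_squared"] = [
            s.to_dict() for s in effects.r_squared(spec, samples, data)
        ]
        result["indirect"] = [s.to_dict() for s in effects.indirect_effects(samples)]
        if spec.variant == "interaction":
            result["conditional_indirect"] = [
                s.to_dict() for s in effects.conditional_indirect_effects(samples)
            ]
            slopes = effects.simple_slopes(samples, data)
            result["simple_slopes"] = {
                g.group: {
                    "es_reference": g.es_reference,
                    "slope": g.slope,
                    "slope_hpdi": list(g.slope_hpdi),
                    "curve": g.curve.to_dict(orient="list"),
                }
                for g in slopes
            }
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Simulate/load → fit all requested variants → compare → effects.

    Returns a JSON-serialisable report bundle; when ``config.output_dir`` is
    set, writes ``report.json`` plus per-style comparison/effects CSV tables
    (rounded to two decimals, full precision in the JSON).
    """
    data = _load_or_generate(config)
    report = {
        "provenance": {
            "seed": config.seed,
            "n": data.n,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in config.__dict__.items()
            },
            "data_meta": data.meta,
        },
        "styles": {},
    }
    for style in config.styles:
        if config.verbosity:
            print(f"[sensmed] fitting {len(config.variants)} variants for {style}")
        report["styles"][style] = _fit_style(style, config, data)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        for style, block in report["styles"].items():
            pd.DataFrame(block["comparison"]).round(2).to_csv(
                out / f"comparison_{style}.csv", index=False
            )
            if "effects" in block:
                pd.DataFrame(block["effects"]).round(2).to_csv(
                    out / f"effects_{style}.csv", index=False
                )
    return report
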