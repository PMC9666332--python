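"""Effect interpretation: ROPE overlap, indirect effects, R², group slopes.

Posterior effects are summarised by their mean, a 90% highest posterior
density interval (HPDI), and the overlap index

    I = 1 − |HPDI ∩ ROPE| / |HPDI|

against a region of practical equivalence (ROPE): I = 1 means the credible
interval lies wholly outside the ROPE (full support for a non-null effect),
I = 0 means it lies wholly inside (practical equivalence to zero).  The ROPE
is (−0.1, 0.1) for direct standardised effects and is tightened to
(−0.01, 0.01) and (−0.02, 0.02) for indirect and conditional indirect
effects, which are products of direct paths.

Derived effects are computed draw-wise (the mean of a product, never the
product of means): the indirect effects are a·b1 and a·b2; the conditional
indirect effects follow the convention (a + k·e)·b with the moderator one
standardised unit above its mean (e = 1) by default, i.e. (a + k)·b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset
from .errors import (
    InvalidParameterError,
    NotApplicableError,
    SchemaError,
)
from .inference import PosteriorSamples, hpdi
from .models import PathModelSpec, build_design

__all__ = [
    "EffectSummary",
    "GroupPrediction",
    "rope_index",
    "sample_rope_index",
    "default_rope",
    "summarize_draws",
    "indirect_effects",
    "conditional_indirect_effects",
    "r_squared",
    "simple_slopes",
]

_ROPES = {
    "direct": (-0.1, 0.1),
    "indirect": (-0.01, 0.01),
    "conditional_indirect": (-0.02, 0.02),
}


@dataclass
class EffectSummary:
    """Posterior mean, 90% HPDI and ROPE overlap for one (derived) effect."""

    name: str
    posterior_mean: float
    hpdi: tuple
    rope: tuple | None = None
    overlap_index: float | None = None

    def __post_init__(self):
        lo, hi = self.hpdi
        if lo > hi:
            raise InvalidParameterError("HPDI endpoints inverted")
        if self.overlap_index is not None and not 0 <= self.overlap_index <= 1:
            raise InvalidParameterError("overlap index must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "posterior_mean": self.posterior_mean,
            "hpdi_low": self.hpdi[0],
            "hpdi_high": self.hpdi[1],
            "rope_low": None if self.rope is None else self.rope[0],
            "rope_high": None if self.rope is None else self.rope[1],
            "overlap_index": self.overlap_index,
        }


@dataclass
class GroupPrediction:
    """Predicted rumination for one sensitivity extreme group.

    ``slope`` is the posterior mean of a + k·ē where ē is the group's mean
    standardised sensitivity; ``curve`` tabulates the predicted response over
    the observed parenting range with a 90% HPD band.
    """

    group: str
    es_reference: float
    slope: float
    slope_hpdi: tuple
    curve: pd.DataFrame


def default_rope(effect_class: str) -> tuple:
    """ROPE bounds for a class of standardised effect."""
    try:
        return _ROPES[effect_class]
    except KeyError:
        raise InvalidParameterError(
            f"unknown effect class {effect_class!r}; expected one of {sorted(_ROPES)}"
        ) from None


def rope_index(hpdi_interval, rope) -> float:
    """Overlap index I = 1 − |HPDI ∩ ROPE| / |HPDI|, clipped to [0, 1].

    A zero-width HPDI (degenerate posterior) gives 0 if the point lies inside
    the ROPE and 1 otherwise.
    """
    lo, hi = map(float, hpdi_interval)
    rlo, rhi = map(float, rope)
    if lo > hi or rlo > rhi:
        raise InvalidParameterError("interval endpoints inverted")
    if hi == lo:
        return 0.0 if rlo <= lo <= rhi else 1.0
    inter = max(0.0, min(hi, rhi) - max(lo, rlo))
    return float(np.clip(1.0 - inter / (hi - lo), 0.0, 1.0))


def sample_rope_index(draws, rope, mass: float = 0.9) -> float:
    """Sample-proportion variant: share of HPDI draws outside the ROPE.

    Published overlap values are occasionally one rounding step away from the
    interval-arithmetic result computed from rounded endpoints; this variant
    works from the draws themselves.
    """
    rlo, rhi = rope
    lo, hi = hpdi(draws, mass)
    d = np.asarray(draws, dtype=float).ravel()
    inside_hpdi = d[(d >= lo) & (d <= hi)]
    if inside_hpdi.size == 0:
        return 0.0
    in_rope = np.mean((inside_hpdi >= rlo) & (inside_hpdi <= rhi))
    return float(1.0 - in_rope)


def summarize_draws(name: str, draws, effect_class: str = "direct",
                    mass: float = 0.9) -> EffectSummary:
    """Summarise a vector of draws as an :class:`EffectSummary`."""
    rope = default_rope(effect_class)
    interval = hpdi(draws, mass)
    return EffectSummary(
        name,
        float(np.mean(draws)),
        interval,
        rope,
        rope_index(interval, rope),
    )


def _require(samples: PosteriorSamples, names) -> None:
    missing = [n for n in names if n not in samples.parameter_names]
    if missing:
        raise SchemaError(f"samples lack required paths: {missing}")


def indirect_effects(samples: PosteriorSamples, mass: float = 0.9):
    """Draw-wise mediated effects a·b1 (age 9) and a·b2 (age 12)."""
    _require(samples, ["a", "b1", "b2"])
    a = samples.get("a")
    return [
        summarize_draws("indirect_depression_9", a * samples.get("b1"),
                        "indirect", mass),
        summarize_draws("indirect_depression_12", a * samples.get("b2"),
                        "indirect", mass),
    ]


def conditional_indirect_effects(samples: PosteriorSamples, mass: float = 0.9,
                                 at_sensitivity: float = 1.0):
    """Draw-wise conditional mediated effects (a + k·e)·b1 and (a + k·e)·b2.

    The default ``at_sensitivity=1`` evaluates the indirect effect for a child
    one standardised unit above mean sensitivity, giving the conventional
    (a + k)·b form.
    """
    _require(samples, ["a", "k", "b1", "b2"])
    mod = samples.get("a") + samples.get("k") * at_sensitivity
    return [
        summarize_draws("conditional_indirect_depression_9",
                        mod * samples.get("b1"), "conditional_indirect", mass),
        summarize_draws("conditional_indirect_depression_12",
                        mod * samples.get("b2"), "conditional_indirect", mass),
    ]


def r_squared(spec: PathModelSpec, samples: PosteriorSamples, data: Dataset,
              mass: float = 0.9):
    """Draw-wise explained variance per endogenous variable with 90% HPDI.

    For each draw the proportion is var(Xβ)/(var(Xβ) + σ²), the Bayesian
    R² of the fitted linear predictor.
    """
    design = build_design(spec, data)
    out = []
    for endo, (y, X, names) in design.equations.items():
        if not names:
            r2 = np.zeros(samples.flat.shape[0])
        else:
            B = np.column_stack([samples.get(p) for p in names])  # (S, p)
            S_x = np.cov(X, rowvar=False, ddof=1).reshape(len(names), len(names))
            v_fit = np.einsum("sp,pq,sq->s", B, S_x, B)
            sig2 = samples.get(f"sigma_{endo}") ** 2
            r2 = v_fit / (v_fit + sig2)
        interval = hpdi(r2, mass) if r2.std() > 0 else (0.0, 0.0)
        out.append(EffectSummary(f"r2_{endo}", float(r2.mean()), interval))
    return out


def simple_slopes(samples: PosteriorSamples, data: Dataset, tail: float = 0.30,
                  mass: float = 0.9, group_reference: str = "empirical_mean",
                  grid_points: int = 25):
    """Moderated parenting → rumination slopes for sensitivity extreme groups.

    Children are split at the bottom/top ``tail`` of the observed sensitivity
    distribution; each group's slope is a + k·ē where ē is either the group's
    mean standardised sensitivity (``group_reference='empirical_mean'``) or
    the tail cutoff value (``'cutoff'``).  Returns (low, high)
    :class:`GroupPrediction` with predicted curves over the observed
    standardised parenting range.
    """
    if "k" not in samples.parameter_names:
        raise NotApplicableError("simple slopes require an interaction model")
    if not 0 < tail < 0.5:
        raise InvalidParameterError("tail must be in (0, 0.5)")
    _require(samples, ["a", "k"])
    from .data import zscore

    df = data.df if isinstance(data, Dataset) else data
    if "es" not in df.columns:
        raise SchemaError("missing column 'es'")
    es = zscore(df["es"].to_numpy())
    lo_cut = np.quantile(es, tail)
    hi_cut = np.quantile(es, 1 - tail)
    refs = {}
    if group_reference == "empirical_mean":
        refs["low"] = float(es[es <= lo_cut].mean())
        refs["high"] = float(es[es >= hi_cut].mean())
    elif group_reference == "cutoff":
        refs["low"], refs["high"] = float(lo_cut), float(hi_cut)
    else:
        raise InvalidParameterError(f"unknown group reference {group_reference!r}")

    a = samples.get("a")
    k = samples.get("k")
    w = (samples.get("w") if "w" in samples.parameter_names
         else np.zeros_like(a))
    # parenting grid on the standardised scale of the style actually fitted
    pcols = [c for c in ("permissive", "authoritarian", "authoritative", "parenting")
             if c in df.columns]
    pz = zscore(df[pcols[0]].to_numpy())
    grid = np.linspace(pz.min(), pz.max(), grid_points)

    out = []
    for group in ("low", "high"):
        e = refs[group]
        slope_draws = a + k * e
        pred = slope_draws[:, None] * grid[None, :] + (w * e)[:, None]
        bands = np.array([hpdi(pred[:, g], mass) for g in range(grid_points)])
        curve = pd.DataFrame(
            {
                "parenting": grid,
                "group": group,
                "mean": pred.mean(axis=0),
                "band_low": bands[:, 0],
                "band_high": bands[:, 1],
            }
        )
        out.append(
            GroupPrediction(
                group, e, float(slope_draws.mean()), hpdi(slope_draws, mass), curve
            )
        )
    return out
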