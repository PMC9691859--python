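"""Synthetic deceased-patient cohort generator.

Emulates the statistical structure of a registry extraction of deceased
metastatic lung-cancer patients: diagnosis years over a configurable range, a
discrete survival-month distribution concentrated in the first three years
(constant per-month hazard, i.e. geometric), and a multinomial cause-of-death
distribution with a planted era-dependent shift in the non-cancer mix plus
multiplicative covariate effects.

Every record is a death; living (censored) patients are not simulated.  The
defaults plant the study conditions the downstream analyses are designed to
detect: the non-cancer share of deaths rises from 5% to 8% at the shift year,
compensated by a lung-cancer decrease, and survival improves modestly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .records import AGE_GROUPS, RACES, RECORD_COLUMNS, SEXES
from .taxonomy import CauseGroup, CauseTaxonomy, default_taxonomy

__all__ = ["CohortConfig", "default_config", "generate_cohort"]


class ConfigurationError(ValueError):
    """An invalid generator configuration, naming the offending field."""


#: Default pre-era cause mix (sums to 1): lung 0.86, other cancers 0.07,
#: non-cancer 0.05, unknown 0.02.
_PRE_MIX: dict[str, float] = {
    "lung cancer": 0.86,
    "colon cancer": 0.020,
    "liver cancer": 0.010,
    "nervous system cancer": 0.010,
    "other cancers": 0.030,
    "heart diseases": 0.013,
    "COPD": 0.008,
    "cerebrovascular disease": 0.005,
    "pneumonia and influenza": 0.004,
    "septicemia": 0.003,
    "other infectious diseases": 0.003,
    "accidents and adverse effects": 0.004,
    "hypertension": 0.002,
    "chronic liver disease and cirrhosis": 0.002,
    "diabetes mellitus": 0.006,
    "unknown": 0.02,
}


def _post_mix() -> dict[str, float]:
    """Post-shift mix: non-cancer share 0.05 -> 0.08 (×1.6 per cause),
    compensated entirely by the lung-cancer share."""
    tax = default_taxonomy()
    mix = dict(_PRE_MIX)
    extra = 0.0
    for c in tax.labels_in_group(CauseGroup.NON_CANCER):
        bump = mix[c] * 0.6
        mix[c] += bump
        extra += bump
    mix["lung cancer"] -= extra
    return mix


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters.

    ``survival_hazard_pre``/``_post`` are the constant per-month death
    hazards; diagnosis years are uniform over ``year_range``.  ``covariate_rr``
    maps a covariate level (e.g. ``">=60"``, ``"male"``, ``"chemotherapy"``)
    to per-cause multiplicative rate modifiers applied to the era's mix and
    renormalized; ``covariate_rr_post`` optionally overrides it after the
    shift year, giving covariates era-dependent effects.

    ``transition_years`` (inclusive interval) optionally blends the two mixes
    and hazards linearly across an ambiguous adoption window.
    """

    n_records: int = 200_000
    year_range: tuple[int, int] = (2000, 2018)
    shift_year: int = 2015
    cause_mix_pre: Mapping[str, float] = field(default_factory=lambda: dict(_PRE_MIX))
    cause_mix_post: Mapping[str, float] = field(default_factory=_post_mix)
    survival_hazard_pre: float = 0.066
    survival_hazard_post: float = 0.055
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {
            "female": 0.45,
            ">=60": 0.65,
            "black": 0.11,
            "AI/AN/AP": 0.09,
            "radiotherapy": 0.40,
            "chemotherapy": 0.45,
        }
    )
    covariate_rr: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            ">=60": {
                "heart diseases": 1.8,
                "COPD": 1.6,
                "cerebrovascular disease": 1.6,
                "diabetes mellitus": 1.5,
            },
            "male": {"heart diseases": 1.3, "chronic liver disease and cirrhosis": 1.4},
        }
    )
    covariate_rr_post: Mapping[str, Mapping[str, float]] | None = None
    transition_years: tuple[int, int] | None = None
    seed: int = 0
    taxonomy: CauseTaxonomy = field(default_factory=default_taxonomy)

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ConfigurationError("n_records must be >= 0")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigurationError("year_range must be an inclusive (lo, hi) interval")
        for name in ("cause_mix_pre", "cause_mix_post"):
            mix = getattr(self, name)
            if set(mix) != set(self.taxonomy.categories):
                raise ConfigurationError(f"{name} keys must match the taxonomy labels")
            vals = np.array([mix[c] for c in self.taxonomy.categories], dtype=float)
            if (vals < 0).any():
                raise ConfigurationError(f"{name} has negative entries")
            if abs(vals.sum() - 1.0) > 1e-12:
                raise ConfigurationError(f"{name} must sum to 1 (got {vals.sum():.15f})")
        for name in ("survival_hazard_pre", "survival_hazard_post"):
            h = getattr(self, name)
            if not (0.0 < h <= 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1]")
        for level, p in self.covariate_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"covariate_prevalences[{level!r}] not a probability")

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)


def default_config(**overrides) -> CohortConfig:
    """The default study conditions (planted non-cancer shift at 2015)."""
    return CohortConfig(**overrides)


def _mix_matrix(cfg: CohortConfig, years: np.ndarray) -> np.ndarray:
    """Per-record base cause-probability rows given diagnosis years."""
    cats = cfg.taxonomy.categories
    pre = np.array([cfg.cause_mix_pre[c] for c in cats])
    post = np.array([cfg.cause_mix_post[c] for c in cats])
    w = _post_weight(cfg, years)
    return (1.0 - w)[:, None] * pre + w[:, None] * post


def _post_weight(cfg: CohortConfig, years: np.ndarray) -> np.ndarray:
    """Blend weight of the post-shift regime per year (0 pre, 1 post)."""
    w = (years >= cfg.shift_year).astype(float)
    if cfg.transition_years is not None:
        lo, hi = cfg.transition_years
        span = hi - lo + 2
        in_win = (years >= lo) & (years <= hi)
        w = np.where(in_win, (years - lo + 1) / span, w)
    return w


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw ``config.n_records`` death records; identical seed, identical output.

    Survival months are geometric with the era's hazard (blended across any
    transition window); the cause is multinomial from the era mix modified
    multiplicatively by the record's covariate levels and renormalized.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_records
    cats = list(cfg.taxonomy.categories)
    if n == 0:
        return pd.DataFrame(columns=list(RECORD_COLUMNS))

    lo, hi = cfg.year_range
    years = rng.integers(lo, hi + 1, size=n)
    w_post = _post_weight(cfg, years)
    hazard = (1.0 - w_post) * cfg.survival_hazard_pre + w_post * cfg.survival_hazard_post
    months = rng.geometric(hazard) - 1  # completed months, support 0,1,2,...

    prev = cfg.covariate_prevalences
    sex = np.where(rng.random(n) < prev.get("female", 0.5), "female", "male")
    age = np.where(rng.random(n) < prev.get(">=60", 0.5), ">=60", "<60")
    u = rng.random(n)
    p_black = prev.get("black", 0.1)
    p_aian = prev.get("AI/AN/AP", 0.1)
    race = np.where(u < p_black, "black", np.where(u < p_black + p_aian, "AI/AN/AP", "white"))
    radio = rng.random(n) < prev.get("radiotherapy", 0.5)
    chemo = rng.random(n) < prev.get("chemotherapy", 0.5)

    probs = _mix_matrix(cfg, years)
    rr_pre = cfg.covariate_rr
    rr_post = cfg.covariate_rr_post if cfg.covariate_rr_post is not None else rr_pre

    def level_mask(level: str) -> np.ndarray:
        if level in SEXES:
            return sex == level
        if level in AGE_GROUPS:
            return age == level
        if level in RACES:
            return race == level
        if level == "radiotherapy":
            return radio
        if level == "chemotherapy":
            return chemo
        raise ConfigurationError(f"covariate_rr level {level!r} not a known covariate level")

    cat_index = {c: k for k, c in enumerate(cats)}
    for era_rr, era_w in ((rr_pre, 1.0 - w_post), (rr_post, w_post)):
        for level, modifiers in era_rr.items():
            mask = level_mask(level)
            for cause, factor in modifiers.items():
                if cause not in cat_index:
                    raise ConfigurationError(f"covariate_rr cause {cause!r} not in taxonomy")
                k = cat_index[cause]
                # blend the multiplier across any transition window
                eff = 1.0 + (factor - 1.0) * era_w[mask]
                probs[mask, k] *= eff
    probs /= probs.sum(axis=1, keepdims=True)

    cum = np.cumsum(probs, axis=1)
    draw = rng.random(n)
    cause_idx = (cum > draw[:, None]).argmax(axis=1)
    cause = np.asarray(cats, dtype=object)[cause_idx]

    df = pd.DataFrame(
        {
            "diagnosis_year": years.astype(int),
            "survival_months": months.astype(int),
            "cause": cause,
            "sex": sex,
            "age_group": age,
            "race": race,
            "radiotherapy": radio,
            "chemotherapy": chemo,
        },
        columns=list(RECORD_COLUMNS),
    )
    return df
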