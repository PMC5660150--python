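"""Synthetic study-level datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes: for
study i, moderators are drawn from configurable marginal distributions, the
true study mean is

.. math:: \\mu_i = \\beta_0 + \\sum_j \\beta_j x_{ij} + u_i, \\qquad
          u_i \\sim N(0, \\tau^2_{true}),

and the observed arm mean is :math:`\\bar y_i \\sim N(\\mu_i, sd^2/n_i)` with
the reported per-arm SD equal to ``sd_within`` exactly (a chi-square "noisy
SD" option exists but is off by default, keeping the sampling-variance
formula v_i = sd^2/n transparent for oracle tests).  Observed means are
clamped to [0, 100] with a logged count — clamping distorts the linear model,
so simulation studies should stay in regimes where it does not trigger.

Deaths are Binomial(total, p) with p a logistic function of configured
moderator effects around a base rate; a configurable fraction of records
carries a second-stage (deaths2, total2) measurement.

Defaults mirror the scale of the real evidence base: ~165 comparisons per
outcome, raw-mean percentage outcomes around 49.8% (infarct/area-at-risk),
arm sizes of a handful of animals, substantial between-study heterogeneity,
unbalanced categorical moderators including explicit "unknown" levels,
scarce age/weight reporting, and a peri-procedural death rate near 16.7%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .data_io import (
    CATEGORICAL_LEVELS,
    Dataset,
    MortalityRecord,
    StudyArm,
)
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

#: marginal level probabilities mirroring the composition of a typical
#: large-animal MI evidence base (heavily dog/pig, mostly temporary LAD
#: occlusion, many unreported sexes)
DEFAULT_LEVEL_PROBABILITIES: Dict[str, Dict[str, float]] = {
    "species": {"dog": 0.74, "pig": 0.25, "sheep": 0.01},
    "strain": {"regular_pig": 0.60, "minipig": 0.05, "unreported": 0.35},
    "sex": {"male": 0.27, "female": 0.07, "both": 0.47, "unknown": 0.19},
    "occlusion": {"permanent": 0.10, "temporary": 0.88, "unknown": 0.02},
    "vessel": {"LAD": 0.65, "LCX": 0.32, "LAD_LCX": 0.02, "RCA": 0.005, "unknown": 0.005},
    "approach": {"open": 0.78, "closed": 0.21, "unknown": 0.01},
    "comedication": {"no": 0.96, "yes": 0.04},
    "immunosuppression": {"no": 0.98, "yes": 0.02},
    "quantification": {"TTC": 0.85, "nitro_blue": 0.06, "planimetry": 0.07, "other": 0.02},
}

#: common follow-up durations (hours): 1 day to 8 weeks
DEFAULT_FOLLOW_UP_CHOICES = (24.0, 48.0, 72.0, 168.0, 336.0, 672.0, 1344.0)
#: common ischemia durations (minutes) for temporary occlusion
DEFAULT_ISCHEMIA_CHOICES = (40.0, 45.0, 60.0, 75.0, 90.0)


@dataclass
class SyntheticConfig:
    """Ground-truth configuration for one synthetic outcome dataset.

    ``true_betas`` keys are either ``"moderator:level"`` for a categorical
    level effect (percentage points added when the study is at that level) or
    a continuous moderator name (points per canonical unit, e.g. points/hour
    for follow_up_hours).
    """

    k_studies: int = 165
    outcome: str = "IS_AAR"
    true_intercept: float = 49.8
    true_betas: Dict[str, float] = field(default_factory=dict)
    tau2_true: float = 100.0
    n_range: Tuple[int, int] = (4, 12)
    sd_within: float = 12.0
    level_probabilities: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LEVEL_PROBABILITIES.items()}
    )
    missingness_rates: Dict[str, float] = field(
        default_factory=lambda: {"weight_kg": 0.04, "age_weeks": 0.97}
    )
    mortality_base_rate: float = 0.167
    post_mortality_base_rate: float = 0.052
    mortality_logit_effects: Dict[str, float] = field(default_factory=dict)
    mortality_n_range: Tuple[int, int] = (10, 30)
    second_stage_fraction: float = 0.1
    follow_up_choices: Tuple[float, ...] = DEFAULT_FOLLOW_UP_CHOICES
    ischemia_choices: Tuple[float, ...] = DEFAULT_ISCHEMIA_CHOICES
    quality_score_range: Tuple[int, int] = (3, 8)
    weight_mean_kg: float = 35.0
    weight_sd_kg: float = 12.0
    age_mean_weeks: float = 20.0
    age_sd_weeks: float = 8.0
    noisy_sd: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.k_studies < 1:
            raise ConfigurationError("k_studies must be positive")
        if self.tau2_true < 0:
            raise ConfigurationError("tau2_true must be >= 0")
        if self.sd_within < 0:
            raise ConfigurationError("sd_within must be >= 0")
        if self.n_range[0] < 2 or self.n_range[1] < self.n_range[0]:
            raise ConfigurationError("n_range lower bound must be >= 2 and ordered")
        for name, probs in self.level_probabilities.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-8:
                raise ConfigurationError(f"probabilities for {name!r} sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"negative probability for {name!r}")
        for name, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"missingness rate for {name!r} outside [0, 1]")
        for rate in (self.mortality_base_rate, self.post_mortality_base_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("mortality rates must lie in [0, 1]")


def _draw_level(rng: np.random.Generator, probs: Dict[str, float]) -> str:
    names = sorted(probs)
    p = np.array([probs[n] for n in names])
    return names[int(rng.choice(len(names), p=p / p.sum()))]


def _draw_moderators(rng: np.random.Generator, config: SyntheticConfig) -> dict:
    lp = config.level_probabilities
    mods = {name: _draw_level(rng, lp[name]) for name in
            ("species", "sex", "occlusion", "vessel", "approach", "quantification")
            if name in lp}
    mods["comedication"] = _draw_level(rng, lp["comedication"]) == "yes"
    mods["immunosuppression"] = _draw_level(rng, lp["immunosuppression"]) == "yes"
    mods["strain"] = (
        _draw_level(rng, lp["strain"]) if mods.get("species") == "pig" else None
    )
    mods["follow_up_hours"] = float(rng.choice(config.follow_up_choices))
    mods["ischemia_minutes"] = (
        float(rng.choice(config.ischemia_choices)) if mods.get("occlusion") == "temporary" else None
    )
    mods["quality_score"] = int(rng.integers(config.quality_score_range[0], config.quality_score_range[1] + 1))
    miss = config.missingness_rates
    mods["weight_kg"] = (
        None
        if rng.random() < miss.get("weight_kg", 0.0)
        else float(max(1.0, rng.normal(config.weight_mean_kg, config.weight_sd_kg)))
    )
    mods["age_weeks"] = (
        None
        if rng.random() < miss.get("age_weeks", 0.0)
        else float(max(1.0, rng.normal(config.age_mean_weeks, config.age_sd_weeks)))
    )
    if rng.random() < miss.get("ischemia_minutes", 0.0):
        mods["ischemia_minutes"] = None
    mods["vf_excluded_untreated"] = bool(rng.random() < 0.1)
    return mods


def _linear_effect(mods: dict, betas: Dict[str, float]) -> float:
    total = 0.0
    for key, beta in betas.items():
        if ":" in key:
            name, level = key.split(":", 1)
            value = mods.get(name)
            if isinstance(value, bool):
                value = "yes" if value else "no"
            if value == level:
                total += beta
        else:
            value = mods.get(key)
            if value is not None:
                total += beta * float(value)
    return total


def generate_arms(config: SyntheticConfig) -> Dataset:
    """Generate one outcome's study arms; deterministic under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    arms: List[StudyArm] = []
    n_clamped = 0
    for i in range(config.k_studies):
        mods = _draw_moderators(rng, config)
        mu = (
            config.true_intercept
            + _linear_effect(mods, config.true_betas)
            + rng.normal(0.0, np.sqrt(config.tau2_true))
        )
        n = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
        sd = config.sd_within
        if config.noisy_sd and sd > 0 and n > 1:
            sd = float(sd * np.sqrt(rng.chisquare(n - 1) / (n - 1)))
        ybar = float(rng.normal(mu, config.sd_within / np.sqrt(n))) if config.sd_within > 0 else float(mu)
        clamped = min(100.0, max(0.0, ybar))
        if clamped != ybar:
            n_clamped += 1
        arms.append(
            StudyArm(
                study_id=f"S{i + 1:04d}",
                outcome=config.outcome,
                mean=clamped,
                sd=float(sd) if sd > 0 else 1e-6,
                n_animals=n,
                **mods,
            )
        )
    if n_clamped:
        logger.warning("clamped %d of %d observed means to [0, 100]", n_clamped, config.k_studies)
    return Dataset(arms=arms, provenance=f"synthetic seed={config.seed}")


def generate_mortality(
    config: SyntheticConfig, phase: str = "peri", base_rate: Optional[float] = None
) -> List[MortalityRecord]:
    """Binomial mortality records with a logistic moderator model.

    p_i = expit(logit(base_rate) + sum of configured log-odds effects), with
    ``mortality_logit_effects`` keyed like ``true_betas``.  A
    ``second_stage_fraction`` of records reports two sequential measurements
    at the same underlying rate.
    """
    config.validate()
    if base_rate is None:
        base_rate = (
            config.mortality_base_rate if phase == "peri" else config.post_mortality_base_rate
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1 if phase == "peri" else 2]))
    records: List[MortalityRecord] = []
    eps = 1e-12
    base = min(max(base_rate, eps), 1 - eps)
    logit0 = np.log(base / (1.0 - base))
    for i in range(config.k_studies):
        mods = _draw_moderators(rng, config)
        eta = logit0 + _linear_effect(mods, config.mortality_logit_effects)
        p = float(1.0 / (1.0 + np.exp(-eta))) if base_rate > 0 else 0.0
        total = int(rng.integers(config.mortality_n_range[0], config.mortality_n_range[1] + 1))
        second = None
        if rng.random() < config.second_stage_fraction:
            # split the phase mortality across two sequential measurements so
            # the combined fraction 1-(1-p1)(1-p2) stays unbiased for p
            p_stage = 1.0 - np.sqrt(1.0 - p)
            deaths = int(rng.binomial(total, p_stage))
            total2 = int(rng.integers(config.mortality_n_range[0], config.mortality_n_range[1] + 1))
            second = (int(rng.binomial(total2, p_stage)), total2)
        else:
            deaths = int(rng.binomial(total, p))
        records.append(
            MortalityRecord(
                study_id=f"M{phase}{i + 1:04d}",
                phase=phase,
                deaths=deaths,
                total=total,
                second_stage=second,
                **mods,
            )
        )
    return records


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """Arms for the configured outcome plus peri- and post-phase mortality."""
    ds = generate_arms(config)
    ds.mortality.extend(generate_mortality(config, "peri"))
    ds.mortality.extend(generate_mortality(config, "post"))
    return ds
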