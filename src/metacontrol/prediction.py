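"""Scenario prediction from a fitted multivariable model, plus auxiliary
ordinary-least-squares association checks.

A scenario names a concrete experimental design (species, occlusion type,
vessel, follow-up, ...); its predicted outcome is the linear predictor
x^T beta with a confidence-of-mean interval
se = sqrt(x^T Cov x) (a new-study interval adding the residual tau^2 is
available by flag, but point predictions are the default report).

Two footnote-style flags mirror how such prediction grids are reported:

``extrapolated_follow_up``
    a continuous moderator value lies outside the fitted data range —
    follow-up enters linearly, so such cells are extrapolations and are
    rendered in parentheses.
``stunning_window``
    ejection-fraction scenarios with follow-up shorter than a configurable
    threshold (default 72 h): early EF is confounded by myocardial stunning
    and is withheld from the default report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InvalidInputError
from .meta_core import Z_95
from .meta_regression import RegressionFit

logger = logging.getLogger(__name__)

#: EF measured earlier than this after reperfusion is treated as confounded
#: by myocardial stunning (an interpretation, configurable)
STUNNING_THRESHOLD_HOURS = 72.0

DEFAULT_FOLLOW_UP_GRID_HOURS = (24.0, 168.0, 672.0)  # 1 day, 1 week, 4 weeks


@dataclass
class PredictionScenario:
    """A named design: one level per categorical moderator, values for
    continuous moderators (follow_up_hours, ischemia_minutes, ...)."""

    name: str
    levels: Dict[str, str] = field(default_factory=dict)
    continuous: Dict[str, float] = field(default_factory=dict)

    def with_follow_up(self, hours: float) -> "PredictionScenario":
        cont = dict(self.continuous)
        cont["follow_up_hours"] = float(hours)
        return PredictionScenario(self.name, dict(self.levels), cont)


@dataclass
class PredictedOutcome:
    point: float
    ci_low: float
    ci_high: float
    flags: frozenset = frozenset()


def default_scenarios() -> List[PredictionScenario]:
    """The three canonical large-animal MI designs used in prediction grids:
    pig 60-min I/R LAD, dog 60-min I/R LAD, pig permanent LAD."""
    common = {"sex": "male", "approach": "open", "quantification": "TTC",
              "comedication": "no", "immunosuppression": "no"}
    return [
        PredictionScenario(
            "Pig I/R (60 min) LAD model",
            {"species": "pig", "occlusion": "temporary", "vessel": "LAD", **common},
            {"ischemia_minutes": 60.0, "quality_score": 5.0},
        ),
        PredictionScenario(
            "Dog I/R (60 min) LAD model",
            {"species": "dog", "occlusion": "temporary", "vessel": "LAD", **common},
            {"ischemia_minutes": 60.0, "quality_score": 5.0},
        ),
        PredictionScenario(
            "Pig permanent LAD model",
            {"species": "pig", "occlusion": "permanent", "vessel": "LAD", **common},
            {"quality_score": 5.0},
        ),
    ]


def _design_row(fit: RegressionFit, scenario: PredictionScenario) -> np.ndarray:
    x = np.zeros(len(fit.term_labels))
    resolved = np.zeros(len(fit.term_labels), dtype=bool)
    for j, lbl in enumerate(fit.term_labels):
        if lbl == "intercept":
            x[j] = 1.0
            resolved[j] = True
    for mod, info in fit.cat_levels.items():
        if mod not in scenario.levels:
            raise ConfigurationError(
                f"scenario {scenario.name!r} does not assign moderator {mod!r}"
            )
        lvl = str(scenario.levels[mod])
        if lvl not in info["levels"]:
            raise ConfigurationError(
                f"scenario {scenario.name!r}: level {lvl!r} of {mod!r} was not "
                f"observed in the fitted data (levels: {info['levels']})"
            )
        idx = info["term_index"][lvl]
        if idx is not None:
            x[idx] = 1.0
        for i in info["term_index"].values():
            if i is not None:
                resolved[i] = True
    for mod in fit.cont_range:
        j = fit.term_labels.index(mod)
        if mod not in scenario.continuous:
            raise ConfigurationError(
                f"scenario {scenario.name!r} does not set continuous moderator {mod!r}"
            )
        x[j] = float(scenario.continuous[mod])
        resolved[j] = True
    if not resolved.all():
        missing = [fit.term_labels[j] for j in np.flatnonzero(~resolved)]
        raise ConfigurationError(f"unresolvable model terms: {', '.join(missing)}")
    return x


def predict_outcome(
    fit: RegressionFit,
    scenario: PredictionScenario,
    outcome: Optional[str] = None,
    new_study: bool = False,
    stunning_threshold_hours: float = STUNNING_THRESHOLD_HOURS,
) -> PredictedOutcome:
    """Linear predictor x^T beta for a scenario with its 95% interval."""
    x = _design_row(fit, scenario)
    point = float(x @ fit.beta)
    var = float(x @ fit.cov_matrix @ x)
    if new_study:
        var += fit.tau2_residual
    se = float(np.sqrt(var))
    flags = set()
    for mod, (lo, hi) in fit.cont_range.items():
        value = float(scenario.continuous.get(mod, np.nan))
        if value < lo or value > hi:
            flags.add("extrapolated_follow_up")
    if outcome == "EF" and scenario.continuous.get("follow_up_hours", np.inf) < stunning_threshold_hours:
        flags.add("stunning_window")
    return PredictedOutcome(point, point - Z_95 * se, point + Z_95 * se, frozenset(flags))


def _render(cell: PredictedOutcome) -> str:
    if "stunning_window" in cell.flags:
        return "—†"
    text = f"{cell.point:.0f}%"
    if "extrapolated_follow_up" in cell.flags:
        return f"({text})*"
    return text


def scenario_report(
    fits: Dict[str, RegressionFit],
    scenarios: Optional[Sequence[PredictionScenario]] = None,
    follow_up_hours: Sequence[float] = DEFAULT_FOLLOW_UP_GRID_HOURS,
    new_study: bool = False,
) -> pd.DataFrame:
    """Scenario × outcome × follow-up prediction grid.

    One row per (scenario, follow-up time, outcome) with the point
    prediction, interval, flags, and a rendered cell using the */ † footnote
    markers (extrapolated / stunning-window).  Cells are independent, so the
    grid is invariant to scenario ordering.
    """
    scenarios = list(scenarios) if scenarios is not None else default_scenarios()
    if not scenarios:
        raise ConfigurationError("at least one scenario is required")
    rows = []
    for scn in scenarios:
        for t in follow_up_hours:
            scn_t = scn.with_follow_up(t)
            for outcome, fit in fits.items():
                cell = predict_outcome(fit, scn_t, outcome=outcome, new_study=new_study)
                rows.append(
                    {
                        "scenario": scn.name,
                        "follow_up_hours": float(t),
                        "outcome": outcome,
                        "point": cell.point,
                        "ci_low": cell.ci_low,
                        "ci_high": cell.ci_high,
                        "flags": ",".join(sorted(cell.flags)),
                        "rendered": _render(cell),
                    }
                )
    return pd.DataFrame(rows)


def ols_association(x: Iterable[float], y: Iterable[float]) -> Tuple[float, float, float]:
    """Ordinary least-squares slope, intercept and two-sided t-test p-value.

    Used for the auxiliary correlation analyses (infarct size vs ejection
    fraction in the same study; therapeutic effect vs control severity).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise InvalidInputError("x and y must have equal length")
    if x.size < 3:
        raise InvalidInputError("need at least 3 points")
    if np.ptp(x) == 0:
        raise InvalidInputError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)
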