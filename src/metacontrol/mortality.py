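"""Mortality-proportion machinery: sequential combination, 1/sqrt(n) weighting,
weighted pooling and weighted meta-regression on death fractions.

Death fractions are analyzed on the raw proportion scale (no logit or
arcsine transform) so regression coefficients read directly as percentage
points per unit; a transform option is not offered because the whole module
is built around raw per-phase ratios.

Two mortality records in the same procedural setting (for example
peri-procedural deaths reported both before and after randomization) are
combined multiplicatively on the survival scale,

.. math:: 1 - p_{total} = (1 - p_1)(1 - p_2),

with effective sample size :math:`n_{eff} = (n_1 + n_2)/2`.

The "1/sqrt(n)" weighting phrase admits two readings; both are implemented
and every output records which was used:

``se_inverse_sqrt_n`` (default)
    treats the standard error as proportional to 1/sqrt(n), hence regression
    weight proportional to n.  Weighting *down* large studies is
    statistically perverse, so this is the default.
``weight_inverse_sqrt_n``
    the literal reading, weight = 1/sqrt(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data_io import MortalityRecord
from .exceptions import InsufficientDataError, InvalidInputError
from .meta_core import Z_95, EffectRecord, MetaFit, pool_random_effects
from .meta_regression import DesignSpec, RegressionFit, design_from_frame, fit_design

logger = logging.getLogger(__name__)

SE_INVERSE_SQRT_N = "se_inverse_sqrt_n"
WEIGHT_INVERSE_SQRT_N = "weight_inverse_sqrt_n"
DEFAULT_CONVENTION = SE_INVERSE_SQRT_N
CONVENTIONS = (SE_INVERSE_SQRT_N, WEIGHT_INVERSE_SQRT_N)


@dataclass(frozen=True)
class WeightedProportion:
    proportion: float
    weight: float
    n_effective: float
    convention: str = DEFAULT_CONVENTION


def mortality_weight(n: float, convention: str = DEFAULT_CONVENTION) -> float:
    """Relative regression weight for a record of n animals.

    Weights are relative: pooling and regression normalize them internally,
    so only ratios matter.
    """
    if not n > 0:
        raise InvalidInputError(f"n must be positive, got {n}")
    if convention == SE_INVERSE_SQRT_N:
        return float(n)
    if convention == WEIGHT_INVERSE_SQRT_N:
        return float(n) ** -0.5
    raise InvalidInputError(f"unknown weighting convention {convention!r}")


def combine_sequential_proportions(
    deaths1: int,
    total1: int,
    deaths2: int,
    total2: int,
    convention: str = DEFAULT_CONVENTION,
) -> WeightedProportion:
    """Combine two sequential death proportions on the survival scale."""
    for d, t in ((deaths1, total1), (deaths2, total2)):
        if t <= 0:
            raise InvalidInputError("totals must be positive")
        if not 0 <= d <= t:
            raise InvalidInputError(f"deaths ({d}) must lie in [0, total ({t})]")
    p1 = deaths1 / total1
    p2 = deaths2 / total2
    p_total = 1.0 - (1.0 - p1) * (1.0 - p2)
    n_eff = (total1 + total2) / 2.0
    return WeightedProportion(p_total, mortality_weight(n_eff, convention), n_eff, convention)


def record_proportion(rec: MortalityRecord, convention: str = DEFAULT_CONVENTION) -> WeightedProportion:
    """Death fraction and weight for one record, combining a second stage if present."""
    if rec.second_stage is not None:
        d2, t2 = rec.second_stage
        return combine_sequential_proportions(rec.deaths, rec.total, d2, t2, convention)
    if rec.total <= 0:
        raise InvalidInputError("total must be positive")
    if rec.total < 2:
        logger.warning("record %r has total < 2; kept but poorly informative", rec.study_id)
    return WeightedProportion(
        rec.deaths / rec.total, mortality_weight(rec.total, convention), float(rec.total), convention
    )


def pool_mortality(
    records: Sequence[MortalityRecord], convention: str = DEFAULT_CONVENTION
) -> MetaFit:
    """Weighted random-effects pool of death fractions, reported in percent.

    The module's weights serve as inverse-variance proxies.  Because the
    proxy scale is arbitrary, it is calibrated from the data: after
    normalizing the weights to sum to k, v_i = c_hat / w_i with c_hat the
    weighted mean squared deviation about the weighted mean (the classic
    analytic-weights variance).  This leaves the weighted point estimate
    untouched, makes the pool exactly invariant to global weight rescaling,
    and gives the CI a data-driven scale.  CIs are clipped to [0, 100]%.
    """
    records = list(records)
    if not records:
        raise InsufficientDataError("cannot pool an empty collection")
    props = [record_proportion(r, convention) for r in records]
    y = np.array([p.proportion for p in props]) * 100.0
    w = np.array([p.weight for p in props])
    k = y.size
    if k == 1:
        p = props[0]
        se = 100.0 * float(np.sqrt(p.proportion * (1 - p.proportion) / p.n_effective))
        lo = max(0.0, y[0] - Z_95 * se)
        hi = min(100.0, y[0] + Z_95 * se)
        return MetaFit(float(y[0]), se, lo, hi, 0.0, 0.0, 0.0, 1, degenerate=True)
    w = w * (k / w.sum())
    mu_w = float(np.sum(w * y) / np.sum(w))
    c_hat = float(np.sum(w * (y - mu_w) ** 2) / (k - 1))
    if c_hat <= 0:  # all proportions identical (e.g. all zero deaths)
        return MetaFit(mu_w, 0.0, mu_w, mu_w, 0.0, 0.0, 0.0, k)
    effects = [
        EffectRecord(float(yi), c_hat / wi, label=r.study_id, n_animals=int(round(p.n_effective)))
        for yi, wi, r, p in zip(y, w, records, props)
    ]
    fit = pool_random_effects(effects)
    return MetaFit(
        fit.mu,
        fit.se,
        max(0.0, fit.ci_low),
        min(100.0, fit.ci_high),
        fit.tau2,
        fit.q_stat,
        fit.i2,
        fit.k,
    )


def mortality_metareg(
    records: Sequence[MortalityRecord],
    spec: Optional[DesignSpec] = None,
    moderators: Optional[Sequence[str]] = None,
    convention: str = DEFAULT_CONVENTION,
) -> RegressionFit:
    """Weighted meta-regression of (combined) death fractions, in percent.

    Delegates to the meta-regression machinery with the module's weights as
    ``weights_override``; tau^2 is then profiled on the normalized inverse
    weights.  The response and all coefficients are in percentage points
    (e.g. points per hour of follow-up).  Ischemia duration only exists for
    temporary-occlusion records, so entering it restricts the fit to that
    complete-case subset.
    """
    records = list(records)
    if len(records) < 2:
        raise InsufficientDataError("meta-regression needs at least 2 records")
    spec = spec or DesignSpec()
    if moderators is None:
        moderators = [m for m in spec.moderators if m not in spec.add_separately]
    props = [record_proportion(r, convention) for r in records]
    y = np.array([p.proportion for p in props]) * 100.0
    w = np.array([p.weight for p in props])
    frame = pd.DataFrame([{m: getattr(r, m) for m in moderators} for r in records])
    dm = design_from_frame(frame, y, np.ones_like(y), moderators, spec.reference_levels)
    # design_from_frame may drop rows with missing moderators; align weights
    keep = dm.frame.index.to_numpy()
    fit = fit_design(dm, weights_override=w[keep])
    fit.weights_convention = convention
    return fit
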