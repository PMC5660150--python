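"""Random-effects meta-analysis of raw-mean percentage outcomes.

Each control arm contributes its raw mean :math:`y_i` (a percentage) with
sampling variance :math:`v_i = sd_i^2 / n_i` (squared standard error of a
mean).  The random-effects model is

.. math:: y_i = \\mu + u_i + e_i, \\qquad u_i \\sim N(0, \\tau^2),
          \\quad e_i \\sim N(0, v_i),

with the between-study variance :math:`\\tau^2` estimated by restricted
maximum likelihood (REML).  Inference uses the normal quantile (z), matching
the conventional metafor-style default, with no Knapp–Hartung adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .data_io import Dataset
from .exceptions import InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)

#: two-sided 95% normal quantile used for every confidence interval
Z_95 = 1.959964

#: upper bound of the tau^2 search interval (percentage points squared)
TAU2_MAX = 1.0e4

#: absolute tolerance on the tau^2 maximizer
TAU2_TOL = 1.0e-10


@dataclass(frozen=True)
class EffectRecord:
    """One study-level effect: estimate y_i (percent), sampling variance v_i."""

    estimate: float
    variance: float
    label: str = ""
    n_animals: int = 1


@dataclass(frozen=True)
class MetaFit:
    """Pooled random-effects result.

    ``degenerate`` marks a single-study "pool" (subset analyses can shrink to
    one study): the study's own values are returned with tau2 = 0.
    """

    mu: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q_stat: float
    i2: float
    k: int
    degenerate: bool = False


def effects_from_dataset(dataset: Dataset, outcome: str) -> list:
    """Build EffectRecords for one outcome with v_i = sd_i^2 / n_i."""
    out = []
    for arm in dataset.arms:
        if arm.outcome != outcome:
            continue
        v = arm.sd ** 2 / arm.n_animals
        if not v > 0:
            raise InvalidInputError(
                f"arm {arm.study_id!r}: nonpositive sampling variance (sd={arm.sd}, n={arm.n_animals})"
            )
        out.append(EffectRecord(arm.mean, v, label=arm.study_id, n_animals=arm.n_animals))
    return out


def _as_arrays(effects: Iterable[EffectRecord]) -> Tuple[np.ndarray, np.ndarray]:
    effects = list(effects)
    y = np.array([e.estimate for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    return y, v


def restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray, X: Optional[np.ndarray] = None) -> float:
    """Restricted log-likelihood of the (mixed) model at a given tau^2.

    Additive constants are dropped; only differences in tau^2 matter.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if X is None:
        X = np.ones((y.size, 1))
    w = 1.0 / (v + tau2)
    xtw = X.T * w
    a = xtw @ X
    beta = np.linalg.solve(a, xtw @ y)
    resid = y - X @ beta
    _, logdet = np.linalg.slogdet(a)
    return -0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * resid * resid))


def reml_tau2(y: np.ndarray, v: np.ndarray, X: Optional[np.ndarray] = None) -> float:
    """Nonnegative REML estimate of tau^2 via bounded scalar maximization.

    Derivative-free Brent search on [0, TAU2_MAX] with tolerance TAU2_TOL;
    the boundary value tau^2 = 0 is compared explicitly since the bounded
    optimizer cannot land exactly on it.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    p = 1 if X is None else np.asarray(X).shape[1]
    if y.size < p + 1:
        raise InsufficientDataError(f"need at least {p + 1} studies, got {y.size}")
    if np.all(v <= 0):
        raise InvalidInputError("all sampling variances are zero")
    if np.any(v < 0):
        raise InvalidInputError("negative sampling variance")
    res = minimize_scalar(
        lambda t2: -restricted_loglik(t2, y, v, X),
        bounds=(0.0, TAU2_MAX),
        method="bounded",
        options={"xatol": TAU2_TOL, "maxiter": 200},
    )
    t2 = float(max(res.x, 0.0))
    if restricted_loglik(0.0, y, v, X) >= restricted_loglik(t2, y, v, X):
        return 0.0
    return t2


def estimate_tau2_reml(effects: Iterable[EffectRecord]) -> float:
    """REML between-study variance for an intercept-only random-effects model."""
    y, v = _as_arrays(effects)
    return reml_tau2(y, v)


def heterogeneity_stats(effects: Iterable[EffectRecord], tau2: Optional[float] = None) -> Tuple[float, float]:
    """Cochran's Q and Higgins' I^2.

    Q uses fixed-effect weights 1/v_i around the fixed-effect mean;
    I^2 = max(0, (Q - (k-1))/Q).  ``tau2`` is accepted for interface
    symmetry with the pooling operations but is not needed by either
    statistic.
    """
    y, v = _as_arrays(effects)
    if y.size < 2:
        raise InsufficientDataError("heterogeneity statistics need k >= 2")
    if np.any(v <= 0):
        raise InvalidInputError("sampling variances must be positive")
    w = 1.0 / v
    mu_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu_fe) ** 2))
    i2 = max(0.0, (q - (y.size - 1)) / q) if q > 0 else 0.0
    return q, i2


def pool_random_effects(effects: Iterable[EffectRecord], tau2: Optional[float] = None) -> MetaFit:
    """Inverse-variance random-effects pool.

    mu = sum(w_i y_i)/sum(w_i) with w_i = 1/(v_i + tau^2) and
    se = sum(w_i)^(-1/2); the 95% CI is mu ± 1.959964·se.  For k = 1 the
    single study is returned with tau2 = 0 and the degenerate flag set.
    """
    effects = list(effects)
    if not effects:
        raise InsufficientDataError("cannot pool an empty collection")
    y, v = _as_arrays(effects)
    if y.size == 1:
        se = float(np.sqrt(v[0]))
        mu = float(y[0])
        return MetaFit(mu, se, mu - Z_95 * se, mu + Z_95 * se, 0.0, 0.0, 0.0, 1, degenerate=True)
    if tau2 is None:
        tau2 = reml_tau2(y, v)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q, i2 = heterogeneity_stats(effects)
    return MetaFit(mu, se, mu - Z_95 * se, mu + Z_95 * se, float(tau2), q, i2, int(y.size))


def _tau2_dersimonian_laird(effects: Iterable[EffectRecord]) -> float:
    """Method-of-moments tau^2 (DerSimonian–Laird); internal cross-check only."""
    y, v = _as_arrays(effects)
    if y.size < 2:
        raise InsufficientDataError("DL estimator needs k >= 2")
    w = 1.0 / v
    q, _ = heterogeneity_stats(effects)
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    return float(max(0.0, (q - (y.size - 1)) / denom))


def forest_table(effects: Sequence[EffectRecord], fit: MetaFit) -> list:
    """Per-study rows (95% CI from y_i ± z·sqrt(v_i)) plus a summary row."""
    rows = []
    for e in effects:
        half = Z_95 * float(np.sqrt(e.variance))
        rows.append(
            {
                "label": e.label,
                "estimate": e.estimate,
                "ci_low": e.estimate - half,
                "ci_high": e.estimate + half,
                "kind": "study",
            }
        )
    rows.append(
        {
            "label": "RE summary",
            "estimate": fit.mu,
            "ci_low": fit.ci_low,
            "ci_high": fit.ci_high,
            "kind": "summary",
        }
    )
    return rows


def forest_plot(effects: Sequence[EffectRecord], fit: MetaFit, path, title: str = "") -> None:
    """Render a forest plot (studies as squares, summary as a diamond)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = forest_table(effects, fit)
    n = len(rows)
    fig, ax = plt.subplots(figsize=(6, 0.35 * n + 1.2))
    for i, row in enumerate(rows):
        ypos = n - 1 - i
        if row["kind"] == "study":
            ax.plot([row["ci_low"], row["ci_high"]], [ypos, ypos], color="k", lw=1)
            ax.plot(row["estimate"], ypos, "ks", ms=4)
        else:
            ax.plot(
                [row["ci_low"], row["estimate"], row["ci_high"], row["estimate"], row["ci_low"]],
                [ypos, ypos + 0.25, ypos, ypos - 0.25, ypos],
                color="b",
                lw=1,
            )
    ax.set_yticks(range(n))
    ax.set_yticklabels([r["label"] for r in reversed(rows)], fontsize=7)
    ax.axvline(fit.mu, color="b", ls=":", lw=0.8)
    ax.set_xlabel("outcome (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
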