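"""Uni- and multivariable random-effects meta-regression with Wald contrasts.

The mixed-effects model extends the intercept-only pool with study-level
moderators:

.. math:: y_i = x_i^T \\beta + u_i + e_i, \\qquad u_i \\sim N(0, \\tau^2),
          \\quad e_i \\sim N(0, v_i).

The residual between-study variance tau^2 is profiled by REML;
:math:`\\hat\\beta = (X^T W X)^{-1} X^T W y` with
:math:`W = \\mathrm{diag}(1/(v_i + \\tau^2))`.  Categorical moderators are
dummy-coded against a reference level; the omnibus test is the Wald
chi-square of all non-intercept terms, and post-hoc pairwise level contrasts
use z statistics without multiplicity adjustment (a Bonferroni/Holm flag is
available but off by default).

Reference-level changes are applied as exact integer reparameterizations of
one canonical fit (dummies against the alphabetically first level), so every
pairwise contrast is bit-stable under any choice of reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr

from .data_io import (
    CATEGORICAL_MODERATORS,
    CONTINUOUS_MODERATORS,
    Dataset,
)
from .exceptions import (
    CollinearityError,
    ConfigurationError,
    InsufficientDataError,
    InvalidInputError,
)
from . import meta_core
from .meta_core import Z_95, EffectRecord, pool_random_effects, reml_tau2

logger = logging.getLogger(__name__)

#: rank-check tolerance relative to the largest singular value
RANK_TOL = 1.0e-10

#: reference levels implied by the reported table phrasings ("vs dog",
#: "vs female", ...) where inferable; alphabetical first level otherwise
DEFAULT_REFERENCES = {
    "species": "dog",
    "sex": "male",
    "occlusion": "permanent",
    "vessel": "LCX",
    "approach": "closed",
    "comedication": "no",
    "immunosuppression": "no",
    "strain": "regular_pig",
    "quantification": "TTC",
}

#: moderators fitted on their available-data subset in the multivariable model
DEFAULT_ADD_SEPARATELY = ("ischemia_minutes", "weight_kg", "age_weeks")

DEFAULT_MODERATORS = (
    "species",
    "sex",
    "comedication",
    "immunosuppression",
    "approach",
    "occlusion",
    "vessel",
    "quantification",
    "follow_up_hours",
    "quality_score",
    "ischemia_minutes",
    "weight_kg",
    "age_weeks",
)


@dataclass
class DesignSpec:
    """Which moderators enter a model, their references and the
    "added separately due to missing data" subset."""

    moderators: List[str] = field(default_factory=lambda: list(DEFAULT_MODERATORS))
    reference_levels: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REFERENCES))
    add_separately: List[str] = field(default_factory=lambda: list(DEFAULT_ADD_SEPARATELY))


@dataclass
class RegressionFit:
    """Meta-regression result in the requested parameterization.

    ``cat_levels`` maps each categorical moderator to its observed levels,
    reference and term indices so that pairwise contrasts and scenario
    predictions can be formed without refitting.
    """

    coefficients: Dict[str, float]
    cov_matrix: np.ndarray
    tau2_residual: float
    k: int
    omnibus_p: Optional[float]
    r2: float
    term_labels: List[str]
    cat_levels: Dict[str, dict] = field(default_factory=dict)
    cont_range: Dict[str, tuple] = field(default_factory=dict)
    n_dropped: int = 0
    weights_convention: Optional[str] = None

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.term_labels])

    def se(self, term: str) -> float:
        i = self.term_labels.index(term)
        return float(np.sqrt(self.cov_matrix[i, i]))


@dataclass
class ContrastResult:
    """A single pairwise Wald contrast, e.g. "pig vs dog"."""

    estimate: float
    se: float
    z: float
    p: float
    label: str


@dataclass
class DesignMatrix:
    """Canonical design plus the exact map to the requested parameterization."""

    y: np.ndarray
    v: np.ndarray
    X: np.ndarray  # canonical coding
    canonical_labels: List[str]
    labels: List[str]  # requested parameterization
    L: np.ndarray  # beta_requested = L @ beta_canonical (integer entries)
    cat_levels: Dict[str, dict]
    cont_range: Dict[str, tuple]
    n_dropped: int = 0
    frame: Optional[pd.DataFrame] = None


def significance_gate(p: float) -> bool:
    """True iff p < 0.05 (strict), the threshold used throughout the pipeline."""
    if not (0.0 <= p <= 1.0):
        raise InvalidInputError(f"p-value {p} outside [0, 1]")
    return p < 0.05


# ---------------------------------------------------------------------------
# Design-matrix construction
# ---------------------------------------------------------------------------

def _moderator_series(frame: pd.DataFrame, name: str) -> pd.Series:
    if name not in frame.columns:
        raise ConfigurationError(f"unknown moderator {name!r}")
    s = frame[name]
    if name in ("comedication", "immunosuppression", "vf_excluded_untreated"):
        return s.map(lambda b: "yes" if b else "no")
    return s


def _is_categorical(name: str) -> bool:
    if name in CATEGORICAL_MODERATORS:
        return True
    if name in CONTINUOUS_MODERATORS:
        return False
    raise ConfigurationError(f"unknown moderator {name!r}")


def design_from_frame(
    frame: pd.DataFrame,
    y: np.ndarray,
    v: np.ndarray,
    moderators: Sequence[str],
    reference_levels: Optional[Dict[str, str]] = None,
) -> DesignMatrix:
    """Encode moderators into a weighted-least-squares design.

    Rows with a missing value in any listed moderator are dropped with a
    logged count.  Categorical moderators observed at a single level are
    skipped with a warning (their dummy block would be empty).
    """
    reference_levels = reference_levels or {}
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)

    cats, conts = [], []
    for m in moderators:
        (cats if _is_categorical(m) else conts).append(m)

    work = pd.DataFrame(index=frame.index)
    for m in cats:
        work[m] = _moderator_series(frame, m).astype(object)
    for m in conts:
        work[m] = pd.to_numeric(_moderator_series(frame, m), errors="coerce")

    keep = ~work.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing moderator values", n_dropped)
    work = work.loc[keep]
    y = y[np.asarray(keep)]
    v = v[np.asarray(keep)]
    if work.shape[0] < 2:
        raise InsufficientDataError("fewer than 2 usable rows after moderator subsetting")

    columns = [np.ones(work.shape[0])]
    canonical_labels = ["intercept"]
    # canonical term layout: intercept, then each categorical block, then
    # continuous terms; requested layout is parallel
    blocks: List[tuple] = []  # (moderator, levels, requested_ref, canonical slice)
    for m in cats:
        levels = sorted(map(str, work[m].unique()))
        if len(levels) < 2:
            logger.warning("moderator %r has a single observed level; skipped", m)
            continue
        req = str(reference_levels.get(m, levels[0]))
        if req not in levels:
            raise ConfigurationError(
                f"reference level {req!r} for {m!r} absent from data (levels: {levels})"
            )
        start = len(canonical_labels)
        for lvl in levels[1:]:
            columns.append((work[m].astype(str) == lvl).to_numpy(dtype=float))
            canonical_labels.append(f"{m}:{lvl}")
        blocks.append((m, levels, req, slice(start, len(canonical_labels))))
    cont_range: Dict[str, tuple] = {}
    cont_index: Dict[str, int] = {}
    for m in conts:
        col = work[m].to_numpy(dtype=float)
        cont_index[m] = len(canonical_labels)
        columns.append(col)
        canonical_labels.append(m)
        cont_range[m] = (float(col.min()), float(col.max()))

    X = np.column_stack(columns)
    p = X.shape[1]

    # exact reparameterization: beta_requested = L @ beta_canonical
    L = np.zeros((p, p))
    L[0, 0] = 1.0
    labels = ["intercept"]
    cat_levels: Dict[str, dict] = {}
    for m, levels, req, sl in blocks:
        canon_pos = {lvl: sl.start + j for j, lvl in enumerate(levels[1:])}
        if req != levels[0]:
            L[0, canon_pos[req]] = 1.0  # intercept absorbs the requested reference
        term_index: Dict[str, Optional[int]] = {}
        for lvl in levels:
            if lvl == req:
                term_index[lvl] = None
                continue
            row = len(labels)
            if lvl != levels[0]:
                L[row, canon_pos[lvl]] = 1.0
            if req != levels[0]:
                L[row, canon_pos[req]] = -1.0
            labels.append(f"{lvl} (vs {req})")
            term_index[lvl] = row
        cat_levels[m] = {"levels": levels, "reference": req, "term_index": term_index}
    for m in conts:
        i = cont_index[m]
        row = len(labels)
        L[row, i] = 1.0
        labels.append(m)

    # disambiguate duplicate labels (two boolean moderators both "yes (vs no)")
    seen: Dict[str, int] = {}
    for lbl in labels:
        seen[lbl] = seen.get(lbl, 0) + 1
    dupes = {lbl for lbl, c in seen.items() if c > 1}
    if dupes:
        for m, info in cat_levels.items():
            for lvl, idx in info["term_index"].items():
                if idx is not None and labels[idx] in dupes:
                    labels[idx] = f"{m}={lvl} (vs {info['reference']})"

    return DesignMatrix(
        y=y,
        v=v,
        X=X,
        canonical_labels=canonical_labels,
        labels=labels,
        L=L,
        cat_levels=cat_levels,
        cont_range=cont_range,
        n_dropped=n_dropped,
        frame=work,
    )


def build_design_matrix(
    data: Dataset, spec: DesignSpec, outcome: str, moderators: Optional[Sequence[str]] = None
) -> DesignMatrix:
    """Design matrix for one outcome: y = arm means, v = sd^2/n.

    ``moderators`` defaults to the spec's non-"add separately" set.
    """
    frame = data.to_frame(outcome)
    if frame.empty:
        raise InsufficientDataError(f"no arms with outcome {outcome!r}")
    if moderators is None:
        moderators = [m for m in spec.moderators if m not in spec.add_separately]
    y = frame["mean"].to_numpy(dtype=float)
    v = (frame["sd"].to_numpy(dtype=float) ** 2) / frame["n_animals"].to_numpy(dtype=float)
    if np.any(v <= 0):
        raise InvalidInputError("every arm needs sd > 0 and n >= 1 for v = sd^2/n")
    return design_from_frame(frame, y, v, moderators, spec.reference_levels)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _check_rank(X: np.ndarray, labels: Sequence[str]) -> None:
    s = np.linalg.svd(X, compute_uv=False)
    rank = int(np.sum(s > RANK_TOL * s[0]))
    if rank < X.shape[1]:
        _, _, piv = qr(X, pivoting=True)
        aliased = [labels[i] for i in sorted(piv[rank:])]
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased terms: {', '.join(aliased)}",
            aliased_terms=aliased,
        )


def fit_meta_regression(
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    term_labels: Optional[Sequence[str]] = None,
    weights_override: Optional[np.ndarray] = None,
) -> RegressionFit:
    """Weighted meta-regression with REML residual tau^2.

    With ``weights_override`` the supplied weights (normalized to sum to the
    number of rows, so the fit is invariant to global rescaling) are treated
    as inverse variances, and tau^2 is then profiled on top of them.  The
    omnibus p-value is the Wald chi-square of all non-intercept terms;
    r2 = max(0, 1 - tau2_residual / tau2_null) with tau2_null from the
    intercept-only fit on the same rows.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if not (len(y) == len(v) == n):
        raise InvalidInputError("y, v and X row counts differ")
    if n < p + 1:
        raise InsufficientDataError(f"need at least {p + 1} rows for {p} terms, got {n}")
    if term_labels is None:
        has_intercept = np.all(X[:, 0] == X[0, 0]) and X[0, 0] != 0
        term_labels = (["intercept"] if has_intercept else ["x0"]) + [
            f"x{j}" for j in range(1, p)
        ]
    term_labels = list(term_labels)
    _check_rank(X, term_labels)

    if weights_override is not None:
        w0 = np.asarray(weights_override, dtype=float)
        if np.any(w0 <= 0):
            raise InvalidInputError("override weights must be positive")
        w0 = w0 * (n / w0.sum())
        v_eff = 1.0 / w0
    else:
        if np.any(v < 0) or np.all(v <= 0):
            raise InvalidInputError("sampling variances must be nonnegative, not all zero")
        v_eff = v

    tau2 = reml_tau2(y, v_eff, X)
    w = 1.0 / (v_eff + tau2)
    xtw = X.T * w
    a = xtw @ X
    beta = np.linalg.solve(a, xtw @ y)
    cov = np.linalg.inv(a)

    nonint = [j for j, lbl in enumerate(term_labels) if lbl != "intercept"]
    if nonint:
        b1 = beta[nonint]
        c11 = cov[np.ix_(nonint, nonint)]
        chi2 = float(b1 @ np.linalg.solve(c11, b1))
        omnibus_p = float(stats.chi2.sf(chi2, df=len(nonint)))
        tau2_null = reml_tau2(y, v_eff)
        r2 = 0.0 if tau2_null <= 0 else min(1.0, max(0.0, 1.0 - tau2 / tau2_null))
    else:
        omnibus_p = None
        r2 = 0.0

    return RegressionFit(
        coefficients=dict(zip(term_labels, beta.tolist())),
        cov_matrix=cov,
        tau2_residual=float(tau2),
        k=int(n),
        omnibus_p=omnibus_p,
        r2=float(r2),
        term_labels=term_labels,
    )


def fit_design(dm: DesignMatrix, weights_override: Optional[np.ndarray] = None) -> RegressionFit:
    """Fit the canonical design, then map exactly to the requested reference."""
    fit_c = fit_meta_regression(dm.y, dm.v, dm.X, dm.canonical_labels, weights_override)
    beta_r = dm.L @ fit_c.beta
    cov_r = dm.L @ fit_c.cov_matrix @ dm.L.T
    return RegressionFit(
        coefficients=dict(zip(dm.labels, beta_r.tolist())),
        cov_matrix=cov_r,
        tau2_residual=fit_c.tau2_residual,
        k=fit_c.k,
        omnibus_p=fit_c.omnibus_p,
        r2=fit_c.r2,
        term_labels=list(dm.labels),
        cat_levels=dm.cat_levels,
        cont_range=dm.cont_range,
        n_dropped=dm.n_dropped,
    )


# ---------------------------------------------------------------------------
# Pairwise contrasts
# ---------------------------------------------------------------------------

def pairwise_category_tests(
    fit: RegressionFit, moderator: str, adjust: Optional[str] = None
) -> List[ContrastResult]:
    """Wald z contrasts for every unordered level pair of one moderator.

    No multiplicity adjustment by default (``adjust`` accepts "bonferroni" or
    "holm" for users who want one).
    """
    info = fit.cat_levels.get(moderator)
    if info is None:
        raise ConfigurationError(f"moderator {moderator!r} is not in the fitted model")
    levels = info["levels"]
    if len(levels) < 2:
        raise ConfigurationError(f"moderator {moderator!r} has fewer than 2 levels")
    beta = fit.beta
    results = []
    for a, b in combinations(levels, 2):
        c = np.zeros(len(beta))
        ia, ib = info["term_index"][a], info["term_index"][b]
        if ia is not None:
            c[ia] = 1.0
        if ib is not None:
            c[ib] = -1.0
        est = float(c @ beta)
        se = float(np.sqrt(c @ fit.cov_matrix @ c))
        z = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2.0 * stats.norm.sf(abs(z)))
        results.append(ContrastResult(est, se, float(z), p, f"{a} vs {b}"))
    if adjust == "bonferroni":
        m = len(results)
        results = [
            ContrastResult(r.estimate, r.se, r.z, min(1.0, r.p * m), r.label) for r in results
        ]
    elif adjust == "holm":
        order = np.argsort([r.p for r in results])
        m = len(results)
        adj, prev = {}, 0.0
        for rank, idx in enumerate(order):
            prev = max(prev, min(1.0, (m - rank) * results[idx].p))
            adj[idx] = prev
        results = [
            ContrastResult(r.estimate, r.se, r.z, adj[i], r.label) for i, r in enumerate(results)
        ]
    elif adjust is not None:
        raise ConfigurationError(f"unknown adjustment {adjust!r}")
    return results


# ---------------------------------------------------------------------------
# Univariable battery and multivariable model
# ---------------------------------------------------------------------------

@dataclass
class UnivariableResult:
    """One moderator's univariable fit plus its per-level pooled subgroups."""

    fit: RegressionFit
    subgroups: pd.DataFrame  # level, n, mean, ci_low, ci_high (categorical only)
    contrasts: List[ContrastResult] = field(default_factory=list)


def _subgroup_table(frame: pd.DataFrame, moderator: str) -> pd.DataFrame:
    """Per-level random-effects pooled means, the default reading of the
    univariable table halves (subgroup pooling rather than regression means)."""
    rows = []
    series = frame[moderator].astype(str)  # already encoded by design_from_frame
    for lvl in sorted(series.unique()):
        sub = frame.loc[series == lvl]
        effects = [
            EffectRecord(m, sd ** 2 / n, label=sid, n_animals=int(n))
            for m, sd, n, sid in zip(sub["mean"], sub["sd"], sub["n_animals"], sub["study_id"])
        ]
        pooled = pool_random_effects(effects)
        rows.append(
            {
                "level": lvl,
                "n": len(effects),
                "mean": pooled.mu,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
            }
        )
    return pd.DataFrame(rows)


def fit_univariable_battery(
    data: Dataset,
    outcome: str,
    moderators: Optional[Sequence[str]] = None,
    spec: Optional[DesignSpec] = None,
) -> Dict[str, UnivariableResult]:
    """One meta-regression per moderator on that moderator's available rows.

    Mirrors the left halves of the reported per-outcome tables: per-category
    pooled means with CI, the moderator's omnibus p, and post-hoc pairwise
    contrasts for categorical moderators.  Moderators observed at a single
    level are skipped with a warning.
    """
    spec = spec or DesignSpec()
    if moderators is None:
        moderators = spec.moderators
    results: Dict[str, UnivariableResult] = {}
    for m in moderators:
        try:
            dm = build_design_matrix(data, spec, outcome, moderators=[m])
        except InsufficientDataError as exc:
            logger.warning("univariable %r skipped: %s", m, exc)
            continue
        if dm.X.shape[1] < 2:  # single observed level
            logger.warning("univariable %r skipped: single observed level", m)
            continue
        fit = fit_design(dm)
        if _is_categorical(m):
            subgroups = _subgroup_table(dm.frame.join(
                data.to_frame(outcome)[["mean", "sd", "n_animals", "study_id"]]
            ), m)
            contrasts = pairwise_category_tests(fit, m)
        else:
            subgroups = pd.DataFrame()
            contrasts = []
        results[m] = UnivariableResult(fit=fit, subgroups=subgroups, contrasts=contrasts)
    return results


@dataclass
class MultivariableResult:
    joint: RegressionFit
    separate: Dict[str, RegressionFit]


def fit_multivariable(
    data: Dataset, outcome: str, spec: Optional[DesignSpec] = None
) -> Tuple[RegressionFit, Dict[str, RegressionFit]]:
    """Joint model over all non-separate moderators, plus one refit per
    "added separately" moderator (joint terms + that single term) on its
    complete-case subset, as the table footnotes describe."""
    spec = spec or DesignSpec()
    main = [m for m in spec.moderators if m not in spec.add_separately]
    dm = build_design_matrix(data, spec, outcome, moderators=main)
    joint = fit_design(dm)
    separate: Dict[str, RegressionFit] = {}
    for m in spec.add_separately:
        if m not in spec.moderators:
            continue
        try:
            dm_m = build_design_matrix(data, spec, outcome, moderators=main + [m])
            separate[m] = fit_design(dm_m)
        except (InsufficientDataError, CollinearityError) as exc:
            logger.warning("separate moderator %r not fitted: %s", m, exc)
    return joint, separate


@dataclass
class OutcomeReport:
    """Full per-outcome analysis: univariable battery, joint model, gated post hoc."""

    outcome: str
    univariable: Dict[str, UnivariableResult]
    joint: RegressionFit
    separate: Dict[str, RegressionFit]
    posthoc: Dict[str, List[ContrastResult]]
    posthoc_skipped: bool


def analyze_outcome(
    data: Dataset, outcome: str, spec: Optional[DesignSpec] = None
) -> OutcomeReport:
    """Run the whole pipeline for one outcome.

    Post-hoc pairwise contrasts on the joint model are computed only when the
    multivariable omnibus test is significant (p < 0.05); otherwise they are
    skipped, mirroring the rule of not proceeding with post-hoc testing after
    a non-significant multivariable model.
    """
    spec = spec or DesignSpec()
    uni = fit_univariable_battery(data, outcome, spec=spec)
    joint, separate = fit_multivariable(data, outcome, spec)
    posthoc: Dict[str, List[ContrastResult]] = {}
    skipped = True
    if joint.omnibus_p is not None and significance_gate(joint.omnibus_p):
        skipped = False
        for m in joint.cat_levels:
            posthoc[m] = pairwise_category_tests(joint, m)
    return OutcomeReport(outcome, uni, joint, separate, posthoc, skipped)
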