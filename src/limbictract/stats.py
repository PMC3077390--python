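"""Group statistics along tracts: pointwise regressions, Bonferroni control,
and partial correlations with clinical scores.

Group differences are tested by ordinary least squares of the metric on
``[intercept, group, age, education, illness duration]`` (group coded
control = 0, patient = 1, so a positive RD coefficient means higher RD in
patients; illness duration is 0 for controls so one model fits both groups).
Tract-based analyses run this regression at each of the 30 arc-length points
of the smoothed profile and flag points at ``p < alpha / family`` with
``family = 30`` (the points of one bundle-metric) by default.

Clinical associations use the partial correlation between the profile value
and a PANSS score given the same covariates, restricted to patients, with
the same per-bundle Bonferroni family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .geometry import smooth_profile

__all__ = [
    "COVARIATES",
    "PointwiseResult",
    "group_regression",
    "roi_analysis",
    "tractwise_analysis",
    "partial_correlation",
    "clinical_correlation",
]

logger = logging.getLogger(__name__)

#: Covariates entering every group model and clinical partial correlation.
COVARIATES = ("age", "education", "duration")

_GROUP_CODES = {"control": 0.0, "patient": 1.0}


def _design(subjects: pd.DataFrame) -> np.ndarray:
    missing = [c for c in ("group",) + COVARIATES if c not in subjects.columns]
    if missing:
        raise ValueError(f"subject table is missing columns: {missing}")
    bad = set(subjects["group"]) - set(_GROUP_CODES)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    g = subjects["group"].map(_GROUP_CODES).to_numpy(float)
    X = np.column_stack(
        [np.ones(len(subjects)), g] + [subjects[c].to_numpy(float) for c in COVARIATES]
    )
    return X


def group_regression(y: np.ndarray, subjects: pd.DataFrame):
    """OLS of y on [intercept, group, age, education, duration].

    Returns ``(coefficient, t, p)`` for the group indicator; the two-sided p
    comes from the t distribution with ``n - 5`` degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = _design(subjects)
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError(f"y must have one value per subject ({n}), got {y.shape}")
    if n <= k + 1:
        raise ValueError(f"too few subjects (n={n}) for {k} predictors")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank-deficient (collinear predictors)")
    fit = sm.OLS(y, X).fit()
    coef, t, p = float(fit.params[1]), float(fit.tvalues[1]), float(fit.pvalues[1])
    scale = max(1.0, float(y @ y))
    if not np.isfinite(t) or fit.ssr <= 1e-20 * scale:
        # perfect fit (zero residual variance up to round-off)
        t = 0.0 if abs(coef) <= 1e-10 * np.sqrt(scale) else np.inf * np.sign(coef)
        p = 1.0 if t == 0.0 else 0.0
    return coef, t, p


def roi_analysis(bundle_means: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Whole-bundle (ROI-level) group regressions.

    ``bundle_means`` is long-format with columns (subject, bundle, metric,
    value): one mean metric value per subject per bundle.  Runs one
    :func:`group_regression` per bundle x metric and returns a sorted table
    of (bundle, metric, coefficient, t, p).  P values are reported raw
    (uncorrected), matching how whole-bundle results are usually presented.
    """
    ids = subjects["id"].tolist()
    rows = []
    for (bundle, metric), sub in bundle_means.groupby(["bundle", "metric"], sort=True):
        sub = sub.set_index("subject")["value"]
        missing = [i for i in ids if i not in sub.index]
        if missing:
            raise ValueError(f"missing subjects for {bundle}/{metric}: {missing}")
        y = sub.loc[ids].to_numpy(float)
        coef, t, p = group_regression(y, subjects)
        rows.append({"bundle": bundle, "metric": metric,
                     "coefficient": coef, "t": t, "p": p})
    return pd.DataFrame(rows).sort_values(["bundle", "metric"]).reset_index(drop=True)


@dataclass
class PointwiseResult:
    """Per-point group statistics for one bundle x metric."""

    bundle: str
    metric: str
    coefficients: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float
    family: int
    kind: str = "group"
    score: str = ""
    r_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        d = {
            "bundle": self.bundle,
            "metric": self.metric,
            "point": np.arange(self.p_values.size),
            "p": self.p_values,
            "significant": self.significant,
        }
        if self.kind == "group":
            d["coefficient"] = self.coefficients
            d["t"] = self.t_values
        else:
            d["score"] = self.score
            d["r"] = self.r_values
        return pd.DataFrame(d)


def _profile_matrix(profiles: pd.DataFrame, subjects: pd.DataFrame,
                    bundle: str, metric: str, n_points: int):
    """Pivot a long profile table to (n_subjects, n_points), subject-ordered,
    smoothing rows that are not yet smoothed."""
    sub = profiles[(profiles["bundle"] == bundle) & (profiles["metric"] == metric)]
    wide = sub.pivot(index="subject", columns="point", values="value")
    ids = [i for i in subjects["id"] if i in wide.index]
    missing = [i for i in subjects["id"] if i not in wide.index]
    if missing:
        raise ValueError(f"profiles missing for subjects: {missing}")
    wide = wide.loc[ids, range(n_points)]
    y = wide.to_numpy(float)
    smoothed_flags = sub.groupby("subject")["smoothed"].all()
    if not smoothed_flags.loc[ids].all():
        logger.info("smoothing unsmoothed profiles for %s/%s before analysis",
                    bundle, metric)
        y = np.vstack([smooth_profile(row, n=n_points) for row in y])
    return y, ids


def tractwise_analysis(profiles: pd.DataFrame, subjects: pd.DataFrame,
                       alpha: float = 0.05, family: int | None = None,
                       n_points: int = 30) -> dict:
    """Pointwise group regressions along every bundle x metric profile.

    ``profiles`` is long-format (subject, bundle, metric, point, value,
    smoothed).  Unsmoothed profiles are smoothed first (with a log notice).
    Bonferroni control is applied within each bundle x metric over the
    ``family`` tests (default: the ``n_points`` arc-length points).
    Returns ``{(bundle, metric): PointwiseResult}``.
    """
    if family is None:
        family = n_points
    results = {}
    for (bundle, metric), _ in profiles.groupby(["bundle", "metric"], sort=True):
        y, ids = _profile_matrix(profiles, subjects, bundle, metric, n_points)
        subj = subjects.set_index("id").loc[ids].reset_index()
        coefs = np.empty(n_points)
        ts = np.empty(n_points)
        ps = np.empty(n_points)
        for j in range(n_points):
            coefs[j], ts[j], ps[j] = group_regression(y[:, j], subj)
        results[(bundle, metric)] = PointwiseResult(
            bundle=bundle, metric=metric, coefficients=coefs, t_values=ts,
            p_values=ps, significant=ps < alpha / family, alpha=alpha, family=family,
        )
    return results


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None = None):
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on ``[intercept, covariates]`` by least
    squares; the Pearson correlation r of the residuals is tested with
    ``t = r * sqrt((n - 2 - k) / (1 - r^2))`` on ``n - 2 - k`` degrees of
    freedom (k covariates).  With no covariates this is the plain Pearson
    correlation.  Returns ``(r, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = C.shape[1]
    if n <= k + 3:
        raise ValueError(f"too few observations (n={n}) for {k} covariates")
    Z = np.column_stack([np.ones(n), C])
    beta_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rx = x - Z @ beta_x
    ry = y - Z @ beta_y
    sx = np.sqrt(np.sum(rx ** 2))
    sy = np.sqrt(np.sum(ry ** 2))
    if sx <= 1e-10 * max(1.0, np.linalg.norm(x)) or \
            sy <= 1e-10 * max(1.0, np.linalg.norm(y)):
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.dot(rx, ry) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p)


DEFAULT_SCORES = ("panss_total", "panss_positive", "panss_negative", "panss_general")


def clinical_correlation(profiles: pd.DataFrame, subjects: pd.DataFrame,
                         scores=DEFAULT_SCORES, alpha: float = 0.05,
                         family: int | None = None, n_points: int = 30) -> dict:
    """Pointwise partial correlations of profiles with clinical scores.

    Restricted to patients; covariates are age, education and illness
    duration.  One Bonferroni family per bundle x metric x score (default
    size ``n_points``).  Returns ``{(bundle, metric, score): PointwiseResult}``
    with r values and significance flags.
    """
    if family is None:
        family = n_points
    missing = [s for s in scores if s not in subjects.columns]
    if missing:
        raise ValueError(f"subject table is missing score columns: {missing}")
    patients = subjects[subjects["group"] == "patient"].reset_index(drop=True)
    if len(patients) < 8:
        raise ValueError(f"need at least 8 patients, have {len(patients)}")
    C = np.column_stack([patients[c].to_numpy(float) for c in COVARIATES])
    results = {}
    for (bundle, metric), _ in profiles.groupby(["bundle", "metric"], sort=True):
        y, ids = _profile_matrix(profiles, patients, bundle, metric, n_points)
        for score in scores:
            s = patients.set_index("id").loc[ids, score].to_numpy(float)
            rs = np.empty(n_points)
            ps = np.empty(n_points)
            for j in range(n_points):
                rs[j], ps[j] = partial_correlation(y[:, j], s, C)
            results[(bundle, metric, score)] = PointwiseResult(
                bundle=bundle, metric=metric, coefficients=rs, t_values=rs,
                p_values=ps, significant=ps < alpha / family, alpha=alpha,
                family=family, kind="correlation", score=score, r_values=rs,
            )
    return results
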