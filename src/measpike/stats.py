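"""Longitudinal statistics: spline mixed models, marginal-mean contrasts with
Holm adjustment, and the two-sample t-test.

Each electrophysiological feature is modeled as

    y_ij = f_g(i)(t_ij) + u_i + e_ij,   u_i ~ N(0, s_u^2),  e_ij ~ N(0, s_e^2)

where f_g is a separate cubic B-spline curve per group (culture or treatment
arm), fit by restricted maximum likelihood with a random intercept per
device.  Group trajectories are compared through estimated marginal means
(EMMs): the fitted curve values at each session timepoint.  Within a
feature's comparison family, p-values are adjusted by the Holm step-down
procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.interpolate import BSpline
import statsmodels.api as sm

__all__ = [
    "SplineLMEResult",
    "bspline_basis",
    "fit_spline_lme",
    "estimated_marginal_means",
    "emm_contrasts_holm",
    "holm_adjust",
    "two_sample_ttest",
]


def bspline_basis(times: np.ndarray, grid: Sequence[float], degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix anchored to the session grid.

    The basis spans the intercept (rows sum to 1); boundary knots sit at the
    first and last session.  Interior knots are chosen from the interior
    sessions so that, for a grid of m sessions, the basis has exactly m
    columns -- full rank on the observed sessions, so each group's curve can
    interpolate its session means and the fixed effects stay identifiable.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size < 2:
        raise ValueError("need at least two distinct sessions")
    m = grid.size
    if m <= degree:
        degree = m - 1
    n_interior = m - degree - 1
    if n_interior > 0:
        pick = np.round(np.linspace(1, m - 2, n_interior)).astype(int)
        interior = grid[pick]
    else:
        interior = np.empty(0)
    t_knots = np.concatenate(
        [np.repeat(grid[0], degree + 1), interior, np.repeat(grid[-1], degree + 1)]
    )
    times = np.asarray(times, dtype=float)
    if times.min() < grid[0] or times.max() > grid[-1]:
        raise ValueError("times outside the session grid")
    # clip the right boundary into the half-open support of the last basis
    t_eval = np.minimum(times, grid[-1] - 1e-12 * max(1.0, abs(grid[-1])))
    return BSpline.design_matrix(t_eval, t_knots, degree).toarray()


@dataclass
class SplineLMEResult:
    """Fitted group-by-spline mixed model (fixed effects + their covariance)."""

    feature: str
    groups: List[str]  # group levels, in design order
    grid: Tuple[float, ...]
    degree: int
    params: np.ndarray  # fixed effects, one spline curve per group
    cov: np.ndarray  # covariance of the fixed effects
    converged: bool
    n_obs: int
    n_devices: int
    scale: float  # residual variance
    re_var: float  # device random-intercept variance

    @property
    def k_basis(self) -> int:
        return self.params.size // len(self.groups)

    def group_curve(self, group: str, times: np.ndarray) -> np.ndarray:
        """Fitted mean trajectory for one group."""
        row = self._emm_rows(group, np.atleast_1d(times))
        return row @ self.params

    def _emm_rows(self, group: str, times: np.ndarray) -> np.ndarray:
        B = bspline_basis(times, self.grid, self.degree)
        k = self.k_basis
        rows = np.zeros((B.shape[0], self.params.size))
        g = self.groups.index(group)
        rows[:, g * k : (g + 1) * k] = B
        return rows


def fit_spline_lme(
    table: pd.DataFrame,
    feature: str,
    group_col: str = "culture",
    time_col: str = "session",
    device_col: str = "device",
    degree: int = 3,
    grid: Optional[Sequence[float]] = None,
) -> SplineLMEResult:
    """Fit the group x B-spline mixed model for one feature.

    Rows with a missing feature value are dropped (sessions where a feature
    was uncomputable, e.g. no active channels after an insult).  The mean
    structure is a separate spline curve per group level; the random
    structure is an intercept per device; fitting is by REML.
    """
    df = table[[device_col, group_col, time_col, feature]].dropna()
    if df.empty:
        raise ValueError(f"no usable observations for feature {feature!r}")
    groups = sorted(df[group_col].astype(str).unique())
    if grid is None:
        grid = sorted(df[time_col].unique())
    t = df[time_col].to_numpy(dtype=float)
    B = bspline_basis(t, grid, degree)
    k = B.shape[1]
    X = np.zeros((len(df), k * len(groups)))
    glabels = df[group_col].astype(str).to_numpy()
    for gi, g in enumerate(groups):
        rows = glabels == g
        X[rows, gi * k : (gi + 1) * k] = B[rows]
    y = df[feature].to_numpy(dtype=float)
    devices = df[device_col].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=devices)
        # gradient optimizers stall on near-boundary variance components;
        # cascade to direct-search methods before giving up
        result = None
        for method in ("lbfgs", "powell", "nm"):
            result = model.fit(reml=True, method=method, maxiter=2000)
            if result.converged:
                break
    scale = float(result.scale)
    re_var = float(np.asarray(result.cov_re).ravel()[0]) if result.cov_re.size else 0.0
    # Fixed-effect covariance by explicit GLS at the estimated variance
    # components: for a random intercept, V_d = s_e^2 I + s_u^2 J per device
    # and cov(beta) = (sum_d X_d' V_d^-1 X_d)^-1.  This is guaranteed PSD,
    # unlike the observed-information covariance at a rough optimum.
    info = np.zeros((X.shape[1], X.shape[1]))
    for dev in pd.unique(devices):
        Xd = X[devices == dev]
        n_d = Xd.shape[0]
        shrink = re_var / (scale + n_d * re_var) if scale + n_d * re_var > 0 else 0.0
        col_sums = Xd.sum(axis=0)
        info += (Xd.T @ Xd - shrink * np.outer(col_sums, col_sums)) / max(scale, 1e-12)
    cov = np.linalg.pinv(info)
    return SplineLMEResult(
        feature=feature,
        groups=groups,
        grid=tuple(float(g) for g in grid),
        degree=degree,
        params=np.asarray(result.fe_params),
        cov=cov,
        converged=bool(result.converged),
        n_obs=len(df),
        n_devices=int(pd.unique(devices).size),
        scale=scale,
        re_var=re_var,
    )


def estimated_marginal_means(
    fit: SplineLMEResult, times: Sequence[float]
) -> pd.DataFrame:
    """EMM (fitted curve value) and its SE per group per timepoint."""
    times = np.asarray(times, dtype=float)
    rows = []
    for g in fit.groups:
        L = fit._emm_rows(g, times)
        est = L @ fit.params
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", L, fit.cov, L), 0.0))
        for t, e, s in zip(times, est, se):
            rows.append({"group": g, "time": t, "emm": e, "se": s})
    return pd.DataFrame(rows)


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment of a family of raw p-values.

    Sorted ascending, the i-th smallest is multiplied by (m - i), running
    maxima enforce monotonicity, and values cap at 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _contrast_df(fit: SplineLMEResult, between_groups: bool) -> float:
    # Between-within residual partition: group contrasts are tested against
    # device-level information, within-group (time) contrasts against
    # observation-level residuals.
    n_groups = len(fit.groups)
    if between_groups:
        return max(fit.n_devices - n_groups, 1)
    return max(fit.n_obs - fit.n_devices - (fit.params.size - n_groups), 1)


def emm_contrasts_holm(
    fit: SplineLMEResult,
    times: Optional[Sequence[float]] = None,
    comparisons: Sequence[str] = ("vs-baseline", "between-groups"),
    baseline: Optional[float] = None,
) -> pd.DataFrame:
    """Marginal-mean contrasts on the session grid with Holm adjustment.

    ``"vs-baseline"`` compares each later timepoint with the first session
    within each group; ``"between-groups"`` compares each group pair at each
    timepoint.  All requested contrasts for the feature form one Holm
    family.  Raises if the model did not converge (contrasts suppressed) or
    its fixed-effect covariance is singular.
    """
    if not fit.converged:
        raise RuntimeError(
            f"model for {fit.feature!r} did not converge; contrasts suppressed"
        )
    if not np.all(np.isfinite(fit.cov)):
        raise np.linalg.LinAlgError("singular fixed-effect covariance")
    if times is None:
        times = fit.grid
    times = np.asarray(sorted(times), dtype=float)
    if baseline is None:
        baseline = times[0]
    rows: List[dict] = []

    def add(L: np.ndarray, timepoint, comparison, label, between):
        est = float(L @ fit.params)
        var = float(L @ fit.cov @ L)
        if var < -1e-8:
            raise np.linalg.LinAlgError("negative contrast variance")
        se = np.sqrt(max(var, 0.0))
        if se == 0:
            t_val, p = 0.0, 1.0
        else:
            t_val = est / se
            p = 2.0 * sstats.t.sf(abs(t_val), _contrast_df(fit, between))
        rows.append(
            {
                "feature": fit.feature,
                "timepoint": timepoint,
                "comparison": comparison,
                "contrast": label,
                "estimate": est,
                "se": se,
                "t": t_val,
                "p_raw": p,
            }
        )

    if "vs-baseline" in comparisons:
        for g in fit.groups:
            Lb = fit._emm_rows(g, np.asarray([baseline]))[0]
            for t in times:
                if t == baseline:
                    continue
                L = fit._emm_rows(g, np.asarray([t]))[0] - Lb
                add(L, t, "vs-baseline", f"{g}: {t} - {baseline}", between=False)
    if "between-groups" in comparisons:
        for i in range(len(fit.groups)):
            for j in range(i + 1, len(fit.groups)):
                g1, g2 = fit.groups[i], fit.groups[j]
                for t in times:
                    L = (
                        fit._emm_rows(g1, np.asarray([t]))[0]
                        - fit._emm_rows(g2, np.asarray([t]))[0]
                    )
                    add(L, t, "between-groups", f"{g1} - {g2} @ {t}", between=True)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def two_sample_ttest(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided pooled-variance (Student's) t-test.

    Degenerate zero-variance samples with equal means give (0, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sstats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise FloatingPointError("zero pooled variance with unequal means")
    return float(t), float(p)
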