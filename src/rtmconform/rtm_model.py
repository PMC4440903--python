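"""Random-slope, fixed-zero-intercept hierarchical model for RTM estimation.

The model explains the rating change ``c`` of item ``i`` in participant
``k`` by the participant's mean-centered initial rating ``r``::

    c_ik = beta1_k * r_ik + eps_ik,   eps_ik ~ N(0, sigma2_eps)
    beta1_k = gamma10 + delta_k,      delta_k ~ N(0, sigma2_delta)

The intercept is identically zero because both ``c`` and ``r`` are
centered within participant, so no intercept parameter is estimated.
``gamma10`` — the average slope of change on initial rating — is the
regression-toward-the-mean rate used downstream for correction.

Estimation maximizes the restricted likelihood (REML; full ML optional)
of the marginal model with per-participant covariance
``V_k = sigma2_delta * r_k r_k' + sigma2_eps * I``.  The criterion is
profiled down to the single variance ratio
``lambda = sigma2_delta / sigma2_eps``: for fixed lambda both the GLS
slope and the residual variance have closed forms, with ``V_k^{-1}``
available analytically through the rank-one (Sherman-Morrison) update.
Denominator degrees of freedom for the fixed-slope test use the
Satterthwaite approximation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["RTMModel", "RTMResults", "fit_control_hlm", "predict_rtm_change"]

_LAMBDA_MAX = 1e3
_LAMBDA_FLOOR = 1e-8


class DegenerateDesignError(ValueError):
    """No usable variance in the centered initial ratings."""


@dataclass
class _SuffStats:
    """Per-participant sufficient statistics of the profiled criterion."""

    S: np.ndarray  # sum r^2 per participant
    t: np.ndarray  # sum r*c per participant
    cc: np.ndarray  # sum c^2 per participant
    n: np.ndarray  # items per participant
    ids: np.ndarray

    @property
    def N(self) -> int:
        return int(self.n.sum())


def _suffstats(r, c, groups) -> _SuffStats:
    df = pd.DataFrame(
        {"r": np.asarray(r, float), "c": np.asarray(c, float), "g": np.asarray(groups)}
    )
    if df[["r", "c"]].isna().any().any():
        raise ValueError("NaN in model variables")
    agg = df.groupby("g", sort=True).apply(
        lambda d: pd.Series(
            {
                "S": (d.r**2).sum(),
                "t": (d.r * d.c).sum(),
                "cc": (d.c**2).sum(),
                "n": len(d),
            }
        ),
        include_groups=False,
    )
    if len(agg) < 2:
        raise ValueError("need at least 2 participants")
    if (agg.n < 2).any():
        raise ValueError("every participant needs at least 2 items")
    if (agg.S <= 0).any():
        raise DegenerateDesignError(
            "a participant has no variance in centered initial ratings"
        )
    return _SuffStats(
        agg.S.to_numpy(),
        agg.t.to_numpy(),
        agg.cc.to_numpy(),
        agg.n.to_numpy(int),
        agg.index.to_numpy(),
    )


def _gls_parts(ss: _SuffStats, lam: float):
    """GLS slope, weighted RSS and the fixed-effect information for a
    given variance ratio, via the rank-one inverse."""
    w = 1.0 + lam * ss.S
    A = (ss.S / w).sum()  # = X' Vtilde^{-1} X
    gamma = (ss.t / w).sum() / A
    rss = (
        ss.cc
        - lam * ss.t**2 / w
        - 2.0 * gamma * ss.t / w
        + gamma**2 * ss.S / w
    ).sum()
    return gamma, rss, A, w


def _neg2loglik_profiled(lam: float, ss: _SuffStats, reml: bool) -> float:
    gamma, rss, A, w = _gls_parts(ss, lam)
    N = ss.N
    dof = N - 1 if reml else N
    sigma2 = rss / dof
    out = dof * (1.0 + np.log(2.0 * np.pi * sigma2)) + np.log(w).sum()
    if reml:
        out += np.log(A)
    return out


def _neg2loglik(theta: np.ndarray, ss: _SuffStats, reml: bool) -> float:
    """Unprofiled criterion in theta = (sigma2_eps, sigma2_delta); used
    for finite-difference curvature around the optimum."""
    s2e, s2d = theta
    if s2e <= 0:
        return np.inf
    lam = s2d / s2e
    w = 1.0 + lam * ss.S
    if (w <= 0).any():
        return np.inf
    A = (ss.S / w).sum() / s2e
    gamma = ((ss.t / w).sum() / s2e) / A
    rss = (
        ss.cc
        - lam * ss.t**2 / w
        - 2.0 * gamma * ss.t / w
        + gamma**2 * ss.S / w
    ).sum()
    N = ss.N
    out = N * np.log(s2e) + np.log(w).sum() + rss / s2e + N * np.log(2 * np.pi)
    if reml:
        out += np.log(A) - np.log(2 * np.pi)
    return out


def _var_gamma(theta: np.ndarray, ss: _SuffStats) -> float:
    s2e, s2d = theta
    return 1.0 / (ss.S / (s2e + s2d * ss.S)).sum()


def _satterthwaite_df(theta: np.ndarray, ss: _SuffStats, reml: bool) -> float:
    """df = 2 Var(gamma)^2 / (g' A g) with g the gradient of Var(gamma)
    in the variance components and A their asymptotic covariance (twice
    the inverse curvature of the -2 log-likelihood)."""
    theta = np.asarray(theta, float)
    steps = 1e-5 * np.maximum(np.abs(theta), 1e-3 * max(theta[0], 1e-12))

    def centralable(i):
        return theta[i] - steps[i] > 0 or (i == 1 and steps[i] * ss.S.max() < 0.5)

    grad = np.empty(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = steps[i]
        if centralable(i):
            grad[i] = (_var_gamma(theta + e, ss) - _var_gamma(theta - e, ss)) / (
                2 * steps[i]
            )
        else:
            grad[i] = (_var_gamma(theta + e, ss) - _var_gamma(theta, ss)) / steps[i]

    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(i + 1):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = steps[i]
            ej[j] = steps[j]
            use_central = centralable(i) and centralable(j)
            if use_central:
                val = (
                    _neg2loglik(theta + ei + ej, ss, reml)
                    - _neg2loglik(theta + ei - ej, ss, reml)
                    - _neg2loglik(theta - ei + ej, ss, reml)
                    + _neg2loglik(theta - ei - ej, ss, reml)
                ) / (4 * steps[i] * steps[j])
            else:
                f0 = _neg2loglik(theta, ss, reml)
                val = (
                    _neg2loglik(theta + ei + ej, ss, reml)
                    - _neg2loglik(theta + ei, ss, reml)
                    - _neg2loglik(theta + ej, ss, reml)
                    + f0
                ) / (steps[i] * steps[j])
            hess[i, j] = hess[j, i] = val
    var_g = _var_gamma(theta, ss)
    try:
        acov = 2.0 * np.linalg.inv(hess)
        denom = float(grad @ acov @ grad)
    except np.linalg.LinAlgError:
        denom = np.nan
    if not np.isfinite(denom) or denom <= 0:
        # curvature unusable (typically the boundary sigma2_delta = 0):
        # fall back to the residual degrees of freedom
        return float(ss.N - 1)
    return 2.0 * var_g**2 / denom


class RTMModel:
    """Random-slope regression of rating change on centered initial rating.

    Parameters
    ----------
    change : array-like
        Rating change ``c`` per item (centered session 2 minus centered
        session 1).
    rating : array-like
        Mean-centered initial rating ``r`` per item.
    groups : array-like
        Participant identifier per item.

    Examples
    --------
    >>> fit = RTMModel.from_dataframe(control_items).fit()
    >>> fit.gamma10, fit.se_gamma10
    """

    def __init__(self, change, rating, groups):
        self.ss = _suffstats(rating, change, groups)
        self._data = (np.asarray(rating, float), np.asarray(change, float))

    @classmethod
    def from_dataframe(
        cls,
        items: pd.DataFrame,
        change_col: str = "c",
        rating_col: str = "r",
        group_col: str = "participant_id",
    ) -> "RTMModel":
        return cls(items[change_col], items[rating_col], items[group_col])

    def fit(self, reml: bool = True, lambda_: float | None = None) -> "RTMResults":
        """Fit by REML (default) or full ML.

        ``lambda_`` fixes the variance ratio sigma2_delta/sigma2_eps
        instead of profiling it (0 constrains the slope to be common, in
        which case the GLS estimate reduces to the pooled through-origin
        least-squares slope).
        """
        ss = self.ss
        dof = ss.N - 1 if reml else ss.N

        # exact-fit degeneracy: a single common slope explains the data
        # perfectly, so the residual variance collapses to zero
        g0, rss0, _, _ = _gls_parts(ss, 0.0)
        total_cc = float(ss.cc.sum())
        if rss0 <= 1e-12 * max(total_cc, 1.0):
            return self._degenerate_results(g0, rss0 / dof, reml)

        if lambda_ is not None:
            if lambda_ < 0:
                raise ValueError("lambda_ must be nonnegative")
            lam = float(lambda_)
            crit = _neg2loglik_profiled(lam, ss, reml)
        else:
            def objective(u: float) -> float:
                return _neg2loglik_profiled(np.exp(u) - _LAMBDA_FLOOR, ss, reml)

            res = optimize.minimize_scalar(
                objective,
                bounds=(np.log(_LAMBDA_FLOOR), np.log(_LAMBDA_MAX + _LAMBDA_FLOOR)),
                method="bounded",
                options={"xatol": 1e-12},
            )
            if not res.success:
                raise RuntimeError(f"variance-ratio search failed: {res.message}")
            lam = max(np.exp(res.x) - _LAMBDA_FLOOR, 0.0)
            crit = float(res.fun)
            # the zero boundary (no slope heterogeneity) is a legal solution
            crit0 = _neg2loglik_profiled(0.0, ss, reml)
            if crit0 <= crit + 1e-10:
                lam, crit = 0.0, crit0

        gamma, rss, A, w = _gls_parts(ss, lam)
        sigma2_eps = rss / dof
        sigma2_delta = lam * sigma2_eps
        theta = np.array([sigma2_eps, sigma2_delta])

        var_gamma = _var_gamma(theta, ss)
        se = float(np.sqrt(var_gamma))
        df_satt = _satterthwaite_df(theta, ss, reml)
        fval = (gamma / se) ** 2
        pval = float(stats.f.sf(fval, 1, df_satt))
        blups = gamma + lam * (ss.t - gamma * ss.S) / w
        return RTMResults(
            model=self,
            gamma10=float(gamma),
            se_gamma10=se,
            sigma2_eps=float(sigma2_eps),
            sigma2_delta=float(sigma2_delta),
            df_satterthwaite=float(df_satt),
            f_stat=float(fval),
            p_value=pval,
            blup_slopes=pd.Series(blups, index=ss.ids, name="beta1k"),
            reml=reml,
            neg2loglik=crit,
        )

    def _degenerate_results(self, gamma: float, sigma2_eps: float, reml: bool) -> "RTMResults":
        ss = self.ss
        return RTMResults(
            model=self,
            gamma10=float(gamma),
            se_gamma10=0.0,
            sigma2_eps=float(sigma2_eps),
            sigma2_delta=0.0,
            df_satterthwaite=float(ss.N - 1),
            f_stat=float("inf"),
            p_value=0.0,
            blup_slopes=pd.Series(np.full(len(ss.ids), gamma), index=ss.ids, name="beta1k"),
            reml=reml,
            neg2loglik=float("-inf"),
        )


@dataclass
class RTMResults:
    """Fitted RTM model: the average slope, its uncertainty, variance
    components and per-participant slope predictions (BLUPs)."""

    model: RTMModel
    gamma10: float
    se_gamma10: float
    sigma2_eps: float
    sigma2_delta: float
    df_satterthwaite: float
    f_stat: float
    p_value: float
    blup_slopes: pd.Series
    reml: bool
    neg2loglik: float

    def predict(self, r) -> np.ndarray | float:
        """Expected RTM-induced rating change at centered initial rating
        ``r``: ``gamma10 * r``."""
        return self.gamma10 * np.asarray(r) if np.ndim(r) else self.gamma10 * r

    def correct(self, items: pd.DataFrame, **kwargs) -> pd.DataFrame:
        """Convenience wrapper around
        :func:`rtmconform.correction.correct_rating_changes`."""
        from .correction import correct_rating_changes

        return correct_rating_changes(items, self.gamma10, **kwargs)

    def to_dict(self) -> dict:
        return {
            "gamma10": self.gamma10,
            "se_gamma10": self.se_gamma10,
            "sigma2_eps": self.sigma2_eps,
            "sigma2_delta": self.sigma2_delta,
            "df_satterthwaite": self.df_satterthwaite,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "reml": self.reml,
            "neg2loglik": self.neg2loglik,
            "blup_slopes": {str(k): float(v) for k, v in self.blup_slopes.items()},
        }

    def to_json(self, path=None, **kwargs) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def summary(self) -> str:
        crit = "REML" if self.reml else "ML"
        lines = [
            "Random-slope RTM model (intercept fixed at 0)",
            "=" * 46,
            f"criterion            {crit}",
            f"participants         {len(self.blup_slopes)}",
            f"observations         {self.model.ss.N}",
            f"gamma10 (avg slope)  {self.gamma10: .4f}  (SE {self.se_gamma10:.4f})",
            f"F(1, {self.df_satterthwaite:.3f})        {self.f_stat:.3f}   p = {self.p_value:.3g}",
            f"sigma2_eps           {self.sigma2_eps:.4f}",
            f"sigma2_delta         {self.sigma2_delta:.4f}",
            f"-2 log-lik           {self.neg2loglik:.3f}",
        ]
        return "\n".join(lines)


def fit_control_hlm(items: pd.DataFrame, reml: bool = True, **cols) -> RTMResults:
    """Fit the RTM model on (control-group) centered items.

    ``items`` must carry columns ``c``, ``r`` and ``participant_id``
    (names overridable via ``change_col``/``rating_col``/``group_col``).
    If a ``group`` column is present, non-control rows are dropped with a
    warning — the RTM rate must come from data free of the social
    manipulation.
    """
    if "group" in items.columns and (items["group"] != "control").any():
        if (items["group"] == "control").any():
            warnings.warn("dropping non-control rows for the RTM fit")
            items = items[items["group"] == "control"]
        else:
            raise ValueError("RTM fit requires control-group data")
    return RTMModel.from_dataframe(items, **cols).fit(reml=reml)


def predict_rtm_change(fit: RTMResults, r):
    """Expected RTM-induced rating change ``gamma10 * r``."""
    return fit.predict(r)
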