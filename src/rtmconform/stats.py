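"""Inferential toolkit: mixed repeated-measures ANOVA with sphericity
handling and generalized eta-squared, Holm-corrected pairwise
comparisons, and t-tests with Cohen's d.

The ANOVA is the classical balanced mixed design: one within-subject
factor (the 3-level Deviation condition) and an optional between-subject
factor (group).  Conventions follow common psychological reporting
practice: Mauchly's test gates the sphericity correction at alpha = .05,
corrected p-values use the Huynh-Feldt epsilon applied to the
(reported-uncorrected) degrees of freedom, and the generalized
eta-squared denominator pools every subject-related error stratum so the
effect size is comparable across designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "TTestResult",
    "cell_means_table",
    "rm_anova_mixed",
    "holm_pairwise",
    "one_sample_t",
    "two_sample_t",
    "paired_t",
    "pearson_between_participants",
]

_SS_TOL = 1e-12


@dataclass(frozen=True)
class EffectRow:
    F: float
    df_num: float
    df_den: float
    p_uncorrected: float
    eta2_G: float
    p_corrected: float | None = None  # within effects only

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("F", "df_num", "df_den", "p_uncorrected", "eta2_G", "p_corrected")}


@dataclass(frozen=True)
class Sphericity:
    mauchly_w: float
    chi2: float
    df: float
    p: float
    epsilon_gg: float
    epsilon_hf: float
    correction_applied: bool

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("mauchly_w", "chi2", "df", "p", "epsilon_gg", "epsilon_hf",
                 "correction_applied")}


@dataclass(frozen=True)
class AnovaResult:
    effects: dict[str, EffectRow]
    sphericity: Sphericity
    n_subjects: int
    n_conditions: int

    def to_dict(self) -> dict:
        return {
            "effects": {k: v.to_dict() for k, v in self.effects.items()},
            "sphericity": self.sphericity.to_dict(),
            "n_subjects": self.n_subjects,
            "n_conditions": self.n_conditions,
        }

    def summary(self) -> str:
        lines = ["effect                F      df        p_unc    p_corr   eta2_G"]
        for name, e in self.effects.items():
            pc = f"{e.p_corrected:.3f}" if e.p_corrected is not None else "  -  "
            lines.append(
                f"{name:<18}{e.F:8.3f}  ({e.df_num:g},{e.df_den:g})"
                f"  {e.p_uncorrected:.3f}    {pc}    {e.eta2_G:.3f}"
            )
        s = self.sphericity
        lines.append(
            f"Mauchly W = {s.mauchly_w:.3f} (p = {s.p:.3f}); "
            f"eps_GG = {s.epsilon_gg:.3f}, eps_HF = {s.epsilon_hf:.3f}"
            + ("  [HF correction applied]" if s.correction_applied else "")
        )
        return "\n".join(lines)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    cohens_d: float
    mean_difference: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("t", "df", "p", "cohens_d", "mean_difference")}


def cell_means_table(
    items: pd.DataFrame,
    value_col: str,
    condition_col: str = "condition",
    participant_col: str = "participant_id",
) -> pd.DataFrame:
    """Participant-by-condition table of cell means; errors on missing cells."""
    table = items.pivot_table(
        index=participant_col, columns=condition_col, values=value_col, aggfunc="mean"
    )
    if table.isna().any().any():
        raise ValueError("unbalanced design: a participant is missing a condition")
    return table


def _sphericity(Y: np.ndarray, group_codes: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Mauchly's W with chi-square p, plus Greenhouse-Geisser and
    Huynh-Feldt epsilons, from the pooled within-group covariance of the
    condition means."""
    n, k = Y.shape
    groups = np.unique(group_codes)
    d = n - len(groups)  # pooled error df
    S = np.zeros((k, k))
    for g in groups:
        sub = Y[group_codes == g]
        if len(sub) > 1:
            S += (len(sub) - 1) * np.cov(sub, rowvar=False)
    S /= d
    # orthonormal contrast basis (k-1 rows orthogonal to the unit vector)
    C = np.linalg.qr(np.vstack([np.ones(k), np.eye(k)[: k - 1]]).T)[0][:, 1:].T
    T = C @ S @ C.T
    tr = float(np.trace(T))
    if tr < _SS_TOL or k < 3:
        return 1.0, 0.0, 0.0, 1.0, 1.0, 1.0
    eps_gg = tr**2 / ((k - 1) * float(np.trace(T @ T)))
    eps_hf = ((d + 1) * (k - 1) * eps_gg - 2) / ((k - 1) * (d - (k - 1) * eps_gg))
    eps_hf = min(eps_hf, 1.0)
    w = float(np.linalg.det(T)) / (tr / (k - 1)) ** (k - 1)
    w = min(max(w, np.finfo(float).tiny), 1.0)
    df_chi = k * (k - 1) / 2 - 1
    mult = d - (2 * (k - 1) ** 2 + (k - 1) + 2) / (6 * (k - 1))
    chi2 = -mult * np.log(w)
    p = float(sps.chi2.sf(chi2, df_chi))
    return w, float(chi2), df_chi, p, eps_gg, eps_hf


def _safe_f(ss_eff: float, df_eff: float, ss_err: float, df_err: float) -> tuple[float, float]:
    if ss_eff < _SS_TOL:
        return 0.0, 1.0
    F = (ss_eff / df_eff) / (ss_err / df_err)
    return float(F), float(sps.f.sf(F, df_eff, df_err))


def rm_anova_mixed(
    cell_means: pd.DataFrame,
    groups: pd.Series | None = None,
    sphericity_alpha: float = 0.05,
) -> AnovaResult:
    """Mixed-design ANOVA on a participant-by-condition cell-mean table.

    Parameters
    ----------
    cell_means
        Wide table, one row per participant, one column per level of the
        within factor (every cell present).
    groups
        Optional between-subject labels indexed like ``cell_means``.
        When omitted the analysis reduces exactly to a one-way
        repeated-measures ANOVA (no between or interaction rows).
    sphericity_alpha
        Mauchly-test level below which the Huynh-Feldt correction is
        applied to the within-effect p-values.
    """
    Y = cell_means.to_numpy(float)
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    if groups is None:
        codes = np.zeros(n, dtype=int)
    else:
        g = pd.Series(groups).reindex(cell_means.index)
        if g.isna().any():
            raise ValueError("group label missing for some participants")
        codes = pd.factorize(g)[0]
    levels = np.unique(codes)
    G = len(levels)
    if groups is not None and min(np.bincount(codes)) < 2:
        raise ValueError("need at least 2 participants per group")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    cond_means = Y.mean(axis=0)
    ss_total = float(((Y - grand) ** 2).sum())
    ss_subjects = float(k * ((subj_means - grand) ** 2).sum())
    ss_cond = float(n * ((cond_means - grand) ** 2).sum())

    if G > 1:
        group_means = np.array([Y[codes == g].mean() for g in levels])
        n_g = np.bincount(codes)
        ss_group = float(k * (n_g * (group_means - grand) ** 2).sum())
        cell = np.vstack([Y[codes == g].mean(axis=0) for g in levels])  # G x k
        ss_int = float(
            (
                n_g[:, None]
                * (cell - group_means[:, None] - cond_means[None, :] + grand) ** 2
            ).sum()
        )
    else:
        ss_group = 0.0
        ss_int = 0.0
    ss_subj_err = ss_subjects - ss_group
    ss_err_within = ss_total - ss_subjects - ss_cond - ss_int

    df_cond = k - 1
    df_group = G - 1
    df_int = (k - 1) * (G - 1)
    df_subj_err = n - G
    df_err_within = (n - G) * (k - 1)

    w, chi2, df_chi, p_sph, eps_gg, eps_hf = _sphericity(Y, codes)
    apply_corr = p_sph < sphericity_alpha

    eta_denom_err = ss_subj_err + ss_err_within

    def make_within(ss_eff: float, df_eff: float) -> EffectRow:
        F, p = _safe_f(ss_eff, df_eff, ss_err_within, df_err_within)
        eta = 0.0 if ss_eff < _SS_TOL else ss_eff / (ss_eff + eta_denom_err)
        if apply_corr and F > 0:
            p_corr = float(sps.f.sf(F, eps_hf * df_eff, eps_hf * df_err_within))
        else:
            p_corr = p
        return EffectRow(F, df_eff, df_err_within, p, eta, p_corr)

    effects: dict[str, EffectRow] = {"deviation": make_within(ss_cond, df_cond)}
    if G > 1:
        F_g, p_g = _safe_f(ss_group, df_group, ss_subj_err, df_subj_err)
        eta_g = 0.0 if ss_group < _SS_TOL else ss_group / (ss_group + eta_denom_err)
        effects["group"] = EffectRow(F_g, df_group, df_subj_err, p_g, eta_g, None)
        effects["deviation_x_group"] = make_within(ss_int, df_int)

    return AnovaResult(
        effects=effects,
        sphericity=Sphericity(w, chi2, df_chi, p_sph, eps_gg, eps_hf, apply_corr),
        n_subjects=n,
        n_conditions=k,
    )


def holm_pairwise(cell_means: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests between all condition pairs with Holm step-down
    adjusted p-values."""
    cols = list(cell_means.columns)
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    rows = []
    for a, b in pairs:
        res = paired_t(cell_means[a].to_numpy(), cell_means[b].to_numpy())
        rows.append(
            {"pair": f"{a} vs {b}", "mean_difference": res.mean_difference,
             "t": res.t, "df": res.df, "p_raw": res.p, "cohens_d": res.cohens_d}
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def _d_and_check(diff: np.ndarray, what: str) -> tuple[float, float]:
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError(f"degenerate {what}: zero standard deviation")
    return float(diff.mean()), float(sd)


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if x.std(ddof=1) == 0 and x.mean() == mu0:
        # every value equals the reference exactly: no evidence either way
        return TTestResult(0.0, float(x.size - 1), 1.0, 0.0, 0.0)
    mean, sd = _d_and_check(x - mu0, "sample")
    t, p = sps.ttest_1samp(x, mu0)
    return TTestResult(float(t), float(x.size - 1), float(p), mean / sd, mean)


def paired_t(values_a, values_b) -> TTestResult:
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def two_sample_t(group_a, group_b) -> TTestResult:
    """Pooled-variance two-sample t with Cohen's d on the pooled sd."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("degenerate samples: zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    diff = float(a.mean() - b.mean())
    return TTestResult(float(t), float(df), float(p), diff / float(np.sqrt(sp2)), diff)


def pearson_between_participants(x_scores, y_scores) -> dict:
    """Pearson correlation across participants with its t-based p-value
    (df = n - 2)."""
    x = np.asarray(x_scores, float)
    y = np.asarray(y_scores, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "df": int(x.size - 2), "p": float(p)}
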