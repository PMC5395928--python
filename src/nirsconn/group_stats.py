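"""Group comparisons and the anxiety-connectivity regression.

Demographic comparisons use Welch's unequal-variance two-sample t-test
(the form that reproduces the published anxiety comparison), accepting
either raw samples or printed (mean, sd, n) summaries.  The
anxiety-connectivity analysis regresses the STAI total score on the Fisher
z of each seed-target edge with age, IQ, education years and daily
cigarette consumption as covariates, pooling both groups, and controls the
family of target channels by Benjamini-Hochberg at FDR 10%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EstimationError, NirsconnError

DEFAULT_COVARIATES = ("age", "iq", "education", "cigarettes")

SIGNIFICANCE_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    for cut, label in SIGNIFICANCE_TIERS:
        if p < cut:
            return label
    return ""


@dataclass(frozen=True)
class StatResult:
    estimate: float
    tstat: float
    df: float
    pvalue: float
    label: str = ""
    qvalue: float = float("nan")

    def as_dict(self):
        return {"estimate": self.estimate, "t": self.tstat, "df": self.df,
                "p": self.pvalue, "q": self.qvalue, "label": self.label}


def _summary_of(sample) -> tuple:
    """(mean, sd, n) from raw samples or a (mean, sd, n) triple."""
    if isinstance(sample, (tuple, list)) and len(sample) == 3 \
            and np.isscalar(sample[0]):
        mean, sd, n = float(sample[0]), float(sample[1]), int(sample[2])
    else:
        x = np.asarray(sample, dtype=float)
        x = x[np.isfinite(x)]
        if len(x) < 2:
            raise NirsconnError("each group needs n >= 2")
        mean, sd, n = float(np.mean(x)), float(np.std(x, ddof=1)), len(x)
    if n < 2:
        raise NirsconnError("each group needs n >= 2")
    return mean, sd, n


def welch_ttest(group_a, group_b, label: str = "") -> StatResult:
    """Two-sided Welch t-test from raw samples or printed summaries."""
    m1, s1, n1 = _summary_of(group_a)
    m2, s2, n2 = _summary_of(group_b)
    if s1 <= 0 and s2 <= 0:
        if m1 == m2:
            return StatResult(0.0, 0.0, float(n1 + n2 - 2), 1.0, label)
        raise NirsconnError("zero variance in both groups with unequal means")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    t = float(res.statistic)
    p = 1.0 if (s1 == 0 and s2 == 0) else float(res.pvalue)
    if m1 == m2:
        t, p = 0.0, 1.0
    return StatResult(m1 - m2, t, float(df), p, label)


def combined_mean(stats_a, stats_b) -> float:
    """Sample-size-weighted mean of two group means: (mean, n) pairs."""
    (m1, n1), (m2, n2) = stats_a, stats_b
    if n1 <= 0 or n2 <= 0:
        raise NirsconnError("group sizes must be positive")
    return (n1 * m1 + n2 * m2) / (n1 + n2)


def bh_fdr(pvalues, q: float = 0.10):
    """Benjamini-Hochberg step-up: returns (qvalues, rejection mask)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def regress_anxiety_on_connectivity(cohort: pd.DataFrame, seed: int,
                                    targets, covariates=DEFAULT_COVARIATES,
                                    fdr_q: float = 0.10,
                                    group_term: bool = False) -> pd.DataFrame:
    """Per-target OLS: STAI ~ z(seed, target) + covariates, both groups pooled.

    ``cohort`` must hold one row per subject with columns ``stai``, the
    covariates, and ``z_<seed>_<target>`` edge values (Fisher z).  The
    connectivity coefficient's t and p are reported per target and the
    family is Benjamini-Hochberg corrected at ``fdr_q``.
    """
    covariates = list(covariates)
    needed = len(covariates) + 3
    rows = []
    for target in targets:
        col = f"z_{seed}_{target}"
        if col not in cohort.columns:
            raise NirsconnError(f"missing edge column {col!r}")
        cols = ["stai", col] + covariates + (["group"] if group_term else [])
        df = cohort[cols].dropna()
        if len(df) < needed:
            rows.append({"target": target, "estimate": np.nan, "t": np.nan,
                         "df": np.nan, "p": np.nan, "n": len(df)})
            continue
        X = df[[col] + covariates].astype(float)
        if group_term:
            X = X.assign(group_hd=(df["group"] == "HD").astype(float))
        zero_var = [c for c in X.columns if np.std(X[c].to_numpy()) == 0]
        if zero_var:
            raise EstimationError(f"zero-variance regressors: {zero_var}")
        Xc = sm.add_constant(X)
        if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
            corr = np.corrcoef(X.to_numpy(), rowvar=False)
            bad = [(X.columns[i], X.columns[j])
                   for i in range(corr.shape[0]) for j in range(i + 1, corr.shape[0])
                   if abs(corr[i, j]) > 0.999]
            raise EstimationError(f"collinear design; offending columns: {bad}")
        fit = sm.OLS(df["stai"].astype(float), Xc).fit()
        rows.append({"target": target, "estimate": float(fit.params[col]),
                     "se": float(fit.bse[col]), "t": float(fit.tvalues[col]),
                     "df": float(fit.df_resid), "p": float(fit.pvalues[col]),
                     "n": len(df)})
    out = pd.DataFrame(rows).set_index("target")
    valid = out["p"].notna()
    out["q"] = np.nan
    out["significant"] = False
    if valid.any():
        qvals, rej = bh_fdr(out.loc[valid, "p"].to_numpy(), q=fdr_q)
        out.loc[valid, "q"] = qvals
        out.loc[valid, "significant"] = rej
    return out


def compare_nodal_strength(strengths: pd.DataFrame,
                           groups: pd.Series) -> pd.DataFrame:
    """Per-channel two-sample Welch test of nodal strength across subjects.

    ``strengths`` is (subjects x channels); ``groups`` labels each subject
    HD or CG.  Channels masked (NaN) for all subjects of a group yield NaN.
    Output includes the significance tier used in figure annotations
    (* p<0.05 ... **** p<0.0001).
    """
    groups = groups.reindex(strengths.index)
    hd = strengths[groups == "HD"]
    cg = strengths[groups == "CG"]
    rows = []
    for ch in strengths.columns:
        a = hd[ch].dropna().to_numpy()
        b = cg[ch].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append({"channel": ch, "mean_hd": np.nan, "mean_cg": np.nan,
                         "t": np.nan, "p": np.nan, "tier": ""})
            continue
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            t, p = (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({"channel": ch, "mean_hd": float(np.mean(a)),
                     "mean_cg": float(np.mean(b)), "t": t, "p": p,
                     "tier": significance_tier(p)})
    return pd.DataFrame(rows).set_index("channel")


def demographic_table(summary: dict, n_hd: int, n_cg: int) -> pd.DataFrame:
    """Recompute combined means and group p-values from printed summaries.

    ``summary`` maps variable -> {"HD": (mean, sd), "CG": (mean, sd)}.
    """
    rows = []
    for var, per_group in summary.items():
        (m_hd, s_hd), (m_cg, s_cg) = per_group["HD"], per_group["CG"]
        res = welch_ttest((m_hd, s_hd, n_hd), (m_cg, s_cg, n_cg), label=var)
        rows.append({
            "variable": var,
            "all_mean": combined_mean((m_hd, n_hd), (m_cg, n_cg)),
            "hd_mean": m_hd, "cg_mean": m_cg,
            "t": res.tstat, "df": res.df, "p": res.pvalue})
    return pd.DataFrame(rows).set_index("variable")
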