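"""Two-group comparisons and ROC analysis.

The group test is the pooled-variance (Student) two-sample t-test with
``df = n_hs + n_pd - 2`` and the sign convention ``t = (mean_HS - mean_PD)
/ SE`` (healthy minus patient).  Significance is controlled with a fixed
Bonferroni factor (default 50, the number of kinematic plus dynamic
variables), so the corrected threshold at alpha = 0.05 is 0.001.

ROC analysis targets the patient group as positive with the raw feature as
score — higher values count as more PD-like, with no orientation flipping,
so variables on which patients score lower (e.g. gait speed) yield
AUC < 0.5.  AUC is the Mann-Whitney probability (ties count 1/2), the
standard error follows Hanley & McNeil (1982), the 95% CI is the normal
approximation ``AUC +/- 1.96*SE``, and the p-value tests AUC against 0.5.
A DeLong-style SE is not provided; only variables that pass the corrected
t-test threshold are sent to ROC by the suite runner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .features import DYNAMIC_VARIABLES, KINEMATIC_VARIABLES


@dataclass
class GroupComparison:
    variable: str
    n_hs: int
    mean_hs: float
    sd_hs: float
    n_pd: int
    mean_pd: float
    sd_pd: float
    t: float
    df: int
    p: float
    significant: bool


@dataclass
class RocResult:
    variable: str
    auc: float
    se: float
    p: float
    ci_lower: float
    ci_upper: float
    significant: bool


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-test significance level alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> Tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics.

    Returns ``(t, df, p)`` with ``t = (mean1 - mean2)/SE``,
    ``df = n1 + n2 - 2`` and a two-sided p from the t distribution.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var == 0.0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        raise ZeroDivisionError("zero pooled variance with unequal means")
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def t_test(
    values_hs: Sequence[float],
    values_pd: Sequence[float],
    variable: str = "",
    threshold: float = 0.001,
) -> GroupComparison:
    """Pooled two-sample t-test on raw per-subject values (HS minus PD)."""
    hs = np.asarray(values_hs, dtype=float)
    pd_ = np.asarray(values_pd, dtype=float)
    if hs.size < 2 or pd_.size < 2:
        raise ValueError("need at least 2 finite values per group")
    if not (np.isfinite(hs).all() and np.isfinite(pd_).all()):
        raise ValueError("non-finite values in input")
    m1, s1 = float(np.mean(hs)), float(np.std(hs, ddof=1))
    m2, s2 = float(np.mean(pd_)), float(np.std(pd_, ddof=1))
    t, df, p = t_from_summary(m1, s1, hs.size, m2, s2, pd_.size)
    return GroupComparison(
        variable=variable,
        n_hs=int(hs.size), mean_hs=m1, sd_hs=s1,
        n_pd=int(pd_.size), mean_pd=m2, sd_pd=s2,
        t=t, df=df, p=p, significant=bool(p < threshold),
    )


def roc_analysis(
    values: Sequence[float],
    labels: Sequence[str],
    variable: str = "",
    threshold: float = 0.001,
) -> RocResult:
    """AUC for 'is PD' with higher feature value scored as more PD-like."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    y = labels == "PD"
    n_pd = int(y.sum())
    n_hs = int((~y).sum())
    if n_pd < 2 or n_hs < 2:
        raise ValueError("need both classes with >= 2 subjects each")
    auc = float(roc_auc_score(y, values))

    # Hanley-McNeil SE; n_pd plays the "abnormal" role
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pd - 1) * (q1 - auc**2)
        + (n_hs - 1) * (q2 - auc**2)
    ) / (n_pd * n_hs)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    return RocResult(
        variable=variable,
        auc=auc,
        se=se,
        p=p,
        ci_lower=auc - 1.96 * se,
        ci_upper=auc + 1.96 * se,
        significant=bool(p < threshold),
    )


@dataclass
class ComparisonReport:
    kinematic: pd.DataFrame
    dynamic: pd.DataFrame
    roc: pd.DataFrame
    threshold: float


def _comparison_frame(rows: List[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "n_hs": r.n_hs, "mean_hs": r.mean_hs, "sd_hs": r.sd_hs,
                "n_pd": r.n_pd, "mean_pd": r.mean_pd, "sd_pd": r.sd_pd,
                "t": r.t, "df": r.df, "p": r.p, "significant": r.significant,
            }
            for r in rows
        ],
        columns=["variable", "n_hs", "mean_hs", "sd_hs", "n_pd", "mean_pd",
                 "sd_pd", "t", "df", "p", "significant"],
    )


def run_comparison_suite(
    features: pd.DataFrame,
    meta,
    alpha: float = 0.05,
    m: int = 50,
) -> ComparisonReport:
    """t-tests for every kinematic then dynamic variable, ROC for the
    kinematic variables that pass the corrected threshold.

    ``features`` is a long table (subject_id, variable, value); ``meta`` is
    a sequence of :class:`gaitmark.core.SubjectMeta` or a DataFrame with
    subject_id and group.  Subjects missing a variable are dropped for that
    variable only (per-variable n is reported).
    """
    threshold = bonferroni_threshold(alpha, m)
    if isinstance(meta, pd.DataFrame):
        groups = dict(zip(meta["subject_id"].astype(str), meta["group"]))
    else:
        groups = {m_.subject_id: m_.group for m_ in meta}
    feats = features.copy()
    feats["subject_id"] = feats["subject_id"].astype(str)
    feats["group"] = feats["subject_id"].map(groups)
    if feats["group"].isna().any():
        missing = sorted(feats.loc[feats["group"].isna(), "subject_id"].unique())
        raise ValueError(f"subjects missing from metadata: {missing}")

    def run_block(variables: List[str]) -> List[GroupComparison]:
        rows = []
        for var in variables:
            sub = feats[(feats["variable"] == var) & feats["value"].notna()]
            hs = sub.loc[sub["group"] == "HS", "value"].to_numpy()
            pd_vals = sub.loc[sub["group"] == "PD", "value"].to_numpy()
            if hs.size < 2 or pd_vals.size < 2:
                continue
            rows.append(t_test(hs, pd_vals, variable=var, threshold=threshold))
        return rows

    kin = run_block(KINEMATIC_VARIABLES)
    dyn = run_block(DYNAMIC_VARIABLES)

    roc_rows: List[RocResult] = []
    for r in kin:
        if not r.significant:
            continue
        sub = feats[(feats["variable"] == r.variable) & feats["value"].notna()]
        roc_rows.append(
            roc_analysis(
                sub["value"].to_numpy(),
                sub["group"].to_numpy(),
                variable=r.variable,
                threshold=threshold,
            )
        )
    roc_df = pd.DataFrame(
        [
            {
                "variable": r.variable, "auc": r.auc, "se": r.se, "p": r.p,
                "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
                "significant": r.significant,
            }
            for r in roc_rows
        ],
        columns=["variable", "auc", "se", "p", "ci_lower", "ci_upper", "significant"],
    )
    return ComparisonReport(
        kinematic=_comparison_frame(kin),
        dynamic=_comparison_frame(dyn),
        roc=roc_df,
        threshold=threshold,
    )
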