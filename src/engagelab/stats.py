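"""Engagement-score statistics.

The response throughout is a per-event Likert engagement rating (1-5)
treated as a continuous outcome in ordinary least squares, pooled across
sessions (events are modelled as independent).  Three kinds of output:

* regression reports pairing, for every predictor, a single-predictor fit
  ("individual") with its row in the all-predictor fit ("total");
* one-way ANOVA of scores by host with the eta-squared effect size
  (SS_between / SS_total), optional seeded down-sampling of every host to
  the smallest host's event count, and Tukey HSD post hoc comparisons;
* inter-rater percent agreement (exact, within one point, and their sum).

P values are raw; no multiple-testing correction is applied, and reports
say so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .praat_io import ValidationError

__all__ = [
    "OlsFit",
    "RegressionReport",
    "AnovaReport",
    "AgreementReport",
    "fit_ols",
    "individual_and_total",
    "downsample_equal",
    "anova_eta2",
    "interrater_agreement",
    "MODEL_PREDICTORS",
]

#: Predictor columns per named model family (general mirrors the combined
#: model: behaviors, host one-hot, group size, time budget — acoustics
#: excluded there by design).
MODEL_PREDICTORS: dict[str, tuple[str, ...]] = {
    "hosts": ("host1", "host2", "host3"),
    "behaviors": (
        "social", "humor", "game", "cue", "affirm", "disclose", "correct", "nonverbal",
    ),
    "acoustic": (
        "d_mean_pitch", "d_max_pitch", "d_min_pitch",
        "d_mean_int", "d_max_int", "d_min_int",
    ),
    "time": (
        "host_time", "control_time", "participant_time",
        "participant_fraction", "silence_fraction",
    ),
    "number": ("number",),
    "general": (
        "social", "humor", "game", "cue", "affirm", "disclose", "correct", "nonverbal",
        "host1", "host2", "host3", "number",
        "participant_time", "host_time", "control_time",
        "participant_fraction", "silence_fraction",
    ),
}

P_VALUE_FOOTNOTE = "p values are raw (no multiple-testing correction applied)"


@dataclass(frozen=True)
class OlsFit:
    """One ordinary-least-squares fit with intercept."""

    params: pd.Series       # coefficient estimates, "const" first
    se: pd.Series
    t: pd.Series
    p: pd.Series
    r2: float
    f_stat: float
    f_p: float
    df_resid: int
    n: int

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.se, "t": self.t, "p": self.p}
        )


def _check_design(X: pd.DataFrame, y: np.ndarray) -> None:
    n, k = X.shape
    if len(y) != n:
        raise ValidationError(f"response length {len(y)} != design rows {n}")
    if n <= k + 1:
        raise ValidationError(f"need n > k+1 (n={n}, k={k})")
    const_cols = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) == 0.0]
    if const_cols:
        raise ValidationError(f"constant predictor column(s) besides intercept: {const_cols}")
    Xc = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name the columns a pivoted QR would discard
        import scipy.linalg

        _, _, piv = scipy.linalg.qr(Xc, pivoting=True, mode="economic")
        names = ["(intercept)"] + list(X.columns)
        dropped = sorted(names[i] for i in piv[rank:])
        raise ValidationError(f"rank-deficient design; collinear column(s): {dropped}")


def fit_ols(X: pd.DataFrame, y: Sequence[float] | np.ndarray) -> OlsFit:
    """OLS of ``y`` on ``X`` plus an intercept.

    Coefficient p values come from the t distribution with ``n - (k+1)``
    degrees of freedom; the F statistic compares against the
    intercept-only model.  A rank-deficient design raises, naming the
    collinear columns.
    """
    y = np.asarray(y, dtype=float)
    _check_design(X, y)
    design = sm.add_constant(X.astype(float), prepend=True)
    res = sm.OLS(y, design).fit()
    return OlsFit(
        params=res.params,
        se=res.bse,
        t=res.tvalues,
        p=res.pvalues,
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        f_p=float(res.f_pvalue),
        df_resid=int(res.df_resid),
        n=int(res.nobs),
    )


@dataclass
class RegressionReport:
    """Individual single-predictor fits side by side with the joint fit.

    ``table`` has one row per predictor with individual_coef/SE/R2/p and
    total_coef/SE/t/p; model-level numbers describe the joint fit.
    """

    table: pd.DataFrame
    total_r2: float
    f_vs_constant: float
    f_p: float
    error_df: int
    n: int
    total_fit: OlsFit
    footnote: str = P_VALUE_FOOTNOTE

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# total_R2={self.total_r2!r} F={self.f_vs_constant!r} "
                     f"F_p={self.f_p!r} error_df={self.error_df} n={self.n}\n")
            fh.write(f"# {self.footnote}\n")
            self.table.to_csv(fh, index=True, index_label="predictor")


def individual_and_total(
    X: pd.DataFrame, y: Sequence[float] | np.ndarray
) -> RegressionReport:
    """Fit each predictor alone (with intercept) and all jointly."""
    y = np.asarray(y, dtype=float)
    total = fit_ols(X, y)
    rows = {}
    for col in X.columns:
        single = fit_ols(X[[col]], y)
        rows[col] = {
            "individual_coef": single.params[col],
            "individual_se": single.se[col],
            "individual_r2": single.r2,
            "individual_p": single.p[col],
            "total_coef": total.params[col],
            "total_se": total.se[col],
            "total_t": total.t[col],
            "total_p": total.p[col],
        }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(X.columns)]
    return RegressionReport(
        table=table,
        total_r2=total.r2,
        f_vs_constant=total.f_stat,
        f_p=total.f_p,
        error_df=total.df_resid,
        n=total.n,
        total_fit=total,
    )


def downsample_equal(
    groups: Mapping[str, Sequence[float]], seed: int
) -> dict[str, np.ndarray]:
    """Reduce every group to the smallest group's size.

    Seeded sampling without replacement; groups already at the minimum
    size are passed through unchanged.  The caller records the seed.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups to balance")
    sizes = {k: len(v) for k, v in groups.items()}
    if min(sizes.values()) == 0:
        raise ValidationError(f"empty group(s): {[k for k, s in sizes.items() if s == 0]}")
    m = min(sizes.values())
    rng = np.random.default_rng(seed)
    out = {}
    for key in groups:  # insertion order keeps draws reproducible
        arr = np.asarray(groups[key], dtype=float)
        if len(arr) == m:
            out[key] = arr.copy()
        else:
            out[key] = arr[rng.choice(len(arr), size=m, replace=False)]
    return out


@dataclass
class AnovaReport:
    """One-way ANOVA with effect size and Tukey HSD post hoc tests."""

    eta_squared: float
    f_stat: float
    p_value: float
    group_means: dict[str, float]
    group_ns: dict[str, int]
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject
    seed: int | None = None  # down-sampling seed, when balancing was applied

    def to_dict(self) -> dict:
        return {
            "eta_squared": self.eta_squared,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "group_means": self.group_means,
            "group_ns": self.group_ns,
            "tukey": self.tukey.to_dict(orient="records"),
            "seed": self.seed,
        }


def anova_eta2(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    seed: int | None = None,
) -> AnovaReport:
    """One-way ANOVA across groups with eta-squared and Tukey HSD.

    eta^2 = SS_between / SS_total; the p value comes from the F
    distribution.  ``seed`` is recorded verbatim when the caller balanced
    the groups first.
    """
    keys = list(groups)
    if len(keys) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    if any(len(a) < 2 for a in arrays):
        raise ValidationError("every group needs >= 2 observations")
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    if ss_total == 0.0:
        raise ValidationError("zero total variance; ANOVA undefined")
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays))
    f_stat, p_value = scipy.stats.f_oneway(*arrays)
    labels = np.concatenate([[k] * len(a) for k, a in zip(keys, arrays)])
    hsd = pairwise_tukeyhsd(allv, labels, alpha=alpha)
    tukey = pd.DataFrame(
        hsd.summary().data[1:],
        columns=[str(c) for c in hsd.summary().data[0]],
    ).rename(columns={"p-adj": "p_adj"})
    return AnovaReport(
        eta_squared=ss_between / ss_total,
        f_stat=float(f_stat),
        p_value=float(p_value),
        group_means={k: float(a.mean()) for k, a in zip(keys, arrays)},
        group_ns={k: int(len(a)) for k, a in zip(keys, arrays)},
        tukey=tukey,
        seed=seed,
    )


@dataclass(frozen=True)
class AgreementReport:
    """Percent agreement between two raters' Likert scores."""

    pct_exact: float
    pct_within_one: float  # exactly one point apart (exclusive of exact)
    n: int

    @property
    def pct_approx(self) -> float:
        """Overall approximate agreement: exact + within one point."""
        return self.pct_exact + self.pct_within_one


def interrater_agreement(
    scores_r1: Sequence[int], scores_r2: Sequence[int]
) -> AgreementReport:
    """Percent exact / within-one-point agreement of two aligned raters."""
    a = np.asarray(scores_r1)
    b = np.asarray(scores_r2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"score vectors must be aligned 1-d (got {a.shape} vs {b.shape})"
        )
    if len(a) == 0:
        raise ValidationError("empty score vectors")
    diff = np.abs(a - b)
    return AgreementReport(
        pct_exact=100.0 * float(np.mean(diff == 0)),
        pct_within_one=100.0 * float(np.mean(diff == 1)),
        n=len(a),
    )
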