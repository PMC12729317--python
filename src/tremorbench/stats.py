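"""Repeated-measures analysis of the three-condition within-subject design.

Implements the study's analysis plan from first principles: one-factor
repeated-measures ANOVA via the classical sums-of-squares decomposition

    SS_total = SS_subject + SS_condition + SS_residual,
    F = MS_condition / MS_residual,  df = (k-1, (k-1)(n-1)),

with partial eta^2 = SS_condition / (SS_condition + SS_residual),
Mauchly's sphericity test and the Greenhouse-Geisser epsilon on the
orthonormal-contrast covariance, Bonferroni-adjusted paired t-tests with
paired Cohen's d (mean difference / SD of differences), descriptive
statistics with 95% t-based confidence intervals, and residual diagnostics
(normal Q-Q and residual-vs-fitted tables).

Both the uncorrected p and the epsilon-corrected p are always reported, so
either reporting style (sphericity held vs corrected) is reproducible.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

__all__ = [
    "RMTable",
    "AnovaResult",
    "PairwiseResult",
    "DegenerateDataError",
    "rm_anova",
    "pairwise_bonferroni",
    "descriptives",
    "assumption_diagnostics",
    "qq_correlation",
    "anova_report",
]


class DegenerateDataError(ValueError):
    """Raised when the residual variance is zero and F is undefined."""


@dataclass
class RMTable:
    """Complete subject x condition outcome matrix (no missing cells)."""

    subjects: list[str]
    conditions: list[str]
    values: np.ndarray  # shape (n_subjects, n_conditions)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = len(self.subjects), len(self.conditions)
        if self.values.shape != (n, k):
            raise ValueError(
                f"values shape {self.values.shape} != ({n} subjects, {k} conditions)"
            )
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 conditions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("table contains missing/non-finite cells (no imputation)")

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def k(self) -> int:
        return len(self.conditions)

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "RMTable":
        """Rows = subjects (index), columns = conditions."""
        return cls(
            subjects=[str(s) for s in df.index],
            conditions=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        value: str,
        subject: str = "subject",
        condition: str = "condition",
    ) -> "RMTable":
        wide = df.pivot(index=subject, columns=condition, values=value)
        if wide.isna().any().any():
            raise ValueError("incomplete design: missing subject x condition cells")
        return cls.from_wide(wide)


@dataclass
class AnovaResult:
    f: float
    df1: int
    df2: int
    p: float
    eta_sq_partial: float
    gg_epsilon: float
    p_gg: float
    mauchly_w: float
    mauchly_p: float
    ss_condition: float = field(repr=False, default=math.nan)
    ss_subject: float = field(repr=False, default=math.nan)
    ss_residual: float = field(repr=False, default=math.nan)
    ss_total: float = field(repr=False, default=math.nan)


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    mean_diff: float
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    cohens_d: float
    degenerate: bool = False


def _contrast_cov(values: np.ndarray) -> np.ndarray:
    """Covariance of the data projected onto orthonormal contrasts."""
    c = helmert(values.shape[1], full=False)  # (k-1, k), rows orthonormal
    projected = values @ c.T
    return np.cov(projected, rowvar=False, ddof=1).reshape(
        values.shape[1] - 1, values.shape[1] - 1
    )


def rm_anova(table: RMTable) -> AnovaResult:
    """One-factor repeated-measures ANOVA with sphericity diagnostics.

    Raises :class:`DegenerateDataError` when the residual variance is zero
    (perfectly additive data), where F is undefined.
    """
    v = table.values
    n, k = table.n, table.k
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_total = float(((v - grand) ** 2).sum())
    ss_subject = float(k * ((row_means - grand) ** 2).sum())
    ss_condition = float(n * ((col_means - grand) ** 2).sum())
    ss_residual = max(0.0, ss_total - ss_subject - ss_condition)
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_residual = ss_residual / df2
    if ms_residual <= 1e-12 * max(1.0, ss_total):
        raise DegenerateDataError(
            "zero residual variance: F is undefined for this table"
        )
    f_stat = (ss_condition / df1) / ms_residual
    p = float(sps.f.sf(f_stat, df1, df2))
    eta_p = ss_condition / (ss_condition + ss_residual)

    s = _contrast_cov(v)
    tr_s = float(np.trace(s))
    eps = tr_s**2 / ((k - 1) * float(np.sum(s * s)))
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))
    p_gg = float(sps.f.sf(f_stat, eps * df1, eps * df2))

    if k == 2:
        w, p_m = 1.0, 1.0  # sphericity holds trivially
    else:
        det = float(np.linalg.det(s))
        if det <= 0 or tr_s <= 0:
            warnings.warn(
                "singular contrast covariance; Mauchly's test undefined",
                stacklevel=2,
            )
            w, p_m = math.nan, math.nan
        else:
            w = det / (tr_s / (k - 1)) ** (k - 1)
            df_m = k * (k - 1) // 2 - 1
            factor = 1.0 - (2 * (k - 1) ** 2 + (k - 1) + 2) / (
                6.0 * (k - 1) * (n - 1)
            )
            chi2 = -(n - 1) * factor * math.log(w)
            p_m = float(sps.chi2.sf(chi2, df_m))
    return AnovaResult(
        f=float(f_stat),
        df1=df1,
        df2=df2,
        p=p,
        eta_sq_partial=float(eta_p),
        gg_epsilon=eps,
        p_gg=p_gg,
        mauchly_w=float(w),
        mauchly_p=float(p_m),
        ss_condition=ss_condition,
        ss_subject=ss_subject,
        ss_residual=ss_residual,
        ss_total=ss_total,
    )


def pairwise_bonferroni(table: RMTable) -> list[PairwiseResult]:
    """Paired t-tests for all k(k-1)/2 condition pairs with Bonferroni
    adjustment ``p_bonf = min(1, m * p_raw)`` and paired Cohen's d.

    Zero-variance difference vectors are flagged ``degenerate``: a zero
    mean difference carries no evidence (p = 1), a nonzero one is reported
    with infinite t (p = 0).
    """
    v = table.values
    n = table.n
    pairs = list(itertools.combinations(range(table.k), 2))
    m = len(pairs)
    out: list[PairwiseResult] = []
    for i, j in pairs:
        d = v[:, i] - v[:, j]
        mean = float(d.mean())
        sd = float(d.std(ddof=1))
        if sd == 0.0:
            if mean == 0.0:
                t, p_raw, cd, degen = math.nan, 1.0, math.nan, True
            else:
                t = math.copysign(math.inf, mean)
                p_raw, cd, degen = 0.0, math.nan, True
        else:
            t = mean / (sd / math.sqrt(n))
            p_raw = float(2 * sps.t.sf(abs(t), n - 1))
            cd = mean / sd
            degen = False
        out.append(
            PairwiseResult(
                pair=(table.conditions[i], table.conditions[j]),
                mean_diff=mean,
                t=float(t),
                df=n - 1,
                p_raw=p_raw,
                p_bonferroni=min(1.0, m * p_raw),
                cohens_d=float(cd) if not math.isnan(cd) else math.nan,
                degenerate=degen,
            )
        )
    return out


def descriptives(table: RMTable, ci: float = 0.95) -> pd.DataFrame:
    """Per-condition mean, SD and t-based confidence interval."""
    v = table.values
    n = table.n
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    tq = sps.t.ppf(0.5 + ci / 2, n - 1)
    half = tq * sd / math.sqrt(n)
    return pd.DataFrame(
        {
            "n": n,
            "mean": mean,
            "sd": sd,
            "ci_low": mean - half,
            "ci_high": mean + half,
        },
        index=pd.Index(table.conditions, name="condition"),
    )


def assumption_diagnostics(table: RMTable) -> pd.DataFrame:
    """Residuals of the additive subject + condition model, as plottable
    tables: fitted values, residuals and Blom normal quantiles."""
    v = table.values
    grand = v.mean()
    row_eff = v.mean(axis=1) - grand
    col_eff = v.mean(axis=0) - grand
    fitted = grand + row_eff[:, None] + col_eff[None, :]
    resid = v - fitted
    rows = []
    for i, subj in enumerate(table.subjects):
        for j, cond in enumerate(table.conditions):
            rows.append(
                {
                    "subject": subj,
                    "condition": cond,
                    "fitted": fitted[i, j],
                    "residual": resid[i, j],
                }
            )
    df = pd.DataFrame(rows)
    n_tot = len(df)
    ranks = df["residual"].rank(method="first")
    df["theoretical_quantile"] = sps.norm.ppf((ranks - 0.375) / (n_tot + 0.25))
    return df


def qq_correlation(diagnostics: pd.DataFrame) -> float:
    """Correlation between sorted residuals and their normal quantiles
    (close to 1 for Gaussian residuals)."""
    r = np.sort(diagnostics["residual"].to_numpy())
    q = np.sort(diagnostics["theoretical_quantile"].to_numpy())
    return float(np.corrcoef(r, q)[0, 1])


def anova_report(table: RMTable) -> dict:
    """JSON-ready report: ANOVA, pairwise comparisons and descriptives."""
    res = rm_anova(table)
    pw = pairwise_bonferroni(table)
    return {
        "anova": {
            "F": res.f,
            "df1": res.df1,
            "df2": res.df2,
            "p": res.p,
            "eta_sq_partial": res.eta_sq_partial,
            "gg_epsilon": res.gg_epsilon,
            "p_gg": res.p_gg,
            "mauchly_w": res.mauchly_w,
            "mauchly_p": res.mauchly_p,
        },
        "pairwise": [
            {
                "pair": list(p.pair),
                "mean_diff": p.mean_diff,
                "t": p.t,
                "df": p.df,
                "p_raw": p.p_raw,
                "p_bonferroni": p.p_bonferroni,
                "cohens_d": p.cohens_d,
            }
            for p in pw
        ],
        "descriptives": {
            cond: {
                "n": int(row["n"]),
                "mean": float(row["mean"]),
                "sd": float(row["sd"]),
                "ci_low": float(row["ci_low"]),
                "ci_high": float(row["ci_high"]),
            }
            for cond, row in descriptives(table).iterrows()
        },
    }
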