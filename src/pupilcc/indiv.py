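"""Between-subject statistics: correlations, forward stepwise regression,
and two-level repeated-measures contrasts with partial eta squared.

Correlation matrices use pairwise deletion because subjects are excluded
per measure, not globally.  Forward stepwise regression standardises the
response and predictors, enters at each step the candidate with the
smallest F-change p-value while it beats the entry criterion, and refuses
to run when candidate predictors are too strongly inter-correlated to
yield interpretable unique contributions.  A two-level repeated-measures
contrast is reported as F = t-squared of the paired t-test with
df = (1, n - 1) and partial eta squared F*df1 / (F*df1 + df2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, MulticollinearityError

__all__ = [
    "CorrelationReport",
    "correlation_matrix",
    "RegressionTerm",
    "StepwiseResult",
    "stepwise_forward",
    "PairedContrast",
    "paired_contrast",
    "partial_eta_squared",
]


@dataclass
class CorrelationReport:
    """Pearson r, two-tailed p and pairwise-complete n per variable pair."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def summary(self) -> str:
        lines = ["Correlations across participants (pairwise-complete)"]
        cols = list(self.r.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                lines.append(
                    f"  {a} ~ {b}: r = {self.r.loc[a, b]:+.2f}, "
                    f"p = {self.p.loc[a, b]:.3f}, n = {int(self.n.loc[a, b])}"
                )
        return "\n".join(lines)


def correlation_matrix(measures: pd.DataFrame, min_pairs: int = 3) -> CorrelationReport:
    """Pearson correlations with two-tailed p for every pair of columns.

    Missing subjects are dropped pairwise.  Pairs with fewer than
    ``min_pairs`` complete observations raise.
    """
    cols = list(measures.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for c in cols:
        n.loc[c, c] = measures[c].notna().sum()
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pair = measures[[a, b]].dropna()
            if len(pair) < min_pairs:
                raise InsufficientDataError(
                    f"fewer than {min_pairs} complete pairs for ({a}, {b})"
                )
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
            n.loc[a, b] = n.loc[b, a] = len(pair)
    return CorrelationReport(r=r, p=p, n=n)


@dataclass
class RegressionTerm:
    name: str
    beta: float  # standardized coefficient
    t: float
    p: float
    df_resid: int
    r2_zero_order: float  # squared zero-order correlation with y


@dataclass
class StepwiseResult:
    entered: list
    rejected: dict  # candidate -> F-change p at last evaluation
    n: int
    model_r2: float
    entry_alpha: float

    def summary(self) -> str:
        lines = [f"Forward stepwise regression (entry p < {self.entry_alpha}, n = {self.n})"]
        if not self.entered:
            lines.append("  no predictor entered the model")
        for term in self.entered:
            lines.append(
                f"  {term.name}: beta = {term.beta:+.2f}, "
                f"t({term.df_resid}) = {term.t:+.2f}, p = {term.p:.3f}, "
                f"r2 = {term.r2_zero_order:.2f}"
            )
        for name, pv in self.rejected.items():
            lines.append(f"  not entered: {name} (F-change p = {pv:.3f})")
        lines.append(f"  model R2 = {self.model_r2:.3f}")
        return "\n".join(lines)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise InsufficientDataError("zero-variance variable in regression")
    return (x - x.mean()) / sd


def stepwise_forward(
    y: pd.Series,
    candidates: pd.DataFrame,
    entry_alpha: float = 0.05,
    guard_r: float = 0.90,
) -> StepwiseResult:
    """Forward stepwise OLS on standardised variables.

    At each step the candidate with the smallest F-change p (equivalently,
    for a single added term, the p of its t statistic) enters while that p
    is below ``entry_alpha``.  Candidates whose pairwise |r| reaches
    ``guard_r`` trip a multicollinearity diagnostic instead of fitting,
    since unique contributions would not be discernible.
    """
    data = pd.concat([y.rename("__y__"), candidates], axis=1).dropna()
    n = len(data)
    names = list(candidates.columns)
    if n <= len(names) + 2:
        raise InsufficientDataError(
            f"n = {n} too small for {len(names)} candidate predictor(s)"
        )
    if len(names) > 1:
        inter = data[names].corr().abs().to_numpy()
        np.fill_diagonal(inter, 0.0)
        if inter.max() >= guard_r:
            i, j = np.unravel_index(int(inter.argmax()), inter.shape)
            raise MulticollinearityError(
                f"inter-predictor |r| = {inter.max():.2f} between "
                f"{names[i]!r} and {names[j]!r} (guard {guard_r})"
            )
    yz = _zscore(data["__y__"].to_numpy(dtype=float))
    Xz = {c: _zscore(data[c].to_numpy(dtype=float)) for c in names}
    entered: list[str] = []
    last_p: dict[str, float] = {}
    while True:
        remaining = [c for c in names if c not in entered]
        if not remaining:
            break
        pvals = {}
        for c in remaining:
            X = sm.add_constant(np.column_stack([Xz[e] for e in entered + [c]]))
            fit = sm.OLS(yz, X).fit()
            pvals[c] = float(fit.pvalues[-1])
        best = min(remaining, key=lambda c: pvals[c])
        last_p.update(pvals)
        if pvals[best] < entry_alpha:
            entered.append(best)
        else:
            break
    if entered:
        X = sm.add_constant(np.column_stack([Xz[e] for e in entered]))
        fit = sm.OLS(yz, X).fit()
        model_r2 = float(fit.rsquared)
        terms = [
            RegressionTerm(
                name=e,
                beta=float(fit.params[k + 1]),
                t=float(fit.tvalues[k + 1]),
                p=float(fit.pvalues[k + 1]),
                df_resid=int(fit.df_resid),
                r2_zero_order=float(np.corrcoef(yz, Xz[e])[0, 1] ** 2),
            )
            for k, e in enumerate(entered)
        ]
    else:
        model_r2 = 0.0
        terms = []
    rejected = {c: last_p[c] for c in names if c not in entered and c in last_p}
    return StepwiseResult(
        entered=terms, rejected=rejected, n=n, model_r2=model_r2, entry_alpha=entry_alpha
    )


@dataclass
class PairedContrast:
    """Two-level repeated-measures contrast."""

    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float
    mean_a: float
    mean_b: float
    n: int
    degenerate: bool = False

    def summary(self) -> str:
        note = " (degenerate: zero-variance difference)" if self.degenerate else ""
        return (
            f"F({self.df1},{self.df2}) = {self.F:.2f}, p = {self.p:.3g}, "
            f"eta_p2 = {self.eta_p2:.3f}{note}"
        )


def partial_eta_squared(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from F and its degrees of freedom."""
    return F * df1 / (F * df1 + df2)


def paired_contrast(a, b) -> PairedContrast:
    """One-way repeated-measures contrast with two levels.

    Equivalent to the paired t-test: F = t^2 with df = (1, n - 1);
    ``eta_p2`` = F / (F + n - 1).  Pairs with a missing value in either
    level are dropped.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n < 3:
        raise InsufficientDataError("paired contrast requires >= 3 complete pairs")
    d = a - b
    sd = d.std(ddof=1)
    df1, df2 = 1, n - 1
    if sd == 0:
        if d.mean() == 0:
            return PairedContrast(0.0, df1, df2, 1.0, 0.0, a.mean(), b.mean(), n, True)
        return PairedContrast(np.inf, df1, df2, 0.0, 1.0, a.mean(), b.mean(), n, True)
    t = d.mean() / (sd / np.sqrt(n))
    F = t * t
    p = 2.0 * stats.t.sf(abs(t), df=df2)
    return PairedContrast(
        F=float(F),
        df1=df1,
        df2=df2,
        p=float(p),
        eta_p2=float(partial_eta_squared(F, df1, df2)),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n=n,
    )
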