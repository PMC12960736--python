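"""Design-based prevalence estimates and Rao-Scott adjusted-F independence tests.

Point estimates are ratio estimators sum(w y)/sum(w); their variance comes
from Taylor linearization treating each respondent as an independent
with-replacement draw (weights fixed).  Confidence intervals default to the
logit-transformed Wald form, which respects the unit interval and matches
the asymmetric intervals typical for rare items.

The independence test follows the second-order Rao-Scott construction:
the Pearson chi-square on the weighted table is referred to an F
distribution after scaling by the trace of the generalized design-effect
matrix, with Satterthwaite-adjusted (possibly fractional) degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .weighting import SurveyDesign


class PrevalenceError(ValueError):
    pass


@dataclass
class PrevalenceEstimate:
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.99
    n_eff: float = 0.0
    se: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
            raise PrevalenceError("CI must satisfy 0 <= low <= point <= high <= 1")


@dataclass
class RaoScottResult:
    F_stat: float
    df1: float
    df2: float
    p_value: float
    first_order_deff: float

    def __post_init__(self) -> None:
        if self.F_stat < -1e-12 or not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise PrevalenceError("invalid test result")
        self.F_stat = max(self.F_stat, 0.0)
        self.p_value = min(self.p_value, 1.0)


def _linearized_variance(y: np.ndarray, w: np.ndarray, point: float) -> float:
    """With-replacement Taylor variance of the ratio estimator sum(wy)/sum(w)."""
    n = y.shape[0]
    total = w.sum()
    resid = w * (y - point)
    return float(n / (n - 1) * np.sum(resid**2) / total**2) if n > 1 else np.nan


def weighted_prevalence(
    item: np.ndarray,
    design: SurveyDesign,
    level: float = 0.99,
    ci_method: str = "logit",
    by: np.ndarray | pd.Series | None = None,
):
    """Weighted prevalence with a design-based confidence interval.

    ci_method='logit' (default) builds the Wald interval on the log-odds
    scale and back-transforms; ci_method='wald' is the plain linear interval
    clipped to [0, 1].  With `by`, returns one estimate per group (the
    country and age-band analyses are this same operation).
    """
    if by is not None:
        return grouped_prevalence(item, design, by, level=level, ci_method=ci_method)
    y = np.asarray(item, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise PrevalenceError("item must be binary 0/1")
    w = design.weights
    if y.shape[0] != w.shape[0]:
        raise PrevalenceError("item and design are not conformable")
    total = w.sum()
    if total <= 0:
        raise PrevalenceError("zero total weight")
    point = float(np.sum(w * y) / total)
    n_eff = float(total**2 / np.sum(w**2))
    alpha = 1.0 - level
    if point in (0.0, 1.0):
        # one-sided exact-binomial-style bound on the effective sample size
        bound = 1.0 - (alpha / 2.0) ** (1.0 / n_eff)
        lo, hi = (0.0, bound) if point == 0.0 else (1.0 - bound, 1.0)
        return PrevalenceEstimate(point, lo, hi, level, n_eff, se=np.nan, degenerate=True)
    var = _linearized_variance(y, w, point)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if ci_method == "logit":
        l = np.log(point / (1.0 - point))
        se_l = se / (point * (1.0 - point))
        lo = 1.0 / (1.0 + np.exp(-(l - z * se_l)))
        hi = 1.0 / (1.0 + np.exp(-(l + z * se_l)))
    elif ci_method == "wald":
        lo = max(0.0, point - z * se)
        hi = min(1.0, point + z * se)
    else:
        raise PrevalenceError(f"unknown ci_method {ci_method!r}")
    return PrevalenceEstimate(point, float(lo), float(hi), level, n_eff, se=se)


def grouped_prevalence(
    item: np.ndarray,
    design: SurveyDesign,
    by: np.ndarray | pd.Series,
    level: float = 0.99,
    ci_method: str = "logit",
) -> dict[str, PrevalenceEstimate]:
    """Per-group prevalence (e.g. by country or age band)."""
    by = pd.Series(np.asarray(by)).astype(str)
    item = np.asarray(item)
    out = {}
    for g in sorted(by.unique()):
        mask = (by == g).to_numpy()
        if design.weights[mask].sum() <= 0:
            raise PrevalenceError(f"zero total weight in group {g!r}")
        sub = SurveyDesign(weights=design.weights[mask], normalization="none")
        out[g] = weighted_prevalence(item[mask], sub, level=level, ci_method=ci_method)
    return out


def _interaction_contrasts(R: int, C: int) -> np.ndarray:
    """Columns spanning the interaction space, residualised on main effects."""
    K = R * C
    rows = np.repeat(np.arange(R), C)
    cols = np.tile(np.arange(C), R)
    X1 = [np.ones(K)]
    for r in range(1, R):
        X1.append((rows == r).astype(float))
    for c in range(1, C):
        X1.append((cols == c).astype(float))
    X1 = np.column_stack(X1)
    X2 = np.column_stack(
        [
            ((rows == r) & (cols == c)).astype(float)
            for r in range(1, R)
            for c in range(1, C)
        ]
    )
    # residualise interaction columns on the main-effects space
    coef, *_ = np.linalg.lstsq(X1, X2, rcond=None)
    return X2 - X1 @ coef


def rao_scott_test(
    item: np.ndarray,
    group: np.ndarray | pd.Series,
    design: SurveyDesign,
) -> RaoScottResult:
    """Second-order Rao-Scott adjusted F test of item x group independence.

    The Pearson statistic on the weighted proportions is divided by the trace
    of the generalized design-effect matrix and referred to
    F(d0, d0 * (n - 1)) with Satterthwaite df d0 = tr(D)^2 / tr(D^2).
    """
    y = np.asarray(item, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise PrevalenceError("item must be binary 0/1")
    g = pd.Series(np.asarray(group)).astype(str)
    levels = sorted(g.unique())
    R = len(levels)
    if R < 2:
        raise PrevalenceError("need at least two groups")
    C = 2
    n = y.shape[0]
    w = design.weights
    total = w.sum()
    for lev in levels:
        if w[(g == lev).to_numpy()].sum() <= 0:
            raise PrevalenceError(f"zero weighted count in group {lev!r}")

    # cell indicator matrix, cells ordered (group, item-value)
    U = np.zeros((n, R * C))
    for r, lev in enumerate(levels):
        mask = (g == lev).to_numpy()
        U[:, r * C + 0] = mask & (y == 0)
        U[:, r * C + 1] = mask & (y == 1)
    phat = (w @ U) / total

    # Pearson chi-square on the weighted table scaled to n observations
    tab = phat.reshape(R, C)
    rowm = tab.sum(axis=1)
    colm = tab.sum(axis=0)
    expected = np.outer(rowm, colm)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (tab - expected) ** 2 / expected, 0.0)
    X2 = float(n * contrib.sum())

    # linearized design covariance of the cell proportions (with-replacement)
    resid = (U - phat) * w[:, None]
    V = (resid.T @ resid) / total**2 * (n / (n - 1))
    # multinomial covariance with the matching finite-sample factor, so that
    # equal weights give a design-effect matrix exactly equal to identity
    Vsrs = (np.diag(phat) - np.outer(phat, phat)) / (n - 1)

    Cmat = _interaction_contrasts(R, C)
    iD = np.where(phat > 0, 1.0 / np.where(phat > 0, phat, 1.0), 0.0)
    iDmat = np.diag(iD)
    denom = Cmat.T @ iDmat @ Vsrs @ iDmat @ Cmat
    numer = Cmat.T @ iDmat @ V @ iDmat @ Cmat
    Delta = np.linalg.solve(denom, numer)
    tr = float(np.trace(Delta))
    tr2 = float(np.trace(Delta @ Delta))
    d0 = tr**2 / tr2
    F = X2 / tr
    df2 = d0 * (n - 1)
    p = float(stats.f.sf(F, d0, df2))
    K = Cmat.shape[1]
    return RaoScottResult(
        F_stat=F, df1=d0, df2=df2, p_value=p, first_order_deff=tr / K
    )


def prevalence_table(
    responses,
    design: SurveyDesign,
    by: np.ndarray | pd.Series | None = None,
    group_name: str = "group",
    level: float = 0.99,
    test: bool = True,
) -> pd.DataFrame:
    """Tidy prevalence table per item (optionally per group, with the F test)."""
    rows = []
    for j, label in enumerate(responses.labels):
        item = responses.values[:, j]
        if by is None:
            est = weighted_prevalence(item, design, level=level)
            rows.append(
                {
                    "item": label,
                    group_name: "pooled",
                    "point": est.point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_eff": est.n_eff,
                }
            )
        else:
            ests = grouped_prevalence(item, design, by, level=level)
            rs = rao_scott_test(item, by, design) if test else None
            for g, est in ests.items():
                row = {
                    "item": label,
                    group_name: g,
                    "point": est.point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_eff": est.n_eff,
                }
                if rs is not None:
                    row.update(
                        {
                            "F": rs.F_stat,
                            "df1": rs.df1,
                            "df2": rs.df2,
                            "p": rs.p_value,
                        }
                    )
                rows.append(row)
    return pd.DataFrame(rows)
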