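"""Unadjusted survey-weighted logistic odds ratios for demographic indicators.

Each cell of the grid is a bivariable weighted logistic regression of one
item on one binary indicator; the OR is exp(slope) with a sandwich CI.  For
a single binary predictor the MLE coincides with the weighted 2x2
cross-product ratio, so model-based and table-based estimates agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import SeparationError, fit_weighted_logit
from .items import ResponseMatrix
from .weighting import SurveyDesign

#: Binary demographic indicators of the correlates grid, in report order.
PREDICTOR_COLUMNS: tuple[str, ...] = (
    "high_income",
    "partnered",
    "employed",
    "university",
    "child_household",
    "works_with_children",
)


@dataclass
class ORResult:
    or_point: float
    ci_low: float
    ci_high: float
    log_or_se: float
    outcome: str = ""
    predictor: str = ""
    level: float = 0.99
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if self.or_point <= 0:
            raise ValueError("odds ratio must be positive")
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")

    @property
    def significant(self) -> bool:
        return self.ci_low > 1.0 or self.ci_high < 1.0


def _weighted_2x2(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted cells [[a, b], [c, d]] = [[y1x1, y0x1], [y1x0, y0x0]]."""
    a = w[(y == 1) & (x == 1)].sum()
    b = w[(y == 0) & (x == 1)].sum()
    c = w[(y == 1) & (x == 0)].sum()
    d = w[(y == 0) & (x == 0)].sum()
    return np.array([[a, b], [c, d]])


def _table_or(cells: np.ndarray, level: float, outcome: str, predictor: str) -> ORResult:
    """Continuity-corrected 2x2 OR fallback for separated data."""
    cells = cells + 0.5
    a, b = cells[0]
    c, d = cells[1]
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    return ORResult(
        or_point=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        log_or_se=se,
        outcome=outcome,
        predictor=predictor,
        level=level,
        continuity_corrected=True,
    )


def weighted_logistic_or(
    outcome: np.ndarray,
    predictor: np.ndarray,
    design: SurveyDesign,
    level: float = 0.99,
    outcome_label: str = "",
    predictor_label: str = "",
    fallback: bool = True,
) -> ORResult:
    """Bivariable weighted logistic OR with robust (sandwich) 99% CI.

    On separation (an empty weighted 2x2 cell) a continuity-corrected
    table estimate is returned with a warning if `fallback`, else the
    SeparationError propagates.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all() or not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("outcome and predictor must be binary 0/1")
    w = design.weights
    cells = _weighted_2x2(y, x, w)
    if (cells == 0).any():
        if not fallback:
            raise SeparationError(
                "empty weighted 2x2 cell; use the continuity-corrected table path"
            )
        warnings.warn(
            f"separation for {outcome_label or 'outcome'} ~ "
            f"{predictor_label or 'predictor'}; using 0.5 continuity correction",
            stacklevel=2,
        )
        return _table_or(cells, level, outcome_label, predictor_label)
    fit = fit_weighted_logit(x, y, w)
    log_or = float(fit.coef[1])
    se = float(fit.se(robust=True)[1])
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    return ORResult(
        or_point=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        log_or_se=se,
        outcome=outcome_label,
        predictor=predictor_label,
        level=level,
    )


def correlate_grid(
    responses: ResponseMatrix,
    demographics: pd.DataFrame,
    design: SurveyDesign,
    predictors: tuple[str, ...] = PREDICTOR_COLUMNS,
    level: float = 0.99,
    holm: bool = False,
) -> pd.DataFrame:
    """Full item x predictor OR grid as a tidy frame.

    Cells that fail outright (beyond the continuity fallback) are recorded
    with NaN estimates rather than aborting the grid.
    """
    rows = []
    for j, item_label in enumerate(responses.labels):
        y = responses.values[:, j]
        for pred in predictors:
            x = demographics[pred].to_numpy()
            try:
                res = weighted_logistic_or(
                    y, x, design, level=level,
                    outcome_label=item_label, predictor_label=pred,
                )
                rows.append(
                    {
                        "item": item_label,
                        "predictor": pred,
                        "or": res.or_point,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "log_or_se": res.log_or_se,
                        "significant": res.significant,
                        "continuity_corrected": res.continuity_corrected,
                        "error": "",
                    }
                )
            except (SeparationError, np.linalg.LinAlgError, ValueError) as exc:
                rows.append(
                    {
                        "item": item_label,
                        "predictor": pred,
                        "or": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "log_or_se": np.nan,
                        "significant": False,
                        "continuity_corrected": False,
                        "error": str(exc),
                    }
                )
    grid = pd.DataFrame(rows)
    if holm:
        pvals = 2.0 * stats.norm.sf(
            np.abs(np.log(grid["or"]) / grid["log_or_se"])
        )
        grid["p_value"] = pvals
        ok = np.isfinite(pvals)
        m = int(ok.sum())
        adj = np.full(len(grid), np.nan)
        order = np.argsort(np.where(ok, pvals, np.inf))[:m]
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
        grid["holm_p"] = adj
        grid["holm_significant"] = grid["holm_p"] < (1.0 - level)
    return grid
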