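"""Post-stratification weighting by iterative proportional fitting (raking).

Weights are repeatedly rescaled so that the weighted sample margin of each
calibration variable matches its population target.  Only marginal totals
are raked (no interaction cells); multi-stratum designs rake each stratum
against its own margins and pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class RakingError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float, n_iter: int):
        super().__init__(message)
        self.residual = residual
        self.n_iter = n_iter


@dataclass
class MarginSpec:
    """Population targets for one calibration variable."""

    variable: str
    targets: dict[str, float]

    def __post_init__(self) -> None:
        self.targets = {str(k): float(v) for k, v in self.targets.items()}
        vals = np.array(list(self.targets.values()))
        if (vals < 0).any():
            raise RakingError(f"negative target proportion for {self.variable!r}")
        if not np.isclose(vals.sum(), 1.0, atol=1e-8):
            raise RakingError(
                f"targets for {self.variable!r} sum to {vals.sum():.6g}, expected 1"
            )

    @property
    def levels(self) -> list[str]:
        return list(self.targets)

    @classmethod
    def from_mapping(cls, variable: str, targets: dict) -> "MarginSpec":
        return cls(variable=variable, targets=targets)


def margins_from_json(path) -> list[MarginSpec]:
    """Read margin specs from a JSON mapping {variable: {level: proportion}}."""
    with open(path) as fh:
        payload = json.load(fh)
    return [MarginSpec(var, targets) for var, targets in payload.items()]


def margins_to_json(margins: list[MarginSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump({m.variable: m.targets for m in margins}, fh, indent=2)


@dataclass
class SurveyDesign:
    """Per-respondent weights plus normalization and convergence metadata."""

    weights: np.ndarray
    normalization: str = "sum-to-n"
    converged: bool = True
    n_iter: int = 0
    max_margin_error: float = 0.0
    trim_cap: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights <= 0).any():
            raise RakingError("all weights must be strictly positive")
        if self.normalization not in ("sum-to-n", "mean-1", "none"):
            raise RakingError(f"unknown normalization {self.normalization!r}")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def equal(cls, n: int) -> "SurveyDesign":
        return cls(weights=np.ones(n))


def _normalize(w: np.ndarray, convention: str) -> np.ndarray:
    if convention == "sum-to-n":
        return w * (w.shape[0] / w.sum())
    if convention == "mean-1":
        return w / w.mean()
    return w


def _level_indicators(
    demographics: pd.DataFrame, margins: list[MarginSpec]
) -> list[tuple[MarginSpec, list[np.ndarray], np.ndarray]]:
    """Per margin: boolean masks for each level plus the target vector."""
    out = []
    for m in margins:
        if m.variable not in demographics.columns:
            raise RakingError(f"variable {m.variable!r} not in demographics")
        col = demographics[m.variable].astype(str)
        sample_levels = set(col.unique())
        extra = sample_levels - set(m.targets)
        if extra:
            raise RakingError(
                f"sample levels {sorted(extra)} of {m.variable!r} missing from margin spec"
            )
        masks, targets = [], []
        for level, target in m.targets.items():
            mask = (col == level).to_numpy()
            if target > 0 and not mask.any():
                raise RakingError(
                    f"margin level {m.variable!r}={level!r} has positive target "
                    f"{target:.4g} but no sample observations"
                )
            if mask.any():
                masks.append(mask)
                targets.append(target)
        t = np.array(targets)
        out.append((m, masks, t / t.sum()))
    return out


def _max_margin_error(w, prepared) -> float:
    err = 0.0
    total = w.sum()
    for _, masks, targets in prepared:
        for mask, target in zip(masks, targets):
            err = max(err, abs(w[mask].sum() / total - target))
    return err


def rake(
    demographics: pd.DataFrame,
    margins: list[MarginSpec],
    tol: float = 1e-6,
    max_iter: int = 200,
    trim_cap: float | None = None,
    base_weights: np.ndarray | None = None,
    normalization: str = "sum-to-n",
) -> SurveyDesign:
    """Iterative proportional fitting of weights to the margin targets.

    Cycles through the margins, multiplying each level's weights by
    target / current weighted proportion, until the maximum absolute margin
    error falls below `tol` or `max_iter` cycles elapse.  If `trim_cap` is
    set, weights are capped at trim_cap x median and re-raked once.
    """
    if tol <= 0:
        raise RakingError("tol must be positive")
    n = len(demographics)
    w = np.ones(n) if base_weights is None else np.asarray(base_weights, dtype=float)
    if (w <= 0).any():
        raise RakingError("base weights must be strictly positive")
    prepared = _level_indicators(demographics, margins)

    def _cycle_until(w, budget):
        it = 0
        err = _max_margin_error(w, prepared)
        while err >= tol and it < budget:
            for _, masks, targets in prepared:
                total = w.sum()
                for mask, target in zip(masks, targets):
                    current = w[mask].sum() / total
                    if current > 0:
                        w[mask] *= target / current
            it += 1
            err = _max_margin_error(w, prepared)
        return w, err, it

    w, err, n_iter = _cycle_until(w, max_iter)
    if err >= tol:
        raise ConvergenceError(
            f"raking did not converge in {max_iter} cycles "
            f"(max margin error {err:.3g} >= tol {tol:.3g})",
            residual=err,
            n_iter=n_iter,
        )
    trimmed = False
    if trim_cap is not None:
        cap = trim_cap * np.median(w)
        if (w > cap).any():
            # cap, then a single re-raking cycle; running to convergence
            # would simply undo the trim (IPF fixed points are product-form)
            w = np.minimum(w, cap)
            trimmed = True
            for _, masks, targets in prepared:
                total = w.sum()
                for mask, target in zip(masks, targets):
                    current = w[mask].sum() / total
                    if current > 0:
                        w[mask] *= target / current
            n_iter += 1
            err = _max_margin_error(w, prepared)
    w = _normalize(w, normalization)
    return SurveyDesign(
        weights=w,
        normalization=normalization,
        converged=True,
        n_iter=n_iter,
        max_margin_error=err,
        trim_cap=trim_cap if trimmed else None,
        meta={"tol": tol, "variables": [m.variable for m in margins]},
    )


def rake_by_stratum(
    demographics: pd.DataFrame,
    margins_by_stratum: dict[str, list[MarginSpec]],
    stratum_col: str = "country",
    **kwargs,
) -> SurveyDesign:
    """Rake each stratum against its own margins, then pool.

    Each stratum's weights are normalised to its own sample size, preserving
    the quota design's relative stratum sizes.
    """
    n = len(demographics)
    covered = demographics[stratum_col].astype(str).isin(
        {str(s) for s in margins_by_stratum}
    )
    if not covered.all():
        missing = sorted(demographics.loc[~covered, stratum_col].astype(str).unique())
        raise RakingError(f"no margins supplied for strata {missing}")
    w = np.empty(n)
    worst = 0.0
    iters = 0
    for stratum, margins in margins_by_stratum.items():
        mask = (demographics[stratum_col].astype(str) == str(stratum)).to_numpy()
        if not mask.any():
            raise RakingError(f"stratum {stratum!r} absent from sample")
        sub = demographics.loc[mask].reset_index(drop=True)
        design = rake(sub, margins, **kwargs)
        w[mask] = design.weights
        worst = max(worst, design.max_margin_error)
        iters = max(iters, design.n_iter)
    return SurveyDesign(
        weights=w,
        normalization=kwargs.get("normalization", "sum-to-n"),
        converged=True,
        n_iter=iters,
        max_margin_error=worst,
        meta={"stratified_by": stratum_col},
    )


def margin_report(
    design: SurveyDesign,
    demographics: pd.DataFrame,
    margins: list[MarginSpec],
) -> pd.DataFrame:
    """Unweighted vs weighted vs target proportion per margin level."""
    if design.n != len(demographics):
        raise RakingError("design and demographics are not conformable")
    w = design.weights
    rows = []
    for m in margins:
        col = demographics[m.variable].astype(str)
        for level, target in m.targets.items():
            mask = (col == level).to_numpy()
            weighted = w[mask].sum() / w.sum()
            rows.append(
                {
                    "variable": m.variable,
                    "level": level,
                    "unweighted": mask.mean(),
                    "weighted": weighted,
                    "target": target,
                    "abs_error": abs(weighted - target),
                }
            )
    return pd.DataFrame(rows)
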