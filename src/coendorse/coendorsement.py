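"""Pairwise co-endorsement: row-proportion overlap and odds-ratio matrices.

Every pair of items is summarised by a weighted 2x2 table: entry (i, j) of
the row-proportion matrix is the weighted share of i-endorsers who also
endorse j, and the OR matrix holds the weighted cross-product ratio.  A
margin-reconstruction utility recovers the OR of a pair from the published
total, the two endorsement counts, and one row proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .items import ResponseMatrix
from .weighting import SurveyDesign


class MarginError(ValueError):
    pass


@dataclass
class CoendorsementTable:
    labels: tuple[str, ...]
    n_vec: np.ndarray          # weighted endorsement count per item
    rowprop: np.ndarray        # (i, j): weighted share of i-endorsers endorsing j
    or_mat: np.ndarray         # pairwise weighted ORs, symmetric
    N: float                   # weighted total
    significant: np.ndarray    # p < .01 flags for the ORs
    corrected: np.ndarray      # pairs where a 0.5 continuity correction was applied

    def to_frame(self) -> pd.DataFrame:
        """Tidy long output: one row per ordered item pair."""
        rows = []
        p = len(self.labels)
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                rows.append(
                    {
                        "item_i": self.labels[i],
                        "item_j": self.labels[j],
                        "n_i": self.n_vec[i],
                        "n_j": self.n_vec[j],
                        "rowprop": self.rowprop[i, j],
                        "or": self.or_mat[i, j],
                        "significant": bool(self.significant[i, j]),
                        "continuity_corrected": bool(self.corrected[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def coendorsement_table(
    responses: ResponseMatrix,
    design: SurveyDesign,
    alpha: float = 0.01,
) -> CoendorsementTable:
    """Weighted overlap and OR matrices across all item pairs."""
    X = responses.values.astype(float)
    p = X.shape[1]
    if p < 2:
        raise MarginError("need at least two items")
    w = design.weights
    if (w <= 0).any():
        raise MarginError("weights must be positive")
    N = float(w.sum())
    n_vec = w @ X
    joint = (X * w[:, None]).T @ X  # joint[i, j] = weighted count endorsing both
    rowprop = np.full((p, p), np.nan)
    or_mat = np.full((p, p), np.nan)
    significant = np.zeros((p, p), dtype=bool)
    corrected = np.zeros((p, p), dtype=bool)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            rowprop[i, j] = joint[i, j] / n_vec[i] if n_vec[i] > 0 else np.nan
            if j < i:
                continue
            a = joint[i, j]
            b = n_vec[i] - a
            c = n_vec[j] - a
            d = N - n_vec[i] - n_vec[j] + a
            cells = np.array([a, b, c, d])
            if (cells <= 0).any():
                cells = cells + 0.5
                corrected[i, j] = corrected[j, i] = True
            a, b, c, d = cells
            log_or = np.log(a * d / (b * c))
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            or_mat[i, j] = or_mat[j, i] = np.exp(log_or)
            significant[i, j] = significant[j, i] = abs(log_or) > z * se
    return CoendorsementTable(
        labels=responses.labels,
        n_vec=n_vec,
        rowprop=rowprop,
        or_mat=or_mat,
        N=N,
        significant=significant,
        corrected=corrected,
    )


def or_from_margins(N: float, n_i: float, n_j: float, rowprop_ij: float) -> float:
    """Reconstruct a pairwise OR from printed margins and one row proportion.

    The implied joint count is a = rowprop_ij * n_i; the OR is the
    cross-product ratio of the completed 2x2 table.
    """
    if not (0 < n_i < N and 0 < n_j < N):
        raise MarginError("endorsement counts must lie strictly between 0 and N")
    if not (0 < rowprop_ij <= 1):
        raise MarginError("row proportion must lie in (0, 1]")
    a = rowprop_ij * n_i
    b = n_i - a
    c = n_j - a
    d = N - n_i - n_j + a
    if min(b, c, d) < 0 or a > min(n_i, n_j):
        raise MarginError(
            f"inconsistent margins: implied cells (a={a:.2f}, b={b:.2f}, "
            f"c={c:.2f}, d={d:.2f}) include a negative count"
        )
    if b == 0 or c == 0:
        return np.inf
    return float(a * d / (b * c))
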