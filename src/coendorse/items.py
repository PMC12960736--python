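"""Binary item battery: canonical labels, response matrix container, recoding.

The battery consists of ten binary indicators.  Items 1-5 are self-reported
behaviours recorded on a yes / no / maybe / unsure vocabulary and are
dichotomised as yes = 1, anything else = 0.  Items 6-9 follow the same rule.
Item 10 is a composite over three likelihood questions (one per age bracket)
and is 1 iff any bracket was answered "very likely" or "definitely".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical short labels, in battery order.
ITEM_LABELS: tuple[str, ...] = (
    "viewed_csam",
    "contact_child",
    "flirted_online",
    "webcam_child",
    "purchased_csam",
    "would_view_csam",
    "would_watch_webcam",
    "feelings",
    "concerned",
    "likely_contact_u14",
)

#: Raw columns holding the three age-bracket likelihood responses.
BRACKET_COLUMNS: tuple[str, ...] = (
    "likely_contact_12_14",
    "likely_contact_10_12",
    "likely_contact_u10",
)

#: Vocabulary for the yes/no-style items; only "yes" maps to 1.
YESNO_LEVELS = frozenset({"yes", "no", "maybe", "unsure"})
#: Vocabulary for the likelihood brackets; qualifying levels map to 1.
LIKELIHOOD_LEVELS = frozenset({"never", "unlikely", "maybe", "very likely", "definitely"})
QUALIFYING_LIKELIHOOD = frozenset({"very likely", "definitely"})


class EncodingError(ValueError):
    """Raised when a raw response column contains unknown levels."""


@dataclass
class ResponseMatrix:
    """n x p matrix of 0/1 item indicators with item labels."""

    values: np.ndarray
    labels: tuple[str, ...] = ITEM_LABELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("responses must be a 2-d array")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("responses must be coded 0/1")
        self.values = self.values.astype(np.int8)
        self.labels = tuple(self.labels)
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count does not match column count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("item labels must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.labels), index=index)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ResponseMatrix":
        return cls(frame.to_numpy(), tuple(frame.columns))


@dataclass
class ItemBattery:
    """Encoded battery plus the raw bracket indicators feeding the composite."""

    responses: ResponseMatrix
    bracket_indicators: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.bracket_indicators is not None:
            composite = self.bracket_indicators.to_numpy().max(axis=1)
            if not np.array_equal(composite, self.responses.column("likely_contact_u14")):
                raise ValueError(
                    "likely_contact_u14 must equal the OR of its bracket indicators"
                )


def _encode_yesno(col: pd.Series) -> np.ndarray:
    vals = col.astype(str).str.strip().str.lower()
    bad = sorted(set(vals) - YESNO_LEVELS)
    if bad:
        raise EncodingError(f"unknown response levels in {col.name!r}: {bad}")
    return (vals == "yes").to_numpy(dtype=np.int8)


def _encode_likelihood(col: pd.Series) -> np.ndarray:
    vals = col.astype(str).str.strip().str.lower()
    bad = sorted(set(vals) - LIKELIHOOD_LEVELS)
    if bad:
        raise EncodingError(f"unknown response levels in {col.name!r}: {bad}")
    return vals.isin(QUALIFYING_LIKELIHOOD).to_numpy(dtype=np.int8)


def encode_items(raw: pd.DataFrame) -> ItemBattery:
    """Dichotomise a raw survey table into the ten-item battery.

    Expects the first nine items as columns named by :data:`ITEM_LABELS`
    (yes/no/maybe/unsure vocabulary) and the three bracket columns of
    :data:`BRACKET_COLUMNS` (never/unlikely/maybe/very likely/definitely).
    """
    cols = {}
    for label in ITEM_LABELS[:9]:
        if label not in raw.columns:
            raise EncodingError(f"missing raw column {label!r}")
        cols[label] = _encode_yesno(raw[label])
    brackets = {}
    for bcol in BRACKET_COLUMNS:
        if bcol not in raw.columns:
            raise EncodingError(f"missing raw column {bcol!r}")
        brackets[bcol] = _encode_likelihood(raw[bcol])
    bracket_frame = pd.DataFrame(brackets, index=raw.index)
    cols["likely_contact_u14"] = bracket_frame.to_numpy().max(axis=1)
    values = np.column_stack([cols[label] for label in ITEM_LABELS])
    return ItemBattery(
        responses=ResponseMatrix(values, ITEM_LABELS),
        bracket_indicators=bracket_frame,
    )
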