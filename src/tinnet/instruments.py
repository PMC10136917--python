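"""Ordinal symptom instruments: data model, validation, scoring and reliability.

An :class:`Instrument` describes one self-report questionnaire whose items are
scored on a small integer scale (0-3 for the PHQ-9 and GAD-7) and whose total
score maps onto ordered severity bands.  An :class:`ItemResponseMatrix` holds a
validated complete-case subjects x items table together with an item ->
community map, and is the single input type every downstream stage consumes.

Missing or out-of-range responses are handled by complete-case exclusion at
validation time: a subject with any invalid cell is dropped and reported, never
imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Instrument",
    "ItemResponseMatrix",
    "SeverityTally",
    "ValidationReport",
    "PHQ9",
    "GAD7",
    "validate_responses",
    "total_score",
    "severity_band",
    "severity_tally",
    "cronbach_alpha",
]


class SchemaError(ValueError):
    """Input table does not cover the declared instrument items."""


class EmptyDataError(ValueError):
    """No subject survived complete-case validation."""


class DegenerateDataError(ValueError):
    """A quantity is undefined on this input (e.g. zero variance)."""


@dataclass(frozen=True)
class Instrument:
    """A fixed-length ordinal questionnaire with severity bands.

    Parameters
    ----------
    name:
        Instrument label, also used as the community label of its items.
    items:
        Ordered ``(item_id, label)`` pairs.
    severity_bands:
        Ordered ``(band_label, lo, hi)`` triples, inclusive on both ends.
        Bands must be contiguous, non-overlapping, and jointly cover
        ``0 .. n_items * max_response``.
    min_response, max_response:
        Allowed per-item response range (defaults 0 and 3).
    """

    name: str
    items: tuple[tuple[str, str], ...]
    severity_bands: tuple[tuple[str, int, int], ...]
    min_response: int = 0
    max_response: int = 3

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.name}: duplicate item ids")
        if not self.min_response < self.max_response:
            raise ValueError(f"{self.name}: min_response must be < max_response")
        lo_expect = 0
        for label, lo, hi in self.severity_bands:
            if lo != lo_expect or hi < lo:
                raise ValueError(
                    f"{self.name}: severity bands must be contiguous and ordered "
                    f"(band {label!r} starts at {lo}, expected {lo_expect})"
                )
            lo_expect = hi + 1
        if lo_expect != self.max_total + 1:
            raise ValueError(
                f"{self.name}: severity bands must cover 0..{self.max_total}"
            )

    @property
    def item_ids(self) -> list[str]:
        return [i for i, _ in self.items]

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def max_total(self) -> int:
        return self.n_items * self.max_response


#: Patient Health Questionnaire-9: nine depression items scored 0-3,
#: total 0-27, standard severity cut points.
PHQ9 = Instrument(
    name="depression",
    items=(
        ("D1", "Anhedonia"),
        ("D2", "Feeling depressed or hopeless"),
        ("D3", "Sleep problems"),
        ("D4", "Energy loss"),
        ("D5", "Appetite changes"),
        ("D6", "Feeling of worthlessness"),
        ("D7", "Trouble concentrating"),
        ("D8", "Psychomotor issues"),
        ("D9", "Suicidal ideation"),
    ),
    severity_bands=(
        ("normal", 0, 4),
        ("mild", 5, 9),
        ("moderate", 10, 14),
        ("moderately severe", 15, 19),
        ("severe", 20, 27),
    ),
)

#: Generalized Anxiety Disorder-7: seven anxiety items scored 0-3, total 0-21.
GAD7 = Instrument(
    name="anxiety",
    items=(
        ("A1", "Feeling nervous or anxious"),
        ("A2", "Unable to control worry"),
        ("A3", "Excessive worry"),
        ("A4", "Relaxation difficulty"),
        ("A5", "Too restless to sit still"),
        ("A6", "Easily annoyed or irritable"),
        ("A7", "Afraid something awful might happen"),
    ),
    severity_bands=(
        ("normal", 0, 4),
        ("mild", 5, 9),
        ("moderate", 10, 14),
        ("severe", 15, 21),
    ),
)


@dataclass
class ItemResponseMatrix:
    """Validated complete-case ordinal responses with community labels.

    ``values`` is an integer array of shape ``(n_subjects, n_items)`` whose
    columns follow ``items``; ``communities`` maps each item id to the name of
    its owning instrument.
    """

    subjects: list[str]
    items: list[str]
    communities: dict[str, str]
    values: np.ndarray
    instruments: tuple[Instrument, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.subjects), len(self.items)):
            raise ValueError("values shape does not match subjects x items")
        if set(self.items) != set(self.communities):
            raise ValueError("communities must label exactly the items present")
        counts = pd.Series(list(self.communities.values())).value_counts()
        if (counts < 2).any():
            raise ValueError("each community needs at least 2 items")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.items)

    def column(self, item_id: str) -> np.ndarray:
        return self.values[:, self.items.index(item_id)]


@dataclass
class ValidationReport:
    """Outcome of complete-case screening: kept/rejected counts and reasons."""

    n_input: int
    n_kept: int
    rejected: list[dict] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def to_records(self) -> list[dict]:
        return list(self.rejected)


@dataclass
class SeverityTally:
    """Per-band subject counts and percentages for one instrument."""

    instrument: str
    bands: list[str]
    counts: list[int]

    @property
    def n_subjects(self) -> int:
        return int(sum(self.counts))

    @property
    def percentages(self) -> list[float]:
        n = self.n_subjects
        return [100.0 * c / n for c in self.counts]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"band": self.bands, "count": self.counts, "percent": self.percentages}
        )


def validate_responses(
    raw_table: pd.DataFrame,
    instruments: Sequence[Instrument],
    subject_id_column: str | None = None,
) -> tuple[ItemResponseMatrix, ValidationReport]:
    """Screen a raw response table and return the complete-case matrix.

    Every declared item must appear as a column (anything else raises
    :class:`SchemaError`).  Subjects with a missing, non-integer or
    out-of-range cell on any item are dropped and itemised in the report;
    if nobody survives an :class:`EmptyDataError` is raised.
    """
    instruments = tuple(instruments)
    item_ids = [iid for ins in instruments for iid in ins.item_ids]
    missing_cols = [c for c in item_ids if c not in raw_table.columns]
    if missing_cols:
        raise SchemaError(f"input table lacks item columns: {missing_cols}")

    if subject_id_column is not None and subject_id_column in raw_table.columns:
        subject_ids = raw_table[subject_id_column].astype(str).tolist()
    else:
        subject_ids = [str(i) for i in raw_table.index]

    communities = {
        iid: ins.name for ins in instruments for iid in ins.item_ids
    }
    bounds = {
        iid: (ins.min_response, ins.max_response)
        for ins in instruments
        for iid in ins.item_ids
    }

    data = raw_table[item_ids]
    numeric = data.apply(pd.to_numeric, errors="coerce")

    rejected: list[dict] = []
    keep_mask = np.ones(len(data), dtype=bool)
    for row_pos, (sid, row) in enumerate(zip(subject_ids, numeric.itertuples(index=False))):
        for iid, val in zip(item_ids, row):
            if pd.isna(val):
                rejected.append({"subject": sid, "item": iid, "reason": "missing"})
                keep_mask[row_pos] = False
                break
            lo, hi = bounds[iid]
            if val != int(val) or not (lo <= val <= hi):
                rejected.append(
                    {"subject": sid, "item": iid, "reason": "out of range",
                     "value": float(val)}
                )
                keep_mask[row_pos] = False
                break

    kept = numeric.loc[keep_mask]
    if kept.empty:
        raise EmptyDataError("all subjects rejected during validation")
    matrix = ItemResponseMatrix(
        subjects=[s for s, k in zip(subject_ids, keep_mask) if k],
        items=item_ids,
        communities=communities,
        values=kept.to_numpy(dtype=np.int64),
        instruments=instruments,
    )
    report = ValidationReport(
        n_input=len(data), n_kept=matrix.n_subjects, rejected=rejected
    )
    if report.n_rejected:
        logger.info(
            "validation dropped %d/%d subjects", report.n_rejected, report.n_input
        )
    return matrix, report


def total_score(responses: ItemResponseMatrix, instrument: Instrument) -> pd.Series:
    """Per-subject total score: the plain sum of the instrument's items."""
    missing = [i for i in instrument.item_ids if i not in responses.items]
    if missing:
        raise SchemaError(f"{instrument.name}: items not in matrix: {missing}")
    cols = [responses.items.index(i) for i in instrument.item_ids]
    totals = responses.values[:, cols].sum(axis=1)
    return pd.Series(totals, index=responses.subjects, name=instrument.name)


def severity_band(score: int, instrument: Instrument) -> str:
    """Label of the unique severity band whose inclusive range contains *score*."""
    if not 0 <= score <= instrument.max_total:
        raise ValueError(
            f"score {score} outside 0..{instrument.max_total} for {instrument.name}"
        )
    for label, lo, hi in instrument.severity_bands:
        if lo <= score <= hi:
            return label
    raise AssertionError("bands cover the full range by construction")


def severity_tally(
    responses: ItemResponseMatrix, instrument: Instrument
) -> SeverityTally:
    """Count subjects per severity band of one instrument."""
    totals = total_score(responses, instrument)
    labels = [label for label, _, _ in instrument.severity_bands]
    counts = {label: 0 for label in labels}
    for s in totals:
        counts[severity_band(int(s), instrument)] += 1
    return SeverityTally(
        instrument=instrument.name, bands=labels, counts=[counts[b] for b in labels]
    )


def cronbach_alpha(
    responses: ItemResponseMatrix, instrument: Instrument
) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total score)),
    using the sample (n-1 denominator) variance throughout.  Raises
    :class:`DegenerateDataError` when the total score has zero variance.
    """
    cols = [responses.items.index(i) for i in instrument.item_ids]
    X = responses.values[:, cols].astype(float)
    k = X.shape[1]
    if k < 2 or X.shape[0] < 2:
        raise DegenerateDataError("alpha needs >=2 items and >=2 subjects")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DegenerateDataError("total score has zero variance; alpha undefined")
    item_vars = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))
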