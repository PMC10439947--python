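"""Grade standards and evaluation objects.

A *grade standard* assigns to every evaluation index either five half-open
value intervals ``(lo, hi]`` (quantitative indexes) or five fixed ordinal
scores 1..5 (qualitative indexes), one per quality grade I (very good)
through V (very poor).  An *evaluation object* is a non-negative vector of
observed index values aligned with a standard.

Readers accept delimited text (CSV) and, for standards, YAML mappings with
the same keys.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DEFAULT_GRADE_LABELS = ("I", "II", "III", "IV", "V")

QUANTITATIVE = "quantitative"
QUALITATIVE = "qualitative"


class ValidationError(ValueError):
    """Raised when a standard, object or input file violates the data contract."""


@dataclass(frozen=True)
class IndexDefinition:
    """One evaluation index: its identity and the per-grade intervals/scores.

    For quantitative indexes ``bounds`` holds one ``(lo, hi)`` pair per grade,
    interpreted as the half-open interval ``(lo, hi]``.  For qualitative
    (ordinal) indexes ``scores`` holds one fixed score per grade; by
    convention grade g carries score g.
    """

    id: str
    name: str = ""
    units: str = ""
    kind: str = QUANTITATIVE
    bounds: tuple[tuple[float, float], ...] = ()
    scores: tuple[float, ...] = ()
    # every published index tiles one contiguous range, so gaps between
    # grade intervals are rejected by default; synthetic standards used to
    # probe grade separation may opt out
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (QUANTITATIVE, QUALITATIVE):
            raise ValidationError(
                f"index {self.id!r}: unknown kind {self.kind!r}"
            )
        if self.kind == QUANTITATIVE:
            self._validate_quantitative()
        else:
            self._validate_qualitative()

    def _validate_quantitative(self) -> None:
        if len(self.bounds) != 5:
            raise ValidationError(
                f"index {self.id!r}: expected 5 grade intervals, "
                f"got {len(self.bounds)}"
            )
        for g, (lo, hi) in enumerate(self.bounds, start=1):
            if lo < 0 or hi < 0:
                raise ValidationError(
                    f"index {self.id!r} grade {g}: negative bound ({lo}, {hi}]"
                )
            if not lo < hi:
                raise ValidationError(
                    f"index {self.id!r} grade {g}: empty interval ({lo}, {hi}]"
                )
        # Intervals must tile a single contiguous range: sorted by lower
        # bound, each upper endpoint is the next lower endpoint.  With
        # allow_gaps only the overlap check remains.
        order = sorted(range(5), key=lambda g: self.bounds[g][0])
        for a, b in zip(order, order[1:]):
            hi_a = self.bounds[a][1]
            lo_b = self.bounds[b][0]
            if self.allow_gaps:
                if hi_a > lo_b + 1e-12:
                    raise ValidationError(
                        f"index {self.id!r}: grades {a + 1} and {b + 1} overlap "
                        f"({self.bounds[a]} vs {self.bounds[b]})"
                    )
            elif not np.isclose(hi_a, lo_b, rtol=0.0, atol=1e-12):
                raise ValidationError(
                    f"index {self.id!r}: grades {a + 1} and {b + 1} are "
                    f"overlapping or non-contiguous "
                    f"({self.bounds[a]} vs {self.bounds[b]})"
                )

    def _validate_qualitative(self) -> None:
        if tuple(self.scores) != (1, 2, 3, 4, 5):
            raise ValidationError(
                f"index {self.id!r}: qualitative scores must be 1..5 in grade "
                f"order, got {self.scores}"
            )

    @property
    def value_range(self) -> tuple[float, float]:
        """Total (lo, hi] range covered by the five grades."""
        if self.kind == QUALITATIVE:
            return (min(self.scores), max(self.scores))
        los = [lo for lo, _ in self.bounds]
        his = [hi for _, hi in self.bounds]
        return (min(los), max(his))


@dataclass(frozen=True)
class GradeStandard:
    """An ordered collection of index definitions plus the grade labels."""

    indexes: tuple[IndexDefinition, ...]
    grade_labels: tuple[str, ...] = DEFAULT_GRADE_LABELS

    def __post_init__(self) -> None:
        if len(self.indexes) < 1:
            raise ValidationError("a standard needs at least one index")
        ids = [ix.id for ix in self.indexes]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate index ids: {ids}")
        if len(self.grade_labels) < 1:
            raise ValidationError("at least one grade label required")
        for ix in self.indexes:
            n_entries = len(ix.bounds) if ix.kind == QUANTITATIVE else len(ix.scores)
            if n_entries != self.n_grades:
                raise ValidationError(
                    f"index {ix.id!r}: {n_entries} grade entries but the "
                    f"standard declares {self.n_grades} grades"
                )

    @property
    def n_grades(self) -> int:
        return len(self.grade_labels)

    @property
    def n_indexes(self) -> int:
        return len(self.indexes)

    @property
    def index_ids(self) -> tuple[str, ...]:
        return tuple(ix.id for ix in self.indexes)

    def index(self, index_id: str) -> IndexDefinition:
        for ix in self.indexes:
            if ix.id == index_id:
                return ix
        raise KeyError(index_id)

    def grade_number(self, label: str) -> int:
        """1-based grade number for a label."""
        return self.grade_labels.index(label) + 1


@dataclass(frozen=True)
class EvaluationObject:
    """A labelled non-negative value vector aligned to a standard's indexes."""

    id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValidationError(f"object {self.id!r}: values must be 1-D")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValidationError(
                f"object {self.id!r}: values must be finite and >= 0"
            )
        object.__setattr__(self, "values", arr)

    def check_against(self, standard: GradeStandard) -> None:
        if len(self.values) != standard.n_indexes:
            raise ValidationError(
                f"object {self.id!r}: {len(self.values)} values for "
                f"{standard.n_indexes} indexes"
            )
        for ix, v in zip(standard.indexes, self.values):
            if ix.kind == QUALITATIVE and v not in (1, 2, 3, 4, 5):
                raise ValidationError(
                    f"object {self.id!r}, index {ix.id!r}: ordinal value {v} "
                    f"not in {{1..5}}"
                )


def grade_of_value(index: IndexDefinition, value: float, labels: Sequence[str] = DEFAULT_GRADE_LABELS) -> str | None:
    """Grade whose interval contains ``value`` under (lo, hi] membership.

    Returns ``None`` when the value falls outside the union of intervals.
    Diagnostic helper only -- classification never bins the target.
    """
    if index.kind == QUALITATIVE:
        for g, score in enumerate(index.scores):
            if value == score:
                return labels[g]
        return None
    for g, (lo, hi) in enumerate(index.bounds):
        if lo < value <= hi:
            return labels[g]
    return None


# ---------------------------------------------------------------------------
# readers / writers

_STANDARD_COLUMNS = ["index_id", "name", "kind", "units"] + [
    f"g{g}_{side}" for g in range(1, 6) for side in ("lo", "hi")
]


def _index_from_record(rec: dict) -> IndexDefinition:
    kind = str(rec["kind"]).strip().lower()
    if kind.startswith("qual"):
        scores = []
        for g in range(1, 6):
            raw = rec.get(f"g{g}_lo")
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                raise ValidationError(
                    f"index {rec['index_id']!r}: missing score for grade {g}"
                )
            scores.append(float(raw))
        return IndexDefinition(
            id=str(rec["index_id"]).strip(),
            name=str(rec.get("name", "") or ""),
            units=str(rec.get("units", "") or ""),
            kind=QUALITATIVE,
            scores=tuple(scores),
        )
    bounds = []
    for g in range(1, 6):
        try:
            lo = float(rec[f"g{g}_lo"])
            hi = float(rec[f"g{g}_hi"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(
                f"index {rec['index_id']!r}: bad interval for grade {g}: {exc}"
            ) from exc
        bounds.append((lo, hi))
    return IndexDefinition(
        id=str(rec["index_id"]).strip(),
        name=str(rec.get("name", "") or ""),
        units=str(rec.get("units", "") or ""),
        kind=QUANTITATIVE,
        bounds=tuple(bounds),
    )


def read_grade_standard(source: str) -> GradeStandard:
    """Parse a grade standard from CSV text or a YAML mapping.

    CSV columns: ``index_id,name,kind,units,g1_lo,g1_hi,...,g5_lo,g5_hi``.
    For qualitative indexes the ``*_lo`` fields carry the five scores and the
    ``*_hi`` fields are empty.  The YAML form is a mapping with an
    ``indexes`` list of records using the same keys.
    """
    text = source.strip()
    if not text:
        raise ValidationError("empty grade-standard source")
    if text.splitlines()[0].replace(" ", "").startswith("index_id,"):
        df = pd.read_csv(io.StringIO(source), dtype={"index_id": str})
        missing = {"index_id", "kind"} - set(df.columns)
        if missing:
            raise ValidationError(f"standard file missing columns: {sorted(missing)}")
        records = df.to_dict("records")
        labels = DEFAULT_GRADE_LABELS
    else:
        doc = yaml.safe_load(source)
        if not isinstance(doc, dict) or "indexes" not in doc:
            raise ValidationError("YAML standard must be a mapping with an 'indexes' list")
        records = doc["indexes"]
        labels = tuple(doc.get("grade_labels", DEFAULT_GRADE_LABELS))
    indexes = tuple(_index_from_record(rec) for rec in records)
    return GradeStandard(indexes=indexes, grade_labels=labels)


def write_grade_standard(standard: GradeStandard) -> str:
    """Serialize to the CSV form read back by :func:`read_grade_standard`."""
    rows = []
    for ix in standard.indexes:
        row: dict[str, object] = {
            "index_id": ix.id,
            "name": ix.name,
            "kind": ix.kind,
            "units": ix.units,
        }
        for g in range(1, standard.n_grades + 1):
            if ix.kind == QUALITATIVE:
                row[f"g{g}_lo"] = _fmt(ix.scores[g - 1])
                row[f"g{g}_hi"] = ""
            else:
                lo, hi = ix.bounds[g - 1]
                row[f"g{g}_lo"] = _fmt(lo)
                row[f"g{g}_hi"] = _fmt(hi)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_STANDARD_COLUMNS)
    return df.to_csv(index=False)


def _fmt(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def read_objects(source: str, standard: GradeStandard) -> list[EvaluationObject]:
    """Parse evaluation objects from CSV text.

    Expected columns: ``object_id`` plus one column per index id of the
    standard (order-insensitive; values are re-ordered to the standard).
    """
    df = pd.read_csv(io.StringIO(source), dtype={"object_id": str})
    if "object_id" not in df.columns:
        raise ValidationError("objects file missing 'object_id' column")
    missing = [ix for ix in standard.index_ids if ix not in df.columns]
    if missing:
        raise ValidationError(f"objects file missing index columns: {missing}")
    objects = []
    for pos, row in df.iterrows():
        values = []
        for ix in standard.indexes:
            cell = row[ix.id]
            try:
                v = float(cell)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"row {pos + 1}, column {ix.id!r}: non-numeric value {cell!r}"
                ) from exc
            if not np.isfinite(v):
                raise ValidationError(
                    f"row {pos + 1}, column {ix.id!r}: non-finite value {cell!r}"
                )
            if v < 0:
                raise ValidationError(
                    f"row {pos + 1}, column {ix.id!r}: negative value {v}"
                )
            lo, hi = ix.value_range
            in_range = (lo < v <= hi) if ix.kind == QUANTITATIVE else v in (1, 2, 3, 4, 5)
            if not in_range:
                if ix.kind == QUALITATIVE:
                    raise ValidationError(
                        f"row {pos + 1}, column {ix.id!r}: ordinal value {v} "
                        f"not in {{1..5}}"
                    )
                # out-of-range quantitative observations stay admissible:
                # classification never bins the target value
                logger.warning(
                    "object %r: %s=%s outside the standard's range (%s, %s]",
                    row["object_id"], ix.id, v, lo, hi,
                )
            values.append(v)
        obj = EvaluationObject(id=str(row["object_id"]), values=np.array(values))
        obj.check_against(standard)
        objects.append(obj)
    return objects


def write_objects(objects: Iterable[EvaluationObject], standard: GradeStandard) -> str:
    """Serialize objects to the CSV form read back by :func:`read_objects`."""
    rows = []
    for obj in objects:
        row = {"object_id": obj.id}
        row.update({ix.id: _fmt(v) for ix, v in zip(standard.indexes, obj.values)})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["object_id", *standard.index_ids])
    return df.to_csv(index=False)
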