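"""Random but valid grade standards and objects, for testing and diagnostics.

``random_standard`` builds a standard whose per-index grade intervals are
contiguous with a controllable width scale; ``object_in_grade`` draws a
target whose every value lies inside one grade's intervals, giving a
known-answer parameter-recovery harness for the classifier.
"""

from __future__ import annotations

import numpy as np

from .grade_model import (
    QUALITATIVE,
    QUANTITATIVE,
    DEFAULT_GRADE_LABELS,
    EvaluationObject,
    GradeStandard,
    IndexDefinition,
)
from .sampler import RandomSource, sample_representative


def random_standard(
    rng: RandomSource,
    n_indexes: int = 6,
    qualitative_fraction: float = 0.2,
    scale: float = 50.0,
) -> GradeStandard:
    """A random valid 5-grade standard.

    Quantitative indexes get five contiguous intervals with random widths;
    roughly half run in increasing grade order, half decreasing.  A
    ``qualitative_fraction`` of indexes become ordinal 1..5.
    """
    g = rng.generator
    indexes = []
    for i in range(n_indexes):
        if g.random() < qualitative_fraction:
            indexes.append(
                IndexDefinition(
                    id=f"S{i + 1}", kind=QUALITATIVE, scores=(1, 2, 3, 4, 5)
                )
            )
            continue
        widths = g.uniform(0.2, 1.0, size=5) * scale
        start = g.uniform(0.0, scale)
        edges = start + np.concatenate([[0.0], np.cumsum(widths)])
        intervals = [(edges[k], edges[k + 1]) for k in range(5)]
        if g.random() < 0.5:
            intervals = intervals[::-1]  # decreasing: grade I gets high values
        indexes.append(
            IndexDefinition(
                id=f"S{i + 1}", kind=QUANTITATIVE, bounds=tuple(intervals)
            )
        )
    return GradeStandard(indexes=tuple(indexes))


def object_in_grade(
    standard: GradeStandard, grade: str, rng: RandomSource, object_id: str = "synthetic"
) -> EvaluationObject:
    """A target drawn entirely from one grade's intervals (known answer)."""
    rep = sample_representative(standard, grade, rng)
    return EvaluationObject(id=object_id, values=rep.values)
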