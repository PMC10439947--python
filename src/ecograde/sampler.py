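"""Stochastic generation of grade-representative objects.

A grade-g representative draws every quantitative index value uniformly
from that index's grade-g interval and fixes every qualitative index at
that grade's ordinal score.  Representatives are regenerated fresh for
every Monte-Carlo trial, never cached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grade_model import QUALITATIVE, EvaluationObject, GradeStandard

DEFAULT_SEED = 42


@dataclass
class RandomSource:
    """Seeded random stream; identical seeds yield identical sample sequences."""

    seed: int = DEFAULT_SEED
    generator: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._seq = np.random.SeedSequence(self.seed)
        self.generator = np.random.default_rng(self._seq)

    def spawn(self, n: int) -> list["RandomSource"]:
        """n independent child streams, deterministic in the parent seed."""
        children = []
        for child_seq in self._seq.spawn(n):
            src = RandomSource.__new__(RandomSource)
            src.seed = self.seed
            src._seq = child_seq
            src.generator = np.random.default_rng(child_seq)
            children.append(src)
        return children


def _grade_bounds_arrays(standard: GradeStandard) -> tuple[np.ndarray, np.ndarray]:
    """(n_grades, n_indexes) lo/hi arrays; qualitative rows collapse to the score."""
    n_g, n_i = standard.n_grades, standard.n_indexes
    lo = np.empty((n_g, n_i))
    hi = np.empty((n_g, n_i))
    for j, ix in enumerate(standard.indexes):
        if ix.kind == QUALITATIVE:
            lo[:, j] = ix.scores
            hi[:, j] = ix.scores
        else:
            lo[:, j] = [b[0] for b in ix.bounds]
            hi[:, j] = [b[1] for b in ix.bounds]
    return lo, hi


def sample_representative(
    standard: GradeStandard, grade: str, rng: RandomSource
) -> EvaluationObject:
    """One synthetic object whose every value typifies the given grade."""
    g = standard.grade_labels.index(grade)
    values = np.empty(standard.n_indexes)
    for j, ix in enumerate(standard.indexes):
        if ix.kind == QUALITATIVE:
            values[j] = ix.scores[g]
        else:
            lo, hi = ix.bounds[g]
            values[j] = rng.generator.uniform(lo, hi)
    return EvaluationObject(id=f"rep:{grade}", values=values)


def sample_representative_set(
    standard: GradeStandard, rng: RandomSource
) -> list[EvaluationObject]:
    """One representative per grade, in grade order."""
    return [
        sample_representative(standard, grade, rng)
        for grade in standard.grade_labels
    ]


def sample_representative_sets(
    standard: GradeStandard, rng: RandomSource, n_sets: int
) -> np.ndarray:
    """Vectorized batch of representative sets.

    Returns an array of shape ``(n_sets, n_grades, n_indexes)``; set ``t``
    row ``g`` is a grade-g representative.  Same sampling law as
    :func:`sample_representative_set`, drawn in one call for speed.
    """
    lo, hi = _grade_bounds_arrays(standard)
    u = rng.generator.random((n_sets, standard.n_grades, standard.n_indexes))
    return lo + u * (hi - lo)
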