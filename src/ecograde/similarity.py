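"""Sqrt-cosine similarity, argmax grade classification, separation diagnostic.

The similarity of two non-negative vectors a, b is

    sim(a, b) = sum_j sqrt(a_j * b_j) / (sqrt(sum_j a_j) * sqrt(sum_j b_j)),

the Hellinger-affinity-style proximity: it equals 1 iff the vectors are
proportional after square-rooting, and lies in [0, 1] by Cauchy-Schwarz.
The sum runs over ALL indexes of the standard.  Classification assigns a
target to the grade whose representative is most similar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grade_model import EvaluationObject, GradeStandard
from .sampler import RandomSource, sample_representative_sets

logger = logging.getLogger(__name__)


class SimilarityError(ValueError):
    pass


def _as_values(obj) -> np.ndarray:
    if isinstance(obj, EvaluationObject):
        return obj.values
    return np.asarray(obj, dtype=float)


def sqrt_cosine_similarity(a, b) -> float:
    """sim(a, b) for two aligned non-negative vectors; symmetric, in [0, 1]."""
    va, vb = _as_values(a), _as_values(b)
    if va.shape != vb.shape:
        raise SimilarityError(f"misaligned vectors: {va.shape} vs {vb.shape}")
    if np.any(va < 0) or np.any(vb < 0):
        raise SimilarityError("similarity requires non-negative components")
    sa, sb = va.sum(), vb.sum()
    if sa == 0 or sb == 0:
        raise SimilarityError("similarity undefined for an all-zero vector")
    return float(np.sqrt(va * vb).sum() / (np.sqrt(sa) * np.sqrt(sb)))


def similarity_to_sets(targets: np.ndarray, rep_sets: np.ndarray) -> np.ndarray:
    """Vectorized similarity of target vector(s) to batched representative sets.

    ``targets``: shape (n_indexes,); ``rep_sets``: (n_sets, n_grades,
    n_indexes).  Returns (n_sets, n_grades).
    """
    t = np.asarray(targets, dtype=float)
    num = np.sqrt(rep_sets * t).sum(axis=-1)
    den = np.sqrt(rep_sets.sum(axis=-1)) * np.sqrt(t.sum())
    return num / den


def normalize_minmax(values: np.ndarray, standard: GradeStandard) -> np.ndarray:
    """Optional per-index min-max rescale onto [0, 1] over the standard's range."""
    lo = np.array([ix.value_range[0] for ix in standard.indexes])
    hi = np.array([ix.value_range[1] for ix in standard.indexes])
    return np.clip((np.asarray(values, float) - lo) / (hi - lo), 0.0, 1.0)


def classify(
    target: EvaluationObject | np.ndarray,
    representatives: Sequence[EvaluationObject] | np.ndarray,
    grade_labels: Sequence[str] = ("I", "II", "III", "IV", "V"),
) -> tuple[str, np.ndarray]:
    """Grade of the most similar representative, plus the similarity vector.

    ``representatives`` must be in grade order, one per grade.  Exact ties
    at the maximum resolve to the most favorable (lowest-numbered) grade
    and are logged.
    """
    t = _as_values(target)
    if isinstance(representatives, np.ndarray):
        reps = representatives
    else:
        reps = np.stack([_as_values(r) for r in representatives])
    sims = similarity_to_sets(t, reps[np.newaxis, :, :])[0]
    best = int(np.argmax(sims))
    if np.sum(sims == sims[best]) > 1:
        logger.info("similarity tie at %.6f; choosing grade %s", sims[best], grade_labels[best])
    return grade_labels[best], sims


@dataclass(frozen=True)
class SeparationReport:
    """Empirical check that same-grade pairs beat different-grade pairs."""

    min_within: float
    max_between: float
    violation_rate: float
    trials: int

    @property
    def separated(self) -> bool:
        return self.min_within > self.max_between


def separation_diagnostic(
    standard: GradeStandard, rng: RandomSource, trials: int = 1000
) -> SeparationReport:
    """Sample pairs of representative sets and compare within- vs between-grade
    similarities.

    Per trial, two independent representative sets are drawn; pairs of
    same-grade representatives give the within-grade similarities, pairs of
    different grades the between-grade ones.  A trial violates separation
    when its min within-grade similarity does not exceed its max
    between-grade similarity.  This is a reported property of a given
    standard, never an assumption of the classifier.
    """
    if trials < 2:
        raise ValueError("trials must be >= 2")
    set_a = sample_representative_sets(standard, rng, trials)
    set_b = sample_representative_sets(standard, rng, trials)
    n_g = standard.n_grades
    # sims[t, g, h] = sim(set_a[t, g], set_b[t, h])
    num = np.sqrt(set_a[:, :, None, :] * set_b[:, None, :, :]).sum(axis=-1)
    den = np.sqrt(set_a.sum(axis=-1))[:, :, None] * np.sqrt(set_b.sum(axis=-1))[:, None, :]
    sims = num / den
    eye = np.eye(n_g, dtype=bool)
    within = sims[:, eye]
    between = sims[:, ~eye]
    min_within = within.min(axis=1)
    max_between = between.max(axis=1)
    violations = np.mean(min_within <= max_between)
    return SeparationReport(
        min_within=float(within.min()),
        max_between=float(between.max()),
        violation_rate=float(violations),
        trials=trials,
    )
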