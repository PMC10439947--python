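"""Monte-Carlo grade evaluation: the initial (static) probability vector.

Each trial draws a fresh set of grade representatives and classifies the
target by maximum sqrt-cosine similarity; over N trials the per-grade
classification counts divided by N give the grade-probability vector.  The
modal grade (maximum probability) is the evaluation result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grade_model import EvaluationObject, GradeStandard
from .sampler import RandomSource, sample_representative_sets
from .similarity import normalize_minmax, similarity_to_sets

DEFAULT_TRIALS = 1000


@dataclass(frozen=True)
class GradeProbabilities:
    """Per-grade trial probabilities P(I)..P(V) for one evaluated object."""

    object_id: str
    grade_labels: tuple[str, ...]
    counts: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.sum() != self.n_trials:
            raise ValueError(
                f"counts sum {counts.sum()} != n_trials {self.n_trials}"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def p(self) -> np.ndarray:
        return self.counts / self.n_trials

    @property
    def modal_grade(self) -> str:
        return self.grade_labels[int(np.argmax(self.counts))]

    def as_dict(self) -> dict:
        return {
            "object_id": self.object_id,
            "n_trials": self.n_trials,
            "counts": self.counts.tolist(),
            "probabilities": self.p.tolist(),
            "modal_grade": self.modal_grade,
        }


def evaluate(
    target: EvaluationObject,
    standard: GradeStandard,
    n_trials: int = DEFAULT_TRIALS,
    rng: RandomSource | None = None,
    normalize: bool = False,
    validate: bool = True,
) -> GradeProbabilities:
    """Monte-Carlo grade probabilities for one target object.

    ``normalize`` applies per-index min-max rescaling to both the target and
    the sampled representatives before computing similarities (off by
    default; raw values reproduce the reference workflow).  ``validate=False``
    skips the ordinal-lattice check on the target, which sensitivity probes
    perturb off-lattice on purpose.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if validate:
        target.check_against(standard)
    if rng is None:
        rng = RandomSource()
    rep_sets = sample_representative_sets(standard, rng, n_trials)
    values = target.values
    if normalize:
        values = normalize_minmax(values, standard)
        lo = np.array([ix.value_range[0] for ix in standard.indexes])
        hi = np.array([ix.value_range[1] for ix in standard.indexes])
        rep_sets = (rep_sets - lo) / (hi - lo)
    if values.sum() == 0:
        raise ValueError(f"object {target.id!r}: all-zero value vector")
    sims = similarity_to_sets(values, rep_sets)
    winners = np.argmax(sims, axis=1)  # ties resolve to the lowest grade
    counts = np.bincount(winners, minlength=standard.n_grades)
    return GradeProbabilities(
        object_id=target.id,
        grade_labels=standard.grade_labels,
        counts=counts,
        n_trials=n_trials,
    )


def evaluate_batch(
    targets: Sequence[EvaluationObject],
    standard: GradeStandard,
    n_trials: int = DEFAULT_TRIALS,
    rng: RandomSource | None = None,
    normalize: bool = False,
) -> list[GradeProbabilities]:
    """Evaluate each target with an independent sub-stream of the seed.

    Sub-streams are derived deterministically from the parent seed, so a
    target's result does not depend on batch composition or order.
    """
    if rng is None:
        rng = RandomSource()
    streams = rng.spawn(len(targets))
    return [
        evaluate(t, standard, n_trials=n_trials, rng=s, normalize=normalize)
        for t, s in zip(targets, streams)
    ]
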