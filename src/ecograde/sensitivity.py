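"""Local index sensitivity of the evaluation output.

For each index i, the relative sensitivity is

    S_i = | ((F(x + d e_i) - F(x)) / F(x)) / (d / x_i) |,

a one-sided finite difference of a scalar output functional F, normalized
by the relative input step.  Both evaluations run under common random
numbers (identical stream) so the Monte-Carlo noise largely cancels.

The default functional is the probability of the base modal grade; a
deterministic alternative (similarity to the modal grade's interval-midpoint
representative) and the expected grade score are also available.

An optional Normal-uncertainty mode replaces the fixed step by draws
x_i' ~ Normal(x_i, sd) truncated at zero.  Under that model every index is
perturbed on the same absolute scale (the shared standard deviation), so
the reported sensitivity is the mean relative output change |dF/F| over
draws with no further input normalization -- dividing by the relative input
step there would simply re-rank indexes by their magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .evaluator import DEFAULT_TRIALS, evaluate
from .grade_model import QUALITATIVE, EvaluationObject, GradeStandard
from .sampler import DEFAULT_SEED, RandomSource
from .similarity import similarity_to_sets

logger = logging.getLogger(__name__)

FUNCTIONALS = ("modal_prob", "midpoint_sim", "expected_grade")


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class SensitivityConfig:
    delta: float = 2.0  # one stated standard deviation
    n_trials: int = DEFAULT_TRIALS
    seed: int = DEFAULT_SEED
    functional: str = "modal_prob"
    normal_draws: int = 0  # >0: average S over Normal(x_i, delta) draws
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise SensitivityError("delta must be nonzero")
        if self.n_trials < 1:
            raise SensitivityError("n_trials must be >= 1")
        if self.functional not in FUNCTIONALS:
            raise SensitivityError(
                f"unknown functional {self.functional!r}; choose from {FUNCTIONALS}"
            )


@dataclass(frozen=True)
class SensitivityResult:
    object_id: str
    index_ids: tuple[str, ...]
    s_values: np.ndarray
    base_value: float
    base_modal_grade: str
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def ranking(self) -> tuple[str, ...]:
        """Index ids in order of decreasing sensitivity."""
        order = np.argsort(-self.s_values, kind="stable")
        return tuple(self.index_ids[i] for i in order)

    def rank_of(self, index_id: str) -> int:
        """1-based rank of an index (1 = most sensitive)."""
        return self.ranking.index(index_id) + 1

    def as_dict(self) -> dict:
        return {
            "object_id": self.object_id,
            "base_value": self.base_value,
            "base_modal_grade": self.base_modal_grade,
            "s": {i: float(s) for i, s in zip(self.index_ids, self.s_values)},
            "ranking": list(self.ranking),
            "skipped": dict(self.skipped),
        }


def _midpoint_representatives(standard: GradeStandard) -> np.ndarray:
    reps = np.empty((standard.n_grades, standard.n_indexes))
    for j, ix in enumerate(standard.indexes):
        if ix.kind == QUALITATIVE:
            reps[:, j] = ix.scores
        else:
            reps[:, j] = [(lo + hi) / 2 for lo, hi in ix.bounds]
    return reps


def make_functional(
    standard: GradeStandard, config: SensitivityConfig
) -> Callable[[np.ndarray], float]:
    """Scalar output functional F(values) for the configured variant.

    ``modal_prob`` and ``expected_grade`` re-run the Monte-Carlo evaluation
    from the same seed on every call (common random numbers).  The base
    modal grade is pinned on the first call so perturbed evaluations
    difference the same output coordinate.
    """
    if config.functional == "midpoint_sim":
        reps = _midpoint_representatives(standard)
        pinned: list[int] = []

        def f_mid(values: np.ndarray) -> float:
            sims = similarity_to_sets(values, reps[np.newaxis])[0]
            if not pinned:
                pinned.append(int(np.argmax(sims)))
            return float(sims[pinned[0]])

        return f_mid

    pinned_grade: list[int] = []

    def f_mc(values: np.ndarray) -> float:
        obj = EvaluationObject(id="sens", values=values)
        probs = evaluate(
            obj,
            standard,
            n_trials=config.n_trials,
            rng=RandomSource(config.seed),
            normalize=config.normalize,
            validate=False,
        )
        if config.functional == "expected_grade":
            grades = np.arange(1, standard.n_grades + 1)
            return float((grades * probs.p).sum())
        if not pinned_grade:
            pinned_grade.append(int(np.argmax(probs.counts)))
        return float(probs.p[pinned_grade[0]])

    return f_mc


def _perturbed(values: np.ndarray, j: int, delta: float, index_kind: str, score_max: float = 5.0) -> np.ndarray:
    out = values.copy()
    v = out[j] + delta
    if index_kind == QUALITATIVE:
        clipped = min(max(v, 1.0), score_max)
        if clipped != v:
            logger.warning("ordinal perturbation %s clipped to %s", v, clipped)
        v = clipped
    elif v < 0:
        logger.warning("perturbed value %s clipped to 0", v)
        v = 0.0
    out[j] = v
    return out


def _s_from_step(f, values, j, delta, kind, base_f) -> float:
    x_i = values[j]
    pert = _perturbed(values, j, delta, kind)
    actual_delta = pert[j] - x_i
    if actual_delta == 0:
        return 0.0
    f_pert = f(pert)
    rel_out = (f_pert - base_f) / base_f
    rel_in = actual_delta / x_i
    return abs(rel_out / rel_in)


def sensitivity_one(
    target: EvaluationObject,
    standard: GradeStandard,
    index_id: str,
    config: SensitivityConfig = SensitivityConfig(),
    functional: Callable[[np.ndarray], float] | None = None,
    base_value: float | None = None,
) -> float:
    """Relative sensitivity S of the output functional to one index."""
    j = list(standard.index_ids).index(index_id)
    values = target.values
    if values[j] == 0:
        raise SensitivityError(f"{index_id}: relative step undefined at x_i = 0")
    f = functional if functional is not None else make_functional(standard, config)
    base = f(values) if base_value is None else base_value
    if base == 0:
        raise SensitivityError("relative change undefined: F(x) = 0")
    kind = standard.indexes[j].kind
    if config.normal_draws > 0:
        draw_rng = np.random.default_rng(np.random.SeedSequence((config.seed, j)))
        s_vals = []
        for _ in range(config.normal_draws):
            x_new = draw_rng.normal(values[j], abs(config.delta))
            x_new = max(x_new, 0.0)
            if kind == QUALITATIVE:
                x_new = min(max(x_new, 1.0), 5.0)
            pert = values.copy()
            pert[j] = x_new
            s_vals.append(abs((f(pert) - base) / base))
        return float(np.mean(s_vals))
    return _s_from_step(f, values, j, config.delta, kind, base)


def sensitivity_all(
    target: EvaluationObject,
    standard: GradeStandard,
    config: SensitivityConfig = SensitivityConfig(),
    functional: Callable[[np.ndarray], float] | None = None,
) -> SensitivityResult:
    """S for every index, sharing one base evaluation; plus the ranking.

    Indexes failing preconditions (for instance x_i = 0) are reported in
    ``skipped`` with the reason, not silently dropped.
    """
    f = functional if functional is not None else make_functional(standard, config)
    base = f(target.values)
    if base == 0:
        raise SensitivityError("relative change undefined: F(x) = 0")
    # recover the pinned modal grade for reporting
    modal = ""
    if functional is None and config.functional == "modal_prob":
        probs = evaluate(
            target, standard, n_trials=config.n_trials,
            rng=RandomSource(config.seed), normalize=config.normalize,
        )
        modal = probs.modal_grade
    s_values = []
    kept_ids = []
    skipped: dict[str, str] = {}
    for ix in standard.indexes:
        try:
            s = sensitivity_one(
                target, standard, ix.id, config, functional=f, base_value=base
            )
        except SensitivityError as exc:
            skipped[ix.id] = str(exc)
            continue
        kept_ids.append(ix.id)
        s_values.append(s)
    return SensitivityResult(
        object_id=target.id,
        index_ids=tuple(kept_ids),
        s_values=np.array(s_values),
        base_value=float(base),
        base_modal_grade=modal,
        skipped=skipped,
    )
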