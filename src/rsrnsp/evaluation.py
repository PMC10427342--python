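"""Performance metrics for the three sequence tasks.

* overall performance — fraction of positions whose next-element
  prediction is correct.
* counting performance — fraction of subsequences whose end-flag
  transition (the prediction made at the n-th repeated element, whose
  correct target is the end flag) is correct.  This is the one prediction
  in each subsequence that requires counting the repeats.  A strict
  variant requires every prediction in the subsequence to be correct.
* generation performance — fraction of autonomously generated symbols that
  correctly continue the target cycle given their predecessor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence

from .network import ContractError
from .tasks import COUNTING, MOTION_GENERATION


@dataclass
class EvalReport:
    """Metrics of one evaluation run, with provenance fields."""

    overall: float | None = None
    counting: float | None = None
    generation: float | None = None
    n: int | None = None
    m: int | None = None
    N: int | None = None
    seed: int | None = None
    task_kind: str | None = None

    def __post_init__(self) -> None:
        for name in ("overall", "counting", "generation"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def to_row(self) -> str:
        """Tab-separated row: metrics as percentages plus provenance."""
        def fmt(v):
            return "" if v is None else f"{100 * v:.2f}"
        return "\t".join([
            self.task_kind or "", str(self.n or ""), str(self.N or ""),
            str(self.seed if self.seed is not None else ""),
            fmt(self.overall), fmt(self.counting), fmt(self.generation),
        ])


def overall_performance(predicted: Sequence, target: Sequence) -> float:
    """Fraction of positions where the prediction equals the target."""
    if len(predicted) != len(target):
        raise ContractError("predicted/target length mismatch")
    if len(predicted) == 0:
        raise ContractError("empty streams")
    hits = sum(p == t for p, t in zip(predicted, target))
    return hits / len(predicted)


def counting_performance(predicted: Sequence, target: Sequence,
                         boundaries: Sequence, strict: bool = False
                         ) -> float:
    """Fraction of subsequences predicted correctly.

    ``predicted[i]`` is the prediction made at input position ``i`` (of the
    element at ``i + 1``); ``target[i]`` is the true element at ``i + 1``.
    ``boundaries`` are ``(start, end)`` pairs delimiting complete
    subsequences ``a b^n c``.  By default a subsequence counts as correct
    when its end-flag transition — the prediction at the last repeated
    element, position ``end - 2`` — is correct; with ``strict=True`` every
    prediction inside the subsequence must be correct.
    """
    if len(boundaries) == 0:
        raise ContractError("boundary list is empty")
    if len(predicted) != len(target):
        raise ContractError("predicted/target length mismatch")
    hits = 0
    for start, end in boundaries:
        if not 0 <= start < end <= len(predicted):
            raise ContractError(f"boundary ({start}, {end}) out of range")
        if strict:
            ok = all(predicted[i] == target[i] for i in range(start, end))
        else:
            ok = predicted[end - 2] == target[end - 2]
        hits += ok
    return hits / len(boundaries)


def generation_performance(generated: Sequence, target_cycle: Sequence,
                           previous=None) -> float:
    """Fraction of generated symbols that continue the cycle correctly.

    Position ``t`` is correct when ``generated[t]`` is the cyclic successor
    of ``generated[t - 1]``; the first position is scored against
    ``previous`` (the seeded start symbol) when given, otherwise skipped.
    """
    if len(generated) == 0:
        raise ContractError("empty generated stream")
    cycle = list(target_cycle)
    n = len(cycle)
    succ = {cycle[i]: cycle[(i + 1) % n] for i in range(n)}
    hits = 0
    total = 0
    prev = previous
    for t, g in enumerate(generated):
        if t == 0 and prev is None:
            prev = g
            continue
        total += 1
        if prev in succ and g == succ[prev]:
            hits += 1
        prev = g
    if total == 0:
        raise ContractError("nothing to score")
    return hits / total


def report_from_inference(result, *, N: int | None = None,
                          seed: int | None = None,
                          m: int | None = None,
                          strict_counting: bool = False) -> EvalReport:
    """Build an :class:`EvalReport` from an inference result namespace."""
    if result.task_kind == MOTION_GENERATION:
        gen = generation_performance(result.generated, result.cycle,
                                     result.previous)
        return EvalReport(generation=gen, n=result.n, m=m, N=N, seed=seed,
                          task_kind=result.task_kind)
    overall = overall_performance(result.predicted, result.targets)
    counting = None
    if result.task_kind == COUNTING:
        counting = counting_performance(result.predicted, result.targets,
                                        result.boundaries,
                                        strict=strict_counting)
    return EvalReport(overall=overall, counting=counting, n=result.n,
                      m=m, N=N, seed=seed, task_kind=result.task_kind)
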