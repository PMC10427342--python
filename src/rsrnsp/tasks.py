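"""Sequence-learning tasks and reward functions.

Three tasks are supported, all built from exactly periodic symbol streams:

* counting — ``(a b^n c)^m``: a start flag, ``n`` repeats of ``b``, an end
  flag.  Predicting the end flag requires counting the repeats.
* motion prediction — ``(1 2 ... n)^m``: next-element prediction of a
  cyclic walk over ``n`` positions.
* motion generation — the same cycle, but the network must produce it
  autonomously, its own output fed back as the next input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

Symbol = Hashable

COUNTING = "counting"
MOTION_PREDICTION = "motion_prediction"
MOTION_GENERATION = "motion_generation"


@dataclass
class SymbolSequence:
    """A task-generated symbol stream with subsequence annotations.

    ``boundaries`` holds ``(start, end)`` index pairs (end exclusive), one
    per subsequence.  ``alphabet`` lists the distinct symbols in a fixed
    order; output neuron ``k`` represents ``alphabet[k]``.
    """

    symbols: list
    boundaries: list
    task_kind: str
    n: int
    m: int
    alphabet: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.alphabet:
            seen = {}
            for s in self.symbols:
                seen.setdefault(s, None)
            self.alphabet = list(seen)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def period(self) -> int:
        """Length of one subsequence (the cycle of the stream)."""
        return len(self.symbols) // self.m

    @property
    def cycle(self) -> list:
        """One period of the stream."""
        return self.symbols[: self.period]

    def symbol_frequencies(self) -> dict:
        """Occurrence probability of each alphabet symbol in the stream.

        Used to set the per-output-neuron intrinsic-plasticity targets.
        """
        counts = {a: 0 for a in self.alphabet}
        for s in self.symbols:
            counts[s] += 1
        total = len(self.symbols)
        return {a: c / total for a, c in counts.items()}

    def to_text(self) -> str:
        return "\n".join(str(s) for s in self.symbols) + "\n"


def make_counting_sequence(n: int, m: int, seed: int | None = None
                           ) -> SymbolSequence:
    """Build the periodic counting stream ``(a b^n c)^m``.

    ``seed`` is accepted for interface symmetry with future stochastic
    variants; the stream itself is deterministic.
    """
    if n < 1 or m < 1:
        raise ValueError(f"n and m must be >= 1, got n={n}, m={m}")
    block = ["a"] + ["b"] * n + ["c"]
    symbols = block * m
    stride = n + 2
    boundaries = [(k * stride, (k + 1) * stride) for k in range(m)]
    return SymbolSequence(symbols, boundaries, COUNTING, n, m,
                          alphabet=["a", "b", "c"])


def make_motion_sequence(n: int, m: int,
                         task_kind: str = MOTION_PREDICTION
                         ) -> SymbolSequence:
    """Build the periodic motion stream ``(1 2 ... n)^m``."""
    if n < 2 or m < 1:
        raise ValueError(f"need n >= 2 and m >= 1, got n={n}, m={m}")
    if task_kind not in (MOTION_PREDICTION, MOTION_GENERATION):
        raise ValueError(f"not a motion task: {task_kind!r}")
    block = list(range(1, n + 1))
    symbols = block * m
    boundaries = [(k * n, (k + 1) * n) for k in range(m)]
    return SymbolSequence(symbols, boundaries, task_kind, n, m,
                          alphabet=block)


def next_target(sequence: SymbolSequence, position: int) -> Symbol:
    """Ground-truth next element at ``position`` (cyclic at the end)."""
    length = len(sequence)
    if not 0 <= position < length:
        raise IndexError(f"position {position} out of range [0, {length})")
    return sequence.symbols[(position + 1) % length]


def prediction_reward(predicted: Symbol, target: Symbol,
                      reward_incorrect: float = 0.0) -> float:
    """Reward 1 for a correct prediction, ``reward_incorrect`` otherwise."""
    if reward_incorrect not in (0, -1, 0.0, -1.0):
        raise ValueError("reward_incorrect must be 0 or -1")
    return 1.0 if predicted == target else float(reward_incorrect)


def _is_cyclic_run(window: Sequence, cycle: Sequence) -> bool:
    """True if ``window`` occurs as a contiguous run of the repeated cycle."""
    n = len(cycle)
    for offset in range(n):
        if all(window[i] == cycle[(offset + i) % n]
               for i in range(len(window))):
            return True
    return False


def generation_reward(recent_outputs: Sequence,
                      target_cycle: Sequence) -> float:
    """Partial-credit reward for autonomous generation.

    The reward is ``L / n`` where ``L`` is the length of the longest suffix
    of the last ``n`` outputs that forms a contiguous run of the repeated
    target cycle, so a fully correct window earns 1, a window whose last
    three symbols continue the cycle earns 3/4 (for ``n = 4``), and so on.
    Entries that are ``None`` (the pre-history padding) never match.
    """
    n = len(target_cycle)
    if n == 0:
        raise ValueError("target cycle must be nonempty")
    window = list(recent_outputs)[-n:]
    for length in range(len(window), 0, -1):
        suffix = window[-length:]
        if any(s is None or s not in target_cycle for s in suffix):
            continue
        if _is_cyclic_run(suffix, target_cycle):
            return length / n
    return 0.0


def cyclic_successor(symbol: Symbol, cycle: Sequence) -> Symbol:
    """The element following ``symbol`` in the repeated cycle."""
    idx = cycle.index(symbol)
    return cycle[(idx + 1) % len(cycle)]
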