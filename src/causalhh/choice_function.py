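"""Choice-function heuristic selection with rate rescaling.

Each low-level heuristic H_i is scored by

    F(H_i) = phi * f1(H_i) + phi * f2(H_j, H_i) + delta * f3(H_i)

where f1 accumulates the heuristic's own improvement rate, f2 the rate
achieved when it follows the previously selected heuristic H_j, and f3
the time elapsed since it was last selected.  After an improving call
phi is rewarded to 0.99; after a deteriorating one it decays linearly by
0.01 down to a floor of 0.01, with delta = 1 - phi throughout — so
sustained stagnation shifts the selection pressure from intensification
(f1, f2) to exploration (f3).

DAG-learning fitness deltas are orders of magnitude larger than call
durations, which would let f1/f2 swamp f3 permanently; recorded raw
rates I/T are therefore linearly rescaled into [a*tbar, b*tbar] (a=0.1,
b=0.2, tbar = mean call duration) before entering f1/f2.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ChoiceFunctionState:
    """Per-subgroup bookkeeping of operator utilities and weights."""

    operators: tuple[str, ...]
    a: float = 0.1
    b: float = 0.2
    phi: float = 0.5
    delta: float = 0.5
    f1: dict[str, float] = field(default_factory=dict)
    f2: dict[tuple[str, str], float] = field(default_factory=dict)
    f3: dict[str, float] = field(default_factory=dict)
    last_op: str | None = None
    last_duration: float = 0.0
    recorded_rates: list[float] = field(default_factory=list)
    tbar: float = 0.0
    calls: int = 0

    def __post_init__(self) -> None:
        for op in self.operators:
            self.f1.setdefault(op, 0.0)
            self.f3.setdefault(op, 0.0)


def select(state: ChoiceFunctionState, rng: np.random.Generator) -> str:
    """argmax of F = phi*f1 + phi*f2[last->op] + delta*f3; ties uniform."""
    scores = {}
    for op in state.operators:
        pair = state.f2.get((state.last_op, op), 0.0) if state.last_op else 0.0
        scores[op] = state.phi * state.f1[op] + state.phi * pair + state.delta * state.f3[op]
    best = max(scores.values())
    tied = [op for op in state.operators if scores[op] == best]
    return tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]


def rescale(state: ChoiceFunctionState, raw_rate: float) -> float:
    """Map the raw rate into [a*tbar, b*tbar] linearly over the recorded
    range; a degenerate range maps to the upper end b*tbar."""
    lo, hi = min(state.recorded_rates), max(state.recorded_rates)
    if hi == lo:
        return state.b * state.tbar
    frac = (raw_rate - lo) / (hi - lo)
    return (state.a + (state.b - state.a) * frac) * state.tbar


def record_call(
    state: ChoiceFunctionState,
    op: str,
    prev_op: str | None,
    delta_fitness: float,
    duration: float,
) -> None:
    """Update f1/f2/f3 and the duration statistics after one call.

    Only improvements contribute (I = max(delta, 0)); a non-improving
    call still decays f1/f2 by the factor phi.  f3 of the called operator
    resets to 0 while every other operator's f3 advances by the call
    duration.
    """
    if duration <= 0:
        duration = sys.float_info.epsilon
    state.calls += 1
    state.tbar += (duration - state.tbar) / state.calls
    improvement = max(delta_fitness, 0.0)

    if improvement > 0:
        rate = improvement / duration
        state.recorded_rates.append(rate)
        state.f1[op] = rescale(state, rate) + state.phi * state.f1[op]
    else:
        state.f1[op] = state.phi * state.f1[op]

    if prev_op is not None:
        key = (prev_op, op)
        if improvement > 0:
            pair_duration = duration + state.last_duration
            pair_rate = improvement / pair_duration
            state.recorded_rates.append(pair_rate)
            state.f2[key] = rescale(state, pair_rate) + state.phi * state.f2.get(key, 0.0)
        else:
            state.f2[key] = state.phi * state.f2.get(key, 0.0)

    for other in state.operators:
        state.f3[other] += duration
    state.f3[op] = 0.0
    state.last_op = op
    state.last_duration = duration


def update_weights(state: ChoiceFunctionState, improved: bool) -> None:
    """Reward phi to 0.99 on improvement; otherwise decay by 0.01 with a
    0.01 floor.  delta = 1 - phi always."""
    state.phi = 0.99 if improved else max(state.phi - 0.01, 0.01)
    state.delta = 1.0 - state.phi
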