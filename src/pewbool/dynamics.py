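"""Stochastic state-update engine for PEW Boolean models.

Three update schemes are supported:

* ``SYNCHRONOUS`` — all nodes recomputed from the pre-step state; one time
  step = N node updates.
* ``RANDOM_ORDER_ASYNC`` — a fresh uniform permutation per sweep; nodes are
  updated one at a time in that order, each evaluation seeing the earlier
  in-sweep updates; one time step = one sweep (= N node updates).
* ``GENERAL_ASYNC`` — one uniformly chosen node re-evaluated per update,
  repetition allowed; one time step = one node update by default (pass
  ``normalize_gasync=True`` to :func:`simulate` to record every N updates
  instead, for cross-scheme comparisons).

Input nodes (nodes with no rule) are held: the schemes never update them;
only :class:`Perturbation` protocols change their value.  Perturbations
re-draw the node each active step — with probability ``prob`` the node is
set to ``value``, otherwise to ``1 - value`` — which turns the pulse
probability into a concentration-like parameter for input signals.

For speed, rule expressions are compiled once per model into Python
closures that mirror :func:`pewbool.noise.eval_expression` exactly (same
child order, one coin per PEW operator per evaluation), so a trajectory is
reproducible from its seed alone.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grammar import (
    And,
    Const,
    NetworkModel,
    Not,
    Or,
    Pew,
    RuleExpression,
    Var,
)
from .noise import get_noise_function

__all__ = [
    "UpdateScheme",
    "Perturbation",
    "Trajectory",
    "make_state",
    "state_to_index",
    "index_to_state",
    "step_synchronous",
    "step_general_async",
    "step_random_order_sweep",
    "apply_perturbations",
    "validate_perturbations",
    "simulate",
    "compile_model",
]


class UpdateScheme(str, Enum):
    SYNCHRONOUS = "sync"
    RANDOM_ORDER_ASYNC = "rasync"
    GENERAL_ASYNC = "gasync"

    @property
    def time_unit(self) -> str:
        return "per_update" if self is UpdateScheme.GENERAL_ASYNC else "per_sweep"


# ---------------------------------------------------------------------------
# State helpers: a state is a mapping node -> {0,1}, equivalently an integer
# index with bit i = nodes[i] (bit 0 = first declared node).
# ---------------------------------------------------------------------------


def make_state(model: NetworkModel, on_nodes: Iterable[str] = ()) -> dict[str, int]:
    state = {name: 0 for name in model.nodes}
    for name in on_nodes:
        if name not in state:
            raise KeyError(f"unknown node {name!r}")
        state[name] = 1
    return state


def state_to_index(model: NetworkModel, state: Mapping[str, int]) -> int:
    idx = 0
    for i, name in enumerate(model.nodes):
        if state[name]:
            idx |= 1 << i
    return idx


def index_to_state(model: NetworkModel, index: int) -> dict[str, int]:
    return {name: (index >> i) & 1 for i, name in enumerate(model.nodes)}


def _state_list(model: NetworkModel, state: Mapping[str, int]) -> list[int]:
    try:
        return [state[name] & 1 for name in model.nodes]
    except KeyError as exc:
        raise KeyError(f"state missing node {exc.args[0]!r}") from None


def _state_dict(model: NetworkModel, values: Sequence[int]) -> dict[str, int]:
    return dict(zip(model.nodes, values))


# ---------------------------------------------------------------------------
# Rule compilation
# ---------------------------------------------------------------------------

_Compiled = Callable[[Sequence[int], random.Random], int]


def _compile_expr(expr: RuleExpression, index: Mapping[str, int]) -> _Compiled:
    if isinstance(expr, Var):
        i = index[expr.name]
        return lambda s, r: s[i]
    if isinstance(expr, Const):
        v = expr.value
        return lambda s, r: v
    if isinstance(expr, Not):
        c = _compile_expr(expr.child, index)
        return lambda s, r: 1 - c(s, r)
    if isinstance(expr, And):
        cs = [_compile_expr(child, index) for child in expr.children]

        def _and(s, r, _cs=cs):
            v = 1
            for c in _cs:
                v &= c(s, r)
            return v

        return _and
    if isinstance(expr, Or):
        cs = [_compile_expr(child, index) for child in expr.children]

        def _or(s, r, _cs=cs):
            v = 0
            for c in _cs:
                v |= c(s, r)
            return v

        return _or
    if isinstance(expr, Pew):
        operand = _compile_expr(expr.operand, index)
        noise = expr.noise
        theta = noise.theta
        if noise.noise_fn == "bernoulli":
            w_on, w_off = noise.w_on, noise.w_off

            def _pew(s, r, _op=operand):
                w = w_on if _op(s, r) > theta else w_off
                return 1 if r.random() < w else 0

            return _pew
        fn = get_noise_function(noise.noise_fn)
        w_on, w_off = noise.w_on, noise.w_off

        def _pew_named(s, r, _op=operand, _fn=fn):
            x = _op(s, r)
            w = w_on if x > theta else w_off
            return 1 if _fn(x, w, r.random()) > theta else 0

        return _pew_named
    raise TypeError(f"not a RuleExpression: {expr!r}")


@lru_cache(maxsize=256)
def compile_model(model: NetworkModel) -> tuple[_Compiled, ...]:
    """Per-node update closures in declaration order (inputs update to self)."""
    index = model.index
    return tuple(
        _compile_expr(model.expression_for(name), index) for name in model.nodes
    )


# ---------------------------------------------------------------------------
# Single steps
# ---------------------------------------------------------------------------


def _sync_step(fns, state: list[int], rng: random.Random) -> list[int]:
    return [f(state, rng) for f in fns]


def _sweep_step(fns, state: list[int], rng: random.Random) -> list[int]:
    order = list(range(len(fns)))
    rng.shuffle(order)
    new = list(state)
    for i in order:
        new[i] = fns[i](new, rng)
    return new


def _gasync_update(fns, state: list[int], rng: random.Random) -> list[int]:
    i = rng.randrange(len(fns))
    new = list(state)
    new[i] = fns[i](new, rng)
    return new


_STEPPERS = {
    UpdateScheme.SYNCHRONOUS: _sync_step,
    UpdateScheme.RANDOM_ORDER_ASYNC: _sweep_step,
    UpdateScheme.GENERAL_ASYNC: _gasync_update,
}


def step_synchronous(
    model: NetworkModel, state: Mapping[str, int], rng: random.Random
) -> dict[str, int]:
    """All nodes recomputed from the pre-step state; PEW coins drawn in
    node-declaration order."""
    fns = compile_model(model)
    return _state_dict(model, _sync_step(fns, _state_list(model, state), rng))


def step_general_async(
    model: NetworkModel, state: Mapping[str, int], rng: random.Random
) -> dict[str, int]:
    """One uniformly chosen node re-evaluated against the current state."""
    fns = compile_model(model)
    return _state_dict(model, _gasync_update(fns, _state_list(model, state), rng))


def step_random_order_sweep(
    model: NetworkModel, state: Mapping[str, int], rng: random.Random
) -> dict[str, int]:
    """One full sweep in a fresh uniform node order; each node update sees
    the earlier in-sweep updates (one sweep = N node updates)."""
    fns = compile_model(model)
    return _state_dict(model, _sweep_step(fns, _state_list(model, state), rng))


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Perturbation:
    """Probabilistic clamp of one node during a time window.

    While ``t_start <= t < t_end`` the node is re-drawn every step: set to
    ``value`` with probability ``prob``, else to ``1 - value``.  After the
    window, if ``after_value`` is not None the node is held at it (washout
    for input nodes); otherwise the node is left to its rule (or, for an
    input, stays at its last drawn value).
    """

    node: str
    value: int
    prob: float = 1.0
    t_start: int = 0
    t_end: int = 2**62
    after_value: int | None = None

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError("perturbation value must be 0 or 1")
        if not (0.0 <= self.prob <= 1.0):
            raise ValueError("perturbation probability must be in [0, 1]")
        if self.t_start < 0 or self.t_end < self.t_start:
            raise ValueError("perturbation window must satisfy 0 <= t_start <= t_end")


def validate_perturbations(
    model: NetworkModel, perturbations: Sequence[Perturbation]
) -> None:
    by_node: dict[str, list[Perturbation]] = {}
    for p in perturbations:
        if p.node not in model.index:
            raise ValueError(f"perturbation targets unknown node {p.node!r}")
        by_node.setdefault(p.node, []).append(p)
    for node, ps in by_node.items():
        ps = sorted(ps, key=lambda p: p.t_start)
        for a, b in zip(ps, ps[1:]):
            if b.t_start < a.t_end:
                raise ValueError(
                    f"overlapping perturbation windows on node {node!r}"
                )


def _apply_perturbations_list(
    perturbations: Sequence[Perturbation],
    state: list[int],
    t: int,
    rng: random.Random,
    index: Mapping[str, int],
) -> None:
    for p in perturbations:
        i = index[p.node]
        if p.t_start <= t < p.t_end:
            state[i] = p.value if rng.random() < p.prob else 1 - p.value
        elif t >= p.t_end and p.after_value is not None:
            state[i] = p.after_value


def apply_perturbations(
    perturbations: Sequence[Perturbation],
    state: Mapping[str, int],
    t: int,
    rng: random.Random,
) -> dict[str, int]:
    """Apply all active perturbations at engine time ``t`` (fresh draws)."""
    new = dict(state)
    for p in perturbations:
        if p.t_start <= t < p.t_end:
            new[p.node] = p.value if rng.random() < p.prob else 1 - p.value
        elif t >= p.t_end and p.after_value is not None:
            new[p.node] = p.after_value
    return new


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Recorded time evolution: row t = state at time t (row 0 = initial)."""

    states: np.ndarray  # (steps+1, N) uint8
    nodes: tuple[str, ...]
    scheme: UpdateScheme
    seed: int | None = None

    def __len__(self) -> int:
        return self.states.shape[0]

    def node_series(self, node: str) -> np.ndarray:
        return self.states[:, self.nodes.index(node)]

    def final_state(self) -> dict[str, int]:
        return dict(zip(self.nodes, (int(v) for v in self.states[-1])))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.nodes))
        df.insert(0, "step", np.arange(len(self)))
        return df

    def write_csv(self, path, metadata: Mapping[str, object] | None = None) -> None:
        with open(path, "w") as fh:
            for key, value in (metadata or {}).items():
                fh.write(f"# {key}: {value}\n")
            self.to_dataframe().to_csv(fh, index=False)


def simulate(
    model: NetworkModel,
    initial: Mapping[str, int] | Iterable[str],
    scheme: UpdateScheme = UpdateScheme.SYNCHRONOUS,
    steps: int = 100,
    perturbations: Sequence[Perturbation] = (),
    seed: int | None = 0,
    rng: random.Random | None = None,
    normalize_gasync: bool = False,
) -> Trajectory:
    """Run one trajectory and record one state per time unit.

    ``initial`` is either a full/partial state mapping (missing nodes are 0)
    or an iterable of ON-node names.  Perturbations are applied after the
    scheme step and before recording, including at t = 0 on the initial
    state.  Given identical arguments and seed, the trajectory is
    bit-reproducible.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    scheme = UpdateScheme(scheme)
    if isinstance(initial, Mapping):
        state0 = make_state(model)
        state0.update({k: int(v) for k, v in initial.items()})
        for k in initial:
            if k not in model.index:
                raise KeyError(f"unknown node {k!r} in initial state")
    else:
        state0 = make_state(model, initial)
    validate_perturbations(model, perturbations)
    if rng is None:
        rng = random.Random(seed)

    fns = compile_model(model)
    stepper = _STEPPERS[scheme]
    updates_per_step = (
        len(model.nodes)
        if (scheme is UpdateScheme.GENERAL_ASYNC and normalize_gasync)
        else 1
    )

    state = _state_list(model, state0)
    _apply_perturbations_list(perturbations, state, 0, rng, model.index)
    recorded = np.empty((steps + 1, model.n), dtype=np.uint8)
    recorded[0] = state
    for t in range(1, steps + 1):
        if scheme is UpdateScheme.GENERAL_ASYNC and updates_per_step > 1:
            for _ in range(updates_per_step):
                state = stepper(fns, state, rng)
        else:
            state = stepper(fns, state, rng)
        _apply_perturbations_list(perturbations, state, t, rng, model.index)
        recorded[t] = state
    return Trajectory(recorded, model.nodes, scheme, seed)
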