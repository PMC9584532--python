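"""Evaluation of PEW operators and PEW-annotated Boolean expressions.

A PEW operator P_e(f, w_on, w_off) applied to an operand value x selects a
branch parameter by comparing x with the threshold theta (w_on if x > theta,
w_off otherwise) and feeds it to a noise function f.  The default f is the
Bernoulli coin toss: the output is 1 with the selected probability.  Custom
noise functions can be registered by name and referenced from rule files via
the ``[f_name, p1, p2]`` syntax.

Two evaluation routes are provided and kept deliberately separate:

* :func:`eval_expression` / :func:`eval_pew` — stochastic, one fresh
  independent random draw per PEW operator per evaluation;
* :func:`pew_branch_probability` / :func:`expression_probability` — the
  closed-form twin, giving the exact probability that a (sub)expression
  evaluates to 1.  This is what the exact Markov-chain analysis consumes.

The closed form for compound expressions relies on the coins of distinct
PEW operators being independent: given a fixed state, the subtrees of an
``and``/``or`` node involve disjoint sets of coins, so their values are
independent Bernoulli variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Protocol

from .grammar import (
    BERNOULLI,
    And,
    Const,
    NoiseSpec,
    Not,
    Or,
    Pew,
    RuleExpression,
    Var,
)

__all__ = [
    "NoiseFunction",
    "register_noise",
    "get_noise_function",
    "eval_pew",
    "pew_branch_probability",
    "eval_expression",
    "expression_probability",
    "UnregisteredNoiseError",
]


class UnregisteredNoiseError(KeyError):
    pass


class _RandomSource(Protocol):
    def random(self) -> float: ...


# A noise function maps (operand value, selected branch parameter, uniform
# draw in [0,1)) to an output value; outputs are thresholded at theta by the
# Boolean engine, so returning values in {0, 1} is the common case.
NoiseFunction = Callable[[float, float, float], float]


@dataclass
class _NoiseEntry:
    fn: NoiseFunction
    # Optional closed form: (operand value, branch parameter) -> Pr(output=1).
    # Required for a named noise function to take part in exact analysis.
    branch_probability: Callable[[float, float], float] | None


_REGISTRY: dict[str, _NoiseEntry] = {}


def register_noise(
    name: str,
    fn: NoiseFunction,
    branch_probability: Callable[[float, float], float] | None = None,
) -> None:
    """Register a noise function usable from rules as ``[name, p1, p2]``.

    Supplying ``branch_probability`` (the exact probability that the output
    is 1 given the operand value and the selected branch parameter) makes
    the function usable by the exact Markov-chain oracle as well.
    """
    _REGISTRY[name] = _NoiseEntry(fn, branch_probability)


def get_noise_function(name: str) -> NoiseFunction:
    try:
        return _REGISTRY[name].fn
    except KeyError:
        raise UnregisteredNoiseError(
            f"noise function {name!r} is not registered"
        ) from None


def _bernoulli(x: float, w: float, u: float) -> float:
    return 1.0 if u < w else 0.0


register_noise(BERNOULLI, _bernoulli, branch_probability=lambda x, w: w)


def _branch_parameter(noise: NoiseSpec, x: float) -> float:
    return noise.w_on if x > noise.theta else noise.w_off


def eval_pew(noise: NoiseSpec, x: int, rng: _RandomSource) -> int:
    """One stochastic evaluation of a PEW operator on operand value ``x``.

    Draws exactly one uniform variate from ``rng``.  Outputs of custom
    noise functions are thresholded at ``noise.theta`` to keep the Boolean
    engine closed over {0, 1}.
    """
    fn = get_noise_function(noise.noise_fn)
    out = fn(x, _branch_parameter(noise, x), rng.random())
    return 1 if out > noise.theta else 0


def pew_branch_probability(noise: NoiseSpec, x: float) -> float:
    """Exact Pr(output = 1) of a PEW operator given its operand value.

    For the default Bernoulli function this is simply w_on (x > theta) or
    w_off (x <= theta).  Named functions must have declared a closed form
    at registration time.
    """
    try:
        entry = _REGISTRY[noise.noise_fn]
    except KeyError:
        raise UnregisteredNoiseError(
            f"noise function {noise.noise_fn!r} is not registered"
        ) from None
    if entry.branch_probability is None:
        raise ValueError(
            f"noise function {noise.noise_fn!r} has no closed-form branch "
            "probability; exact analysis is unavailable for it"
        )
    return entry.branch_probability(x, _branch_parameter(noise, x))


def eval_expression(
    expr: RuleExpression, state: Mapping[str, int], rng: _RandomSource
) -> int:
    """Evaluate an expression against a state, drawing one independent coin
    per PEW operator.

    All children of ``and``/``or`` nodes are evaluated (no short-circuit),
    so the number and order of random draws depends only on the expression
    tree, which keeps seeded runs reproducible.
    """
    if isinstance(expr, Var):
        try:
            return state[expr.name]
        except KeyError:
            raise KeyError(f"unbound variable {expr.name!r}") from None
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Not):
        return 1 - eval_expression(expr.child, state, rng)
    if isinstance(expr, And):
        value = 1
        for child in expr.children:
            value &= eval_expression(child, state, rng)
        return value
    if isinstance(expr, Or):
        value = 0
        for child in expr.children:
            value |= eval_expression(child, state, rng)
        return value
    if isinstance(expr, Pew):
        return eval_pew(expr.noise, eval_expression(expr.operand, state, rng), rng)
    raise TypeError(f"not a RuleExpression: {expr!r}")


def expression_probability(expr: RuleExpression, state: Mapping[str, int]) -> float:
    """Exact Pr(expr = 1) given a fixed Boolean state.

    The recursion exploits the independence of PEW coins across disjoint
    subtrees; for a PEW node whose operand is itself stochastic with
    Pr(operand=1) = q, the output is 1 with probability
    q * P(1-branch) + (1-q) * P(0-branch).
    """
    if isinstance(expr, Var):
        try:
            return float(state[expr.name])
        except KeyError:
            raise KeyError(f"unbound variable {expr.name!r}") from None
    if isinstance(expr, Const):
        return float(expr.value)
    if isinstance(expr, Not):
        return 1.0 - expression_probability(expr.child, state)
    if isinstance(expr, And):
        p = 1.0
        for child in expr.children:
            p *= expression_probability(child, state)
        return p
    if isinstance(expr, Or):
        q = 1.0
        for child in expr.children:
            q *= 1.0 - expression_probability(child, state)
        return 1.0 - q
    if isinstance(expr, Pew):
        q = expression_probability(expr.operand, state)
        return q * pew_branch_probability(expr.noise, 1) + (1.0 - q) * (
            pew_branch_probability(expr.noise, 0)
        )
    raise TypeError(f"not a RuleExpression: {expr!r}")
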