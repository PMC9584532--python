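"""Bundled models and model transforms.

Contents:

* a small epithelial-mesenchymal transition (EMT) network built around the
  ZEB / miR-200 mutual-repression switch driven by a TGFB input pulse, with
  PEW operators on the two self-sustaining feedback edges (the ZEB -| miR200
  repression and the SNAI1 self-loop) so that the mesenchymal lock-in
  becomes slowly reversible;
* structural PEW edit helpers (install an operator on a selected clause of
  an existing rule), including the documented recipe for weakening the
  CyclinB-Cdk1 -> {MCL1, BCLXL, BCL2} anti-apoptotic hyperedges of a cell
  cycle model supplied as a rule file;
* a BNp emulation wrapper (universal per-update flip noise);
* a loader for external BooleanNet-dialect rule files and a seeded random
  network generator used as a test fixture factory.

The EMT rules are a compact reconstruction: TGFB reaches ZEB through a SMAD
shortcut, reaches SNAI1 through a delay chain of n dummy nodes (SNAI1
activates later than ZEB), and inhibits miR200 through a shorter chain of m
dummy nodes (m < n); SNAI1 maintains itself through a weighted local
positive feedback loop.  With TGFB absent and the PEW weights set to the
identity, the epithelial state (Ecad = miR200 = ON, everything else OFF) is
a fixed point, and a sufficient TGFB pulse locks the noise-free model into
the mesenchymal state permanently; the PEW weights make that lock-in decay.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from .dynamics import Perturbation
from .grammar import (
    And,
    NetworkModel,
    NoiseSpec,
    Not,
    Or,
    Pew,
    Rule,
    RuleExpression,
    Var,
    parse_expression,
    parse_model,
    render_noise,
)

__all__ = [
    "EmtConfig",
    "build_emt_model",
    "emt_wild_type",
    "emt_mutant",
    "EPITHELIAL_PATTERN",
    "MESENCHYMAL_PATTERN",
    "emt_pulse",
    "PewEdit",
    "apply_pew_edits",
    "cyclin_cdk1_edits",
    "bnp_wrap",
    "load_booleannet_file",
    "load_builtin_model",
    "builtin_model_names",
    "generate_random_model",
]


# ---------------------------------------------------------------------------
# EMT model
# ---------------------------------------------------------------------------

#: Node pattern identifying the epithelial attractor (remaining nodes free).
EPITHELIAL_PATTERN = {"Ecad": 1, "miR200": 1, "ZEB": 0}

#: Node pattern identifying the mesenchymal state.
MESENCHYMAL_PATTERN = {"ZEB": 1, "miR200": 0, "Ecad": 0}

WILD_TYPE_WEIGHT = NoiseSpec(0.95, 0.0)
MUTANT_WEIGHT = NoiseSpec(0.05, 0.0)


@dataclass(frozen=True)
class EmtConfig:
    """Parameters of the EMT reconstruction.

    ``n`` is the length of the TGFB -> SNAI1 activation delay chain, ``m``
    (< n) the length of the TGFB -| miR200 inhibitory chain.
    ``zeb_mir200_weight`` is the PEW operator on the ZEB -| miR200 edge
    (wild type [0.95, 0]; the mutant, with a weakened ZEB binding site on
    miR200, uses [0.05, 0]); ``snai1_loop_weight`` sits on the SNAI1
    self-activation loop in both variants.
    """

    n: int = 6
    m: int = 3
    zeb_mir200_weight: NoiseSpec = WILD_TYPE_WEIGHT
    snai1_loop_weight: NoiseSpec = WILD_TYPE_WEIGHT

    def __post_init__(self) -> None:
        if not 1 <= self.m < self.n:
            raise ValueError(f"delay chains require 1 <= m < n, got n={self.n}, m={self.m}")


def build_emt_model(config: EmtConfig = EmtConfig()) -> NetworkModel:
    """Build the EMT network for ``config``; TGFB is a held input node."""
    n, m = config.n, config.m
    w_zm = render_noise(config.zeb_mir200_weight)
    w_s = render_noise(config.snai1_loop_weight)
    lines = ["SMAD* = TGFB", "d1* = TGFB"]
    lines += [f"d{i}* = d{i - 1}" for i in range(2, n + 1)]
    lines.append("a1* = TGFB")
    lines += [f"a{j}* = a{j - 1}" for j in range(2, m + 1)]
    lines += [
        f"SNAI1* = d{n} or {w_s} SNAI1",
        "ZEB* = (SMAD or SNAI1) and not miR200",
        f"miR200* = not {w_zm} ZEB and not a{m}",
        "Ecad* = not ZEB",
    ]
    return parse_model("\n".join(lines))


def emt_wild_type(n: int = 6, m: int = 3) -> NetworkModel:
    """Wild type: slight noise ([0.95, 0]) on both feedback edges."""
    return build_emt_model(EmtConfig(n=n, m=m))


def emt_mutant(n: int = 6, m: int = 3) -> NetworkModel:
    """Mutant: the ZEB -| miR200 edge almost severed ([0.05, 0]); the SNAI1
    loop keeps the wild-type weight."""
    return build_emt_model(EmtConfig(n=n, m=m, zeb_mir200_weight=MUTANT_WEIGHT))


def emt_pulse(prob: float = 1.0, t_start: int = 0, t_end: int = 200) -> Perturbation:
    """A TGFB pulse protocol: the input is re-drawn every step with
    ON-probability ``prob`` (its "concentration") during the window, and
    washed out (held at 0) afterwards."""
    return Perturbation("TGFB", 1, prob=prob, t_start=t_start, t_end=t_end, after_value=0)


# ---------------------------------------------------------------------------
# Structural PEW edits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PewEdit:
    """Install a PEW operator around one clause of one rule.

    ``selector`` is a structural pattern (an expression, or text parsed into
    one); it must match exactly one subtree of the target's rule, which is
    then wrapped in ``Pew(noise, subtree)``.
    """

    target: str
    selector: RuleExpression | str
    noise: NoiseSpec

    def selector_expression(self) -> RuleExpression:
        if isinstance(self.selector, str):
            return parse_expression(self.selector)
        return self.selector


def _wrap_matches(
    expr: RuleExpression, selector: RuleExpression, noise: NoiseSpec
) -> tuple[RuleExpression, int]:
    if expr == selector:
        return Pew(noise, expr), 1
    if isinstance(expr, Not):
        child, k = _wrap_matches(expr.child, selector, noise)
        return (Not(child), k) if k else (expr, 0)
    if isinstance(expr, (And, Or)):
        total = 0
        children = []
        for c in expr.children:
            new, k = _wrap_matches(c, selector, noise)
            children.append(new)
            total += k
        return (type(expr)(tuple(children)), total) if total else (expr, 0)
    if isinstance(expr, Pew):
        inner, k = _wrap_matches(expr.operand, selector, noise)
        return (Pew(expr.noise, inner), k) if k else (expr, 0)
    return expr, 0


def apply_pew_edits(model: NetworkModel, edits: Sequence[PewEdit]) -> NetworkModel:
    """Return a new model with each edit's clause wrapped in its operator.

    Raises if a selector matches no clause or more than one clause of the
    target's rule; the input model is left unmodified.
    """
    result = model
    for edit in edits:
        rule = result.rules_by_target.get(edit.target)
        if rule is None:
            raise ValueError(f"node {edit.target!r} has no rule to edit")
        selector = edit.selector_expression()
        new_expr, count = _wrap_matches(rule.expression, selector, edit.noise)
        if count == 0:
            raise ValueError(
                f"selector {edit.selector!r} matches no clause of {edit.target!r}"
            )
        if count > 1:
            raise ValueError(
                f"selector {edit.selector!r} is ambiguous in {edit.target!r} "
                f"({count} matches)"
            )
        result = result.with_rule(edit.target, new_expr)
    return result


def cyclin_cdk1_edits(
    p_on: float,
    targets: Sequence[str] = ("MCL1", "BCLXL", "BCL2"),
    clause: str = "Cdk1 and CyclinB",
) -> list[PewEdit]:
    """The documented edit recipe for the cell cycle model: weaken the
    CyclinB-Cdk1 complex's inhibitory hyperedges onto the anti-apoptotic
    nodes with a [p_on, 0] operator (same weight on all three clauses).

    Adjust ``targets``/``clause`` spellings to match the loaded rule file.
    """
    noise = NoiseSpec(p_on, 0.0)
    return [PewEdit(t, clause, noise) for t in targets]


# ---------------------------------------------------------------------------
# BNp emulation
# ---------------------------------------------------------------------------


def bnp_wrap(model: NetworkModel, p: float) -> NetworkModel:
    """Emulate a perturbed Boolean network (BNp) with universal flip noise.

    Every rule expression E is replaced by ``[1-p, p] (E)``: each node
    update evaluates its deterministic function and then flips the outcome
    with probability ``p``.  For 0 < p < 1 this makes the chain irreducible
    (every state reachable from every state).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("flip probability must be in [0, 1]")
    if not model.is_noise_free:
        raise ValueError("bnp_wrap expects a noise-free model")
    noise = NoiseSpec(1.0 - p, p)
    rules = tuple(
        Rule(r.target, Pew(noise, r.expression)) for r in model.rules
    )
    return NetworkModel(model.nodes, rules)


# ---------------------------------------------------------------------------
# File and builtin loaders
# ---------------------------------------------------------------------------


def load_booleannet_file(path) -> NetworkModel:
    """Load a rule file in the (PEW-extended) BooleanNet dialect.

    This is the route for externally published models, e.g. the 89-node
    cell cycle network, which is distributed with its own publication and is
    not vendored here; combine with :func:`cyclin_cdk1_edits` to apply the
    anti-apoptotic edge-weakening recipe to it.
    """
    return parse_model(Path(path).read_text())


_MODEL_DIR = resources.files("pewbool") / "models"


def builtin_model_names() -> list[str]:
    return sorted(p.name[: -len(".txt")] for p in _MODEL_DIR.iterdir() if p.name.endswith(".txt"))


def load_builtin_model(name: str) -> NetworkModel:
    """Load a bundled model by name (see :func:`builtin_model_names`)."""
    candidate = _MODEL_DIR / f"{name}.txt"
    try:
        text = candidate.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"no builtin model {name!r}; available: {', '.join(builtin_model_names())}"
        ) from None
    return parse_model(text)


# ---------------------------------------------------------------------------
# Random fixture generator
# ---------------------------------------------------------------------------


def generate_random_model(
    nodes: int,
    k_inputs_per_node: int = 2,
    pew_fraction: float = 0.0,
    seed: int = 0,
) -> NetworkModel:
    """Seeded random Boolean network in the Kauffman NK style.

    Each node gets ``k_inputs_per_node`` distinct regulators chosen
    uniformly; its rule is a random and/or combination of the (possibly
    negated) regulators, and each single-variable literal is independently
    wrapped in a random Bernoulli PEW operator with probability
    ``pew_fraction``.
    """
    if nodes < 1:
        raise ValueError("nodes must be >= 1")
    rnd = random.Random(seed)
    names = [f"n{i}" for i in range(nodes)]
    k = min(k_inputs_per_node, nodes)
    rules = []
    for name in names:
        regulators = rnd.sample(names, k)
        literals: list[RuleExpression] = []
        for reg in regulators:
            lit: RuleExpression = Var(reg)
            if rnd.random() < 0.3:
                lit = Not(lit)
            if rnd.random() < pew_fraction:
                w_on = round(rnd.random(), 2)
                w_off = round(rnd.random(), 2)
                lit = Pew(NoiseSpec(w_on, w_off), lit)
            literals.append(lit)
        expr = literals[0]
        for lit in literals[1:]:
            op = And if rnd.random() < 0.5 else Or
            expr = op((expr, lit))
        rules.append(Rule(name, expr))
    return NetworkModel(tuple(names), tuple(rules))
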