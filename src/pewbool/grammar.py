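"""Rule grammar for Boolean models with probabilistic edge-weight (PEW) operators.

The dialect is a superset of BooleanNet rule syntax: one ``Name* = expr``
assignment per line, ``and`` / ``or`` / ``not`` connectives, parentheses,
``True`` / ``False`` (or ``1`` / ``0``) constants and ``#`` comments.  The
extension is the PEW operator, written as a bracketed token placed to the
left of the clause it weights::

    A* = B and [0.3,0] C        # noise on the C -> A edge
    A* = [0.3,0] (B and C)      # noise on the B,C -> A hyperedge
    A* = [mynoise, 0.2, 0.8] C  # named noise function with branch parameters

A PEW operator behaves like any left-hand-side operator (the same as
``not``): it binds to the first clause on its right — a variable, a
parenthesized sub-expression or a ``not``-expression.  Hence
``[a,b] not C`` wraps the negation, while ``not [a,b] C`` negates the
weighted variable.

Node names are case-sensitive.  A name that is referenced by some rule but
never assigned is treated as a held *input node*: the dynamics never update
it, only perturbation protocols change its value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
from typing import Iterator, Union

__all__ = [
    "NoiseSpec",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "Pew",
    "RuleExpression",
    "Rule",
    "NetworkModel",
    "ParseError",
    "parse_model",
    "parse_expression",
    "parse_pew_token",
    "render_expression",
    "render_model",
]

BERNOULLI = "bernoulli"


class ParseError(ValueError):
    """Syntax or validation error in a rule file, with a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one PEW operator.

    ``w_on`` applies when the operand evaluates above the threshold
    ``theta`` (ON branch), ``w_off`` when it evaluates at or below it.  For
    the default Bernoulli noise function the parameters are probabilities
    that the operator outputs 1; for a named noise function they are that
    function's per-branch parameters (p1 = ON branch, p2 = OFF branch) and
    are not range-checked here.
    """

    w_on: float
    w_off: float
    noise_fn: str = BERNOULLI
    theta: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_fn == BERNOULLI:
            for name, w in (("w_on", self.w_on), ("w_off", self.w_off)):
                if not (0.0 <= w <= 1.0):
                    raise ValueError(
                        f"Bernoulli PEW weight {name}={w} outside [0, 1]"
                    )

    @property
    def is_identity(self) -> bool:
        """True when the operator is the no-noise Bernoulli spec [1,0]."""
        return self.noise_fn == BERNOULLI and self.w_on == 1.0 and self.w_off == 0.0


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Const:
    value: int  # 0 or 1


@dataclass(frozen=True)
class Not:
    child: "RuleExpression"


@dataclass(frozen=True)
class And:
    children: tuple["RuleExpression", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["RuleExpression", ...]


@dataclass(frozen=True)
class Pew:
    """A PEW operator wrapping exactly one operand subtree (its hyperedge)."""

    noise: NoiseSpec
    operand: "RuleExpression"


RuleExpression = Union[Var, Const, Not, And, Or, Pew]


@dataclass(frozen=True)
class Rule:
    target: str
    expression: RuleExpression


@dataclass(frozen=True)
class NetworkModel:
    """A Boolean network (V, E, F): named nodes and one rule per non-input node.

    ``nodes`` is the stable declaration order; bit *i* of an integer state
    index corresponds to ``nodes[i]`` (bit 0 = first node).  Nodes without a
    rule are held inputs.
    """

    nodes: tuple[str, ...]
    rules: tuple[Rule, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rule in self.rules:
            if rule.target in seen:
                raise ValueError(f"duplicate rule for node {rule.target!r}")
            seen.add(rule.target)
            if rule.target not in self.nodes:
                raise ValueError(f"rule target {rule.target!r} not a declared node")
        declared = set(self.nodes)
        for rule in self.rules:
            for var in iter_variables(rule.expression):
                if var not in declared:
                    raise ValueError(
                        f"rule for {rule.target!r} references undeclared node {var!r}"
                    )

    @cached_property
    def rules_by_target(self) -> dict[str, Rule]:
        return {r.target: r for r in self.rules}

    @cached_property
    def input_nodes(self) -> tuple[str, ...]:
        ruled = {r.target for r in self.rules}
        return tuple(n for n in self.nodes if n not in ruled)

    @cached_property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)

    def expression_for(self, node: str) -> RuleExpression:
        """The update expression of ``node``; inputs update to themselves."""
        rule = self.rules_by_target.get(node)
        return rule.expression if rule is not None else Var(node)

    @cached_property
    def is_noise_free(self) -> bool:
        """True if every PEW operator is absent or the identity spec [1,0]."""
        return all(
            pew.noise.is_identity
            for rule in self.rules
            for pew in iter_pew_nodes(rule.expression)
        )

    def with_rule(self, target: str, expression: RuleExpression) -> "NetworkModel":
        """A copy with the rule for ``target`` replaced (or added)."""
        if target not in self.nodes:
            raise ValueError(f"unknown node {target!r}")
        rules = list(self.rules)
        for i, rule in enumerate(rules):
            if rule.target == target:
                rules[i] = Rule(target, expression)
                break
        else:
            rules.append(Rule(target, expression))
        return NetworkModel(self.nodes, tuple(rules))


def iter_variables(expr: RuleExpression) -> Iterator[str]:
    if isinstance(expr, Var):
        yield expr.name
    elif isinstance(expr, Not):
        yield from iter_variables(expr.child)
    elif isinstance(expr, (And, Or)):
        for child in expr.children:
            yield from iter_variables(child)
    elif isinstance(expr, Pew):
        yield from iter_variables(expr.operand)


def iter_pew_nodes(expr: RuleExpression) -> Iterator[Pew]:
    if isinstance(expr, Pew):
        yield expr
        yield from iter_pew_nodes(expr.operand)
    elif isinstance(expr, Not):
        yield from iter_pew_nodes(expr.child)
    elif isinstance(expr, (And, Or)):
        for child in expr.children:
            yield from iter_pew_nodes(child)


# --------------------------------------------------------------------------
# Tokenizer / parser
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<number>-?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?)
  | (?P<punct>[()\[\],*=])
    """,
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "True", "False"}


@dataclass
class _Token:
    kind: str  # "name" | "number" | punctuation literal
    text: str


def _tokenize(text: str, line: int) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError(f"unexpected character {text[pos]!r}", line)
        pos = m.end()
        if m.lastgroup == "ws":
            continue
        if m.lastgroup == "punct":
            tokens.append(_Token(m.group(), m.group()))
        else:
            tokens.append(_Token(m.lastgroup, m.group()))
    return tokens


def _noise_from_parts(parts: list[_Token], line: int | None) -> NoiseSpec:
    if not parts:
        raise ParseError("empty PEW operator []", line)
    if parts[0].kind == "number":
        if len(parts) != 2 or any(p.kind != "number" for p in parts):
            raise ParseError(
                "numeric PEW operator must be [w_on, w_off]", line
            )
        try:
            return NoiseSpec(float(parts[0].text), float(parts[1].text))
        except ValueError as exc:
            raise ParseError(str(exc), line) from None
    if parts[0].kind != "name":
        raise ParseError(f"bad PEW operator token {parts[0].text!r}", line)
    name = parts[0].text
    params = parts[1:]
    if len(params) != 2 or any(p.kind != "number" for p in params):
        raise ParseError(
            f"named PEW operator must be [{name}, p1, p2]", line
        )
    return NoiseSpec(float(params[0].text), float(params[1].text), noise_fn=name)


def parse_pew_token(token: str) -> NoiseSpec:
    """Parse a standalone bracket token such as ``"[0.3,0]"``.

    The numeric form yields the default Bernoulli spec; the
    ``[f_name, p1, p2]`` form records the noise-function name with the ON
    (p1) and OFF (p2) branch parameters.  Whether ``f_name`` is registered
    is checked at evaluation time, not here.
    """
    tokens = _tokenize(token.strip(), line=0)
    if not tokens or tokens[0].text != "[" or tokens[-1].text != "]":
        raise ParseError(f"PEW token must be bracketed: {token!r}")
    parts = [t for t in tokens[1:-1] if t.text != ","]
    commas = sum(1 for t in tokens[1:-1] if t.text == ",")
    if commas != len(parts) - 1:
        raise ParseError(f"malformed PEW token {token!r}")
    return _noise_from_parts(parts, None)


class _Parser:
    """Recursive descent over one rule line.

    Precedence (loosest to tightest): ``or`` < ``and`` < unary
    (``not`` and PEW, composing in textual order) < primary.
    """

    def __init__(self, tokens: list[_Token], line: int):
        self.tokens = tokens
        self.line = line
        self.pos = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of rule", self.line)
        self.pos += 1
        return tok

    def expect(self, text: str) -> _Token:
        tok = self.next()
        if tok.text != text:
            raise ParseError(f"expected {text!r}, found {tok.text!r}", self.line)
        return tok

    def at_end(self) -> bool:
        return self.pos >= len(self.tokens)

    def parse_rule(self) -> Rule:
        head = self.next()
        if head.kind != "name" or head.text in _KEYWORDS:
            raise ParseError(f"expected node name, found {head.text!r}", self.line)
        self.expect("*")
        self.expect("=")
        expr = self.parse_or()
        if not self.at_end():
            raise ParseError(f"trailing input {self.peek().text!r}", self.line)
        return Rule(head.text, expr)

    def parse_or(self) -> RuleExpression:
        children = [self.parse_and()]
        while (tok := self.peek()) is not None and tok.text == "or":
            self.next()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def parse_and(self) -> RuleExpression:
        children = [self.parse_unary()]
        while (tok := self.peek()) is not None and tok.text == "and":
            self.next()
            children.append(self.parse_unary())
        return children[0] if len(children) == 1 else And(tuple(children))

    def parse_unary(self) -> RuleExpression:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of rule", self.line)
        if tok.text == "not":
            self.next()
            return Not(self.parse_unary())
        if tok.text == "[":
            noise = self.parse_noise()
            return Pew(noise, self.parse_unary())
        return self.parse_primary()

    def parse_noise(self) -> NoiseSpec:
        self.expect("[")
        parts: list[_Token] = []
        expecting_part = True
        while True:
            tok = self.next()
            if tok.text == "]":
                break
            if tok.text == ",":
                if expecting_part:
                    raise ParseError("malformed PEW operator", self.line)
                expecting_part = True
                continue
            if not expecting_part:
                raise ParseError(
                    f"expected ',' or ']' in PEW operator, found {tok.text!r}",
                    self.line,
                )
            parts.append(tok)
            expecting_part = False
        return _noise_from_parts(parts, self.line)

    def parse_primary(self) -> RuleExpression:
        tok = self.next()
        if tok.text == "(":
            expr = self.parse_or()
            self.expect(")")
            return expr
        if tok.text == "True":
            return Const(1)
        if tok.text == "False":
            return Const(0)
        if tok.kind == "number":
            if tok.text not in ("0", "1"):
                raise ParseError(f"numeric constant must be 0 or 1: {tok.text}", self.line)
            return Const(int(tok.text))
        if tok.kind == "name" and tok.text not in _KEYWORDS:
            return Var(tok.text)
        raise ParseError(f"unexpected token {tok.text!r}", self.line)


def parse_expression(text: str) -> RuleExpression:
    """Parse a bare expression (used by clause selectors and tests)."""
    parser = _Parser(_tokenize(text, line=0), line=0)
    expr = parser.parse_or()
    if not parser.at_end():
        raise ParseError(f"trailing input {parser.peek().text!r}")
    return expr


def parse_model(text: str) -> NetworkModel:
    """Parse a rule file into a :class:`NetworkModel`.

    Node order is the order of rule lines, followed by referenced-but-unruled
    input nodes in order of first appearance.
    """
    rules: list[Rule] = []
    targets: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = _tokenize(line, lineno)
        rule = _Parser(tokens, lineno).parse_rule()
        if rule.target in targets:
            raise ParseError(f"duplicate rule for node {rule.target!r}", lineno)
        targets.add(rule.target)
        rules.append(rule)
    nodes: list[str] = [r.target for r in rules]
    known = set(nodes)
    for rule in rules:
        for var in iter_variables(rule.expression):
            if var not in known:
                known.add(var)
                nodes.append(var)
    return NetworkModel(tuple(nodes), tuple(rules))


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

_PREC_OR, _PREC_AND, _PREC_UNARY = 1, 2, 3


def _fmt_weight(w: float) -> str:
    return repr(float(w))


def render_noise(noise: NoiseSpec) -> str:
    if noise.noise_fn == BERNOULLI:
        return f"[{_fmt_weight(noise.w_on)},{_fmt_weight(noise.w_off)}]"
    return f"[{noise.noise_fn}, {_fmt_weight(noise.w_on)}, {_fmt_weight(noise.w_off)}]"


def render_expression(expr: RuleExpression, parent_prec: int = 0) -> str:
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Const):
        return "True" if expr.value else "False"
    # Unary children are rendered at AND precedence so that chains like
    # ``not not A`` and ``[a,b] not C`` stay unparenthesized (the unary
    # chain is parsed greedily, so they are unambiguous), while nested
    # same-precedence and/or children get explicit parentheses so that the
    # parse/render round trip is the structural identity.
    if isinstance(expr, Not):
        text = "not " + render_expression(expr.child, _PREC_AND)
        prec = _PREC_UNARY
    elif isinstance(expr, Pew):
        text = render_noise(expr.noise) + " " + render_expression(expr.operand, _PREC_AND)
        prec = _PREC_UNARY
    elif isinstance(expr, And):
        text = " and ".join(render_expression(c, _PREC_AND) for c in expr.children)
        prec = _PREC_AND
    elif isinstance(expr, Or):
        text = " or ".join(render_expression(c, _PREC_OR) for c in expr.children)
        prec = _PREC_OR
    else:  # pragma: no cover
        raise TypeError(f"not a RuleExpression: {expr!r}")
    if prec <= parent_prec:
        return f"({text})"
    return text


def render_model(model: NetworkModel) -> str:
    """Render rules back to file text; ``parse_model`` round-trips the AST."""
    lines = [
        f"{model.rules_by_target[node].target}* = "
        f"{render_expression(model.rules_by_target[node].expression)}"
        for node in model.nodes
        if node in model.rules_by_target
    ]
    return "\n".join(lines) + "\n"
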