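"""Boolean network representation, BoolNet-dialect parsing, and the derived
signed interaction graph.

A :class:`BooleanNetwork` is an ordered list of named nodes, each with one
update rule built from NOT (``!``), AND (``&``), OR (``|``), parentheses and
the constants ``0``/``1``.  Node declaration order is stable and defines bit
positions: network states are encoded as integers where bit ``i`` holds the
state of ``nodes[i]``, and print as 0/1 strings in declaration order.

The signed interaction graph is obtained per rule by exact monotonicity
testing over all regulator assignments: a regulator contributes a positive
edge where the rule is monotonically increasing in it, a negative edge where
decreasing, and both edges when the dependence is non-monotone.  Regulators
the rule does not actually depend on are dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping

import networkx as nx
import sympy
from sympy import And, Not, Or, Symbol
from sympy.logic.boolalg import BooleanFalse, BooleanTrue

from .errors import CapacityError, ModelError

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")

__all__ = [
    "BooleanNetwork",
    "SignedGraph",
    "Perturbation",
    "PhenotypeSpec",
    "parse_bnet",
    "parse_expression",
    "serialize_bnet",
    "expression_to_bnet",
    "derive_signed_graph",
    "apply_perturbation",
    "booleanize_multivalued",
    "decode_level",
]


# ---------------------------------------------------------------------------
# expression parsing


class _Tokenizer:
    _TOKEN_RE = re.compile(r"\s*(?:(\()|(\))|(!)|(&+)|(\|+)|([01])|([A-Za-z_][A-Za-z0-9_]*))")

    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tokens: list[tuple[str, str]] = []
        while self.pos < len(text):
            m = self._TOKEN_RE.match(text, self.pos)
            if m is None or m.end() == self.pos:
                if text[self.pos :].strip():
                    raise ModelError(f"unexpected character {text[self.pos]!r} in expression {text!r}")
                break
            self.pos = m.end()
            kinds = ("lpar", "rpar", "not", "and", "or", "const", "name")
            for kind, val in zip(kinds, m.groups()):
                if val is not None:
                    self.tokens.append((kind, val))
                    break
        self.idx = 0

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.idx] if self.idx < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise ModelError(f"unexpected end of expression in {self.text!r}")
        self.idx += 1
        return tok


def parse_expression(text: str) -> sympy.Basic:
    """Parse a rule expression (``!``, ``&``, ``|``, parens, 0/1) to a sympy
    boolean expression.  ``&&``/``||`` are accepted as synonyms."""
    tz = _Tokenizer(text)

    def expr():
        node = term()
        while tz.peek() and tz.peek()[0] == "or":
            tz.next()
            node = Or(node, term(), evaluate=False)
        return node

    def term():
        node = factor()
        while tz.peek() and tz.peek()[0] == "and":
            tz.next()
            node = And(node, factor(), evaluate=False)
        return node

    def factor():
        kind, val = tz.next()
        if kind == "not":
            return Not(factor(), evaluate=False)
        if kind == "lpar":
            node = expr()
            k, _ = tz.next()
            if k != "rpar":
                raise ModelError(f"missing ')' in expression {text!r}")
            return node
        if kind == "const":
            return sympy.true if val == "1" else sympy.false
        if kind == "name":
            return Symbol(val)
        raise ModelError(f"unexpected token {val!r} in expression {text!r}")

    if not tz.tokens:
        raise ModelError(f"empty expression: {text!r}")
    node = expr()
    if tz.peek() is not None:
        raise ModelError(f"trailing tokens after expression in {text!r}")
    return node


def expression_to_bnet(expr: sympy.Basic) -> str:
    """Render a sympy boolean expression in the ``!``/``&``/``|`` dialect."""
    if expr is sympy.true or isinstance(expr, BooleanTrue):
        return "1"
    if expr is sympy.false or isinstance(expr, BooleanFalse):
        return "0"
    if isinstance(expr, Symbol):
        return expr.name
    if isinstance(expr, Not):
        inner = expr.args[0]
        s = expression_to_bnet(inner)
        if isinstance(inner, (Symbol, BooleanTrue, BooleanFalse)) or inner in (sympy.true, sympy.false):
            return f"!{s}"
        return f"!({s})"
    if isinstance(expr, And):
        parts = []
        for a in expr.args:
            s = expression_to_bnet(a)
            if isinstance(a, Or):
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)
    if isinstance(expr, Or):
        return " | ".join(expression_to_bnet(a) for a in expr.args)
    raise ModelError(f"cannot serialize expression {expr!r}")


# ---------------------------------------------------------------------------
# core types


@dataclass(frozen=True)
class BooleanNetwork:
    """Ordered, validated logical model.

    ``nodes`` fixes bit positions; ``rules`` maps every node to exactly one
    sympy boolean expression over declared node names.
    """

    nodes: tuple[str, ...]
    rules: dict[str, sympy.Basic]

    def __post_init__(self):
        if not self.nodes:
            raise ModelError("network has no nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ModelError("duplicate node names")
        if set(self.rules) != set(self.nodes):
            missing = set(self.nodes) - set(self.rules)
            extra = set(self.rules) - set(self.nodes)
            raise ModelError(f"rules do not match nodes (missing={sorted(missing)}, extra={sorted(extra)})")
        declared = set(self.nodes)
        for name in self.nodes:
            for sym in self.rules[name].free_symbols:
                if sym.name not in declared:
                    raise ModelError(f"rule for {name!r} references undeclared node {sym.name!r}")

    # -- state encoding -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise ModelError(f"unknown node {node!r}") from None

    def state_to_str(self, key: int) -> str:
        return "".join(str((key >> i) & 1) for i in range(self.n))

    def str_to_state(self, s: str) -> int:
        if len(s) != self.n or set(s) - {"0", "1"}:
            raise ModelError(f"bad state string {s!r} for {self.n}-node network")
        return sum(int(c) << i for i, c in enumerate(s))

    def dict_to_state(self, assignment: Mapping[str, int]) -> int:
        key = 0
        for name, v in assignment.items():
            key |= (1 if v else 0) << self.index(name)
        return key

    def state_to_dict(self, key: int) -> dict[str, int]:
        return {name: (key >> i) & 1 for i, name in enumerate(self.nodes)}

    # -- rule evaluation ----------------------------------------------------

    def compiled_rules(self) -> list[Callable[[int], int]]:
        """One callable per node evaluating its rule on an encoded state."""
        idx = {name: i for i, name in enumerate(self.nodes)}
        funcs = []
        for name in self.nodes:
            src = _expr_to_py(self.rules[name], idx)
            funcs.append(eval(f"lambda s: {src}"))  # noqa: S307 - generated from validated AST
        return funcs

    def inputs(self) -> tuple[str, ...]:
        """Nodes whose rule is themselves or a constant (external inputs)."""
        out = []
        for name in self.nodes:
            r = self.rules[name]
            if r == Symbol(name) or r in (sympy.true, sympy.false) or isinstance(r, (BooleanTrue, BooleanFalse)):
                out.append(name)
        return tuple(out)

    def regulators(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(s.name for s in self.rules[node].free_symbols))


def _expr_to_py(expr: sympy.Basic, idx: Mapping[str, int]) -> str:
    if expr is sympy.true or isinstance(expr, BooleanTrue):
        return "1"
    if expr is sympy.false or isinstance(expr, BooleanFalse):
        return "0"
    if isinstance(expr, Symbol):
        return f"((s>>{idx[expr.name]})&1)"
    if isinstance(expr, Not):
        return f"(1-{_expr_to_py(expr.args[0], idx)})"
    if isinstance(expr, And):
        return "(" + "&".join(_expr_to_py(a, idx) for a in expr.args) + ")"
    if isinstance(expr, Or):
        return "(" + "|".join(_expr_to_py(a, idx) for a in expr.args) + ")"
    raise ModelError(f"cannot compile expression {expr!r}")


@dataclass(frozen=True)
class SignedGraph:
    """Signed interaction digraph: edges are (source, target, sign)."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str, int]]

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, s in sorted(self.edges):
            g.add_edge(u, v, sign=s)
        return g

    def structure(self) -> nx.DiGraph:
        """Plain digraph (parallel signed edges collapsed)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, _ in self.edges:
            g.add_edge(u, v)
        return g

    def edge_signs(self) -> dict[tuple[str, str], set[int]]:
        out: dict[tuple[str, str], set[int]] = {}
        for u, v, s in self.edges:
            out.setdefault((u, v), set()).add(s)
        return out


@dataclass(frozen=True)
class Perturbation:
    """Sustained pinning of node states (drug model): node -> 0/1."""

    pins: dict[str, int]

    def __post_init__(self):
        for name, v in self.pins.items():
            if v not in (0, 1):
                raise ModelError(f"pin value for {name!r} must be 0 or 1, got {v!r}")

    def validate(self, net: BooleanNetwork) -> None:
        for name in self.pins:
            if name not in net.nodes:
                raise ModelError(f"pinned node {name!r} is not declared in the network")


@dataclass(frozen=True)
class PhenotypeSpec:
    """Phenotype marker nodes with signed weights.

    Positive weights mark desirable read-outs (e.g. antisurvival), negative
    weights undesirable ones (e.g. prosurvival).  With ``normalize`` the
    preference is scaled by the total absolute weight so it lies in [-1, 1].
    """

    markers: dict[str, float]
    normalize: bool = True

    def __post_init__(self):
        if not self.markers:
            raise ModelError("phenotype spec needs at least one marker")

    def validate(self, net: BooleanNetwork) -> None:
        for name in self.markers:
            if name not in net.nodes:
                raise ModelError(f"marker {name!r} is not declared in the network")

    def state_preference(self, net: BooleanNetwork, key: int) -> float:
        total = sum(w * ((key >> net.index(m)) & 1) for m, w in self.markers.items())
        if self.normalize:
            total /= sum(abs(w) for w in self.markers.values())
        return total


# ---------------------------------------------------------------------------
# parsing / serialization


def parse_bnet(text: str) -> BooleanNetwork:
    """Parse BoolNet-style ``targets, factors`` text into a network."""
    if not text or not text.strip():
        raise ModelError("empty model text")
    nodes: list[str] = []
    raw_rules: dict[str, tuple[str, int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if lineno == 1 or not raw_rules and not nodes:
            if re.fullmatch(r"targets\s*,\s*factors", line, flags=re.IGNORECASE):
                continue
        if "," not in line:
            raise ModelError(f"line {lineno}: expected 'node, rule', got {line!r}")
        name, rule_text = line.split(",", 1)
        name = name.strip()
        if not _NAME_RE.fullmatch(name):
            raise ModelError(f"line {lineno}: invalid node name {name!r}")
        if name in raw_rules:
            raise ModelError(f"line {lineno}: duplicate rule for node {name!r}")
        nodes.append(name)
        raw_rules[name] = (rule_text.strip(), lineno)
    if not nodes:
        raise ModelError("model text contains no rules")
    declared = set(nodes)
    rules: dict[str, sympy.Basic] = {}
    for name in nodes:
        rule_text, lineno = raw_rules[name]
        expr = parse_expression(rule_text)
        for sym in expr.free_symbols:
            if sym.name not in declared:
                raise ModelError(f"line {lineno}: rule for {name!r} references undeclared node {sym.name!r}")
        rules[name] = expr
    return BooleanNetwork(tuple(nodes), rules)


def serialize_bnet(net: BooleanNetwork) -> str:
    """Serialize to the BoolNet dialect; round-trips through parse_bnet."""
    lines = ["targets, factors"]
    for name in net.nodes:
        lines.append(f"{name}, {expression_to_bnet(net.rules[name])}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# signed graph / perturbation


def derive_signed_graph(net: BooleanNetwork) -> SignedGraph:
    """Signed dependency graph by exhaustive monotonicity testing per rule."""
    idx = {name: i for i, name in enumerate(net.nodes)}
    edges: set[tuple[str, str, int]] = set()
    funcs = net.compiled_rules()
    for t_i, target in enumerate(net.nodes):
        regs = net.regulators(target)
        f = funcs[t_i]
        for r in regs:
            others = [x for x in regs if x != r]
            if len(others) > 20:
                raise CapacityError(f"rule for {target!r} has too many regulators to sign exactly")
            inc = dec = False
            for mask in range(1 << len(others)):
                base = 0
                for j, o in enumerate(others):
                    if (mask >> j) & 1:
                        base |= 1 << idx[o]
                v0 = f(base)
                v1 = f(base | (1 << idx[r]))
                if v1 > v0:
                    inc = True
                elif v1 < v0:
                    dec = True
                if inc and dec:
                    break
            if inc:
                edges.add((r, target, 1))
            if dec:
                edges.add((r, target, -1))
            # neither: rule constant in r -> non-functional dependency dropped
    return SignedGraph(net.nodes, frozenset(edges))


def apply_perturbation(net: BooleanNetwork, pert: Perturbation) -> BooleanNetwork:
    """Replace each pinned node's rule by the pinned constant."""
    pert.validate(net)
    rules = dict(net.rules)
    for name, v in pert.pins.items():
        rules[name] = sympy.true if v else sympy.false
    return BooleanNetwork(net.nodes, rules)


# ---------------------------------------------------------------------------
# multi-valued node encoding


def booleanize_multivalued(
    boolean_rules: Mapping[str, str],
    multilevel: Mapping[str, list[str]],
    weights: Mapping[str, float] | None = None,
) -> tuple[BooleanNetwork, dict[str, float]]:
    """Encode multi-level nodes as nested threshold indicators.

    A node ``X`` with ``L`` level conditions (for levels 1..L) becomes
    indicator nodes ``X_geq_1 .. X_geq_L`` whose rules are the level
    conditions.  Conditions must be nested (level l implies level l-1);
    non-nested logic is rejected.  A phenotype weight on ``X`` is split
    uniformly over its indicators, so the summed preference of the
    indicators equals the weight times the normalized level ``level/L``.

    Returns the encoded network and the distributed marker weights.
    """
    rules: dict[str, str] = dict(boolean_rules)
    out_weights: dict[str, float] = {}
    weights = dict(weights or {})
    for name, w in weights.items():
        if name in boolean_rules:
            out_weights[name] = w
    for name, conds in multilevel.items():
        if len(conds) < 2:
            raise ModelError(f"multi-level node {name!r} must declare max level >= 2")
        exprs = [parse_expression(c) for c in conds]
        # nestedness check: cond_l must imply cond_{l-1} over all assignments
        symbols = sorted({s.name for e in exprs for s in e.free_symbols})
        for lvl in range(1, len(exprs)):
            hi, lo = exprs[lvl], exprs[lvl - 1]
            for mask in range(1 << len(symbols)):
                sub = {Symbol(s): bool((mask >> j) & 1) for j, s in enumerate(symbols)}
                if bool(hi.subs(sub)) and not bool(lo.subs(sub)):
                    raise ModelError(
                        f"multi-level node {name!r}: level {lvl + 1} condition does not imply "
                        f"level {lvl} condition (non-thresholded logic); levels must be nested"
                    )
        for lvl, cond in enumerate(conds, start=1):
            rules[f"{name}_geq_{lvl}"] = cond
        if name in weights:
            for lvl in range(1, len(conds) + 1):
                out_weights[f"{name}_geq_{lvl}"] = weights[name] / len(conds)
    text = "\n".join(f"{k}, {v}" for k, v in rules.items())
    return parse_bnet(text), out_weights


def decode_level(indicator_values: Mapping[str, int], name: str) -> int:
    """Decoded level = highest l such that all indicators 1..l are active."""
    lvl = 0
    while indicator_values.get(f"{name}_geq_{lvl + 1}", 0) == 1:
        lvl += 1
    return lvl
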