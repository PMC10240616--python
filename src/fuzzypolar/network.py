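"""Boolean regulatory networks: parsing, validation, serialization.

A network is a set of named nodes, each either *extracellular* (an input that
is only ever set exogenously, e.g. a cytokine concentration) or a
*transcription factor* (an internal node governed by a Boolean update rule
over the other nodes). Rules are expression trees over ``AND``/``OR``/``NOT``
with the literal constants ``0``/``1`` permitted. The signed interaction list
is derived from the rules, never stored: ``(s, t)`` is an edge iff ``s``
appears in ``t``'s rule, with sign ``+`` when every occurrence of ``s`` sits
under an even number of negations, ``-`` when odd, and ``+-`` when mixed.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "NodeClass",
    "Node",
    "Expr",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "BooleanRule",
    "RegulatoryNetwork",
    "MarkerTable",
    "RuleSyntaxError",
    "NetworkValidationError",
    "parse_rule",
    "parse_expression",
    "boolean_evaluate",
    "load_network",
    "loads_network",
    "serialize_network",
    "load_boolnet",
    "load_markers",
    "macrophage_network",
    "macrophage_markers",
    "DEFAULT_ALIASES",
    "TAG_ORDER",
]


class NodeClass(str, Enum):
    extracellular = "extracellular"
    transcription_factor = "transcription_factor"


@dataclass(frozen=True)
class Node:
    name: str
    klass: NodeClass


# ---------------------------------------------------------------------------
# Expression trees


class Expr:
    """Base class for Boolean expression tree nodes."""

    __slots__ = ()

    def names(self) -> set[str]:
        """All node names referenced in the expression."""
        out: set[str] = set()
        _collect_names(self, out)
        return out


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Const(Expr):
    value: int  # 0 or 1

    def __str__(self) -> str:
        return str(self.value)


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr

    def __str__(self) -> str:
        if isinstance(self.operand, (Var, Const, Not)):
            return f"NOT {self.operand}"
        return f"NOT ({self.operand})"


def _binary_str(expr: "And | Or", op: str) -> str:
    parts = []
    for side in (expr.left, expr.right):
        if isinstance(side, (And, Or)) and type(side) is not type(expr):
            parts.append(f"({side})")
        else:
            parts.append(str(side))
    return f"{parts[0]} {op} {parts[1]}"


@dataclass(frozen=True)
class And(Expr):
    left: Expr
    right: Expr

    def __str__(self) -> str:
        return _binary_str(self, "AND")


@dataclass(frozen=True)
class Or(Expr):
    left: Expr
    right: Expr

    def __str__(self) -> str:
        return _binary_str(self, "OR")


def _collect_names(expr: Expr, out: set[str]) -> None:
    if isinstance(expr, Var):
        out.add(expr.name)
    elif isinstance(expr, Not):
        _collect_names(expr.operand, out)
    elif isinstance(expr, (And, Or)):
        _collect_names(expr.left, out)
        _collect_names(expr.right, out)


@dataclass(frozen=True)
class BooleanRule:
    """Update rule for one target node."""

    target: str
    expression: Expr

    def __str__(self) -> str:
        return f"{self.target} = {self.expression}"


# ---------------------------------------------------------------------------
# Rule parser (recursive descent)
#
# Grammar:  expr    := and_expr (OR and_expr)*
#           and_expr:= unary (AND unary)*
#           unary   := NOT unary | atom
#           atom    := NAME | 0 | 1 | '(' expr ')'
#
# AND/OR are left-associative; NOT binds tightest.


class RuleSyntaxError(ValueError):
    """Malformed rule text; carries the offending token index."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at token {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z_][A-Za-z0-9_\-]*|[01])")
_KEYWORDS = {"AND", "OR", "NOT"}


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            rest = text[pos:].strip()
            if not rest:
                break
            raise RuleSyntaxError(f"unexpected character {rest[0]!r}", len(tokens) + 1)
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of expression", self.i + 1)
        self.i += 1
        return tok

    def parse(self) -> Expr:
        if not self.tokens:
            raise RuleSyntaxError("empty expression", 1)
        expr = self.expr()
        if self.peek() is not None:
            raise RuleSyntaxError(f"unexpected token {self.peek()!r}", self.i + 1)
        return expr

    def expr(self) -> Expr:
        left = self.and_expr()
        while (tok := self.peek()) is not None and tok.upper() == "OR":
            self.take()
            left = Or(left, self.and_expr())
        return left

    def and_expr(self) -> Expr:
        left = self.unary()
        while (tok := self.peek()) is not None and tok.upper() == "AND":
            self.take()
            left = And(left, self.unary())
        return left

    def unary(self) -> Expr:
        tok = self.peek()
        if tok is not None and tok.upper() == "NOT":
            self.take()
            return Not(self.unary())
        return self.atom()

    def atom(self) -> Expr:
        tok = self.take()
        if tok == "(":
            inner = self.expr()
            closing = self.take()
            if closing != ")":
                raise RuleSyntaxError(f"expected ')', got {closing!r}", self.i)
            return inner
        if tok in ("0", "1"):
            return Const(int(tok))
        if tok == ")":
            raise RuleSyntaxError("unexpected ')'", self.i)
        if tok.upper() in _KEYWORDS:
            raise RuleSyntaxError(f"operator {tok!r} in operand position", self.i)
        return Var(tok)


def parse_expression(text: str) -> Expr:
    """Parse an infix AND/OR/NOT expression into a tree."""
    return _Parser(_tokenize(text)).parse()


def parse_rule(text: str, target: str = "") -> BooleanRule:
    """Parse a rule string like ``"STAT1 AND NOT SOCS1"`` into a BooleanRule.

    Raises :class:`RuleSyntaxError` with the offending token index on
    malformed input.
    """
    return BooleanRule(target=target, expression=parse_expression(text))


# ---------------------------------------------------------------------------
# Boolean evaluation


def boolean_evaluate(rule: Union[BooleanRule, Expr], state: Mapping[str, int]) -> int:
    """Classical truth value (0/1) of a rule under a complete 0/1 assignment.

    Raises ``KeyError`` if a referenced node has no value in ``state``.
    """
    expr = rule.expression if isinstance(rule, BooleanRule) else rule
    return _beval(expr, state)


def _beval(expr: Expr, state: Mapping[str, int]) -> int:
    if isinstance(expr, Var):
        return 1 if state[expr.name] else 0
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Not):
        return 1 - _beval(expr.operand, state)
    if isinstance(expr, And):
        return _beval(expr.left, state) & _beval(expr.right, state)
    if isinstance(expr, Or):
        return _beval(expr.left, state) | _beval(expr.right, state)
    raise TypeError(f"unknown expression node {expr!r}")


# ---------------------------------------------------------------------------
# Networks


class NetworkValidationError(ValueError):
    pass


@dataclass
class RegulatoryNetwork:
    """Nodes plus one Boolean rule per transcription-factor node.

    The node order given at construction defines the state-vector layout used
    by every downstream module.
    """

    nodes: list[Node]
    rules: dict[str, BooleanRule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -----------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def index(self) -> dict[str, int]:
        return {n.name: i for i, n in enumerate(self.nodes)}

    @property
    def tf_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.klass is NodeClass.transcription_factor]

    @property
    def input_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.klass is NodeClass.extracellular]

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def __len__(self) -> int:
        return len(self.nodes)

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        names = self.names
        seen: set[str] = set()
        for name in names:
            if name in seen:
                raise NetworkValidationError(f"duplicate node {name!r}")
            seen.add(name)
        for node in self.nodes:
            has_rule = node.name in self.rules
            if node.klass is NodeClass.extracellular and has_rule:
                raise NetworkValidationError(
                    f"extracellular node {node.name!r} must not have a rule"
                )
            if node.klass is NodeClass.transcription_factor and not has_rule:
                raise NetworkValidationError(
                    f"transcription-factor node {node.name!r} has no rule"
                )
        for target, rule in self.rules.items():
            if target not in seen:
                raise NetworkValidationError(f"rule for undeclared node {target!r}")
            for ref in rule.expression.names():
                if ref not in seen:
                    raise NetworkValidationError(
                        f"rule for {target!r} references undeclared node {ref!r}"
                    )

    # -- derived structure ---------------------------------------------------

    def edges(self) -> list[tuple[str, str, str]]:
        """Signed interaction list derived from the rules.

        Sign is ``'+'`` if every occurrence of the source in the target's rule
        is under an even number of NOTs, ``'-'`` if odd, ``'+-'`` if mixed.
        Order follows node order of targets, then first occurrence of sources.
        """
        out: list[tuple[str, str, str]] = []
        for node in self.nodes:
            rule = self.rules.get(node.name)
            if rule is None:
                continue
            parities: dict[str, set[int]] = {}
            order: list[str] = []
            _collect_parities(rule.expression, 0, parities, order)
            for src in order:
                p = parities[src]
                sign = "+-" if len(p) == 2 else ("+" if 0 in p else "-")
                out.append((src, node.name, sign))
        return out

    def to_networkx(self):
        """Signed digraph of the derived interactions (networkx.DiGraph)."""
        import networkx as nx

        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node.name, klass=node.klass.value)
        for s, t, sign in self.edges():
            g.add_edge(s, t, sign=sign)
        return g


def _collect_parities(
    expr: Expr, depth: int, parities: dict[str, set[int]], order: list[str]
) -> None:
    if isinstance(expr, Var):
        if expr.name not in parities:
            parities[expr.name] = set()
            order.append(expr.name)
        parities[expr.name].add(depth % 2)
    elif isinstance(expr, Not):
        _collect_parities(expr.operand, depth + 1, parities, order)
    elif isinstance(expr, (And, Or)):
        _collect_parities(expr.left, depth, parities, order)
        _collect_parities(expr.right, depth, parities, order)


# ---------------------------------------------------------------------------
# Name normalization

# Variant spellings seen in the literature for the macrophage fixture nodes.
DEFAULT_ALIASES: dict[str, str] = {
    "NFKB": "NFkB",
    "NF-KB": "NFkB",
    "NFKAPPAB": "NFkB",
    "HIF1A": "HIF1a",
    "HIF1-A": "HIF1a",
    "HIF1-ALPHA": "HIF1a",
    "HIF1ALPHA": "HIF1a",
    "TNFA-E": "TNFAe",
    "TNFAE": "TNFAe",
    "IL10E": "IL10e",
    "IL4E": "IL4e",
    "IL6E": "IL6e",
    "IL1-B": "IL1B",
    "IL1BETA": "IL1B",
    "IFN-G": "IFNG",
    "IFN-B": "IFNB",
    "AP-1": "AP1",
    "GC": "GCGCR",
    "ADENOSINE": "A2a",
    "A2A": "A2a",
}


def normalize_name(name: str, aliases: Mapping[str, str] | None = None) -> str:
    aliases = DEFAULT_ALIASES if aliases is None else aliases
    return aliases.get(name.upper(), aliases.get(name, name))


# ---------------------------------------------------------------------------
# Network file I/O
#
# Plain-text format, one line per node:
#     <name>, <klass>, <rule-or-dash>
# klass in {extracellular, input} or {transcription_factor, tf};
# '#' starts a comment.


_KLASS_TOKENS = {
    "extracellular": NodeClass.extracellular,
    "input": NodeClass.extracellular,
    "transcription_factor": NodeClass.transcription_factor,
    "tf": NodeClass.transcription_factor,
}


def loads_network(text: str) -> RegulatoryNetwork:
    nodes: list[Node] = []
    rules: dict[str, BooleanRule] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",", 2)]
        if len(parts) != 3:
            raise NetworkValidationError(
                f"line {lineno}: expected '<name>, <klass>, <rule-or-dash>'"
            )
        name, klass_tok, rule_text = parts
        klass = _KLASS_TOKENS.get(klass_tok.lower())
        if klass is None:
            raise NetworkValidationError(
                f"line {lineno}: unknown node class {klass_tok!r}"
            )
        nodes.append(Node(name, klass))
        if rule_text != "-":
            if klass is NodeClass.extracellular:
                raise NetworkValidationError(
                    f"line {lineno}: extracellular node {name!r} must not have a rule"
                )
            try:
                rules[name] = parse_rule(rule_text, target=name)
            except RuleSyntaxError as exc:
                raise NetworkValidationError(
                    f"line {lineno}: bad rule for {name!r}: {exc}"
                ) from exc
    return RegulatoryNetwork(nodes=nodes, rules=rules)


def load_network(path: str | Path) -> RegulatoryNetwork:
    """Read a network-definition file (see module docstring for the format)."""
    return loads_network(Path(path).read_text())


def serialize_network(network: RegulatoryNetwork) -> str:
    lines = []
    for node in network.nodes:
        rule = network.rules.get(node.name)
        rule_text = str(rule.expression) if rule is not None else "-"
        klass = "extracellular" if node.klass is NodeClass.extracellular else "tf"
        lines.append(f"{node.name}, {klass}, {rule_text}")
    return "\n".join(lines) + "\n"


def load_boolnet(path: str | Path) -> RegulatoryNetwork:
    """Read a BoolNet-style ``targets, factors`` file.

    Operators ``!``, ``&``, ``|`` are accepted alongside NOT/AND/OR. A node
    whose factor is exactly itself (``A, A``) or that never appears as a
    target is treated as extracellular.
    """
    entries: list[tuple[str, str]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().replace(" ", "") == "targets,factors":
            continue
        target, _, factors = line.partition(",")
        entries.append((target.strip(), factors.strip()))

    def translate(text: str) -> str:
        return text.replace("!", " NOT ").replace("&", " AND ").replace("|", " OR ")

    targets = {t for t, _ in entries}
    referenced: set[str] = set()
    parsed: dict[str, Expr] = {}
    for target, factors in entries:
        expr = parse_expression(translate(factors))
        parsed[target] = expr
        referenced |= expr.names()

    nodes: list[Node] = []
    rules: dict[str, BooleanRule] = {}
    for target, _ in entries:
        expr = parsed[target]
        if isinstance(expr, Var) and expr.name == target:
            nodes.append(Node(target, NodeClass.extracellular))
        else:
            nodes.append(Node(target, NodeClass.transcription_factor))
            rules[target] = BooleanRule(target, expr)
    for name in sorted(referenced - targets):
        nodes.append(Node(name, NodeClass.extracellular))
    return RegulatoryNetwork(nodes=nodes, rules=rules)


# ---------------------------------------------------------------------------
# Marker tables

TAG_ORDER: tuple[str, ...] = ("M1", "M1a", "M2a", "M2b", "M2c", "M2d")


@dataclass
class MarkerTable:
    """Ordered (marker node, phenotype tag) pairs with the canonical tag order.

    The default macrophage table maps NFkB to M1, STAT1 to M1a, STAT6 to M2a,
    ERK to M2b, STAT3 to M2c and HIF1a to M2d.
    """

    entries: list[tuple[str, str]]
    tag_order: tuple[str, ...] = TAG_ORDER

    def __post_init__(self) -> None:
        for marker, tag in self.entries:
            if tag not in self.tag_order:
                raise ValueError(f"marker {marker!r} has unknown tag {tag!r}")
        markers = [m for m, _ in self.entries]
        if len(set(markers)) != len(markers):
            raise ValueError("duplicate marker in table")

    @property
    def markers(self) -> list[str]:
        return [m for m, _ in self.entries]

    def tag_of(self, marker: str) -> str:
        for m, tag in self.entries:
            if m == marker:
                return tag
        raise KeyError(marker)

    def validate_against(self, network: RegulatoryNetwork) -> None:
        klass = {n.name: n.klass for n in network.nodes}
        for marker, _ in self.entries:
            if marker not in klass:
                raise NetworkValidationError(f"marker {marker!r} not in network")
            if klass[marker] is not NodeClass.transcription_factor:
                raise NetworkValidationError(
                    f"marker {marker!r} is not a transcription-factor node"
                )


def load_markers(path: str | Path) -> MarkerTable:
    """Read a marker-signature file (CSV with marker,tag columns, or JSON)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        entries = [(str(m), str(t)) for m, t in payload["entries"]]
        tag_order = tuple(payload.get("tag_order", TAG_ORDER))
        return MarkerTable(entries=entries, tag_order=tag_order)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if r and not r[0].lstrip().startswith("#")]
    if rows and rows[0][0].strip().lower() == "marker":
        rows = rows[1:]
    entries = [(r[0].strip(), r[1].strip()) for r in rows]
    return MarkerTable(entries=entries)


# ---------------------------------------------------------------------------
# Vendored macrophage fixture

_DATA_DIR = Path(__file__).parent / "data"


def macrophage_network() -> RegulatoryNetwork:
    """The vendored 29-node macrophage polarization network.

    15 extracellular nodes (cytokines, immune complexes, metabolic signals)
    and 14 transcription-factor/secretion nodes with 60 signed interactions.
    The rule set is a reconstruction from published mechanism descriptions;
    see the header of ``data/macrophage.net`` and ``docs/methods.md``.
    """
    return load_network(_DATA_DIR / "macrophage.net")


def macrophage_markers() -> MarkerTable:
    """Default marker table for the macrophage fixture."""
    return load_markers(_DATA_DIR / "macrophage_markers.csv")
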