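"""Karva-notation chromosomes and expression trees.

A chromosome is a fixed-length linear string over function and terminal
symbols, split into a *head* (length h, functions or terminals) and a
*tail* (length t = h*(a_max - 1) + 1, terminals only, a_max the maximum
function arity). With a_max = 2 the tail has h + 1 symbols, so a head of
20 gives a gene of 41 symbols. This head/tail structure guarantees that
level-order (breadth-first) decoding always yields a syntactically valid
expression tree, whatever the symbols are — the closure property that
makes blind genetic operators safe.

Function symbols and their protected evaluation semantics:

====== ===== =========================================================
symbol arity semantics
====== ===== =========================================================
add    2     a + b
sub    2     a - b
mul    2     a * b
div    2     a / b if \\|b\\| > 1e-12 else 1.0   (protected division)
eq     2     1 if \\|a - b\\| <= 1e-9 else 0
max    2     max(a, b)
min    2     min(a, b)
sqrt   1     sqrt(\\|x\\|)
log    1     ln(\\|x\\| + 1e-12)
exp    1     exp(min(x, 30))
abs    1     \\|x\\|
====== ===== =========================================================

Every evaluation result is finite: non-finite intermediates are clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

#: function symbol -> arity
FUNCTIONS: dict[str, int] = {
    "add": 2, "sub": 2, "mul": 2, "div": 2, "eq": 2, "max": 2, "min": 2,
    "sqrt": 1, "log": 1, "exp": 1, "abs": 1,
}
MAX_ARITY = 2

#: the four coefficient terminals available to evolution
CONSTANT_TERMINALS: tuple[str, ...] = ("0.1", "0.2", "0.5", "1.0")

_DIV_EPS = 1e-12
_LOG_EPS = 1e-12
_EQ_TOL = 1e-9
_EXP_CAP = 30.0
_CLAMP = 1e150


def is_function(symbol: str) -> bool:
    return symbol in FUNCTIONS


def is_constant(symbol: str) -> bool:
    try:
        float(symbol)
        return True
    except ValueError:
        return False


def tail_length(head_length: int, max_arity: int = MAX_ARITY) -> int:
    """t = h*(a_max - 1) + 1, the tail size that guarantees closure."""
    return head_length * (max_arity - 1) + 1


def gene_length(head_length: int, max_arity: int = MAX_ARITY) -> int:
    return head_length + tail_length(head_length, max_arity)


@dataclass(frozen=True)
class Chromosome:
    """Fixed-length Karva string: one or more genes, each head + tail."""

    symbols: tuple[str, ...]
    head_length: int
    gene_count: int = 1

    def __post_init__(self):
        if self.head_length < 1:
            raise ValueError("head_length must be >= 1")
        if len(self.symbols) != self.gene_count * gene_length(self.head_length):
            raise ValueError(
                f"chromosome length {len(self.symbols)} does not match "
                f"{self.gene_count} gene(s) with head {self.head_length}"
            )

    @property
    def gene_size(self) -> int:
        return gene_length(self.head_length)

    def genes(self) -> list[tuple[str, ...]]:
        g = self.gene_size
        return [self.symbols[i * g:(i + 1) * g] for i in range(self.gene_count)]

    def validate_domains(self) -> bool:
        """Head positions hold functions or terminals; tail positions hold
        terminals only."""
        for gene in self.genes():
            for pos, sym in enumerate(gene):
                if pos >= self.head_length and is_function(sym):
                    return False
        return True


@dataclass(frozen=True)
class Node:
    """Expression-tree node: a function with children, or a leaf."""

    symbol: str
    children: tuple["Node", ...] = ()

    def __post_init__(self):
        arity = FUNCTIONS.get(self.symbol, 0)
        if len(self.children) != arity:
            raise ValueError(
                f"symbol {self.symbol!r} has arity {arity}, got {len(self.children)} children"
            )

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterable[str]:
        if self.is_leaf:
            yield self.symbol
        else:
            for c in self.children:
                yield from c.leaves()

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)


def random_chromosome(head_length: int, terminals: tuple[str, ...],
                      rng: np.random.Generator,
                      functions: tuple[str, ...] = tuple(FUNCTIONS),
                      gene_count: int = 1) -> Chromosome:
    """Uniform random chromosome: head from functions + terminals, tail
    from terminals only."""
    if not terminals:
        raise ValueError("terminal set must not be empty")
    head_pool = tuple(functions) + tuple(terminals)
    syms: list[str] = []
    t = tail_length(head_length)
    for _ in range(gene_count):
        syms.extend(head_pool[i] for i in rng.integers(0, len(head_pool), head_length))
        syms.extend(terminals[i] for i in rng.integers(0, len(terminals), t))
    return Chromosome(tuple(syms), head_length, gene_count)


def _decode_gene(gene: tuple[str, ...]) -> Node:
    # Level-order expansion: the open reading frame of a K-expression.
    levels = [[gene[0]]]
    pos = 1
    while True:
        need = sum(FUNCTIONS.get(s, 0) for s in levels[-1])
        if need == 0:
            break
        levels.append(list(gene[pos:pos + need]))
        pos += need
    return _decode_levels(levels)


def _decode_levels(levels: list[list[str]]) -> Node:
    # Bottom level is all leaves; fold upwards attaching children in order.
    nodes: list[Node] = [Node(s) for s in levels[-1]]
    for level in reversed(levels[:-1]):
        parents: list[Node] = []
        cursor = 0
        for sym in level:
            arity = FUNCTIONS.get(sym, 0)
            parents.append(Node(sym, tuple(nodes[cursor:cursor + arity])))
            cursor += arity
        nodes = parents
    return nodes[0]


def decode(chromosome: Chromosome) -> Node:
    """Decode a chromosome to its expression tree (level-order Karva
    expansion). Symbols beyond the tree's closure are non-coding. Genes of
    a multigenic chromosome are linked by addition."""
    trees = [_decode_gene(g) for g in chromosome.genes()]
    root = trees[0]
    for t in trees[1:]:
        root = Node("add", (root, t))
    return root


# ---------------------------------------------------------------------------
# evaluation


def _finite(x: np.ndarray | float):
    return np.clip(np.nan_to_num(x, nan=0.0, posinf=_CLAMP, neginf=-_CLAMP),
                   -_CLAMP, _CLAMP)


def evaluate(tree: Node, frame: Mapping[str, np.ndarray | float]):
    """Evaluate a tree over a frame of feature arrays (or scalars).

    ``frame`` maps feature names to equally-shaped numpy arrays; constants
    in the tree are broadcast. Unknown leaf names raise ``KeyError``.
    Protected semantics keep every result finite.
    """
    sym = tree.symbol
    if tree.is_leaf:
        if is_constant(sym):
            return float(sym)
        if sym not in frame:
            raise KeyError(f"unknown feature {sym!r}")
        return frame[sym]
    args = [evaluate(c, frame) for c in tree.children]
    with np.errstate(all="ignore"):
        if sym == "add":
            out = args[0] + args[1]
        elif sym == "sub":
            out = args[0] - args[1]
        elif sym == "mul":
            out = args[0] * args[1]
        elif sym == "div":
            a, b = np.asarray(args[0], dtype=float), np.asarray(args[1], dtype=float)
            out = np.where(np.abs(b) > _DIV_EPS, a / np.where(np.abs(b) > _DIV_EPS, b, 1.0), 1.0)
        elif sym == "eq":
            out = (np.abs(np.asarray(args[0], dtype=float) - args[1]) <= _EQ_TOL).astype(float)
        elif sym == "max":
            out = np.maximum(args[0], args[1])
        elif sym == "min":
            out = np.minimum(args[0], args[1])
        elif sym == "sqrt":
            out = np.sqrt(np.abs(args[0]))
        elif sym == "log":
            out = np.log(np.abs(args[0]) + _LOG_EPS)
        elif sym == "exp":
            out = np.exp(np.minimum(args[0], _EXP_CAP))
        elif sym == "abs":
            out = np.abs(args[0])
        else:  # unreachable given Node validation
            raise ValueError(f"unknown function {sym!r}")
    return _finite(out)


def evaluate_tree(tree: Node, features: Mapping[str, float]) -> float:
    """Evaluate a tree on a single protein's feature vector."""
    return float(np.asarray(evaluate(tree, {k: float(v) for k, v in features.items()})))


# ---------------------------------------------------------------------------
# rendering and parsing

_INFIX = {"add": "+", "sub": "-", "mul": "*", "div": "/"}
_CALLS = {"min": "Min", "max": "Max", "abs": "Abs", "sqrt": "Sqrt",
          "log": "Log", "exp": "Exp", "eq": "Eq"}
_CALL_NAMES = {v.lower(): k for k, v in _CALLS.items()}


def _format_constant(symbol: str) -> str:
    return repr(float(symbol))


def render_expression(tree: Node) -> str:
    """Infix text form: binary + - * / fully parenthesized, the rest as
    named calls (Min, Max, Abs, Sqrt, Log, Exp, Eq). Constants are printed
    with minimal decimals. Round-trips through :func:`parse_expression`."""
    sym = tree.symbol
    if tree.is_leaf:
        return _format_constant(sym) if is_constant(sym) else sym
    if sym in _INFIX:
        a, b = (render_expression(c) for c in tree.children)
        return f"({a}{_INFIX[sym]}{b})"
    name = _CALLS[sym]
    return f"{name}({','.join(render_expression(c) for c in tree.children)})"


class ExpressionParseError(ValueError):
    """Syntax or naming error in an expression string; carries position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


_TOKEN_CHARS = set("+-*/(),")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in _TOKEN_CHARS:
            tokens.append(("op", ch, i))
            i += 1
        elif ch.isdigit() or (ch == "." and i + 1 < n and text[i + 1].isdigit()):
            j = i
            while j < n and (text[j].isdigit() or text[j] == "."):
                j += 1
            tokens.append(("num", text[i:j], i))
            i = j
        elif ch.isalpha() or ch == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(("ident", text[i:j], i))
            i = j
        else:
            raise ExpressionParseError(f"unexpected character {ch!r}", i)
    tokens.append(("end", "", n))
    return tokens


def parse_expression(text: str, feature_names: Iterable[str]) -> Node:
    """Parse infix expression text into an expression tree.

    Grammar: binary ``+ - * /`` with usual precedence, unary minus, named
    calls Min/Max/Abs/Sqrt/Log/Exp/Eq (case-insensitive), numeric
    literals, and identifiers drawn from ``feature_names``. Evaluation of
    the result follows the protected semantics of :func:`evaluate`.
    """
    names = set(feature_names)
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos]

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def expect(value: str):
        kind, val, at = peek()
        if val != value:
            raise ExpressionParseError(f"expected {value!r}, found {val or 'end of input'!r}", at)
        return advance()

    def parse_expr() -> Node:
        node = parse_term()
        while peek()[1] in ("+", "-"):
            op = advance()[1]
            rhs = parse_term()
            node = Node("add" if op == "+" else "sub", (node, rhs))
        return node

    def parse_term() -> Node:
        node = parse_unary()
        while peek()[1] in ("*", "/"):
            op = advance()[1]
            rhs = parse_unary()
            node = Node("mul" if op == "*" else "div", (node, rhs))
        return node

    def parse_unary() -> Node:
        if peek()[1] == "-":
            at = advance()[2]
            operand = parse_unary()
            if operand.is_leaf and is_constant(operand.symbol):
                return Node(repr(-float(operand.symbol)))
            return Node("sub", (Node("0.0"), operand))
        return parse_primary()

    def parse_primary() -> Node:
        kind, val, at = advance()
        if val == "(":
            node = parse_expr()
            expect(")")
            return node
        if kind == "num":
            try:
                return Node(repr(float(val)))
            except ValueError:
                raise ExpressionParseError(f"bad number {val!r}", at) from None
        if kind == "ident":
            if peek()[1] == "(":
                fname = _CALL_NAMES.get(val.lower())
                if fname is None:
                    raise ExpressionParseError(f"unknown function {val!r}", at)
                advance()  # (
                args = [parse_expr()]
                while peek()[1] == ",":
                    advance()
                    args.append(parse_expr())
                expect(")")
                arity = FUNCTIONS[fname]
                if len(args) != arity:
                    raise ExpressionParseError(
                        f"{_CALLS[fname]} takes {arity} argument(s), got {len(args)}", at)
                return Node(fname, tuple(args))
            if val not in names:
                raise ExpressionParseError(f"unknown identifier {val!r}", at)
            return Node(val)
        raise ExpressionParseError(f"unexpected token {val or 'end of input'!r}", at)

    tree = parse_expr()
    kind, val, at = peek()
    if kind != "end":
        raise ExpressionParseError(f"trailing input {val!r}", at)
    return tree


#: The final classifier expression reported for the yeast network, in
#: canonical form. The original printed string ends in a two-argument
#: ``Abs(.., 1))`` with unbalanced parentheses; we read it as the
#: absolute deviation from 1 — ``Abs(Min(cytoplasm - vacuole, 0.1) - 1)``
#: — which is an interpretation, flagged as such.
PUBLISHED_CLASSIFIER = (
    "Min(lysosome, WDC - 0.5) + (ION - 0.9)"
    " + Max(0.4, Max(endoplasmic_reticulum, nucleus) - Min(0.5, SC))"
    " - Abs(Min(cytoplasm - vacuole, 0.1) - 1.0)"
)
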