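"""Grammatical evolution core: BNF grammars, codon-to-rule mapping, expression trees.

Grammatical evolution (GE) maps a chromosome of integers ("codons") onto a
program by walking a leftmost derivation of a BNF grammar: at each nonterminal
the next codon ``V`` selects production rule ``V mod NR``, where ``NR`` is the
number of rules for that nonterminal.  The grammar used for feature
construction derives arithmetic expressions over the original feature vector
``x1 .. xd``: binary operators (+, -, *, /), unary functions (sin, cos, exp,
log), input variables, and optionally decimal constants.

Expressions are represented as small trees that evaluate vectorised over
pattern matrices, serialise to parenthesised infix, and parse back.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "BNFGrammar",
    "Chromosome",
    "ExpressionTree",
    "MappingResult",
    "default_feature_grammar",
    "map_chromosome",
    "evaluate_expression",
    "parse_expression",
]

# Guards used when evaluating expressions on real data: division by a
# near-zero denominator, logarithms of non-positive arguments and numeric
# blow-ups all mark the result as non-finite instead of raising.
_DIV_GUARD = 1e-100
_OVERFLOW_GUARD = 1e100

_BINARY_OPS = ("+", "-", "*", "/")
_UNARY_FUNCS = ("sin", "cos", "exp", "log")


# ---------------------------------------------------------------------------
# Expression trees


@dataclass(frozen=True)
class ExpressionTree:
    """A node of an arithmetic expression over variables ``x1 .. xd``.

    ``kind`` is one of ``"binary"``, ``"unary"``, ``"variable"``,
    ``"constant"``.  ``payload`` holds the operator symbol, function name,
    1-based variable index, or constant value respectively.
    """

    kind: str
    payload: object
    children: tuple["ExpressionTree", ...] = ()

    # -- constructors -------------------------------------------------------

    @staticmethod
    def binary(op: str, left: "ExpressionTree", right: "ExpressionTree") -> "ExpressionTree":
        if op not in _BINARY_OPS:
            raise ValueError(f"unknown binary operator {op!r}")
        return ExpressionTree("binary", op, (left, right))

    @staticmethod
    def unary(func: str, arg: "ExpressionTree") -> "ExpressionTree":
        if func not in _UNARY_FUNCS:
            raise ValueError(f"unknown function {func!r}")
        return ExpressionTree("unary", func, (arg,))

    @staticmethod
    def variable(index: int) -> "ExpressionTree":
        if index < 1:
            raise ValueError("variable indices are 1-based")
        return ExpressionTree("variable", int(index))

    @staticmethod
    def constant(value: float) -> "ExpressionTree":
        return ExpressionTree("constant", float(value))

    # -- views --------------------------------------------------------------

    def max_variable_index(self) -> int:
        if self.kind == "variable":
            return int(self.payload)  # type: ignore[arg-type]
        return max((c.max_variable_index() for c in self.children), default=0)

    def __str__(self) -> str:
        return serialize_expression(self)


def serialize_expression(expr: ExpressionTree) -> str:
    """Parenthesised infix form, e.g. ``(x2+cos(x3))``."""
    if expr.kind == "variable":
        return f"x{expr.payload}"
    if expr.kind == "constant":
        return repr(float(expr.payload))  # type: ignore[arg-type]
    if expr.kind == "unary":
        return f"{expr.payload}({serialize_expression(expr.children[0])})"
    left, right = expr.children
    return f"({serialize_expression(left)}{expr.payload}{serialize_expression(right)})"


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<func>sin|cos|exp|log)|(?P<var>x\d+)|"
    r"(?P<num>\d+(?:\.\d+)?)|(?P<punct>[()+\-*/]))"
)


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ValueError(f"cannot tokenise {text[pos:]!r}")
        tokens.append(next(g for g in m.groups() if g is not None))
        pos = m.end()
    return tokens


def parse_expression(text: str) -> ExpressionTree:
    """Parse the infix dialect emitted by :func:`serialize_expression`.

    The grammar only produces fully parenthesised binary operations, so no
    precedence handling is required.
    """
    tokens = _tokenize(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take(expected: str | None = None) -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError("unexpected end of expression")
        tok = tokens[pos]
        if expected is not None and tok != expected:
            raise ValueError(f"expected {expected!r}, found {tok!r}")
        pos += 1
        return tok

    def parse_node() -> ExpressionTree:
        tok = take()
        if tok == "(":
            left = parse_node()
            op = take()
            if op not in _BINARY_OPS:
                raise ValueError(f"expected operator, found {op!r}")
            right = parse_node()
            take(")")
            return ExpressionTree.binary(op, left, right)
        if tok in _UNARY_FUNCS:
            take("(")
            arg = parse_node()
            take(")")
            return ExpressionTree.unary(tok, arg)
        if tok.startswith("x") and tok[1:].isdigit():
            return ExpressionTree.variable(int(tok[1:]))
        return ExpressionTree.constant(float(tok))

    node = parse_node()
    if peek() is not None:
        raise ValueError(f"trailing tokens: {tokens[pos:]!r}")
    return node


def evaluate_expression(
    expr: ExpressionTree, x: Sequence[float] | np.ndarray
) -> tuple[float, bool]:
    """Evaluate ``expr`` at a single pattern ``x`` (1-based variable lookup).

    Returns ``(value, finite)``; ``finite`` is False when a guard fired
    (division by |b| < 1e-100, log of a non-positive argument, or magnitude
    above 1e100) anywhere in the tree.  Errors on variable indices beyond
    ``len(x)``.
    """
    x = np.asarray(x, dtype=float)
    if expr.max_variable_index() > x.shape[0]:
        raise ValueError(
            f"expression uses x{expr.max_variable_index()} but pattern has "
            f"dimension {x.shape[0]}"
        )
    value, finite = _eval_node(expr, x)
    return float(value), bool(finite)


def _eval_node(expr: ExpressionTree, x: np.ndarray) -> tuple[float, bool]:
    if expr.kind == "variable":
        return float(x[int(expr.payload) - 1]), True  # type: ignore[arg-type]
    if expr.kind == "constant":
        return float(expr.payload), True  # type: ignore[arg-type]
    if expr.kind == "unary":
        v, ok = _eval_node(expr.children[0], x)
        if not ok:
            return 0.0, False
        func = str(expr.payload)
        if func == "log":
            if v <= 0.0:
                return 0.0, False
            out = math.log(v)
        elif func == "exp":
            if v > 700.0:  # exp overflow guard before the generic one
                return 0.0, False
            out = math.exp(v)
        else:
            out = getattr(math, func)(v)
        return _clip_or_fail(out)
    a, ok_a = _eval_node(expr.children[0], x)
    b, ok_b = _eval_node(expr.children[1], x)
    if not (ok_a and ok_b):
        return 0.0, False
    op = str(expr.payload)
    if op == "+":
        out = a + b
    elif op == "-":
        out = a - b
    elif op == "*":
        out = a * b
    else:
        if abs(b) < _DIV_GUARD:
            return 0.0, False
        out = a / b
    return _clip_or_fail(out)


def _clip_or_fail(v: float) -> tuple[float, bool]:
    if not math.isfinite(v) or abs(v) > _OVERFLOW_GUARD:
        return 0.0, False
    return v, True


def evaluate_expression_batch(
    expr: ExpressionTree, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised evaluation over an ``(n, d)`` pattern matrix.

    Returns ``(values, finite_mask)``; positions where a guard fired hold 0
    and are flagged False.  Used on the hot path of the fitness function.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (patterns x features)")
    if expr.max_variable_index() > X.shape[1]:
        raise ValueError("expression dimension exceeds pattern dimension")
    with np.errstate(all="ignore"):
        values, finite = _eval_node_batch(expr, X)
    values = np.where(finite, values, 0.0)
    return values, finite


def _eval_node_batch(expr: ExpressionTree, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[0]
    if expr.kind == "variable":
        return X[:, int(expr.payload) - 1].copy(), np.ones(n, dtype=bool)  # type: ignore[arg-type]
    if expr.kind == "constant":
        return np.full(n, float(expr.payload)), np.ones(n, dtype=bool)  # type: ignore[arg-type]
    if expr.kind == "unary":
        v, ok = _eval_node_batch(expr.children[0], X)
        func = str(expr.payload)
        if func == "log":
            bad = v <= 0.0
            out = np.log(np.where(bad, 1.0, v))
            ok = ok & ~bad
        elif func == "exp":
            bad = v > 700.0
            out = np.exp(np.where(bad, 0.0, v))
            ok = ok & ~bad
        elif func == "sin":
            out = np.sin(v)
        else:
            out = np.cos(v)
        return _mask_overflow(out, ok)
    a, ok_a = _eval_node_batch(expr.children[0], X)
    b, ok_b = _eval_node_batch(expr.children[1], X)
    ok = ok_a & ok_b
    op = str(expr.payload)
    if op == "+":
        out = a + b
    elif op == "-":
        out = a - b
    elif op == "*":
        out = a * b
    else:
        bad = np.abs(b) < _DIV_GUARD
        out = a / np.where(bad, 1.0, b)
        ok = ok & ~bad
    return _mask_overflow(out, ok)


def _mask_overflow(out: np.ndarray, ok: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = ok & np.isfinite(out) & (np.abs(out) <= _OVERFLOW_GUARD)
    return np.where(ok, out, 0.0), ok


# ---------------------------------------------------------------------------
# BNF grammar


@dataclass(frozen=True)
class BNFGrammar:
    """An ordered BNF grammar G = (N, T, S, P).

    ``productions`` maps each nonterminal to its ordered rule list; each rule
    is a tuple of symbols, where symbols present in ``nonterminals`` are
    expanded and all others are terminals.
    """

    nonterminals: frozenset[str]
    terminals: frozenset[str]
    start: str
    productions: dict[str, tuple[tuple[str, ...], ...]]

    def __post_init__(self) -> None:
        if self.start not in self.nonterminals:
            raise ValueError("start symbol must be a nonterminal")
        for nt, rules in self.productions.items():
            if nt not in self.nonterminals:
                raise ValueError(f"production head {nt!r} not in N")
            if not rules:
                raise ValueError(f"nonterminal {nt!r} has no rules")
            for rule in rules:
                for sym in rule:
                    if sym not in self.nonterminals and sym not in self.terminals:
                        raise ValueError(f"unknown symbol {sym!r} in rule for {nt!r}")

    def n_rules(self, nonterminal: str) -> int:
        """NR(nt): the divisor of the ``V mod NR`` rule-selection step."""
        return len(self.productions[nonterminal])

    def to_bnf_text(self) -> str:
        lines = []
        for nt, rules in self.productions.items():
            alts = " | ".join(" ".join(rule) if rule else "<empty>" for rule in rules)
            lines.append(f"<{nt}> ::= {alts}")
        return "\n".join(lines)


def default_feature_grammar(d: int, include_constants: bool = True) -> BNFGrammar:
    """Grammar deriving arithmetic expressions over ``d`` input variables.

    Rule order (the order the ``mod`` indexing refers to):

    * ``expr``     -> ``(expr op expr)`` | ``func(expr)`` | ``terminal``
    * ``op``       -> ``+`` | ``-`` | ``*`` | ``/``
    * ``func``     -> ``sin`` | ``cos`` | ``exp`` | ``log``
    * ``terminal`` -> ``xlist`` | ``const``
    * ``xlist``    -> ``x1`` | ... | ``xd``
    * ``const``    -> ``digit . digit``  (a decimal literal from two digits)

    With ``include_constants=False`` the ``terminal`` nonterminal keeps both
    rules' positions collapsed to ``xlist`` only (NR(terminal)=1), which is
    occasionally useful for tracing derivations that never take the constant
    branch; the default keeps NR(terminal)=2.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    variables = tuple(f"x{i}" for i in range(1, d + 1))
    digits = tuple(str(i) for i in range(10))
    nonterminals = {"expr", "op", "func", "terminal", "xlist"}
    terminals = set(variables) | set(_BINARY_OPS) | set(_UNARY_FUNCS) | {"(", ")"}
    productions: dict[str, tuple[tuple[str, ...], ...]] = {
        "expr": (
            ("(", "expr", "op", "expr", ")"),
            ("func", "(", "expr", ")"),
            ("terminal",),
        ),
        "op": tuple((op,) for op in _BINARY_OPS),
        "func": tuple((f,) for f in _UNARY_FUNCS),
        "xlist": tuple((v,) for v in variables),
    }
    if include_constants:
        nonterminals |= {"const", "digit"}
        terminals |= set(digits) | {"."}
        productions["terminal"] = (("xlist",), ("const",))
        productions["const"] = (("digit", ".", "digit"),)
        productions["digit"] = tuple((dg,) for dg in digits)
    else:
        productions["terminal"] = (("xlist",),)
    return BNFGrammar(
        nonterminals=frozenset(nonterminals),
        terminals=frozenset(terminals),
        start="expr",
        productions=productions,
    )


# ---------------------------------------------------------------------------
# Chromosomes and mapping


@dataclass(frozen=True)
class Chromosome:
    """A fixed-length integer chromosome; each codon selects one rule."""

    codons: tuple[int, ...]
    bounds: int = 255

    def __post_init__(self) -> None:
        for c in self.codons:
            if not (0 <= c <= self.bounds):
                raise ValueError(f"codon {c} outside [0, {self.bounds}]")

    def __len__(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class MappingResult:
    """Outcome of mapping one chromosome through a grammar.

    ``derivation`` records, for every codon-consuming step in leftmost order,
    the triple ``(nonterminal, codon, rule_index)`` with
    ``rule_index = codon mod NR(nonterminal)``.
    """

    expression: ExpressionTree | None
    codons_consumed: int
    wraps_used: int
    valid: bool
    derivation: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    @property
    def rule_indices(self) -> tuple[int, ...]:
        return tuple(step[2] for step in self.derivation)


class _CodonStream:
    """Sequential codon supply with classic GE wrapping.

    ``offset`` lets several expressions be mapped from one chromosome, each
    resuming where the previous one stopped.  The wrap counter is per stream
    instance; exceeding ``max_wraps`` raises :class:`_WrapExhausted`.
    """

    def __init__(self, codons: Sequence[int], offset: int, max_wraps: int) -> None:
        self.codons = list(codons)
        self.cursor = offset % len(self.codons) if self.codons else 0
        self.max_wraps = max_wraps
        self.wraps = 0
        self.consumed = 0

    def next(self) -> int:
        if not self.codons:
            raise _WrapExhausted
        if self.cursor >= len(self.codons):
            # Wrap only when another codon is actually requested, so consuming
            # exactly the whole chromosome counts as zero wraps.
            self.cursor = 0
            self.wraps += 1
            if self.wraps > self.max_wraps:
                raise _WrapExhausted
        v = self.codons[self.cursor]
        self.cursor += 1
        self.consumed += 1
        return v


class _WrapExhausted(Exception):
    pass


# Hard cap on derivation length, guarding against pathological recursion when
# wrapping keeps feeding the expansive rule.
_MAX_STEPS = 100_000


def map_chromosome(
    chrom: Chromosome | Sequence[int],
    grammar: BNFGrammar,
    max_wraps: int = 2,
    _offset: int = 0,
) -> MappingResult:
    """Leftmost GE derivation: each nonterminal consumes one codon.

    Rule selection is ``codon mod NR(nonterminal)``.  When the codon stream is
    exhausted it wraps to the start, up to ``max_wraps`` times; a derivation
    still containing nonterminals after the wrap budget is marked invalid.
    """
    codons = chrom.codons if isinstance(chrom, Chromosome) else tuple(int(c) for c in chrom)
    if len(codons) == 0:
        return MappingResult(None, 0, 0, False)
    stream = _CodonStream(codons, _offset, max_wraps)
    derivation: list[tuple[str, int, int]] = []
    try:
        expr = _derive(grammar.start, grammar, stream, derivation, depth=0)
    except (_WrapExhausted, RecursionError):
        return MappingResult(None, stream.consumed, stream.wraps, False, tuple(derivation))
    return MappingResult(expr, stream.consumed, stream.wraps, True, tuple(derivation))


def _derive(
    symbol: str,
    grammar: BNFGrammar,
    stream: _CodonStream,
    derivation: list[tuple[str, int, int]],
    depth: int,
) -> ExpressionTree:
    if depth > 500 or len(derivation) > _MAX_STEPS:
        raise _WrapExhausted
    codon = stream.next()
    rules = grammar.productions[symbol]
    rule_index = codon % len(rules)
    derivation.append((symbol, codon, rule_index))
    rule = rules[rule_index]

    if symbol == "expr":
        if rule_index == 0:  # (expr op expr)
            left = _derive("expr", grammar, stream, derivation, depth + 1)
            op = _derive_leaf("op", grammar, stream, derivation)
            right = _derive("expr", grammar, stream, derivation, depth + 1)
            return ExpressionTree.binary(op, left, right)
        if rule[0] == "func":  # func(expr)
            func = _derive_leaf("func", grammar, stream, derivation)
            arg = _derive("expr", grammar, stream, derivation, depth + 1)
            return ExpressionTree.unary(func, arg)
        return _derive("terminal", grammar, stream, derivation, depth + 1)
    if symbol == "terminal":
        if rule[0] == "xlist":
            var = _derive_leaf("xlist", grammar, stream, derivation)
            return ExpressionTree.variable(int(var[1:]))
        return _derive_const(grammar, stream, derivation)
    raise AssertionError(f"unexpected recursive symbol {symbol!r}")  # pragma: no cover


def _derive_leaf(
    symbol: str,
    grammar: BNFGrammar,
    stream: _CodonStream,
    derivation: list[tuple[str, int, int]],
) -> str:
    codon = stream.next()
    rules = grammar.productions[symbol]
    rule_index = codon % len(rules)
    derivation.append((symbol, codon, rule_index))
    return rules[rule_index][0]


def _derive_const(
    grammar: BNFGrammar,
    stream: _CodonStream,
    derivation: list[tuple[str, int, int]],
) -> ExpressionTree:
    # const -> digit . digit; the const nonterminal itself has one rule and
    # therefore still consumes a codon (every nonterminal expansion does).
    int_digit = _derive_leaf("digit", grammar, stream, derivation)
    frac_digit = _derive_leaf("digit", grammar, stream, derivation)
    return ExpressionTree.constant(float(f"{int_digit}.{frac_digit}"))


def map_expressions(
    chrom: Chromosome | Sequence[int],
    grammar: BNFGrammar,
    n_expressions: int,
    max_wraps: int = 2,
) -> list[MappingResult]:
    """Map ``n_expressions`` from one chromosome by sequential consumption.

    Expression ``i+1`` resumes at the codon after the one expression ``i``
    stopped on (modulo chromosome length).  Any individual failure leaves the
    remaining slots unmapped; callers treat the whole set as invalid.
    """
    codons = chrom.codons if isinstance(chrom, Chromosome) else tuple(int(c) for c in chrom)
    results: list[MappingResult] = []
    offset = 0
    for _ in range(n_expressions):
        res = map_chromosome(codons, grammar, max_wraps=max_wraps, _offset=offset)
        results.append(res)
        if not res.valid:
            break
        offset = (offset + res.codons_consumed) % max(len(codons), 1)
    return results


def random_chromosome(
    rng: np.random.Generator, length: int = 100, bounds: int = 255
) -> Chromosome:
    """Uniform random chromosome, the GE population initialiser's unit."""
    return Chromosome(tuple(int(v) for v in rng.integers(0, bounds + 1, size=length)), bounds)


def iter_valid_chromosomes(
    rng: np.random.Generator,
    grammar: BNFGrammar,
    length: int = 100,
    bounds: int = 255,
) -> Iterator[tuple[Chromosome, MappingResult]]:
    """Yield random chromosomes whose mapping succeeds (testing helper)."""
    while True:
        chrom = random_chromosome(rng, length, bounds)
        res = map_chromosome(chrom, grammar)
        if res.valid:
            yield chrom, res
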