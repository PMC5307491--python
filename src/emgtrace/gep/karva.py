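"""Karva-encoded genes: representation, decoding and protected evaluation.

A gene is a fixed-length linear string: a *head* of length h that may hold
functions or terminals, and a *tail* of length t = h(n_max - 1) + 1 holding
terminals only, where n_max is the maximum function arity.  The tail-length
relation guarantees that every gene decodes to a syntactically valid
expression tree regardless of head content.  Decoding is breadth-first
(karva notation): symbols are read left to right and fill the tree level by
level; the prefix actually consumed is the open reading frame (ORF) and
symbols beyond it are silent.

All arithmetic is *protected* so that any chromosome evaluates to a finite
number on finite inputs: x/0 -> 1, Inv(0) -> 1, Sqrt acts on |x|, Exp's
argument is capped at +-700, and every intermediate is clamped to
+-1e300 with NaN (from indeterminate forms such as 0 * inf) mapped to 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "FunctionSet",
    "DEFAULT_FUNCTIONS",
    "Gene",
    "Chromosome",
    "orf_length",
    "decode",
    "evaluate_gene",
    "evaluate_chromosome",
    "to_infix",
    "RNC_SYMBOL",
]

_MAX = 1e300
RNC_SYMBOL = "?"


def _san(x: np.ndarray) -> np.ndarray:
    x = np.nan_to_num(x, nan=0.0, posinf=_MAX, neginf=-_MAX)
    return np.clip(x, -_MAX, _MAX)


def _p_add(a, b):
    return _san(a + b)


def _p_sub(a, b):
    return _san(a - b)


def _p_mul(a, b):
    with np.errstate(all="ignore"):
        return _san(a * b)


def _p_div(a, b):
    with np.errstate(all="ignore"):
        safe = np.where(b == 0, 1.0, b)
        return _san(np.where(b == 0, 1.0, a / safe))


def _p_sqrt(a):
    return _san(np.sqrt(np.abs(a)))


def _p_exp(a):
    with np.errstate(all="ignore"):
        return _san(np.exp(np.clip(a, -700.0, 700.0)))


def _p_inv(a):
    with np.errstate(all="ignore"):
        safe = np.where(a == 0, 1.0, a)
        return _san(np.where(a == 0, 1.0, 1.0 / safe))


def _p_sqr(a):
    with np.errstate(all="ignore"):
        return _san(a * a)


def _p_sin(a):
    return _san(np.sin(np.clip(a, -1e15, 1e15)))


def _p_cos(a):
    return _san(np.cos(np.clip(a, -1e15, 1e15)))


# symbol -> (arity, vectorized protected implementation, infix template)
_FUNCS = {
    "+": (2, _p_add, "({0} + {1})"),
    "-": (2, _p_sub, "({0} - {1})"),
    "*": (2, _p_mul, "({0} * {1})"),
    "/": (2, _p_div, "({0} / {1})"),
    "sqrt": (1, _p_sqrt, "sqrt({0})"),
    "exp": (1, _p_exp, "exp({0})"),
    "inv": (1, _p_inv, "(1 / {0})"),
    "sqr": (1, _p_sqr, "({0})^2"),
    "sin": (1, _p_sin, "sin({0})"),
    "cos": (1, _p_cos, "cos({0})"),
}


@dataclass(frozen=True)
class FunctionSet:
    """The function alphabet F = {+, -, *, /, Sqrt, Exp, Inv, x^2, Sin, Cos}."""

    symbols: tuple = tuple(_FUNCS)

    def __post_init__(self) -> None:
        unknown = [s for s in self.symbols if s not in _FUNCS]
        if unknown:
            raise ValueError(f"functions without a protected rule: {unknown}")

    def arity(self, symbol: str) -> int:
        return _FUNCS[symbol][0]

    @property
    def max_arity(self) -> int:
        return max(_FUNCS[s][0] for s in self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __iter__(self):
        return iter(self.symbols)


DEFAULT_FUNCTIONS = FunctionSet()


@dataclass(frozen=True)
class Gene:
    """One karva gene: head + tail symbols, optionally an RNC domain.

    ``symbols`` has length head + tail; with random numerical constants
    (RNC) enabled, the terminal ``?`` may appear and is resolved through
    ``dc`` (indices, length = tail) into ``constants``.
    """

    symbols: tuple
    head: int
    dc: Optional[tuple] = None
    constants: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not 0 < self.head < len(self.symbols):
            raise ValueError("head length must be in (0, gene size)")

    @property
    def tail(self) -> int:
        return len(self.symbols) - self.head


def validate_gene(gene: Gene, functions: FunctionSet, terminals: Sequence[str]) -> None:
    """Raise if the gene violates the head/tail alphabet invariants."""
    terms = set(terminals)
    if gene.dc is not None:
        terms.add(RNC_SYMBOL)
    for i, s in enumerate(gene.symbols):
        if i < gene.head:
            if s not in functions and s not in terms:
                raise ValueError(f"unknown head symbol {s!r} at position {i}")
        elif s not in terms:
            raise ValueError(f"function {s!r} in tail at position {i}")


@dataclass(frozen=True)
class Chromosome:
    """A multigenic individual; the phenotype is the sum of its gene trees
    (addition linking)."""

    genes: tuple

    def __len__(self) -> int:
        return len(self.genes)


def _layout(gene: Gene, functions: FunctionSet):
    """ORF symbol list plus each node's child index block (karva order)."""
    syms = gene.symbols
    required = 1
    i = 0
    arities = []
    while i < required:
        a = functions.arity(syms[i]) if syms[i] in functions else 0
        arities.append(a)
        required += a
        i += 1
    first_child = np.empty(i, dtype=int)
    nxt = 1
    for j in range(i):
        first_child[j] = nxt
        nxt += arities[j]
    return syms[:i], arities, first_child


def orf_length(gene: Gene, functions: FunctionSet = DEFAULT_FUNCTIONS) -> int:
    return len(_layout(gene, functions)[0])


def decode(gene: Gene, functions: FunctionSet = DEFAULT_FUNCTIONS):
    """Decode to a nested-tuple expression tree.

    Functions become ``(symbol, child, ...)``; terminals ``(symbol,)``;
    RNC leaves ``("const", value)``.  A function symbol in the tail raises.
    """
    for i, s in enumerate(gene.symbols[gene.head:], start=gene.head):
        if s in functions:
            raise ValueError(f"malformed gene: function {s!r} in tail at {i}")
    syms, arities, first_child = _layout(gene, functions)
    consts = _orf_constants(gene, syms)
    nodes: list = [None] * len(syms)
    # ?-leaves map to Dc elements in karva *reading* order
    const_at = {}
    k = 0
    for j, s in enumerate(syms):
        if s == RNC_SYMBOL:
            const_at[j] = consts[k]
            k += 1
    for j in range(len(syms) - 1, -1, -1):
        a = arities[j]
        if a == 0:
            nodes[j] = ("const", const_at[j]) if syms[j] == RNC_SYMBOL else (syms[j],)
        else:
            nodes[j] = (syms[j], *(nodes[first_child[j] + c] for c in range(a)))
    return nodes[0]


def _orf_constants(gene: Gene, orf_syms) -> list:
    """Constant values consumed by ?-leaves, in karva reading order."""
    n_q = sum(1 for s in orf_syms if s == RNC_SYMBOL)
    if n_q == 0:
        return []
    if not gene.dc or gene.constants is None:
        raise ValueError("RNC symbol in a gene without a constant domain")
    return [gene.constants[gene.dc[k % len(gene.dc)]] for k in range(n_q)]


def evaluate_tree(tree, data: Mapping[str, np.ndarray]) -> np.ndarray:
    """Evaluate a nested-tuple expression tree under protected arithmetic.

    ``data`` maps terminal names to equal-length arrays (or scalars).
    Shared with the fixed published-formula predictors so both run under
    one arithmetic contract.
    """
    head = tree[0]
    if head == "const":
        return np.asarray(tree[1], dtype=float)
    if len(tree) == 1:
        if head not in data:
            raise KeyError(f"missing terminal value for {head!r}")
        return np.asarray(data[head], dtype=float)
    fn = _FUNCS[head][1]
    return fn(*(evaluate_tree(c, data) for c in tree[1:]))


def evaluate_gene(
    gene: Gene,
    data: Mapping[str, np.ndarray],
    functions: FunctionSet = DEFAULT_FUNCTIONS,
) -> np.ndarray:
    """Vectorized ORF evaluation (no tree objects; bottom-up over karva order)."""
    syms, arities, first_child = _layout(gene, functions)
    n = len(syms)
    consts = _orf_constants(gene, syms)
    values: list = [None] * n
    k = 0
    for j, s in enumerate(syms):
        if arities[j] == 0 and s == RNC_SYMBOL:
            values[j] = np.asarray(consts[k], dtype=float)
            k += 1
    for j in range(n - 1, -1, -1):
        a = arities[j]
        if a == 0:
            if values[j] is None:
                if syms[j] not in data:
                    raise KeyError(f"missing terminal value for {syms[j]!r}")
                values[j] = np.asarray(data[syms[j]], dtype=float)
        else:
            fn = _FUNCS[syms[j]][1]
            values[j] = fn(*(values[first_child[j] + c] for c in range(a)))
    return values[0]


def evaluate_chromosome(
    chrom: Chromosome,
    data: Mapping[str, np.ndarray],
    functions: FunctionSet = DEFAULT_FUNCTIONS,
) -> np.ndarray:
    """Phenotype value: sum of the gene-tree values (addition linking)."""
    total = evaluate_gene(chrom.genes[0], data, functions)
    for g in chrom.genes[1:]:
        total = _p_add(total, evaluate_gene(g, data, functions))
    return total


def _tree_infix(tree) -> str:
    head = tree[0]
    if head == "const":
        return f"{tree[1]:g}"
    if len(tree) == 1:
        return head
    template = _FUNCS[head][2]
    return template.format(*(_tree_infix(c) for c in tree[1:]))


def to_infix(obj, functions: FunctionSet = DEFAULT_FUNCTIONS) -> str:
    """Human-readable infix rendering of a Gene or Chromosome phenotype."""
    if isinstance(obj, Gene):
        return _tree_infix(decode(obj, functions))
    return " + ".join(_tree_infix(decode(g, functions)) for g in obj.genes)


def orf_key(gene: Gene, functions: FunctionSet = DEFAULT_FUNCTIONS):
    """Hashable key identifying the gene's phenotype (for value caching)."""
    syms, _, _ = _layout(gene, functions)
    if gene.dc is None:
        return syms
    n_q = sum(1 for s in syms if s == RNC_SYMBOL)
    if n_q == 0:
        return syms
    consts = tuple(
        gene.constants[gene.dc[k % len(gene.dc)]] for k in range(n_q)
    )
    return (syms, consts)
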