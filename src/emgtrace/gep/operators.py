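"""The eight canonical GEP genetic operators plus roulette selection.

All structural operators preserve the head/tail invariants by construction:
mutation respects the position's alphabet (tail positions draw terminals
only), inversion acts within the head, IS transposition inserts into a
non-root head position with the displaced head symbols shifted right and
truncated at the head boundary (the tail is never touched), RIS inserts a
function-rooted segment at the root, gene transposition moves a whole gene
to the front, and the three recombination flavours splice whole parent
strings at symbol or gene granularity.  Application order follows the
canonical flow: replication (selection) -> mutation -> inversion -> IS ->
RIS -> gene transposition -> one-point -> two-point -> gene recombination.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .karva import Chromosome, Gene

__all__ = ["roulette_select", "apply_operators"]

_SEGMENT_LENGTHS = (1, 2, 3)  # inversion/transposition segment sizes


def roulette_select(
    fitnesses: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Fitness-proportional sampling of ``n`` parent indices.

    Falls back to uniform sampling if all fitnesses are zero (degenerate
    but contractually handled).
    """
    f = np.asarray(fitnesses, dtype=float)
    total = f.sum()
    if not np.isfinite(total) or total <= 0:
        return rng.integers(0, f.size, size=n)
    cum = np.cumsum(f / total)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(n), side="right")


def _flat(chrom: Chromosome) -> list:
    out = []
    for g in chrom.genes:
        out.extend(g.symbols)
    return out


def _rebuild(template: Chromosome, flat: Sequence[str]) -> Chromosome:
    genes = []
    pos = 0
    for g in template.genes:
        size = len(g.symbols)
        genes.append(
            Gene(tuple(flat[pos : pos + size]), g.head, g.dc, g.constants)
        )
        pos += size
    return Chromosome(tuple(genes))


def _mutate(chrom, cfg, rng):
    h, size = cfg.head, cfg.gene_size
    n_sym = len(chrom.genes) * size
    k = rng.binomial(n_sym, cfg.mutation_rate)
    if k == 0:
        return chrom
    flat = _flat(chrom)
    head_alphabet = list(cfg.functions) + list(cfg.head_terminals)
    tail_alphabet = list(cfg.tail_terminals)
    for pos in rng.choice(n_sym, size=k, replace=False):
        in_head = (pos % size) < h
        flat[pos] = rng.choice(head_alphabet if in_head else tail_alphabet)
    chrom = _rebuild(chrom, flat)
    if cfg.rnc:
        chrom = _mutate_rnc(chrom, cfg, rng)
    return chrom


def _mutate_rnc(chrom, cfg, rng):
    """Dc point mutation and constant refresh at the symbol mutation rate."""
    genes = list(chrom.genes)
    for i, g in enumerate(genes):
        if g.dc is None:
            continue
        dc = list(g.dc)
        consts = list(g.constants)
        k = rng.binomial(len(dc), cfg.mutation_rate)
        for pos in rng.choice(len(dc), size=k, replace=False):
            dc[pos] = int(rng.integers(0, len(consts)))
        kc = rng.binomial(len(consts), cfg.mutation_rate)
        lo, hi = cfg.rnc_range
        for pos in rng.choice(len(consts), size=kc, replace=False):
            consts[pos] = float(rng.uniform(lo, hi))
        if k or kc:
            genes[i] = Gene(g.symbols, g.head, tuple(dc), tuple(consts))
    return Chromosome(tuple(genes))


def _invert(chrom, cfg, rng):
    if rng.random() >= cfg.inversion_rate:
        return chrom
    gi = int(rng.integers(0, len(chrom.genes)))
    g = chrom.genes[gi]
    seg = min(int(rng.choice(_SEGMENT_LENGTHS)), g.head)
    start = int(rng.integers(0, g.head - seg + 1))
    syms = list(g.symbols)
    syms[start : start + seg] = syms[start : start + seg][::-1]
    genes = list(chrom.genes)
    genes[gi] = Gene(tuple(syms), g.head, g.dc, g.constants)
    return Chromosome(tuple(genes))


def _is_transpose(chrom, cfg, rng):
    if rng.random() >= cfg.is_rate:
        return chrom
    src = chrom.genes[int(rng.integers(0, len(chrom.genes)))]
    seg_len = int(rng.choice(_SEGMENT_LENGTHS))
    start = int(rng.integers(0, len(src.symbols) - seg_len + 1))
    seg = list(src.symbols[start : start + seg_len])
    ti = int(rng.integers(0, len(chrom.genes)))
    tgt = chrom.genes[ti]
    if tgt.head < 2:
        return chrom
    ins = int(rng.integers(1, tgt.head))  # never the root
    head = list(tgt.symbols[: tgt.head])
    head = (head[:ins] + seg + head[ins:])[: tgt.head]
    tail = list(tgt.symbols[tgt.head :])  # tail untouched: invariants preserved
    genes = list(chrom.genes)
    genes[ti] = Gene(tuple(head + tail), tgt.head, tgt.dc, tgt.constants)
    return Chromosome(tuple(genes))


def _ris_transpose(chrom, cfg, rng):
    if rng.random() >= cfg.ris_rate:
        return chrom
    gi = int(rng.integers(0, len(chrom.genes)))
    g = chrom.genes[gi]
    head = list(g.symbols[: g.head])
    func_pos = [i for i, s in enumerate(head) if s in cfg.functions]
    if not func_pos:
        return chrom  # nothing to root-insert; operator skipped
    start = int(rng.choice(func_pos))
    seg_len = min(int(rng.choice(_SEGMENT_LENGTHS)), g.head - start)
    seg = head[start : start + seg_len]
    head = (seg + head)[: g.head]
    genes = list(chrom.genes)
    genes[gi] = Gene(tuple(head + list(g.symbols[g.head :])), g.head, g.dc, g.constants)
    return Chromosome(tuple(genes))


def _gene_transpose(chrom, cfg, rng):
    if len(chrom.genes) < 2 or rng.random() >= cfg.gene_transposition_rate:
        return chrom
    j = int(rng.integers(1, len(chrom.genes)))
    genes = list(chrom.genes)
    moved = genes.pop(j)
    return Chromosome(tuple([moved] + genes))


def _one_point(a, b, cfg, rng):
    flat_a, flat_b = _flat(a), _flat(b)
    point = int(rng.integers(1, len(flat_a)))
    new_a = flat_a[:point] + flat_b[point:]
    new_b = flat_b[:point] + flat_a[point:]
    return _rebuild(a, new_a), _rebuild(b, new_b)


def _two_point(a, b, cfg, rng):
    flat_a, flat_b = _flat(a), _flat(b)
    p1, p2 = sorted(rng.choice(len(flat_a), size=2, replace=False))
    new_a = flat_a[:p1] + flat_b[p1:p2] + flat_a[p2:]
    new_b = flat_b[:p1] + flat_a[p1:p2] + flat_b[p2:]
    return _rebuild(a, new_a), _rebuild(b, new_b)


def _gene_recombine(a, b, cfg, rng):
    j = int(rng.integers(0, len(a.genes)))
    ga, gb = list(a.genes), list(b.genes)
    ga[j], gb[j] = gb[j], ga[j]
    return Chromosome(tuple(ga)), Chromosome(tuple(gb))


def apply_operators(
    population: list, cfg, rng: np.random.Generator
) -> list:
    """One round of variation over a replicated population.

    ``cfg`` is a :class:`~emgtrace.gep.model.GepConfig`.  Returns a new
    population of the same size; every offspring satisfies the gene
    structural invariants.
    """
    pop = [_mutate(c, cfg, rng) for c in population]
    pop = [_invert(c, cfg, rng) for c in pop]
    pop = [_is_transpose(c, cfg, rng) for c in pop]
    pop = [_ris_transpose(c, cfg, rng) for c in pop]
    pop = [_gene_transpose(c, cfg, rng) for c in pop]
    for op, rate in (
        (_one_point, cfg.one_point_rate),
        (_two_point, cfg.two_point_rate),
        (_gene_recombine, cfg.gene_recombination_rate),
    ):
        if len(pop) < 2:
            break
        order = rng.permutation(len(pop))
        for i in range(0, len(order) - 1, 2):
            if rng.random() < rate:
                ia, ib = order[i], order[i + 1]
                pop[ia], pop[ib] = op(pop[ia], pop[ib], cfg, rng)
    return pop
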