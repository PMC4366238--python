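"""In-silico one-pot annealing/ligation and oligo synthesis-error models.

The join rule idealizes 65 °C ligation stringency: two same-strand oligos
A→B ligate iff some opposite-strand oligo is perfectly complementary
across their junction for at least ``anneal_k`` bases on each side.
Products are the maximal paths of the resulting ligation graph; a product
whose constituents span more than one gene is a chimera (gene fusion),
and a terminus with two or more competing joins is flagged as ambiguous.
The search is combinatorial — no concentrations or kinetics.

The error model reflects microarray oligo synthesis quality (2–2.7
errors/kb overall, dominated by single-base deletions): each position
independently suffers substitution or deletion; per-gap insertions are
available but default to zero.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._seq import revcomp, validate_dna
from .errors import EmptyPoolError
from .tiling import BOTTOM, TOP, Oligo

_BASES = "ACGT"


@dataclass(frozen=True)
class ErrorModel:
    """Per-nucleotide error rates. Defaults: 2.35 errors/kb, 70% deletions."""

    substitution_rate: float = 0.705e-3
    deletion_rate: float = 1.645e-3
    insertion_rate: float = 0.0

    def __post_init__(self):
        for r in (self.substitution_rate, self.deletion_rate, self.insertion_rate):
            if not (0 <= r < 1) or not math.isfinite(r):
                raise ValueError("rates must be finite and in [0, 1)")

    @property
    def total_rate(self) -> float:
        return self.substitution_rate + self.deletion_rate + self.insertion_rate


def mutate_sequence(
    seq: str,
    model: ErrorModel,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> str:
    """Apply independent per-position substitutions/deletions (+ optional
    per-gap insertions). Deterministic for a fixed seed."""
    validate_dna(seq, "sequence")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(seq)
    u = rng.random(n)
    dels = u < model.deletion_rate
    subs = (~dels) & (u < model.deletion_rate + model.substitution_rate)
    sub_draws = rng.integers(0, 3, size=int(subs.sum()))
    if model.insertion_rate > 0:
        ins_mask = rng.random(n + 1) < model.insertion_rate
        ins_bases = rng.integers(0, 4, size=int(ins_mask.sum()))
    else:
        ins_mask = np.zeros(n + 1, dtype=bool)
        ins_bases = np.empty(0, dtype=int)

    out: list[str] = []
    si = ii = 0
    for i in range(n):
        if ins_mask[i]:
            out.append(_BASES[ins_bases[ii]])
            ii += 1
        if dels[i]:
            continue
        if subs[i]:
            others = _BASES.replace(seq[i], "")
            out.append(others[sub_draws[si]])
            si += 1
        else:
            out.append(seq[i])
    if ins_mask[n]:
        out.append(_BASES[ins_bases[ii]])
    return "".join(out)


def fraction_perfect(length: int, rate_per_kb: float) -> float:
    """Closed-form probability that a product of *length* bp is error-free,
    exp(−rate · length / 1000), for a Poisson error process."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if rate_per_kb < 0:
        raise ValueError("rate must be >= 0")
    return math.exp(-rate_per_kb * length / 1000.0)


def fraction_perfect_mc(
    length: int,
    model: ErrorModel,
    n_reps: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of the error-free fraction under the same
    per-position event model as :func:`mutate_sequence`."""
    rng = np.random.default_rng(seed)
    p = model.substitution_rate + model.deletion_rate
    events = rng.binomial(length, p, size=n_reps)
    if model.insertion_rate > 0:
        events = events + rng.binomial(length + 1, model.insertion_rate, size=n_reps)
    return float(np.mean(events == 0))


# --- ligation graph --------------------------------------------------------


@dataclass(frozen=True)
class AssemblyProduct:
    sequence: str  # top-strand sense
    constituents: tuple[str, ...]  # oligo names, in ligation order
    gene_ids: tuple[str, ...]
    full_length: bool
    chimeric: bool
    strand: str


@dataclass
class LigationResult:
    products: list[AssemblyProduct]
    chimeras: list[AssemblyProduct]
    ambiguous_termini: list[str]  # oligo names with >= 2 competing joins
    truncated: bool  # product enumeration hit the cap


def _find_joins(
    primaries: Sequence[Oligo], bridges: Sequence[Oligo], k: int
) -> dict[int, set[int]]:
    """Edges i->j between same-strand oligos bridged by an opposite-strand
    oligo perfectly complementary over >= k nt on each side of the nick."""
    suffix_idx: dict[str, list[int]] = defaultdict(list)
    prefix_idx: dict[str, list[int]] = defaultdict(list)
    for i, o in enumerate(primaries):
        if len(o.sequence) >= k:
            suffix_idx[o.sequence[-k:]].append(i)
            prefix_idx[o.sequence[:k]].append(i)
    edges: dict[int, set[int]] = defaultdict(set)
    for c in bridges:
        t = revcomp(c.sequence)  # primary-strand sense
        for pos in range(k, len(t) - k + 1):
            for i in suffix_idx.get(t[pos - k : pos], ()):
                for j in prefix_idx.get(t[pos : pos + k], ()):
                    if i != j:
                        edges[i].add(j)
    return edges


def _maximal_paths(n: int, edges: dict[int, set[int]], cap: int) -> tuple[list[list[int]], bool]:
    indeg = defaultdict(int)
    for tgts in edges.values():
        for j in tgts:
            indeg[j] += 1
    starts = [i for i in range(n) if indeg[i] == 0]
    paths: list[list[int]] = []
    truncated = False

    def walk(path: list[int], on_path: set[int]) -> None:
        nonlocal truncated
        if truncated:
            return
        nxt = [j for j in sorted(edges.get(path[-1], ())) if j not in on_path]
        if not nxt:
            paths.append(list(path))
            if len(paths) >= cap:
                truncated = True
            return
        for j in nxt:
            path.append(j)
            on_path.add(j)
            walk(path, on_path)
            on_path.discard(j)
            path.pop()

    for s in starts:
        walk([s], {s})
    return paths, truncated


def simulate_ligation(
    oligos: Iterable[Oligo],
    anneal_k: int = 10,
    max_products: int = 10_000,
    gene_lengths: dict[str, int] | None = None,
) -> LigationResult:
    """Enumerate ligation products of a pooled oligo library.

    ``gene_lengths`` (gene -> synthon length) defaults to the maximal end
    coordinate seen per gene; it defines what counts as full length.
    """
    pool = list(oligos)
    if not pool:
        raise EmptyPoolError("no oligos")
    if anneal_k < 1:
        raise ValueError("anneal_k must be >= 1")
    if gene_lengths is None:
        gene_lengths = {}
        for o in pool:
            gene_lengths[o.gene_id] = max(gene_lengths.get(o.gene_id, 0), o.end)

    tops = [o for o in pool if o.strand == TOP]
    bottoms = [o for o in pool if o.strand == BOTTOM]

    by_seq: dict[str, AssemblyProduct] = {}
    chimeras: list[AssemblyProduct] = []
    ambiguous: list[str] = []
    truncated = False

    for primaries, bridges, strand in ((tops, bottoms, TOP), (bottoms, tops, BOTTOM)):
        if not primaries:
            continue
        edges = _find_joins(primaries, bridges, anneal_k)
        indeg: dict[int, int] = defaultdict(int)
        for i, tgts in edges.items():
            if len(tgts) > 1:
                ambiguous.append(primaries[i].name)
            for j in tgts:
                indeg[j] += 1
        for j, d in indeg.items():
            if d > 1:
                ambiguous.append(primaries[j].name)
        paths, trunc = _maximal_paths(len(primaries), edges, max_products)
        truncated = truncated or trunc
        for path in paths:
            members = [primaries[i] for i in path]
            raw = "".join(o.sequence for o in members)
            seq = raw if strand == TOP else revcomp(raw)
            genes = tuple(dict.fromkeys(o.gene_id for o in members))
            if strand == TOP:
                full = members[0].start == 0 and members[-1].end == gene_lengths[members[-1].gene_id]
            else:
                full = (
                    members[0].end == gene_lengths[members[0].gene_id]
                    and members[-1].start == 0
                )
            product = AssemblyProduct(
                sequence=seq,
                constituents=tuple(o.name for o in members),
                gene_ids=genes,
                full_length=full and len(genes) == 1,
                chimeric=len(genes) > 1,
                strand=strand,
            )
            if product.chimeric:
                chimeras.append(product)
            by_seq.setdefault(seq, product)

    return LigationResult(
        products=list(by_seq.values()),
        chimeras=chimeras,
        ambiguous_termini=sorted(set(ambiguous)),
        truncated=truncated,
    )
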