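"""Constraint-satisfying oligo tiling for one-pot ligation assembly.

A synthon is split into overlapping top- and bottom-strand oligos that
jointly double-tile it. Nicks strictly alternate between strands (the
first nick after the 5' end is on the bottom strand), so every inter-nick
segment is an annealed overlap held by exactly one top and one bottom
oligo. Constraints, following the design rules of thermostable-ligase
assembly from pooled microarray oligos:

* every oligo length within [len_min, len_max] (default 25–175 nt);
* every overlap's nearest-neighbor Tm >= tm_target − tm_tolerance
  (default 65 ± 2.5 °C) so only designed junctions survive 65 °C ligation;
* terminal uniqueness: no two oligo termini anywhere in the pooled library
  may share an exact terminal match longer than ``terminal_unique_k``
  (default 15 nt), in any orientation — the property that stops a bridging
  oligo from ligating across genes.

The search is greedy left-to-right, preferring the highest-Tm overlap at
each step, with full backtracking under a node budget.

Terminal-match bookkeeping uses the fact that all four anchored
comparisons between two termini (5'–5' prefix, 3'–3' suffix, and the two
reverse-complement cross modes) equal the longest common prefix of the
termini's "inward words": the oligo sequence itself for a 5' terminus and
its reverse complement for a 3' terminus. A nick at top-strand coordinate
y therefore contributes exactly two (k+1)-mer words, revcomp(seq[y-k-1:y])
and seq[y:y+k+1], regardless of which strand is nicked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from ._seq import longest_common_prefix, revcomp
from .errors import TilingInfeasibleError
from .synthon import Synthon
from .thermo import TmPrefix, compute_tm

TOP = "top"
BOTTOM = "bottom"


@dataclass(frozen=True)
class TilingConstraints:
    tm_target: float = 65.0
    tm_tolerance: float = 2.5
    len_min: int = 25
    len_max: int = 175
    terminal_unique_k: int = 15
    min_overlap: int = 10
    tm_model: str = "nearest_neighbor"
    search_budget: int = 200_000

    def __post_init__(self):
        if self.len_min >= self.len_max:
            raise ValueError("len_min must be < len_max")
        if self.terminal_unique_k < 1:
            raise ValueError("terminal_unique_k must be >= 1")

    @property
    def tm_floor(self) -> float:
        return self.tm_target - self.tm_tolerance


@dataclass(frozen=True)
class Oligo:
    gene_id: str
    strand: str  # "top" | "bottom"
    start: int  # synthon top-strand coordinates, 0-based half-open
    end: int
    sequence: str  # 5'->3' on its own strand

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start:
            raise ValueError("oligo sequence length disagrees with coordinates")

    @property
    def name(self) -> str:
        return f"{self.gene_id}|{self.strand}|{self.start}-{self.end}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Overlap:
    start: int
    end: int
    tm: float


@dataclass(frozen=True)
class Junction:
    """A nick and the two overlaps flanking it."""

    strand: str
    position: int
    left: Overlap
    right: Overlap


@dataclass
class OligoSet:
    gene_id: str
    oligos: list[Oligo]
    junctions: list[Junction]
    segments: list[Overlap]

    @property
    def top(self) -> list[Oligo]:
        return [o for o in self.oligos if o.strand == TOP]

    @property
    def bottom(self) -> list[Oligo]:
        return [o for o in self.oligos if o.strand == BOTTOM]


class TerminalIndex:
    """Library-wide index of terminal uniqueness words.

    Words are split into *junction* words (termini created by nicks, which
    are ligation-competent) and *outer* words (the blunt 5'/3' ends of a
    synthon, where no nick exists). Outer words are shared across a
    library by design — every synthon starts with the universal forward
    primer region and ends with the universal reverse one — so outer-vs-
    outer collisions are designed and allowed; any collision involving a
    junction word is cross-talk.
    """

    def __init__(self, k: int = 15):
        self.k = k
        self._junction: dict[str, list[tuple[str, int]]] = {}
        self._outer: dict[str, list[tuple[str, int]]] = {}

    def __contains__(self, word: str) -> bool:
        return word in self._junction or word in self._outer

    def conflicts(self, word: str, outer: bool = False) -> bool:
        if outer:
            return word in self._junction
        return word in self._junction or word in self._outer

    def add(self, word: str, gene_id: str, coord: int, outer: bool = False) -> None:
        table = self._outer if outer else self._junction
        table.setdefault(word, []).append((gene_id, coord))

    def __len__(self) -> int:
        return len(self._junction) + len(self._outer)


def tile_synthon(
    synthon: Synthon,
    constraints: TilingConstraints | None = None,
    index: TerminalIndex | None = None,
) -> OligoSet:
    """Tile one synthon; registers its junction words in *index* on success.

    Deterministic: the search order depends only on the sequence and the
    constraints. Raises :class:`TilingInfeasibleError` naming the stuck
    coordinate window when no placement satisfies all constraints.
    """
    c = constraints or TilingConstraints()
    seq = synthon.sequence
    L = len(seq)
    if L < c.len_min:
        raise TilingInfeasibleError(f"synthon shorter than len_min ({L} bp)")
    k1 = c.terminal_unique_k + 1
    s_lo = max(c.min_overlap, k1)
    s_hi = max(s_lo, c.len_max // 2)
    if index is None:
        index = TerminalIndex(c.terminal_unique_k)

    if c.tm_model == "nearest_neighbor":
        prefix = TmPrefix(seq)
        seg_tm = prefix.tm
    else:
        seg_tm = lambda a, b: compute_tm(seq[a:b], model=c.tm_model)  # noqa: E731

    start_word = seq[0:k1]
    end_word = revcomp(seq[L - k1 : L])
    for word, what in ((start_word, "5' end"), (end_word, "3' end")):
        if index.conflicts(word, outer=True):
            raise TilingInfeasibleError(
                f"{synthon.gene_id}: {what} word collides with a junction "
                "word already in the library index"
            )

    pending: set[str] = {start_word}
    nicks: list[int] = []
    budget = c.search_budget
    deepest = 0

    def candidates(xi: int) -> list[int]:
        hi = min(xi + s_hi, L)
        scored = []
        for y in range(xi + s_lo, hi + 1):
            if y != L and L - y < s_lo:
                continue  # unreachable tail
            tm = seg_tm(xi, y)
            if tm < c.tm_floor:
                continue
            scored.append((-tm, y))
        scored.sort()
        return [y for _, y in scored]

    def search(xi: int, i: int, prev_top: int, prev_bottom: int) -> bool:
        nonlocal budget, deepest
        deepest = max(deepest, xi)
        if budget <= 0:
            return False
        for y in candidates(xi):
            budget -= 1
            strand = BOTTOM if i % 2 == 0 else TOP
            if y == L:
                if not (c.len_min <= L - prev_top <= c.len_max):
                    continue
                if not (c.len_min <= L - prev_bottom <= c.len_max):
                    continue
                if end_word in pending and end_word != start_word:
                    continue  # a junction word equals the outer 3' word
                return True
            prev_same = prev_bottom if strand == BOTTOM else prev_top
            if not (c.len_min <= y - prev_same <= c.len_max):
                continue
            w_left = revcomp(seq[y - k1 : y])
            w_right = seq[y : y + k1]
            if (
                w_left == w_right
                or w_left in pending or w_right in pending
                or index.conflicts(w_left) or index.conflicts(w_right)
                or end_word in (w_left, w_right)
            ):
                continue
            nicks.append(y)
            pending.add(w_left)
            pending.add(w_right)
            nxt = (prev_top, y) if strand == BOTTOM else (y, prev_bottom)
            if search(y, i + 1, *nxt):
                return True
            nicks.pop()
            pending.discard(w_left)
            pending.discard(w_right)
        return False

    if not search(0, 0, 0, 0):
        raise TilingInfeasibleError(
            f"tiling infeasible for {synthon.gene_id}; search stuck near "
            f"coordinate window [{max(0, deepest - s_hi)}, {min(L, deepest + s_hi)})"
        )

    oligo_set = _build_oligo_set(synthon.gene_id, seq, nicks, seg_tm)
    index.add(start_word, synthon.gene_id, 0, outer=True)
    index.add(end_word, synthon.gene_id, L, outer=True)
    for y in nicks:
        index.add(revcomp(seq[y - k1 : y]), synthon.gene_id, y)
        index.add(seq[y : y + k1], synthon.gene_id, y)
    return oligo_set


def _build_oligo_set(gene_id, seq, nicks, seg_tm) -> OligoSet:
    L = len(seq)
    bottom_nicks = [y for i, y in enumerate(nicks) if i % 2 == 0]
    top_nicks = [y for i, y in enumerate(nicks) if i % 2 == 1]
    oligos: list[Oligo] = []
    for bounds, strand in ((top_nicks, TOP), (bottom_nicks, BOTTOM)):
        edges = [0, *bounds, L]
        for a, b in zip(edges, edges[1:]):
            s = seq[a:b] if strand == TOP else revcomp(seq[a:b])
            oligos.append(Oligo(gene_id, strand, a, b, s))
    merged = [0, *nicks, L]
    segments = [Overlap(a, b, seg_tm(a, b)) for a, b in zip(merged, merged[1:])]
    junctions = []
    for i, y in enumerate(nicks):
        strand = BOTTOM if i % 2 == 0 else TOP
        junctions.append(Junction(strand, y, segments[i], segments[i + 1]))
    return OligoSet(gene_id=gene_id, oligos=oligos, junctions=junctions, segments=segments)


def tile_library(
    synthons: Sequence[Synthon],
    constraints: TilingConstraints | None = None,
    index: TerminalIndex | None = None,
) -> dict[str, OligoSet]:
    """Tile many synthons against one shared terminal-uniqueness index."""
    c = constraints or TilingConstraints()
    index = index if index is not None else TerminalIndex(c.terminal_unique_k)
    return {s.gene_id: tile_synthon(s, c, index) for s in synthons}


# --- terminal uniqueness auditing -----------------------------------------


@dataclass(frozen=True)
class _Terminus:
    oligo: Oligo
    kind: str  # "5p" | "3p"
    coord: int
    inward: str
    outer: bool  # sits at a synthon blunt end (coordinate 0 or L)


@dataclass(frozen=True)
class Violation:
    oligo_a: str
    oligo_b: str
    kind_a: str
    kind_b: str
    match_length: int


def _termini(oligo_sets) -> list[_Terminus]:
    oligos: list[Oligo] = []
    for item in oligo_sets:
        if isinstance(item, Oligo):
            oligos.append(item)
        else:
            oligos.extend(item.oligos)
    gene_len: dict[str, int] = {}
    for o in oligos:
        gene_len[o.gene_id] = max(gene_len.get(o.gene_id, 0), o.end)
    out = []
    for o in oligos:
        c5 = o.start if o.strand == TOP else o.end
        c3 = o.end if o.strand == TOP else o.start
        for kind, coord, inward in (
            ("5p", c5, o.sequence),
            ("3p", c3, revcomp(o.sequence)),
        ):
            outer = coord == 0 or coord == gene_len[o.gene_id]
            out.append(_Terminus(o, kind, coord, inward, outer))
    return out


def _scan_termini(oligo_sets, k: int) -> tuple[list[Violation], int]:
    # Outer-vs-outer pairs are skipped: synthon blunt ends share the
    # universal primer regions by design and carry no ligation junction
    # (the same-gene case is the two strands' designed complementary ends).
    # Any pair involving a junction terminus is audited.
    termini = _termini(oligo_sets)
    violations: list[Violation] = []
    worst = 0
    n = len(termini)
    for i in range(n):
        a = termini[i]
        for j in range(i + 1, n):
            b = termini[j]
            if a.oligo is b.oligo and a.kind == b.kind:
                continue
            if a.outer and b.outer:
                continue
            m = longest_common_prefix(a.inward, b.inward)
            if m > worst:
                worst = m
            if m > k:
                violations.append(
                    Violation(a.oligo.name, b.oligo.name, a.kind, b.kind, m)
                )
    return violations, worst


def check_terminal_uniqueness(oligo_sets, k: int = 15) -> list[Violation]:
    """Brute-force all-pairs terminal-match audit.

    Reports every pair of distinct oligo termini whose exact terminal match
    (any orientation) exceeds *k*. An empty list means the library passes
    the 15-nt uniqueness rule.
    """
    if not _termini(oligo_sets):
        raise ValueError("no oligos to check")
    return _scan_termini(oligo_sets, k)[0]


def max_terminal_match(oligo_sets) -> int:
    """Largest terminal match between any two distinct termini (nt)."""
    return _scan_termini(oligo_sets, k=10**9)[1]


# --- self-consistency report ----------------------------------------------


@dataclass
class TilingReport:
    checks: list[tuple[str, bool, str]]
    length_min: int
    length_max: int
    length_median: float
    overlap_tms: list[float]

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)


def validate_tiling(
    oligo_set: OligoSet,
    synthon: Synthon,
    constraints: TilingConstraints | None = None,
) -> TilingReport:
    """Machine-readable audit of one oligo set against its synthon."""
    c = constraints or TilingConstraints()
    seq = synthon.sequence
    L = len(seq)
    checks: list[tuple[str, bool, str]] = []

    strand_nicks: dict[str, list[int]] = {}
    for strand in (TOP, BOTTOM):
        oligos = sorted(
            (o for o in oligo_set.oligos if o.strand == strand), key=lambda o: o.start
        )
        ok = True
        detail = "full double-strand coverage"
        pos = 0
        for o in oligos:
            if o.start > pos:
                ok, detail = False, f"coverage gap [{pos}, {o.start})"
                break
            if o.start < pos:
                ok, detail = False, f"overlapping tiles at {o.start}"
                break
            expected = seq[o.start : o.end] if strand == TOP else revcomp(seq[o.start : o.end])
            if o.sequence != expected:
                ok, detail = False, f"sequence mismatch in {o.name}"
                break
            pos = o.end
        if ok and pos != L:
            ok, detail = False, f"coverage gap [{pos}, {L})"
        checks.append((f"{strand}_coverage", ok, detail))
        strand_nicks[strand] = [o.end for o in oligos[:-1]]

    if strand_nicks[TOP] and strand_nicks[BOTTOM]:
        stagger = min(
            abs(t - b) for t in strand_nicks[TOP] for b in strand_nicks[BOTTOM]
        )
        checks.append(
            ("nick_stagger", stagger >= c.min_overlap, f"min stagger {stagger} nt")
        )

    merged = sorted({0, L, *strand_nicks[TOP], *strand_nicks[BOTTOM]})
    tms = [compute_tm(seq[a:b], model=c.tm_model) for a, b in zip(merged, merged[1:])]
    tm_ok = all(t >= c.tm_floor for t in tms)
    checks.append(
        ("overlap_tm", tm_ok, f"min overlap Tm {min(tms):.2f} °C" if tms else "n/a")
    )

    lengths = [len(o) for o in oligo_set.oligos]
    len_ok = all(c.len_min <= n <= c.len_max for n in lengths)
    checks.append(("oligo_lengths", len_ok, f"range {min(lengths)}-{max(lengths)} nt"))

    return TilingReport(
        checks=checks,
        length_min=min(lengths),
        length_max=max(lengths),
        length_median=float(median(lengths)),
        overlap_tms=tms,
    )
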