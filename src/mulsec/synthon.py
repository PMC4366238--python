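"""Standardized synthon construction.

Every gene is packaged into a fixed-layout double-stranded unit:

    UF – SF – RE1(EcoRI) – ORF – RE2(BamHI) – FILLER – SR – UR

The restriction window (RE1..RE2) carries the ORF so that excised inserts
fuse in frame to the downstream reporter; a GC-balanced random filler after
RE2 pads every core (RE1+ORF+RE2+FILLER) to exactly ``core_length`` bp
(default 711), and the whole assembly stays under ``total_cap`` (default
950 bp). UF/UR are shared by the whole library for pooled amplification;
SF/SR are gene-specific, mutually orthogonal primer landing sites.

The suppression-PCR tail is a sequence constant used by downstream wet
protocols; it is exported here but never embedded in a synthon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import gc_fraction, max_homopolymer, revcomp, validate_dna
from .codon import (
    DEFAULT_FORBIDDEN_MOTIFS,
    OptimizationConfig,
    default_codon_table,
    reverse_translate,
    scan_motifs,
)
from .errors import CloningSiteConflictError, DesignInfeasibleError
from .thermo import tm_nearest_neighbor

SUPPRESSION_TAIL = "CATCAGGTTTCATCCTGCCGGCATGAGCGGCTAACGG"
SUPPRESSION_PRIMER = "CATCAGGTTTCATCCTGCCGG"
assert SUPPRESSION_TAIL.startswith(SUPPRESSION_PRIMER)

SEGMENT_ORDER = ("UF", "SF", "RE1", "ORF", "RE2", "FILLER", "SR", "UR")


@dataclass(frozen=True)
class SynthonLayout:
    """Library-wide layout constants (lengths in bp)."""

    core_length: int = 711
    total_cap: int = 950
    re1: str = "GAATTC"  # EcoRI
    re2: str = "GGATCC"  # BamHI

    def __post_init__(self):
        validate_dna(self.re1, "RE1")
        validate_dna(self.re2, "RE2")
        if self.core_length <= len(self.re1) + len(self.re2):
            raise ValueError("core_length leaves no room for an ORF")

    def max_orf_length(self) -> int:
        return self.core_length - len(self.re1) - len(self.re2)


@dataclass(frozen=True)
class PrimerSet:
    """Universal (UF/UR) and per-gene specific (SF/SR) primer regions."""

    uf: str
    ur: str
    specific: Mapping[str, tuple[str, str]]
    tm_target: float = 57.0
    max_cross_match: int = 12
    suppression_tail: str = SUPPRESSION_TAIL
    suppression_primer: str = SUPPRESSION_PRIMER

    def __post_init__(self):
        validate_dna(self.uf, "UF")
        validate_dna(self.ur, "UR")
        for gene, (sf, sr) in self.specific.items():
            validate_dna(sf, f"SF[{gene}]")
            validate_dna(sr, f"SR[{gene}]")
        if not self.suppression_tail.startswith(self.suppression_primer):
            raise ValueError("suppression primer must be a prefix of the tail")


@dataclass(frozen=True)
class Synthon:
    gene_id: str
    sequence: str
    segments: Mapping[str, tuple[int, int]]  # 0-based half-open, top strand
    orf: str

    def __post_init__(self):
        s, e = self.segments["ORF"]
        if self.sequence[s:e] != self.orf:
            raise ValueError("ORF coordinates do not slice to the ORF")

    @property
    def core_length(self) -> int:
        return self.segments["FILLER"][1] - self.segments["RE1"][0]

    def __len__(self) -> int:
        return len(self.sequence)


def generate_filler(
    length: int,
    gc_target: float = 0.5,
    gc_tolerance: float = 0.05,
    forbidden_motifs: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    max_homopolymer_run: int = 6,
    avoid_kmers: frozenset[str] = frozenset(),
    avoid_k: int = 16,
    max_attempts: int = 1000,
) -> str:
    """Random ~50% GC padding with motif / homopolymer / cross-match screens.

    GC is constrained to ``gc_target ± gc_tolerance`` for lengths >= 40 bp
    and left unconstrained below that (too few bases for the tolerance to
    be meaningful). ``avoid_kmers`` lets the synthon builder keep primer
    binding sites unique: no ``avoid_k``-mer of the filler (either strand)
    may appear in the set.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    if length == 0:
        return ""
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2])
    bases = np.array(list("ACGT"))
    for _ in range(max_attempts):
        filler = "".join(rng.choice(bases, size=length, p=p))
        if length >= 40 and abs(gc_fraction(filler) - gc_target) > gc_tolerance:
            continue
        if max_homopolymer(filler) > max_homopolymer_run:
            continue
        if scan_motifs(filler, forbidden_motifs, both_strands=True):
            continue
        if avoid_kmers and _hits_kmers(filler, avoid_kmers, avoid_k):
            continue
        return filler
    raise DesignInfeasibleError(f"filler infeasible for length {length}")


def _hits_kmers(seq: str, kmer_set: frozenset[str], k: int) -> bool:
    for strand in (seq, revcomp(seq)):
        for i in range(len(strand) - k + 1):
            if strand[i : i + k] in kmer_set:
                return True
    return False


class PrimerDesigner:
    """Generates mutually orthogonal primer regions.

    Orthogonality is enforced by a shared index of every accepted primer's
    (max_cross_match+1)-mers on both strands: a candidate sharing any such
    word with the library would have a longest common substring (in either
    orientation) exceeding ``max_cross_match`` and is rejected. Candidates
    must also sit within ``tm_tolerance`` of the Tm target, avoid forbidden
    motifs on both strands, and avoid homopolymer runs > 4 nt.
    """

    def __init__(
        self,
        length: int = 20,
        tm_target: float = 57.0,
        tm_tolerance: float = 3.0,
        max_cross_match: int = 12,
        forbidden_motifs: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS,
        rng: np.random.Generator | None = None,
        seed: int | None = None,
        max_attempts: int = 20000,
    ):
        if length < max_cross_match:
            raise ValueError("primer length must be >= max_cross_match")
        self.length = length
        self.tm_target = tm_target
        self.tm_tolerance = tm_tolerance
        self.max_cross_match = max_cross_match
        self.forbidden_motifs = tuple(forbidden_motifs)
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        self.max_attempts = max_attempts
        self._index: set[str] = set()
        self.primers: list[str] = []

    def _words(self, seq: str) -> set[str]:
        k = self.max_cross_match + 1
        words = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        rc = revcomp(seq)
        words |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
        return words

    def make_primer(self) -> str:
        bases = np.array(list("ACGT"))
        for _ in range(self.max_attempts):
            cand = "".join(self.rng.choice(bases, size=self.length))
            if max_homopolymer(cand) > 4:
                continue
            if abs(tm_nearest_neighbor(cand) - self.tm_target) > self.tm_tolerance:
                continue
            if scan_motifs(cand, self.forbidden_motifs, both_strands=True):
                continue
            words = self._words(cand)
            if words & self._index:
                continue
            self._index |= words
            self.primers.append(cand)
            return cand
        raise DesignInfeasibleError(
            f"primer design infeasible after {len(self.primers)} primers"
        )

    def make_pair(self) -> tuple[str, str]:
        return self.make_primer(), self.make_primer()


def design_specific_primers(
    n_genes: int,
    length: int = 20,
    tm_target: float = 57.0,
    max_cross_match: int = 12,
    seed: int = 0,
    **kwargs,
) -> list[tuple[str, str]]:
    """n_genes orthogonal (SF, SR) pairs; see :class:`PrimerDesigner`."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    designer = PrimerDesigner(
        length=length, tm_target=tm_target, max_cross_match=max_cross_match,
        seed=seed, **kwargs,
    )
    return [designer.make_pair() for _ in range(n_genes)]


def build_synthon(
    gene_id: str,
    orf: str,
    uf: str,
    ur: str,
    sf: str,
    sr: str,
    layout: SynthonLayout | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    forbidden_motifs: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS,
    primer_avoid_k: int = 16,
    max_attempts: int = 50,
) -> Synthon:
    """Assemble one synthon around a motif-free ORF.

    The filler is regenerated until the full sequence carries RE1 and RE2
    exactly once each (segment junctions can create stray sites). A stray
    site that does not touch the filler cannot be fixed here and raises
    :class:`CloningSiteConflictError` so the caller can redesign the ORF
    or the specific primers.
    """
    layout = layout or SynthonLayout()
    if rng is None:
        rng = np.random.default_rng(seed)
    validate_dna(orf, "ORF")
    if scan_motifs(orf, (layout.re1, layout.re2), both_strands=True):
        raise CloningSiteConflictError("ORF contains cloning site")
    filler_len = layout.max_orf_length() - len(orf)
    if filler_len < 0:
        raise DesignInfeasibleError(
            f"gene too long for standardized synthon ({len(orf)} bp ORF, "
            f"core {layout.core_length} bp)"
        )
    primer_kmers = set()
    for p in (uf, ur, sf, sr):
        for s in (p, revcomp(p)):
            primer_kmers |= {
                s[i : i + primer_avoid_k] for i in range(len(s) - primer_avoid_k + 1)
            }
    avoid = frozenset(primer_kmers)

    stray: int | None = None
    for _ in range(max_attempts):
        filler = generate_filler(
            filler_len, forbidden_motifs=forbidden_motifs, rng=rng,
            avoid_kmers=avoid, avoid_k=primer_avoid_k,
        )
        seq = uf + sf + layout.re1 + orf + layout.re2 + filler + sr + ur
        if len(seq) >= layout.total_cap:
            raise DesignInfeasibleError(
                f"total assembly length {len(seq)} exceeds cap {layout.total_cap}"
            )
        coords = _segment_coords(uf, sf, layout, orf, filler, sr, ur)
        expected = {(coords["RE1"][0], layout.re1), (coords["RE2"][0], layout.re2)}
        hits = set(scan_motifs(seq, (layout.re1, layout.re2), both_strands=True))
        extra = hits - expected
        if not extra:
            return Synthon(gene_id=gene_id, sequence=seq, segments=coords, orf=orf)
        fs, fe = coords["FILLER"]
        motif_len = max(len(layout.re1), len(layout.re2))
        fixable = all(fs - motif_len < pos < fe for pos, _ in extra)
        if not fixable:
            pos, motif = sorted(extra)[0]
            stray = pos
            raise CloningSiteConflictError(
                f"stray {motif} at {pos} outside filler in {gene_id}",
                position=pos, motif=motif,
            )
    raise DesignInfeasibleError(f"filler infeasible for {gene_id} (stray site at {stray})")


def _segment_coords(uf, sf, layout, orf, filler, sr, ur) -> dict[str, tuple[int, int]]:
    parts = {
        "UF": uf, "SF": sf, "RE1": layout.re1, "ORF": orf,
        "RE2": layout.re2, "FILLER": filler, "SR": sr, "UR": ur,
    }
    coords = {}
    pos = 0
    for name in SEGMENT_ORDER:
        coords[name] = (pos, pos + len(parts[name]))
        pos += len(parts[name])
    return coords


@dataclass
class LibraryDesign:
    synthons: list[Synthon]
    primer_set: PrimerSet
    layout: SynthonLayout


def build_library(
    proteins: Iterable[tuple[str, str]],
    codon_table=None,
    layout: SynthonLayout | None = None,
    seed: int = 0,
    primer_length: int = 20,
    primer_tm_target: float = 57.0,
    max_cross_match: int = 12,
    forbidden_motifs: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS,
    gene_attempts: int = 10,
) -> LibraryDesign:
    """Design a whole library: ORFs, shared UF/UR, per-gene SF/SR, synthons.

    On a stray restriction site spanning a segment junction the offending
    gene's ORF is re-sampled (new codon seed) and its SF/SR pair replaced,
    then the build is retried.
    """
    proteins = list(proteins)
    codon_table = codon_table or default_codon_table()
    layout = layout or SynthonLayout()
    ss = np.random.SeedSequence(seed)
    primer_rng = np.random.default_rng(ss.spawn(1)[0])
    designer = PrimerDesigner(
        length=primer_length, tm_target=primer_tm_target,
        max_cross_match=max_cross_match, forbidden_motifs=forbidden_motifs,
        rng=primer_rng,
    )
    uf, ur = designer.make_pair()
    synthons: list[Synthon] = []
    specific: dict[str, tuple[str, str]] = {}
    gene_seeds = ss.spawn(len(proteins))
    for (gene_id, protein), child in zip(proteins, gene_seeds):
        streams = child.spawn(gene_attempts)
        sf, sr = designer.make_pair()
        last_err: Exception | None = None
        for attempt in range(gene_attempts):
            rng = np.random.default_rng(streams[attempt])
            orf = reverse_translate(
                protein, codon_table,
                OptimizationConfig(forbidden_motifs=tuple(forbidden_motifs)),
                rng=rng,
            )
            try:
                syn = build_synthon(
                    gene_id, orf, uf, ur, sf, sr, layout=layout, rng=rng,
                    forbidden_motifs=forbidden_motifs,
                )
                synthons.append(syn)
                specific[gene_id] = (sf, sr)
                last_err = None
                break
            except CloningSiteConflictError as err:
                last_err = err
                sf, sr = designer.make_pair()
        if last_err is not None:
            raise DesignInfeasibleError(
                f"could not build synthon for {gene_id}: {last_err}"
            )
    primer_set = PrimerSet(
        uf=uf, ur=ur, specific=specific,
        tm_target=primer_tm_target, max_cross_match=max_cross_match,
    )
    return LibraryDesign(synthons=synthons, primer_set=primer_set, layout=layout)
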