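"""Weighted-random reverse translation with restriction-motif exclusion.

Proteins are converted to DNA by sampling, independently at each residue,
a codon with probability proportional to host codon-usage weights. Designs
containing a forbidden motif (EcoRI ``GAATTC`` and BamHI ``GGATCC`` by
default, on either strand) are repaired by resampling only the codons that
overlap each motif hit, then rescanned; the procedure fails loudly if no
motif-free design is found within the attempt budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

from ._seq import revcomp, validate_dna
from .errors import DesignInfeasibleError, MalformedSequenceError, UnknownResidueError

DEFAULT_FORBIDDEN_MOTIFS = ("GAATTC", "GGATCC")  # EcoRI, BamHI


def _standard_code() -> dict[str, str]:
    table = _BioCodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


GENETIC_CODE: dict[str, str] = _standard_code()


@dataclass(frozen=True)
class CodonUsageTable:
    """Amino acid (1-letter, ``*`` for stop) -> [(codon, weight), ...]."""

    entries: Mapping[str, Sequence[tuple[str, float]]]

    def __post_init__(self):
        for aa, codons in self.entries.items():
            if not codons:
                raise ValueError(f"amino acid {aa!r} has no codons")
            total = 0.0
            for codon, weight in codons:
                validate_dna(codon, f"codon for {aa!r}")
                if len(codon) != 3:
                    raise ValueError(f"codon {codon!r} is not a 3-mer")
                if GENETIC_CODE[codon] != aa:
                    raise ValueError(f"codon {codon} does not translate to {aa!r}")
                if weight < 0:
                    raise ValueError(f"negative weight for {codon}")
                total += weight
            if total <= 0:
                raise ValueError(f"weights for {aa!r} are not normalizable")

    @classmethod
    def from_tsv(cls, path) -> "CodonUsageTable":
        """Read a 3-column TSV: aa, codon, weight (``#`` comments allowed)."""
        entries: dict[str, list[tuple[str, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                aa, codon, weight = line.split("\t")
                entries.setdefault(aa, []).append((codon.upper(), float(weight)))
        return cls(entries)

    def probabilities(self, aa: str, min_weight: float = 0.0) -> tuple[list[str], np.ndarray]:
        """Normalized codon probabilities for one amino acid.

        ``min_weight`` drops codons whose normalized frequency is below the
        floor (optional rare-codon filter; off by default).
        """
        if aa not in self.entries:
            raise UnknownResidueError(f"unknown residue {aa!r}")
        codons = [c for c, _ in self.entries[aa]]
        weights = np.array([w for _, w in self.entries[aa]], dtype=float)
        probs = weights / weights.sum()
        if min_weight > 0:
            keep = probs >= min_weight
            if not keep.any():
                raise DesignInfeasibleError(f"min_weight filter removed all codons for {aa!r}")
            codons = [c for c, k in zip(codons, keep) if k]
            probs = probs[keep] / probs[keep].sum()
        return codons, probs


@lru_cache(maxsize=1)
def default_codon_table() -> CodonUsageTable:
    """The packaged E. coli K-12 codon-usage table."""
    path = resources.files("mulsec.data").joinpath("ecoli_k12_codon_usage.tsv")
    with resources.as_file(path) as p:
        return CodonUsageTable.from_tsv(p)


@dataclass(frozen=True)
class OptimizationConfig:
    forbidden_motifs: tuple[str, ...] = DEFAULT_FORBIDDEN_MOTIFS
    seed: int = 0
    max_attempts: int = 100
    strip_stop: bool = True
    both_strands: bool = True
    min_weight: float = 0.0

    def __post_init__(self):
        for m in self.forbidden_motifs:
            validate_dna(m, "forbidden motif")
            if len(m) < 4:
                raise ValueError(f"forbidden motif {m!r} shorter than 4 nt")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


def translate(orf: str) -> str:
    """Translate an ACGT ORF with the standard genetic code (stop -> ``*``)."""
    validate_dna(orf, "ORF")
    if len(orf) % 3 != 0:
        raise MalformedSequenceError("ORF length is not a multiple of 3")
    return "".join(GENETIC_CODE[orf[i : i + 3]] for i in range(0, len(orf), 3))


def scan_motifs(
    seq: str, motifs: Sequence[str], both_strands: bool = False
) -> list[tuple[int, str]]:
    """All exact (overlapping) motif occurrences as sorted (position, motif).

    Positions are 0-based on *seq*. With ``both_strands`` the reverse
    complement of each motif is scanned too; hits are still reported at
    their top-strand position under the original motif name.
    """
    hits: set[tuple[int, str]] = set()
    for motif in motifs:
        if not motif:
            raise ValueError("motifs must be non-empty")
        targets = {motif.upper()}
        if both_strands:
            targets.add(revcomp(motif.upper()))
        for target in targets:
            start = seq.find(target)
            while start != -1:
                hits.add((start, motif))
                start = seq.find(target, start + 1)
    return sorted(hits)


def reverse_translate(
    protein: str,
    table: CodonUsageTable | None = None,
    config: OptimizationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Reverse-translate *protein* into a motif-free, usage-weighted ORF.

    Deterministic for a fixed (protein, table, seed). Raises
    :class:`DesignInfeasibleError` rather than ever returning a sequence
    containing a forbidden motif.
    """
    table = table or default_codon_table()
    config = config or OptimizationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    if config.strip_stop:
        protein = protein.rstrip("*")
    if not protein:
        raise MalformedSequenceError("protein is empty")
    if "*" in protein[:-1] and config.strip_stop:
        raise MalformedSequenceError("internal stop in protein")

    choices = {aa: table.probabilities(aa, config.min_weight) for aa in set(protein)}

    def draw(aa: str) -> str:
        codons, probs = choices[aa]
        return codons[rng.choice(len(codons), p=probs)]

    codons = [draw(aa) for aa in protein]
    motif_len = max(len(m) for m in config.forbidden_motifs)
    for _ in range(config.max_attempts):
        seq = "".join(codons)
        hits = scan_motifs(seq, config.forbidden_motifs, config.both_strands)
        if not hits:
            return seq
        resample: set[int] = set()
        for pos, motif in hits:
            first = pos // 3
            last = (pos + max(len(motif), motif_len) - 1) // 3
            resample.update(range(first, min(last + 1, len(codons))))
        for idx in sorted(resample):
            codons[idx] = draw(protein[idx])
    raise DesignInfeasibleError(
        f"no motif-free design found within {config.max_attempts} attempts"
    )
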