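"""Small DNA string utilities shared across modules."""

from __future__ import annotations

from .errors import MalformedSequenceError

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def validate_dna(seq: str, name: str = "sequence") -> None:
    """Raise MalformedSequenceError unless *seq* is uppercase ACGT only."""
    if not set(seq) <= set(DNA_BASES):
        bad = sorted(set(seq) - set(DNA_BASES))
        raise MalformedSequenceError(f"{name} contains non-ACGT characters: {bad}")


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run."""
    best = 0
    run = 0
    prev = ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best


def longest_common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i
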