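"""Synthetic inputs with ground truth: proteins, selection, reads.

Three generators mirror the stages of a pooled solubility-selection
screen:

* :func:`random_proteins` — uniform-residue test proteins (leading Met);
* :func:`simulate_selection` — survival on ampicillin modeled as a
  logistic weight in each gene's solubility score,
  w_g(a) = 1 / (1 + exp(−k · (s_g − θ(a)))), with θ non-decreasing in
  the ampicillin level; post-selection abundances are the renormalized
  product of initial abundance and survival weight, optionally resampled
  binomially at a finite depth;
* :func:`simulate_reads` — random plasmid fragmentation: each read picks
  a gene by abundance, a uniform start, a uniform strand; emitted as
  FASTQ and/or a truth-bearing SAM (correct names/positions/CIGAR) so the
  quantifier can be exercised without an aligner.

All outputs are bit-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from ._seq import revcomp
from .assembly import ErrorModel, mutate_sequence
from .errors import MulsecError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_proteins(
    n: int,
    length_range: tuple[int, int] = (120, 200),
    seed: int = 0,
) -> list[tuple[str, str]]:
    """n random proteins with uniform residues and an enforced leading Met."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo < 10:
        raise ValueError("proteins must be at least 10 aa")
    rng = np.random.default_rng(seed)
    residues = np.array(list(AMINO_ACIDS))
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(residues, size=length - 1))
        out.append((f"gene{i:03d}", "M" + body))
    return out


@dataclass(frozen=True)
class SelectionModel:
    """Logistic solubility->survival map per ampicillin level."""

    amp_levels: tuple[float, ...]
    thresholds: tuple[float, ...]  # solubility score at half-survival, per level
    steepness: float = 10.0

    def __post_init__(self):
        if len(self.amp_levels) != len(self.thresholds):
            raise ValueError("one threshold per ampicillin level")
        if any(b < a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be non-decreasing in ampicillin")
        if not self.steepness > 0:
            raise ValueError("steepness must be > 0")

    def survival(self, solubility: np.ndarray, level_index: int) -> np.ndarray:
        s = np.asarray(solubility, dtype=float)
        theta = self.thresholds[level_index]
        if np.isinf(self.steepness):  # step-function limit
            return np.where(s > theta, 1.0, np.where(s < theta, 0.0, 0.5))
        return 1.0 / (1.0 + np.exp(-self.steepness * (s - theta)))


@dataclass
class GenePool:
    """Genes with solubility scores and initial pool abundances."""

    genes: list[tuple[str, str, float]]  # (gene_id, sequence, solubility in [0,1])
    abundance: dict[str, float]

    def __post_init__(self):
        for _, _, s in self.genes:
            if not 0 <= s <= 1:
                raise ValueError("solubility scores must be in [0, 1]")
        total = sum(self.abundance.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("abundances must sum to 1")


def simulate_selection(
    pool: GenePool,
    model: SelectionModel,
    seed: int = 0,
    depth: int | None = None,
) -> dict[float, dict[str, float]]:
    """Post-selection abundance per ampicillin level.

    With ``depth`` set, the renormalized fractions are resampled as a
    multinomial of that many survivors (sampling noise); otherwise the
    closed-form renormalized product is returned.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g for g, _, _ in pool.genes]
    sol = np.array([s for _, _, s in pool.genes])
    init = np.array([pool.abundance[g] for g in gene_ids])
    out: dict[float, dict[str, float]] = {}
    for li, level in enumerate(model.amp_levels):
        w = model.survival(sol, li)
        post = init * w
        total = post.sum()
        if total <= 0:
            out[level] = {g: 0.0 for g in gene_ids}
            continue
        post = post / total
        if depth is not None:
            counts = rng.multinomial(depth, post)
            post = counts / depth
        out[level] = dict(zip(gene_ids, post.astype(float)))
    return out


def simulate_reads(
    references: Mapping[str, str],
    abundances: Mapping[str, float],
    n_reads: int,
    read_length: int = 150,
    seed: int = 0,
    sam_path=None,
    fastq_path=None,
    error_model: ErrorModel | None = None,
) -> pd.DataFrame:
    """Randomly fragmented single-end reads with per-gene ground truth.

    Returns a truth table (gene_id, true_fraction, read_count). Reads are
    error-free unless an ``error_model`` is given (errors affect FASTQ
    sequences only; SAM records keep truth coordinates and a full-match
    CIGAR for direct quantifier ingestion).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    gene_ids = sorted(references)
    for g in gene_ids:
        if read_length >= len(references[g]):
            raise MulsecError(f"read longer than reference {g!r}")
    rng = np.random.default_rng(seed)
    p = np.array([abundances.get(g, 0.0) for g in gene_ids], dtype=float)
    if p.sum() <= 0:
        raise MulsecError("abundances sum to zero")
    p = p / p.sum()
    counts = rng.multinomial(n_reads, p)

    sam = None
    if sam_path is not None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": g, "LN": len(references[g])} for g in gene_ids],
        }
        sam = pysam.AlignmentFile(str(sam_path), "w", header=header)
    fastq = open(fastq_path, "w") if fastq_path is not None else None

    try:
        read_no = 0
        for gi, gene in enumerate(gene_ids):
            ref = references[gene]
            c = int(counts[gi])
            if c == 0:
                continue
            starts = rng.integers(0, len(ref) - read_length + 1, size=c)
            strands = rng.integers(0, 2, size=c)
            for start, minus in zip(starts, strands):
                read_no += 1
                name = f"read{read_no:07d}"
                fragment = ref[start : start + read_length]
                if sam is not None:
                    rec = pysam.AlignedSegment(sam.header)
                    rec.query_name = name
                    rec.flag = 16 if minus else 0
                    rec.reference_id = gi
                    rec.reference_start = int(start)
                    rec.mapping_quality = 60
                    rec.cigarstring = f"{read_length}M"
                    rec.query_sequence = fragment
                    sam.write(rec)
                if fastq is not None:
                    seq = revcomp(fragment) if minus else fragment
                    if error_model is not None:
                        seq = mutate_sequence(seq, error_model, rng=rng)
                    fastq.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    finally:
        if sam is not None:
            sam.close()
        if fastq is not None:
            fastq.close()

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_fraction": p,
            "read_count": counts,
        }
    )
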