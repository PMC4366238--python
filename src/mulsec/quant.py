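"""Per-gene representation from pooled-selection sequencing coverage.

Reads from each ampicillin pool are aligned to the gene references; the
per-gene representation score is the **median of per-base coverage over
all reference positions** (zeros included, so partial gene fragments are
penalized), pool-normalized by dividing by the sum of medians in that
pool. A gene "passes" a pool when its normalized fraction is at least the
cutoff (default 0.05%). Enrichment between two ampicillin conditions is
the ratio of a gene's fractions; a zero denominator is a dropout, never
infinity. Small derived statistics used when interpreting such screens
(confusion rates, soluble fraction, fold killing) live here too.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from numbers import Real
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import DropoutError, EmptyPoolError, MulsecError, UnknownReferenceError

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.0005  # "median reads per gene >= 0.05% of pool total"


@dataclass
class CoverageProfile:
    """Per-base read depth over one gene reference."""

    gene_id: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def length(self) -> int:
        return int(self.counts.size)


def coverage_from_alignments(
    alignments,
    references: Mapping[str, int] | None = None,
    include_secondary: bool = False,
) -> dict[str, CoverageProfile]:
    """Per-base coverage from a SAM file (path or open AlignmentFile).

    Each aligned base (CIGAR match/mismatch) increments its reference
    position; deletions, skips and clips do not. Unmapped records are
    skipped; secondary/supplementary records are excluded by default.
    ``references`` (name -> length) restricts and orders the output;
    otherwise the SAM header defines the reference set. An aligned record
    naming an unknown reference raises :class:`UnknownReferenceError`;
    malformed records are skipped with a logged warning count.
    """
    own = isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__")
    af = pysam.AlignmentFile(str(alignments), "r") if own else alignments
    try:
        lengths = dict(
            references
            if references is not None
            else zip(af.references, af.lengths)
        )
        profiles = {name: np.zeros(length, dtype=np.int64) for name, length in lengths.items()}
        skipped = 0
        for read in af:
            if read.is_unmapped:
                continue
            if not include_secondary and (read.is_secondary or read.is_supplementary):
                continue
            name = read.reference_name
            if name not in profiles:
                raise UnknownReferenceError(f"unknown reference {name!r}")
            try:
                positions = read.get_reference_positions()
            except (ValueError, TypeError):
                skipped += 1
                continue
            np.add.at(profiles[name], positions, 1)
        if skipped:
            logger.warning("skipped %d malformed alignment records", skipped)
    finally:
        if own:
            af.close()
    return {name: CoverageProfile(name, arr) for name, arr in profiles.items()}


def read_pileup_tsv(path, lengths: Mapping[str, int] | None = None) -> dict[str, CoverageProfile]:
    """Read a pileup-like TSV (gene_id, pos, depth; 0-based positions)."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["gene_id", "pos", "depth"], header=None)
    if df.empty:
        raise EmptyPoolError("pileup table is empty")
    profiles = {}
    for gene, sub in df.groupby("gene_id", sort=True):
        n = lengths[gene] if lengths else int(sub["pos"].max()) + 1
        arr = np.zeros(n, dtype=np.int64)
        arr[sub["pos"].to_numpy()] = sub["depth"].to_numpy()
        profiles[gene] = CoverageProfile(str(gene), arr)
    return profiles


def read_median_tsv(path) -> dict[str, float]:
    """Read a per-gene median table (gene_id, median)."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["gene_id", "median"], header=None)
    return {str(g): float(m) for g, m in zip(df["gene_id"], df["median"])}


def median_coverage(profile: CoverageProfile, nonzero_only: bool = False) -> float:
    """Median depth over all reference positions (zeros included by default)."""
    if profile.length < 1:
        raise EmptyPoolError("empty profile")
    counts = profile.counts
    if nonzero_only:
        counts = counts[counts > 0]
        if counts.size == 0:
            return 0.0
    return float(np.median(counts))


def normalize_pool(medians: Mapping[str, float]) -> dict[str, float]:
    """fraction_g = median_g / Σ medians; fractions sum to 1 within 1e-9."""
    if not medians:
        raise EmptyPoolError("no genes in pool")
    total = float(sum(medians.values()))
    if total <= 0:
        raise EmptyPoolError("all-zero pool")
    return {gene: m / total for gene, m in medians.items()}


def apply_cutoff(fractions: Mapping[str, float], threshold: float = DEFAULT_CUTOFF) -> set[str]:
    """Genes whose pool fraction is >= threshold (inclusive)."""
    return {gene for gene, f in fractions.items() if f >= threshold}


def enrichment(fraction_high: float, fraction_low: float) -> float:
    """Fold change between two conditions; zero denominator is a dropout."""
    if fraction_low == 0:
        raise DropoutError("gene absent in the low condition (dropout)")
    if fraction_low < 0 or fraction_high < 0:
        raise ValueError("fractions must be >= 0")
    return fraction_high / fraction_low


def enrichment_table(
    fractions_high: Mapping[str, float], fractions_low: Mapping[str, float]
) -> pd.DataFrame:
    """Per-gene fold change; dropouts get status 'dropout' and NaN fold."""
    rows = []
    for gene in sorted(set(fractions_high) | set(fractions_low)):
        hi = fractions_high.get(gene, 0.0)
        lo = fractions_low.get(gene, 0.0)
        try:
            fold, status = enrichment(hi, lo), "ok"
        except DropoutError:
            fold, status = math.nan, "dropout"
        rows.append((gene, lo, hi, fold, status))
    return pd.DataFrame(
        rows, columns=["gene_id", "fraction_low", "fraction_high", "fold", "status"]
    )


def confusion_stats(predicted_positive: set, observed_positive: set) -> dict[str, float]:
    """True-positive / false-negative rates (percent) of a prediction set
    against an observed positive set."""
    if not observed_positive:
        raise MulsecError("undefined rates: observed set is empty")
    tp = 100.0 * len(set(predicted_positive) & set(observed_positive)) / len(observed_positive)
    return {"tp_rate": tp, "fn_rate": 100.0 - tp}


def soluble_fraction(soluble_intensity: float, insoluble_intensity: float) -> float:
    """s / (s + i): fraction of protein in the soluble lysate fraction."""
    if soluble_intensity < 0 or insoluble_intensity < 0:
        raise ValueError("intensities must be >= 0")
    total = soluble_intensity + insoluble_intensity
    if total == 0:
        raise MulsecError("no signal")
    return soluble_intensity / total


def fold_killing(count_no_amp: Real, count_amp: Real) -> float:
    """Viable colonies without ampicillin ÷ colonies at 100 µg/mL.

    A zero selected count returns ``inf`` (report as '> count_no_amp', a
    censored value); a zero control count is a failed experiment.
    """
    if count_no_amp == 0:
        raise MulsecError("no growth control failure")
    if count_amp == 0:
        return math.inf
    return count_no_amp / count_amp


@dataclass
class PoolQuant:
    """Per-pool gene representation after selection at one ampicillin level."""

    pool_id: str
    ampicillin: float  # µg/mL, metadata
    medians: dict[str, float]
    fractions: dict[str, float] = field(default_factory=dict)
    cutoff: float = DEFAULT_CUTOFF
    passing: set[str] = field(default_factory=set)

    @classmethod
    def from_medians(
        cls, pool_id: str, ampicillin: float, medians: Mapping[str, float],
        cutoff: float = DEFAULT_CUTOFF,
    ) -> "PoolQuant":
        fractions = normalize_pool(medians)
        return cls(
            pool_id=pool_id,
            ampicillin=ampicillin,
            medians=dict(medians),
            fractions=fractions,
            cutoff=cutoff,
            passing=apply_cutoff(fractions, cutoff),
        )

    @property
    def detected(self) -> set[str]:
        return {g for g, m in self.medians.items() if m > 0}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, self.medians[g], self.fractions[g], g in self.passing)
            for g in sorted(self.medians)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "median", "fraction", "pass"])


def quantify_pool(
    profiles: Mapping[str, CoverageProfile],
    pool_id: str = "pool",
    ampicillin: float = float("nan"),
    cutoff: float = DEFAULT_CUTOFF,
    nonzero_only: bool = False,
) -> PoolQuant:
    medians = {g: median_coverage(p, nonzero_only) for g, p in profiles.items()}
    return PoolQuant.from_medians(pool_id, ampicillin, medians, cutoff)


def pool_summary(quants: Sequence[PoolQuant]) -> pd.DataFrame:
    """Per-pool table: genes detected, genes passing the cutoff, median
    fraction of passing genes, and 1.5×IQR outliers among passing genes."""
    if not quants:
        raise ValueError("need at least one pool")
    rows = []
    for q in quants:
        passing = sorted(q.passing)
        fracs = np.array([q.fractions[g] for g in passing])
        if fracs.size:
            med = float(np.median(fracs))
            q1, q3 = np.percentile(fracs, [25, 75])
            iqr = q3 - q1
            outliers = [
                g for g, f in zip(passing, fracs)
                if f < q1 - 1.5 * iqr or f > q3 + 1.5 * iqr
            ]
        else:
            med, outliers = math.nan, []
        rows.append(
            (q.pool_id, q.ampicillin, len(q.medians), len(q.detected),
             len(passing), med, ",".join(outliers))
        )
    return pd.DataFrame(
        rows,
        columns=["pool_id", "ampicillin", "n_genes", "n_detected",
                 "n_passing", "median_fraction_passing", "outliers"],
    )
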