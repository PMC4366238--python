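"""DNA duplex melting-temperature models.

Two models are provided:

* ``nearest_neighbor`` — the unified dinucleotide stacking model,
  Tm = 1000·ΔH° / (ΔS° + ΔS_salt + R·ln(C_T/x)) − 273.15,
  with ΔH° in kcal/mol, ΔS° in cal/(mol·K), R = 1.987 cal/(mol·K),
  the monovalent-salt entropy correction ΔS_salt = 0.368·(N−1)·ln[Na⁺],
  total strand concentration C_T (default 0.25 µM) and x = 4 for
  non-self-complementary duplexes. Parameters live in
  ``data/nn_unified_dna.tsv``, not in code.
* ``wallace`` — the 2·(A+T) + 4·(G+C) rule of thumb.

The ligation-assembly designer scores every overlap with the
nearest-neighbor model; Wallace is kept as a cheap cross-check.
"""

from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources

from ._seq import revcomp, validate_dna
from .errors import MalformedSequenceError

GAS_CONSTANT = 1.987  # cal/(mol*K)

DEFAULT_CT = 0.25e-6  # total strand concentration, M
DEFAULT_NA = 0.05  # monovalent cation concentration, M
DEFAULT_X = 4.0  # duplex formation factor for non-self-complementary strands


@lru_cache(maxsize=1)
def nn_parameters() -> tuple[dict[str, tuple[float, float]], dict[str, tuple[float, float]], tuple[float, float]]:
    """Load (steps, initiation, symmetry) parameter tables from package data.

    ``steps`` maps all 16 dinucleotides (a step's parameters equal those of
    its reverse complement); ``initiation`` maps terminal base -> (dH, dS).
    """
    raw: dict[str, tuple[float, float]] = {}
    path = resources.files("mulsec.data").joinpath("nn_unified_dna.tsv")
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, dh, ds = line.split("\t")
        raw[key] = (float(dh), float(ds))
    steps: dict[str, tuple[float, float]] = {}
    for key, val in raw.items():
        if len(key) == 2 and not key.startswith("init"):
            steps[key] = val
            steps[revcomp(key)] = val
    init = {
        "A": raw["init_A"], "T": raw["init_A"],
        "G": raw["init_G"], "C": raw["init_G"],
    }
    return steps, init, raw["sym"]


def tm_wallace(seq: str) -> float:
    """Wallace rule: 2 °C per A/T, 4 °C per G/C."""
    validate_dna(seq, "duplex")
    if len(seq) < 2:
        raise MalformedSequenceError("duplex must be at least 2 nt")
    s = seq.upper()
    at = s.count("A") + s.count("T")
    gc = s.count("G") + s.count("C")
    return 2.0 * at + 4.0 * gc


def tm_nearest_neighbor(
    seq: str,
    ct: float = DEFAULT_CT,
    na: float = DEFAULT_NA,
    x: float = DEFAULT_X,
) -> float:
    """Unified nearest-neighbor Tm (°C) with monovalent-salt correction."""
    validate_dna(seq, "duplex")
    if len(seq) < 2:
        raise MalformedSequenceError("duplex must be at least 2 nt")
    steps, init, sym = nn_parameters()
    dh = init[seq[0]][0] + init[seq[-1]][0]
    ds = init[seq[0]][1] + init[seq[-1]][1]
    for i in range(len(seq) - 1):
        sh, ss = steps[seq[i : i + 2]]
        dh += sh
        ds += ss
    if seq == revcomp(seq):  # self-complementary duplex
        dh += sym[0]
        ds += sym[1]
        x = 1.0
    ds_salt = ds + 0.368 * (len(seq) - 1) * math.log(na)
    return 1000.0 * dh / (ds_salt + GAS_CONSTANT * math.log(ct / x)) - 273.15


def compute_tm(seq: str, model: str = "nearest_neighbor", **params) -> float:
    """Dispatch to a Tm model by name (``nearest_neighbor`` or ``wallace``)."""
    if model == "nearest_neighbor":
        return tm_nearest_neighbor(seq, **params)
    if model == "wallace":
        return tm_wallace(seq)
    raise ValueError(f"unknown Tm model: {model!r}")


class TmPrefix:
    """O(1) nearest-neighbor Tm of any slice of a fixed sequence.

    Precomputes cumulative stacking sums so the tiler can score thousands
    of candidate overlaps cheaply. Slices are assumed (and asserted in
    tests) to agree with :func:`tm_nearest_neighbor` for the common
    non-self-complementary case; self-complementary slices fall back to
    the scalar routine.
    """

    def __init__(self, seq: str, ct: float = DEFAULT_CT, na: float = DEFAULT_NA, x: float = DEFAULT_X):
        validate_dna(seq, "sequence")
        self.seq = seq
        self.ct = ct
        self.na = na
        self.x = x
        steps, self._init, _ = nn_parameters()
        n = len(seq)
        self._dh = [0.0] * n
        self._ds = [0.0] * n
        for i in range(n - 1):
            sh, ss = steps[seq[i : i + 2]]
            self._dh[i + 1] = self._dh[i] + sh
            self._ds[i + 1] = self._ds[i] + ss
        self._logct = math.log(ct / x)
        self._logna = math.log(na)

    def tm(self, start: int, end: int) -> float:
        """Tm of ``seq[start:end]`` in °C."""
        sub = self.seq[start:end]
        if len(sub) < 2:
            raise MalformedSequenceError("duplex must be at least 2 nt")
        if sub == revcomp(sub):
            return tm_nearest_neighbor(sub, self.ct, self.na, self.x)
        dh = self._dh[end - 1] - self._dh[start]
        ds = self._ds[end - 1] - self._ds[start]
        dh += self._init[sub[0]][0] + self._init[sub[-1]][0]
        ds += self._init[sub[0]][1] + self._init[sub[-1]][1]
        n = end - start
        ds_salt = ds + 0.368 * (n - 1) * self._logna
        return 1000.0 * dh / (ds_salt + GAS_CONSTANT * self._logct) - 273.15
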