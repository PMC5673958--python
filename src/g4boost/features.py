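"""Sequence feature digestion for PQS stability modelling.

Each PQS plus its 50-nt flanks is digested into 209 features:

* 3 x 67 composition features — for each of the three segments (the PQS
  itself, prefix ``G4``; the 5'-flank, prefix ``5f``; the 3'-flank,
  prefix ``3f``) the 64 overlapping-triad counts AAA..TTT plus 3
  singleton counts (G, C, A; T is the linearly dependent fourth given
  the segment length);
* 5 topology features — overall PQS length, number of loops (more than
  3 is possible under the extended merged-motif definition) and the
  lengths of the first three loops 5'->3';
* 3 energy features — ensemble-averaged hairpin folding free energies
  (kcal/mol) of the first three loop sequences, looked up from an
  energy table covering 5-12-nt loops (shorter loops score 0).

Feature values are median-centred and SD-scaled with parameters learned
on training data only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import PQSHit

BASES = "ACGT"
TRIADS = ["".join(t) for t in itertools.product(BASES, repeat=3)]
SINGLETONS = ["G", "C", "A"]
SEGMENT_PREFIXES = ["G4", "5f", "3f"]

TOPOLOGY_FEATURES = ["G4_length", "G4_numlps", "G4_lp1len", "G4_lp2len", "G4_lp3len"]
ENERGY_FEATURES = ["G4_lp1efe", "G4_lp2efe", "G4_lp3efe"]

FEATURE_NAMES: list[str] = (
    [f"{p}_{k}" for p in SEGMENT_PREFIXES for k in TRIADS + SINGLETONS]
    + TOPOLOGY_FEATURES
    + ENERGY_FEATURES
)
N_FEATURES = len(FEATURE_NAMES)  # 209

_BASE_CODE = {b: i for i, b in enumerate(BASES)}

ENERGY_LEN_MIN = 5
ENERGY_LEN_MAX = 12


def count_triads_sliding(segment: str) -> np.ndarray:
    """Count all 64 triads with a sliding (overlapping) window.

    Overlapping occurrences each count, so e.g. ``GGGG`` contributes 2
    to the GGG count.  Windows containing a non-ACGT character are
    skipped.  The total over all triads equals ``max(0, len - 2)`` for
    N-free segments.
    """
    counts = np.zeros(64, dtype=np.int64)
    if len(segment) < 3:
        return counts
    codes = np.array([_BASE_CODE.get(c, -1) for c in segment], dtype=np.int64)
    idx = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
    valid = (codes[:-2] >= 0) & (codes[1:-1] >= 0) & (codes[2:] >= 0)
    np.add.at(counts, idx[valid], 1)
    return counts


def count_singletons(segment: str) -> np.ndarray:
    """Counts of G, C and A (T is implied by the segment length)."""
    return np.array([segment.count(b) for b in SINGLETONS], dtype=np.int64)


# ---------------------------------------------------------------------------
# Loop-energy engines and look-up table


class ViennaEnergyEngine:
    """Ensemble folding free energy via the ViennaRNA partition function
    with DNA (Mathews 2004) parameters at 37 C."""

    provenance = "ViennaRNA pf, DNA Mathews2004, 37C"

    def __init__(self) -> None:
        import RNA  # deferred: heavy import

        RNA.params_load_DNA_Mathews2004()
        self._RNA = RNA
        self._md = RNA.md()
        self._md.temperature = 37.0

    def __call__(self, sequence: str) -> float:
        fc = self._RNA.fold_compound(sequence, self._md)
        _, dg = fc.pf()
        return float(dg)


class StackingHairpinEngine:
    """Non-canonical fallback: a Nussinov-style dynamic programme with a
    crude base-pair stacking score, mapped onto a kcal/mol-like scale.

    This is a bundled approximation, not a partition-function
    thermodynamic model; it preserves the qualitative ordering (more
    self-complementary loops score lower/more negative) and scores
    unstructured sequences 0.
    """

    provenance = "bundled Nussinov-style stacking approximation"

    _PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    _PAIR_E = {("G", "C"): -2.2, ("C", "G"): -2.2, ("A", "T"): -1.1, ("T", "A"): -1.1}
    _MIN_HAIRPIN = 3  # minimum unpaired span inside a hairpin loop

    def __call__(self, sequence: str) -> float:
        n = len(sequence)
        best = np.zeros((n, n))
        for span in range(self._MIN_HAIRPIN + 1, n):
            for i in range(0, n - span):
                j = i + span
                e = best[i + 1][j - 1] + self._PAIR_E.get(
                    (sequence[i], sequence[j]), np.inf
                )
                e = min(e, best[i + 1][j], best[i][j - 1])
                for k in range(i + 1, j):
                    e = min(e, best[i][k] + best[k + 1][j])
                best[i][j] = min(0.0, e)
        return float(best[0][n - 1])


def default_energy_engine():
    """ViennaRNA when importable, otherwise the bundled approximation."""
    try:
        return ViennaEnergyEngine()
    except ImportError:  # pragma: no cover - exercised only without ViennaRNA
        return StackingHairpinEngine()


@dataclass
class EnergyTable:
    """Memoized loop-sequence -> folding free energy (kcal/mol) table.

    The table addresses loops of ``len_min``..``len_max`` nt; the full
    [5, 12] table has sum(4^i) = 22,369,280 key slots and is only ever
    filled lazily or by an explicit offline build.
    """

    engine: object
    len_min: int = ENERGY_LEN_MIN
    len_max: int = ENERGY_LEN_MAX
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.len_min > self.len_max:
            raise ValueError("len_min must not exceed len_max")

    @property
    def n_slots(self) -> int:
        return sum(4**i for i in range(self.len_min, self.len_max + 1))

    @property
    def provenance(self) -> str:
        return getattr(self.engine, "provenance", type(self.engine).__name__)

    def energy(self, loop: str) -> float:
        """Energy of one loop; loops shorter than ``len_min`` score 0."""
        if len(loop) > self.len_max:
            raise ValueError(f"loop longer than table range: {loop!r}")
        if len(loop) < self.len_min:
            return 0.0
        if loop not in self._cache:
            try:
                self._cache[loop] = float(self.engine(loop))
            except Exception as exc:
                raise RuntimeError(f"energy engine failed on loop {loop!r}") from exc
        return self._cache[loop]

    def fill(self) -> None:
        """Explicitly compute every slot (hours of CPU for the full
        [5, 12] table; intended as an offline build)."""
        for k in range(self.len_min, self.len_max + 1):
            for t in itertools.product(BASES, repeat=k):
                self.energy("".join(t))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#engine\t{self.provenance}\n")
            fh.write(f"#range\t{self.len_min}\t{self.len_max}\n")
            for k in sorted(self._cache):
                fh.write(f"{k}\t{self._cache[k]:.6f}\n")

    @classmethod
    def load(cls, path, engine=None) -> "EnergyTable":
        provenance, len_min, len_max = None, ENERGY_LEN_MIN, ENERGY_LEN_MAX
        cache: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#engine"):
                    provenance = line.split("\t", 1)[1]
                elif line.startswith("#range"):
                    _, lo, hi = line.split("\t")
                    len_min, len_max = int(lo), int(hi)
                elif line:
                    seq, val = line.split("\t")
                    cache[seq] = float(val)
        table = cls(engine=engine or _FrozenEngine(provenance), len_min=len_min,
                    len_max=len_max)
        table._cache = cache
        return table


class _FrozenEngine:
    """Placeholder engine for tables loaded from disk; refuses to
    compute new entries."""

    def __init__(self, provenance):
        self.provenance = f"frozen: {provenance}"

    def __call__(self, sequence: str) -> float:
        raise RuntimeError("frozen energy table has no live engine")


def loop_energy(loop: str, engine_or_table) -> float:
    """Ensemble folding free energy (kcal/mol) of one loop sequence."""
    if isinstance(engine_or_table, EnergyTable):
        return engine_or_table.energy(loop)
    return EnergyTable(engine=engine_or_table).energy(loop)


def build_energy_table(
    len_min: int = ENERGY_LEN_MIN,
    len_max: int = ENERGY_LEN_MAX,
    engine=None,
    fill: bool = False,
) -> EnergyTable:
    """Create an energy table for loops of ``len_min``..``len_max`` nt.

    The table is lazy by default; pass ``fill=True`` to compute every
    slot up front (the full 5-12 table is an offline, hours-long build).
    """
    table = EnergyTable(engine=engine or default_energy_engine(),
                        len_min=len_min, len_max=len_max)
    if fill:
        table.fill()
    return table


# ---------------------------------------------------------------------------
# Feature extraction


def extract_features(hit: PQSHit, table: EnergyTable) -> pd.Series:
    """Digest one PQS (with flanks populated) into the 209 features.

    Loops beyond the third contribute only to ``G4_numlps``; a missing
    loop yields length 0 and energy 0.  The result is a named Series in
    canonical feature order; extraction is a pure function of the hit.
    """
    values: list[float] = []
    for segment in (hit.pqs_sequence, hit.flank5, hit.flank3):
        values.extend(count_triads_sliding(segment))
        values.extend(count_singletons(segment))

    loops = hit.loops
    lp_lens = [len(loops[i]) if i < len(loops) else 0 for i in range(3)]
    values.extend([len(hit.pqs_sequence), len(loops)] + lp_lens)
    for i in range(3):
        if i < len(loops) and len(loops[i]) >= table.len_min:
            values.append(table.energy(loops[i]))
        else:
            values.append(0.0)
    return pd.Series(values, index=FEATURE_NAMES, dtype=float)


def extract_feature_matrix(hits, table: EnergyTable) -> pd.DataFrame:
    """Feature rows for many hits, one per hit, in input order."""
    return pd.DataFrame(
        [extract_features(h, table) for h in hits], columns=FEATURE_NAMES
    )


# ---------------------------------------------------------------------------
# Median/SD scaling


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature median and standard deviation learned on training
    data; persisted with the trained model."""

    median: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if not self.median.index.equals(self.sd.index):
            raise ValueError("median/sd feature names differ")
        if (self.sd < 0).any():
            raise ValueError("negative standard deviation")

    @property
    def feature_names(self) -> list[str]:
        return list(self.median.index)

    def save(self, path) -> None:
        pd.DataFrame({"median": self.median, "sd": self.sd}).to_csv(
            path, sep="\t", index_label="feature"
        )

    @classmethod
    def load(cls, path) -> "ScalingParams":
        df = pd.read_csv(path, sep="\t", index_col="feature")
        return cls(median=df["median"], sd=df["sd"])


def fit_scaler(matrix: pd.DataFrame) -> ScalingParams:
    """Learn per-feature median and SD from a (training) feature
    matrix.  Fit on training rows only."""
    return ScalingParams(median=matrix.median(axis=0), sd=matrix.std(axis=0, ddof=1))


def apply_scaler(params: ScalingParams, data):
    """Centre by median and divide by SD; zero-SD features map to 0.

    Accepts a Series (one PQS) or DataFrame (many) whose feature names
    must match the scaler's.
    """
    names = (
        list(data.index) if isinstance(data, pd.Series) else list(data.columns)
    )
    if names != params.feature_names:
        raise ValueError("feature names do not match scaler parameters")
    sd = params.sd.replace(0.0, np.inf)  # zero-variance guard
    return (data - params.median) / sd


def reduce_features(data, selected: list[str]):
    """Project a feature Series/DataFrame onto an ordered subset of
    feature names (e.g. an importance-screened 119-name list)."""
    known = set(data.index if isinstance(data, pd.Series) else data.columns)
    unknown = [s for s in selected if s not in known]
    if unknown:
        raise KeyError(f"unknown feature names: {unknown}")
    if not selected:
        warnings.warn("empty feature selection produces an empty vector")
    return data[selected]
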