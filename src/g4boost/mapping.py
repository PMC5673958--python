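"""Mapping of per-bin mismatch-level (mm%) signal onto PQS hits.

G4-seq-style experiments report, per short genomic bin (typically
15 nt), the percentage of base mismatches caused by polymerase stalling
at G-quadruplexes; higher mm% indicates a more stable G4.  Because the
mismatch peak falls near — not necessarily on — the structure, each PQS
receives the *maximum* mm% over all bins overlapping the PQS plus its
50-nt flanks.  PQSs with another PQS inside their flanks share an
inflated peak and are excluded from training by the isolation filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .motifs import DEFAULT_FLANK_LEN, PQSHit

TRACK_COLUMNS = ["seq_name", "start", "end", "mm"]


@dataclass
class MismatchTrack:
    """Per-sequence sorted, mm%-valued intervals with fast overlap
    lookup (bedGraph-like; bins are typically 15 nt)."""

    _by_seq: dict = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MismatchTrack":
        if (df["end"] <= df["start"]).any() or (df["start"] < 0).any():
            raise ValueError("track intervals must be non-negative and non-empty")
        if not np.isfinite(df["mm"]).all():
            raise ValueError("mm% values must be finite")
        track = cls()
        for name, sub in df.groupby("seq_name", sort=False):
            sub = sub.sort_values("start", kind="mergesort")
            track._by_seq[name] = (
                sub["start"].to_numpy(dtype=np.int64),
                sub["end"].to_numpy(dtype=np.int64),
                sub["mm"].to_numpy(dtype=float),
            )
        return track

    def n_bins(self, seq_name: Optional[str] = None) -> int:
        if seq_name is not None:
            return len(self._by_seq.get(seq_name, ((),))[0])
        return sum(len(v[0]) for v in self._by_seq.values())

    def max_over(self, seq_name: str, start: int, end: int) -> float:
        """Maximum mm% over bins sharing >= 1 base with [start, end);
        NaN when nothing overlaps."""
        if seq_name not in self._by_seq:
            return np.nan
        starts, ends, values = self._by_seq[seq_name]
        mask = (ends > start) & (starts < end)
        if not mask.any():
            return np.nan
        return float(values[mask].max())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, (starts, ends, values) in self._by_seq.items():
            rows.append(
                pd.DataFrame(
                    {"seq_name": name, "start": starts, "end": ends, "mm": values}
                )
            )
        if not rows:
            return pd.DataFrame(columns=TRACK_COLUMNS)
        return pd.concat(rows, ignore_index=True)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_mm_track(path) -> MismatchTrack:
    """Read a 4-column (chrom, start, end, mm%) bedGraph-like text file.

    Unsorted input is sorted on load; malformed lines raise with their
    line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return MismatchTrack.from_frame(df)


@dataclass(frozen=True)
class MappedPQS:
    """A PQS hit with its assigned mm% (NaN when the site lacks
    coverage)."""

    hit: PQSHit
    mm: float

    @property
    def covered(self) -> bool:
        return not np.isnan(self.mm)


def assign_mm(
    hit: PQSHit, track: MismatchTrack, flank_len: int = DEFAULT_FLANK_LEN
) -> MappedPQS:
    """Assign one PQS the maximum mm% over bins overlapping the PQS
    plus ``flank_len``-nt flanks (>= 1 shared base); NaN without
    coverage."""
    mm = track.max_over(hit.seq_name, hit.start - flank_len, hit.end + flank_len)
    return MappedPQS(hit=hit, mm=mm)


def assign_mm_many(
    hits: Iterable[PQSHit], track: MismatchTrack, flank_len: int = DEFAULT_FLANK_LEN
) -> list[MappedPQS]:
    return [assign_mm(h, track, flank_len) for h in hits]


def filter_isolated(
    hits: list[PQSHit], flank_len: int = DEFAULT_FLANK_LEN
) -> list[PQSHit]:
    """Keep only PQSs with no other PQS (either strand, same sequence)
    within their ``flank_len``-nt flanks.

    A neighbour closer than ``flank_len`` shares the mismatch peak and
    inflates the signal, so *both* members of such a pair are dropped.
    The gap is measured between interval ends; a gap of exactly
    ``flank_len`` keeps both.  Idempotent.
    """
    by_seq: dict[str, list[int]] = {}
    for i, h in enumerate(hits):
        by_seq.setdefault(h.seq_name, []).append(i)
    keep = [True] * len(hits)
    for idx in by_seq.values():
        starts = np.array([hits[i].start for i in idx])
        ends = np.array([hits[i].end for i in idx])
        for k, i in enumerate(idx):
            # neighbours overlapping the hit's flank window (incl. itself)
            n_near = int(
                ((starts < ends[k] + flank_len) & (ends > starts[k] - flank_len)).sum()
            )
            keep[i] = n_near == 1
    return [h for h, k in zip(hits, keep) if k]


def copy_number_stats(
    mapped_hits: Iterable[MappedPQS],
    min_copies: int = 5,
    lowess_frac: float = 0.6,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Flank-effect analysis over repeated genomic copies of the same
    PQS sequence.

    Groups covered hits by their motif string, keeps groups with at
    least ``min_copies`` genomic copies (same G4, different flanks) and
    reports each group's mean and SD of mm%, plus a Lowess trend of SD
    against mean.  With fewer than 2 groups the trend is omitted with a
    warning.
    """
    rows = [
        {"pqs_sequence": m.hit.pqs_sequence, "mm": m.mm}
        for m in mapped_hits
        if m.covered
    ]
    df = pd.DataFrame(rows, columns=["pqs_sequence", "mm"])
    stats = (
        df.groupby("pqs_sequence")["mm"]
        .agg(n="size", mean_mm="mean", sd_mm="std")
        .reset_index()
    )
    stats = stats[stats["n"] >= min_copies].reset_index(drop=True)
    if len(stats) < 2:
        warnings.warn("fewer than 2 copy-number groups; Lowess trend omitted")
        return stats, None
    from statsmodels.nonparametric.smoothers_lowess import lowess

    smoothed = lowess(
        stats["sd_mm"], stats["mean_mm"], frac=lowess_frac, return_sorted=True
    )
    trend = pd.DataFrame(smoothed, columns=["mean_mm", "sd_trend"])
    return stats, trend


def mapped_to_table(mapped: Iterable[MappedPQS]) -> pd.DataFrame:
    """Hit table with an extra mm% column."""
    from .motifs import hits_to_table

    mapped = list(mapped)
    table = hits_to_table([m.hit for m in mapped])
    table["mm"] = [m.mm for m in mapped]
    return table
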