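"""Synthetic genomes with planted PQSs and matching mismatch tracks.

The generator emulates the study design end to end without any
download: a background sequence guaranteed free of G-tracts on either
strand, planted extended-PQS motifs of known tract/loop make-up on
random strands, and a binned mm% track whose peaks encode a bimodal
latent stability (a weak and a strong mode, echoing the two clusters
seen for genomic PQSs) plus a flank-sequence effect and Gaussian noise.

The latent mm% mean of a planted G4 is a declared function of its
tract lengths, loop lengths and flank G-content, so part of the signal
deliberately lives in flank features.  The flank-effect amplitude
shrinks above a knee mm% value, reproducing the decreasing SD-vs-mean
trend of repeated genomic copies.  Peak heights are clipped to
[0, 100], a mild nonlinearity the regressor must tolerate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .features import EnergyTable, build_energy_table, extract_feature_matrix
from .mapping import MismatchTrack, assign_mm_many, filter_isolated
from .motifs import (
    DEFAULT_FLANK_LEN,
    GenomicSequence,
    extract_flanks,
    find_pqs,
    revcomp,
)

TRUTH_COLUMNS = [
    "pqs_id", "seq_name", "start", "end", "strand", "pqs_sequence",
    "n_tracts", "total_tract_g", "mean_loop_len", "stability_class",
    "latent_mean", "flank_effect",
]

_FORBIDDEN = re.compile(r"GGG|CCC")


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic genome: the planted PQS records
    and the generator parameters that produced them."""

    records: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def threshold(self) -> float:
        """Midpoint between the two latent modes — the generator's own
        stable/weak operating point."""
        return 0.5 * (self.params["mode_weak"] + self.params["mode_strong"])

    def save(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _background(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    """Random DNA with no G-run or C-run of length >= 3 on the forward
    strand, hence no tract on either strand."""
    if n <= 0:
        return ""
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])
    while True:
        m = _FORBIDDEN.search(seq)
        if m is None:
            return seq
        swap = "T" if seq[m.start()] == "G" else "A"
        seq = seq[: m.start() + 1] + swap + seq[m.start() + 2 :]


def _plant_motif(
    rng: np.random.Generator, cls: str, p_extra_tract: float
) -> tuple[str, int, int, float]:
    """One extended PQS of the given stability class: returns (motif,
    n_tracts, total G in tracts, mean loop length).

    Stability is sequence-determined: "strong" motifs carry extended
    G-tracts (4-6 G) and short loops (1-3 nt), "weak" motifs minimal
    tracts (mostly 3 G) and long loops (4-7 nt).  Loops use {A, C, T}
    with C-runs capped at 2 so the reverse strand stays tract-free
    inside loops.
    """
    n_tracts = 5 if rng.random() < p_extra_tract else 4
    if cls == "strong":
        tract_lens = 3 + rng.choice([1, 2, 3], size=n_tracts, p=[0.5, 0.35, 0.15])
        loop_lens = rng.integers(1, 4, size=n_tracts - 1)
    else:
        tract_lens = 3 + rng.choice([0, 1], size=n_tracts, p=[0.85, 0.15])
        loop_lens = rng.integers(4, 8, size=n_tracts - 1)
    parts = []
    for i, tl in enumerate(tract_lens):
        parts.append("G" * int(tl))
        if i < n_tracts - 1:
            loop = "".join(
                np.array(list("ACT"))[rng.choice(3, size=int(loop_lens[i]))]
            )
            while "CCC" in loop:
                loop = loop.replace("CCC", "CAC", 1)
            parts.append(loop)
    motif = "".join(parts)
    return motif, n_tracts, int(tract_lens.sum()), float(loop_lens.mean())


def generate_genome(
    n_pqs: int,
    length: int,
    composition: Optional[dict] = None,
    seed: int = 0,
    spacing: int = 130,
    seq_name: str = "synth",
    p_strong: float = 0.5,
    p_extra_tract: float = 0.1,
    mode_weak: float = 8.0,
    mode_strong: float = 40.0,
    flank_amp_weak: float = 3.0,
    flank_amp_strong: float = 1.0,
    knee: float = 20.0,
    copy_groups: int = 0,
    copies_per_group: int = 6,
) -> tuple[GenomicSequence, SyntheticTruth]:
    """Build a genome of ``length`` nt with ``n_pqs`` planted PQSs.

    The background between motifs carries no G3+/C3+ run, planted
    motifs are separated by at least ``spacing`` nt (default 130 keeps
    every motif isolated under the 50-nt flank rule), and strands are
    assigned at random.  When ``copy_groups`` > 0 the first
    ``copy_groups * copies_per_group`` plants reuse shared motif
    strings (same G4, different flanks) for copy-number analyses.
    Deterministic per seed; raises when the motifs cannot be packed
    into ``length`` at the requested spacing.
    """
    rng = np.random.default_rng(seed)
    composition = composition or {"A": 0.3, "C": 0.25, "G": 0.2, "T": 0.25}
    probs = np.array([composition[b] for b in "ACGT"], dtype=float)
    probs = probs / probs.sum()

    # -- draw motif records (copy groups first, then singletons)
    motifs: list[tuple[str, int, int, float, str]] = []  # + class
    group_defs = []
    for _ in range(copy_groups):
        cls = "strong" if rng.random() < p_strong else "weak"
        group_defs.append((_plant_motif(rng, cls, p_extra_tract), cls))
    for g in range(copy_groups):
        for _ in range(copies_per_group):
            motifs.append((*group_defs[g][0], group_defs[g][1]))
    if len(motifs) > n_pqs:
        raise ValueError("copy_groups * copies_per_group exceeds n_pqs")
    while len(motifs) < n_pqs:
        cls = "strong" if rng.random() < p_strong else "weak"
        motifs.append((*_plant_motif(rng, cls, p_extra_tract), cls))

    # latent mm% is a declared function of the realized sequence:
    # base + slope * excess tract G - penalty * (mean loop len - 1),
    # calibrated so the class-typical motifs sit at the two modes
    # class expectations: weak  E[excess G] = 0.6, E[mean loop] = 5.5
    #                     strong E[excess G] = 6.6, E[mean loop] = 2.0
    loop_penalty = 0.8
    g_slope = (mode_strong - mode_weak - loop_penalty * (5.5 - 2.0)) / (6.6 - 0.6)
    base = mode_weak - g_slope * 0.6 + loop_penalty * 4.5

    total_motif = sum(len(m[0]) for m in motifs)
    gap = (length - total_motif) // (n_pqs + 1) if n_pqs else length
    if n_pqs and gap < spacing:
        raise ValueError(
            f"cannot pack {n_pqs} motifs into {length} nt at spacing {spacing}"
        )

    # -- assemble; boundary bases of every gap forced to A/T so planted
    #    tracts can neither extend nor chain into the background
    pieces: list[str] = []
    records = []
    pos = 0
    order = rng.permutation(n_pqs) if n_pqs else np.array([], dtype=int)
    for k in range(n_pqs):
        block = _background(rng, gap, probs)
        block = "T" + block[1:-1] + "A" if len(block) >= 2 else "TA"[: len(block)]
        pieces.append(block)
        pos += len(block)
        motif, n_tracts, total_g, mean_loop, cls = motifs[order[k]]
        strand = "+" if rng.random() < 0.5 else "-"
        planted = motif if strand == "+" else revcomp(motif)
        latent = base + g_slope * (total_g - 3 * n_tracts) \
            - loop_penalty * (mean_loop - 1.0)
        records.append(
            {
                "pqs_id": k,
                "seq_name": seq_name,
                "start": pos,
                "end": pos + len(planted),
                "strand": strand,
                "pqs_sequence": motif,
                "n_tracts": n_tracts,
                "total_tract_g": total_g,
                "mean_loop_len": mean_loop,
                "stability_class": cls,
                "latent_mean": float(np.clip(latent, 2.0, 95.0)),
            }
        )
        pieces.append(planted)
        pos += len(planted)
    tail = length - pos
    block = _background(rng, tail, probs)
    if n_pqs and len(block) >= 1:
        block = "T" + block[1:]
    pieces.append(block)
    residues = "".join(pieces)
    genome = GenomicSequence(seq_name, residues) if residues else GenomicSequence(seq_name, "A")

    truth_df = pd.DataFrame(records, columns=[c for c in TRUTH_COLUMNS if c != "flank_effect"])

    # -- flank effect: standardised own-strand flank G-content, with an
    #    amplitude that shrinks above the knee (SD-vs-mean inversion)
    if n_pqs:
        g_counts = []
        for rec in records:
            lo = max(0, rec["start"] - DEFAULT_FLANK_LEN)
            hi = min(len(residues), rec["end"] + DEFAULT_FLANK_LEN)
            fl = residues[lo : rec["start"]] + residues[rec["end"] : hi]
            g_counts.append(fl.count("G") if rec["strand"] == "+" else fl.count("C"))
        g_counts = np.array(g_counts, dtype=float)
        sd = g_counts.std() or 1.0
        z = (g_counts - g_counts.mean()) / sd
        amp = np.where(truth_df["latent_mean"] < knee, flank_amp_weak, flank_amp_strong)
        truth_df["flank_effect"] = np.clip(amp * z, -3 * amp, 3 * amp)
    else:
        truth_df["flank_effect"] = pd.Series(dtype=float)

    # -- integrity: the scan must recover exactly the planted intervals
    found = {(h.start, h.end, h.strand) for h in find_pqs(genome, "both")}
    planted_set = {
        (r["start"], r["end"], r["strand"]) for r in truth_df.to_dict("records")
    }
    if found != planted_set:
        raise AssertionError("synthetic background produced spurious or lost PQSs")

    params = {
        "n_pqs": n_pqs, "length": length, "seed": seed, "spacing": spacing,
        "p_strong": p_strong, "p_extra_tract": p_extra_tract,
        "mode_weak": mode_weak, "mode_strong": mode_strong,
        "flank_amp_weak": flank_amp_weak, "flank_amp_strong": flank_amp_strong,
        "knee": knee, "composition": composition,
        "copy_groups": copy_groups, "copies_per_group": copies_per_group,
    }
    return genome, SyntheticTruth(records=truth_df, params=params)


def generate_mm_track(
    truth: SyntheticTruth,
    genome: GenomicSequence,
    bin_size: int = 15,
    noise_sd: float = 5.0,
    background_mm: float = 0.5,
    uncovered_frac: float = 0.0,
    seed: int = 0,
) -> MismatchTrack:
    """Binned mm% track for a synthetic genome.

    Every planted PQS emits one peak bin at a jittered position within
    its flank window, of height latent mean + flank effect + N(0,
    noise_sd), clipped to [0, 100]; background bins sit near zero.  A
    fraction ``uncovered_frac`` of PQSs can be left without any
    overlapping bins to emulate missing sequencing coverage.
    """
    rng = np.random.default_rng(seed)
    n = len(genome)
    starts = np.arange(0, n, bin_size, dtype=np.int64)
    ends = np.minimum(starts + bin_size, n)
    values = np.abs(rng.normal(0.0, background_mm, size=len(starts)))

    rec = truth.records
    uncovered_ids: set[int] = set()
    if uncovered_frac > 0 and len(rec):
        k = int(round(uncovered_frac * len(rec)))
        uncovered_ids = set(rng.choice(rec["pqs_id"].to_numpy(), size=k, replace=False))

    for r in rec.itertuples(index=False):
        if r.pqs_id in uncovered_ids:
            continue
        lo = max(0, r.start - 35)
        hi = min(n - 1, r.end + 35)
        peak_pos = int(rng.integers(lo, hi + 1))
        peak = float(np.clip(
            r.latent_mean + r.flank_effect + rng.normal(0.0, noise_sd), 0.0, 100.0
        ))
        b = peak_pos // bin_size
        values[b] = max(values[b], peak)

    df = pd.DataFrame(
        {"seq_name": genome.name, "start": starts, "end": ends, "mm": values}
    )
    if uncovered_ids:
        drop = np.zeros(len(df), dtype=bool)
        for r in rec.itertuples(index=False):
            if r.pqs_id in uncovered_ids:
                w0, w1 = r.start - DEFAULT_FLANK_LEN, r.end + DEFAULT_FLANK_LEN
                drop |= (df["end"].to_numpy() > w0) & (df["start"].to_numpy() < w1)
        df = df[~drop].reset_index(drop=True)
    return MismatchTrack.from_frame(df)


def make_dataset(
    truth: Optional[SyntheticTruth],
    genome: GenomicSequence,
    track: MismatchTrack,
    energy_table: Optional[EnergyTable] = None,
    flank_len: int = DEFAULT_FLANK_LEN,
) -> pd.DataFrame:
    """Assemble the modelling table: one row per isolated, covered PQS
    with the 209 features plus the assigned mm% target.

    Runs the real scanners/mappers end to end (both strands, isolation
    filter, max-over-bins mapping).  When ``truth`` is given, every
    kept row is checked to coincide with a planted record.  Rows are
    sorted by coordinate for byte-stable output; the coordinates form
    the row MultiIndex (seq_name, start, end, strand) so the columns
    are exactly the 209 features plus the mm% target.
    """
    table = energy_table or build_energy_table()
    hits = find_pqs(genome, "both")
    hits = filter_isolated(hits, flank_len=flank_len)
    hits = [extract_flanks(genome, h, flank_len=flank_len) for h in hits]
    mapped = assign_mm_many(hits, track, flank_len=flank_len)
    mapped = [m for m in mapped if m.covered]
    mapped.sort(key=lambda m: (m.hit.seq_name, m.hit.start))

    if truth is not None and len(truth.records):
        planted = {
            (r.seq_name, r.start, r.end, r.strand)
            for r in truth.records.itertuples(index=False)
        }
        for m in mapped:
            key = (m.hit.seq_name, m.hit.start, m.hit.end, m.hit.strand)
            if key not in planted:
                raise AssertionError(f"unplanted PQS in dataset: {key}")

    feats = extract_feature_matrix([m.hit for m in mapped], table)
    out = feats.reset_index(drop=True)
    out["mm"] = [m.mm for m in mapped]
    out.index = pd.MultiIndex.from_tuples(
        [(m.hit.seq_name, m.hit.start, m.hit.end, m.hit.strand) for m in mapped],
        names=["seq_name", "start", "end", "strand"],
    )
    return out


def join_truth(dataset: pd.DataFrame, truth: SyntheticTruth) -> pd.DataFrame:
    """Inner-join dataset rows with their planted ground-truth records
    on coordinates (adds latent mean, class, flank effect)."""
    return dataset.reset_index().merge(
        truth.records, on=["seq_name", "start", "end", "strand"], how="inner",
        validate="one_to_one",
    )
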