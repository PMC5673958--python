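"""Detection of extended putative G-quadruplex sequences (PQSs) in DNA.

A canonical G-quadruplex motif is four tracts of at least three guanines
separated by 1-12 nt loops.  The extended definition used here,
``{G3+ N1-12}3+ G3+``, additionally merges nested or chained motifs: any
maximal run of G-tracts whose inter-tract gaps are all at most 12 nt is
reported as a single hit spanning from the first to the last tract, so a
hit may carry more than four tracts (and more than three loops).

Coordinates are 0-based half-open on the forward strand throughout the
library; the command-line layer converts to 1-based inclusive on output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

MAX_LOOP_LEN = 12
MIN_TRACT_LEN = 3
MIN_TRACTS = 4
DEFAULT_FLANK_LEN = 50

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_G_RUN = re.compile(r"G{3,}")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-pairs)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicSequence:
    """A named DNA sequence over the {A, C, G, T, N} alphabet.

    Input is upper-cased on construction; any other character is
    rejected.  Empty residues are tolerated at the dataclass level (the
    scanner simply finds nothing); the FASTA loader rejects empty
    records.
    """

    name: str
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        bad = set(residues) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains invalid characters: "
                f"{sorted(bad)}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PQSHit:
    """One detected PQS with its tract/loop decomposition and flanks.

    ``start``/``end`` are 0-based half-open forward-strand coordinates.
    ``pqs_sequence`` is read 5'->3' on the hit's own strand, as are the
    tract offsets, loops and flanks.  ``tracts`` are (offset, length)
    pairs of the maximal G-runs >= 3 within ``pqs_sequence``; ``loops``
    are the spans between consecutive tracts.
    """

    seq_name: str
    start: int
    end: int
    strand: str
    pqs_sequence: str
    tracts: tuple[tuple[int, int], ...]
    loops: tuple[str, ...]
    flank5: str = ""
    flank3: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def parse_tracts_loops(
    pqs_sequence: str,
) -> tuple[tuple[tuple[int, int], ...], tuple[str, ...]]:
    """Decompose a motif string into maximal G-runs >= 3 and the loops
    between them.  A run of 4+ Gs is one tract, never tract + loop-G."""
    tracts = tuple(
        (m.start(), m.end() - m.start()) for m in _G_RUN.finditer(pqs_sequence)
    )
    loops = tuple(
        pqs_sequence[tracts[i][0] + tracts[i][1] : tracts[i + 1][0]]
        for i in range(len(tracts) - 1)
    )
    return tracts, loops


def _scan_one_strand(residues: str) -> Iterator[tuple[int, int]]:
    """Yield (start, end) of merged PQS hits on the given string.

    Maximal G-runs >= 3 are chained while the gap to the next run is
    1-12 nt and free of N; every maximal chain holding at least four
    tracts becomes one leftmost-longest hit.  Chains are disjoint by
    construction, so hits never overlap on a strand.
    """
    runs = [(m.start(), m.end()) for m in _G_RUN.finditer(residues)]
    chain: list[tuple[int, int]] = []
    for run in runs:
        if chain:
            gap_lo, gap_hi = chain[-1][1], run[0]
            gap = residues[gap_lo:gap_hi]
            if 1 <= len(gap) <= MAX_LOOP_LEN and "N" not in gap:
                chain.append(run)
                continue
            if len(chain) >= MIN_TRACTS:
                yield chain[0][0], chain[-1][1]
            chain = []
        chain.append(run)
    if len(chain) >= MIN_TRACTS:
        yield chain[0][0], chain[-1][1]


def find_pqs(seq: GenomicSequence, strands: str = "both") -> list[PQSHit]:
    """Find all extended PQS motifs on the requested strand(s).

    Parameters
    ----------
    seq
        Input sequence.
    strands
        ``"forward"`` (or ``"+"``), ``"reverse"`` (or ``"-"``), or
        ``"both"``.

    Returns
    -------
    Hits sorted by forward-strand start coordinate.  Reverse-strand hits
    carry forward-strand coordinates with ``strand == "-"`` and their
    motif string as read on the reverse strand.
    """
    selector = {"forward": "+", "+": "+", "reverse": "-", "-": "-", "both": "b"}
    if strands not in selector:
        raise ValueError(f"invalid strand selector: {strands!r}")
    mode = selector[strands]

    hits: list[PQSHit] = []
    residues = seq.residues
    n = len(residues)
    if mode in ("+", "b"):
        for start, end in _scan_one_strand(residues):
            motif = residues[start:end]
            tracts, loops = parse_tracts_loops(motif)
            hits.append(
                PQSHit(seq.name, start, end, "+", motif, tracts, loops)
            )
    if mode in ("-", "b"):
        rc = revcomp(residues)
        for rs, re_ in _scan_one_strand(rc):
            motif = rc[rs:re_]
            tracts, loops = parse_tracts_loops(motif)
            hits.append(
                PQSHit(seq.name, n - re_, n - rs, "-", motif, tracts, loops)
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def extract_flanks(
    seq: GenomicSequence, hit: PQSHit, flank_len: int = DEFAULT_FLANK_LEN
) -> PQSHit:
    """Return the hit with up to ``flank_len``-nt 5' and 3' flanks.

    Flanks are strand-aware: for a minus-strand hit the 5' flank is the
    reverse complement of the forward-strand bases 3' of the interval.
    Flanks are truncated as-is at sequence ends.
    """
    if not (0 <= hit.start <= hit.end <= len(seq)):
        raise ValueError(
            f"hit {hit.start}:{hit.end} outside sequence {seq.name!r}"
        )
    residues = seq.residues
    upstream = residues[max(0, hit.start - flank_len) : hit.start]
    downstream = residues[hit.end : hit.end + flank_len]
    if hit.strand == "+":
        return replace(hit, flank5=upstream, flank3=downstream)
    return replace(hit, flank5=revcomp(downstream), flank3=revcomp(upstream))


def read_fasta(path) -> list[GenomicSequence]:
    """Load a (multi-record) FASTA file; sequences are validated and
    upper-cased."""
    records = [
        GenomicSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    for rec in records:
        if not rec.residues:
            raise ValueError(f"FASTA record {rec.name!r} is empty")
    return records


def write_fasta(path, seqs: Iterable[GenomicSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def hits_to_table(hits: Iterable[PQSHit]) -> pd.DataFrame:
    """Tabulate hits: seq_name, start, end, strand, length, sequence."""
    return pd.DataFrame(
        [
            {
                "seq_name": h.seq_name,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "length": h.length,
                "sequence": h.pqs_sequence,
            }
            for h in hits
        ],
        columns=["seq_name", "start", "end", "strand", "length", "sequence"],
    )
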