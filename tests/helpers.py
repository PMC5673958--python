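"""Independent brute-force oracles used to validate the fast
implementations.  These deliberately share no code with the package:
motif matching is done by exhaustive substring validation and triad
counting by naive per-pattern scans."""

from __future__ import annotations

import itertools


def _maximal_g_runs(s: str) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(s):
        if s[i] == "G":
            j = i
            while j < len(s) and s[j] == "G":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def is_valid_pqs(sub: str, max_loop: int = 12, min_tract: int = 3,
                 min_tracts: int = 4) -> bool:
    """Does the whole string parse as an extended PQS?  Must start and
    end with a G-tract, hold >= 4 tracts of >= 3 G, with every
    inter-tract gap 1..12 nt and free of N."""
    if "N" in sub:
        return False
    tracts = [r for r in _maximal_g_runs(sub) if r[1] - r[0] >= min_tract]
    if len(tracts) < min_tracts:
        return False
    if tracts[0][0] != 0 or tracts[-1][1] != len(sub):
        return False
    for (_, e0), (s1, _) in zip(tracts, tracts[1:]):
        if not (1 <= s1 - e0 <= max_loop):
            return False
    return True


def oracle_find_pqs(seq: str) -> list[tuple[int, int]]:
    """Exhaustive-enumeration scanner: every maximal valid substring,
    then greedy leftmost-longest non-overlapping selection."""
    n = len(seq)
    starts = [i for i in range(n - 2) if seq[i : i + 3] == "GGG"
              and (i == 0 or seq[i - 1] != "G")]
    ends = [j for j in range(3, n + 1) if seq[j - 3 : j] == "GGG"
            and (j == n or seq[j] != "G")]
    valid = []
    for i in starts:
        best = None
        for j in ends:
            if j - i >= 15 and is_valid_pqs(seq[i:j]):
                best = j
        if best is not None:
            valid.append((i, best))
    maximal = [
        iv for iv in valid
        if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in valid)
    ]
    maximal.sort()
    out, pos = [], 0
    for s, e in maximal:
        if s >= pos:
            out.append((s, e))
            pos = e
    return out


TRIADS_64 = ["".join(t) for t in itertools.product("ACGT", repeat=3)]


def naive_triad_counts(segment: str) -> dict[str, int]:
    """O(n * 64) substring counter including overlaps."""
    return {
        t: sum(1 for i in range(len(segment) - 2) if segment[i : i + 3] == t)
        for t in TRIADS_64
    }


def random_dna(rng, n: int, p_g: float = 0.35) -> str:
    """Random DNA enriched in G so PQSs actually occur."""
    rest = (1.0 - p_g) / 3.0
    return "".join(rng.choice(list("ACGT"), size=n, p=[rest, rest, p_g, rest]))
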