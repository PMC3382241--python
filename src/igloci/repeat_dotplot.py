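"""Windowed dot-matrix comparison and switch-region detection.

The dot matrix is the exact windowed predicate used in classical desktop
sequence-comparison tools: a point at (i, j) means the length-``window``
words starting at i in one sequence and j in the other differ at no more
than ``max_mismatch`` positions (defaults 30 bp / 9 mismatches).  No
hashing or seeding heuristics are used — the predicate is evaluated for
every window pair.

Class-switch (S) regions upstream of heavy-chain constant genes are dense
tandem arrays of pentamers (canonically GAGCT and GGGCT).  They are
detected here by sliding-window pentamer density segmentation rather than
visual dot-plot inspection, so the calls are reproducible and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import Interval, Scaffold, revcomp


@dataclass
class DotMatrix:
    seq_x_id: str
    seq_y_id: str
    window: int
    max_mismatch: int
    points: set[tuple[int, int]] = field(default_factory=set)


def dot_matrix(
    a: str,
    b: str,
    window: int = 30,
    max_mismatch: int = 9,
    a_id: str = "x",
    b_id: str = "y",
) -> DotMatrix:
    """Exact dot matrix: point (i, j) iff hamming(a[i:i+w], b[j:j+w]) <= m.

    N counts as a mismatch against everything, including N (matching the
    scanner's treatment of assembly gaps).  Computed per diagonal with a
    windowed cumulative sum, so it is exact yet fast enough for loci of a
    few hundred kb.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not (0 <= max_mismatch < window):
        raise ValueError("max_mismatch must satisfy 0 <= m < window")
    if len(a) < window or len(b) < window:
        raise ValueError("both sequences must be at least one window long")
    xa = np.frombuffer(a.encode(), dtype="S1")
    xb = np.frombuffer(b.encode(), dtype="S1")
    na_mask = xa == b"N"
    nb_mask = xb == b"N"
    points: set[tuple[int, int]] = set()
    # diagonal d: pairs (i, i + d) with i in [max(0,-d), ...)
    for d in range(-(len(a) - window), len(b) - window + 1):
        i0 = max(0, -d)
        j0 = i0 + d
        L = min(len(a) - i0, len(b) - j0)
        if L < window:
            continue
        mm = (xa[i0 : i0 + L] != xb[j0 : j0 + L]) | na_mask[i0 : i0 + L] | nb_mask[j0 : j0 + L]
        cs = np.concatenate(([0], np.cumsum(mm)))
        wsum = cs[window:] - cs[: L - window + 1]
        for k in np.nonzero(wsum <= max_mismatch)[0]:
            points.add((i0 + int(k), j0 + int(k)))
    return DotMatrix(a_id, b_id, window, max_mismatch, points)


@dataclass
class SwitchRegion:
    interval: Interval
    repeat_units: dict[str, int]
    density: float  # pentamer starts per kb over the region
    length_kb: float


def find_switch_regions(
    scaffold: Scaffold,
    pentamers: tuple[str, ...] = ("GAGCT", "GGGCT"),
    window_kb: float = 0.5,
    min_density: float = 15.0,
    min_len_kb: float = 1.0,
    merge_gap_bp: int = 200,
) -> list[SwitchRegion]:
    """Detect pentameric tandem-repeat (switch) arrays by density segmentation.

    Occurrences of the pentamers and their reverse complements are counted
    in a sliding window of ``window_kb``; maximal stretches whose density
    exceeds ``min_density`` per kb are merged across gaps of up to
    ``merge_gap_bp`` and reported if at least ``min_len_kb`` long.  Region
    boundaries are trimmed to the outermost pentamer occurrence.
    """
    if not pentamers:
        raise ValueError("at least one pentamer is required")
    for p in pentamers:
        if len(p) != 5 or any(c not in "ACGT" for c in p):
            raise ValueError(f"malformed pentamer {p!r}")
    motifs = sorted({m for p in pentamers for m in (p, revcomp(p))})
    n = len(scaffold)
    occ = np.zeros(n, dtype=np.int32)
    per_motif: dict[str, np.ndarray] = {}
    for m in motifs:
        starts = []
        i = scaffold.seq.find(m)
        while i != -1:
            starts.append(i)
            i = scaffold.seq.find(m, i + 1)
        hit = np.zeros(n, dtype=np.int32)
        if starts:
            hit[np.array(starts)] = 1
        per_motif[m] = hit
        occ += hit

    w = int(round(window_kb * 1000))
    if n < w:
        return []
    cs = np.concatenate(([0], np.cumsum(occ)))
    counts = cs[w:] - cs[: n - w + 1]  # pentamer starts in [i, i+w)
    above = counts >= min_density * window_kb

    # maximal above-threshold window runs -> base intervals [i, i+w)
    regions: list[list[int]] = []
    idx = np.nonzero(above)[0]
    for i in idx:
        if regions and i <= regions[-1][1] + merge_gap_bp:
            regions[-1][1] = i + w
        else:
            regions.append([int(i), int(i) + w])

    out: list[SwitchRegion] = []
    edge_w = 150  # bp; a region edge must carry half the core repeat density
    for start, end in regions:
        # the merged window span overhangs the true array by up to one
        # window; trim each edge to the outermost occurrence that is still
        # backed by near-core repeat density within edge_w inward
        span = occ[start:end]
        nz = np.nonzero(span)[0]
        if nz.size == 0:
            continue
        quarter = (end - start) // 4
        core = occ[start + quarter : end - quarter]
        core_density = 1000.0 * core.sum() / max(1, core.size)
        req = max(2.0, 0.5 * core_density * edge_w / 1000.0)
        lo, hi = 0, nz.size - 1
        while lo < hi and cs[min(n, start + nz[lo] + edge_w)] - cs[start + nz[lo]] < req:
            lo += 1
        while hi > lo and cs[start + nz[hi] + 5] - cs[max(0, start + nz[hi] + 5 - edge_w)] < req:
            hi -= 1
        s = start + int(nz[lo])
        e = start + int(nz[hi]) + 5
        if (e - s) / 1000.0 < min_len_kb:
            continue
        units = {m: int(per_motif[m][s:e].sum()) for m in motifs}
        total = sum(units.values())
        out.append(
            SwitchRegion(
                interval=Interval(s, e),
                repeat_units=units,
                density=1000.0 * total / (e - s),
                length_kb=(e - s) / 1000.0,
            )
        )
    return out
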