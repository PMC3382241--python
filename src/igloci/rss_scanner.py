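"""Recombination-signal-sequence (RSS) scanning under a mismatch budget.

An RSS is a conserved heptamer (consensus ``CACAGTG``), a poorly conserved
spacer of approximately 12 or 23 bp, and a conserved nonamer (consensus
``ACAAAAACC``).  The heptamer is always the gene-proximal element: read in
the 5'->3' direction of the gene segment it serves, an RSS downstream of a
V or D segment is heptamer-spacer-nonamer, while an RSS upstream of a D or
J segment is nonamer-spacer-heptamer (so its heptamer appears as ``CACTGTG``
on the top strand).

The scanner enumerates, exactly, every (heptamer window, nonamer window)
pair on either strand whose spacer length falls in the model's range and
whose mismatch counts fit the budgets — a fuzzy-motif search in the style
of EMBOSS fuzznuc.  N counts as a mismatch against every base, including N,
so assembly gaps cannot silently satisfy a motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .genome_io import Interval, Scaffold, _validate_alphabet

DEFAULT_HEPTAMER = "CACAGTG"
DEFAULT_NONAMER = "ACAAAAACC"

SpacerClass = Literal["12-type", "23-type"]

DEFAULT_SPACER_RANGES: dict[str, tuple[int, int]] = {
    "12-type": (11, 13),
    "23-type": (21, 24),
}


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N mismatches everything.

    The N rule is deliberately conservative: an N differs even from another
    N, so motif matches cannot be manufactured inside assembly gaps.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming: length mismatch ({len(a)} vs {len(b)})")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


@dataclass(frozen=True)
class RssModel:
    """Consensus motifs, spacer class and mismatch budgets for one RSS type.

    ``max_mismatch_total`` caps heptamer + nonamer mismatches jointly;
    ``max_mismatch_heptamer`` additionally restricts the heptamer, whose
    CAC core is functionally critical.
    """

    spacer_class: SpacerClass = "23-type"
    heptamer_consensus: str = DEFAULT_HEPTAMER
    nonamer_consensus: str = DEFAULT_NONAMER
    spacer_range: tuple[int, int] | None = None
    max_mismatch_total: int = 5
    max_mismatch_heptamer: int = 2

    def __post_init__(self) -> None:
        if len(self.heptamer_consensus) != 7:
            raise ValueError("heptamer consensus must be exactly 7 nt")
        if len(self.nonamer_consensus) != 9:
            raise ValueError("nonamer consensus must be exactly 9 nt")
        if self.spacer_class not in DEFAULT_SPACER_RANGES:
            raise ValueError(f"unknown spacer class {self.spacer_class!r}")
        if self.spacer_range is None:
            object.__setattr__(
                self, "spacer_range", DEFAULT_SPACER_RANGES[self.spacer_class]
            )
        lo, hi = self.spacer_range
        if lo > hi or lo < 0:
            raise ValueError(f"empty or negative spacer range [{lo}, {hi}]")
        if self.max_mismatch_total < 0 or self.max_mismatch_heptamer < 0:
            raise ValueError("mismatch budgets must be >= 0")


@dataclass(frozen=True)
class RssHit:
    """One heptamer-spacer-nonamer match.

    ``strand`` is the strand on which the motif reads in consensus order
    (heptamer, then spacer, then nonamer, 5'->3').  A ``+`` hit therefore
    sits downstream of a top-strand gene segment; a ``-`` hit, whose
    elements appear reverse-complemented on the top strand with the
    heptamer rightmost, sits upstream of a top-strand gene segment (or
    downstream of a bottom-strand one).
    """

    scaffold_id: str
    heptamer_interval: Interval
    nonamer_interval: Interval
    spacer_len: int
    strand: str
    spacer_class: SpacerClass
    mismatches_heptamer: int
    mismatches_nonamer: int
    orientation: Literal["downstream-of-gene", "upstream-of-gene"]

    @property
    def mismatches_total(self) -> int:
        return self.mismatches_heptamer + self.mismatches_nonamer


def _mismatch_profile(arr: np.ndarray, motif: str) -> np.ndarray:
    """profile[i] = mismatches of seq[i:i+len(motif)] vs motif (N rule applied)."""
    n, w = arr.size, len(motif)
    if n < w:
        return np.zeros(0, dtype=np.int32)
    m = np.frombuffer(motif.encode(), dtype="S1")
    is_n = arr == b"N"
    out = np.zeros(n - w + 1, dtype=np.int32)
    for k in range(w):
        col = arr[k : n - w + 1 + k]
        out += (col != m[k]) | is_n[k : n - w + 1 + k] | (m[k] == b"N")
    return out


def scan_rss(scaffold: Scaffold, model: RssModel) -> list[RssHit]:
    """All RSS matches on both strands of a scaffold under the model budgets.

    Every qualifying (heptamer, nonamer) window pair is reported exactly
    once; overlapping hits are all kept (see :func:`dedupe_hits`).  Hits are
    sorted by heptamer start, then strand, then spacer length.
    """
    arr = np.frombuffer(scaffold.seq.encode(), dtype="S1")
    lo, hi = model.spacer_range
    max_t, max_h = model.max_mismatch_total, model.max_mismatch_heptamer

    hept_mm = _mismatch_profile(arr, model.heptamer_consensus)
    nona_mm = _mismatch_profile(arr, model.nonamer_consensus)
    # Reverse-complement reading: on the top strand a '-' hit appears as
    # revcomp(nonamer), spacer, revcomp(heptamer), heptamer rightmost.
    from .genome_io import revcomp

    rc_hept_mm = _mismatch_profile(arr, revcomp(model.heptamer_consensus))
    rc_nona_mm = _mismatch_profile(arr, revcomp(model.nonamer_consensus))

    hits: list[RssHit] = []
    n = arr.size
    for spacer in range(lo, hi + 1):
        # '+' strand: heptamer at i, nonamer at i + 7 + spacer
        shift = 7 + spacer
        m = min(hept_mm.size, nona_mm.size - shift)
        if m > 0:
            h = hept_mm[:m]
            no = nona_mm[shift : shift + m]
            idx = np.nonzero((h <= max_h) & (h + no <= max_t))[0]
            for i in idx:
                hits.append(
                    RssHit(
                        scaffold_id=scaffold.id,
                        heptamer_interval=Interval(int(i), int(i) + 7, "+"),
                        nonamer_interval=Interval(int(i) + shift, int(i) + shift + 9, "+"),
                        spacer_len=spacer,
                        strand="+",
                        spacer_class=model.spacer_class,
                        mismatches_heptamer=int(h[i]),
                        mismatches_nonamer=int(no[i]),
                        orientation="downstream-of-gene",
                    )
                )
        # '-' strand: rc(nonamer) at j, rc(heptamer) at j + 9 + spacer
        shift = 9 + spacer
        m = min(rc_nona_mm.size, rc_hept_mm.size - shift)
        if m > 0:
            no = rc_nona_mm[:m]
            h = rc_hept_mm[shift : shift + m]
            idx = np.nonzero((h <= max_h) & (h + no <= max_t))[0]
            for j in idx:
                hits.append(
                    RssHit(
                        scaffold_id=scaffold.id,
                        heptamer_interval=Interval(int(j) + shift, int(j) + shift + 7, "-"),
                        nonamer_interval=Interval(int(j), int(j) + 9, "-"),
                        spacer_len=spacer,
                        strand="-",
                        spacer_class=model.spacer_class,
                        mismatches_heptamer=int(h[j]),
                        mismatches_nonamer=int(no[j]),
                        orientation="upstream-of-gene",
                    )
                )
    hits.sort(key=lambda r: (r.heptamer_interval.start, r.strand, r.spacer_len))
    return hits


def dedupe_hits(hits: Sequence[RssHit]) -> list[RssHit]:
    """Collapse hits sharing a heptamer window and strand.

    Keeps the lowest total mismatch count, then the shortest spacer, then
    the leftmost nonamer — a deterministic tie-break for near-duplicate
    matches produced by tolerant spacer ranges.
    """
    best: dict[tuple, RssHit] = {}
    for h in hits:
        key = (h.scaffold_id, h.strand, h.spacer_class,
               h.heptamer_interval.start, h.heptamer_interval.end)
        cur = best.get(key)
        if cur is None or (
            (h.mismatches_total, h.spacer_len, h.nonamer_interval.start)
            < (cur.mismatches_total, cur.spacer_len, cur.nonamer_interval.start)
        ):
            best[key] = h
    out = list(best.values())
    out.sort(key=lambda r: (r.heptamer_interval.start, r.strand, r.spacer_len))
    return out


def filter_hits_near(
    hits: Sequence[RssHit],
    anchor: Interval,
    side: Literal["5prime", "3prime"],
    max_gap: int,
) -> list[RssHit]:
    """Hits whose gene-proximal heptamer lies within ``max_gap`` bp of the
    stated side of ``anchor``, in the strand sense of the anchor.

    For a ``+`` anchor the 3' side is to the genomic right and expects a
    ``+`` hit (heptamer-first); the 5' side expects a ``-`` hit ending at
    the anchor start.  A ``-`` anchor mirrors both.  Results are ordered by
    distance from the anchor.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if side not in ("5prime", "3prime"):
        raise ValueError(f"side must be '5prime' or '3prime', got {side!r}")

    # (wanted hit strand, measure from heptamer left edge?) for each case
    right_side = (side == "3prime") == (anchor.strand == "+")
    want_strand = anchor.strand if side == "3prime" else ("-" if anchor.strand == "+" else "+")

    selected: list[tuple[int, RssHit]] = []
    for h in hits:
        if h.strand != want_strand:
            continue
        if right_side:
            dist = h.heptamer_interval.start - anchor.end
        else:
            dist = anchor.start - h.heptamer_interval.end
        if 0 <= dist <= max_gap:
            selected.append((dist, h))
    selected.sort(key=lambda t: (t[0], t[1].heptamer_interval.start))
    return [h for _, h in selected]
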