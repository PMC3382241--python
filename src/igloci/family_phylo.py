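"""V gene family assignment, neighbor-joining trees and clan classification.

Germline V segments are conventionally grouped into *families* by pairwise
nucleotide identity: above ~75% two segments belong to the same family,
below 70% to different families, and the 70-75% band is ambiguous.  The
operative rule here is single-linkage clustering at >70% identity, with the
70-75% borderline pairs surfaced separately for manual review rather than
silently decided.  Families can be re-clustered at a higher threshold into
subfamilies, and placed into the deep mammalian V-gene *clans* (I-III) by
nesting within reference sequences on a neighbor-joining tree.

"Similarity" is operationalized as global-alignment nucleotide identity
over aligned columns, excluding terminal gap overhangs.  Tree building is
Saitou-Nei neighbor joining (via scikit-bio), with bootstrap support from
column resampling of an aligned block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj as _skbio_nj


# ---------------------------------------------------------------------------
# pairwise identity

def _make_nuc_aligner(match: float = 1, mismatch: float = -1,
                      gap_open: float = -5, gap_extend: float = -1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_identity(a: str, b: str, aligner: Optional[Align.PairwiseAligner] = None) -> float:
    """Fractional nucleotide identity from a global alignment.

    Needleman-Wunsch with affine gaps (defaults: match +1, mismatch -1, gap
    open -5, extend -1); identity = matches / aligned columns after trimming
    terminal gap overhangs.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if aligner is None:
        aligner = _make_nuc_aligner()
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    # trim terminal overhang columns (leading/trailing gap in either row)
    left = 0
    right = len(row_a)
    while left < right and (row_a[left] == "-" or row_b[left] == "-"):
        left += 1
    while right > left and (row_a[right - 1] == "-" or row_b[right - 1] == "-"):
        right -= 1
    if right == left:
        return 0.0
    matches = sum(1 for x, y in zip(row_a[left:right], row_b[left:right]) if x == y and x != "-")
    return matches / (right - left)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix (1 - fractional identity)."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def identity_matrix(seqs: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise identity for every pair of labeled sequences."""
    labels = list(seqs)
    n = len(labels)
    ident = np.eye(n)
    aligner = _make_nuc_aligner()
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(
                seqs[labels[i]], seqs[labels[j]], aligner
            )
    return labels, ident


# ---------------------------------------------------------------------------
# families

@dataclass
class GeneFamily:
    family_id: int
    members: list[str]
    subfamilies: Optional[list[list[str]]] = None
    clan: Optional[str] = None


def _single_linkage(labels: Sequence[str], ident: np.ndarray, threshold: float) -> list[list[str]]:
    """Single-linkage components joining pairs with identity > threshold."""
    parent = list(range(len(labels)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if ident[i, j] > threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[str]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(find(i), []).append(lab)
    return list(groups.values())


def assign_families(
    seqs: Mapping[str, str],
    threshold_same: float = 0.75,
    threshold_diff: float = 0.70,
    subfamily_threshold: float = 0.80,
    positions: Optional[Mapping[str, int]] = None,
    precomputed: Optional[tuple[list[str], np.ndarray]] = None,
) -> list[GeneFamily]:
    """Group V segments into families by single-linkage identity clustering.

    The operative threshold is ``threshold_diff`` (>70% identity joins two
    segments); ``threshold_same`` only delimits the borderline band reported
    by :func:`borderline_pairs`.  Families are numbered by descending size,
    then by leftmost genomic position of their members (``positions``), and
    each family is re-clustered at ``subfamily_threshold`` into subfamilies.
    """
    if not seqs:
        raise ValueError("assign_families requires at least one segment")
    for t in (threshold_same, threshold_diff, subfamily_threshold):
        if not (0.0 < t < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
    if threshold_diff > threshold_same:
        raise ValueError("threshold_diff must not exceed threshold_same")
    labels, ident = precomputed if precomputed is not None else identity_matrix(seqs)
    groups = _single_linkage(labels, ident, threshold_diff)

    def group_pos(g: list[str]) -> int:
        if positions:
            return min(positions.get(m, 1 << 60) for m in g)
        return min(labels.index(m) for m in g)

    groups.sort(key=lambda g: (-len(g), group_pos(g)))
    families = []
    idx = {lab: i for i, lab in enumerate(labels)}
    for fid, g in enumerate(groups, start=1):
        sub_ident = ident[np.ix_([idx[m] for m in g], [idx[m] for m in g])]
        subs = _single_linkage(g, sub_ident, subfamily_threshold)
        subs.sort(key=lambda s: (-len(s), group_pos(s)))
        families.append(GeneFamily(family_id=fid, members=sorted(g, key=lambda m: group_pos([m])),
                                   subfamilies=subs if len(subs) > 1 else None))
    return families


def borderline_pairs(
    seqs: Mapping[str, str],
    threshold_same: float = 0.75,
    threshold_diff: float = 0.70,
    precomputed: Optional[tuple[list[str], np.ndarray]] = None,
) -> list[tuple[str, str, float]]:
    """Pairs in the ambiguous identity band (threshold_diff, threshold_same],
    flagged for case-by-case review."""
    labels, ident = precomputed if precomputed is not None else identity_matrix(seqs)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if threshold_diff < ident[i, j] <= threshold_same:
                out.append((labels[i], labels[j], float(ident[i, j])))
    return out


# ---------------------------------------------------------------------------
# neighbor joining

@dataclass
class PhyloTree:
    """An unrooted NJ tree with optional per-bipartition bootstrap support."""

    tree: TreeNode
    supports: Optional[dict[frozenset, float]] = None
    clamped_negative_branches: int = 0

    def tip_names(self) -> list[str]:
        return sorted(t.name for t in self.tree.tips())

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.tree)

    def tip_distances(self) -> DistanceMatrix:
        dm = self.tree.tip_tip_distances()
        return DistanceMatrix(list(dm.ids), dm.data.copy())

    def to_newick(self) -> str:
        t = self.tree.copy()
        if self.supports is not None:
            names = frozenset(x.name for x in t.tips())
            for node in t.non_tips():
                bip = _canonical_bipartition(
                    frozenset(x.name for x in node.tips()), names
                )
                if bip in self.supports:
                    node.name = str(int(round(self.supports[bip])))
        return str(t).strip()


def _canonical_bipartition(side: frozenset, all_names: frozenset) -> frozenset:
    """Represent a split by the side not containing the lexicographically
    first taxon, so both orientations hash identically."""
    ref = min(all_names)
    return all_names - side if ref in side else side


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    names = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(names) - 1:
            out.add(_canonical_bipartition(side, names))
    return out


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    On an additive distance matrix the returned tree's path-length metric
    reproduces the input distances exactly; negative branch-length
    estimates are clamped to zero and counted.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    # exact symmetrization: floating-point asymmetry below our own validation
    # tolerance would still be rejected by skbio's strict check
    sk = _SkbioDM((dm.d + dm.d.T) / 2.0, ids=dm.labels)
    raw = _skbio_nj(sk, neg_as_zero=False)
    clamped = sum(1 for n in raw.traverse() if n.length is not None and n.length < 0)
    tree = _skbio_nj(sk, neg_as_zero=True) if clamped else raw
    return PhyloTree(tree=tree, clamped_negative_branches=clamped)


# ---------------------------------------------------------------------------
# bootstrap

def _p_distance_matrix(arr: np.ndarray, labels: list[str]) -> DistanceMatrix:
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = (arr[i] != arr[i + 1 :]).mean(axis=1)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return DistanceMatrix(labels, d)


def alignment_to_array(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    # canonical label order makes the result invariant to input ordering
    labels = sorted(alignment)
    lengths = {len(alignment[l]) for l in labels}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must all have the same length")
    arr = np.array([list(alignment[l]) for l in labels])
    return labels, arr


def bootstrap_support(
    alignment: Mapping[str, str],
    replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree from an aligned block with column-resampling bootstrap.

    Builds the full-data tree from p-distances, then resamples alignment
    columns with replacement ``replicates`` times, rebuilds NJ on each
    replicate, and maps bipartition frequencies (percent) onto the
    full-data tree.  Seeded and reproducible.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    labels, arr = alignment_to_array(alignment)
    if len(labels) < 4:
        raise ValueError("bootstrap requires at least 4 sequences")
    full = nj_tree(_p_distance_matrix(arr, labels))
    target = full.bipartitions()
    counts = {b: 0 for b in target}
    rng = np.random.default_rng(seed)
    ncol = arr.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = nj_tree(_p_distance_matrix(arr[:, cols], labels))
        for b in rep.bipartitions():
            if b in counts:
                counts[b] += 1
    full.supports = {b: 100.0 * c / replicates for b, c in counts.items()}
    return full


# ---------------------------------------------------------------------------
# clans

def assign_clans(
    segments: Mapping[str, str],
    references: Mapping[str, tuple[str, str]],
) -> dict[str, str]:
    """Place V segments into clans by nesting among reference sequences.

    ``references`` maps a label to (nucleotide sequence, clan tag).  A joint
    NJ tree is built from pairwise-alignment distances; each segment
    inherits the majority clan of the references in the smallest clade
    containing it and at least one reference.  Ties yield ``"unassigned"``.
    """
    if not references:
        raise ValueError("assign_clans requires reference sequences")
    clans = {clan for _, clan in references.values()}
    if len(clans) < 2:
        raise ValueError("references must span at least two clans")
    overlap = set(segments) & set(references)
    if overlap:
        raise ValueError(f"segment/reference label collision: {sorted(overlap)}")
    seqs = {**segments, **{k: v[0] for k, v in references.items()}}
    labels, ident = identity_matrix(seqs)
    tree = nj_tree(DistanceMatrix(labels, 1.0 - ident)).tree
    # midpoint rooting: NJ trees are unrooted, and the arbitrary skbio root
    # can make a segment look nested inside the wrong reference clade
    try:
        tree = tree.root_at_midpoint()
    except Exception:  # zero-length degenerate trees
        pass
    ref_clan = {k: v[1] for k, v in references.items()}

    out: dict[str, str] = {}
    for seg in segments:
        node = tree.find(seg)
        clade_refs: list[str] = []
        while node.parent is not None and not clade_refs:
            node = node.parent
            clade_refs = [t.name for t in node.tips() if t.name in ref_clan]
        if not clade_refs:
            clade_refs = list(ref_clan)
        votes: dict[str, int] = {}
        for r in clade_refs:
            votes[ref_clan[r]] = votes.get(ref_clan[r], 0) + 1
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out[seg] = "unassigned"
        else:
            out[seg] = ranked[0][0]
    return out
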