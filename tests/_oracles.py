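"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — direct window enumeration and
per-frame translation scans — and shares no code path with the package
beyond trivial helpers like reverse complement.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def naive_scan(seq: str, heptamer: str, nonamer: str,
               spacer_lo: int, spacer_hi: int,
               max_total: int, max_hept: int) -> set[tuple]:
    """Enumerate every qualifying RSS window pair on both strands.

    Returns tuples in genomic (top-strand) coordinates:
    (hept_start, hept_end, nona_start, nona_end, strand, spacer, mm_h, mm_n).
    """
    n = len(seq)
    out: set[tuple] = set()
    for strand, s in (("+", seq), ("-", rc(seq))):
        for i in range(n - 7 + 1):
            mh = mismatches(s[i : i + 7], heptamer)
            if mh > max_hept:
                continue
            for spacer in range(spacer_lo, spacer_hi + 1):
                j = i + 7 + spacer
                if j + 9 > n:
                    continue
                mn = mismatches(s[j : j + 9], nonamer)
                if mh + mn > max_total:
                    continue
                if strand == "+":
                    out.add((i, i + 7, j, j + 9, "+", spacer, mh, mn))
                else:
                    out.add((n - i - 7, n - i, n - j - 9, n - j, "-", spacer, mh, mn))
    return out


def naive_orfs(seq: str, min_aa: int) -> set[tuple]:
    """(frame, start, end) of every maximal stop-free codon stretch >= min_aa."""
    stops = {"TAA", "TAG", "TGA"}
    out = set()
    for frame in range(3):
        run_start = frame
        pos = frame
        while pos + 3 <= len(seq):
            if seq[pos : pos + 3] in stops:
                if (pos - run_start) // 3 >= min_aa:
                    out.add((frame, run_start, pos))
                run_start = pos + 3
            pos += 3
        if (pos - run_start) // 3 >= min_aa:
            out.add((frame, run_start, pos))
    return out


def naive_dot_points(a: str, b: str, window: int, max_mm: int) -> set[tuple[int, int]]:
    """O(nm) double loop over all window pairs."""
    pts = set()
    for i in range(len(a) - window + 1):
        wa = a[i : i + window]
        for j in range(len(b) - window + 1):
            if mismatches(wa, b[j : j + window]) <= max_mm:
                pts.add((i, j))
    return pts


def random_binary_tree(rng, n_taxa: int, bl_lo: float = 0.1, bl_hi: float = 2.0):
    """A random unrooted binary tree as (adjacency dict, leaf names).

    Built by sequential random joins; edges carry lengths in [bl_lo, bl_hi].
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = list(labels)
    adj: dict[str, list[tuple[str, float]]] = {x: [] for x in labels}
    internal = 0

    def connect(u: str, v: str) -> None:
        w = float(rng.uniform(bl_lo, bl_hi))
        adj[u].append((v, w))
        adj[v].append((u, w))

    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        u = f"n{internal}"
        internal += 1
        adj[u] = []
        connect(nodes[i], u)
        connect(nodes[j], u)
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [u]
    hub = f"n{internal}"
    adj[hub] = []
    for x in nodes:
        connect(x, hub)
    return adj, labels


def tree_path_distances(adj: dict, labels: list[str]):
    """All-pairs path-length distances between leaves by BFS."""
    import collections

    dist = {}
    for src in labels:
        d = {src: 0.0}
        q = collections.deque([src])
        while q:
            u = q.popleft()
            for v, w in adj[u]:
                if v not in d:
                    d[v] = d[u] + w
                    q.append(v)
        for dst in labels:
            dist[(src, dst)] = d[dst]
    return dist


def tree_bipartitions(adj: dict, labels: list[str]) -> set[frozenset]:
    """Non-trivial splits of the leaf set induced by internal edges."""
    all_leaves = frozenset(labels)
    ref = min(all_leaves)
    out = set()
    seen_edges = set()
    for u in adj:
        for v, _ in adj[u]:
            if (v, u) in seen_edges:
                continue
            seen_edges.add((u, v))
            # leaves on v's side when edge u-v is removed
            stack, side, visited = [v], set(), {u, v}
            while stack:
                x = stack.pop()
                if x in labels:
                    side.add(x)
                for y, _ in adj[x]:
                    if y not in visited:
                        visited.add(y)
                        stack.append(y)
            if 1 < len(side) < len(labels) - 1:
                s = frozenset(side)
                out.add(all_leaves - s if ref in s else s)
    return out
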