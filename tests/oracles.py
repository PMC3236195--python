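"""Independent reference implementations used only to check the package.

These deliberately share no code with panorth: a textbook O(mn) affine-gap
local-alignment dynamic program, a breadth-first connected-components
search, and a brute-force mutual-best-hit scan.
"""

from __future__ import annotations

from collections import deque

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def dp_local_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman with affine gaps; a gap of length g costs
    open + g * extend (first gap residue costs open + extend)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    e = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    f = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] - first, e[i][j - 1] - gap_extend)
            f[i][j] = max(h[i - 1][j] - first, f[i - 1][j] - gap_extend)
            diag = h[i - 1][j - 1] + _BLOSUM62[a[i - 1], b[j - 1]]
            h[i][j] = max(0.0, diag, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


def bfs_components(nodes, edges):
    """Connected components by breadth-first search; sorted for comparison."""
    adj = {n: set() for n in nodes}
    for x, y in edges:
        adj[x].add(y)
        adj[y].add(x)
    seen = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = []
        queue = deque([start])
        seen.add(start)
        while queue:
            v = queue.popleft()
            comp.append(v)
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    queue.append(w)
        comps.append(sorted(comp))
    return sorted(comps)


def brute_force_bbh(weights: dict[tuple[str, str], float], taxon_of: dict[str, str]):
    """Mutual best inter-taxon partners by exhaustive argmax.

    ``weights`` maps unordered id pairs (both orders present) to weights.
    Ties resolved toward the lexicographically smallest partner id.
    """
    nodes = sorted(taxon_of)
    best: dict[str, str | None] = {}
    for x in nodes:
        cands = [
            (w, y)
            for (p, y), w in weights.items()
            if p == x and taxon_of[y] != taxon_of[x]
        ]
        if not cands:
            best[x] = None
            continue
        top = max(w for w, _ in cands)
        best[x] = min(y for w, y in cands if w == top)
    out = set()
    for x in nodes:
        y = best[x]
        if y is not None and best.get(y) == x:
            out.add((x, y) if x < y else (y, x))
    return sorted(out)
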