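"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with phamkit's alignment or clustering
paths: plain-Python Gotoh dynamic programming for global/local affine-gap
scores, and breadth-first search for connected components.
"""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def _sub(a: str, b: str) -> float:
    return float(_B62[a, b])


def gotoh_global_score(a: str, b: str, open_: float = -11.0, ext: float = -1.0) -> float:
    """Optimal global alignment score, affine gaps (open = first residue)."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Iy[0][j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = diag + _sub(a[i - 1], b[j - 1])
            Ix[i][j] = max(M[i - 1][j] + open_, Ix[i - 1][j] + ext,
                           Iy[i - 1][j] + open_)
            Iy[i][j] = max(M[i][j - 1] + open_, Iy[i][j - 1] + ext,
                           Ix[i][j - 1] + open_)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def gotoh_local_score(a: str, b: str, open_: float = -11.0, ext: float = -1.0) -> float:
    """Optimal local alignment score, affine gaps; 0 if nothing positive."""
    n, m = len(a), len(b)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_, E[i][j - 1] + ext)
            F[i][j] = max(H[i - 1][j] + open_, F[i - 1][j] + ext)
            H[i][j] = max(0.0, H[i - 1][j - 1] + _sub(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def bfs_components(nodes, edges):
    """Connected components as a sorted list of sorted node lists."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        queue, comp = [start], []
        seen.add(start)
        while queue:
            node = queue.pop()
            comp.append(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(sorted(comp))
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps
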