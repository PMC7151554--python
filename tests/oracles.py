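"""Independent brute-force oracles used to validate the package's primitives.

Everything here is written as plain, slow, obviously-correct Python with full
dynamic-programming matrices and exhaustive enumeration — deliberately sharing
no code with the implementations under test.  The alignment oracles follow the
same documented conventions as the package (gap of length k costs
open + k*extend; needle-style free end gaps counted in the identity
denominator; traceback tie-break diagonal > gap-in-a > gap-in-b) because those
conventions are part of the contract being checked.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.Align import substitution_matrices

NEG = float("-inf")
_BLOSUM = substitution_matrices.load("BLOSUM62")


def blosum(a: str, b: str) -> int:
    return int(_BLOSUM[a, b])


# ---------------------------------------------------------------------------
# local alignment (Smith–Waterman, affine gaps)
# ---------------------------------------------------------------------------

def sw_score_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal local alignment score by full three-matrix DP."""
    m, n = len(a), len(b)
    first = gap_open + gap_extend  # cost of a length-1 gap
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + blosum(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return int(best)


# ---------------------------------------------------------------------------
# global alignment with free end gaps (needle semantics)
# ---------------------------------------------------------------------------

def nw_identity_oracle(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> Tuple[int, int]:
    """(identities, alignment length) of the optimal free-end-gap global
    alignment, traceback tie-break diag > gap-in-a (left) > gap-in-b (up)."""
    m, n = len(a), len(b)
    first = gap_open + gap_extend
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (consumes b)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (consumes a)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                H[i - 1][j - 1] + blosum(a[i - 1], b[j - 1]), E[i][j], F[i][j]
            )
    # free trailing gaps: best cell on last row/column, preferring the corner,
    # then larger j on the bottom row, then larger i on the right column —
    # mirrors scanning order of the implementation (strict improvement only)
    bi, bj, best = m, n, H[m][n]
    for j in range(n + 1):
        if H[m][j] > best:
            best, bi, bj = H[m][j], m, j
    for i in range(m + 1):
        if H[i][n] > best:
            best, bi, bj = H[i][n], i, n
    ident = 0
    length = (m - bi) + (n - bj)
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            diag = H[i - 1][j - 1] + blosum(a[i - 1], b[j - 1])
            if H[i][j] == diag:
                ident += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
                length += 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            length += 1
            # extension strictly preferred only when it beat opening
            ext = E[i][j - 1] - gap_extend
            opn = H[i][j - 1] - first
            j -= 1
            state = "E" if ext > opn else "H"
        else:
            length += 1
            ext = F[i - 1][j] - gap_extend
            opn = H[i - 1][j] - first
            i -= 1
            state = "F" if ext > opn else "H"
    length += i + j
    return ident, length


def global_identity_oracle(a: str, b: str) -> float:
    ident, length = nw_identity_oracle(a, b)
    return 100.0 * ident / length if length else 0.0


# ---------------------------------------------------------------------------
# reciprocal best hits by exhaustive enumeration
# ---------------------------------------------------------------------------

def rbh_oracle(
    ids: Sequence[str],
    scores: np.ndarray,
    passing: np.ndarray,
    genome_of: Optional[Mapping[str, str]] = None,
) -> Set[Tuple[str, str]]:
    """All reciprocal best-hit pairs from a full score matrix.

    Best hit of q within a scope (one genome, or everything when no genome
    map) = highest passing score, ties to lexicographically smallest subject.
    """
    n = len(ids)

    def best(qi: int, scope: List[int]) -> Optional[int]:
        cands = [c for c in scope if c != qi and passing[qi, c]]
        if not cands:
            return None
        top = max(scores[qi, c] for c in cands)
        return min((ids[c], c) for c in cands if scores[qi, c] == top)[1]

    pairs: Set[Tuple[str, str]] = set()
    for qi in range(n):
        for si in range(n):
            if qi == si:
                continue
            if genome_of is None:
                scope_q = list(range(n))
                scope_s = list(range(n))
            else:
                if genome_of[ids[qi]] == genome_of[ids[si]]:
                    continue
                scope_q = [k for k in range(n) if genome_of[ids[k]] == genome_of[ids[si]]]
                scope_s = [k for k in range(n) if genome_of[ids[k]] == genome_of[ids[qi]]]
            if best(qi, scope_q) == si and best(si, scope_s) == qi:
                pairs.add(tuple(sorted((ids[qi], ids[si]))))
    return pairs


# ---------------------------------------------------------------------------
# textbook dense Markov clustering
# ---------------------------------------------------------------------------

def mcl_reference(
    nodes: Sequence[str],
    weighted_edges: Sequence[Tuple[str, str, float]],
    inflation: float = 2.0,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> Set[frozenset]:
    """Whole-matrix expansion/inflation loop; clusters read as the connected
    components of the attractor overlap structure.

    Shares the package's numeric conventions (self-loop = max incident
    weight, entry pruning, column renormalization) but none of its code: one
    dense matrix for the entire graph, no component decomposition.
    """
    nodes = sorted(nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, w in weighted_edges:
        M[index[u], index[v]] = w
        M[index[v], index[u]] = w
    for i in range(n):
        M[i, i] = M[:, i].max() if M[:, i].max() > 0 else 1.0
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = np.power(M @ M, inflation)
        M[M < prune_threshold] = 0.0
        s = M.sum(axis=0, keepdims=True)
        s[s == 0.0] = 1.0
        M = M / s
        if np.abs(M - prev).max() < tol:
            break
    attractors = [i for i in range(n) if M[i, i] > tol] or [int(np.argmax(M.diagonal()))]
    # union attractors sharing flow, then assign every node to the attractor
    # system receiving the largest share of its column flow
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(attractors)
    for a in attractors:
        for b in attractors:
            if a < b and (M[a, b] > tol or M[b, a] > tol):
                g.add_edge(a, b)
    systems = [sorted(c) for c in nx.connected_components(g)]
    clusters: Dict[int, Set[str]] = {}
    for j, v in enumerate(nodes):
        flows = [sum(M[a, j] for a in sys) for sys in systems]
        if max(flows) <= 0.0:
            clusters[-(j + 1)] = {v}
            continue
        top = max(flows)
        winners = [k for k, f in enumerate(flows) if f == top]
        k = min(winners, key=lambda k: nodes[systems[k][0]])
        clusters.setdefault(systems[k][0], set()).add(v)
    return {frozenset(c) for c in clusters.values()}


# ---------------------------------------------------------------------------
# annotation best hit by exhaustive comparison
# ---------------------------------------------------------------------------

def best_reference_hit_oracle(
    query: str,
    reference: Mapping[str, str],
) -> Optional[str]:
    """Reference id with the highest local-alignment score (exhaustive; ties
    to lexicographically smallest id)."""
    scored = sorted(
        ((-sw_score_oracle(query, seq), rid) for rid, seq in reference.items())
    )
    return scored[0][1] if scored else None
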