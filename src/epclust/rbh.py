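"""Within-domain reciprocal best hits (rBBH) on exact local-alignment scores.

Best hits follow the orthology-screen convention: for every query sequence and
every *other genome*, the top-scoring subject in that genome (ties broken by
lexicographically smallest subject id); a pair is reciprocal when each member
is the other's best hit in the partner genome.  When no genome map is given,
"best" means the single best hit in the whole collection.  Reciprocal pairs
are annotated with needle-style global identity and retained only if they pass
the domain's global-identity cutoff (25% for prokaryote pairs, 40% for
eukaryote pairs in the default pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .align import (
    DEFAULT_GLOBAL,
    DEFAULT_SCORING,
    GlobalScoring,
    ScoringScheme,
    all_vs_all_scores,
    global_identity,
    min_score_for_evalue,
)

__all__ = ["RBHPair", "best_hit_table", "reciprocal_best_hits", "rbh_graph_for_domain"]


@dataclass(frozen=True)
class RBHPair:
    """An unordered reciprocal-best-hit pair with its global identity."""

    id_a: str
    id_b: str
    global_identity: float

    def __post_init__(self):
        if self.id_a > self.id_b:
            a, b = self.id_a, self.id_b
            object.__setattr__(self, "id_a", b)
            object.__setattr__(self, "id_b", a)
        if not 0.0 <= self.global_identity <= 100.0:
            raise ValueError("global identity outside [0, 100]")

    def key(self) -> Tuple[str, str]:
        return (self.id_a, self.id_b)


def best_hit_table(
    ids: Sequence[str],
    scores: np.ndarray,
    passing: np.ndarray,
    genome_of: Optional[Mapping[str, str]] = None,
) -> Dict[str, Dict[str, str]]:
    """Best hit of each query, per subject genome (or single-best overall).

    ``scores`` is the symmetric all-vs-all score matrix over ``ids``;
    ``passing`` a boolean matrix of E-value acceptance.  Self-hits are
    excluded; within the scope, the highest score wins and score ties go to
    the lexicographically smallest subject id.  Returns
    ``query -> {subject_genome -> subject_id}`` (genome key ``"*"`` without a
    genome map).
    """
    n = len(ids)
    order = np.argsort(np.asarray(ids, dtype=object), kind="stable")
    best: Dict[str, Dict[str, str]] = {q: {} for q in ids}
    if genome_of is None:
        groups = {"*": order}
        qgenome = np.array([""] * n, dtype=object)
    else:
        grouped: Dict[str, List[int]] = {}
        for pos in order:
            grouped.setdefault(genome_of[ids[pos]], []).append(pos)
        groups = {g: np.asarray(p) for g, p in grouped.items()}
        qgenome = np.array([genome_of[i] for i in ids], dtype=object)
    # genomes outer, all queries at once: argmax over the (few) columns of one
    # genome is vectorized across the whole query axis
    for gname in sorted(groups):
        cols = groups[gname]
        sub = np.where(passing[:, cols], scores[:, cols], -1)
        if len(cols) > 1:
            # mask self-hits (they sit on the matrix diagonal)
            for local_j, c in enumerate(cols):
                sub[c, local_j] = -1
            jbest = np.argmax(sub, axis=1)  # ids sorted -> ties lexicographic
            vals = sub[np.arange(n), jbest]
        else:
            jbest = np.zeros(n, dtype=int)
            vals = sub[:, 0]
            vals[cols[0]] = -1
        for qi in np.nonzero(vals >= 0)[0]:
            if genome_of is not None and qgenome[qi] == gname:
                continue  # best hits only against other genomes
            best[ids[qi]][gname] = ids[cols[jbest[qi]]]
    return best


def reciprocal_best_hits(
    sequences: Mapping[str, str],
    genome_of: Optional[Mapping[str, str]] = None,
    min_global_identity: float = 25.0,
    scoring: ScoringScheme = DEFAULT_SCORING,
    global_scoring: GlobalScoring = DEFAULT_GLOBAL,
    scores: Optional[np.ndarray] = None,
    ids: Optional[Sequence[str]] = None,
) -> List[RBHPair]:
    """Reciprocal best hits within one domain, filtered by global identity.

    A pair (a, b) is emitted iff b is a's best passing hit (within b's genome
    scope) and a is b's best passing hit, and the needle-style global identity
    of the pair passes ``min_global_identity``.  A precomputed score matrix
    over ``ids`` may be supplied to avoid re-aligning.
    """
    if ids is None:
        ids = sorted(sequences)
    if genome_of is not None:
        missing = [i for i in ids if i not in genome_of]
        if missing:
            raise KeyError(f"ids without genome assignment: {missing[:5]}")
    if scores is None:
        scores = all_vs_all_scores([sequences[i] for i in ids], scoring=scoring)
    lens = np.array([len(sequences[i]) for i in ids])
    db_len = int(lens.sum())
    thresholds = np.array([min_score_for_evalue(L, db_len, scoring) for L in lens])
    passing = scores >= thresholds[:, None]  # E cutoff per query row
    best = best_hit_table(list(ids), scores, passing, genome_of)
    pairs: List[RBHPair] = []
    seen = set()
    for a, per_genome in best.items():
        for b in per_genome.values():
            key = (a, b) if a < b else (b, a)
            if key in seen:
                continue
            ga = genome_of[a] if genome_of is not None else "*"
            if best.get(b, {}).get(ga) == a:
                seen.add(key)
                gi = global_identity(sequences[key[0]], sequences[key[1]], global_scoring)
                if gi >= min_global_identity:
                    pairs.append(RBHPair(key[0], key[1], gi))
    pairs.sort(key=RBHPair.key)
    return pairs


def rbh_graph_for_domain(
    sequences: Mapping[str, str],
    genome_of: Mapping[str, str],
    min_global_identity: float,
    scoring: ScoringScheme = DEFAULT_SCORING,
    scores: Optional[np.ndarray] = None,
    ids: Optional[Sequence[str]] = None,
):
    """networkx similarity graph whose edges are RBH pairs weighted by global
    identity (the input to Markov clustering)."""
    import networkx as nx

    pairs = reciprocal_best_hits(
        sequences,
        genome_of=genome_of,
        min_global_identity=min_global_identity,
        scoring=scoring,
        scores=scores,
        ids=ids,
    )
    g = nx.Graph()
    g.add_nodes_from(sorted(sequences))
    for p in pairs:
        g.add_edge(p.id_a, p.id_b, weight=p.global_identity)
    return g
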