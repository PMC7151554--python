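"""Majority-rule functional annotation of EPCs and distribution reporting.

Each member protein of an EPC is assigned the function of its single best hit
in a labeled reference set, provided that hit passes E <= 1e-10 and covers at
least 80% of the query; the EPC's function is the modal assignment over its
annotated members (unannotated members are ignored; ties go to the
lexicographically smallest function id and are flagged).  Category-level
summaries report, per top-level function category, the bacterial vs archaeal
fraction of EPCs and of the eukaryotic sequences inside them.  The
presence/absence reporter emits the EPC x genome binary matrix with genomes
sorted taxonomically and EPCs sorted by their eukaryote-group distribution
signature (photosynthetic-lineage blocks first, then ascending presence).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import (
    DEFAULT_SCORING,
    ScoringScheme,
    all_vs_all_scores,
    e_value,
    local_hit_details,
)
from .epc import EPC
from .simulate import FUNCTION_CATEGORIES, GenomeRecord, PLASTID_GROUPS

__all__ = [
    "AnnotationReference",
    "ClusterAnnotation",
    "annotate_proteins",
    "majority_function",
    "annotate_epcs",
    "category_origin_summary",
    "presence_absence_matrix",
]

DOMAIN_ORDER = {"eukaryote": 0, "bacteria": 1, "archaea": 2}


@dataclass
class AnnotationReference:
    """Labeled reference proteins: seq -> (function id, top-level category)."""

    sequences: Dict[str, str]
    labels: Dict[str, Tuple[str, str]]  # ref_id -> (function_id, category)

    def __post_init__(self):
        if set(self.sequences) != set(self.labels):
            raise ValueError("reference sequences and labels disagree")
        bad = {c for _, c in self.labels.values()} - set(FUNCTION_CATEGORIES)
        if bad:
            raise ValueError(f"categories outside the fixed vocabulary: {sorted(bad)}")

    def __len__(self):
        return len(self.sequences)


@dataclass
class ClusterAnnotation:
    """Majority-rule annotation of one EPC."""

    epc_id: str
    function_id: Optional[str]
    category: Optional[str]
    votes: Dict[str, int]
    tie: bool = False


def annotate_proteins(
    members: Mapping[str, str],
    reference: AnnotationReference,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_coverage: float = 80.0,
    precomputed_scores: Optional[np.ndarray] = None,
    ref_ids: Optional[Sequence[str]] = None,
) -> Dict[str, Optional[str]]:
    """Best-reference-hit function for each member protein.

    A member is annotated with the function of its single best reference hit
    (highest score; ties to the lexicographically smallest reference id) if
    that hit passes the E-value cutoff and covers >= ``min_coverage`` percent
    of the query; otherwise it is unannotated (``None``).
    """
    if len(reference) == 0:
        raise ValueError("empty annotation reference")
    if ref_ids is None:
        ref_ids = sorted(reference.sequences)
    member_ids = sorted(members)
    if precomputed_scores is None:
        scores = all_vs_all_scores(
            [members[m] for m in member_ids],
            [reference.sequences[r] for r in ref_ids],
            scoring,
        )
    else:
        scores = precomputed_scores
    db_len = sum(len(reference.sequences[r]) for r in ref_ids)
    out: Dict[str, Optional[str]] = {}
    for i, mid in enumerate(member_ids):
        j = int(np.argmax(scores[i]))  # ref_ids sorted -> ties lexicographic
        raw = int(scores[i][j])
        ev = e_value(raw, len(members[mid]), db_len, scoring)
        if ev > scoring.evalue_cutoff:
            out[mid] = None
            continue
        _, _, cov = local_hit_details(members[mid], reference.sequences[ref_ids[j]], scoring)
        out[mid] = reference.labels[ref_ids[j]][0] if cov >= min_coverage else None
    return out


def majority_function(
    assignments: Mapping[str, Optional[str]],
    epc_id: str,
    function_category: Mapping[str, str],
) -> ClusterAnnotation:
    """Modal function over annotated members; unannotated members ignored.

    All-unannotated clusters get ``None``.  Ties resolve to the
    lexicographically smallest function id and are flagged.
    """
    votes = Counter(f for f in assignments.values() if f is not None)
    if not votes:
        return ClusterAnnotation(epc_id, None, None, {})
    top = max(votes.values())
    winners = sorted(f for f, c in votes.items() if c == top)
    func = winners[0]
    return ClusterAnnotation(
        epc_id,
        func,
        function_category[func],
        dict(votes),
        tie=len(winners) > 1,
    )


def annotate_epcs(
    epcs: Sequence[EPC],
    sequence_lookup: Mapping[str, str],
    reference: AnnotationReference,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_coverage: float = 80.0,
) -> Dict[str, ClusterAnnotation]:
    """Per-EPC majority-rule annotation over all member proteins (eukaryotic
    and prokaryotic), scored against the reference in one batch."""
    function_category = {f: c for f, c in reference.labels.values()}
    ref_ids = sorted(reference.sequences)
    all_members: Dict[str, str] = {}
    per_epc: Dict[str, List[str]] = {}
    for e in epcs:
        fams = [e.euk_family] + e.prok_families()
        ids = [m for f in fams for m in f.members]
        per_epc[e.epc_id] = ids
        for m in ids:
            all_members[m] = sequence_lookup[m]
    if not all_members:
        return {}
    assignments = annotate_proteins(all_members, reference, scoring, min_coverage)
    out = {}
    for e in epcs:
        sub = {m: assignments[m] for m in per_epc[e.epc_id]}
        out[e.epc_id] = majority_function(sub, e.epc_id, function_category)
    return out


def category_origin_summary(
    annotations: Mapping[str, ClusterAnnotation],
    epcs: Sequence[EPC],
) -> pd.DataFrame:
    """Bacterial vs archaeal fractions per function category.

    Reported at two levels: annotated EPCs (clusters) and the eukaryotic
    sequences inside them.  Only exclusive-origin EPCs enter; categories with
    no annotated EPC are omitted.
    """
    rows = []
    for e in epcs:
        if e.origin not in ("bacterial", "archaeal"):
            continue
        ann = annotations.get(e.epc_id)
        if ann is None or ann.category is None:
            continue
        rows.append(
            {
                "category": ann.category,
                "origin": e.origin,
                "n_euk_seqs": len(e.euk_family.members),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "category",
                "n_epcs",
                "frac_bacterial_epcs",
                "frac_archaeal_epcs",
                "frac_bacterial_seqs",
                "frac_archaeal_seqs",
            ]
        )
    df = pd.DataFrame(rows)
    out = []
    for cat, sub in df.groupby("category"):
        n = len(sub)
        fb = (sub.origin == "bacterial").mean()
        wb = sub.loc[sub.origin == "bacterial", "n_euk_seqs"].sum() / sub.n_euk_seqs.sum()
        out.append(
            {
                "category": cat,
                "n_epcs": n,
                "frac_bacterial_epcs": fb,
                "frac_archaeal_epcs": 1.0 - fb,
                "frac_bacterial_seqs": wb,
                "frac_archaeal_seqs": 1.0 - wb,
            }
        )
    return pd.DataFrame(out).sort_values("category").reset_index(drop=True)


def _epc_sort_key(epc: EPC, genome_info: Mapping[str, GenomeRecord]):
    groups = sorted(
        {genome_info[g].group for g in epc.euk_genomes if genome_info[g].group}
    )
    photosynthetic_only = bool(groups) and all(g in PLASTID_GROUPS for g in groups)
    presence = len(epc.euk_genomes) + len(epc.prok_genomes)
    # photosynthetic-lineage blocks first, narrower signatures before wider,
    # then ascending presence density, then id for determinism
    return (0 if photosynthetic_only else 1, len(groups), tuple(groups), presence, epc.epc_id)


def presence_absence_matrix(
    epcs: Sequence[EPC],
    genomes: Sequence[GenomeRecord],
    figure_path: Optional[str] = None,
) -> pd.DataFrame:
    """Binary EPC x genome presence matrix with the survey's display ordering.

    Rows are EPCs sorted by eukaryote-group signature (clusters confined to
    the photosynthetic lineages — Archaeplastida, and SAR/Hacrobia where
    shared with Archaeplastida only — first), then ascending presence density;
    columns are genomes sorted taxonomically (eukaryotes by group, then
    bacteria by genus, then archaea).  Optionally renders a raster figure.
    """
    info = {g.genome_id: g for g in genomes}
    for e in epcs:
        for g in e.euk_genomes | e.prok_genomes:
            if g not in info:
                raise KeyError(f"genome {g} present in EPC {e.epc_id} but not in metadata")
    cols = sorted(
        genomes,
        key=lambda g: (DOMAIN_ORDER[g.domain], g.group, g.genus, g.genome_id),
    )
    col_ids = [g.genome_id for g in cols]
    ordered = sorted(epcs, key=lambda e: _epc_sort_key(e, info))
    mat = pd.DataFrame(
        0, index=[e.epc_id for e in ordered], columns=col_ids, dtype=np.int8
    )
    for e in ordered:
        for g in e.euk_genomes | e.prok_genomes:
            mat.at[e.epc_id, g] = 1
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 5))
        ax.imshow(mat.values, aspect="auto", cmap="Greys", interpolation="nearest")
        ax.set_xlabel("genomes (taxonomic order)")
        ax.set_ylabel("EPCs (distribution order)")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return mat
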