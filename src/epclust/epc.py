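"""Eukaryote–prokaryote cluster (EPC) assembly.

Links eukaryotic protein families to prokaryotic families with the
reciprocal-best-cluster rule: a eukaryote family and a prokaryote family are
linked when at least half of each family's qualifying best interdomain hits
land in the other (qualifying: E <= 1e-10 and local identity >= 30%; members
without a qualifying hit are excluded from the denominator — configurable).
Best interdomain hits are taken per prokaryotic domain, so a eukaryote family
can expose both its best bacterial and its best archaeal partner.

Each linked eukaryote family becomes an EPC with an origin:

* ``bacterial`` / ``archaeal`` — exclusive single-domain link;
* ``dual`` — one bacterial and one archaeal link whose prokaryotic families
  are themselves homologous (merged; excluded from origin proportions);
* ``ambiguous`` — links to multiple non-homologous prokaryotic families
  (excluded entirely).

Exclusive EPCs are then *rechecked*: if any eukaryote member has a hit in the
remaining prokaryotic domain at E <= 1e-10 and global identity >= 25%, the EPC
is excluded from origin assignment (``excluded_by_recheck``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Mapping, Sequence, Tuple

from .mcl import ProteinFamily

__all__ = ["ClusterLink", "EPC", "link_clusters", "classify_epc", "recheck_exclusive", "epc_accounting"]

EXCLUSIVE_ORIGINS = ("bacterial", "archaeal")


@dataclass(frozen=True)
class ClusterLink:
    """A reciprocal-best-cluster link between a eukaryote and a prokaryote family."""

    euk_family_id: str
    prok_family_id: str
    prok_domain: str  # bacteria | archaea
    forward_correspondence: float  # fraction of euk best hits landing in prok family
    reverse_correspondence: float  # fraction of prok best hits landing in euk family

    def __post_init__(self):
        for v in (self.forward_correspondence, self.reverse_correspondence):
            if not 0.0 <= v <= 1.0:
                raise ValueError("correspondence outside [0, 1]")


@dataclass
class EPC:
    """A eukaryote family merged with its homologous prokaryote family/families."""

    epc_id: str
    euk_family: ProteinFamily
    bacterial_families: List[ProteinFamily] = field(default_factory=list)
    archaeal_families: List[ProteinFamily] = field(default_factory=list)
    origin: str = "none"
    euk_genomes: FrozenSet[str] = frozenset()  # each genome once, paralogs collapsed
    prok_genomes: FrozenSet[str] = frozenset()

    def prok_families(self) -> List[ProteinFamily]:
        return self.bacterial_families + self.archaeal_families


def link_clusters(
    euk_families: Sequence[ProteinFamily],
    prok_families: Sequence[ProteinFamily],
    best_interdomain_hits: Mapping[str, Mapping[str, Tuple[str, float, float]]],
    min_correspondence: float = 0.5,
    min_local_identity: float = 30.0,
    evalue_cutoff: float = 1e-10,
    denominator: str = "hit_bearing",
) -> List[ClusterLink]:
    """Reciprocal-best-cluster links between retained families.

    ``best_interdomain_hits`` maps each sequence id to, per opposite domain
    (``"bacteria"``/``"archaea"`` for eukaryote sequences, ``"eukaryote"`` for
    prokaryote sequences), its best interdomain hit as
    ``(subject_id, e_value, local_identity)``.  A link is emitted iff both the
    forward (eukaryote-side) and reverse (prokaryote-side) correspondences
    reach ``min_correspondence``, counting only qualifying hits.

    ``denominator`` selects the correspondence denominator: ``"hit_bearing"``
    (members with a qualifying hit; default) or ``"all_members"``.
    """
    if denominator not in ("hit_bearing", "all_members"):
        raise ValueError("denominator must be 'hit_bearing' or 'all_members'")
    fam_of_seq: Dict[str, str] = {}
    for fam in list(euk_families) + list(prok_families):
        for m in fam.members:
            fam_of_seq[m] = fam.family_id
    prok_by_id = {f.family_id: f for f in prok_families}

    def qualifying(hit) -> bool:
        if hit is None:
            return False
        sid, ev, ident = hit
        if sid not in fam_of_seq:
            raise KeyError(f"hit subject {sid} outside any retained family")
        return ev <= evalue_cutoff and ident >= min_local_identity

    links: List[ClusterLink] = []
    for ef in euk_families:
        # forward: where do this family's best per-domain hits land?
        votes: Dict[Tuple[str, str], int] = {}
        denom: Dict[str, int] = {"bacteria": 0, "archaea": 0}
        for m in ef.members:
            per_domain = best_interdomain_hits.get(m, {})
            for dom in ("bacteria", "archaea"):
                hit = per_domain.get(dom)
                if qualifying(hit):
                    denom[dom] += 1
                    votes[(dom, fam_of_seq[hit[0]])] = votes.get((dom, fam_of_seq[hit[0]]), 0) + 1
                elif denominator == "all_members":
                    denom[dom] += 1
        for (dom, pfid), count in sorted(votes.items()):
            fwd = count / denom[dom] if denom[dom] else 0.0
            if fwd < min_correspondence:
                continue
            pf = prok_by_id[pfid]
            rev_hits = 0
            rev_denom = 0
            for m in pf.members:
                hit = best_interdomain_hits.get(m, {}).get("eukaryote")
                if qualifying(hit):
                    rev_denom += 1
                    if fam_of_seq[hit[0]] == ef.family_id:
                        rev_hits += 1
                elif denominator == "all_members":
                    rev_denom += 1
            rev = rev_hits / rev_denom if rev_denom else 0.0
            if rev >= min_correspondence:
                links.append(ClusterLink(ef.family_id, pfid, dom, fwd, rev))
    return links


def classify_epc(
    euk_family: ProteinFamily,
    links: Sequence[ClusterLink],
    prok_families: Mapping[str, ProteinFamily],
    prok_homology: Callable[[str, str], bool],
    epc_id: str,
) -> EPC:
    """Assign an origin to a linked eukaryote family.

    One bacterial link only -> bacterial; one archaeal link only -> archaeal;
    one of each whose prokaryotic families are homologous -> dual (merged EPC,
    excluded from origin proportions); links to multiple non-homologous
    prokaryote families -> ambiguous; no links -> eukaryote-specific
    (origin ``none``, not an EPC).
    """
    for l in links:
        if l.euk_family_id != euk_family.family_id:
            raise ValueError("link does not reference this eukaryote family")
    bact = sorted({l.prok_family_id for l in links if l.prok_domain == "bacteria"})
    arch = sorted({l.prok_family_id for l in links if l.prok_domain == "archaea"})
    epc = EPC(
        epc_id=epc_id,
        euk_family=euk_family,
        bacterial_families=[prok_families[f] for f in bact],
        archaeal_families=[prok_families[f] for f in arch],
    )
    n_linked = len(bact) + len(arch)
    if n_linked == 0:
        epc.origin = "none"
    elif len(bact) == 1 and not arch:
        epc.origin = "bacterial"
    elif len(arch) == 1 and not bact:
        epc.origin = "archaeal"
    elif len(bact) == 1 and len(arch) == 1 and prok_homology(bact[0], arch[0]):
        epc.origin = "dual"
    else:
        epc.origin = "ambiguous"
    epc.euk_genomes = frozenset(euk_family.genomes)
    epc.prok_genomes = frozenset(
        g for f in epc.prok_families() for g in f.genomes
    )
    return epc


def recheck_exclusive(
    epc: EPC,
    other_domain_hit: Callable[[str], bool],
) -> EPC:
    """Exclude an exclusive EPC whose eukaryote members still detect the
    remaining prokaryotic domain.

    ``other_domain_hit(seq_id)`` reports whether a eukaryote member has a hit
    in the *other* prokaryotic domain passing E <= 1e-10 and global identity
    >= 25%.  Idempotent: re-running on an already-excluded or non-exclusive
    EPC returns it unchanged.
    """
    if epc.origin not in EXCLUSIVE_ORIGINS:
        return epc
    if any(other_domain_hit(m) for m in epc.euk_family.members):
        out = replace_origin(epc, "excluded_by_recheck")
        return out
    return epc


def replace_origin(epc: EPC, origin: str) -> EPC:
    out = EPC(
        epc_id=epc.epc_id,
        euk_family=epc.euk_family,
        bacterial_families=list(epc.bacterial_families),
        archaeal_families=list(epc.archaeal_families),
        origin=origin,
        euk_genomes=epc.euk_genomes,
        prok_genomes=epc.prok_genomes,
    )
    return out


def epc_accounting(epcs: Sequence[EPC]) -> Dict[str, int]:
    """Counters for the pipeline manifest's accounting identities."""
    by = lambda o: sum(1 for e in epcs if e.origin == o)
    n_bact, n_arch, n_dual, n_amb = (
        by("bacterial"),
        by("archaeal"),
        by("dual"),
        by("ambiguous"),
    )
    n_excluded = by("excluded_by_recheck")
    return {
        "n_bacterial_only": n_bact,
        "n_archaeal_only": n_arch,
        "n_dual": n_dual,
        "n_ambiguous": n_amb,
        "n_recheck_excluded": n_excluded,
        "n_epc": n_bact + n_arch + n_dual + n_excluded,
        "n_exclusive_before_recheck": n_bact + n_arch + n_excluded,
        "n_final": n_bact + n_arch,
    }
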