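"""EPC assembly: reciprocal-best-cluster links, origin classes, recheck."""

import pytest

from epclust.epc import (
    EPC,
    ClusterLink,
    classify_epc,
    epc_accounting,
    link_clusters,
    recheck_exclusive,
)
from epclust.mcl import ProteinFamily


def fam(fid, domain, genomes):
    members = [f"{fid}_m{i}" for i in range(len(genomes))]
    return ProteinFamily(fid, domain, members, list(genomes))


def hits_for(family, domain_key, target_family, n_hitting, evalue=1e-20, ident=60.0):
    """Best-hit table entries: first n members hit the target family."""
    out = {}
    for i, m in enumerate(family.members):
        if i < n_hitting:
            out[m] = {domain_key: (target_family.members[0], evalue, ident)}
    return out


def test_link_requires_both_correspondences():
    ef = fam("E1", "eukaryote", [f"e{i}" for i in range(10)])
    pf = fam("B1", "bacteria", [f"b{i}" for i in range(9)])
    hits = {}
    # forward: 6/10 euk members' best bacterial hits land in B1
    for i, m in enumerate(ef.members):
        if i < 6:
            hits[m] = {"bacteria": (pf.members[0], 1e-20, 60.0)}
    # reverse: 7/9 prok members' best eukaryote hits land in E1
    other = fam("E9", "eukaryote", ["x1", "x2"])
    for i, m in enumerate(pf.members):
        target = ef.members[0] if i < 7 else other.members[0]
        hits[m] = {"eukaryote": (target, 1e-20, 60.0)}
    links = link_clusters([ef, other], [pf], hits)
    assert len(links) == 1
    l = links[0]
    assert (l.euk_family_id, l.prok_family_id) == ("E1", "B1")
    assert l.forward_correspondence == 1.0  # 6 of the 6 hit-bearing members
    assert l.reverse_correspondence == pytest.approx(7 / 9)


def test_all_members_denominator_blocks_sparse_links():
    ef = fam("E1", "eukaryote", [f"e{i}" for i in range(10)])
    pf = fam("B1", "bacteria", [f"b{i}" for i in range(5)])
    hits = hits_for(ef, "bacteria", pf, n_hitting=4)
    for m in pf.members:
        hits[m] = {"eukaryote": (ef.members[0], 1e-20, 60.0)}
    assert link_clusters([ef], [pf], hits, denominator="all_members") == []
    assert len(link_clusters([ef], [pf], hits, denominator="hit_bearing")) == 1


def test_low_identity_hits_do_not_qualify():
    """Hits at 29% local identity are ignored by the correspondence counts."""
    ef = fam("E1", "eukaryote", ["e0", "e1"])
    pf = fam("B1", "bacteria", ["b0", "b1", "b2", "b3", "b4"])
    hits = {m: {"bacteria": (pf.members[0], 1e-20, 29.0)} for m in ef.members}
    for m in pf.members:
        hits[m] = {"eukaryote": (ef.members[0], 1e-20, 29.0)}
    assert link_clusters([ef], [pf], hits) == []


def test_evalue_gate_on_links():
    ef = fam("E1", "eukaryote", ["e0", "e1"])
    pf = fam("B1", "bacteria", ["b0", "b1", "b2", "b3", "b4"])
    hits = {m: {"bacteria": (pf.members[0], 1e-5, 60.0)} for m in ef.members}
    for m in pf.members:
        hits[m] = {"eukaryote": (ef.members[0], 1e-5, 60.0)}
    assert link_clusters([ef], [pf], hits) == []


def link(ef, pf, dom):
    return ClusterLink(ef.family_id, pf.family_id, dom, 1.0, 1.0)


def test_origin_classification_matrix():
    ef = fam("E1", "eukaryote", ["e1", "e2"])
    b1 = fam("B1", "bacteria", ["g1"] * 5)
    b2 = fam("B2", "bacteria", ["g2"] * 5)
    a1 = fam("A1", "archaea", ["h1"] * 5)
    fams = {f.family_id: f for f in (b1, b2, a1)}
    always = lambda x, y: True
    never = lambda x, y: False

    assert classify_epc(ef, [link(ef, b1, "bacteria")], fams, never, "P1").origin == "bacterial"
    assert classify_epc(ef, [link(ef, a1, "archaea")], fams, never, "P2").origin == "archaeal"
    dual = classify_epc(
        ef, [link(ef, b1, "bacteria"), link(ef, a1, "archaea")], fams, always, "P3"
    )
    assert dual.origin == "dual"
    assert (
        classify_epc(
            ef, [link(ef, b1, "bacteria"), link(ef, a1, "archaea")], fams, never, "P4"
        ).origin
        == "ambiguous"
    )
    assert (
        classify_epc(
            ef, [link(ef, b1, "bacteria"), link(ef, b2, "bacteria")], fams, never, "P5"
        ).origin
        == "ambiguous"
    )
    assert classify_epc(ef, [], fams, never, "P6").origin == "none"


def test_presence_sets_collapse_paralogs():
    ef = ProteinFamily("E1", "eukaryote", ["m1", "m2", "m3"], ["e1", "e1", "e2"])
    b1 = fam("B1", "bacteria", ["g1", "g2", "g1", "g3", "g2"])
    epc = classify_epc(ef, [link(ef, b1, "bacteria")], {"B1": b1}, lambda x, y: False, "P1")
    assert epc.euk_genomes == frozenset({"e1", "e2"})  # e1 counted once
    assert epc.prok_genomes == frozenset({"g1", "g2", "g3"})


def make_exclusive_epc(origin="bacterial"):
    ef = fam("E1", "eukaryote", ["e1", "e2"])
    b1 = fam("B1", "bacteria", ["g1"] * 5)
    return classify_epc(ef, [link(ef, b1, "bacteria")], {"B1": b1}, lambda x, y: False, "P1")


def test_recheck_excludes_on_other_domain_hit():
    epc = make_exclusive_epc()
    hit = lambda seq_id: True  # e.g. archaeal match at 26% global identity, E=1e-12
    out = recheck_exclusive(epc, hit)
    assert out.origin == "excluded_by_recheck"
    # idempotent
    assert recheck_exclusive(out, hit).origin == "excluded_by_recheck"


def test_recheck_keeps_clean_epcs():
    epc = make_exclusive_epc()
    assert recheck_exclusive(epc, lambda s: False).origin == "bacterial"


def test_accounting_identities_on_mixture():
    epcs = []
    for i, origin in enumerate(
        ["bacterial"] * 5 + ["archaeal"] * 3 + ["dual"] * 2 + ["ambiguous"] + ["excluded_by_recheck"]
    ):
        e = make_exclusive_epc()
        e.origin = origin
        epcs.append(e)
    acc = epc_accounting(epcs)
    assert acc["n_epc"] == acc["n_bacterial_only"] + acc["n_archaeal_only"] + acc["n_dual"] + acc["n_recheck_excluded"]
    assert acc["n_final"] == 5 + 3
    assert acc["n_exclusive_before_recheck"] == 5 + 3 + 1


def test_link_with_unknown_subject_raises():
    ef = fam("E1", "eukaryote", ["e0"])
    pf = fam("B1", "bacteria", ["b0"] * 5)
    hits = {"E1_m0": {"bacteria": ("nobody", 1e-20, 60.0)}}
    with pytest.raises(KeyError):
        link_clusters([ef], [pf], hits)
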