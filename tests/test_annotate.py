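"""Majority-rule annotation, category summaries, presence/absence matrix."""

import random

import numpy as np
import pandas as pd
import pytest

from epclust.annotate import (
    AnnotationReference,
    annotate_proteins,
    category_origin_summary,
    majority_function,
    presence_absence_matrix,
)
from epclust.epc import EPC
from epclust.mcl import ProteinFamily
from epclust.simulate import GenomeRecord

from conftest import mutated, random_protein
from oracles import best_reference_hit_oracle


def make_reference(rng, n=5, length=120):
    seqs = {f"r{i}": random_protein(rng, length) for i in range(n)}
    labels = {f"r{i}": (f"K{i:03d}", "metabolism") for i in range(n)}
    return AnnotationReference(seqs, labels)


def test_self_match_gets_reference_function():
    rng = random.Random(0)
    ref = make_reference(rng)
    members = {"m1": ref.sequences["r2"]}
    assert annotate_proteins(members, ref) == {"m1": "K002"}


def test_coverage_gate_blocks_partial_alignments():
    rng = random.Random(1)
    ref = make_reference(rng, n=1, length=100)
    # member shares only its first half with the reference: ~50% coverage
    member = ref.sequences["r0"][:50] + random_protein(rng, 50)
    hit60 = annotate_proteins({"m": member}, ref, min_coverage=80.0)
    assert hit60 == {"m": None}
    assert annotate_proteins({"m": member}, ref, min_coverage=40.0) == {"m": "K000"}


def test_no_passing_hit_means_unannotated():
    rng = random.Random(2)
    ref = make_reference(rng)
    assert annotate_proteins({"m": random_protein(rng, 120)}, ref) == {"m": None}
    with pytest.raises(ValueError):
        annotate_proteins({"m": "MKVL"}, AnnotationReference({}, {}))


def test_best_hit_matches_exhaustive_oracle():
    rng = random.Random(3)
    base = random_protein(rng, 90)
    ref_seqs = {f"r{i}": mutated(rng, base, rng.uniform(0.5, 0.9)) for i in range(5)}
    labels = {f"r{i}": (f"K{i:03d}", "information") for i in range(5)}
    ref = AnnotationReference(ref_seqs, labels)
    for trial in range(6):
        member = mutated(rng, base, rng.uniform(0.6, 0.95))
        got = annotate_proteins({"m": member}, ref)["m"]
        expected_rid = best_reference_hit_oracle(member, ref_seqs)
        assert got == labels[expected_rid][0]


def test_majority_rule_and_ties():
    cat = {"K1": "metabolism", "K2": "information"}
    ann = majority_function({"a": "K1", "b": "K1", "c": "K1", "d": "K2"}, "P1", cat)
    assert ann.function_id == "K1" and ann.category == "metabolism" and not ann.tie
    # unannotated members are ignored and never change the outcome
    ann2 = majority_function(
        {"a": "K1", "b": "K1", "c": "K1", "d": "K2", "x": None, "y": None}, "P1", cat
    )
    assert ann2.function_id == "K1"
    # all unannotated -> none
    assert majority_function({"a": None}, "P1", cat).function_id is None
    # tie -> lexicographically smallest, flagged
    tie = majority_function({"a": "K2", "b": "K1"}, "P1", cat)
    assert tie.function_id == "K1" and tie.tie


def euk_fam(fid, genomes, n_members=None):
    n = n_members or len(genomes)
    return ProteinFamily(fid, "eukaryote", [f"{fid}_m{i}" for i in range(n)], list(genomes))


def make_epc(epc_id, origin, euk_genomes, prok_genomes=("b1",), n_members=None):
    e = EPC(epc_id=epc_id, euk_family=euk_fam(f"{epc_id}E", euk_genomes, n_members), origin=origin)
    e.euk_genomes = frozenset(euk_genomes)
    e.prok_genomes = frozenset(prok_genomes)
    return e


class FakeAnnotation:
    def __init__(self, epc_id, category):
        self.epc_id = epc_id
        self.category = category
        self.function_id = "K000"


def test_category_origin_summary_recovers_planted_correlation():
    """Planted P(metabolism | bacterial) = 0.7 must be recovered within the
    binomial band at >= 100 families."""
    rng = random.Random(4)
    epcs, anns = [], {}
    for i in range(120):
        origin = "bacterial" if i < 70 else "archaeal"
        if origin == "bacterial":
            cat = "metabolism" if rng.random() < 0.7 else "information"
        else:
            cat = "information" if rng.random() < 0.7 else "metabolism"
        e = make_epc(f"P{i}", origin, ["e1", "e2"])
        epcs.append(e)
        anns[e.epc_id] = FakeAnnotation(e.epc_id, cat)
    table = category_origin_summary(anns, epcs).set_index("category")
    met_b = table.loc["metabolism", "frac_bacterial_epcs"]
    inf_b = table.loc["information", "frac_bacterial_epcs"]
    assert met_b > 0.5 > inf_b
    # 70-ish bacterial metabolism EPCs vs 15-ish archaeal ones
    assert met_b == pytest.approx(0.77, abs=0.1)


def test_category_summary_empty_input():
    assert len(category_origin_summary({}, [])) == 0


def genome(gid, domain, group="", genus="", plastid=False):
    return GenomeRecord(gid, domain, genus or gid, group, plastid, False)


def test_presence_matrix_marginals_and_all_ones_row():
    genomes = [
        genome("e1", "eukaryote", "Archaeplastida", plastid=True),
        genome("e2", "eukaryote", "Opisthokonts"),
        genome("b1", "bacteria"),
        genome("b2", "bacteria"),
        genome("a1", "archaea"),
    ]
    epcs = [
        make_epc("P1", "bacterial", ["e1", "e2"], ["b1", "b2", "a1"]),
        make_epc("P2", "bacterial", ["e1"], ["b1"]),
        make_epc("P3", "archaeal", ["e2"], ["a1"]),
    ]
    mat = presence_absence_matrix(epcs, genomes)
    assert mat.shape == (3, 5)
    assert mat.loc["P1"].sum() == 5  # present everywhere -> all-ones line
    assert mat.loc["P2"].sum() == 2
    assert mat.values.sum() == sum(
        len(e.euk_genomes | e.prok_genomes) for e in epcs
    )


def test_presence_matrix_photosynthetic_blocks_first():
    genomes = [
        genome("e1", "eukaryote", "Archaeplastida", plastid=True),
        genome("e2", "eukaryote", "SAR", plastid=True),
        genome("e3", "eukaryote", "Opisthokonts"),
        genome("b1", "bacteria"),
    ]
    confined = make_epc("P_arc", "bacterial", ["e1"], ["b1"])  # Archaeplastida only
    shared_photo = make_epc("P_as", "bacterial", ["e1", "e2"], ["b1"])  # +SAR
    universal = make_epc("P_uni", "bacterial", ["e1", "e2", "e3"], ["b1"])
    mat = presence_absence_matrix([universal, shared_photo, confined], genomes)
    order = list(mat.index)
    assert order.index("P_arc") < order.index("P_uni")
    assert order.index("P_as") < order.index("P_uni")
    assert order.index("P_arc") < order.index("P_as")  # narrower signature first


def test_presence_matrix_unknown_genome_raises():
    genomes = [genome("e1", "eukaryote", "SAR")]
    with pytest.raises(KeyError):
        presence_absence_matrix([make_epc("P1", "bacterial", ["e1"], ["bX"])], genomes)
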