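"""Downsampling estimator: quotas, replicate scoring, proportions, summaries."""

import numpy as np
import pandas as pd
import pytest

from epclust.ancestry import (
    AncestryEstimate,
    DownsampleScheme,
    draw_bacterial_subsample,
    estimate_proportions,
    group_summary,
    largest_remainder_quotas,
    score_replicate,
    size_correlation,
)
from epclust.epc import EPC
from epclust.mcl import ProteinFamily


def make_epc(epc_id, origin, euk_genomes, prok_genomes):
    ef = ProteinFamily(f"{epc_id}_E", "eukaryote", list(euk_genomes), list(euk_genomes))
    e = EPC(epc_id=epc_id, euk_family=ef, origin=origin)
    e.euk_genomes = frozenset(euk_genomes)
    e.prok_genomes = frozenset(prok_genomes)
    return e


def test_quota_arithmetic_matches_hand_computation():
    # a genus holding 50% of the genomes gets 50 of a 100-genome sample
    assert largest_remainder_quotas([100, 60, 40], 100) == [50, 30, 20]
    # fractional remainders: 3 * [3,3,1]/7 = [1.29, 1.29, 0.43] -> largest
    # remainder sends the spare unit to the third stratum
    assert largest_remainder_quotas([3, 3, 1], 3) == [1, 1, 1]
    # quotas never exceed stratum sizes; surplus is reallocated
    assert largest_remainder_quotas([5, 1], 6) == [5, 1]
    assert sum(largest_remainder_quotas([7, 5, 3, 2], 10)) == 10


def test_scheme_validation():
    table = {"g1": ["b1", "b2"], "g2": ["b3"]}
    with pytest.raises(ValueError):
        DownsampleScheme(table, sample_size=0)
    with pytest.raises(ValueError):
        DownsampleScheme(table, sample_size=4)
    with pytest.raises(ValueError):
        DownsampleScheme(table, sample_size=2, n_replicates=0)


def test_draw_is_deterministic_and_exhaustive_at_full_size():
    table = {"g1": ["b1", "b2", "b3"], "g2": ["b4", "b5"]}
    scheme = DownsampleScheme(table, sample_size=5, n_replicates=3, seed=9)
    for r in range(3):
        assert draw_bacterial_subsample(scheme, r) == {"b1", "b2", "b3", "b4", "b5"}
    partial = DownsampleScheme(table, sample_size=3, n_replicates=3, seed=9)
    s1 = draw_bacterial_subsample(partial, 1)
    assert s1 == draw_bacterial_subsample(partial, 1)
    assert len(s1) == 3
    # stratified: quota 2 from the 3-genome genus, 1 from the other
    assert len(s1 & {"b1", "b2", "b3"}) == 2


def test_score_replicate_counts_once_per_epc():
    epcs = [
        make_epc("P1", "bacterial", ["e1"], ["b1", "b2"]),
        make_epc("P2", "bacterial", ["e1"], ["b2"]),
        make_epc("P3", "bacterial", ["e1", "e2"], ["b3"]),
        make_epc("P4", "archaeal", ["e1"], ["a1"]),
    ]
    counts = score_replicate(epcs, bacterial_sample={"b1", "b2", "b3"}, archaeal_set={"a1"})
    assert counts["e1"] == (3, 1)
    assert counts["e2"] == (1, 0)
    # absence rule: a bacterial EPC with no sampled carrier contributes nothing
    counts2 = score_replicate(epcs, bacterial_sample={"b3"}, archaeal_set={"a1"})
    assert counts2["e1"] == (1, 1)


def test_score_replicate_rejects_nonexclusive():
    with pytest.raises(ValueError):
        score_replicate([make_epc("P", "dual", ["e1"], ["b1"])], {"b1"}, set())


def full_table(n):
    return {"g": [f"b{i}" for i in range(n)]}


def test_full_population_sampling_equals_direct_counting():
    """Unbiasedness guard: with sample_size = the whole population the
    replicate mean equals the deterministic direct count exactly."""
    epcs = [
        make_epc("P1", "bacterial", ["e1", "e2"], ["b0", "b3"]),
        make_epc("P2", "bacterial", ["e2"], ["b4"]),
        make_epc("P3", "archaeal", ["e1"], ["a1"]),
    ]
    scheme = DownsampleScheme(full_table(6), sample_size=6, n_replicates=25, seed=3)
    ests = {e.genome_id: e for e in estimate_proportions(epcs, scheme, {"a1"})}
    assert ests["e1"].mean_bacterial == 1.0 and ests["e1"].mean_archaeal == 1.0
    assert ests["e2"].mean_bacterial == 2.0
    assert ests["e1"].sd_bacterial == 0.0
    assert ests["e1"].p_bacterial == 0.5


def test_estimates_order_invariant_and_seeded():
    epcs = [
        make_epc("P1", "bacterial", ["e1"], ["b0", "b1"]),
        make_epc("P2", "archaeal", ["e1"], ["a1"]),
        make_epc("P3", "bacterial", ["e1"], ["b2"]),
    ]
    scheme = DownsampleScheme(full_table(4), sample_size=2, n_replicates=40, seed=5)
    a = estimate_proportions(epcs, scheme, {"a1"})
    b = estimate_proportions(list(reversed(epcs)), scheme, {"a1"})
    assert [(e.genome_id, e.mean_bacterial, e.mean_archaeal) for e in a] == [
        (e.genome_id, e.mean_bacterial, e.mean_archaeal) for e in b
    ]


def test_zero_count_genomes_flagged_undefined():
    epcs = [make_epc("P1", "bacterial", ["e1"], ["b0"])]
    scheme = DownsampleScheme(full_table(2), sample_size=2, n_replicates=5, seed=1)
    ests = estimate_proportions(epcs, scheme, {"a1"}, eukaryote_genomes=["e1", "e9"])
    by_id = {e.genome_id: e for e in ests}
    assert by_id["e9"].undefined and by_id["e9"].p_bacterial is None
    assert by_id["e1"].p_bacterial == 1.0


def test_group_summary_means_and_composites():
    ests = [
        AncestryEstimate("e1", 6.0, 4.0, 0.0, 0.0),  # p_bact 0.6
        AncestryEstimate("e2", 7.0, 3.0, 0.0, 0.0),  # p_bact 0.7
        AncestryEstimate("e3", 2.0, 8.0, 0.0, 0.0),  # p_bact 0.2
    ]
    gmap = {
        "e1": {"group": "Opisthokonts", "plastid": False, "parasite": False},
        "e2": {"group": "Opisthokonts", "plastid": False, "parasite": False},
        "e3": {"group": "Archaeplastida", "plastid": True, "parasite": True},
    }
    table = group_summary(ests, gmap).set_index("group")
    assert table.loc["Opisthokonts", "p_bacterial"] == pytest.approx(0.65)
    assert table.loc["Archaeplastida", "p_bacterial"] == pytest.approx(0.2)
    assert table.loc["All eukaryotes", "p_bacterial"] == pytest.approx(0.5)
    assert table.loc["All with plastids", "p_bacterial"] == pytest.approx(0.2)
    assert table.loc["Parasites", "n_genomes"] == 1
    # archaeal and bacterial columns are complementary
    assert np.allclose(table.p_archaeal + table.p_bacterial, 1.0)
    with pytest.raises(KeyError):
        group_summary(ests, {"e1": gmap["e1"]})


def test_size_correlation_perfect_and_closed_form():
    ests = [AncestryEstimate(f"e{i}", 2.0 * s, 1.0 * s, 0, 0) for i, s in enumerate([1, 2, 3, 4, 5])]
    sizes = {f"e{i}": s * 100 for i, s in enumerate([1, 2, 3, 4, 5])}
    r2a, r2b = size_correlation(ests, sizes)
    assert r2a == pytest.approx(1.0) and r2b == pytest.approx(1.0)

    # 5-point toy table vs the covariance formula computed by hand
    bact = [3.0, 5.0, 4.0, 8.0, 6.0]
    arch = [2.0, 2.0, 7.0, 4.0, 9.0]
    size = [100.0, 150.0, 170.0, 210.0, 260.0]
    ests = [AncestryEstimate(f"g{i}", b, a, 0, 0) for i, (b, a) in enumerate(zip(bact, arch))]
    sz = {f"g{i}": s for i, s in enumerate(size)}

    def r2(x, y):
        x, y = np.asarray(x), np.asarray(y)
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        return cov**2 / (x.var() * y.var())

    r2a, r2b = size_correlation(ests, sz)
    assert r2a == pytest.approx(r2(arch, size))
    assert r2b == pytest.approx(r2(bact, size))

    with pytest.raises(ValueError):
        size_correlation(ests[:2], sz)
    with pytest.raises(ValueError):
        size_correlation(ests, {f"g{i}": 100.0 for i in range(5)})
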