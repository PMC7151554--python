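"""Synthetic-data generator: determinism, planted structure, calibration."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epclust.align import global_identity
from epclust.simulate import (
    SimulationConfig,
    mutate_sequence,
    simulate_dataset,
    write_dataset,
)


def small_config(**kw):
    defaults = dict(
        n_bacteria=6,
        genus_sizes=(4, 2),
        n_archaea=5,
        n_eukaryotes=4,
        n_euk_specific=1,
        n_euk_bact=6,
        n_euk_arch=4,
        n_euk_dual=1,
        n_prok_only=1,
        presence_prob={"bacteria": 1.0, "archaea": 1.0, "eukaryote": 1.0},
        seq_length_range=(50, 80),
        seed=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_seeded_determinism_in_memory_and_on_disk(tmp_path):
    cfg = small_config(seed=7)
    g1, t1 = simulate_dataset(cfg)
    g2, t2 = simulate_dataset(cfg)
    assert [g.proteins for g in g1] == [g.proteins for g in g2]
    assert t1.to_frame().equals(t2.to_frame())
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_dataset(g1, t1, d1)
    write_dataset(g2, t2, d2)
    for p1 in sorted(d1.rglob("*")):
        p2 = d2 / p1.relative_to(d1)
        if p1.is_file():
            assert p1.read_bytes() == p2.read_bytes()


def test_dataset_round_trip(tmp_path):
    from epclust.simulate import read_dataset

    genomes, truth = simulate_dataset(small_config(seed=2))
    write_dataset(genomes, truth, tmp_path)
    genomes2, truth2 = read_dataset(tmp_path)
    assert {g.genome_id: g.proteins for g in genomes} == {
        g.genome_id: g.proteins for g in genomes2
    }
    assert truth.to_frame().equals(truth2.to_frame())
    assert [g.parasite for g in genomes] == [g.parasite for g in genomes2]


def test_category_counts_match_config():
    cfg = small_config(n_euk_bact=60, n_euk_arch=40, n_bacteria=4, genus_sizes=(4,))
    _, truth = simulate_dataset(cfg)
    origins = list(truth.origin.values())
    assert origins.count("bacterial") == 60
    assert origins.count("archaeal") == 40
    counts = truth.category_counts()
    assert counts["euk_bact"] == 60 and counts["euk_arch"] == 40


def test_headers_unique_and_resolve_to_one_family():
    genomes, truth = simulate_dataset(small_config())
    seen = set()
    for g in genomes:
        for sid in g.proteins:
            assert sid not in seen
            seen.add(sid)
            assert truth.family_of(sid) in truth.category


def test_realized_within_domain_identity_near_target():
    """Mean within-family same-domain identity must land within 10 points of
    the configured 80%, measured with the global-alignment oracle route."""
    cfg = small_config(seed=3, n_euk_bact=4, n_euk_arch=3, seq_length_range=(80, 110))
    genomes, truth = simulate_dataset(cfg)
    lookup = {sid: s for g in genomes for sid, s in g.proteins.items()}
    domain_of = {g.genome_id: g.domain for g in genomes}
    idents = []
    for fam, per_genome in truth.members.items():
        per_domain = {}
        for genome, sids in per_genome.items():
            per_domain.setdefault(domain_of[genome], []).extend(sids)
        for dom, sids in per_domain.items():
            for a, b in itertools.combinations(sids, 2):
                idents.append(global_identity(lookup[a], lookup[b]))
    assert 70.0 <= np.mean(idents) <= 90.0


def test_interdomain_identity_below_within_domain():
    cfg = small_config(seed=4, seq_length_range=(80, 110))
    genomes, truth = simulate_dataset(cfg)
    lookup = {sid: s for g in genomes for sid, s in g.proteins.items()}
    domain_of = {g.genome_id: g.domain for g in genomes}
    cross = []
    for fam, per_genome in truth.members.items():
        if truth.category[fam] != "euk_bact":
            continue
        euk = [s for g, ss in per_genome.items() if domain_of[g] == "eukaryote" for s in ss]
        bact = [s for g, ss in per_genome.items() if domain_of[g] == "bacteria" for s in ss]
        for a, b in itertools.product(euk[:2], bact[:2]):
            cross.append(global_identity(lookup[a], lookup[b]))
    assert 35.0 <= np.mean(cross) <= 55.0  # target 45, +-10 band


def test_cross_family_pairs_fall_below_prokaryote_cutoff():
    """Unrelated families must sit below the 25% global-identity cutoff for
    at least 99% of sampled pairs at default lengths."""
    cfg = small_config(seed=5, n_euk_bact=8, n_euk_arch=6, seq_length_range=(120, 200))
    genomes, truth = simulate_dataset(cfg)
    lookup = {sid: s for g in genomes for sid, s in g.proteins.items()}
    fam_of = {sid: truth.family_of(sid) for sid in lookup}
    ids = sorted(lookup)
    rng = random.Random(0)
    below = total = 0
    while total < 300:
        a, b = rng.sample(ids, 2)
        if fam_of[a] == fam_of[b]:
            continue
        total += 1
        below += global_identity(lookup[a], lookup[b]) < 25.0
    assert below / total >= 0.99


def test_parasites_lose_bacteria_linked_families():
    """Expectation over seeds: parasite genomes carry fewer euk_bact families
    than non-parasites, by roughly the configured loss multiplier."""
    par_counts, free_counts = [], []
    for seed in range(20):
        cfg = small_config(
            seed=seed,
            n_eukaryotes=4,
            parasite_ids=("euk0001", "euk0003"),
            parasite_loss_multiplier=2.0,
            presence_prob={"bacteria": 1.0, "archaea": 1.0, "eukaryote": 0.7},
        )
        _, truth = simulate_dataset(cfg)
        for fam, cat in truth.category.items():
            if cat != "euk_bact":
                continue
            for g in ("euk0001", "euk0003"):
                par_counts.append(g in truth.members[fam])
            for g in ("euk0002", "euk0004"):
                free_counts.append(g in truth.members[fam])
    assert np.mean(par_counts) < np.mean(free_counts)
    # loss rate doubled: presence 0.7 -> 0.4
    assert np.mean(par_counts) == pytest.approx(0.4, abs=0.06)
    assert np.mean(free_counts) == pytest.approx(0.7, abs=0.06)


def test_mutate_sequence_boundaries():
    anc = "MKVLITGAWQ" * 10
    assert mutate_sequence(anc, 100.0, 1) == anc
    resampled = mutate_sequence(anc, 0.0, 1)
    assert all(x != y for x, y in zip(anc, resampled))
    with pytest.raises(ValueError):
        mutate_sequence("", 50.0, 1)
    with pytest.raises(ValueError):
        mutate_sequence(anc, 150.0, 1)


def test_mutate_sequence_binomial_fraction():
    rng = np.random.default_rng(0)
    anc = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=1000))
    desc = mutate_sequence(anc, 50.0, 123)
    frac = np.mean([x == y for x, y in zip(anc, desc)])
    assert 0.45 <= frac <= 0.55  # binomial CI at n=1000


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1), st.floats(10.0, 95.0))
def test_mutate_sequence_length_preserving(seed, target):
    anc = "MKVLITGAWQERTYIPASDF"
    desc = mutate_sequence(anc, target, seed)
    assert len(desc) == len(anc)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        small_config(genus_sizes=(5, 5)).validate()  # != n_bacteria
    with pytest.raises(ValueError):
        small_config(n_eukaryotes=0).validate()  # euk families but no genomes
    with pytest.raises(ValueError):
        small_config(presence_prob={"bacteria": 1.5}).validate()
    with pytest.raises(ValueError):
        small_config(within_domain_identity=40.0, interdomain_identity=45.0).validate()
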