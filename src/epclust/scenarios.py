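"""Canonical simulation scenarios for validating the estimator.

These configurations are the package's study conditions; the test suite and
the reproduction script both run them unchanged.

``recovery_conditions``
    Balanced-taxon parameter recovery: 30 bacteria in 5 genera with skewed
    sizes, 12 archaea, 8 eukaryotes; 60 bacteria-linked and 40 archaea-linked
    eukaryote families (planted bacterial fraction 0.600); presence
    probability 0.7 in every domain; within-domain identity 80%, interdomain
    45%; sequence lengths 120-200 aa; 200 downsampling replicates of 12
    bacteria (the archaeal count).

``imbalance_conditions``
    Downsampling bias correction under a 10:1 bacteria:archaea genome excess.
    The detection asymmetry that downsampling corrects only exists when
    families are carried by a small fraction of a large genome pool (in the
    real data most bacterial families occur in a few dozen of 5,443 genomes,
    while the subsample has only 212 slots); a small pool with dense presence
    makes naive and downsampled counting numerically identical, and sparse
    presence with few archaea collides with the five-member family filter.
    The scenario therefore uses 800 bacteria vs 80 archaea with per-genome
    presence 0.1 in both prokaryotic domains (symmetric, patchy), 12
    bacteria-linked vs 8 archaea-linked families (planted fraction 0.600
    preserved), and 1,000 replicates of 80 bacteria.  A small residual
    inflation of the bacterial fraction (~+0.02-0.03) remains by design:
    archaeal families falling under the five-member filter are lost entirely,
    a bias that downsampling does not, and cannot, repair.

``parasite_conditions``
    Reductive-evolution sign test: 6 eukaryotes of which 3 are flagged
    parasites losing bacteria-linked families at twice the baseline loss
    rate, plus origin-correlated function labels for the category report.
"""

from __future__ import annotations

from .pipeline import PipelineConfig
from .simulate import SimulationConfig

__all__ = [
    "recovery_conditions",
    "imbalance_conditions",
    "parasite_conditions",
]


def recovery_conditions(seed: int) -> PipelineConfig:
    sim = SimulationConfig(
        n_bacteria=30,
        genus_sizes=(14, 8, 4, 3, 1),
        n_archaea=12,
        n_eukaryotes=8,
        n_euk_specific=4,
        n_euk_bact=60,
        n_euk_arch=40,
        n_euk_dual=2,
        n_prok_only=3,
        within_domain_identity=80.0,
        interdomain_identity=45.0,
        presence_prob={"bacteria": 0.7, "archaea": 0.7, "eukaryote": 0.7},
        seq_length_range=(120, 200),
    )
    return PipelineConfig(
        simulation=sim,
        n_replicates=200,
        sample_size=12,
        seed=seed,
    )


def imbalance_conditions(seed: int) -> PipelineConfig:
    sim = SimulationConfig(
        n_bacteria=800,
        genus_sizes=(370, 215, 110, 75, 30),
        n_archaea=80,
        n_eukaryotes=8,
        n_euk_specific=2,
        n_euk_bact=12,
        n_euk_arch=8,
        n_euk_dual=1,
        n_prok_only=1,
        within_domain_identity=80.0,
        interdomain_identity=45.0,
        presence_prob={"bacteria": 0.1, "archaea": 0.1, "eukaryote": 0.7},
        seq_length_range=(120, 200),
    )
    return PipelineConfig(
        simulation=sim,
        n_replicates=1000,
        sample_size=80,
        seed=seed,
        run_annotation=False,
        run_presence_matrix=False,
    )


def parasite_conditions(seed: int) -> PipelineConfig:
    sim = SimulationConfig(
        n_bacteria=20,
        genus_sizes=(9, 6, 5),
        n_archaea=10,
        n_eukaryotes=6,
        n_euk_specific=2,
        n_euk_bact=20,
        n_euk_arch=15,
        n_euk_dual=1,
        n_prok_only=1,
        within_domain_identity=80.0,
        interdomain_identity=45.0,
        presence_prob={"bacteria": 0.8, "archaea": 0.8, "eukaryote": 0.7},
        parasite_ids=("euk0002", "euk0004", "euk0006"),
        parasite_loss_multiplier=2.0,
        p_metabolism_given_bact=0.8,
        p_information_given_arch=0.8,
        seq_length_range=(80, 140),
    )
    return PipelineConfig(
        simulation=sim,
        n_replicates=200,
        sample_size=10,
        seed=seed,
        run_presence_matrix=False,
    )
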