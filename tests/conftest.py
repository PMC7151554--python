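import random

import numpy as np
import pytest

from epclust import PipelineConfig, SimulationConfig, run_pipeline
from epclust.align import AMINO_ACIDS


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def mutated(rng: random.Random, seq: str, identity: float) -> str:
    out = []
    for c in seq:
        if rng.random() < identity:
            out.append(c)
        else:
            out.append(rng.choice(AMINO_ACIDS.replace(c, "")))
    return "".join(out)


@pytest.fixture(scope="session")
def tiny_config() -> PipelineConfig:
    """A seconds-scale end-to-end configuration with full (deterministic)
    family presence, used by pipeline-level unit tests."""
    sim = SimulationConfig(
        n_bacteria=10,
        genus_sizes=(5, 3, 2),
        n_archaea=8,
        n_eukaryotes=6,
        n_euk_specific=2,
        n_euk_bact=6,
        n_euk_arch=4,
        n_euk_dual=1,
        n_prok_only=2,
        presence_prob={"bacteria": 1.0, "archaea": 1.0, "eukaryote": 1.0},
        seq_length_range=(60, 90),
    )
    return PipelineConfig(simulation=sim, n_replicates=50, sample_size=8, seed=11)


@pytest.fixture(scope="session")
def tiny_result(tiny_config):
    return run_pipeline(tiny_config)
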