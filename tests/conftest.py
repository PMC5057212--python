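"""Shared fixtures: one small simulated dataset with every planted feature,
generated once per session."""

from __future__ import annotations

import pytest

from riboheat.simulate import (
    SimulationConfig, generate_transcriptome, simulate_counts_and_coverage,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7,
        n_genes=60,
        depth=150.0,
        lfc_effect=2.0,
        n_per_class={
            "both_up": 5, "both_down": 5, "mrna_only_up": 5, "mrna_only_down": 5,
            "rpf_only_up": 5, "rpf_only_down": 5, "null": 30,
        },
        n_quadruplex_genes={"UTR5": 8, "UTR3": 8},
        n_plastid_singletons=10,
    )


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    return generate_transcriptome(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_transcriptome):
    models, truth = small_transcriptome
    samples, spikes = simulate_counts_and_coverage(models, truth, small_config)
    return models, truth, samples, spikes
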