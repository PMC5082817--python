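import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from eggstim.datatypes import SimulationConfig


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A fast, fully featured synthetic study for unit tests."""
    defaults = dict(
        n_subjects_per_group={"AC": 5, "BET": 6, "BER": 8},
        n_genes=400,
        n_de_genes=30,
        n_modules=2,
        module_sizes=(60, 60),
        n_signatures=60,
        n_categories=8,
        n_planted_signatures=5,
        signature_size=30,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def module_config(seed: int = 1) -> SimulationConfig:
    """The module-recovery study: 3 planted modules of 100 genes at
    correlation 0.8, 300 background genes, 60 samples."""
    return SimulationConfig(
        n_subjects_per_group={"AC": 5, "BET": 10, "BER": 15},
        n_genes=600,
        n_de_genes=0,
        n_planted_signatures=0,
        n_modules=3,
        module_sizes=(100, 100, 100),
        module_cor=0.8,
        seed=seed,
    )


@pytest.fixture
def sim_small():
    from eggstim.synthetic import generate_expression

    cfg = small_config(seed=11)
    expr, samples, truth = generate_expression(cfg)
    return cfg, expr, samples, truth
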