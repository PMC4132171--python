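import pytest

from fishmap import (
    ChromatinClass,
    ChromosomeModel,
    Segment,
    SimConfig,
    simulate_genome,
)


@pytest.fixture
def toy_model() -> ChromosomeModel:
    """Short arm 5 µm, long arm 10 µm; eu|het|kin|het|eu tiling."""
    eu, het, kin = (
        ChromatinClass.EUCHROMATIN,
        ChromatinClass.HETEROCHROMATIN,
        ChromatinClass.KINETOCHORE,
    )
    return ChromosomeModel(
        "toy",
        5.0,
        10.0,
        [
            Segment(0.0, 2.5, eu),
            Segment(2.5, 4.5, het),
            Segment(4.5, 5.5, kin),
            Segment(5.5, 8.5, het),
            Segment(8.5, 15.0, eu),
        ],
    )


def zero_noise_config(seed: int = 11, **overrides) -> SimConfig:
    defaults = dict(
        n_chromosomes=2,
        scaffolds_per_chromosome=6,
        focus_noise_sd_um=0.0,
        arm_length_cv=0.0,
        n_spreads=10,
        small_scaffold_rate=0.5,
    )
    defaults.update(overrides)
    return SimConfig(seed=seed, **defaults)


@pytest.fixture
def zero_noise_truth():
    return simulate_genome(zero_noise_config())
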