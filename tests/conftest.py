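import numpy as np
import pytest

from soyenergy import datasets
from soyenergy.records import SampleAssay
from soyenergy.simulate import GeneratorConfig, gen_samples, gen_true_energy, gen_trial


def make_sample(**overrides) -> SampleAssay:
    base = dict(
        sample_id="S01", plant_id="1", dehulled=False,
        cp=39.97, ee=24.49, ash=5.32, cf=4.53, adf=5.34, ndf=10.42,
        hemicellulose=5.08, ca=0.33, p=0.55, phytic_p=0.36,
        ua=0.046, ps=81.74, soluble_protein=32.66, ge=5826.0,
    )
    base.update(overrides)
    return SampleAssay(**base)


@pytest.fixture
def sample():
    return make_sample()


@pytest.fixture(scope="session")
def plant_records():
    return datasets.plant_records()


@pytest.fixture(scope="session")
def diet_energy_table():
    return datasets.load_diet_energy()


@pytest.fixture(scope="session")
def small_trial():
    """One generated trial at survey defaults (14 samples, 8 pigs/diet)."""
    cfg = GeneratorConfig(seed=7)
    rng = np.random.default_rng(cfg.seed)
    samples, plants = gen_samples(cfg, rng)
    truths = gen_true_energy(samples, cfg, rng)
    pigs, collections, diets = gen_trial(samples, truths, cfg, rng)
    return cfg, samples, plants, truths, pigs, collections, diets
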