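import numpy as np
import pytest

from scapkin import (GeneratorConfig, compute_svic_references, generate_svic,
                     generate_trial)
from scapkin.core import MUSCLES


def quiet_config(seed: int = 3) -> GeneratorConfig:
    """Noise-free, variability-free generator configuration."""
    return GeneratorConfig(
        seed=seed, noise_sd_kin=0.0, noise_sd_emg=0.0, noise_sd_accel=0.0,
        rom_subject_sd=0.0, rom_trial_sd=0.0,
        emg_subject_sd=0.0, emg_trial_sd=0.0,
    )


@pytest.fixture(scope="session")
def quiet_cfg() -> GeneratorConfig:
    return quiet_config()


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def quiet_trial(quiet_cfg):
    return generate_trial(quiet_cfg, "S01", 1, "M0")


@pytest.fixture(scope="session")
def quiet_refs(quiet_cfg):
    svic = {m: generate_svic(quiet_cfg, m, "S01") for m in MUSCLES}
    return compute_svic_references(svic)


@pytest.fixture(scope="session")
def default_refs(default_cfg):
    svic = {m: generate_svic(default_cfg, m, "S01") for m in MUSCLES}
    return compute_svic_references(svic)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
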