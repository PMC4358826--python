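import numpy as np
import pytest

from objdensity import (
    EnvGenConfig,
    ObjectRecord,
    ObjectTable,
    ObserverGenConfig,
    RatioLine,
    gen_env_objects,
    gen_observer_trials,
)


def make_table(volumes, densities, dataset="D1", prefix="obj"):
    """Object table from explicit volumes and densities (weights derived)."""
    from objdensity.objects_io import DATASET_CLASSES

    cat, lift = DATASET_CLASSES[dataset]
    records = [
        ObjectRecord(
            id=f"{prefix}-{i}",
            name=f"{prefix} {i}",
            dataset=dataset,
            category=cat,
            liftable=lift,
            volume=float(v),
            weight=float(v * d),
        )
        for i, (v, d) in enumerate(zip(volumes, densities))
    ]
    return ObjectTable(records)


@pytest.fixture
def power_table():
    """Noiseless d = 2 * V**-0.4 over a log-spaced volume grid."""
    volumes = np.logspace(0, 4, 25)
    densities = 2.0 * volumes**-0.4
    return make_table(volumes, densities)


@pytest.fixture
def noisy_table():
    """Power-law population with lognormal scatter, 195 objects."""
    return gen_env_objects(
        EnvGenConfig(n_objects=195, density_exponent=-0.387, log_noise_sd=0.5, seed=42)
    )


@pytest.fixture
def noiseless_cohort():
    """Deterministic cohort: beta = 1, environmental prior, no noise."""
    cfg = ObserverGenConfig(
        n_per_group=10,
        compression_beta=1.0,
        prior_line=RatioLine(-0.387, 0.114, "density"),
        report_log_noise_sd=0.0,
        trials_per_cell=2,
        seed=0,
    )
    return gen_observer_trials(cfg)


@pytest.fixture
def noisy_cohort():
    cfg = ObserverGenConfig(
        n_per_group=10,
        compression_beta=0.85,
        prior_line=RatioLine(-0.387, 0.114, "density"),
        report_log_noise_sd=0.25,
        trials_per_cell=10,
        seed=7,
    )
    return gen_observer_trials(cfg)
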