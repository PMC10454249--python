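import numpy as np
import pytest

from covnet import (
    Cohort,
    RegionSet,
    SyntheticSpec,
    generate_cohort,
    make_correlation_template,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_region_set():
    return RegionSet("test", ("R1", "R2", "R3", "R4", "R5"))


def make_uniform_spec(
    n_per_group=30,
    n_regions=5,
    strength=0.5,
    seed=0,
    groups=("A", "B"),
    noise_sd=200.0,
    age_effect=-5.0,
    sex_effect=100.0,
):
    tmpl = make_correlation_template(n_regions, "uniform", strength)
    return SyntheticSpec(
        group_sizes={g: n_per_group for g in groups},
        region_count=n_regions,
        mean_volumes=np.full(n_regions, 5000.0),
        age_effect=np.full(n_regions, age_effect),
        sex_effect=np.full(n_regions, sex_effect),
        target_correlation={g: tmpl for g in groups},
        noise_sd=np.full(n_regions, noise_sd),
        seed=seed,
    )


@pytest.fixture
def two_group_cohort():
    return generate_cohort(make_uniform_spec(seed=42))


def random_weight_matrix(rng, n, density=0.7):
    """Random symmetric weight matrix in [0, 1], zero diagonal."""
    w = rng.random((n, n))
    w[rng.random((n, n)) > density] = 0.0
    w = np.triu(w, k=1)
    return w + w.T


def manual_cohort(region_set, rows):
    """rows: (subject_id, group, age, sex, volumes...)."""
    return Cohort(
        region_set,
        [r[0] for r in rows],
        [r[1] for r in rows],
        [r[2] for r in rows],
        [r[3] for r in rows],
        np.array([r[4] for r in rows], dtype=float),
    )
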