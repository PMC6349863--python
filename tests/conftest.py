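import numpy as np
import pandas as pd
import pytest

from normmap import CohortSpec, Geometry, ScalarMap, generate_cohort


@pytest.fixture(scope="session")
def small_geometry() -> Geometry:
    """A deliberately tiny geometry so per-test fits stay in milliseconds."""
    return Geometry(surface_shape=(8, 6), grid_shape=(8, 8, 8))


@pytest.fixture(scope="session")
def toy_geometry() -> Geometry:
    return Geometry.toy()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_covariates(n: int, rng: np.random.Generator, group: str = "control") -> pd.DataFrame:
    """Random but realistic covariate table for n subjects of one group."""
    return pd.DataFrame(
        {
            "subject_id": [f"{group[:3]}-{i:03d}" for i in range(n)],
            "group": group,
            "age": rng.uniform(45, 85, n),
            "sex": rng.integers(0, 2, n),
            "icv": rng.normal(1.45e6, 1.2e5, n),
        }
    )


def make_control_maps(
    covariates: pd.DataFrame,
    n_locations: int,
    rng: np.random.Generator,
    beta=(2.5, -5e-3, 0.02, 1e-7),
    noise_sd: float = 0.1,
    modality: str = "thickness",
    space: str = "surface",
) -> list[ScalarMap]:
    """Maps following the linear-Gaussian normative model with known betas."""
    X = np.column_stack(
        [
            np.ones(len(covariates)),
            covariates["age"],
            covariates["sex"],
            covariates["icv"],
        ]
    )
    mean = X @ np.asarray(beta)
    return [
        ScalarMap(
            sid,
            modality,
            space,
            mean[i] + rng.normal(0, noise_sd, n_locations),
        )
        for i, sid in enumerate(covariates["subject_id"])
    ]


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return generate_cohort(CohortSpec(seed=7))
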