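import numpy as np
import pandas as pd
import pytest

from metasig import CohortSpec, ExpressionMatrix, build_pairs, generate_cohort


def make_matrix(values: np.ndarray, tissue_codes: list[str],
                patients: list[str] | None = None,
                probes: list[str] | None = None,
                log_scale: bool = True) -> ExpressionMatrix:
    """Hand-rolled matrix helper for small fixtures."""
    n_probes, n_samples = values.shape
    probes = probes or [f"p{i}" for i in range(n_probes)]
    patients = patients or [f"pat{i}" for i in range(n_samples)]
    samples = [f"{code}_{i}" for i, code in enumerate(tissue_codes)]
    ann = pd.DataFrame({
        "sample_id": samples, "tissue_code": tissue_codes,
        "patient_id": patients, "study_id": ["s0"] * n_samples,
    })
    vals = pd.DataFrame(values, index=probes, columns=samples)
    return ExpressionMatrix(vals, ann, log_scale=log_scale)


@pytest.fixture
def paired_matrix():
    """4 probes x 3 patients with CT+HM each, plus one CT-only patient."""
    rng = np.random.default_rng(1)
    values = rng.normal(8, 1, (4, 7))
    codes = ["CT", "HM", "CT", "HM", "CT", "HM", "CT"]
    patients = ["a", "a", "b", "b", "c", "c", "d"]
    return make_matrix(values, codes, patients)


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free, contamination-free cohort with planted effects."""
    spec = CohortSpec(n_probes=200, n_planted_de=20, n_liver_decoys=20,
                      n_tumor_de=20, noise_sd=0.0, lambda_range=(0.0, 0.0),
                      seed=11)
    matrix, truth = generate_cohort(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-noise cohort at reduced probe count for fast tests."""
    spec = CohortSpec(n_probes=1000, n_planted_de=50, n_liver_decoys=100,
                      n_tumor_de=50, seed=4)
    matrix, truth = generate_cohort(spec)
    return spec, matrix, truth


@pytest.fixture
def ct_hm_design(small_cohort):
    _, matrix, _ = small_cohort
    return build_pairs(matrix, "CT", "HM")
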