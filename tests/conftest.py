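"""Shared fixtures: one seeded synthetic cohort and its corrected form."""

import warnings

import numpy as np
import pytest

from lipidmark.cohort import default_config, diagnosis_vector, generate_cohort
from lipidmark.evaluation import stratified_split
from lipidmark.preprocess import apply_correction, fit_correction, scan_outliers

#: informative markers of the default panel and their planted directions
INFORMATIVE = {
    "GluCerC16": "<",
    "HETE15S": "<",
    "LPA20:4": "<",
    "biopterin": "<",
    "OEA": "<",
    "PEA": "<",
    "LacCerC24:1": ">",
    "C16Sphinganin": ">",
}


@pytest.fixture(scope="session")
def cohort():
    """Default 403-subject cohort, seed 0."""
    return generate_cohort(default_config(seed=0))


@pytest.fixture(scope="session")
def corrected(cohort):
    """Outlier-screened, age/sex-corrected cohort (controls-only fit)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screened, _ = scan_outliers(cohort)
        model = fit_correction(screened)
        return apply_correction(screened, model)


@pytest.fixture(scope="session")
def split(corrected):
    """Stratified 2/3 : 1/3 train/test split of the corrected cohort."""
    return stratified_split(corrected, seed=100)


@pytest.fixture(scope="session")
def labels(cohort):
    return diagnosis_vector(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
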