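"""Shared fixtures: the published final model and small synthetic datasets."""

import warnings

import numpy as np
import pytest

import ceftriaxpk as cpk


@pytest.fixture(scope="session")
def final_model():
    return cpk.final_model()


@pytest.fixture(scope="session")
def median_params():
    """Structural parameters at the published population values."""
    return cpk.StructuralParams(CL=11.57, V1=43.6, Q=19.8, V2=40.94)


@pytest.fixture(scope="session")
def sparse_dataset(final_model):
    """One study-design dataset: 24 episodes, 3 samples each."""
    return cpk.generate_dataset(
        cpk.StudyDesign(), final_model, np.random.default_rng(42)
    )


@pytest.fixture(scope="session")
def rich_design():
    """Dense sampling over one dosing interval (identifies all 4 parameters)."""
    return cpk.StudyDesign(
        n_episodes=50,
        sampling_offsets=(0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 11.5),
    )


@pytest.fixture(scope="session")
def rich_fit(final_model, rich_design):
    """A converged SAEM fit on rich data generated from the final model."""
    data = cpk.generate_dataset(rich_design, final_model, np.random.default_rng(7))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = cpk.saem_fit(data, final_model, cpk.SaemSettings(seed=1))
    return data, fit
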