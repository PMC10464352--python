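import numpy as np
import pytest

from mutprev.panel import mock_panel, make_barcodes
from mutprev.simulate import SimulationConfig, uniform_error_matrix


@pytest.fixture(scope="session")
def panel():
    return mock_panel()


@pytest.fixture(scope="session")
def small_config():
    """A fast study: small library, shallow duplication, visible error."""
    return SimulationConfig(
        seed=7, n_subjects_case=2, n_subjects_control=2,
        molecules_per_target_nt=1_500, molecules_per_target_is=1_500,
        eccl_rungs=(1_500, 150, 15, 5), reads_per_molecule_mean=4.0,
        clone_mean_case=2.0, clone_mean_control=0.5,
        clone_vaf_range=(5e-3, 1e-2),
        error_matrix=uniform_error_matrix(3e-4))


def barcoded(panel, subjects, seed=9):
    return panel.with_barcodes(make_barcodes(
        [s.subject_id for s in subjects], seed=seed))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
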