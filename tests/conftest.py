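import numpy as np
import pytest

from volatempo import (RMASCA, asca_benchmark, fit_parafac2, make_design,
                       scale_matrix, simulate_tensor, study_templates)


@pytest.fixture(scope="session")
def study_design():
    return make_design()


@pytest.fixture(scope="session")
def small_templates(study_design):
    templates, class_map = study_templates(study_design, n_compounds=24, seed=0)
    return templates, class_map


@pytest.fixture(scope="session")
def noiseless_tensor():
    """Exact 3-component PARAFAC2 tensor with retention shifts."""
    return simulate_tensor(n_scans=120, mz_axis=np.arange(35, 96),
                           n_samples=12, n_components=3,
                           shift_range_scans=5, noise_snr_db=None, seed=1)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_tensor):
    tensor, _truth = noiseless_tensor
    return fit_parafac2(tensor, 3, seed=0, n_restarts=3)


@pytest.fixture(scope="session")
def benchmark_fit():
    """Fitted RM-ASCA on the study-mimic benchmark (native noise scale)."""
    table, truth = asca_benchmark(seed=0)
    fit = RMASCA(scale_matrix(table, method="none"), n_components=3).fit(
        engine="ols"
    )
    return table, truth, fit
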