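import warnings

import pytest

import triadswitch as ts
from triadswitch.enhancers import calibrate_omegas


@pytest.fixture(scope="session")
def reference_tables():
    return ts.reference_library()


@pytest.fixture(scope="session")
def reference_fit():
    """Auto-K fit of the packaged reference library (shared: expensive)."""
    return ts.fit_reference_triad()


@pytest.fixture(scope="session")
def wt_params(reference_fit):
    return reference_fit.params


@pytest.fixture(scope="session")
def wt_zero_states(wt_params):
    return ts.find_steady_states(wt_params)


def triad_from_truth(seed: int) -> ts.TriadParameters:
    """Triad built from a random synthetic ground truth, promoter factors
    calibrated to the wild-type 3.5x/4x fold increases."""
    truth = ts.generate_truth(seed)
    m = truth.models
    with warnings.catch_warnings():
        # Unsaturated random enhancers can imply omega < 1; fine for tests.
        warnings.simplefilter("ignore", UserWarning)
        gata = calibrate_omegas(m["Gata2-3"], fold_notch=3.5, fold_bmp4=4.0)
        fli = calibrate_omegas(m["Fli1+12"], fold_bmp4=4.0)
    return ts.build_triad(m["Scl+19"], gata, fli)
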