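import numpy as np
import pytest

from benchnmr.library import load_library
from benchnmr.spin import (LineshapeParams, default_axis, first_order_peaks,
                           render_spectrum)


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def axis60():
    return default_axis(60.0, n_points=8192)


@pytest.fixture(scope="session")
def acetate_tsp_spectrum(library, axis60):
    """Noiseless 10 mM acetate + 0.5 mM TSP at 60 MHz, TSP-normalized."""
    from benchnmr.spin import PeakList
    from benchnmr.processing import reference_and_normalize
    peaks = PeakList.concatenate([
        first_order_peaks(library["acetate"], 60.0).scaled(10.0),
        first_order_peaks(library["tsp"], 60.0).scaled(0.5),
    ])
    spec = render_spectrum(peaks, axis60, LineshapeParams(width_hz=1.4))
    return reference_and_normalize(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """One default 36-sample cohort at 60 MHz on a reduced grid."""
    from benchnmr.cohort import CohortDesign, synthesize_cohort
    design = CohortDesign.default(seed=11)
    spectra, truth = synthesize_cohort(design, fields=(60.0,), n_points=4096)
    return spectra, truth


def rng(seed=0):
    return np.random.default_rng(seed)
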