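import numpy as np
import pytest

import filmdose as fd

# Published cubic calibration coefficients (cGy) per beam quality.
CURVE_COEFS = {
    "125 kVp": (933.1, -446.7, 5147.0, 3.5),
    "180 kVp": (897.6, -123.5, 4639.0, 9.0),
    "250 kVp": (834.3, 260.2, 4363.0, None),  # HVL quoted in mm Cu, not Al
}


@pytest.fixture(scope="session")
def al_table() -> fd.AttenuationTable:
    return fd.aluminum_table()


@pytest.fixture(scope="session")
def truth_curve() -> fd.CalibrationCurve:
    return fd.default_truth_curve()


@pytest.fixture(scope="session")
def all_curves() -> dict[str, fd.CalibrationCurve]:
    return {
        label: fd.CalibrationCurve(label, a1, a2, a3, hvl_mm=hvl)
        for label, (a1, a2, a3, hvl) in CURVE_COEFS.items()
    }


@pytest.fixture
def quiet_models(truth_curve):
    """Noise-free film + scanner models for exact round trips."""
    return fd.FilmModel(truth_curve).quiet(), fd.ScannerModel().quiet()


@pytest.fixture
def noisy_models(truth_curve):
    """Default-noise film + scanner models (film 1.6%, bed 0.8%, drift 0.1%, k=2)."""
    return fd.FilmModel(truth_curve), fd.ScannerModel()
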