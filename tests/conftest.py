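"""Shared fixtures: reference E_GSH measurements and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from redoxpheno.biosensor import CalibrationState, RoGFPConstants

# Published reference E_GSH values (mV, mean over seedlings) for the wild
# type and the eight glutathione-peroxidase-like mutants, per organ.  Used as
# round-trip inputs for the Nernst mapping.
REFERENCE_EGSH = {
    "Col-0": {"cotyledon": -302.27, "root": -302.48},
    "gpxl1": {"cotyledon": -274.25, "root": -269.30},
    "gpxl2": {"cotyledon": -294.59, "root": -289.84},
    "gpxl3": {"cotyledon": -285.03, "root": -296.69},
    "gpxl4": {"cotyledon": -298.93, "root": -271.86},
    "gpxl5": {"cotyledon": -298.46, "root": -298.77},
    "gpxl6": {"cotyledon": -287.90, "root": -278.71},
    "gpxl7": {"cotyledon": -277.97, "root": -300.50},
    "gpxl8": {"cotyledon": -284.01, "root": -281.32},
}


@pytest.fixture(scope="session")
def constants() -> RoGFPConstants:
    return RoGFPConstants()


@pytest.fixture(scope="session")
def calib() -> CalibrationState:
    return CalibrationState(r_red=0.2, r_ox=1.4, i488_red=300.0, i488_ox=120.0)


@pytest.fixture(scope="session")
def symmetric_calib() -> CalibrationState:
    """Equal 488 intensities: OxD reduces to linear ratio interpolation."""
    return CalibrationState(r_red=0.2, r_ox=1.4, i488_red=200.0, i488_ox=200.0)


def bisect_oxd_for_egsh(egsh: float, constants: RoGFPConstants,
                        tol: float = 1e-12) -> float:
    """Independent bisection inversion of the forward Nernst formula."""
    lo, hi = 1e-15, 1.0 - 1e-15

    def forward(oxd: float) -> float:
        return constants.midpoint_potential - constants.nernst_slope * np.log10(
            (1.0 - oxd) / oxd
        )

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if forward(mid) < egsh:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
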