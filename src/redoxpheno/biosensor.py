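"""Ratiometric roGFP2 model: fluorescence ratio -> degree of oxidation -> E_GSH.

roGFP2 is a ratiometric redox biosensor: oxidation of its engineered cysteine
pair raises the fluorescence excited near 405 nm (protonated chromophore band)
and lowers the fluorescence excited near 488 nm (anionic band).  The 405/488
excitation ratio R, bracketed by calibration ratios of the fully reduced
(DTT-treated) and fully oxidized (H2O2-treated) sensor, yields the degree of
oxidation OxD; the Nernst equation then maps OxD to the glutathione redox
potential E_GSH in millivolts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoGFPConstants",
    "CalibrationState",
    "BiosensorMeasurement",
    "OxDResult",
    "compute_oxd",
    "egsh_from_oxd",
    "oxd_from_egsh",
    "egsh_from_intensities",
]


class CalibrationError(ValueError):
    """Calibration endpoints are inconsistent (e.g. R_ox <= R_red)."""


@dataclass(frozen=True)
class RoGFPConstants:
    """Physical constants of the Nernst mapping for roGFP2.

    Parameters
    ----------
    midpoint_potential : float
        Sensor midpoint potential E0 in mV (potential at OxD = 0.5).
        Default −272 mV for roGFP2.
    gas_constant : float
        Molar gas constant in J K⁻¹ mol⁻¹.
    temperature : float
        Absolute temperature in K.
    electrons_transferred : int
        Electrons transferred in the dithiol/disulfide couple (2).
    faraday : float
        Faraday constant in C mol⁻¹.
    """

    midpoint_potential: float = -272.0
    gas_constant: float = 8.315
    temperature: float = 298.15
    electrons_transferred: int = 2
    faraday: float = 96485.0

    def __post_init__(self) -> None:
        if not (
            self.gas_constant > 0
            and self.temperature > 0
            and self.electrons_transferred > 0
            and self.faraday > 0
        ):
            raise ValueError("gas_constant, temperature, z and F must be positive")
        if not math.isfinite(self.midpoint_potential):
            raise ValueError("midpoint_potential must be finite")

    @property
    def nernst_slope(self) -> float:
        """Decadic Nernst slope in mV: 1000·ln(10)·R·T/(z·F) ≈ 29.58 mV."""
        return (
            1000.0
            * math.log(10.0)
            * self.gas_constant
            * self.temperature
            / (self.electrons_transferred * self.faraday)
        )


@dataclass(frozen=True)
class CalibrationState:
    """Fully reduced / fully oxidized calibration endpoints.

    ``r_red``/``r_ox`` are the 405/488 excitation ratios of the fully reduced
    (10 mM DTT) and fully oxidized (20 mM H2O2) sensor; ``i488_red``/``i488_ox``
    the corresponding 488-excited intensities.  Oxidation raises the ratio, so
    ``r_ox > r_red`` is required.
    """

    r_red: float
    r_ox: float
    i488_red: float
    i488_ox: float

    def __post_init__(self) -> None:
        vals = (self.r_red, self.r_ox, self.i488_red, self.i488_ox)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("calibration values must be finite")
        if self.r_red <= 0 or self.i488_red <= 0 or self.i488_ox <= 0:
            raise CalibrationError("calibration ratios and intensities must be positive")
        if self.r_ox <= self.r_red:
            raise CalibrationError(
                f"r_ox ({self.r_ox}) must exceed r_red ({self.r_red}): "
                "oxidation raises the 405/488 ratio"
            )

    @property
    def intensity_factor(self) -> float:
        """I488_red / I488_ox, the instrument factor in the OxD formula."""
        return self.i488_red / self.i488_ox


@dataclass(frozen=True)
class BiosensorMeasurement:
    """Background-corrected channel intensities for one ROI."""

    i405: float
    i488: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (math.isfinite(self.i405) and math.isfinite(self.i488)):
            raise ValueError("intensities must be finite")
        if self.i488 <= 0:
            raise ValueError("i488 must be positive to form the 405/488 ratio")
        if self.i405 < 0:
            raise ValueError("i405 must be nonnegative")

    @property
    def ratio(self) -> float:
        return self.i405 / self.i488


@dataclass(frozen=True)
class OxDResult:
    """Degree of oxidation with provenance flags."""

    oxd: float
    clamped: bool = False
    flags: tuple[str, ...] = ()


def _clamp_ratio(ratio: float, calib: CalibrationState) -> tuple[float, bool]:
    if ratio < calib.r_red:
        return calib.r_red, True
    if ratio > calib.r_ox:
        return calib.r_ox, True
    return ratio, False


def compute_oxd(
    measurement: BiosensorMeasurement | float,
    calib: CalibrationState,
    *,
    invert_intensity_factor: bool = False,
) -> OxDResult:
    """Degree of oxidation from a ratio measurement and calibration endpoints.

    Implements

        OxD = (R − R_red) / [ (I488_red / I488_ox) · (R_ox − R) + (R − R_red) ]

    Ratios outside [R_red, R_ox] (noise can push them there) are clamped to the
    nearer endpoint and flagged rather than rejected, so batch processing
    survives occasional out-of-range ROIs.

    Parameters
    ----------
    measurement : BiosensorMeasurement or float
        ROI measurement, or the bare 405/488 ratio.
    calib : CalibrationState
    invert_intensity_factor : bool
        Use I488_ox / I488_red instead (the reciprocal convention found in the
        literature).  Both orientations satisfy OxD(R_red)=0 and OxD(R_ox)=1.
    """
    if isinstance(measurement, BiosensorMeasurement):
        ratio = measurement.ratio
        flags = measurement.flags
    else:
        ratio = float(measurement)
        flags = ()
    if not math.isfinite(ratio) or ratio <= 0:
        raise ValueError(f"ratio must be finite and positive, got {ratio}")

    ratio, clamped = _clamp_ratio(ratio, calib)
    factor = calib.intensity_factor
    if invert_intensity_factor:
        factor = 1.0 / factor
    num = ratio - calib.r_red
    den = factor * (calib.r_ox - ratio) + num
    oxd = num / den
    if clamped:
        flags = flags + ("ratio_clamped",)
    return OxDResult(oxd=oxd, clamped=clamped, flags=flags)


def egsh_from_oxd(
    oxd: float,
    constants: RoGFPConstants = RoGFPConstants(),
    *,
    eps: float | None = 1e-6,
) -> float:
    """Glutathione redox potential (mV) from the degree of oxidation.

    E_GSH = E0 − slope · log10((1 − OxD) / OxD), slope = 1000·ln(10)·R·T/(zF).

    OxD is clamped into [eps, 1−eps] before the log (pass ``eps=None`` to
    disable clamping, in which case OxD outside (0, 1) raises).
    """
    oxd = float(oxd)
    if not math.isfinite(oxd):
        raise ValueError("oxd must be finite")
    if eps is not None:
        oxd = min(max(oxd, eps), 1.0 - eps)
    if not 0.0 < oxd < 1.0:
        raise ValueError(f"oxd must lie strictly in (0, 1), got {oxd}")
    return constants.midpoint_potential - constants.nernst_slope * math.log10(
        (1.0 - oxd) / oxd
    )


def oxd_from_egsh(egsh: float, constants: RoGFPConstants = RoGFPConstants()) -> float:
    """Inverse Nernst mapping: OxD = 1 / (1 + 10^((E0 − E)/slope)).

    Total on the real line (logistic form); OxD(E0) = 0.5.
    """
    egsh = float(egsh)
    if not math.isfinite(egsh):
        raise ValueError("egsh must be finite")
    return 1.0 / (
        1.0
        + 10.0 ** ((constants.midpoint_potential - egsh) / constants.nernst_slope)
    )


def egsh_from_intensities(
    i405: float,
    i488: float,
    calib: CalibrationState,
    constants: RoGFPConstants = RoGFPConstants(),
    *,
    invert_intensity_factor: bool = False,
    eps: float | None = 1e-6,
) -> tuple[float, OxDResult, float]:
    """Full chain for one ROI: (ratio, OxD result, E_GSH in mV).

    Equal by construction to ``compute_oxd`` followed by ``egsh_from_oxd``;
    the clamping flag is carried through on the OxD result.
    """
    meas = BiosensorMeasurement(i405=i405, i488=i488)
    oxd_res = compute_oxd(
        meas, calib, invert_intensity_factor=invert_intensity_factor
    )
    egsh = egsh_from_oxd(oxd_res.oxd, constants, eps=eps)
    return meas.ratio, oxd_res, egsh


def constants_from_mapping(mapping: dict) -> RoGFPConstants:
    """Build constants from a plain ``key: value`` mapping (config files)."""
    known = {
        "midpoint_potential",
        "gas_constant",
        "temperature",
        "electrons_transferred",
        "faraday",
    }
    kwargs = {k: v for k, v in mapping.items() if k in known}
    if "electrons_transferred" in kwargs:
        kwargs["electrons_transferred"] = int(kwargs["electrons_transferred"])
    return RoGFPConstants(**{k: (v if k == "electrons_transferred" else float(v)) for k, v in kwargs.items()})


def calibration_from_mapping(mapping: dict) -> CalibrationState:
    """Build a calibration state from a plain ``key: value`` mapping."""
    return CalibrationState(
        r_red=float(mapping["r_red"]),
        r_ox=float(mapping["r_ox"]),
        i488_red=float(mapping["i488_red"]),
        i488_ox=float(mapping["i488_ox"]),
    )
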