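"""Linear fluorescence calibrations: intensity <-> concentration.

Two calibrations convert the annulus measurements into concentrations: a
membrane-dye curve mapping background-subtracted membrane intensity to the
bound-DNA fraction (mol %), and a solution-dye curve mapping local
background intensity to the free-DNA concentration (µM).  Both are ordinary
least-squares lines, intensity = gain * concentration + offset; the
background-subtracted membrane signal has its offset cancelled, so membrane
conversions default to a zero net offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "ConcentrationResult",
    "fit_calibration",
    "to_membrane_conc",
    "to_free_conc",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear intensity-vs-concentration calibration for one channel.

    ``gain`` is intensity per concentration unit (mol % for membrane
    channels, µM for solution channels), ``offset`` the zero-concentration
    intensity.  ``valid_range`` is the concentration interval covered by the
    calibration points; conversions outside it are flagged, not rejected.
    """

    channel: str
    gain: float
    offset: float
    r_squared: float = float("nan")
    valid_range: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError(f"channel {self.channel!r}: gain must be positive")

    def forward(self, concentration):
        """Predicted intensity at a concentration."""
        return self.gain * np.asarray(concentration, dtype=float) + self.offset


@dataclass(frozen=True)
class ConcentrationResult:
    """A converted concentration with quality flags."""

    value: float
    clipped: bool = False  # raw conversion was negative, floored at 0
    out_of_range: bool = False  # outside the calibration's valid_range


def fit_calibration(concentration, intensity, channel: str = "") -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, intensity) points.

    Requires at least 3 points over at least 2 distinct concentrations.
    A non-positive fitted gain raises: fluorescence must increase with
    fluorophore concentration, so a negative slope signals corrupted input.
    """
    conc = np.asarray(concentration, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if conc.size < 3:
        raise ValueError("need >= 3 calibration points")
    if np.unique(conc).size < 2:
        raise ValueError("calibration concentrations are degenerate (all equal)")
    res = stats.linregress(conc, inten)
    if res.slope <= 0:
        raise ValueError(
            f"fitted gain {res.slope:g} is not positive; calibration data look corrupted"
        )
    return CalibrationCurve(
        channel=channel,
        gain=float(res.slope),
        offset=float(res.intercept),
        r_squared=float(res.rvalue**2),
        valid_range=(float(conc.min()), float(conc.max())),
    )


def _invert(intensity: float, gain: float, offset: float,
            valid_range: tuple[float, float]) -> ConcentrationResult:
    raw = (intensity - offset) / gain
    clipped = raw < 0
    value = max(raw, 0.0)
    lo, hi = valid_range
    return ConcentrationResult(value=value, clipped=bool(clipped),
                               out_of_range=bool(value < lo or value > hi))


def to_membrane_conc(i_net: float, cal: CalibrationCurve,
                     offset_net: float = 0.0) -> ConcentrationResult:
    """Bound-DNA fraction (mol %) from background-subtracted membrane intensity.

    The membrane calibration applies to the net signal I_mem - I_bg, whose
    additive offset cancels in the subtraction — hence ``offset_net``
    defaults to 0.  Negative conversions (background-subtraction noise) are
    floored at zero and flagged rather than rejected.
    """
    return _invert(float(i_net), cal.gain, offset_net, cal.valid_range)


def to_free_conc(i_bg: float, cal: CalibrationCurve) -> ConcentrationResult:
    """Free-DNA concentration (µM) from the local background intensity."""
    return _invert(float(i_bg), cal.gain, cal.offset, cal.valid_range)
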