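"""Ratiometric sensor calibration.

Both cytosolic (FURA-2, R = F340/F380) and ER-luminal (D1ER cameleon,
R = F_Citrine/F_CFP) sensors map ratio to free Ca2+ through the standard
ratiometric relation

    [Ca2+] = K * (R - R_min) / (R_max - R)

where K is the system-specific apparent Ca2+ dissociation constant of the
sensor, and R_min / R_max are the ratios at zero and saturating Ca2+.
These three constants must be calibrated per imaging system; the module
ships generic placeholder defaults that are NOT physiological measurements
and exist only so that simulated round trips have something to run through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationRangeError, DomainError

__all__ = [
    "CalibrationParams",
    "ratio_to_concentration",
    "concentration_to_ratio",
    "PLACEHOLDER_FURA2",
    "PLACEHOLDER_D1ER",
]


@dataclass(frozen=True)
class CalibrationParams:
    """Constants of the ratiometric equation for one sensor.

    Parameters
    ----------
    sensor_id:
        ``"fura2"`` (cytosolic) or ``"d1er"`` (ER-luminal).
    K:
        Apparent Ca2+ dissociation constant of the sensor in the imaging
        system, in µM.
    R_min, R_max:
        Sensor ratio at zero and at saturating Ca2+ (dimensionless).
    """

    sensor_id: str
    K: float
    R_min: float
    R_max: float

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise DomainError(f"K must be > 0, got {self.K}")
        if not (0 < self.R_min < self.R_max):
            raise DomainError(
                f"need 0 < R_min < R_max, got R_min={self.R_min}, R_max={self.R_max}"
            )


#: Placeholder constants for quick-look simulations. Not calibrated values:
#: every real analysis must supply system-specific K, R_min, R_max.
PLACEHOLDER_FURA2 = CalibrationParams("fura2", K=0.2, R_min=0.5, R_max=5.0)
PLACEHOLDER_D1ER = CalibrationParams("d1er", K=200.0, R_min=1.0, R_max=6.0)


def ratio_to_concentration(R, cal: CalibrationParams):
    """Convert sensor ratio(s) to free Ca2+ concentration in µM.

    Samples with ``R < R_min`` or ``R >= R_max`` are rejected (not clipped):
    silently clipping noise excursions would distort peak amplitudes, so the
    caller must pre-clip explicitly if that is intended. The error names the
    offending sample indices.
    """
    R_arr = np.asarray(R, dtype=float)
    bad = (R_arr < cal.R_min) | (R_arr >= cal.R_max)
    if np.any(bad):
        idx = np.flatnonzero(np.atleast_1d(bad))
        shown = ", ".join(map(str, idx[:10]))
        more = f" (+{idx.size - 10} more)" if idx.size > 10 else ""
        raise CalibrationRangeError(
            f"{idx.size} ratio sample(s) outside [R_min={cal.R_min}, "
            f"R_max={cal.R_max}) for sensor '{cal.sensor_id}' at index(es) "
            f"{shown}{more}",
            indices=idx,
        )
    conc = cal.K * (R_arr - cal.R_min) / (cal.R_max - R_arr)
    return conc if R_arr.ndim else float(conc)


def concentration_to_ratio(C, cal: CalibrationParams):
    """Invert the ratiometric equation: concentration (µM) -> ratio.

    Algebraic inverse used by the synthetic-trace generator to emit
    ratio-mode output. Approaches ``R_max`` from below as C grows; exact
    inverse of :func:`ratio_to_concentration` on C >= 0.
    """
    C_arr = np.asarray(C, dtype=float)
    if np.any(C_arr < 0):
        idx = np.flatnonzero(np.atleast_1d(C_arr < 0))
        raise DomainError(
            f"negative concentration(s) at index(es) {', '.join(map(str, idx[:10]))}"
        )
    ratio = (cal.R_min * cal.K + cal.R_max * C_arr) / (cal.K + C_arr)
    return ratio if C_arr.ndim else float(ratio)
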