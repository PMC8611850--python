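"""Forward models of the two bench instruments used to measure liquid properties.

Surface tension is measured by the pull-off (du Noüy ring) method: the
voltage drop of the instrument's force transducer at the moment the ring
tears free of the liquid film, divided by the calibration coefficient and
the wetted ring perimeter, gives the surface-tension coefficient.

Viscosity is measured by falling-ball viscometry: a small sphere falling at
terminal speed through a liquid column, with Ladenburg wall (d/D) and depth
(d/2H) corrections applied to the Stokes drag.

Both functions are pure arithmetic and are used by the synthetic-data
generator as physically grounded forward models.
"""

from __future__ import annotations

import math

__all__ = [
    "CalibrationError",
    "MeasurementError",
    "surface_tension_from_instrument",
    "viscosity_from_falling_ball",
    "STANDARD_GRAVITY",
]

#: Standard gravitational acceleration, m/s^2.
STANDARD_GRAVITY = 9.80665


class CalibrationError(ValueError):
    """Instrument calibration constants are physically invalid."""


class MeasurementError(ValueError):
    """A reading is inconsistent with the measurement principle."""


def surface_tension_from_instrument(
    u1: float, u2: float, k: float, d1: float, d2: float
) -> float:
    """Surface-tension coefficient from a pull-off measurement.

    Parameters
    ----------
    u1, u2:
        Voltmeter readings (V) immediately before and after the ring's
        liquid film breaks; ``u1 >= u2``.
    k:
        Instrument conversion coefficient (calibrated by the stepwise
        difference method); must be positive.
    d1, d2:
        Inner and outer diameters of the ring (m); their sum must be
        positive.

    Returns
    -------
    float
        Surface tension sigma = (U1 - U2) / (K * pi * (D1 + D2)) in N/m.
    """
    if k <= 0 or (d1 + d2) <= 0:
        raise CalibrationError(
            f"invalid calibration: K={k!r}, D1+D2={d1 + d2!r} (both must be > 0)"
        )
    if u1 < u2:
        raise MeasurementError(
            f"invalid reading: U1={u1!r} < U2={u2!r}; the pre-break voltage "
            "cannot be below the post-break voltage"
        )
    return (u1 - u2) / (k * math.pi * (d1 + d2))


def viscosity_from_falling_ball(
    rho: float,
    rho0: float,
    d: float,
    big_d: float,
    h: float,
    v: float,
    g: float = STANDARD_GRAVITY,
) -> float:
    """Dynamic viscosity from a falling-ball measurement, in mPa·s.

    Parameters
    ----------
    rho, rho0:
        Densities of the ball and of the liquid (kg/m^3); the ball must be
        denser than the liquid, otherwise it does not sink.
    d, big_d:
        Ball diameter and cylinder inner diameter (m), ``0 < d < D``.
    h:
        Liquid depth (m), positive.
    v:
        Measured terminal (uniform) fall speed (m/s), positive.
    g:
        Gravitational acceleration (m/s^2); standard gravity by default.

    Returns
    -------
    float
        eta = (rho - rho0) g d^2 / (18 v [(1 + 2.4 d/D)(1 + 3.3 d/2H)]),
        evaluated in SI (Pa·s) and returned in mPa·s.

    Notes
    -----
    The two bracketed factors are the wall and finite-depth corrections to
    Stokes drag; both are >= 1 for valid geometry, so the corrected
    viscosity never exceeds the uncorrected Stokes value.
    """
    if v <= 0:
        raise MeasurementError(f"terminal speed must be positive, got v={v!r}")
    if not (0 < d < big_d):
        raise MeasurementError(
            f"geometry requires 0 < d < D, got d={d!r}, D={big_d!r}"
        )
    if h <= 0:
        raise MeasurementError(f"liquid depth must be positive, got H={h!r}")
    if rho <= rho0:
        raise MeasurementError(
            f"ball density {rho!r} must exceed liquid density {rho0!r} "
            "(the ball must sink)"
        )
    correction = (1.0 + 2.4 * d / big_d) * (1.0 + 3.3 * d / (2.0 * h))
    eta_si = (rho - rho0) * g * d * d / (18.0 * v * correction)
    return eta_si * 1000.0
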