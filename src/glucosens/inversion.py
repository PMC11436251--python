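"""Inversion of the glucose-induced scattering change.

The measurable in vivo quantity is the sensitivity of the differential
absorbance to glucose, dA_D/dCg (a.u. per mmol/L).  Monte Carlo
simulation of the same probe geometry supplies the proportionality
between A_D and the dermis scattering coefficient, dA_D/dmu_s
(a.u. per mm^-1).  Their quotient

    d mu_s / dCg = (dA_D/dCg) / (dA_D/dmu_s)

recovers the absolute scattering change per unit glucose, and dividing
by a reference mu_s turns it into the relative rate rho that the Mie
argument extends across the band.  Both inputs must use the same
(r_A, r_B) ring-role convention; only the quotient's sign is
convention-independent and physically meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .mie_extension import RelativeScatterChange

__all__ = [
    "DifferentialSensitivity",
    "DifferentialSlope",
    "IllConditionedInversionError",
    "invert_scatter_change",
    "relative_rate",
    "phantom_ratio",
    "DEFAULT_SLOPE_FLOOR",
]

#: Below this |dA_D/dmu_s| the quotient is numerically meaningless
#: (the ring pair sits near a floating-reference condition).
DEFAULT_SLOPE_FLOOR = 1e-4  # a.u. per mm^-1


class IllConditionedInversionError(ArithmeticError):
    """Raised when the differential slope is too close to zero to invert."""


@dataclass(frozen=True)
class DifferentialSensitivity:
    """dA_D/dCg with its ring-pair convention and provenance."""

    dAD_dCg: float                 # a.u. per mmol/L
    sds_pair: tuple[float, float]  # (r_A, r_B), mm
    source: str = "synthetic"      # "measured" | "synthetic"
    relative_uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.dAD_dCg):
            raise ValueError("dAD_dCg must be finite")
        if self.sds_pair[0] == self.sds_pair[1]:
            raise ValueError("sds_pair members must be distinct rings")


@dataclass(frozen=True)
class DifferentialSlope:
    """dA_D/dmu_s from a simulated sweep, with fit provenance."""

    dAD_dmus: float                # a.u. per mm^-1
    sds_pair: tuple[float, float]  # (r_A, r_B), mm
    r_squared: float = float("nan")
    sweep: tuple[float, ...] = ()
    relative_uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.dAD_dmus) or self.dAD_dmus == 0.0:
            raise ValueError("dAD_dmus must be finite and nonzero")
        if self.sds_pair[0] == self.sds_pair[1]:
            raise ValueError("sds_pair members must be distinct rings")


def invert_scatter_change(
    sens: DifferentialSensitivity,
    slope: DifferentialSlope,
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
) -> tuple[float, float]:
    """d mu_s/dCg = (dA_D/dCg) / (dA_D/dmu_s), with propagated uncertainty.

    Returns ``(value, relative_uncertainty)`` where the relative
    uncertainty combines the inputs' in quadrature (first-order error
    propagation for a quotient).  Raises if the ring pairs disagree or
    the slope magnitude is below ``slope_floor``.
    """
    if tuple(sens.sds_pair) != tuple(slope.sds_pair):
        raise ValueError(
            f"sds_pair mismatch: sensitivity {sens.sds_pair} vs slope {slope.sds_pair}"
        )
    if abs(slope.dAD_dmus) < slope_floor:
        raise IllConditionedInversionError(
            f"|dA_D/dmu_s| = {abs(slope.dAD_dmus):.3g} is below the floor "
            f"{slope_floor:.3g}; the ring pair is too close to a "
            "floating-reference condition to invert"
        )
    value = sens.dAD_dCg / slope.dAD_dmus
    rel_u = math.hypot(sens.relative_uncertainty, slope.relative_uncertainty)
    return value, rel_u


def relative_rate(
    dmus_dCg: float,
    mus_ref: float,
    reference_wavelength: float,
    relative_uncertainty: float = 0.0,
) -> RelativeScatterChange:
    """rho = (d mu_s/dCg) / mu_s at the reference wavelength."""
    if not mus_ref > 0:
        raise ValueError(f"mus_ref must be > 0, got {mus_ref}")
    rho = dmus_dCg / mus_ref
    return RelativeScatterChange(
        rho=rho,
        reference_wavelength=reference_wavelength,
        uncertainty=abs(rho) * relative_uncertainty,
    )


def phantom_ratio(
    rho_vivo: RelativeScatterChange,
    rho_phantom: RelativeScatterChange | float,
) -> float:
    """Ratio of the in-vivo relative scattering rate to a phantom's.

    Living tissue responds to glucose far more strongly than lipid
    phantoms; this ratio quantifies the gap.
    """
    phantom = rho_phantom.rho if isinstance(rho_phantom, RelativeScatterChange) else float(rho_phantom)
    if phantom == 0.0:
        raise ZeroDivisionError("phantom relative rate is zero")
    if rho_vivo.rho == 0.0:
        raise ValueError("in-vivo relative rate is zero")
    return rho_vivo.rho / phantom
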