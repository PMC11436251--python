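"""Wavelength extension of the glucose-induced scattering change.

Glucose raises the refractive index of the interstitial medium toward
that of the cellular scatterers, reducing the scattering coefficient —
the dominant glucose signal in vivo.  For a simplified medium of
spherical scatterers, Mie theory gives the reduced scattering
coefficient as

    mu_s' = K * (n_s / n_0 - 1)^2

with K a factor set by particle density, size and wavelength, and
n_s, n_0 the refractive indices of scatterer and medium.  The relative
change per unit glucose,

    (d mu_s'/dCg) / mu_s' = 2 n_s / (n_0 (n_0 - n_s)) * dn_0/dCg,

is independent of K, and since both the index term and dn_0/dCg are
nearly constant over the NIR window, the relative scattering change
measured at one wavelength applies across the whole 1000-1700 nm band.
Multiplying it by the mu_s spectrum of a layer yields the absolute
change spectrum d mu_s/dCg(lambda).  Anisotropy is treated as
glucose-invariant, so the relative change of mu_s equals that of mu_s'.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .optical_model import SpectralTable

__all__ = [
    "MieMediumModel",
    "RelativeScatterChange",
    "reduced_scattering",
    "relative_change",
    "extend_to_band",
]


@dataclass(frozen=True)
class MieMediumModel:
    """Spherical-scatterer medium for the index-matching argument.

    Defaults are illustrative soft-tissue values (cell organelles in
    interstitial fluid); the relative-change result does not depend on
    K, and the pipeline only uses the *constancy* of the relative
    change, not its absolute Mie prediction.
    """

    K: float = 100.0          # mm^-1, density/size/wavelength factor
    n_s: float = 1.45         # scatterer refractive index
    n_0: float = 1.35         # medium refractive index
    dn0_dCg: float = 2.5e-5   # medium index change per mmol/L glucose

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError("K must be > 0")
        if self.n_s < 1 or self.n_0 < 1:
            raise ValueError("refractive indices must be >= 1")
        if self.n_s == self.n_0:
            raise ValueError(
                "n_s must differ from n_0 (perfect index matching scatters nothing)"
            )


@dataclass(frozen=True)
class RelativeScatterChange:
    """rho = (d mu_s/dCg) / mu_s per mmol/L, anchored at one wavelength."""

    rho: float                    # dimensionless rate per mmol/L
    reference_wavelength: float   # nm
    uncertainty: float = 0.0      # same units as rho

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.rho):
            raise ValueError("rho must be finite")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")

    @property
    def percent(self) -> float:
        return 100.0 * self.rho


def reduced_scattering(model: MieMediumModel) -> float:
    """mu_s' = K (n_s/n_0 - 1)^2, in mm^-1."""
    return model.K * (model.n_s / model.n_0 - 1.0) ** 2


def relative_change(model: MieMediumModel) -> float:
    """Relative change of mu_s' per mmol/L glucose; independent of K."""
    return 2.0 * model.n_s / (model.n_0 * (model.n_0 - model.n_s)) * model.dn0_dCg


def extend_to_band(
    rho: RelativeScatterChange,
    table: SpectralTable,
    layer: str,
) -> pd.Series:
    """Absolute scattering-change spectrum d mu_s/dCg(lambda) for a layer.

    Multiplies the (wavelength-flat) relative rate by the layer's mu_s
    spectrum; at the reference wavelength the product reproduces the
    measured absolute change.  Returns a Series indexed by wavelength
    (nm) with values in mm^-1 per mmol/L.
    """
    if layer not in table.layers:
        raise ValueError(f"layer {layer!r} not in table (have {table.layers})")
    mus = table.mus_spectrum(layer)
    out = rho.rho * mus
    out.name = "dmus_dCg_mm-1_per_mmolL"
    return out
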