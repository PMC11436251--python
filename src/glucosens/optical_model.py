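"""Tissue and phantom optical models.

The scene for photon transport is a stack of plane-parallel layers, each
carrying the four bulk optical properties that govern NIR light
propagation: the absorption coefficient ``mu_a`` (mm^-1), the scattering
coefficient ``mu_s`` (mm^-1), the scattering anisotropy ``g`` (mean
cosine of the single-scattering deflection angle) and the refractive
index ``n``.  Two geometries are provided:

* a three-layer forearm skin model (epidermis / dermis / subcutis)
  under a 0.2-mm glass probe window, with per-wavelength properties
  interpolated from a bundled spectral table, and
* a homogeneous semi-infinite intralipid phantom whose scattering
  scales linearly with lipid concentration from a bundled 2% table.

Spectral tables are CSV files with columns
``wavelength_nm, layer, mu_a_mm-1, mu_s_mm-1, g, n`` on a strictly
increasing wavelength grid spanning 1000-1700 nm; values between grid
nodes are linearly interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OpticalProperties",
    "LayerSpec",
    "TissueModel",
    "SpectralTable",
    "load_skin_table",
    "load_intralipid_table",
    "load_glucose_absorption",
    "skin_three_layer",
    "intralipid_model",
    "SEMI_INFINITE",
    "INTRALIPID_RHO_PER_MMOL",
]

#: Marker thickness for a bottom layer treated as unbounded.
SEMI_INFINITE = math.inf

#: Relative scattering change of 2% intralipid per mmol/L glucose
#: (index-matching effect measured in tissue-simulating phantoms at a
#: 700-nm anchor wavelength; treated as wavelength-flat).
INTRALIPID_RHO_PER_MMOL = -0.0002  # -0.02 %

_GLASS_N = 1.4
_GLASS_THICKNESS_MM = 0.2
_SKIN_THICKNESS_MM = {"epidermis": 0.1, "dermis": 1.0, "subcutis": 10.0}


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a homogeneous medium."""

    mu_a: float  # absorption coefficient, mm^-1
    mu_s: float  # scattering coefficient, mm^-1
    g: float     # anisotropy factor, dimensionless
    n: float     # refractive index

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"g must lie in [-1, 1], got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (mm^-1)."""
        return self.mu_a + self.mu_s

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g) (mm^-1)."""
        return self.mu_s * (1.0 - self.g)


@dataclass(frozen=True)
class LayerSpec:
    """One plane-parallel layer: a name, a thickness and its properties."""

    name: str
    thickness: float  # mm; SEMI_INFINITE marks an unbounded bottom layer
    props: OpticalProperties

    def __post_init__(self) -> None:
        if not (self.thickness > 0):
            raise ValueError(
                f"layer {self.name!r}: thickness must be > 0, got {self.thickness}"
            )


@dataclass(frozen=True)
class TissueModel:
    """A probe window plus an ordered top-to-bottom stack of tissue layers.

    ``interface`` is the non-scattering glass cap the beam enters
    through; it may be ``None`` for bare media (phantoms).  By default
    the half-space above the window is index-matched to it, so no
    specular or detection Fresnel loss occurs at the top surface: such
    constant multiplicative losses cancel in every derivative and
    differential quantity the pipeline reports.
    """

    layers: tuple[LayerSpec, ...]
    interface: LayerSpec | None = None
    ambient_n_above: float | None = None  # default: matched to top medium
    ambient_n_below: float | None = None  # default: matched to bottom medium

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("at least one tissue layer is required")
        if self.interface is not None and self.interface.props.mu_t != 0.0:
            raise ValueError("interface window must have mu_a = mu_s = 0")
        for lay in self.layers[:-1]:
            if math.isinf(lay.thickness):
                raise ValueError("only the bottom layer may be semi-infinite")

    @property
    def stack(self) -> tuple[LayerSpec, ...]:
        """All layers the photon traverses, window first."""
        if self.interface is None:
            return self.layers
        return (self.interface,) + self.layers

    @property
    def n_above(self) -> float:
        return self.ambient_n_above if self.ambient_n_above is not None else self.stack[0].props.n

    @property
    def n_below(self) -> float:
        return self.ambient_n_below if self.ambient_n_below is not None else self.stack[-1].props.n

    def layer(self, name: str) -> LayerSpec:
        for lay in self.stack:
            if lay.name == name:
                return lay
        raise KeyError(name)

    def with_layer_props(self, name: str, **changes: float) -> "TissueModel":
        """Return a copy with one layer's optical properties modified."""
        found = False
        new_layers = []
        for lay in self.layers:
            if lay.name == name:
                new_layers.append(replace(lay, props=replace(lay.props, **changes)))
                found = True
            else:
                new_layers.append(lay)
        if not found:
            raise KeyError(name)
        return replace(self, layers=tuple(new_layers))


@dataclass(frozen=True)
class SpectralTable:
    """Per-layer optical properties on a wavelength grid.

    Thin wrapper over a tidy DataFrame (one row per wavelength and
    layer) providing validated, linearly interpolated lookups.
    """

    frame: pd.DataFrame = field(repr=False)
    provenance: str = ""

    _COLUMNS = ("wavelength_nm", "layer", "mu_a_mm-1", "mu_s_mm-1", "g", "n")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"spectral table missing columns: {sorted(missing)}")
        for layer in self.layers:
            w = self._layer_frame(layer)["wavelength_nm"].to_numpy()
            if not np.all(np.diff(w) > 0):
                raise ValueError(f"wavelength grid for {layer!r} not strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "") -> "SpectralTable":
        frame = pd.read_csv(path)
        return cls(frame=frame, provenance=provenance or str(path))

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(self.frame["layer"].unique())

    @property
    def span(self) -> tuple[float, float]:
        w = self.frame["wavelength_nm"]
        return float(w.min()), float(w.max())

    def _layer_frame(self, layer: str) -> pd.DataFrame:
        sub = self.frame[self.frame["layer"] == layer]
        if sub.empty:
            raise KeyError(f"layer {layer!r} not in table (have {self.layers})")
        return sub.sort_values("wavelength_nm")

    def _check_span(self, wavelength: float) -> None:
        lo, hi = self.span
        if not lo <= wavelength <= hi:
            raise ValueError(
                f"wavelength {wavelength} nm outside table span [{lo}, {hi}] nm"
            )

    def lookup(self, wavelength: float, layer: str) -> OpticalProperties:
        """Interpolated properties of ``layer`` at ``wavelength`` (nm)."""
        self._check_span(wavelength)
        sub = self._layer_frame(layer)
        w = sub["wavelength_nm"].to_numpy()
        interp = {
            col: float(np.interp(wavelength, w, sub[col].to_numpy()))
            for col in ("mu_a_mm-1", "mu_s_mm-1", "g", "n")
        }
        return OpticalProperties(
            mu_a=interp["mu_a_mm-1"], mu_s=interp["mu_s_mm-1"],
            g=interp["g"], n=interp["n"],
        )

    def mus_spectrum(self, layer: str) -> pd.Series:
        """mu_s (mm^-1) of ``layer`` indexed by wavelength (nm)."""
        sub = self._layer_frame(layer)
        return pd.Series(
            sub["mu_s_mm-1"].to_numpy(), index=sub["wavelength_nm"].to_numpy(),
            name=f"mu_s[{layer}]",
        )


def _bundled(name: str) -> Path:
    return Path(resources.files("glucosens").joinpath("data", name))  # type: ignore[arg-type]


def load_skin_table() -> SpectralTable:
    """The bundled representative three-layer skin table (1000-1700 nm)."""
    return SpectralTable.from_csv(
        _bundled("skin_three_layer.csv"),
        provenance="bundled representative skin table; dermis pinned to "
        "mu_a=2.05 mm^-1, mu_s=13 mm^-1 at 1314 nm",
    )


def load_glucose_absorption() -> pd.DataFrame:
    """Bundled representative dmu_a/dCg spectrum (mm^-1 per mmol/L).

    Stands in for published glucose molar-absorption data; negligible
    below ~1350 nm and a broad positive hump toward the NIR
    combination-band region.
    """
    return pd.read_csv(_bundled("glucose_absorption.csv"))


def load_intralipid_table() -> SpectralTable:
    """The bundled representative 2% intralipid table (1000-1700 nm)."""
    return SpectralTable.from_csv(
        _bundled("intralipid_2pct.csv"),
        provenance="bundled representative 2% intralipid table",
    )


def skin_three_layer(wavelength: float, table: SpectralTable | None = None) -> TissueModel:
    """Three-layer skin under a glass window at one wavelength.

    Geometry: glass 0.2 mm (n = 1.4, non-scattering), epidermis 0.1 mm,
    dermis 1.0 mm, subcutis 10.0 mm; layer properties interpolated from
    ``table`` (the bundled skin table by default).
    """
    table = table if table is not None else load_skin_table()
    glass = LayerSpec(
        "glass", _GLASS_THICKNESS_MM,
        OpticalProperties(mu_a=0.0, mu_s=0.0, g=0.0, n=_GLASS_N),
    )
    layers = tuple(
        LayerSpec(name, thick, table.lookup(wavelength, name))
        for name, thick in _SKIN_THICKNESS_MM.items()
    )
    return TissueModel(layers=layers, interface=glass)


def intralipid_model(
    wavelength: float,
    concentration: float = 2.0,
    table: SpectralTable | None = None,
) -> TissueModel:
    """Homogeneous semi-infinite intralipid phantom.

    ``concentration`` is the lipid percentage; scattering scales
    linearly from the bundled 2% reference table while absorption
    (water-dominated), g and n are kept at the reference values.
    """
    if not concentration > 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    table = table if table is not None else load_intralipid_table()
    ref = table.lookup(wavelength, "intralipid_2pct")
    props = replace(ref, mu_s=ref.mu_s * concentration / 2.0)
    layer = LayerSpec("intralipid", SEMI_INFINITE, props)
    return TissueModel(layers=(layer,))
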