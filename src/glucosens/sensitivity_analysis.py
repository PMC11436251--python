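"""Absorbance sensitivity to glucose via Monte Carlo parameter sweeps.

The absorbance sensitivity at a given wavelength and source-detector
separation decomposes into an absorption and a scattering channel:

    S_A = dA/dCg = (dA/dmu_a) (dmu_a/dCg) + (dA/dmu_s) (dmu_s/dCg)
        = S_mua + S_mus

The partial derivatives dA/dmu_a and dA/dmu_s are estimated by sweeping
the dermis coefficient over a grid, simulating the reflectance at each
sweep point with deterministically derived child seeds, and fitting an
ordinary-least-squares line of A(ring) versus the swept coefficient.
The glucose coefficients dmu_a/dCg and dmu_s/dCg come from a bundled
literature-style table and from the Mie band extension respectively.

``floating_reference`` locates, per wavelength, the SDS at which S_A
crosses zero: the detected signal there is insensitive to glucose and
can serve as a physiological-background reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .optical_model import TissueModel
from .photon_transport import (
    DetectorGrid,
    ReflectanceRecord,
    SimulationConfig,
    absorbance,
    run_mc,
)

__all__ = [
    "SlopeFit",
    "PartialDerivatives",
    "GlucoseCoefficients",
    "SensitivityResult",
    "partial_wrt_mus",
    "partial_wrt_mua",
    "differential_slope_from_fits",
    "assemble_sensitivity",
    "floating_reference",
]


@dataclass(frozen=True)
class SlopeFit:
    """OLS line of absorbance versus a swept optical coefficient."""

    slope: float       # a.u. per mm^-1
    intercept: float   # a.u.
    r_squared: float
    stderr: float      # standard error of the slope
    sweep: tuple[float, ...]        # swept coefficient values, mm^-1
    absorbances: tuple[float, ...]  # fitted A values, a.u.

    def __post_init__(self) -> None:
        if len(self.sweep) < 3:
            raise ValueError("a slope fit needs at least 3 sweep points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class PartialDerivatives:
    """dA/dmu_a and dA/dmu_s on a (wavelength, SDS) grid (tidy frame)."""

    frame: pd.DataFrame = field(repr=False)  # wavelength_nm, sds_mm, dA_dmua, dA_dmus

    def __post_init__(self) -> None:
        required = {"wavelength_nm", "sds_mm", "dA_dmua", "dA_dmus"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"frame must have columns {sorted(required)}")
        vals = self.frame[["dA_dmua", "dA_dmus"]].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("partial derivatives must be finite")


@dataclass(frozen=True)
class GlucoseCoefficients:
    """Per-wavelength dmu_a/dCg and dmu_s/dCg (mm^-1 per mmol/L)."""

    frame: pd.DataFrame = field(repr=False)  # wavelength_nm, dmua_dCg, dmus_dCg

    def __post_init__(self) -> None:
        required = {"wavelength_nm", "dmua_dCg", "dmus_dCg"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"frame must have columns {sorted(required)}")
        vals = self.frame[["dmua_dCg", "dmus_dCg"]].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("glucose coefficients must be finite")
        dmus = self.frame["dmus_dCg"].to_numpy()
        nz = dmus[dmus != 0]
        if nz.size and not (np.all(nz > 0) or np.all(nz < 0)):
            raise ValueError("dmus_dCg sign must be uniform across the band")


@dataclass(frozen=True)
class SensitivityResult:
    """S_mua, S_mus and S_A per (wavelength, SDS), tidy."""

    frame: pd.DataFrame = field(repr=False)  # wavelength_nm, sds_mm, S_mua, S_mus, S_A

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def at(self, wavelength: float, sds: float) -> pd.Series:
        sel = self.frame[
            (self.frame["wavelength_nm"] == wavelength)
            & (self.frame["sds_mm"] == sds)
        ]
        if sel.empty:
            raise KeyError((wavelength, sds))
        return sel.iloc[0]


def _sweep_records(
    tissue: TissueModel,
    detectors: DetectorGrid,
    layer: str,
    coefficient: str,
    values: list[float],
    config: SimulationConfig,
) -> list[ReflectanceRecord]:
    records = []
    for i, v in enumerate(values):
        child_seed = int(
            np.random.SeedSequence([config.seed, i]).generate_state(1, np.uint32)[0]
            & 0x7FFFFFFF
        )
        cfg = replace(config, seed=child_seed)
        records.append(run_mc(tissue.with_layer_props(layer, **{coefficient: v}), detectors, cfg))
    return records


def _fit_per_ring(
    records: list[ReflectanceRecord],
    detectors: DetectorGrid,
    values: list[float],
) -> dict[float, SlopeFit]:
    fits: dict[float, SlopeFit] = {}
    for ring in detectors.ring_centers:
        a_vals = [absorbance(rec, ring) for rec in records]
        res = stats.linregress(values, a_vals)
        fits[float(ring)] = SlopeFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue) ** 2,
            stderr=float(res.stderr),
            sweep=tuple(float(v) for v in values),
            absorbances=tuple(float(a) for a in a_vals),
        )
    return fits


def _validate_sweep(values: list[float]) -> list[float]:
    values = [float(v) for v in values]
    if len(values) < 3:
        raise ValueError("sweep needs at least 3 values")
    if not all(b > a for a, b in zip(values, values[1:])):
        raise ValueError("sweep values must be strictly increasing")
    return values


def partial_wrt_mus(
    tissue: TissueModel,
    detectors: DetectorGrid,
    mus_sweep: list[float],
    config: SimulationConfig,
    layer: str = "dermis",
) -> dict[float, SlopeFit]:
    """Per-ring OLS slope of A versus the swept layer mu_s.

    One Monte Carlo run per sweep value with child seeds derived from
    ``config.seed``; everything but the swept coefficient is held fixed.
    """
    values = _validate_sweep(mus_sweep)
    records = _sweep_records(tissue, detectors, layer, "mu_s", values, config)
    return _fit_per_ring(records, detectors, values)


def partial_wrt_mua(
    tissue: TissueModel,
    detectors: DetectorGrid,
    mua_sweep: list[float],
    config: SimulationConfig,
    layer: str = "dermis",
) -> dict[float, SlopeFit]:
    """Per-ring OLS slope of A versus the swept layer mu_a."""
    values = _validate_sweep(mua_sweep)
    records = _sweep_records(tissue, detectors, layer, "mu_a", values, config)
    return _fit_per_ring(records, detectors, values)


def differential_slope_from_fits(
    fits: dict[float, SlopeFit],
    sds_pair: tuple[float, float],
) -> float:
    """dA_D/d(coefficient) = slope(r_A) - slope(r_B) for a ring pair."""
    r_a, r_b = sds_pair
    return fits[r_a].slope - fits[r_b].slope


def assemble_sensitivity(
    partials: PartialDerivatives,
    coeffs: GlucoseCoefficients,
) -> SensitivityResult:
    """Combine MC partial derivatives with glucose coefficients.

    S_mua = (dA/dmu_a)(dmu_a/dCg); S_mus = (dA/dmu_s)(dmu_s/dCg);
    S_A = S_mua + S_mus, element-wise on the shared (wavelength, SDS)
    grid.  A wavelength present in one input but not the other is a
    grid mismatch and raises.
    """
    pw = set(partials.frame["wavelength_nm"].unique())
    cw = set(coeffs.frame["wavelength_nm"].unique())
    if pw != cw:
        raise ValueError(
            f"wavelength grids differ: partials-only {sorted(pw - cw)}, "
            f"coefficients-only {sorted(cw - pw)}"
        )
    merged = partials.frame.merge(coeffs.frame, on="wavelength_nm", how="left")
    out = merged[["wavelength_nm", "sds_mm"]].copy()
    out["S_mua"] = merged["dA_dmua"] * merged["dmua_dCg"]
    out["S_mus"] = merged["dA_dmus"] * merged["dmus_dCg"]
    out["S_A"] = out["S_mua"] + out["S_mus"]
    return SensitivityResult(frame=out)


def floating_reference(
    result: SensitivityResult,
    wavelength_band: tuple[float, float] | None = None,
) -> pd.Series:
    """Zero-crossing SDS of S_A per wavelength, or NaN when none exists.

    S_A is linearly interpolated across the SDS grid; only crossings
    inside [min SDS, max SDS] are reported (no extrapolation).  When a
    band is given, wavelengths outside it are dropped.
    """
    frame = result.frame
    if wavelength_band is not None:
        lo, hi = wavelength_band
        frame = frame[(frame["wavelength_nm"] >= lo) & (frame["wavelength_nm"] <= hi)]
    out: dict[float, float] = {}
    for wl, sub in frame.groupby("wavelength_nm"):
        sub = sub.sort_values("sds_mm")
        if len(sub) < 2:
            raise ValueError(f"need >= 2 SDS points at {wl} nm")
        sds = sub["sds_mm"].to_numpy(dtype=float)
        sa = sub["S_A"].to_numpy(dtype=float)
        crossing = float("nan")
        for i in range(len(sa) - 1):
            y0, y1 = sa[i], sa[i + 1]
            if y0 == 0.0:
                crossing = sds[i]
                break
            if y0 * y1 < 0.0:
                crossing = sds[i] + (sds[i + 1] - sds[i]) * (-y0) / (y1 - y0)
                break
        else:
            if sa[-1] == 0.0:
                crossing = sds[-1]
        out[float(wl)] = crossing
    return pd.Series(out, name="floating_reference_sds_mm").sort_index()
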