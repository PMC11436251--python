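"""End-to-end orchestration of the sensitivity-evaluation pipeline.

Stages, in dependency order:

1. ``simulate``   — baseline skin reflectance at the anchor wavelength.
2. ``partials``   — dermis mu_s and mu_a sweeps at the anchor wavelength,
                    per-ring OLS slopes, and the differential slope
                    dA_D/dmu_s for the configured ring pair.
3. ``synth-ogtt`` — synthetic OGTT cohort, per-subject sensitivity
                    estimates and cohort summaries.
4. ``invert``     — dmu_s/dCg from the differential sensitivity (cohort
                    mean, or a measured value given in the config) and
                    the simulated differential slope; relative rate rho
                    and the in-vivo/phantom ratio.
5. ``extend``     — rho times the dermis mu_s spectrum: the
                    dmu_s/dCg(lambda) band spectrum.
6. ``sensitivity``— band sweeps at every grid wavelength, S_mua / S_mus
                    / S_A per (wavelength, SDS), floating-reference
                    SDSs, and calculated differential sensitivities.
7. ``compare``    — relative error between cohort-mean and calculated
                    differential sensitivities per wavelength.
8. ``report``     — one JSON aggregating everything.

Each stage communicates with the next only through serialized artifacts
in the output directory; a stage whose artifact already exists is
skipped, so deleting a late artifact and re-running regenerates only
the downstream stages.  All randomness derives from the seeds in the
config, making a repeated run byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inversion import (
    DifferentialSensitivity,
    DifferentialSlope,
    invert_scatter_change,
    phantom_ratio,
    relative_rate,
)
from .mie_extension import RelativeScatterChange, extend_to_band
from .ogtt import (
    DEFAULT_WAVELENGTHS_NM,
    CohortSpec,
    cohort_estimates,
    cohort_summary,
    compare_sensitivities,
    make_cohort,
)
from .optical_model import (
    INTRALIPID_RHO_PER_MMOL,
    SpectralTable,
    load_glucose_absorption,
    load_skin_table,
    skin_three_layer,
)
from .photon_transport import DetectorGrid, SimulationConfig, run_mc
from .sensitivity_analysis import (
    GlucoseCoefficients,
    PartialDerivatives,
    SensitivityResult,
    assemble_sensitivity,
    differential_slope_from_fits,
    floating_reference,
    partial_wrt_mua,
    partial_wrt_mus,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = (
    "simulate",
    "partials",
    "synth-ogtt",
    "invert",
    "extend",
    "sensitivity",
    "compare",
    "report",
)


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    outdir: str = "glucosens_out"
    seed: int = 0
    n_photons: int = 10_000_000      # anchor-wavelength sweeps
    band_photons: int = 200_000      # per run on the band grid
    batch_count: int = 10
    anchor_wavelength: float = 1314.0
    sds_mm: tuple[float, ...] = (1.7, 2.0, 2.3, 2.6, 2.9)
    ring_half_width: float = 0.15
    r_a: float = 2.0                 # far ring of the differential pair
    r_b: float = 1.7                 # near ring
    mus_sweep: tuple[float, ...] = (5.0, 7.0, 9.0, 11.0, 13.0)
    mua_sweep_offsets: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    band_start: float = 1000.0
    band_stop: float = 1700.0
    band_step: float = 100.0
    cohort_wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM
    skin_table: str | None = None    # path to CSV; None = bundled
    measured_dAD_dCg: float | None = None  # a.u. per mmol/L; None = cohort mean
    cohort_seed: int = 20240
    cohort_noise_sd: float | None = None   # None = calibrated default
    intralipid_rho: float = INTRALIPID_RHO_PER_MMOL
    group_sizes: dict = field(default_factory=dict)  # {} = 6/7/6/6 default

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.skin_table is not None and not Path(cfg.skin_table).exists():
            raise FileNotFoundError(cfg.skin_table)
        return cfg

    def resolved(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d

    # -- derived helpers -------------------------------------------------
    def detectors(self) -> DetectorGrid:
        return DetectorGrid(tuple(self.sds_mm), self.ring_half_width)

    def table(self) -> SpectralTable:
        if self.skin_table is not None:
            return SpectralTable.from_csv(self.skin_table)
        return load_skin_table()

    def band_wavelengths(self) -> list[float]:
        grid = set(np.arange(self.band_start, self.band_stop + 1e-9, self.band_step))
        grid.update(self.cohort_wavelengths)
        grid.add(self.anchor_wavelength)
        return sorted(float(w) for w in grid)

    def cohort_spec(self) -> CohortSpec:
        kwargs = {}
        if self.group_sizes:
            kwargs["group_sizes"] = dict(self.group_sizes)
        if self.cohort_noise_sd is not None:
            kwargs["noise_sd"] = self.cohort_noise_sd
        return CohortSpec(**kwargs)


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def _sweep_partials(cfg, tissue, detectors, wavelength, n_photons, seed_tag):
    """Both sweeps at one wavelength; returns (mus_fits, mua_fits)."""
    base_mua = tissue.layer("dermis").props.mu_a
    sim = SimulationConfig(
        n_photons=n_photons,
        seed=int(np.random.SeedSequence([cfg.seed, seed_tag]).generate_state(1)[0] & 0x7FFFFFFF),
        batch_count=cfg.batch_count,
    )
    mus_fits = partial_wrt_mus(tissue, detectors, list(cfg.mus_sweep), sim)
    sim2 = SimulationConfig(
        n_photons=n_photons,
        seed=int(np.random.SeedSequence([cfg.seed, seed_tag + 1]).generate_state(1)[0] & 0x7FFFFFFF),
        batch_count=cfg.batch_count,
    )
    mua_sweep = [base_mua + off for off in cfg.mua_sweep_offsets]
    mua_fits = partial_wrt_mua(tissue, detectors, mua_sweep, sim2)
    return mus_fits, mua_fits


# -- stages --------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> Path:
    art = out / "reflectance_anchor.json"
    if art.exists():
        return art
    tissue = skin_three_layer(cfg.anchor_wavelength, cfg.table())
    sim = SimulationConfig(
        n_photons=cfg.n_photons, seed=cfg.seed, batch_count=cfg.batch_count
    )
    rec = run_mc(tissue, cfg.detectors(), sim)
    rec.to_csv(out / "reflectance_anchor.csv")
    rec.to_json(art)
    return art


def stage_partials(cfg: PipelineConfig, out: Path) -> Path:
    art = out / "partials_anchor.json"
    if art.exists():
        return art
    tissue = skin_three_layer(cfg.anchor_wavelength, cfg.table())
    mus_fits, mua_fits = _sweep_partials(
        cfg, tissue, cfg.detectors(), cfg.anchor_wavelength, cfg.n_photons, seed_tag=1
    )
    pair = (cfg.r_a, cfg.r_b)
    diff_slope = differential_slope_from_fits(mus_fits, pair)
    rel_u = float(
        np.hypot(mus_fits[cfg.r_a].stderr, mus_fits[cfg.r_b].stderr) / abs(diff_slope)
    )
    payload = {
        "wavelength_nm": cfg.anchor_wavelength,
        "sds_pair": list(pair),
        "dAD_dmus": diff_slope,
        "dAD_dmus_rel_uncertainty": rel_u,
        "mus_fits": {
            str(r): {
                "slope": f.slope, "intercept": f.intercept,
                "r_squared": f.r_squared, "stderr": f.stderr,
                "sweep": list(f.sweep), "absorbances": list(f.absorbances),
            }
            for r, f in mus_fits.items()
        },
        "mua_fits": {
            str(r): {
                "slope": f.slope, "intercept": f.intercept,
                "r_squared": f.r_squared, "stderr": f.stderr,
                "sweep": list(f.sweep), "absorbances": list(f.absorbances),
            }
            for r, f in mua_fits.items()
        },
    }
    _write_json(art, payload)
    return art


def stage_synth_ogtt(cfg: PipelineConfig, out: Path) -> Path:
    art = out / "cohort_summary.json"
    if art.exists():
        return art
    profiles = make_cohort(cfg.cohort_spec(), seed=cfg.cohort_seed)
    estimates = cohort_estimates(profiles, wavelengths=cfg.cohort_wavelengths)
    estimates.to_csv(out / "cohort_estimates.csv", index=False)
    summary = cohort_summary(estimates)
    payload = {
        "n_subjects": int(estimates["subject_id"].nunique()),
        "by_wavelength": summary["by_wavelength"].to_dict(orient="records"),
        "by_group": summary["by_group"].to_dict(orient="records"),
    }
    _write_json(art, payload)
    return art


def stage_invert(cfg: PipelineConfig, out: Path) -> Path:
    art = out / "inversion.json"
    if art.exists():
        return art
    partials = json.loads((out / "partials_anchor.json").read_text())
    pair = tuple(partials["sds_pair"])
    slope = DifferentialSlope(
        dAD_dmus=partials["dAD_dmus"],
        sds_pair=pair,
        relative_uncertainty=partials["dAD_dmus_rel_uncertainty"],
    )
    if cfg.measured_dAD_dCg is not None:
        sens_value, source = cfg.measured_dAD_dCg, "measured"
    else:
        summary = json.loads((out / "cohort_summary.json").read_text())
        rec = next(
            r for r in summary["by_wavelength"]
            if r["wavelength_nm"] == cfg.anchor_wavelength
        )
        sens_value, source = rec["mean_dAD_dCg"], "synthetic"
    sens = DifferentialSensitivity(dAD_dCg=sens_value, sds_pair=pair, source=source)
    dmus_dCg, rel_u = invert_scatter_change(sens, slope)
    mus_ref = cfg.table().lookup(cfg.anchor_wavelength, "dermis").mu_s
    rho = relative_rate(dmus_dCg, mus_ref, cfg.anchor_wavelength, rel_u)
    ratio = phantom_ratio(rho, cfg.intralipid_rho)
    _write_json(
        art,
        {
            "dAD_dCg": sens_value,
            "dAD_dCg_source": source,
            "dAD_dmus": slope.dAD_dmus,
            "sds_pair": list(pair),
            "dmus_dCg_mm-1_per_mmolL": dmus_dCg,
            "relative_uncertainty": rel_u,
            "mus_ref_mm-1": mus_ref,
            "rho_per_mmolL": rho.rho,
            "rho_percent": rho.percent,
            "reference_wavelength_nm": rho.reference_wavelength,
            "intralipid_rho_per_mmolL": cfg.intralipid_rho,
            "vivo_phantom_ratio": ratio,
        },
    )
    return art


def stage_extend(cfg: PipelineConfig, out: Path) -> Path:
    art = out / "dmus_dCg_band.csv"
    if art.exists():
        return art
    inv = json.loads((out / "inversion.json").read_text())
    rho = RelativeScatterChange(
        rho=inv["rho_per_mmolL"],
        reference_wavelength=inv["reference_wavelength_nm"],
    )
    spectrum = extend_to_band(rho, cfg.table(), "dermis")
    spectrum.rename_axis("wavelength_nm").reset_index().to_csv(art, index=False)
    return art


def stage_sensitivity(cfg: PipelineConfig, out: Path) -> Path:
    art = out / "sensitivity.csv"
    if art.exists():
        return art
    band = json.loads((out / "inversion.json").read_text())
    rho = band["rho_per_mmolL"]
    table = cfg.table()
    detectors = cfg.detectors()
    dmua_table = load_glucose_absorption()

    partial_rows = []
    coeff_rows = []
    for i, wl in enumerate(cfg.band_wavelengths()):
        tissue = skin_three_layer(wl, table)
        mus_fits, mua_fits = _sweep_partials(
            cfg, tissue, detectors, wl, cfg.band_photons, seed_tag=100 + 10 * i
        )
        for r in detectors.ring_centers:
            partial_rows.append(
                {
                    "wavelength_nm": wl,
                    "sds_mm": float(r),
                    "dA_dmua": mua_fits[float(r)].slope,
                    "dA_dmus": mus_fits[float(r)].slope,
                }
            )
        mus_wl = table.lookup(wl, "dermis").mu_s
        dmua = float(
            np.interp(
                wl,
                dmua_table["wavelength_nm"],
                dmua_table["dmua_dCg_mm-1_per_mmolL"],
            )
        )
        coeff_rows.append(
            {"wavelength_nm": wl, "dmua_dCg": dmua, "dmus_dCg": rho * mus_wl}
        )

    partials = PartialDerivatives(frame=pd.DataFrame(partial_rows))
    coeffs = GlucoseCoefficients(frame=pd.DataFrame(coeff_rows))
    result = assemble_sensitivity(partials, coeffs)
    result.to_csv(art)
    partials.frame.to_csv(out / "partial_derivatives.csv", index=False)

    ref = floating_reference(result)
    ref.rename_axis("wavelength_nm").reset_index().to_csv(
        out / "floating_reference.csv", index=False
    )

    # calculated differential sensitivity for the configured ring pair
    rows = []
    for wl, sub in result.frame.groupby("wavelength_nm"):
        sub = sub.set_index("sds_mm")
        rows.append(
            {
                "wavelength_nm": float(wl),
                "dAD_dCg_calc": float(
                    sub.loc[cfg.r_a, "S_A"] - sub.loc[cfg.r_b, "S_A"]
                ),
            }
        )
    pd.DataFrame(rows).to_csv(out / "differential_sensitivity_calc.csv", index=False)
    return art


def stage_compare(cfg: PipelineConfig, out: Path) -> Path:
    art = out / "comparison.json"
    if art.exists():
        return art
    calc = pd.read_csv(out / "differential_sensitivity_calc.csv")
    summary = json.loads((out / "cohort_summary.json").read_text())
    exp = {
        float(r["wavelength_nm"]): float(r["mean_dAD_dCg"])
        for r in summary["by_wavelength"]
    }
    calc_map = {
        float(r.wavelength_nm): float(r.dAD_dCg_calc)
        for r in calc.itertuples()
        if float(r.wavelength_nm) in exp
    }
    errors = compare_sensitivities(calc_map, exp)
    _write_json(
        art,
        {
            "wavelength_nm": [float(w) for w in errors.index],
            "calculated": [calc_map[float(w)] for w in errors.index],
            "experimental": [exp[float(w)] for w in errors.index],
            "relative_error_pct": [float(v) for v in errors.values],
        },
    )
    return art


def stage_report(cfg: PipelineConfig, out: Path) -> Path:
    art = out / "report.json"
    if art.exists():
        return art
    report = {"config": cfg.resolved()}
    report["partials"] = json.loads((out / "partials_anchor.json").read_text())
    report["inversion"] = json.loads((out / "inversion.json").read_text())
    report["cohort"] = json.loads((out / "cohort_summary.json").read_text())
    report["comparison"] = json.loads((out / "comparison.json").read_text())
    report["sensitivity_csv"] = "sensitivity.csv"
    report["floating_reference"] = {
        str(r.wavelength_nm): (None if np.isnan(r.floating_reference_sds_mm) else float(r.floating_reference_sds_mm))
        for r in pd.read_csv(out / "floating_reference.csv").itertuples()
    }
    _write_json(art, report)
    return art


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "partials": stage_partials,
    "synth-ogtt": stage_synth_ogtt,
    "invert": stage_invert,
    "extend": stage_extend,
    "sensitivity": stage_sensitivity,
    "compare": stage_compare,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order; returns the final report.

    Raises with the failing stage's name on error.  Stages whose
    artifact already exists in ``cfg.outdir`` are skipped.
    """
    if cfg.cohort_spec() is None:  # pragma: no cover - CohortSpec validates
        raise ValueError("invalid cohort")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.yaml").write_text(yaml.safe_dump(cfg.resolved()))
    for name in stages:
        if name not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {name!r} (have {STAGES})")
        try:
            _STAGE_FUNCS[name](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    report_path = out / "report.json"
    if report_path.exists():
        return json.loads(report_path.read_text())
    return {}
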