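import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glucosens.sensitivity_analysis as sa
from glucosens.photon_transport import DetectorGrid, SimulationConfig
from glucosens.sensitivity_analysis import (
    GlucoseCoefficients,
    PartialDerivatives,
    SensitivityResult,
    assemble_sensitivity,
    differential_slope_from_fits,
    floating_reference,
    partial_wrt_mus,
)


def _fake_run_mc_linear(intercepts, slope_per_mm):
    """Stand-in MC whose absorbance is exactly affine in dermis mu_s."""

    def fake(tissue, detectors, config):
        mus = tissue.layer("dermis").props.mu_s
        fractions = np.array(
            [np.exp(-(a + slope_per_mm * r * mus)) for r, a in zip(detectors.ring_centers, intercepts)]
        )
        from glucosens.photon_transport import ReflectanceRecord

        return ReflectanceRecord(
            detectors=detectors,
            fractions=fractions,
            standard_errors=np.zeros_like(fractions),
            diffuse_reflectance=float(fractions.sum()),
            transmittance=0.0,
            absorbed_fraction=1.0 - float(fractions.sum()),
            specular_loss=0.0,
            conservation_se=0.0,
            n_photons=config.n_photons,
            seed=config.seed,
        )

    return fake


class TestSlopeFits:
    def test_collinear_absorbances_recovered_exactly(self, skin_1314, monkeypatch):
        detectors = DetectorGrid(ring_centers=(1.7, 2.0))
        monkeypatch.setattr(sa, "run_mc", _fake_run_mc_linear([1.0, 1.2], 0.01))
        fits = partial_wrt_mus(
            skin_1314, detectors, [5, 7, 9, 11, 13], SimulationConfig(n_photons=10, seed=0)
        )
        assert fits[1.7].slope == pytest.approx(0.01 * 1.7, rel=1e-12)
        assert fits[2.0].slope == pytest.approx(0.01 * 2.0, rel=1e-12)
        assert fits[1.7].r_squared == pytest.approx(1.0)

    def test_degenerate_sweep_rejected(self, skin_1314, detectors):
        cfg = SimulationConfig(n_photons=10, seed=0)
        with pytest.raises(ValueError):
            partial_wrt_mus(skin_1314, detectors, [9, 9, 9], cfg)
        with pytest.raises(ValueError):
            partial_wrt_mus(skin_1314, detectors, [5, 7], cfg)

    def test_slope_matches_endpoint_finite_difference(self, mus_sweep_fits):
        # OLS slope vs independent two-point finite difference, 2 combined SE
        for ring in (1.7, 2.0):
            fit = mus_sweep_fits[ring]
            fd = (fit.absorbances[-1] - fit.absorbances[0]) / (fit.sweep[-1] - fit.sweep[0])
            assert fit.slope == pytest.approx(fd, abs=max(4.0 * fit.stderr, 1e-12))

    def test_mua_slopes_positive_for_skin(self, mua_sweep_fits):
        # more absorption always means higher absorbance
        for ring, fit in mua_sweep_fits.items():
            assert fit.slope > 0, f"ring {ring}"

    def test_mua_slope_grows_with_sds(self, mua_sweep_fits):
        # longer mean path at larger SDS => stronger response to mu_a
        rings = sorted(mua_sweep_fits)
        for r1, r2 in zip(rings, rings[1:]):
            f1, f2 = mua_sweep_fits[r1], mua_sweep_fits[r2]
            allowance = 3.0 * np.hypot(f1.stderr, f2.stderr)
            assert f2.slope > f1.slope - allowance

    def test_differential_slope_role_assignment(self, mus_sweep_fits):
        d = differential_slope_from_fits(mus_sweep_fits, (2.0, 1.7))
        assert d == pytest.approx(mus_sweep_fits[2.0].slope - mus_sweep_fits[1.7].slope)
        assert differential_slope_from_fits(mus_sweep_fits, (1.7, 2.0)) == pytest.approx(-d)


def _grid_frames(s_mua_vals, s_mus_vals, dmua=1.0, dmus=1.0):
    wavelengths = [1100.0, 1300.0]
    rows_p, rows_c = [], []
    i = 0
    for wl in wavelengths:
        for sds in (1.7, 2.0):
            rows_p.append(
                {"wavelength_nm": wl, "sds_mm": sds,
                 "dA_dmua": s_mua_vals[i % len(s_mua_vals)],
                 "dA_dmus": s_mus_vals[i % len(s_mus_vals)]}
            )
            i += 1
        rows_c.append({"wavelength_nm": wl, "dmua_dCg": dmua, "dmus_dCg": dmus})
    return PartialDerivatives(frame=pd.DataFrame(rows_p)), GlucoseCoefficients(
        frame=pd.DataFrame(rows_c)
    )


class TestAssembleSensitivity:
    def test_zero_coefficients_give_zero_sensitivity(self):
        p, _ = _grid_frames([1.0, 2.0], [-0.5, -1.0])
        _, c = _grid_frames([1.0], [1.0], dmua=0.0, dmus=0.0)
        res = assemble_sensitivity(p, c)
        assert np.allclose(res.frame[["S_mua", "S_mus", "S_A"]], 0.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        mua=st.floats(0.1, 5.0), mus=st.floats(-3.0, -0.01),
        dmua=st.floats(0.0, 1e-3), dmus=st.floats(-0.1, -1e-4),
    )
    def test_additivity_exact(self, mua, mus, dmua, dmus):
        p, c = _grid_frames([mua], [mus], dmua=dmua, dmus=dmus)
        res = assemble_sensitivity(p, c)
        assert np.array_equal(
            res.frame["S_A"].to_numpy(),
            (res.frame["S_mua"] + res.frame["S_mus"]).to_numpy(),
        )

    def test_linear_in_each_coefficient(self):
        p, c1 = _grid_frames([1.5], [-0.8], dmua=2e-5, dmus=-0.02)
        _, c2 = _grid_frames([1.5], [-0.8], dmua=2e-5, dmus=-0.04)
        r1 = assemble_sensitivity(p, c1)
        r2 = assemble_sensitivity(p, c2)
        assert np.allclose(r2.frame["S_mus"], 2.0 * r1.frame["S_mus"])
        assert np.allclose(r2.frame["S_mua"], r1.frame["S_mua"])

    def test_wavelength_grid_mismatch_rejected(self):
        p, _ = _grid_frames([1.0], [1.0])
        c = GlucoseCoefficients(
            frame=pd.DataFrame(
                [{"wavelength_nm": 999.0, "dmua_dCg": 0.0, "dmus_dCg": -1.0}]
            )
        )
        with pytest.raises(ValueError, match="grids differ"):
            assemble_sensitivity(p, c)

    def test_nonuniform_dmus_sign_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            GlucoseCoefficients(
                frame=pd.DataFrame(
                    {
                        "wavelength_nm": [1000.0, 1100.0],
                        "dmua_dCg": [0.0, 0.0],
                        "dmus_dCg": [-1.0, 1.0],
                    }
                )
            )


def _result(sds, sa_vals, wl=1200.0):
    frame = pd.DataFrame(
        {
            "wavelength_nm": wl,
            "sds_mm": sds,
            "S_mua": 0.0,
            "S_mus": sa_vals,
            "S_A": sa_vals,
        }
    )
    return SensitivityResult(frame=frame)


class TestFloatingReference:
    def test_symmetric_crossing_interpolated(self):
        res = _result([1.7, 2.9], [1.0, -1.0])
        ref = floating_reference(res)
        assert ref.loc[1200.0] == pytest.approx(2.3)

    def test_same_sign_yields_absence(self):
        ref = floating_reference(_result([1.7, 2.0, 2.9], [1.0, 0.5, 0.2]))
        assert np.isnan(ref.loc[1200.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        vals=st.lists(
            st.floats(-1e-3, 1e-3, allow_nan=False).filter(lambda v: v != 0),
            min_size=2, max_size=6,
        )
    )
    def test_crossing_never_extrapolates(self, vals):
        sds = [1.7 + 0.3 * i for i in range(len(vals))]
        ref = floating_reference(_result(sds, vals))
        v = ref.loc[1200.0]
        assert np.isnan(v) or sds[0] <= v <= sds[-1]

    def test_band_filter(self):
        frame = pd.concat(
            [_result([1.7, 2.9], [1.0, -1.0], wl=1100.0).frame,
             _result([1.7, 2.9], [1.0, -1.0], wl=1650.0).frame]
        )
        ref = floating_reference(SensitivityResult(frame=frame), wavelength_band=(1000.0, 1300.0))
        assert list(ref.index) == [1100.0]
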