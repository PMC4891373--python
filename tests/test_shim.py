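"""Shim calibration decomposition and constrained current optimisation."""

import numpy as np
import pytest

from ptxh import phantom, shim
from ptxh.core import FieldMap
from ptxh.harmonics import lm_terms, real_sh_basis


def _pure_coil_cal(names_and_coeffs, limits):
    """Calibration whose coils are exact solid-harmonic terms."""
    terms = lm_terms(4)
    coils = []
    for name, lm, hz in names_and_coeffs:
        c = np.zeros(len(terms))
        c[terms.index(lm)] = hz
        coils.append(shim.ShimCoil(name, c, limits[name]))
    return shim.ShimCalibration(coils, order_max=4)


def _grid_search(F, y, limits, rounds=4, pts=21):
    """Dense coordinate grid search oracle for <=3-coil problems."""
    lo, hi = -limits.copy(), limits.copy()
    best = None
    for _ in range(rounds):
        axes = [np.linspace(lo[i], hi[i], pts) for i in range(len(limits))]
        mesh = np.meshgrid(*axes, indexing="ij")
        C = np.stack([m.ravel() for m in mesh], axis=1)
        cost = ((C @ F.T + y[None, :]) ** 2).sum(axis=1)
        best = C[np.argmin(cost)]
        span = (hi - lo) / (pts - 1)
        lo = np.maximum(best - span, -limits)
        hi = np.minimum(best + span, limits)
    return best


class TestDecompose:
    def test_pure_z2_coil(self, head_mask):
        spec = phantom.PhantomSpec(b0_sh_coeffs={"Z2": 250.0}, b0_local_perturbations=())
        fm = phantom.make_b0_map(spec, head_mask)
        coeffs, resid = shim.decompose_coil_field(fm, head_mask)
        terms = lm_terms(4)
        assert coeffs[terms.index((2, 0))] == pytest.approx(250.0, rel=1e-9)
        others = np.delete(coeffs, terms.index((2, 0)))
        assert np.abs(others).max() < 1e-6
        assert resid < 1e-9

    def test_mixture_recovered_to_1e6(self, head_mask):
        spec = phantom.PhantomSpec(
            b0_sh_coeffs={(2, 0): 0.9 * 100, (4, 0): 0.1 * 100},
            b0_local_perturbations=(),
        )
        fm = phantom.make_b0_map(spec, head_mask)
        coeffs, _ = shim.decompose_coil_field(fm, head_mask)
        terms = lm_terms(4)
        assert coeffs[terms.index((2, 0))] == pytest.approx(90.0, rel=1e-6)
        assert coeffs[terms.index((4, 0))] == pytest.approx(10.0, rel=1e-6)

    def test_zero_field_gives_zero_vector(self, head_mask):
        fm = FieldMap(np.zeros(head_mask.data.shape), head_mask.affine, head_mask)
        coeffs, resid = shim.decompose_coil_field(fm, head_mask)
        assert np.allclose(coeffs, 0.0)
        assert resid == 0.0

    def test_too_few_voxels_rejected(self, head_mask):
        from ptxh.core import Mask

        tiny = np.zeros_like(head_mask.data)
        tiny[25, 25, 22] = True
        with pytest.raises(ValueError):
            shim.decompose_coil_field(
                FieldMap(np.zeros(tiny.shape), head_mask.affine),
                Mask(tiny, head_mask.affine),
            )


class TestOptimize:
    def test_single_coil_interior_optimum(self, head_mask):
        cal = _pure_coil_cal([("Z2", (2, 0), 200.0)], {"Z2": 5.0})
        unit = cal.unit_fields(head_mask.coords_mm(), ["Z2"])[:, 0]
        vol = np.zeros(head_mask.data.shape)
        vol[head_mask.data] = -3.0 * unit
        b0 = FieldMap(vol, head_mask.affine, head_mask)
        setting = shim.optimize_shim_currents(b0, cal, head_mask, ["Z2"])
        assert setting.currents["Z2"] == pytest.approx(3.0, abs=1e-6)
        assert setting.predicted_stats.std_hz < 1e-6

    def test_single_coil_active_constraint(self, head_mask):
        cal = _pure_coil_cal([("Z2", (2, 0), 200.0)], {"Z2": 1.0})
        coords = head_mask.coords_mm()
        unit = cal.unit_fields(coords, ["Z2"])[:, 0]
        vol = np.zeros(head_mask.data.shape)
        vol[head_mask.data] = -3.0 * unit
        b0 = FieldMap(vol, head_mask.affine, head_mask)
        setting = shim.optimize_shim_currents(b0, cal, head_mask, ["Z2"])
        assert setting.currents["Z2"] == pytest.approx(1.0, abs=1e-9)
        # residual equals -2x the unit field
        assert setting.predicted_stats.std_hz == pytest.approx(
            2.0 * unit.std(ddof=1), rel=1e-6
        )

    def test_zero_field_gives_zero_currents(self, head_mask):
        cal = phantom.make_shim_calibration(seed=5)
        b0 = FieldMap(np.zeros(head_mask.data.shape), head_mask.affine, head_mask)
        setting = shim.optimize_shim_currents(b0, cal, head_mask)
        assert np.allclose(list(setting.currents.values()), 0.0, atol=1e-8)

    def test_matches_grid_search_oracle_three_coils(self, head_mask, b0_true):
        cal = _pure_coil_cal(
            [("Z", (1, 0), 400.0), ("Z2", (2, 0), 250.0), ("X", (1, 1), 400.0)],
            {"Z": 0.08, "Z2": 0.15, "X": 0.05},  # tight limits: constraints active
        )
        names = ["Z", "Z2", "X"]
        setting = shim.optimize_shim_currents(b0_true, cal, head_mask, names)
        F = cal.unit_fields(head_mask.coords_mm(), names)
        y = b0_true.values[head_mask.data]
        limits = np.array([cal.coil(n).limit for n in names])
        oracle = _grid_search(F, y, limits)
        got = np.array([setting.currents[n] for n in names])
        assert np.all(np.abs(got - oracle) <= 1e-3 * 2 * limits)

    def test_third_order_never_hurts(self, head_mask, b0_true):
        cal = phantom.make_shim_calibration(seed=6)
        first_second = ["X", "Y", "Z", "Z2", "ZX", "ZY", "X2Y2", "XY"]
        s12 = shim.optimize_shim_currents(b0_true, cal, head_mask, first_second)
        s123 = shim.optimize_shim_currents(b0_true, cal, head_mask)
        assert s123.predicted_stats.std_hz <= s12.predicted_stats.std_hz + 1e-9

    def test_limits_always_respected(self, head_mask, b0_true):
        cal = phantom.make_shim_calibration(
            limits={n: 0.05 for n in ("X", "Y", "Z")}, seed=7
        )
        setting = shim.optimize_shim_currents(b0_true, cal, head_mask)
        for c in cal.coils:
            assert abs(setting.currents[c.name]) <= c.limit + 1e-9

    def test_unknown_coil_rejected(self, head_mask, b0_true):
        cal = phantom.make_shim_calibration()
        with pytest.raises(KeyError):
            shim.optimize_shim_currents(b0_true, cal, head_mask, ["Z9"])


class TestPredict:
    def test_zero_currents_leave_field_unchanged(self, b0_true, head_mask):
        cal = phantom.make_shim_calibration()
        out = shim.predict_shimmed_field(
            b0_true, cal, {n: 0.0 for n in cal.names()}, head_mask
        )
        assert np.array_equal(out.values, b0_true.values)

    def test_oracle_case_cancels_field(self, head_mask):
        cal = _pure_coil_cal([("Z2", (2, 0), 200.0)], {"Z2": 5.0})
        coords = head_mask.coords_mm()
        unit = cal.unit_fields(coords, ["Z2"])[:, 0]
        vol = np.zeros(head_mask.data.shape)
        vol[head_mask.data] = -3.0 * unit
        b0 = FieldMap(vol, head_mask.affine, head_mask)
        setting = shim.optimize_shim_currents(b0, cal, head_mask, ["Z2"])
        out = shim.predict_shimmed_field(b0, cal, setting, head_mask)
        assert np.abs(out.values[head_mask.data]).max() < 1e-6

    def test_low_order_truth_fully_shimmed(self, head_mask):
        """Order <=2 field with a full 1st+2nd coil set and generous limits."""
        spec = phantom.PhantomSpec(
            b0_sh_coeffs={"Z": -55.0, "X": 26.0, "Z2": 130.0, "ZY": 62.0, "X2Y2": 44.0},
            b0_local_perturbations=(),
        )
        b0 = phantom.make_b0_map(spec, head_mask)
        cal = phantom.make_shim_calibration(imperfection=0.0, seed=8)
        subset = ["X", "Y", "Z", "Z2", "ZX", "ZY", "X2Y2", "XY"]
        setting = shim.optimize_shim_currents(b0, cal, head_mask, subset)
        pre = b0.values[head_mask.data].std(ddof=1)
        assert setting.predicted_stats.std_hz < 0.01 * pre

    def test_grid_mismatch_rejected(self, small_mask, b0_true):
        cal = phantom.make_shim_calibration()
        with pytest.raises(ValueError):
            shim.predict_shimmed_field(
                b0_true, cal, {n: 0.0 for n in cal.names()}, small_mask
            )


def test_calibration_json_round_trip(tmp_path):
    cal = phantom.make_shim_calibration(seed=9)
    cal.save_json(tmp_path / "cal.json")
    back = shim.ShimCalibration.load_json(tmp_path / "cal.json")
    assert back.names() == cal.names()
    for a, b in zip(cal.coils, back.coils):
        assert np.allclose(a.coeffs, b.coeffs)
        assert a.limit == b.limit
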