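"""Sweep driver, regression statistics, percent change, invariance check."""

import numpy as np
import pandas as pd
import pytest

from trabflow import (
    GapGeometry,
    MicrocrackSpec,
    PressureBC,
    SolverSettings,
    SweepConfig,
    crack_invariance_check,
    linear_fit_r2,
    percent_change,
    run_sweep,
)
from trabflow.sweeps import SweepResult, report_peak
from trabflow.wall_shear import WSSProfile

GROOVE = MicrocrackSpec(100.0, 50.0)
BASE_2D = GapGeometry(1500.0, 100.0, 100.0, crack=GROOVE)


class TestLinearFit:
    def test_exact_line(self):
        fit = linear_fit_r2([0.0, 1.0, 2.0, 3.0], [1.0, 3.0, 5.0, 7.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y_has_zero_r2(self):
        fit = linear_fit_r2([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])
        assert fit.r_squared == 0.0

    def test_matches_brute_force_sums(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        fit = linear_fit_r2(x, y)
        # independent arithmetic: normal equations by direct summation
        n = len(x)
        sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        ss_res = ((y - slope * x - intercept) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)

    def test_affine_rescaling_of_x_preserves_r2(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        r2a = linear_fit_r2(x, y).r_squared
        r2b = linear_fit_r2(250.0 * x - 17.0, y).r_squared
        assert r2a == pytest.approx(r2b, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            linear_fit_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            linear_fit_r2([1.0, 2.0], [1.0, 2.0])


class TestPercentChange:
    @pytest.mark.parametrize("ref,val,expect", [
        (14.0, 10.0, pytest.approx(28.571428, rel=1e-6)),
        (10.0, 10.0, 0.0),
        (10.0, 0.0, 100.0),
    ])
    def test_values(self, ref, val, expect):
        assert percent_change(ref, val) == expect

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestSweepConfigValidation:
    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            SweepConfig("delta_p", (100.0,), BASE_2D)

    def test_duplicates_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            SweepConfig("delta_p", (100.0, 100.0), BASE_2D)
        with pytest.raises(ValueError):
            SweepConfig("gap_height", (100.0, -5.0), BASE_2D)

    def test_width_sweep_requires_3d(self):
        with pytest.raises(ValueError):
            SweepConfig("gap_width", (800.0, 100.0), BASE_2D)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            SweepConfig("viscosity", (1.0, 2.0), BASE_2D)


@pytest.fixture(scope="module")
def small_pressure_sweep():
    cfg = SweepConfig("delta_p", (50.0, 100.0, 200.0, 250.0), BASE_2D,
                      PressureBC(300.0, 0.0), target_size_um=20.0,
                      refine_crack_factor=0.5, n_samples=150)
    return cfg, run_sweep(cfg)


class TestRunSweep:
    def test_peak_fss_increases_with_delta_p(self, small_pressure_sweep):
        _, res = small_pressure_sweep
        peaks = res.table["peak_fss_pa"].to_numpy()
        assert (np.diff(peaks) > 0).all()
        assert res.table["converged"].all()

    def test_rows_ordered_as_requested(self, small_pressure_sweep):
        cfg, res = small_pressure_sweep
        assert tuple(res.table["value"]) == cfg.values

    def test_deterministic_rerun(self, small_pressure_sweep):
        cfg, res = small_pressure_sweep
        res2 = run_sweep(cfg)
        pd.testing.assert_frame_equal(res.table.drop(columns="solve_time_s"),
                                      res2.table.drop(columns="solve_time_s"))

    def test_stokes_pressure_sweep_r2_exactly_one(self):
        cfg = SweepConfig("delta_p", (50.0, 100.0, 200.0), BASE_2D,
                          PressureBC(300.0, 0.0),
                          settings=SolverSettings(model="stokes"),
                          target_size_um=25.0, refine_crack_factor=0.5,
                          n_samples=100)
        res = run_sweep(cfg)
        fit = linear_fit_r2(res.table["value"], res.table["peak_fss_pa"])
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


class TestReportPeak:
    def test_upstream_plateau_ignores_corner_spike(self):
        x = np.linspace(2.5, 1497.5, 300)
        v = np.full(300, 10.0)
        v[(x > 720) & (x < 780)] = 0.0     # crack dip
        v[np.argmin(np.abs(x - 785.0))] = 14.0  # corner spike
        prof = WSSProfile(x_um=x, values=v)
        assert report_peak(prof, BASE_2D) == pytest.approx(10.0)

    def test_plain_channel_uses_interior(self):
        geom = GapGeometry(1500.0, 100.0, 100.0, crack=None)
        x = np.linspace(2.5, 1497.5, 300)
        v = np.full(300, 7.0)
        v[0] = 99.0   # end artifact
        prof = WSSProfile(x_um=x, values=v)
        assert report_peak(prof, geom) == pytest.approx(7.0)


def _fake_result(peaks, converged=True):
    cfg = SweepConfig("crack_depth", tuple(float(10 * (i + 1)) for i in range(len(peaks))),
                      BASE_2D, PressureBC(300.0, 0.0))
    table = pd.DataFrame({
        "value": cfg.values, "peak_fss_pa": peaks,
        "converged": [converged] * len(peaks),
    })
    return SweepResult(config=cfg, table=table)


class TestCrackInvariance:
    def test_identical_peaks_pass_with_zero_spread(self):
        ok, spread = crack_invariance_check(_fake_result([10.0, 10.0, 10.0]),
                                            _fake_result([10.0, 10.0]))
        assert ok and spread == 0.0

    def test_doubled_peak_fails(self):
        ok, spread = crack_invariance_check(_fake_result([10.0, 20.0, 10.0]),
                                            _fake_result([10.0, 10.0]))
        assert not ok and spread > 5.0

    def test_unconverged_rows_raise(self):
        with pytest.raises(ValueError):
            crack_invariance_check(_fake_result([10.0, 10.0], converged=False),
                                   _fake_result([10.0, 10.0]))
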