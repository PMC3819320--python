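import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

import pibquant as pq
from pibquant.kinetics import cumtrapz_from_origin, logan_ref, srtm_tac
from pibquant.phantom import frame_average


def make_tac(values, mid_times, name="roi"):
    return pq.TimeActivityCurve(region=name, values=np.asarray(values, float),
                                mid_times=np.asarray(mid_times, float), n_voxels=10)


class TestLoganReference:
    def test_self_reference_gives_zero_binding(self, ref_tac):
        r = logan_ref(ref_tac, ref_tac, k2_ref=0.16)
        assert r.bp_nd == pytest.approx(0.0, abs=1e-12)
        assert r.dvr == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k2_ref", [0.05, 0.16, 0.5])
    @pytest.mark.parametrize("ratio", [0.7, 1.5, 2.3])
    def test_constant_ratio_target_is_exact(self, ref_tac, k2_ref, ratio):
        # target = a * ref makes Y = a*X - 1/k2' exactly, so slope = a
        target = make_tac(ratio * ref_tac.values, ref_tac.mid_times)
        r = logan_ref(target, ref_tac, k2_ref=k2_ref)
        assert r.bp_nd == pytest.approx(ratio - 1.0, abs=1e-10)
        assert r.intercept == pytest.approx(-1.0 / k2_ref, rel=1e-6)

    def test_scale_invariance_of_dvr(self, ref_tac):
        target = make_tac(1.4 * ref_tac.values, ref_tac.mid_times)
        base = logan_ref(target, ref_tac)
        both = logan_ref(
            make_tac(7.0 * target.values, ref_tac.mid_times),
            make_tac(7.0 * ref_tac.values, ref_tac.mid_times),
        )
        only_target = logan_ref(make_tac(2.0 * target.values, ref_tac.mid_times), ref_tac)
        assert both.dvr == pytest.approx(base.dvr, rel=1e-12)
        assert only_target.dvr == pytest.approx(2.0 * base.dvr, rel=1e-12)

    def test_too_few_late_frames_rejected(self, ref_tac):
        with pytest.raises(ValueError, match="at least 3"):
            logan_ref(ref_tac, ref_tac, t_star=3500.0)

    def test_nonpositive_activity_in_window_rejected(self, ref_tac):
        bad = ref_tac.values.copy()
        bad[-2] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            logan_ref(make_tac(bad, ref_tac.mid_times), ref_tac)

    def test_mismatched_mid_times_rejected(self, ref_tac):
        other = make_tac(ref_tac.values[:-1], ref_tac.mid_times[:-1] + 1.0)
        with pytest.raises(ValueError, match="mid-times"):
            logan_ref(other, ref_tac)

    @pytest.mark.parametrize("bp_true", [0.0, 0.2, 0.5, 1.0, 1.5])
    def test_srtm_recovery_within_two_percent_points(self, fine_ref, schedule, ref_tac, bp_true):
        t, cr = fine_ref
        ct = srtm_tac(t, cr, pq.SRTMParams(1.0, 0.16, bp_true))
        target = make_tac(frame_average(t, ct, schedule), schedule.mid_times)
        r = logan_ref(target, ref_tac, t_star=1800.0)
        assert abs(r.bp_nd - bp_true) <= 0.02


class TestK2Sensitivity:
    def test_constant_ratio_has_zero_spread(self, ref_tac):
        target = make_tac(1.5 * ref_tac.values, ref_tac.mid_times)
        bp, spread = pq.k2_sensitivity(target, ref_tac, [0.05, 0.16, 0.5])
        assert spread == pytest.approx(0.0, abs=1e-10)

    def test_srtm_phantom_spread_is_small(self, fine_ref, schedule, ref_tac):
        t, cr = fine_ref
        ct = srtm_tac(t, cr, pq.SRTMParams(1.0, 0.16, 0.5))
        target = make_tac(frame_average(t, ct, schedule), schedule.mid_times)
        bp, spread = pq.k2_sensitivity(target, ref_tac, [0.05, 0.16, 0.5])
        assert spread < 0.05

    def test_empty_grid_rejected(self, ref_tac):
        with pytest.raises(ValueError, match="empty"):
            pq.k2_sensitivity(ref_tac, ref_tac, [])


class TestSRTMForwardModel:
    def test_zero_binding_unit_delivery_reproduces_reference(self, fine_ref):
        t, cr = fine_ref
        ct = srtm_tac(t, cr, pq.SRTMParams(1.0, 0.23, 0.0))
        np.testing.assert_allclose(ct, cr, rtol=1e-10, atol=1e-12)

    def test_early_time_delivery_limit(self, fine_ref):
        t, cr = fine_ref
        ct = srtm_tac(t, cr, pq.SRTMParams(2.0, 0.16, 0.0))
        i = np.argmax(cr > 0.01 * cr.max())
        assert ct[i] / cr[i] == pytest.approx(2.0, rel=1e-2)

    def test_matches_stiff_ode_integration(self, fine_ref):
        # SRTM as a state equation: C_T = R1*C_R + (k2 - R1*k2a)*B, dB/dt = C_R - k2a*B
        t, cr = fine_ref
        params = pq.SRTMParams(r1=0.9, k2=0.18, bp_nd_true=0.7)
        cr_i = interp1d(t, cr, kind="cubic", fill_value=0.0, bounds_error=False)
        sol = solve_ivp(
            lambda tt, b: cr_i(tt) - params.k2a * b,
            (0, t[-1]), [0.0], t_eval=t, method="LSODA", rtol=1e-9, atol=1e-12,
        )
        expected = params.r1 * cr + (params.k2 - params.r1 * params.k2a) * sol.y[0]
        got = srtm_tac(t, cr, params)
        scale = np.max(np.abs(expected))
        assert np.max(np.abs(got - expected)) < 1e-3 * scale

    def test_non_uniform_grid_rejected(self):
        t = np.array([0.0, 1.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="uniform"):
            srtm_tac(t, np.ones_like(t), pq.SRTMParams(1.0, 0.16, 0.5))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            pq.SRTMParams(-1.0, 0.16, 0.5)
        with pytest.raises(ValueError):
            pq.SRTMParams(1.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            pq.SRTMParams(1.0, 0.16, -0.1)


def test_running_integral_anchored_at_origin():
    t = np.array([1.0, 2.0, 4.0])
    y = np.array([2.0, 2.0, 2.0])
    # triangle 0->1 (area 1) then flat segments
    np.testing.assert_allclose(cumtrapz_from_origin(t, y), [1.0, 3.0, 7.0])
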