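import math

import numpy as np
import pytest

from aqueduct import flow as fl
from aqueduct import synthesis as syn
from aqueduct.workflows import flow_pipeline


def make_series(velocities, dt=0.087, pixel_area=4.0, venc=100.0):
    return fl.VelocitySeries(np.asarray(velocities, dtype=float), dt, pixel_area, venc)


def sine_cycle(amplitude=100.0, tc=0.85, n=24, offset=0.0):
    t = np.linspace(0.0, tc, n)
    return fl.FlowCurve(t, amplitude * np.sin(2 * np.pi * t / tc) + offset)


@pytest.fixture(scope="module")
def noisy_phantom():
    spec = syn.FlowSpec(noise_sd=3.4, offset=3.0, seed=3)
    vel, gt = syn.make_phantom_series(spec)
    return make_series(vel), gt, spec


class TestDetectRoi:
    def test_phantom_disk_found(self, noisy_phantom):
        series, gt, _ = noisy_phantom
        roi = fl.detect_roi(series)
        inter = np.logical_and(roi.mask, gt["roi_mask"]).sum()
        dice = 2 * inter / (roi.mask.sum() + gt["roi_mask"].sum())
        assert dice >= 0.8

    def test_static_series_raises(self):
        with pytest.raises(fl.FlowError, match="manual ROI"):
            fl.detect_roi(make_series(np.full((300, 16, 16), 2.0)))

    def test_override_mask_bypasses_detection(self, noisy_phantom):
        series, gt, _ = noisy_phantom
        roi = fl.detect_roi(series, override_mask=gt["roi_mask"])
        np.testing.assert_array_equal(roi.mask, gt["roi_mask"])

    def test_equivalent_diameter_definition(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:4] = True  # 4 px of 4 mm² = 16 mm²
        roi = fl.RoiMask(mask, 4.0)
        assert roi.equivalent_diameter == pytest.approx(2 * math.sqrt(16 / math.pi), rel=1e-12)


class TestDealias:
    def test_single_wrap_corrected(self):
        # true 120 mm/s recorded as -80 at VENC 100
        rec = np.array([60.0, -80.0, 60.0])
        out = fl.dealias(rec, 100.0)
        assert out[1] == pytest.approx(120.0)

    def test_within_venc_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-60, 60, 200)  # jumps can exceed venc -> smooth it
        v = np.convolve(v, np.ones(5) / 5, mode="same")
        np.testing.assert_allclose(fl.dealias(v, 100.0), v, atol=1e-12)

    def test_wrap_roundtrip_on_supravenc_sinusoid(self):
        t = np.arange(0, 26.1, 0.087)
        true = 150.0 * np.sin(2 * np.pi * t / 0.85)  # peaks at 1.5 venc
        wrapped = syn.wrap_velocity(true, 100.0)
        assert np.abs(fl.dealias(wrapped, 100.0) - true).max() < 1e-9


class TestBackgroundCorrect:
    def test_constant_offset_removed_exactly(self):
        spec = syn.FlowSpec(noise_sd=0.0, offset=5.0)
        vel, gt = syn.make_phantom_series(spec)
        series = make_series(vel)
        roi = fl.RoiMask(gt["roi_mask"], 4.0)
        corrected = fl.background_correct(series, roi)
        q = fl.compute_flow_curve(corrected, roi)
        np.testing.assert_allclose(q.flow, gt["q_true"], atol=1e-6)

    def test_zero_offset_unchanged(self):
        spec = syn.FlowSpec(noise_sd=0.0, offset=0.0)
        vel, gt = syn.make_phantom_series(spec)
        series = make_series(vel)
        corrected = fl.background_correct(series, fl.RoiMask(gt["roi_mask"], 4.0))
        np.testing.assert_allclose(corrected.velocities, series.velocities, atol=1e-9)

    def test_offset_recovery_under_noise(self):
        # estimator error must stay within 3 sd of its sampling error
        errors = []
        for seed in range(40):
            spec = syn.FlowSpec(noise_sd=1.0, offset=2.0, seed=seed)
            vel, gt = syn.make_phantom_series(spec)
            series = make_series(vel)
            roi = fl.RoiMask(gt["roi_mask"], 4.0)
            corrected = fl.background_correct(series, roi)
            errors.append(series.velocities.mean() - corrected.velocities.mean() - 2.0)
        errors = np.array(errors)
        # ~70+ stationary pixels x 300 frames per estimate
        assert np.abs(errors).mean() < 3 * 1.0 / math.sqrt(50 * 300)

    def test_fallback_warns_when_no_quiet_annulus(self):
        rng = np.random.default_rng(2)
        t = np.arange(120) * 0.087
        cardiac = np.sin(2 * np.pi * t / 0.85)
        vel = cardiac[:, None, None] * rng.uniform(5, 10, (8, 8))[None] + 2.0
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        with pytest.warns(UserWarning, match="lowest-SD"):
            fl.background_correct(make_series(vel), fl.RoiMask(mask, 4.0))


class TestComputeFlowCurve:
    def test_single_pixel_definition(self):
        vel = np.zeros((5, 4, 4))
        vel[:, 2, 2] = 10.0
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 2] = True
        q = fl.compute_flow_curve(make_series(vel), fl.RoiMask(mask, 4.0))
        np.testing.assert_allclose(q.flow, 40.0)

    def test_parabolic_disk_closed_form(self):
        # Poiseuille profile: Q = v_max * pi * a^2 / 2 on a fine grid
        n, px = 400, 0.05
        a, v_max = 3.0, 50.0
        y = (np.arange(n) + 0.5) * px - n * px / 2
        yy, xx = np.meshgrid(y, y, indexing="ij")
        rr = (yy**2 + xx**2) / a**2
        profile = v_max * np.clip(1 - rr, 0, None)
        series = fl.VelocitySeries(profile[None].repeat(2, axis=0), 0.087, px**2, 100.0)
        q = fl.compute_flow_curve(series, fl.RoiMask(profile > 0, px**2))
        assert q.flow[0] == pytest.approx(v_max * math.pi * a**2 / 2, rel=1e-3)

    def test_zero_velocities(self):
        mask = np.ones((4, 4), dtype=bool)
        q = fl.compute_flow_curve(make_series(np.zeros((5, 4, 4))), fl.RoiMask(mask, 4.0))
        assert (q.flow == 0).all()

    def test_linearity_in_velocity(self, noisy_phantom):
        series, gt, _ = noisy_phantom
        roi = fl.RoiMask(gt["roi_mask"], 4.0)
        q1 = fl.compute_flow_curve(series, roi).flow
        doubled = make_series(2 * series.velocities)
        np.testing.assert_allclose(fl.compute_flow_curve(doubled, roi).flow, 2 * q1, rtol=1e-12)


class TestSegmentCycles:
    def test_sinusoid_cut_at_minima(self):
        dt, tc = 0.087, 0.85
        t = np.arange(500) * dt
        curve = fl.FlowCurve(t, 100 * np.sin(2 * np.pi * t / tc))
        cycles = fl.segment_cycles(curve, tc_estimate=tc)
        # one cycle between successive minima; first/last partials dropped
        assert len(cycles) == int(t[-1] / tc) - 1
        for c in cycles:
            # cut sample within half a frame of the true minimum
            assert c.flow[0] == pytest.approx(-100.0, abs=100 * (1 - math.cos(math.pi * 0.087 / tc)))

    def test_constant_curve_raises(self):
        t = np.arange(300) * 0.087
        with pytest.raises(fl.FlowError):
            fl.segment_cycles(fl.FlowCurve(t, np.full_like(t, 5.0)), tc_estimate=0.85)

    def test_modulated_sinusoid_periods_within_one_frame(self):
        dt, tc, tb = 0.087, 0.85, 4.1
        t = np.arange(500) * dt
        q = (1 + 0.1 * np.sin(2 * np.pi * t / tb)) * 100 * np.sin(2 * np.pi * t / tc)
        cycles = fl.segment_cycles(fl.FlowCurve(t, q), tc_estimate=tc)
        durations = np.array([c.times[-1] - c.times[0] for c in cycles])
        assert np.abs(durations - tc).max() <= dt + 1e-9

    def test_too_short_series_raises(self):
        t = np.arange(20) * 0.087
        with pytest.raises(fl.FlowError, match="3 cardiac cycles"):
            fl.segment_cycles(fl.FlowCurve(t, np.sin(t)), tc_estimate=0.85)


class TestBuildEnsemble:
    def test_identical_cycles_zero_sd(self):
        cycles = [sine_cycle() for _ in range(5)]
        ens = fl.build_ensemble(cycles)
        np.testing.assert_allclose(ens.sd_curve, 0.0, atol=1e-9)
        np.testing.assert_allclose(ens.loa_upper, ens.mean_curve, atol=1e-9)

    def test_scaled_cycles_sd_matches_hand_value(self):
        factors = [0.9, 1.0, 1.1]
        cycles = [sine_cycle(100 * f) for f in factors]
        ens = fl.build_ensemble(cycles)
        # pointwise sample SD = |waveform| * SD({0.9, 1, 1.1})
        base = fl.build_ensemble([sine_cycle(100.0)] * 3).mean_curve
        expected = np.abs(base) * np.std(factors, ddof=1)
        np.testing.assert_allclose(ens.sd_curve, expected, atol=1e-9)
        np.testing.assert_allclose(ens.loa_upper - ens.mean_curve,
                                   ens.mean_curve - ens.loa_lower, atol=1e-9)

    def test_loa_ordering(self, noisy_phantom):
        series, _, _ = noisy_phantom
        res = flow_pipeline(series)
        ens = res["ensemble"]
        assert (ens.loa_upper >= ens.mean_curve).all()
        assert (ens.mean_curve >= ens.loa_lower).all()

    def test_gaussian_jitter_coverage_near_95pct(self):
        rng = np.random.default_rng(42)
        cycles = [sine_cycle(100 * (1 + rng.normal(0, 0.1))) for _ in range(200)]
        ens = fl.build_ensemble(cycles)
        inside = (ens.cycles >= ens.loa_lower) & (ens.cycles <= ens.loa_upper)
        assert inside.mean() == pytest.approx(0.95, abs=0.02)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(fl.FlowError):
            fl.build_ensemble([sine_cycle(), sine_cycle()])


class TestFlowMetrics:
    def make_metrics(self, cycles, curve=None):
        ens = fl.build_ensemble(cycles)
        if curve is None:
            t = np.arange(400) * 0.087
            curve = fl.FlowCurve(t, 10 * np.sin(2 * np.pi * t / 4.1) + np.sin(2 * np.pi * t / 0.85))
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        return fl.flow_metrics(ens, curve, fl.RoiMask(mask, 4.0)), ens

    def test_pure_sine_closed_forms(self):
        m, _ = self.make_metrics([sine_cycle(100.0, n=33)] * 3)
        assert m.Qc_plus == pytest.approx(100.0, rel=0.01)
        assert m.Qc_minus == pytest.approx(100.0, rel=0.01)
        assert m.Qb == pytest.approx(0.0, abs=1e-9)
        assert m.SV == pytest.approx(100 * 0.85 / math.pi, rel=0.01)  # A·Tc/π
        assert m.Q_net == pytest.approx(0.0, abs=1e-6)

    def test_offset_shifts_qnet(self):
        m, _ = self.make_metrics([sine_cycle(100.0, n=33, offset=10.0)] * 3)
        assert m.Q_net == pytest.approx(10.0, abs=0.1)

    def test_respiratory_period_from_curve(self):
        m, _ = self.make_metrics([sine_cycle(100.0)] * 3)
        assert m.Tb == pytest.approx(4.1, rel=0.1)

    def test_sv_qnet_invariant_to_phase_rotation(self):
        cycles = [sine_cycle(100.0, n=33)] * 3
        m0, ens = self.make_metrics(cycles)
        rolled = np.roll(ens.cycles, 7, axis=1)
        ens_rolled = fl.CycleEnsemble(rolled, ens.durations)
        t = np.arange(400) * 0.087
        curve = fl.FlowCurve(t, 10 * np.sin(2 * np.pi * t / 4.1))
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        m1 = fl.flow_metrics(ens_rolled, curve, fl.RoiMask(mask, 4.0))
        assert m1.SV == pytest.approx(m0.SV, rel=1e-6)
        assert m1.Q_net == pytest.approx(m0.Q_net, rel=1e-6, abs=1e-9)

    def test_qc_qb_are_directional_averages(self, noisy_phantom):
        series, _, _ = noisy_phantom
        m = flow_pipeline(series)["metrics"]
        assert m.Qc == pytest.approx(0.5 * (m.Qc_plus + m.Qc_minus), rel=1e-12)
        assert m.Qb == pytest.approx(0.5 * (m.Qb_plus + m.Qb_minus), rel=1e-12)
        assert min(m.Qb_plus, m.Qb_minus) >= 0


class TestParameterRecovery:
    def test_study_conditions_recovered(self):
        """300 frames at 87 ms, VENC 100 mm/s, SNR 10: Tc/Qc/Q_net recovery."""
        tc_err, qc_err, qnet_err = [], [], []
        for seed in range(5):
            spec = syn.FlowSpec(noise_sd=3.4, seed=seed)
            vel, gt = syn.make_phantom_series(spec)
            res = flow_pipeline(make_series(vel))
            m = res["metrics"]
            tc_err.append(abs(m.Tc / gt["tc"] - 1))
            qc_err.append(abs(m.Qc / gt["qc"] - 1))
            # net flow of the analysed cycles: fine-integrated truth over the
            # same retained spans (breathing makes the net span-dependent)
            truth = np.mean([
                spec.true_flow(np.linspace(c.times[0], c.times[-1], 2000, endpoint=False)).mean()
                for c in res["cycles"]
            ])
            qnet_err.append(m.Q_net - truth)
        assert max(tc_err) < 0.02
        assert max(qc_err) < 0.05
        assert np.abs(qnet_err).mean() < 2.0


class TestCardiacPhaseSplit:
    def _aqueduct_cycles(self, flow_fn, tc=0.85, n_cycles=6, dt=0.017):
        cycles = []
        for k in range(n_cycles):
            t = k * tc + np.arange(0, tc + dt / 2, dt)
            cycles.append(fl.FlowCurve(t, flow_fn(t)))
        return cycles

    def test_rectified_sinusoid_systole_is_rising_half(self):
        tc = 0.85
        t = np.arange(0, 6 * tc, 0.017)
        arterial = fl.FlowCurve(t, np.abs(np.sin(np.pi * t / tc)))
        cycles = self._aqueduct_cycles(lambda tt: np.sin(2 * np.pi * tt / tc))
        ph = fl.cardiac_phase_split(arterial, cycles)
        sys_idx = ph.systole_indices()
        assert len(sys_idx) == pytest.approx(16, abs=2)  # half of 32 phases
        # onset at the steepest arterial upslope (cycle start for |sin|)
        assert ph.systole_start in (0, 1, 31)

    def test_zero_aqueduct_flow_zero_volumes(self):
        tc = 0.85
        t = np.arange(0, 6 * tc, 0.017)
        arterial = fl.FlowCurve(t, np.abs(np.sin(np.pi * t / tc)))
        cycles = self._aqueduct_cycles(lambda tt: np.zeros_like(tt))
        ph = fl.cardiac_phase_split(arterial, cycles)
        assert ph.systolic_volume == 0.0 and ph.diastolic_volume == 0.0

    def test_volumes_sum_to_net_displacement(self):
        tc = 0.85
        t = np.arange(0, 8 * tc, 0.017)
        arterial = fl.FlowCurve(t, 1 + 0.5 * np.sin(2 * np.pi * t / tc))
        cycles = self._aqueduct_cycles(lambda tt: 100 * np.sin(2 * np.pi * tt / tc) + 5)
        ph = fl.cardiac_phase_split(arterial, cycles)
        ens = fl.build_ensemble(cycles)
        q_net_vol = ens.mean_curve.mean() * ens.Tc
        assert ph.systolic_volume + ph.diastolic_volume == pytest.approx(q_net_vol, rel=1e-6)

    def test_flat_arterial_curve_raises(self):
        tc = 0.85
        t = np.arange(0, 6 * tc, 0.017)
        arterial = fl.FlowCurve(t, np.full_like(t, 3.0))
        cycles = self._aqueduct_cycles(lambda tt: np.sin(2 * np.pi * tt / tc))
        with pytest.raises(fl.FlowError):
            fl.cardiac_phase_split(arterial, cycles)

    def test_phantom_phase_boundary_within_one_sample(self):
        # arterial pulse with known steepest-upslope phase
        tc, dt = 0.85, 0.017
        t = np.arange(0, 8 * tc, dt)
        phase = (t % tc) / tc
        arterial = fl.FlowCurve(t, np.sin(2 * np.pi * phase) ** 2 * (phase < 0.5))
        cycles = self._aqueduct_cycles(lambda tt: np.sin(2 * np.pi * tt / tc), n_cycles=8, dt=dt)
        ph = fl.cardiac_phase_split(arterial, cycles)
        # steepest upslope of sin^2 on [0, 0.5) is at phase 1/8 -> index 4 of 32
        assert abs(ph.systole_start - 4) <= 1
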