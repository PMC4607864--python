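import math

import numpy as np
import pytest
from scipy.signal import lfilter

import voxmon.ibif as ib
from voxmon.ibif import (
    QParams,
    SkinParams,
    TractGeometry,
    build_model,
    cycle_measures,
    default_geometry,
    estimate_q,
    forward_simulate,
    frame_average_measures,
    h1h2_db,
    ibif_inverse,
    measure_cycles,
    segment_cycles,
    single_formant_inverse_filter,
    spl_logmfdr_regression,
    transfer_function,
)
from voxmon.signal_io import RawSignal
from voxmon.synth import (
    VoiceSpec,
    synth_acc_signal,
    synth_calibration_vowels,
    synth_glottal_flow,
)

FS = 11025.0


def nodal_oracle(model, freqs):
    """Independent ladder solution by dense nodal analysis.

    Builds the full node-admittance matrix of the T-network (series arms
    Z_a/2, shunt branches, skin branch at the sensor node, resistive lung
    termination) and solves K v = i with a unit flow source at the glottis —
    no recursion shared with the implementation under test.
    """
    rho, c, mu = ib.RHO, ib.C_SOUND, ib.MU
    out = np.zeros(len(freqs), complex)
    lengths = model.seg_lengths_cm * 1e-2
    areas = model.seg_areas_cm2 * 1e-4
    perims = 2 * np.sqrt(np.pi * areas)
    skin = model.skin
    s_patch = skin.sensing_area_cm2 * 1e-4
    nseg = len(lengths)
    for fi, f in enumerate(freqs):
        if f <= 0:
            continue
        w = 2 * np.pi * f
        # node numbering: 0 = glottal end, then one mid node and one exit
        # node per segment -> total 1 + 2*nseg nodes; ground is implicit
        nn = 1 + 2 * nseg
        K = np.zeros((nn, nn), complex)
        cur = np.zeros(nn, complex)
        cur[0] = 1.0  # unit glottal flow injected

        def stamp(a, b, z):
            y = 1.0 / z
            if a is not None:
                K[a, a] += y
            if b is not None:
                K[b, b] += y
            if a is not None and b is not None:
                K[a, b] -= y
                K[b, a] -= y

        for i in range(nseg):
            l, A, P = lengths[i], areas[i], perims[i]
            za_half = 0.5 * ((l * P / A**2) * math.sqrt(w * rho * mu / 2)
                             + 1j * w * rho * l / A)
            c_air = l * A / (rho * c**2)
            s_wall = P * l
            z_wall = (ib.WALL_RESISTANCE + 1j * w * ib.WALL_MASS
                      + ib.WALL_STIFFNESS / (1j * w)) / s_wall
            z_shunt = 1.0 / (1j * w * c_air + 1.0 / z_wall)
            n_in, n_mid, n_out = 2 * i, 2 * i + 1, 2 * i + 2
            stamp(n_in, n_mid, za_half)
            stamp(n_mid, None, z_shunt)          # shunt to ground
            stamp(n_mid, n_out, za_half)
        z_skin_spec = (skin.skin_resistance
                       + 1j * w * (skin.skin_inertance + skin.accelerometer_load_mass)
                       + skin.skin_stiffness / (1j * w))
        sensor_node = 2 * model.sensor_node
        stamp(sensor_node, None, z_skin_spec / s_patch)
        stamp(2 * nseg, None, rho * c / areas[-1])  # lung termination
        v = np.linalg.solve(K, cur)
        out[fi] = 1j * w * v[sensor_node] / z_skin_spec
    return out


class TestBuildModel:
    def test_identity_scaling(self):
        m = build_model(q=QParams())
        g = default_geometry()
        np.testing.assert_allclose(m.geometry.segment_lengths, g.segment_lengths)
        assert m.skin == ib.default_skin()

    def test_q4_doubles_series_inertance(self):
        m1 = build_model(q=QParams())
        m2 = build_model(q=QParams(q4=2.0, q5=1.0))
        la1 = np.sum(m1.seg_lengths_cm / m1.seg_areas_cm2)
        la2 = np.sum(m2.seg_lengths_cm / m2.seg_areas_cm2)
        assert la2 == pytest.approx(2 * la1, rel=1e-9)

    def test_sensor_outside_tract_rejected(self):
        with pytest.raises(ValueError, match="sensor position"):
            build_model(q=QParams(q5=5.0))

    def test_skin_scaling(self):
        m = build_model(q=QParams(1.5, 2.0, 0.5, 1.0, 1.0))
        s = ib.default_skin()
        assert m.skin.skin_inertance == pytest.approx(1.5 * s.skin_inertance)
        assert m.skin.skin_resistance == pytest.approx(2.0 * s.skin_resistance)
        assert m.skin.skin_stiffness == pytest.approx(0.5 * s.skin_stiffness)

    def test_q_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside bounds"):
            QParams(q1=20.0)


class TestTransferFunction:
    def test_matches_nodal_oracle_single_segment(self):
        geom = TractGeometry(segment_lengths=np.array([10.0]),
                             segment_areas=np.array([2.5]),
                             sensor_position_cm=5.0)
        model = build_model(geom)
        freqs = np.array([0.0, 100.0, 300.0, 800.0, 2000.0, 5000.0])
        h = transfer_function(model, freqs).response
        oracle = nodal_oracle(model, freqs)
        np.testing.assert_allclose(h[1:], oracle[1:], rtol=1e-9)

    def test_matches_nodal_oracle_default_tract(self):
        model = build_model()
        freqs = np.linspace(50, 5000, 23)
        h = transfer_function(model, freqs).response
        oracle = nodal_oracle(model, freqs)
        np.testing.assert_allclose(h, oracle, rtol=1e-9)

    def test_dc_bin_zeroed(self):
        model = build_model()
        h = transfer_function(model, np.array([0.0, 100.0])).response
        assert h[0] == 0.0
        assert h[1] != 0.0

    def test_skin_resonance_scales_sqrt_with_stiffness(self):
        """Doubling skin stiffness (q3 = 2) moves the skin branch's
        mass-spring resonance up by sqrt(2)."""

        def resonance(q3):
            skin = build_model(q=QParams(q3=q3)).skin
            m = skin.skin_inertance + skin.accelerometer_load_mass
            return math.sqrt(skin.skin_stiffness / m) / (2 * math.pi)

        assert resonance(2.0) / resonance(1.0) == pytest.approx(math.sqrt(2))

    def test_segment_count_converged(self):
        f = np.linspace(100, 3000, 10)
        h15 = transfer_function(build_model(default_geometry(15)), f).response
        h30 = transfer_function(build_model(default_geometry(30)), f).response
        ratio = np.abs(h30) / np.abs(h15)
        assert np.all(np.abs(np.log10(ratio)) < 0.2)  # < ~4 dB everywhere


class TestForwardSimulate:
    def test_zero_flow_zero_acc(self):
        model = build_model()
        acc = forward_simulate(RawSignal(np.zeros(2048), FS), model)
        np.testing.assert_allclose(acc.samples, 0.0, atol=1e-12)

    def test_linearity(self, pulse_train):
        flow, _ = pulse_train
        model = build_model()
        a1 = forward_simulate(flow, model)
        a3 = forward_simulate(RawSignal(3 * flow.samples, FS), model)
        np.testing.assert_allclose(a3.samples, 3 * a1.samples, rtol=1e-9)

    def test_sine_gain_and_phase_match_transfer_function(self):
        model = build_model()
        n = 11025  # 1 s: 200 Hz sits exactly on bin 200
        t = np.arange(n) / FS
        flow = RawSignal(np.sin(2 * np.pi * 200 * t), FS)
        acc = forward_simulate(flow, model)
        h = transfer_function(model, np.array([200.0])).response[0]
        expected = np.abs(h) * np.sin(2 * np.pi * 200 * t + np.angle(h))
        # ignore bin leakage at the edges
        np.testing.assert_allclose(acc.samples[100:-100], expected[100:-100],
                                   rtol=1e-6, atol=1e-9 * np.abs(h))


class TestInverse:
    def test_round_trip_relative_error_below_1pct(self, pulse_train):
        flow, _ = pulse_train
        model = build_model()
        rec = ibif_inverse(forward_simulate(flow, model), model)
        ref = flow.samples - flow.samples.mean()
        err = np.sqrt(np.mean((rec.samples - ref) ** 2) / np.mean(ref**2))
        assert err < 0.01

    def test_sine_amplitude_recovered(self):
        model = build_model()
        t = np.arange(11025) / FS
        flow = RawSignal(np.sin(2 * np.pi * 200 * t), FS)
        rec = ibif_inverse(forward_simulate(flow, model), model)
        assert np.ptp(rec.samples[500:-500]) == pytest.approx(2.0, rel=0.01)

    def test_mismatched_model_degrades_recovery(self, pulse_train):
        flow, _ = pulse_train
        truth = build_model()
        acc = forward_simulate(flow, truth)
        ref = flow.samples - flow.samples.mean()

        def err(model):
            rec = ibif_inverse(acc, model)
            return np.sqrt(np.mean((rec.samples - ref) ** 2) / np.mean(ref**2))

        assert err(build_model(q=QParams(q4=1.2))) > err(truth)

    def test_fs_mismatch_rejected(self):
        model = build_model()
        with pytest.raises(ValueError, match="fs"):
            estimate_q(RawSignal(np.zeros(100), 8000.0),
                       RawSignal(np.zeros(100), FS))


class TestEstimateQ:
    def test_truth_start_stays_at_truth(self):
        """With q = 1 ground truth and a noise-free signal, the optimum is
        at the start and the residual is ~0."""
        model = build_model()
        accs, flows = synth_calibration_vowels(model, duration_s=1.0)
        est = estimate_q(accs[1], flows[1], n_starts=1, seed=0)
        np.testing.assert_allclose(est.q.as_array(), 1.0, atol=0.02)
        assert est.mse < 1e-6

    def test_perturbed_q_recovered_at_20db_snr(self):
        """20% perturbations of all five Q factors are recovered within 10%
        each from the three-vowel calibration at 20 dB SNR."""
        qstar = np.array([1.2, 0.8, 1.2, 1.2, 0.8])
        model = build_model(q=QParams(*qstar))
        accs, flows = synth_calibration_vowels(model, duration_s=3.0,
                                               noise_snr_db=20.0, seed=1)
        est = estimate_q(accs, flows, seed=0)
        rel = np.abs(est.q.as_array() - qstar) / qstar
        assert np.all(rel < 0.10), rel

    def test_bound_saturation_flagged(self):
        """True q4 outside the search box: the estimate saturates the bounds
        (other factors compensate as far as they can) and the large residual
        flags the failed fit."""
        model = build_model(q=QParams(q4=1.5))
        accs, flows = synth_calibration_vowels(model, duration_s=1.0)
        est = estimate_q(accs[1], flows[1], bounds=(0.9, 1.1),
                         n_starts=2, seed=0)
        q = est.q.as_array()
        at_bound = np.isclose(q, 0.9, atol=1e-3) | np.isclose(q, 1.1, atol=1e-3)
        assert at_bound.any()
        assert est.q.q4 > 1.0  # pushed toward the true value
        assert est.mse > 1e-2  # orders of magnitude above the matched floor


class TestSingleFormantInverseFilter:
    def test_known_resonance_recovered(self):
        spec = VoiceSpec(f0_hz=150.0, duration_s=1.0, open_fraction=0.6,
                         speed_ratio=2.0)
        flow, _ = synth_glottal_flow(spec, FS)
        r = math.exp(-math.pi * 80 / FS)
        theta = 2 * math.pi * 600 / FS
        a = np.array([1.0, -2 * r * math.cos(theta), r * r])
        filtered = RawSignal(lfilter([a.sum()], a, flow.samples), FS,
                             "oral_airflow")
        out, f_res, bw = single_formant_inverse_filter(filtered)
        assert f_res == pytest.approx(600.0, rel=0.05)
        # inverse filtering reduces the resonant ripple
        hf_in = np.mean(np.diff(filtered.samples) ** 2)
        hf_out = np.mean(np.diff(out.samples) ** 2)
        assert hf_out < hf_in

    def test_unfiltered_pulse_train_near_identity(self, pulse_train):
        flow, _ = pulse_train
        out, f_res, bw = single_formant_inverse_filter(flow)
        ref = flow.samples - flow.samples.mean()
        err = np.sqrt(np.mean((out.samples - ref) ** 2) / np.mean(ref**2))
        assert err < 0.05

    def test_white_noise_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="resonance"):
            single_formant_inverse_filter(
                RawSignal(rng.standard_normal(8192), FS, "oral_airflow"))


class TestCycleSegmentation:
    def test_pulse_count_and_period(self):
        spec = VoiceSpec(f0_hz=200.0, duration_s=10.5 / 200.0,
                         open_fraction=0.6, speed_ratio=1.0)
        flow, _ = synth_glottal_flow(spec, FS)
        bounds = segment_cycles(flow, 200.0)
        periods = np.diff(bounds) / FS
        np.testing.assert_allclose(periods, 1 / 200.0, atol=1.5 / FS)

    def test_constant_flow_empty(self):
        assert segment_cycles(RawSignal(np.full(2000, 0.5), FS), 200.0).size == 0

    def test_jittered_boundaries_match_minima_oracle(self):
        rng = np.random.default_rng(9)
        fs = FS
        x = np.zeros(int(0.3 * fs))
        t0, starts = 0.0, []
        while t0 < 0.29:
            starts.append(t0)
            period = (1 + 0.02 * rng.standard_normal()) / 200.0
            n0, n1 = int(t0 * fs), min(int((t0 + 0.6 * period) * fs), len(x))
            seg = np.sin(np.pi * np.arange(n1 - n0) / max(n1 - n0, 1))
            x[n0:n1] = seg
            t0 += period
        flow = RawSignal(x, fs)
        bounds = segment_cycles(flow, 200.0)
        # oracle: brute-force minimum inside each expected period window
        for b in bounds:
            lo, hi = max(b - 10, 0), min(b + 11, len(x))
            assert x[b] <= x[lo:hi].min() + 1e-12


class TestCycleMeasures:
    @staticmethod
    def triangle_cycle(n=551, oq=0.6, sr=1.0, fs=FS):
        spec = VoiceSpec(f0_hz=fs / n, duration_s=5 * n / fs,
                         open_fraction=oq, speed_ratio=sr)
        flow, truth = synth_glottal_flow(spec, fs)
        bounds = segment_cycles(flow, fs / n)
        return flow.samples[bounds[0]:bounds[1]], truth[0]

    def test_symmetric_triangle(self):
        cyc, truth = self.triangle_cycle(oq=0.6, sr=1.0)
        m = cycle_measures(cyc, FS)
        dt = 1 / FS
        assert m.oq == pytest.approx(0.6, abs=2 * dt / m.period_s)
        assert m.sq == pytest.approx(100.0, rel=0.05)

    def test_asymmetric_triangle_closed_forms(self):
        """rise = 2 x fall: SQ = 200, MFDR = AC/t_fall, NAQ = t_fall/T."""
        cyc, truth = self.triangle_cycle(n=551, oq=0.6, sr=2.0)
        m = cycle_measures(cyc, FS)
        period = m.period_s
        t_fall = 0.6 * period / 3
        dt = 1 / FS
        assert m.sq == pytest.approx(200.0, rel=(dt / t_fall + dt / (2 * t_fall)))
        assert m.mfdr == pytest.approx(truth.ac_flow / t_fall, rel=dt / t_fall)
        assert m.naq == pytest.approx(t_fall / period, rel=0.05)

    def test_two_harmonic_h1h2(self):
        t = np.arange(4410) / FS
        x = 2.0 * np.sin(2 * np.pi * 200 * t) + 1.0 * np.sin(2 * np.pi * 400 * t)
        assert h1h2_db(x, FS, 200.0) == pytest.approx(20 * math.log10(2), abs=0.2)

    def test_degenerate_cycle_rejected(self):
        assert cycle_measures(np.zeros(100), FS) is None


class TestFrameAveraging:
    def test_identical_cycles_pass_through(self, pulse_train):
        flow, truth = pulse_train
        cycles = measure_cycles(flow, 200.0)
        frames = frame_average_measures(cycles)
        assert frames
        for fr in frames:
            assert fr.ac_flow == pytest.approx(cycles[0].ac_flow, rel=0.05)
            assert fr.oq == pytest.approx(cycles[0].oq, rel=0.05)

    def test_overlap_counts_cycles_about_twice(self, pulse_train):
        flow, _ = pulse_train
        cycles = measure_cycles(flow, 200.0)
        frames = frame_average_measures(cycles, frame_s=0.050, overlap=0.5)
        total_assigned = sum(f.n_cycles for f in frames)
        assert abs(total_assigned - 2 * len(cycles)) <= 4  # edge effects

    def test_empty_cycles_empty_frames(self):
        assert frame_average_measures([]) == []


class TestSplLogMfdrRegression:
    def test_pure_scaling_slope_one(self):
        """Scaling the flow scales SPL and MFDR by the same dB amount."""
        k = np.array([0.5, 0.8, 1.0, 1.5, 2.0, 3.0])
        mfdr = 400.0 * k
        spl = 90.0 + 20 * np.log10(k)
        slope, r = spl_logmfdr_regression(spl, mfdr)
        assert slope == pytest.approx(1.0, abs=0.02)
        assert r > 0.999

    def test_nine_db_per_doubling(self):
        doublings = np.arange(6)
        mfdr = 100.0 * 2.0**doublings
        spl = 70.0 + 9.0 * doublings
        slope, _ = spl_logmfdr_regression(spl, mfdr)
        assert slope == pytest.approx(9 / (20 * math.log10(2)), abs=0.01)

    def test_constant_mfdr_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            spl_logmfdr_regression([80, 85, 90], [300, 300, 300])
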