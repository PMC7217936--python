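"""Real-time phase forecasting: montage, filter, AR fit, forecast, triggers."""

import numpy as np
import pytest
from scipy.signal import filtfilt, firwin
from statsmodels.regression.linear_model import yule_walker as sm_yule_walker

from phasermt.containers import Recording, circ_distance, wrap_phase
from phasermt.realtime import (
    RtConfig,
    TriggerNotFound,
    ar_yule_walker,
    bandpass_fir,
    detect_trigger,
    estimate_phase_at,
    fir_attenuation_db,
    forecast,
    instantaneous_phase,
    laplacian,
    power_gate_threshold,
)
from phasermt.synth import MuSourceParams, generate_recording

FS = 5000.0


def _recording(channel_data: dict) -> Recording:
    labels = tuple(channel_data)
    data = np.vstack([channel_data[c] for c in labels])
    return Recording(data=data, fs=FS, channels=labels)


class TestLaplacian:
    def test_identical_channels_cancel(self):
        x = np.sin(np.linspace(0, 10, 500))
        rec = _recording({c: x.copy() for c in ("C3", "FC1", "FC5", "CP1", "CP5")})
        assert np.allclose(laplacian(rec, "C3"), 0.0)

    def test_identity_when_neighbors_silent(self):
        s = np.random.default_rng(0).standard_normal(300)
        chans = {"C3": s, **{c: np.zeros(300) for c in ("FC1", "FC5", "CP1", "CP5")}}
        assert np.allclose(laplacian(_recording(chans), "C3"), s)

    def test_arithmetic(self):
        chans = {"C3": np.full(10, 4.0), "FC1": np.full(10, 1.0),
                 "FC5": np.full(10, 2.0), "CP1": np.full(10, 3.0),
                 "CP5": np.full(10, 6.0)}
        assert np.allclose(laplacian(_recording(chans), "C3"), 1.0)

    def test_missing_channel_raises(self):
        rec = _recording({"C3": np.zeros(10), "FC1": np.zeros(10),
                          "FC5": np.zeros(10), "CP1": np.zeros(10)})
        with pytest.raises(KeyError):
            laplacian(rec, "C3")


class TestBandpass:
    def test_in_band_amplitude_and_phase_preserved(self):
        t = np.arange(5000) / FS
        x = np.cos(2 * np.pi * 10.0 * t)
        y = bandpass_fir(x, (8, 13), FS)
        mid = slice(1500, 3500)
        amp = (y[mid].max() - y[mid].min()) / 2
        assert abs(amp - 1.0) < 0.05
        # zero-phase: peaks coincide with the input's peaks
        i = 2500  # t = 0.5 s -> 5 full cycles -> input peak
        assert x[i] == pytest.approx(1.0)
        k = np.argmax(y[i - 50 : i + 51]) - 50
        assert abs(k) * 360.0 * 10.0 / FS < 1.0  # < 1 degree at 10 Hz

    def test_out_of_band_attenuation(self):
        # one octave above the high edge: >= 30 dB for the two-pass filter.
        # (No window-compatible FIR at 5 kHz can deliver 30 dB one octave
        # below the 8-Hz edge; the low side relies on the AR stage's
        # demeaning and the narrowband fit instead.)
        assert fir_attenuation_db(26.0, (8, 13), FS) >= 30.0
        assert fir_attenuation_db(50.0, (8, 13), FS) >= 30.0

    def test_dc_offset_attenuated_and_irrelevant_to_phase(self):
        # constant input is attenuated (not perfectly nulled: the band's
        # low edge sits a fraction of a transition width above DC) ...
        y = bandpass_fir(np.ones(3000), (8, 13), FS)
        assert np.abs(y).max() < 0.3
        # ... and a DC offset cannot change the phase estimate, because
        # the AR stage demeans its fit span
        t = np.arange(4000) / FS
        x = np.cos(2 * np.pi * 10.0 * t)
        cfg = RtConfig()
        p0, _ = estimate_phase_at(x, 3000, cfg)
        p1, _ = estimate_phase_at(x + 57.0, 3000, cfg)
        assert circ_distance(p0, p1) < np.radians(0.5)

    def test_zero_phase_time_reversal_property(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2500)
        a = bandpass_fir(x[::-1], (8, 13), FS)[::-1]
        b = bandpass_fir(x, (8, 13), FS)
        assert np.allclose(a, b, atol=1e-9)

    def test_matches_scipy_filtfilt(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(2500)
        b = firwin(625, (8, 13), pass_zero=False, fs=FS)
        ref = filtfilt(b, 1.0, x, padlen=1875)
        assert np.allclose(bandpass_fir(x, (8, 13), FS, numtaps=625), ref,
                           atol=1e-10)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            bandpass_fir(np.zeros(100), (8, 13), FS, numtaps=625)


class TestYuleWalker:
    def test_recovers_ar1(self):
        rng = np.random.default_rng(0)
        x = np.zeros(10_000)
        for i in range(1, len(x)):
            x[i] = 0.9 * x[i - 1] + rng.standard_normal()
        a = ar_yule_walker(x, 1)
        assert abs(a[0] - 0.9) < 0.02

    def test_white_noise_has_no_structure(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        a = ar_yule_walker(x, 2)
        assert np.abs(a).max() < 0.05

    def test_order30_on_fit_span_is_well_posed(self):
        t = np.arange(1860) / FS
        x = np.cos(2 * np.pi * 10 * t) + 0.1 * np.random.default_rng(2).standard_normal(1860)
        a = ar_yule_walker(x, 30)
        assert np.all(np.isfinite(a)) and len(a) == 30

    def test_matches_statsmodels_biased_variant(self):
        x = np.random.default_rng(5).standard_normal(2000)
        ours = ar_yule_walker(x, 8, ridge=0.0, method="biased")
        rho, _ = sm_yule_walker(x, order=8, method="mle")
        assert np.allclose(ours, rho, atol=1e-8)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            ar_yule_walker(np.ones(100), 4)


class TestForecast:
    def test_exact_sinusoid_recursion_continues(self):
        # AR(2) with coefficients [2 cos w, -1] reproduces a sinusoid exactly
        w = 2 * np.pi * 10.0 / FS
        coeffs = np.array([2 * np.cos(w), -1.0])
        t = np.arange(1000)
        x = np.cos(w * t)
        pred = forecast(x, coeffs, 320)
        true = np.cos(w * (1000 + np.arange(320)))
        assert np.abs(pred - true).max() < 0.01

    def test_zero_input_zero_forecast(self):
        assert np.allclose(forecast(np.zeros(100), np.array([0.5, 0.2]), 50), 0.0)

    def test_nonpositive_horizon_rejected(self):
        with pytest.raises(ValueError):
            forecast(np.zeros(100), np.array([0.5]), 0)

    def test_noiseless_mu_phase_at_segment_center(self, noiseless_recording):
        cfg = RtConfig()
        lap = laplacian(noiseless_recording, "C3")
        errs = []
        for t in range(cfg.window_samples, cfg.window_samples + 5000, 500):
            phase, _ = estimate_phase_at(lap, t, cfg)
            true = float(noiseless_recording.true_phase(t))
            errs.append(np.degrees(circ_distance(phase, true)))
        assert max(errs) < 5.0


class TestInstantaneousPhase:
    def _segment(self, center_phase):
        n = 640
        t = (np.arange(n) - n // 2) / FS
        return np.cos(2 * np.pi * 10 * t + center_phase)

    @pytest.mark.parametrize("phi,expected", [
        (0.0, 0.0),                 # central sample at a maximum
        (np.pi, -np.pi),            # central sample at a minimum (wrapped)
        (-np.pi / 2, -np.pi / 2),   # rising zero-crossing
    ])
    def test_peak_convention(self, phi, expected):
        est = instantaneous_phase(self._segment(phi))
        assert circ_distance(est, expected) < np.radians(0.5)

    def test_output_wrapped(self, rng):
        seg = rng.standard_normal(640)
        assert -np.pi <= instantaneous_phase(seg) < np.pi

    def test_all_zero_segment_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(640))


class TestDetectTrigger:
    def test_negative_peak_triggers_on_minima(self, noiseless_recording):
        cfg = RtConfig()
        lap = laplacian(noiseless_recording, "C3")
        t = cfg.window_samples
        errs = []
        for _ in range(8):
            ev = detect_trigger(lap, "negative_peak", cfg, start_sample=t)
            true = noiseless_recording.true_phase(ev.sample_index)
            errs.append(np.degrees(circ_distance(true, np.pi)))
            t = ev.sample_index + 2500
        assert max(errs) < 5.0

    def test_power_gate_blocks_everything(self, noiseless_recording):
        cfg = RtConfig(power_threshold=1e9)
        lap = laplacian(noiseless_recording, "C3")
        with pytest.raises(TriggerNotFound):
            detect_trigger(lap, "negative_peak", cfg,
                           start_sample=cfg.window_samples)

    def test_random_condition_phase_uniform(self, noiseless_recording):
        pingouin = pytest.importorskip("pingouin")
        cfg = RtConfig()
        lap = laplacian(noiseless_recording, "C3")
        rng = np.random.default_rng(0)
        t = cfg.window_samples
        phases = []
        for _ in range(50):
            ev = detect_trigger(lap, "random", cfg, start_sample=t, rng=rng)
            phases.append(float(noiseless_recording.true_phase(ev.sample_index)))
            t = ev.sample_index + 600
        _, p = pingouin.circ_rayleigh(np.asarray(phases))
        assert p > 0.01

    def test_unknown_condition_rejected(self, noiseless_recording):
        with pytest.raises(ValueError):
            detect_trigger(laplacian(noiseless_recording, "C3"), "trough",
                           RtConfig())

    def test_deterministic_given_trace_and_config(self, noiseless_recording):
        cfg = RtConfig()
        lap = laplacian(noiseless_recording, "C3")
        e1 = detect_trigger(lap, "positive_peak", cfg, start_sample=3000)
        e2 = detect_trigger(lap, "positive_peak", cfg, start_sample=3000)
        assert e1 == e2


def test_phase_error_degrades_with_snr():
    """Median absolute phase-estimate error grows as SNR falls."""
    cfg = RtConfig()
    medians = []
    for snr in (20.0, 5.0, 0.0):
        params = MuSourceParams(mu_freq=10.0, target_snr_db=snr)
        rec = generate_recording(params, duration=40.0, seed=11,
                                 channels=("C3", "FC1", "FC5", "CP1", "CP5"))
        lap = laplacian(rec, "C3")
        pos = np.random.default_rng(1).integers(cfg.window_samples, len(lap), 120)
        errs = []
        for t in pos:
            phase, _ = estimate_phase_at(lap, int(t), cfg)
            if phase is not None:
                errs.append(circ_distance(phase, float(rec.true_phase(int(t)))))
        medians.append(np.median(errs))
    assert medians[0] < medians[1] < medians[2]


def test_power_gate_threshold_orders_percentiles(snr5_recording):
    cfg = RtConfig()
    lap = laplacian(snr5_recording, "C3")
    lo = power_gate_threshold(lap[: int(30 * cfg.fs)], cfg, 25)
    hi = power_gate_threshold(lap[: int(30 * cfg.fs)], cfg, 90)
    assert 0 < lo < hi
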