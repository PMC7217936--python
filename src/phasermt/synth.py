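"""Synthetic EEG/EMG sessions and cohorts with known ground truth.

The generator emulates the study's raw material so that every downstream
stage is testable without any recorded data: a fixed-frequency
sensorimotor mu-oscillation (8-13 Hz) with exactly known analytic phase,
embedded in 1/f noise at a configurable mu-band SNR on a Laplacian
montage; an MEP responder whose probability of exceeding 50 uV follows a
cumulative Gaussian in stimulus intensity with phase-condition-specific
thresholds; and a cohort whose per-subject phase-dependency index
PHASE = (RMT_pos - RMT_neg)/RMT_rand is drawn from a bivariate normal
across hemispheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import csd, welch
from scipy.special import ndtr, ndtri

from .containers import DEFAULT_MONTAGE, LAPLACIAN_NEIGHBORS, Recording, wrap_phase
from .preprocess import fit_one_over_f
from .realtime import RtConfig, detect_trigger

CONDITIONS = ("positive_peak", "negative_peak", "random")
HEMISPHERES = ("dominant", "non_dominant")

#: Exceedance criterion for an MEP, uV peak-to-peak.
MEP_CRITERION_UV = 50.0


@dataclass
class MuSourceParams:
    """Parameters of the synthetic mu source and its 1/f background.

    ``noise_scale`` is the one-sided noise PSD at 1 Hz in uV^2/Hz; the
    background falls off as 1/f**noise_exponent.  When ``target_snr_db``
    is given the source amplitude is calibrated so the Laplacian trace's
    measured mu-band SNR (1/f-subtracted spectral peak) hits the target;
    otherwise ``mu_amp`` is used directly as the source amplitude (uV).
    """

    mu_freq: float = 10.0
    mu_amp: float = 1.0
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    target_snr_db: float | None = None
    #: Log-SD of the slow lognormal amplitude envelope (waxing/waning of
    #: the rhythm over seconds); 0 gives a constant-amplitude sinusoid.
    mod_depth: float = 0.6
    #: Bandwidth of the envelope process, Hz (well below the mu band, so
    #: the analytic phase of the modulated component stays the carrier
    #: phase).
    mod_cutoff_hz: float = 0.5

    def __post_init__(self) -> None:
        if not (8.0 <= self.mu_freq <= 13.0):
            raise ValueError("mu_freq must lie in the 8-13 Hz mu band")
        if self.mu_amp < 0 or self.noise_scale < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.target_snr_db is not None and not np.isfinite(self.target_snr_db):
            raise ValueError("target_snr_db must be finite")
        if self.mod_depth < 0 or self.mod_cutoff_hz <= 0:
            raise ValueError("invalid envelope parameters")


@dataclass
class ResponderParams:
    """Ground-truth MEP responder of one hemisphere.

    The true RMT of each phase condition is the cumulative-Gaussian
    threshold (%MSO); ``spread`` is the psychometric slope parameter.
    """

    threshold_neg: float = 53.70
    threshold_pos: float = 55.55
    threshold_rand: float | None = None  # None -> midpoint of pos/neg
    spread: float = 2.0
    mep_scale: float = MEP_CRITERION_UV
    log_spread: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_rand is None:
            # random phase averages over the cycle
            self.threshold_rand = 0.5 * (self.threshold_neg + self.threshold_pos)
        for thr in (self.threshold_neg, self.threshold_pos, self.threshold_rand):
            if not (0.0 < thr < 100.0):
                raise ValueError("thresholds must lie in (0, 100) %MSO")
        if self.spread <= 0:
            raise ValueError("spread must be positive")

    def threshold(self, condition: str) -> float:
        try:
            return {
                "negative_peak": self.threshold_neg,
                "positive_peak": self.threshold_pos,
                "random": self.threshold_rand,
            }[condition]
        except KeyError as err:
            raise ValueError(f"unknown condition {condition!r}") from err


@dataclass
class CohortParams:
    """Cohort-level distribution of the phase-dependency index PHASE.

    Defaults are the emulated study conditions: 51 subjects, PHASE means
    0.022 / 0.025 and SDs 0.025 / 0.029 for the motor-dominant and
    motor-non-dominant hemisphere, interhemispheric correlation 0.45.
    """

    n_subjects: int = 51
    phase_mean_dom: float = 0.022
    phase_mean_nondom: float = 0.025
    phase_sd_dom: float = 0.025
    phase_sd_nondom: float = 0.029
    interhemispheric_corr: float = 0.45
    rmt_rand_mean: tuple[float, float] = (54.85, 55.85)
    rmt_rand_sd: float = 8.0
    rmt_rand_interhem_corr: float = 0.8
    spread: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if abs(self.interhemispheric_corr) > 1:
            raise ValueError("|interhemispheric_corr| must be <= 1")
        if self.phase_sd_dom < 0 or self.phase_sd_nondom < 0:
            raise ValueError("phase SDs must be non-negative")


@dataclass
class SubjectTruth:
    """Ground truth for one synthetic subject: a responder per hemisphere
    plus resting mu-band features used by the exploratory analyses."""

    subject: int
    responders: dict[str, ResponderParams]
    phase_true: dict[str, float]
    snr_db: dict[str, float]
    peak_freq: dict[str, float]


# ---------------------------------------------------------------------------
# Recording synthesis
# ---------------------------------------------------------------------------

def one_over_f_noise(n: int, fs: float, exponent: float, scale: float, rng) -> np.ndarray:
    """Real 1/f**exponent noise with one-sided PSD ~ scale / f**exponent
    (uV^2/Hz), synthesised by spectral shaping of white noise."""
    if scale == 0.0 or n == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    c = np.zeros_like(freqs)
    pos = freqs > 0
    c[pos] = np.sqrt(scale * freqs[pos] ** (-exponent) * n * fs / 2.0)
    eps = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) / np.sqrt(2.0)
    spec = c * eps
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real * np.sqrt(2.0)
    return np.fft.irfft(spec, n=n)


def _mu_envelope(n: int, fs: float, depth: float, cutoff_hz: float, rng) -> np.ndarray:
    """Slow positive lognormal envelope with unit median amplitude."""
    if depth == 0.0 or n == 0:
        return np.ones(n)
    # low-pass Gaussian process with unit variance, by spectral synthesis
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.exp(-0.5 * (freqs / cutoff_hz) ** 2)
    shape[0] = 0.0
    eps = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) / np.sqrt(2)
    z = np.fft.irfft(shape * eps, n=n)
    sd = z.std()
    if sd > 0:
        z /= sd
    return np.exp(depth * z)


def _calibrate_amplitude(lap_noise: np.ndarray, fs: float, unit_mu: np.ndarray,
                         mu_freq: float, target_snr_db: float,
                         band=(8.0, 13.0)) -> float:
    """Laplacian-trace mu amplitude that yields the target mu-band SNR.

    Both the fitted 1/f background of the Laplacian noise and the Welch
    peak power of the unit-amplitude mu component (including its
    envelope) are measured with the same estimator the SNR operation
    uses, so the calibration is consistent with the measurement.
    """
    nperseg = int(round(2.0 * fs))
    freqs, psd_noise = welch(lap_noise, fs=fs, window="hann", nperseg=nperseg,
                             noverlap=nperseg // 2)
    bg = fit_one_over_f(freqs, psd_noise, exclude=band)
    bg_at_mu = np.interp(mu_freq, freqs, bg)
    _, psd_mu = welch(unit_mu, fs=fs, window="hann", nperseg=nperseg,
                      noverlap=nperseg // 2)
    near = np.abs(freqs - mu_freq) <= 1.0
    i_pk = np.argmax(psd_mu[near])
    p_unit = psd_mu[near][i_pk]
    # the composite residual at the peak bin is a^2 Pmu + 2a C + Pnoise - bg,
    # where C is the real mu-noise cross spectrum; solving the quadratic in a
    # removes both the noise's own spectral fluctuation and the cross term
    # from the calibration error
    _, cross = csd(unit_mu, lap_noise, fs=fs, window="hann", nperseg=nperseg,
                   noverlap=nperseg // 2)
    c = float(np.real(cross[near][i_pk]))
    resid_noise = psd_noise[near][i_pk] - bg[near][i_pk]
    target = 10.0 ** (target_snr_db / 10.0) * bg_at_mu
    disc = c**2 + p_unit * (target - resid_noise)
    if disc <= 0:
        return 0.0
    return float(max((-c + np.sqrt(disc)) / p_unit, 0.0))


def generate_recording(params: MuSourceParams, duration: float, fs: float = 5000.0,
                       channels=None, seed: int = 0, center: str = "C3",
                       neighbor_gain: float = 0.25) -> Recording:
    """Synthesize a multichannel EEG recording with a known mu component.

    The mu source (a sinusoid at ``mu_freq`` with random initial phase)
    projects with gain 1 onto the Laplacian centre and with
    ``neighbor_gain`` onto its four neighbours; every channel receives
    independent 1/f noise.  The injected phase is exactly recoverable via
    :meth:`Recording.true_phase`.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if channels is None:
        channels = DEFAULT_MONTAGE
    channels = tuple(channels)
    neighbors = LAPLACIAN_NEIGHBORS.get(center)
    if neighbors is None or center not in channels or any(
        nb not in channels for nb in neighbors
    ):
        raise ValueError(
            "channels must include the Laplacian centre and its four neighbours"
        )
    n = int(round(duration * fs))
    if n < int(round(0.5 * fs)):
        raise ValueError("recording must cover at least one 500-ms sliding window")

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(channels) + 2)
    rng_phase = np.random.default_rng(child[0])
    phi0 = float(rng_phase.uniform(-np.pi, np.pi))
    envelope = _mu_envelope(n, fs, params.mod_depth, params.mod_cutoff_hz,
                            np.random.default_rng(child[1]))

    noise = {
        ch: one_over_f_noise(n, fs, params.noise_exponent, params.noise_scale,
                             np.random.default_rng(child[2 + i]))
        for i, ch in enumerate(channels)
    }

    t = np.arange(n) / fs
    mu = envelope * np.cos(2.0 * np.pi * params.mu_freq * t + phi0)
    if params.target_snr_db is not None and params.noise_scale > 0:
        lap_noise = noise[center] - sum(noise[nb] for nb in neighbors) / 4.0
        lap_amp = _calibrate_amplitude(lap_noise, fs, mu, params.mu_freq,
                                       params.target_snr_db)
        amp = lap_amp / (1.0 - neighbor_gain)
    else:
        amp = params.mu_amp

    data = np.empty((len(channels), n))
    for i, ch in enumerate(channels):
        gain = 1.0 if ch == center else (neighbor_gain if ch in neighbors else 0.0)
        data[i] = gain * amp * mu + noise[ch]
    return Recording(
        data=data, fs=fs, channels=channels,
        ground_truth={"mu_freq": params.mu_freq, "phi0": phi0, "amp": amp,
                      "center": center, "neighbor_gain": neighbor_gain},
    )


# ---------------------------------------------------------------------------
# MEP responder
# ---------------------------------------------------------------------------

def mep_response(intensity: float, responder: ResponderParams, condition: str,
                 rng) -> float:
    """Draw one MEP peak-to-peak amplitude (uV) at a stimulus intensity.

    Amplitudes are lognormal around the 50-uV criterion, with the log
    location tied to the Phi-quantile of the exceedance probability so
    that P(amplitude > 50 uV) = Phi((intensity - threshold)/spread)
    holds exactly (for the default ``mep_scale`` of 50 uV).
    """
    if not (0.0 <= intensity <= 100.0):
        raise ValueError("intensity must lie in [0, 100] %MSO")
    thr = responder.threshold(condition)
    p = ndtr((intensity - thr) / responder.spread)
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    z = rng.standard_normal()
    return float(responder.mep_scale * np.exp(responder.log_spread * (z + ndtri(p))))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(params: CohortParams) -> list[SubjectTruth]:
    """Draw per-subject ground-truth responders for both hemispheres.

    True PHASE values are bivariate normal across hemispheres with the
    configured means, SDs, and correlation; the ground-truth random-phase
    threshold is the midpoint of the positive/negative-peak thresholds,
    so the condition thresholds follow from (PHASE, RMT_rand) exactly:
    neg = rand - PHASE*rand/2, pos = rand + PHASE*rand/2.
    """
    rho = params.interhemispheric_corr
    cov = np.array([
        [params.phase_sd_dom**2, rho * params.phase_sd_dom * params.phase_sd_nondom],
        [rho * params.phase_sd_dom * params.phase_sd_nondom, params.phase_sd_nondom**2],
    ])
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-12:
        raise ValueError("PHASE covariance matrix is not positive semi-definite")

    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss)
    phases = rng.multivariate_normal(
        [params.phase_mean_dom, params.phase_mean_nondom], cov,
        size=params.n_subjects, method="svd",
    )
    # interhemispherically correlated baseline excitability (RMT_rand)
    r = params.rmt_rand_interhem_corr
    shared = rng.standard_normal(params.n_subjects)
    rands = np.empty((params.n_subjects, 2))
    for h in range(2):
        own = rng.standard_normal(params.n_subjects)
        z = r * shared + np.sqrt(1.0 - r**2) * own
        rands[:, h] = np.clip(params.rmt_rand_mean[h] + params.rmt_rand_sd * z,
                              20.0, 90.0)
    # resting mu features: shared per subject with small interhemispheric scatter
    snr_base = rng.normal(10.0, 3.0, params.n_subjects)
    snr = np.clip(snr_base[:, None] + rng.normal(0.0, 1.3, (params.n_subjects, 2)),
                  5.0, 25.0)
    pf_base = rng.normal(10.5, 0.9, params.n_subjects)
    peak_freq = np.clip(pf_base[:, None] + rng.normal(0.0, 0.15, (params.n_subjects, 2)),
                        8.0, 13.0)

    seeds = [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(2 * params.n_subjects)]
    cohort = []
    for i in range(params.n_subjects):
        responders, phase_true = {}, {}
        for h, hemi in enumerate(HEMISPHERES):
            rand = float(rands[i, h])
            d = float(phases[i, h]) * rand
            neg = float(np.clip(rand - d / 2.0, 1.0, 99.0))
            pos = float(np.clip(rand + d / 2.0, 1.0, 99.0))
            responders[hemi] = ResponderParams(
                threshold_neg=neg, threshold_pos=pos, threshold_rand=rand,
                spread=params.spread, seed=seeds[2 * i + h],
            )
            phase_true[hemi] = (pos - neg) / rand
        cohort.append(SubjectTruth(
            subject=i, responders=responders, phase_true=phase_true,
            snr_db={h: float(snr[i, k]) for k, h in enumerate(HEMISPHERES)},
            peak_freq={h: float(peak_freq[i, k]) for k, h in enumerate(HEMISPHERES)},
        ))
    return cohort


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

def make_schedule(n_trials: int, rng=None, conditions=CONDITIONS) -> list[str]:
    """Pseudorandomised condition sequence in blocks of three: every
    consecutive aligned block contains each condition exactly once."""
    if n_trials % len(conditions):
        raise ValueError("n_trials must be divisible by the number of conditions")
    if rng is None:
        rng = np.random.default_rng()
    schedule: list[str] = []
    for _ in range(n_trials // len(conditions)):
        block = list(conditions)
        rng.shuffle(block)
        schedule.extend(block)
    return schedule


@dataclass
class TrialRecord:
    """One simulated stimulus with its ground truth."""

    sample: int
    condition: str
    intensity: float
    true_phase: float
    phase_estimate: float
    mep_amp: float
    eeg_contaminated: bool = False
    emg_contaminated: bool = False


@dataclass
class Session:
    """A simulated stimulation session: trigger records plus the raw
    Laplacian EEG and continuous EMG traces the offline chain consumes."""

    fs: float
    trials: list[TrialRecord]
    eeg_lap: np.ndarray
    emg: np.ndarray
    recording: Recording | None = None

    @property
    def trigger_samples(self) -> np.ndarray:
        return np.array([t.sample for t in self.trials], dtype=int)


def _mep_waveform(fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit peak-to-peak biphasic MEP waveform on 15-45 ms, with offsets."""
    t = np.arange(int(round(0.015 * fs)), int(round(0.045 * fs)))
    tau = t / fs * 1000.0  # ms after the pulse
    w = np.exp(-((tau - 25.0) ** 2) / (2 * 2.5**2)) - 0.9 * np.exp(
        -((tau - 33.0) ** 2) / (2 * 3.5**2)
    )
    return t, w / (w.max() - w.min())


def _perfect_trigger_sample(recording: Recording, target_phase: float,
                            t_min: int) -> int:
    """First sample >= t_min where the injected mu phase equals the target."""
    gt = recording.ground_truth
    f, phi0, fs = gt["mu_freq"], gt["phi0"], recording.fs
    # 2*pi*f*t/fs + phi0 = target (mod 2*pi)
    t0 = (target_phase - phi0) / (2.0 * np.pi * f) * fs
    period = fs / f
    k = np.ceil((t_min - t0) / period)
    return int(round(t0 + k * period))


def simulate_session(recording: Recording, responder: ResponderParams,
                     schedule, tracker, rt_config: RtConfig | None = None,
                     phase_mode: str = "perfect", min_isi_s: float = 2.0,
                     seed=None, emg_noise_uv: float = 3.0,
                     emg_contam_frac: float = 0.16,
                     eeg_contam_frac: float = 0.01) -> Session:
    """Run one full stimulation session on a synthetic recording.

    For each scheduled condition a trigger is placed (``phase_mode``
    'perfect': analytically at the ground-truth target phase; 'realtime':
    by the forecasting detector on the Laplacian trace), the tracker
    supplies the stimulus intensity, the responder draws the MEP
    amplitude, and the EMG trace receives the embedded MEP.  Consecutive
    triggers are at least ``min_isi_s`` seconds apart.

    Default contamination fractions emulate the study's offline discard
    bookkeeping: ~16% of trials receive an EMG pre-innervation burst and
    ~1% an EEG baseline artifact (inserted after trigger placement), so
    the downstream rejection stages discard ~17% in total.
    """
    if phase_mode not in ("perfect", "realtime"):
        raise ValueError("phase_mode must be 'perfect' or 'realtime'")
    if rt_config is None:
        rt_config = RtConfig(fs=recording.fs)
    if recording.ground_truth is None:
        raise ValueError("simulate_session needs a recording with ground truth")
    schedule = list(schedule)
    fs = recording.fs
    isi = int(round(min_isi_s * fs))
    needed = len(schedule) * isi + rt_config.window_samples + int(fs)
    if recording.n_samples < needed:
        raise ValueError(
            f"recording too short: {recording.n_samples} samples, "
            f"~{needed} needed for {len(schedule)} triggers"
        )
    from .realtime import laplacian

    center = recording.ground_truth["center"]
    lap = laplacian(recording, center)
    rng = np.random.default_rng(seed if seed is not None else responder.seed)
    rng_rt = np.random.default_rng(rng.integers(2**31))

    trials: list[TrialRecord] = []
    # leave 2 s of history before the first stimulus so offline epoching
    # (up to 1-s pre-pulse windows) never runs off the trace start
    t_min = max(rt_config.window_samples, int(round(2.0 * fs)))
    for condition in schedule:
        if phase_mode == "perfect":
            if condition == "random":
                target = float(rng.uniform(-np.pi, np.pi))
            else:
                target = {"positive_peak": 0.0, "negative_peak": np.pi}[condition]
            sample = _perfect_trigger_sample(recording, target, t_min)
            phase_est = float(recording.true_phase(sample))
        else:
            ev = detect_trigger(lap, condition, rt_config, start_sample=t_min,
                                rng=rng_rt)
            sample, phase_est = ev.sample_index, ev.phase_estimate
        true_phase = float(recording.true_phase(sample))
        intensity = tracker.next_intensity(condition)
        amp = mep_response(intensity, responder, condition, rng)
        tracker.update(condition, intensity, amp > MEP_CRITERION_UV)
        trials.append(TrialRecord(
            sample=sample, condition=condition, intensity=intensity,
            true_phase=true_phase, phase_estimate=phase_est, mep_amp=amp,
        ))
        t_min = sample + isi

    # EMG trace: baseline noise + embedded MEPs + pre-innervation bursts
    n = recording.n_samples
    emg = rng.normal(0.0, emg_noise_uv, n)
    t_off, w = _mep_waveform(fs)
    burst_len = int(round(0.2 * fs))
    eeg_lap = lap.copy()
    for tr in trials:
        idx = tr.sample + t_off
        idx = idx[idx < n]
        emg[idx] += tr.mep_amp * w[: len(idx)]
        if rng.uniform() < emg_contam_frac:
            tr.emg_contaminated = True
            sl = slice(max(tr.sample - burst_len, 0), tr.sample)
            emg[sl] += rng.normal(0.0, 12.0 * emg_noise_uv, sl.stop - sl.start)
        if rng.uniform() < eeg_contam_frac:
            tr.eeg_contaminated = True
            spike_at = tr.sample - int(round(0.3 * fs))
            scale = 20.0 * (np.abs(eeg_lap).mean() + 1.0)
            eeg_lap[spike_at : spike_at + int(0.02 * fs)] += scale
    return Session(fs=fs, trials=trials, eeg_lap=eeg_lap, emg=emg,
                   recording=recording)
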