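"""End-to-end study orchestration: simulate a cohort, estimate RMTs per
phase condition and hemisphere, and run the cohort statistics.

Two simulation depths are available.  ``mode='tracking'`` runs the
responder/tracker loop directly (no EEG synthesis): fast, and exact with
respect to the psychometric ground truth.  ``mode='signal'`` synthesises
EEG/EMG, places triggers by ground-truth phase ('perfect') or with the
real-time forecasting detector ('realtime'), runs the full offline
preprocessing chain, and fits the RMT posteriors from the measured MEP
amplitudes of the accepted trials; it is intended for small cohorts and
validation runs.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import Recording
from .preprocess import (
    epoch_and_baseline_eeg,
    mad_threshold,
    mep_amplitude,
    prestim_mu_power,
    preprocess_emg,
    reject_eeg_trials,
    reject_emg_trials,
    rejection_summary,
    resting_snr,
)
from .realtime import RtConfig
from .rmt import (
    ThresholdGrid,
    likelihood_surface,
    prob_pos_exceeds_neg,
    rmt_posterior,
    run_threshold_session,
    ThresholdTracker,
)
from .stats import CohortResult, analyze_cohort, render_report
from .synth import (
    CohortParams,
    HEMISPHERES,
    MEP_CRITERION_UV,
    MuSourceParams,
    SubjectTruth,
    generate_cohort,
    generate_recording,
    make_schedule,
    simulate_session,
)

_COND_SHORT = {"negative_peak": "neg", "positive_peak": "pos", "random": "rand"}


@dataclass
class PipelineConfig:
    """Declarative configuration of a full study run.

    A run is reproducible from this object plus nothing else: every
    random draw derives from ``seed``.
    """

    seed: int = 0
    n_subjects: int = 51
    n_trials_per_condition: int = 100
    mode: str = "tracking"           # 'tracking' | 'signal'
    phase_mode: str = "perfect"      # trigger placement in 'signal' mode
    start_intensity: float = 50.0
    cohort: CohortParams = field(default_factory=CohortParams)
    mu: MuSourceParams = field(default_factory=lambda: MuSourceParams(target_snr_db=10.0))
    rt: RtConfig = field(default_factory=RtConfig)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("tracking", "signal"):
            raise ValueError("mode must be 'tracking' or 'signal'")
        self.cohort = dataclasses.replace(
            self.cohort, n_subjects=self.n_subjects, seed=self.seed
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_jsonable(dataclasses.asdict(self))))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, klass in (("cohort", CohortParams), ("mu", MuSourceParams),
                           ("rt", RtConfig)):
            if key in raw and isinstance(raw[key], dict):
                if key == "rt":
                    raw[key].setdefault("band", (8.0, 13.0))
                    raw[key]["band"] = tuple(raw[key]["band"])
                if key == "cohort" and "rmt_rand_mean" in raw[key]:
                    raw[key]["rmt_rand_mean"] = tuple(raw[key]["rmt_rand_mean"])
                raw[key] = klass(**raw[key])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def process_session(session, prestim_power: bool = True,
                    eeg_threshold_k: float = 5.0,
                    emg_threshold_k: float = 5.0) -> pd.DataFrame:
    """Offline chain on one simulated session: epoch, reject, measure.

    Returns the per-trial table (condition, intensity, accept flags,
    measured MEP amplitude, pre-stimulus mu power).
    """
    fs = session.fs
    trig = session.trigger_samples
    eeg_epochs = epoch_and_baseline_eeg(session.eeg_lap, trig, fs)
    emg_epochs = preprocess_emg(session.emg, trig, fs)
    eeg_thr = mad_threshold(eeg_epochs, k=eeg_threshold_k, window_ms=(-600.0, 0.0))
    emg_thr = mad_threshold(emg_epochs, k=emg_threshold_k, window_ms=(-200.0, 0.0))
    eeg_ok = reject_eeg_trials(eeg_epochs, eeg_thr)
    emg_ok = reject_emg_trials(emg_epochs, emg_thr)
    rows = []
    for i, tr in enumerate(session.trials):
        accepted = bool(eeg_ok[i] and emg_ok[i])
        amp = mep_amplitude(emg_epochs[i])
        power = (
            prestim_mu_power(eeg_epochs[i]) if (prestim_power and accepted) else np.nan
        )
        rows.append({
            "trial": i, "condition": tr.condition, "intensity": tr.intensity,
            "true_phase": tr.true_phase, "phase_estimate": tr.phase_estimate,
            "mep_amp": amp, "mep_amp_true": tr.mep_amp,
            "eeg_accepted": bool(eeg_ok[i]), "emg_accepted": bool(emg_ok[i]),
            "accepted": accepted, "prestim_mu_power": power,
        })
    df = pd.DataFrame(rows)
    df.attrs["rejections"] = rejection_summary(eeg_ok, emg_ok)
    return df


def _fit_condition_posteriors(trial_df: pd.DataFrame, grid: ThresholdGrid):
    posteriors = {}
    for cond, sub in trial_df[trial_df["accepted"]].groupby("condition"):
        trials = list(zip(sub["intensity"], sub["mep_amp"] > MEP_CRITERION_UV))
        posteriors[cond] = rmt_posterior(likelihood_surface(trials, grid))
    return posteriors


def _tracking_hemisphere(truth: SubjectTruth, hemi: str, config: PipelineConfig,
                         rng) -> dict:
    responder = truth.responders[hemi]
    schedule = make_schedule(3 * config.n_trials_per_condition, rng)
    _, posteriors = run_threshold_session(
        responder, schedule, start_intensity=config.start_intensity,
        rng=rng,
    )
    return _hemisphere_row(posteriors, truth, hemi)


def _signal_hemisphere(truth: SubjectTruth, hemi: str, config: PipelineConfig,
                       rng) -> dict:
    responder = truth.responders[hemi]
    n_trials = 3 * config.n_trials_per_condition
    center = "C3" if hemi == "dominant" else "C4"
    mu = dataclasses.replace(config.mu, mu_freq=truth.peak_freq[hemi],
                             target_snr_db=truth.snr_db[hemi])
    duration = n_trials * 2.2 + 4.0
    rec = generate_recording(mu, duration, fs=config.rt.fs, seed=responder.seed,
                             center=center)
    schedule = make_schedule(n_trials, rng)
    tracker = ThresholdTracker(start_intensity=config.start_intensity)
    session = simulate_session(rec, responder, schedule, tracker,
                               rt_config=config.rt, phase_mode=config.phase_mode,
                               seed=responder.seed)
    trial_df = process_session(session, prestim_power=False)
    posteriors = _fit_condition_posteriors(trial_df, ThresholdGrid())
    row = _hemisphere_row(posteriors, truth, hemi)
    from .realtime import laplacian

    summary = resting_snr(laplacian(rec, center), rec.fs)
    row[f"snr_db_{hemi}"] = summary.snr_db
    row[f"peak_freq_{hemi}"] = summary.peak_freq
    row[f"discard_fraction_{hemi}"] = trial_df.attrs["rejections"]["discard_fraction"]
    return row


def _hemisphere_row(posteriors, truth: SubjectTruth, hemi: str) -> dict:
    row = {}
    for cond, short in _COND_SHORT.items():
        row[f"rmt_{short}_{hemi}"] = posteriors[cond].rmt_mode
    row[f"p_pos_gt_neg_{hemi}"] = prob_pos_exceeds_neg(
        posteriors["positive_peak"], posteriors["negative_peak"]
    )
    row[f"snr_db_{hemi}"] = truth.snr_db[hemi]
    row[f"peak_freq_{hemi}"] = truth.peak_freq[hemi]
    return row


def run_study(config: PipelineConfig):
    """Run the full study simulation and analysis.

    Returns ``(CohortResult, subjects_df)``; when ``config.out_dir`` is
    set, also writes ``subjects.csv``, ``report.txt``,
    ``cohort_stats.json``, ``config.yaml`` and ``runlog.json``.
    Deterministic given ``config.seed``: rerunning with the same config
    reproduces the tables byte for byte.
    """
    cohort = generate_cohort(config.cohort)
    ss = np.random.SeedSequence([config.seed, 2**16 + 1])
    children = ss.spawn(len(cohort) * len(HEMISPHERES))
    rows = []
    for i, truth in enumerate(cohort):
        row: dict = {"subject": truth.subject}
        # hemisphere order fixed: dominant first, as in the emulated protocol
        for h, hemi in enumerate(HEMISPHERES):
            rng = np.random.default_rng(children[i * len(HEMISPHERES) + h])
            try:
                if config.mode == "tracking":
                    row.update(_tracking_hemisphere(truth, hemi, config, rng))
                else:
                    row.update(_signal_hemisphere(truth, hemi, config, rng))
            except Exception as err:
                raise RuntimeError(
                    f"stage '{config.mode}-session' failed for subject "
                    f"{truth.subject}, hemisphere {hemi}: {err}"
                ) from err
            row[f"phase_true_{hemi}"] = truth.phase_true[hemi]
        rows.append(row)
    df = pd.DataFrame(rows)
    # a single-subject run yields only the per-subject table
    result = analyze_cohort(df) if len(df) >= 2 else None

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "subjects.csv", index=False, float_format="%.6g")
        if result is not None:
            (out / "report.txt").write_text(render_report(result) + "\n")
            (out / "cohort_stats.json").write_text(
                json.dumps(_jsonable(result), indent=2, default=str)
            )
        config.to_yaml(out / "config.yaml")
        from . import __version__

        (out / "runlog.json").write_text(json.dumps({
            "phasermt_version": __version__,
            "numpy_version": np.__version__,
            "python_version": platform.python_version(),
            "seed": config.seed,
            "mode": config.mode,
            "n_subjects": config.n_subjects,
            "n_trials_per_condition": config.n_trials_per_condition,
            "start_intensity": config.start_intensity,
        }, indent=2))
    return result, df
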