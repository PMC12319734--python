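"""Synthetic dual-platform MEG cohorts with subject-stable response signatures.

Each subject carries a parameter set — bilateral sensory source positions,
beta-band peak frequency and bandwidth, event-related desynchronization
(ERD) depth, a per-stimulus rebound profile, evoked-response amplitude and
latency, and an attentional modulation depth — that acts as that subject's
"neural fingerprint". The same parameters (up to small run-level jitter)
drive all four sessions (2 OPM runs + 2 SQUID runs), so a faithful analysis
pipeline should recover the subject's identity from any pair of sessions.

The source model per hemisphere is a small dipole cluster whose moment is

    m(t) = A_beta * env(t) * carrier(t) + evoked(t)    [nAm]

where ``carrier`` is band-limited Gaussian noise at the subject's beta peak
with unit mean Hilbert envelope, ``env`` encodes the ERD dips, post-stimulus
rebounds and the attention-side tonic suppression, and ``evoked`` is a
biphasic pulse at each stimulus onset and offset. Sensor data are the lead
field projection of the sources plus white sensor noise at the platform
noise floor (15 fT/√Hz OPM, 5 fT/√Hz SQUID), optionally with a spatially
uniform interference field and a reference-correlated drift for testing the
interference-suppression steps.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import next_fast_len

from .paradigm import (
    TrialSchedule,
    generate_schedule,
    schedule_to_events,
)
from .geometry import (
    LeadField,
    SensorArray,
    KIND_GRAD,
    KIND_REF,
)

__all__ = [
    "SubjectFingerprintParams",
    "SourceSet",
    "Recording",
    "sample_cohort_params",
    "perturb_for_run",
    "simulate_sources",
    "project_and_noise",
    "simulate_dataset",
    "generate_cohort",
]

DEFAULT_LEAD_IN_S = 2.0

# cohort-mean parameter values; spreads are scaled by between_subject_scale
_POS_LEFT = np.array([-0.042, 0.010, 0.060])
_POS_RIGHT = np.array([0.042, 0.010, 0.060])


@dataclass
class SubjectFingerprintParams:
    """Subject-level generative parameters (the planted fingerprint)."""

    pos_left: np.ndarray
    pos_right: np.ndarray
    moment_angle_left: float  # rad, in the tangential plane
    moment_angle_right: float
    extent_sigma_m: float  # spatial extent of the beta-modulated patch
    beta_peak_hz: float
    beta_bandwidth_hz: float
    beta_amp_nAm: float  # baseline oscillatory envelope amplitude
    erd_depth: float  # fractional envelope drop during stimulation, (0, 1]
    rebound_amps: np.ndarray  # fractional rise above baseline per stimulus 1..5
    evoked_amp_nAm: float
    evoked_latency_s: float
    evoked_width_s: float
    attention_depth: float  # fractional contralateral beta drop after the cue
    run_jitter_scale: float

    def validate(self) -> None:
        if not (0.0 < self.erd_depth <= 1.0):
            raise ValueError("erd_depth must lie in (0, 1]")
        if np.any(self.rebound_amps < 0):
            raise ValueError("rebound amplitudes must be >= 0")
        if not (13.0 <= self.beta_peak_hz <= 30.0):
            raise ValueError("beta peak must lie in [13, 30] Hz")


@dataclass
class SourceSet:
    """Ground-truth dipole clusters with shared moment timecourses."""

    positions: list[np.ndarray]  # per source: (n_dipoles, 3)
    weights: list[np.ndarray]  # per source: (n_dipoles,)
    moment_dirs: list[np.ndarray]  # per source: (3,)
    moments_nAm: list[np.ndarray]  # per source: (n_samples,)
    envelopes: list[np.ndarray]  # planted modulation env(t), dimensionless
    rate_hz: float
    lead_in_s: float
    schedule: TrialSchedule

    @property
    def n_samples(self) -> int:
        return len(self.moments_nAm[0])


@dataclass
class Recording:
    """One session of continuous sensor data in fT (gradient fT for SQUIDs)."""

    platform: str
    subject: str
    run: int
    data: np.ndarray  # (n_channels, n_samples) float32
    sampling_rate_hz: float
    events: pd.DataFrame
    array: SensorArray
    lead_in_s: float = DEFAULT_LEAD_IN_S
    schedule: TrialSchedule | None = None

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if len(self.events) and int(self.events["sample"].max()) >= self.n_samples:
            raise ValueError("event sample beyond record length")


def _tangential_dir(pos: np.ndarray, angle: float) -> np.ndarray:
    radial = pos / np.linalg.norm(pos)
    ref = np.array([0.0, 0.0, 1.0]) if abs(radial[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t1 = np.cross(ref, radial)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(radial, t1)
    return np.cos(angle) * t1 + np.sin(angle) * t2


def sample_cohort_params(
    n_subjects: int,
    seed: int | np.random.Generator = 0,
    between_subject_scale: float = 1.0,
    run_jitter_scale: float = 0.05,
) -> list[SubjectFingerprintParams]:
    """Draw one fingerprint parameter set per subject.

    ``between_subject_scale`` multiplies every between-subject spread around
    the cohort mean: 1 reproduces the default heterogeneous cohort, 0 makes
    all subjects statistically identical (identification then falls to
    chance). ``run_jitter_scale`` is stored on the parameters and applied by
    :func:`perturb_for_run` as a fractional session-to-session wobble.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    s = float(between_subject_scale)
    out = []
    for _ in range(n_subjects):
        pos_l = _POS_LEFT + s * rng.normal(0.0, 0.005, 3)
        pos_r = _POS_RIGHT + s * rng.normal(0.0, 0.005, 3)
        for p in (pos_l, pos_r):  # keep sources inside the source sphere
            n = np.linalg.norm(p)
            if n > 0.075:
                p *= 0.075 / n
        rebound = 0.4 + s * rng.uniform(-0.15, 0.25) + s * rng.uniform(-0.05, 0.1) * np.arange(5)
        params = SubjectFingerprintParams(
            pos_left=pos_l,
            pos_right=pos_r,
            moment_angle_left=s * rng.uniform(-0.6, 0.6),
            moment_angle_right=s * rng.uniform(-0.6, 0.6),
            extent_sigma_m=0.008 + s * rng.uniform(-0.003, 0.005),
            beta_peak_hz=float(np.clip(22.0 + s * rng.uniform(-6.0, 6.0), 13.0, 30.0)),
            beta_bandwidth_hz=4.0 + s * rng.uniform(-1.0, 1.0),
            beta_amp_nAm=8.0 * float(np.exp(s * rng.normal(0.0, 0.2))),
            erd_depth=float(np.clip(0.55 + s * rng.uniform(-0.2, 0.2), 0.05, 1.0)),
            rebound_amps=np.clip(rebound, 0.0, None),
            evoked_amp_nAm=15.0 * float(np.exp(s * rng.normal(0.0, 0.25))),
            evoked_latency_s=0.05 + s * rng.normal(0.0, 0.008),
            evoked_width_s=float(np.clip(0.012 + s * rng.uniform(-0.003, 0.003), 0.005, 0.03)),
            attention_depth=float(np.clip(0.2 + s * rng.uniform(-0.1, 0.1), 0.0, 0.9)),
            run_jitter_scale=run_jitter_scale,
        )
        params.validate()
        out.append(params)
    return out


def perturb_for_run(
    params: SubjectFingerprintParams, rng: np.random.Generator
) -> SubjectFingerprintParams:
    """Session-level copy of ``params`` with multiplicative amplitude jitter.

    Positions, peak frequency and moment orientation are treated as stable
    anatomy/physiology and left untouched; response amplitudes and depths
    wobble by ``run_jitter_scale`` fractionally between sessions.
    """
    j = params.run_jitter_scale

    def wobble(x):
        return x * float(np.exp(rng.normal(0.0, j)))

    return SubjectFingerprintParams(
        pos_left=params.pos_left.copy(),
        pos_right=params.pos_right.copy(),
        moment_angle_left=params.moment_angle_left,
        moment_angle_right=params.moment_angle_right,
        extent_sigma_m=params.extent_sigma_m,
        beta_peak_hz=params.beta_peak_hz,
        beta_bandwidth_hz=params.beta_bandwidth_hz,
        beta_amp_nAm=wobble(params.beta_amp_nAm),
        erd_depth=float(np.clip(wobble(params.erd_depth), 0.01, 1.0)),
        rebound_amps=np.clip(params.rebound_amps * np.exp(rng.normal(0.0, j, 5)), 0.0, None),
        evoked_amp_nAm=wobble(params.evoked_amp_nAm),
        evoked_latency_s=params.evoked_latency_s + rng.normal(0.0, j * 0.02),
        evoked_width_s=params.evoked_width_s,
        attention_depth=float(np.clip(wobble(params.attention_depth), 0.0, 0.9)),
        run_jitter_scale=j,
    )


def _smooth_box(t: np.ndarray, start: float, stop: float, ramp: float) -> np.ndarray:
    """1 inside [start, stop], raised-cosine ramps of width ``ramp`` outside."""
    up = np.clip((t - (start - ramp)) / ramp, 0.0, 1.0)
    down = np.clip(((stop + ramp) - t) / ramp, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))


def _trial_envelope_template(
    params: SubjectFingerprintParams, timing, rate_hz: float
) -> np.ndarray:
    """Within-trial envelope modulation (ERD dips + rebound bumps), len = trial."""
    n = int(round(timing.trial_duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    env = np.ones(n)
    for k, onset in enumerate(timing.stimulus_onsets_s):
        # ERD: full depth over [onset+0.2, onset+0.5], 50 ms cosine ramps
        env -= params.erd_depth * _smooth_box(t, onset + 0.2, onset + 0.5, 0.05)
        # rebound: Gaussian bump in the late window, centre onset+0.9 s
        env += params.rebound_amps[k] * np.exp(-0.5 * ((t - (onset + 0.9)) / 0.12) ** 2)
    return np.clip(env, 0.0, None)


def _evoked_template(params: SubjectFingerprintParams, rate_hz: float, stim_dur: float) -> np.ndarray:
    """Biphasic evoked transient with onset and (smaller) offset responses."""
    sigma = params.evoked_width_s
    t = np.arange(0.0, stim_dur + 0.25, 1.0 / rate_hz)

    def pulse(centre, amp):
        return amp * (
            np.exp(-0.5 * ((t - centre) / sigma) ** 2)
            - 0.6 * np.exp(-0.5 * ((t - centre - 2.2 * sigma) / (1.4 * sigma)) ** 2)
        )

    tau = params.evoked_latency_s
    return pulse(tau, params.evoked_amp_nAm) + pulse(stim_dur + tau, 0.6 * params.evoked_amp_nAm)


def _beta_carrier(n: int, rate_hz: float, peak: float, bw: float, rng) -> np.ndarray:
    """Band-limited Gaussian noise with unit mean Hilbert envelope."""
    x = rng.standard_normal(n)
    lo, hi = peak - bw / 2.0, peak + bw / 2.0
    numtaps = int(round(3.0 * rate_hz / bw)) | 1
    taps = signal.firwin(numtaps, [lo, hi], fs=rate_hz, pass_zero=False)
    x = signal.fftconvolve(x, taps, mode="same")
    env = np.abs(signal.hilbert(x, N=next_fast_len(n))[:n])
    return x / env.mean()


def simulate_sources(
    params: SubjectFingerprintParams,
    schedule: TrialSchedule,
    rate_hz: float,
    seed: int | np.random.Generator = 0,
    lead_in_s: float = DEFAULT_LEAD_IN_S,
    noise_free_envelope: bool = False,
) -> SourceSet:
    """Synthesise the bilateral dipole moment timecourses for one session.

    Each hemisphere's source is a 3-dipole cluster (centre plus two flankers
    at ±``extent_sigma_m`` along a tangential direction, weights
    0.5/0.25/0.25) sharing one moment timecourse. With
    ``noise_free_envelope`` the stochastic carrier is replaced by a pure
    sinusoid at the beta peak, which makes the planted envelope directly
    readable from the Hilbert envelope (used by oracle tests).
    """
    if rate_hz < 150:
        raise ValueError("rate_hz must be >= 150 Hz to carry 1-100 Hz content")
    rng = np.random.default_rng(seed)
    timing = schedule.timing
    # +1 so the final trial_end event falls on the last stored sample
    n = int(round((lead_in_s + schedule.total_duration_s) * rate_hz)) + 1
    t = np.arange(n) / rate_hz

    template = _trial_envelope_template(params, timing, rate_hz)
    evoked_tpl = _evoked_template(params, rate_hz, timing.stimulus_duration_s)

    positions, weights, dirs, moments, envs = [], [], [], [], []
    for side, pos, angle in (
        ("left", params.pos_left, params.moment_angle_left),
        ("right", params.pos_right, params.moment_angle_right),
    ):
        env = np.ones(n)
        evoked = np.zeros(n)
        for i, trial in enumerate(schedule.trials):
            i0 = int(round((lead_in_s + schedule.trial_start_s(i)) * rate_hz))
            seg = min(len(template), n - i0)
            env[i0 : i0 + seg] *= template[:seg]
            # tonic contralateral suppression around the cue end
            contralateral = (side == "left") == (trial.cue_side == "right")
            if contralateral and params.attention_depth > 0:
                t0 = lead_in_s + schedule.trial_start_s(i)
                a0, a1 = max(0.0, t0 - 1.1), t0 + 1.3
                j0, j1 = int(a0 * rate_hz), min(n, int(a1 * rate_hz) + 1)
                env[j0:j1] *= 1.0 - params.attention_depth * _smooth_box(
                    t[j0:j1], t0 - 0.8, t0 + 1.0, 0.2
                )
            for onset in trial.stimulus_onsets_s:
                k0 = int(round((lead_in_s + schedule.trial_start_s(i) + onset) * rate_hz))
                seg = min(len(evoked_tpl), n - k0)
                if seg > 0:
                    evoked[k0 : k0 + seg] += evoked_tpl[:seg]
        if noise_free_envelope:
            carrier = np.sin(2 * np.pi * params.beta_peak_hz * t)
        else:
            carrier = _beta_carrier(n, rate_hz, params.beta_peak_hz, params.beta_bandwidth_hz, rng)
        moment = params.beta_amp_nAm * env * carrier + evoked

        radial = pos / np.linalg.norm(pos)
        ref = np.array([0.0, 0.0, 1.0]) if abs(radial[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        t1 = np.cross(ref, radial)
        t1 /= np.linalg.norm(t1)
        cluster = np.stack([pos, pos + params.extent_sigma_m * t1, pos - params.extent_sigma_m * t1])
        positions.append(cluster)
        weights.append(np.array([0.5, 0.25, 0.25]))
        dirs.append(_tangential_dir(pos, angle))
        moments.append(moment)
        envs.append(env)

    return SourceSet(positions, weights, dirs, moments, envs, rate_hz, lead_in_s, schedule)


def project_and_noise(
    sources: SourceSet,
    leadfield: LeadField,
    array: SensorArray,
    seed: int | np.random.Generator = 0,
    subject: str = "sub-01",
    run: int = 1,
    noise_floor: np.ndarray | None = None,
    uniform_interference_fT: float = 0.0,
    ref_drift_fT: float = 0.0,
) -> Recording:
    """Project source moments through the lead field and add sensor noise.

    Noise is white with per-sample standard deviation
    ``floor_fT_sqrtHz * sqrt(rate / 2)``. Optional extras: a spatially
    uniform interference field (seen by magnetometers in proportion to
    orientation, rejected exactly by coaxial gradiometers) and a slow drift
    common to reference and scalp channels (for the reference-regression
    step).
    """
    if abs(sources.rate_hz - array.sampling_rate_hz) > 1e-9:
        raise ValueError("source and array sampling rates differ")
    rng = np.random.default_rng(seed)
    n_ch, n = array.n_channels, sources.n_samples
    data = np.zeros((n_ch, n), dtype=np.float32)

    for cluster, w, direction, moment in zip(
        sources.positions, sources.weights, sources.moment_dirs, sources.moments_nAm
    ):
        gain = np.zeros(n_ch)
        for pos, wk in zip(cluster, w):
            gain += wk * leadfield.gain_for(pos, direction)
        data += gain.astype(np.float32)[:, None] * moment.astype(np.float32)[None, :]

    floor = array.noise_floor if noise_floor is None else np.asarray(noise_floor, float)
    if np.any(floor > 0):
        sigma = (floor * np.sqrt(array.sampling_rate_hz / 2.0)).astype(np.float32)
        data += sigma[:, None] * rng.standard_normal((n_ch, n)).astype(np.float32)

    if uniform_interference_fT > 0:
        b = _slow_noise(rng, 3, n, array.sampling_rate_hz) * uniform_interference_fT
        gains = array.orientations.copy()
        gains[[k == KIND_GRAD for k in array.kinds]] = 0.0  # gradiometers reject uniform fields
        data += (gains @ b).astype(np.float32)

    if ref_drift_fT > 0:
        g = _slow_noise(rng, 1, n, array.sampling_rate_hz)[0] * ref_drift_fT
        is_ref = np.array([k == KIND_REF for k in array.kinds])
        coup = rng.uniform(0.5, 1.5, n_ch)
        coup[~is_ref] *= 0.3  # scalp channels see an attenuated version
        data += np.outer(coup, g).astype(np.float32)

    events = schedule_to_events(sources.schedule, array.sampling_rate_hz)
    shift = int(round(sources.lead_in_s * array.sampling_rate_hz))
    events = events.assign(
        onset=events["onset"] + sources.lead_in_s, sample=events["sample"] + shift
    )
    rec = Recording(
        platform=array.platform,
        subject=subject,
        run=run,
        data=data,
        sampling_rate_hz=array.sampling_rate_hz,
        events=events,
        array=array,
        lead_in_s=sources.lead_in_s,
        schedule=sources.schedule,
    )
    rec.validate()
    return rec


def _slow_noise(rng, n_rows: int, n: int, rate_hz: float) -> np.ndarray:
    """Unit-RMS low-frequency (<2 Hz) Gaussian noise rows."""
    x = rng.standard_normal((n_rows, n))
    sos = signal.butter(4, 2.0, btype="low", fs=rate_hz, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=-1)
    return x / np.sqrt(np.mean(x**2, axis=-1, keepdims=True))


def simulate_dataset(
    params: SubjectFingerprintParams,
    array: SensorArray,
    leadfield: LeadField,
    n_trials: int,
    subject: str,
    run: int,
    seed: int | np.random.Generator,
    **noise_kwargs,
) -> Recording:
    """One session: seeded schedule + run-jittered params + projection + noise."""
    rng = np.random.default_rng(seed)
    schedule = generate_schedule(n_trials, rng)
    run_params = perturb_for_run(params, rng)
    sources = simulate_sources(run_params, schedule, array.sampling_rate_hz, rng)
    return project_and_noise(
        sources, leadfield, array, rng, subject=subject, run=run, **noise_kwargs
    )


def generate_cohort(
    out_dir: str | Path,
    n_subjects: int = 15,
    runs_per_platform: int = 2,
    n_trials: int = 80,
    seed: int = 0,
    arrays: dict[str, SensorArray] | None = None,
    leadfields: dict[str, LeadField] | None = None,
    source_spacing_m: float = 0.005,
    between_subject_scale: float = 1.0,
    run_jitter_scale: float = 0.05,
) -> list[Path]:
    """Write a BIDS-like synthetic cohort tree and return the session paths.

    Layout: ``sub-XX/ses-{platform}{run}/meg/`` with an HDF5 data container,
    ``*_events.tsv``, ``*_channels.tsv`` and a JSON sidecar. Subject
    generative parameters are logged to ``cohort_params.json`` at the root
    so that reconstruction accuracy is directly checkable.
    """
    from . import io as mio
    from .geometry import build_array, build_source_space, compute_leadfield

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if arrays is None:
        arrays = {"opm": build_array("opm"), "squid": build_array("squid")}
    if leadfields is None:
        space = build_source_space(spacing_m=source_spacing_m)
        leadfields = {p: compute_leadfield(space, a) for p, a in arrays.items()}

    ss = np.random.SeedSequence(seed)
    cohort = sample_cohort_params(
        n_subjects, np.random.default_rng(ss.spawn(1)[0]),
        between_subject_scale=between_subject_scale, run_jitter_scale=run_jitter_scale,
    )
    _log_params(cohort, out_dir / "cohort_params.json")

    paths = []
    for si, params in enumerate(cohort):
        subject = f"sub-{si + 1:02d}"
        for platform in ("opm", "squid"):
            for run in range(1, runs_per_platform + 1):
                child = np.random.SeedSequence((seed, si, 0 if platform == "opm" else 1, run))
                rec = simulate_dataset(
                    params, arrays[platform], leadfields[platform], n_trials,
                    subject, run, np.random.default_rng(child),
                )
                ses = out_dir / subject / f"ses-{platform}{run}" / "meg"
                mio.write_recording(rec, ses)
                paths.append(ses)
    return paths


def _log_params(cohort: list[SubjectFingerprintParams], path: Path) -> None:
    import json

    payload = []
    for p in cohort:
        d = asdict(p)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        payload.append(d)
    path.write_text(json.dumps(payload, indent=1))
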