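"""Hilbert-envelope time-frequency spectra and trial-averaged envelopes.

The time-frequency spectrogram (TFS) of relative amplitude change is

    R(t, f) = (A(t, f) - B(f)) / B(f),

where A is the trial-averaged Hilbert envelope of the virtual-electrode
signal filtered into overlapping 1 Hz-wide bands, and B(f) is the mean of A
over a quiet baseline window late in the trial (default 12-13.5 s after the
cue end, inside the rest period). R and the trial-averaged beta envelope at
the peak beta-modulation voxels are the two dynamic fingerprint features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

from .preprocess import design_bandpass

__all__ = [
    "TFS",
    "EnvelopeTimecourse",
    "hilbert_envelope",
    "compute_tfs",
    "beta_envelope",
    "evoked_power_timecourse",
    "resample_timecourse",
    "default_band_centres",
]

BASELINE_WINDOW_S = (12.0, 13.5)
BAND_WIDTH_HZ = 1.0
EDGE_PAD_S = 0.5


def default_band_centres(step_hz: float = 0.5, lo: float = 1.5, hi: float = 99.5) -> np.ndarray:
    """Centres of the overlapping 1 Hz-wide analysis bands (1-100 Hz)."""
    return np.arange(lo, hi + step_hz / 2, step_hz)


def hilbert_envelope(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Instantaneous amplitude: |analytic signal| along ``axis``."""
    x = np.asarray(x, float)
    n = x.shape[axis]
    analytic = sps.hilbert(x, N=next_fast_len(n), axis=axis)
    return np.abs(np.take(analytic, np.arange(n), axis=axis))


@dataclass
class TFS:
    """Relative-amplitude time-frequency matrix R[time, frequency]."""

    R: np.ndarray  # (n_times, n_freqs)
    times: np.ndarray
    freqs: np.ndarray  # band centres, Hz
    baseline_s: tuple[float, float]
    voxel: int | None = None

    def on_grid(self, grid: np.ndarray) -> np.ndarray:
        """Resample to a common time grid (linear interpolation per band)."""
        out = np.empty((len(grid), self.R.shape[1]), dtype=np.float32)
        for j in range(self.R.shape[1]):
            out[:, j] = np.interp(grid, self.times, self.R[:, j])
        return out


@dataclass
class EnvelopeTimecourse:
    """Trial-averaged band envelope per condition."""

    amplitude: dict[str, np.ndarray]  # condition -> (n_times,)
    times: np.ndarray
    band: str
    voxel: int | None = None


def _band_envelope(
    epochs_1d: np.ndarray, rate_hz: float, low: float, high: float, pad_s: float = EDGE_PAD_S
) -> np.ndarray:
    """Per-trial Hilbert envelope of band-passed data, reflection-padded."""
    n_pad = int(round(pad_s * rate_hz))
    x = np.pad(np.asarray(epochs_1d, float), [(0, 0), (n_pad, n_pad)], mode="reflect")
    taps = design_bandpass(low, high, rate_hz)
    x = sps.fftconvolve(x, taps[None, :], mode="same", axes=-1)
    env = hilbert_envelope(x, axis=-1)
    return env[:, n_pad:-n_pad]


def compute_tfs(
    ve_epochs: np.ndarray,
    rate_hz: float,
    t_start: float,
    centres_hz: np.ndarray | None = None,
    bandwidth_hz: float = BAND_WIDTH_HZ,
    baseline_s: tuple[float, float] = BASELINE_WINDOW_S,
    voxel: int | None = None,
) -> TFS:
    """Time-frequency spectrogram of relative amplitude change.

    Parameters
    ----------
    ve_epochs:
        Broadband virtual-electrode epochs, (n_trials, n_samples), aligned
        so that sample 0 sits at ``t_start`` relative to the cue end.
    centres_hz:
        Band centres; defaults to 1.5 .. 99.5 Hz in 0.5 Hz steps
        (overlapping 1 Hz-wide bands).
    """
    if ve_epochs.ndim != 2 or ve_epochs.shape[0] < 1:
        raise ValueError("ve_epochs must be (n_trials, n_samples) with >= 1 trial")
    centres = default_band_centres() if centres_hz is None else np.asarray(centres_hz, float)
    n_t = ve_epochs.shape[1]
    times = t_start + np.arange(n_t) / rate_hz
    base = (times >= baseline_s[0]) & (times <= baseline_s[1])
    if not base.any():
        raise ValueError("epoch does not cover the baseline window")

    R = np.empty((n_t, len(centres)))
    for j, c in enumerate(centres):
        env = _band_envelope(ve_epochs, rate_hz, c - bandwidth_hz / 2, c + bandwidth_hz / 2)
        A = env.mean(axis=0)
        B = A[base].mean()
        if B <= 0:
            raise ZeroDivisionError(f"zero baseline amplitude in band {c} Hz")
        R[:, j] = (A - B) / B
    return TFS(R=R, times=times, freqs=centres, baseline_s=baseline_s, voxel=voxel)


def beta_envelope(
    ve_epochs: np.ndarray,
    rate_hz: float,
    t_start: float,
    conditions: dict[str, np.ndarray] | None = None,
    band: tuple[float, float] = (13.0, 30.0),
    prefiltered: bool = False,
    voxel: int | None = None,
) -> EnvelopeTimecourse:
    """Trial-averaged Hilbert envelope of the beta-band virtual electrode.

    ``conditions`` maps labels to trial-index arrays; the average over all
    trials is always included under ``"all"``. Set ``prefiltered`` when the
    virtual electrode was already beta-band filtered.
    """
    if ve_epochs.shape[0] < 1:
        raise ValueError("need at least one trial")
    if prefiltered:
        n_pad = int(round(EDGE_PAD_S * rate_hz))
        x = np.pad(np.asarray(ve_epochs, float), [(0, 0), (n_pad, n_pad)], mode="reflect")
        env = hilbert_envelope(x, axis=-1)[:, n_pad:-n_pad]
    else:
        env = _band_envelope(ve_epochs, rate_hz, band[0], band[1])
    out = {"all": env.mean(axis=0)}
    for label, idx in (conditions or {}).items():
        idx = np.asarray(idx, int)
        if idx.size == 0:
            raise ValueError(f"condition {label!r} has no trials")
        out[label] = env[idx].mean(axis=0)
    times = t_start + np.arange(ve_epochs.shape[1]) / rate_hz
    return EnvelopeTimecourse(amplitude=out, times=times, band=f"{band[0]}-{band[1]}Hz", voxel=voxel)


def evoked_power_timecourse(
    power: np.ndarray,
    peak_voxel: int,
    times: np.ndarray,
    window_s: tuple[float, float] = (0.0, 1.2),
) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature-summed evoked power at the peak voxel over the stimulus window."""
    sel = (times >= window_s[0] - 1e-9) & (times <= window_s[1] + 1e-9)
    return power[peak_voxel, sel].copy(), times[sel].copy()


def resample_timecourse(times: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Linear resampling onto a shared grid (used for 375 vs 600 Hz comparisons)."""
    return np.interp(grid, times, values)
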