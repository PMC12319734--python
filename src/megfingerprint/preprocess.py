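"""Channel screening, interference suppression, filtering and trial rejection.

Processing order is fixed: screen -> HFC (OPM) / reference gradiometry
(SQUID) -> band-pass -> epoch -> peak-to-peak rejection. Every step is
either linear or a pure selection, so signal and noise can be processed
separately and summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .geometry import SensorArray, KIND_REF
from .simulate import Recording

__all__ = [
    "Epochs",
    "channel_screen",
    "homogeneous_field_correction",
    "reference_gradiometry",
    "bandpass",
    "epoch_and_reject",
]

NOISE_BAND_HZ = (60.0, 80.0)
LOW_FLOOR_FT_SQRTHZ = 5.0  # below: channel considered non-operational
HIGH_FLOOR_FT_SQRTHZ = 20.0  # above: channel considered excessively noisy
P2P_LIMIT_FT = 4000.0  # 4 pT


@dataclass
class Epochs:
    """Trial-segmented data: data[trial, channel, sample].

    ``t_start`` is the window start relative to the locking event;
    ``retained`` indexes the surviving trials into the original event list;
    ``events`` holds the corresponding event-table rows.
    """

    data: np.ndarray
    t_start: float
    sampling_rate_hz: float
    retained: np.ndarray
    events: pd.DataFrame
    band: str = "broadband"

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.data.shape[2]) / self.sampling_rate_hz

    def window_slice(self, t0: float, t1: float) -> slice:
        i0 = int(np.ceil((t0 - self.t_start) * self.sampling_rate_hz - 1e-9))
        i1 = int(np.floor((t1 - self.t_start) * self.sampling_rate_hz + 1e-9)) + 1
        if i0 < 0 or i1 > self.data.shape[2]:
            raise ValueError(f"window ({t0}, {t1}) outside epoch")
        return slice(i0, i1)


def noise_floor_asd(
    data: np.ndarray, rate_hz: float, band: tuple[float, float] = NOISE_BAND_HZ
) -> np.ndarray:
    """Per-channel mean amplitude spectral density over ``band``, fT/sqrt(Hz).

    Welch estimate with 2 s Hann segments and 50% overlap.
    """
    nperseg = min(int(2 * rate_hz), data.shape[-1])
    f, psd = signal.welch(data, fs=rate_hz, window="hann", nperseg=nperseg, axis=-1)
    sel = (f >= band[0]) & (f <= band[1])
    return np.sqrt(psd[..., sel]).mean(axis=-1)


def channel_screen(
    recording: Recording,
    low_fT_sqrtHz: float = LOW_FLOOR_FT_SQRTHZ,
    high_fT_sqrtHz: float = HIGH_FLOOR_FT_SQRTHZ,
    band: tuple[float, float] = NOISE_BAND_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Screen channels by their 60-80 Hz noise floor.

    Channels whose mean amplitude spectral density in ``band`` is below
    ``low_fT_sqrtHz`` (not operational) or above ``high_fT_sqrtHz``
    (excessively noisy) are marked for removal. Reference channels are
    always kept (they never enter source analysis but feed gradiometry).

    Returns
    -------
    kept : integer channel indices retained
    floors : per-channel noise floor, fT/sqrt(Hz)
    """
    if recording.n_samples < 10 * recording.sampling_rate_hz:
        raise ValueError("need >= 10 s of data for a stable Welch floor estimate")
    floors = noise_floor_asd(recording.data, recording.sampling_rate_hz, band)
    is_ref = np.array([k == KIND_REF for k in recording.array.kinds])
    ok = ((floors >= low_fT_sqrtHz) & (floors <= high_fT_sqrtHz)) | is_ref
    kept = np.flatnonzero(ok)
    if kept.size == 0:
        raise ValueError("channel screening removed every channel")
    return kept, floors


def hfc_projector(orientations: np.ndarray) -> np.ndarray:
    """Projector removing the spatially uniform field component.

    The model is b = A c + e with A the (n_channels, 3) matrix of sensor
    orientation unit vectors and c the uniform field vector; the returned
    matrix is I - A A^+, the orthogonal complement of the uniform-field
    subspace.
    """
    A = np.asarray(orientations, float)
    if A.shape[0] < 3:
        raise ValueError("HFC needs at least 3 channels")
    return np.eye(A.shape[0]) - A @ np.linalg.pinv(A)


def homogeneous_field_correction(
    data: np.ndarray, orientations: np.ndarray
) -> np.ndarray:
    """Subtract the least-squares uniform-field fit from every time sample.

    Computed in the input dtype (float64 input gives projector-accuracy
    residuals; float32 input keeps the pipeline's memory footprint down).
    """
    P = hfc_projector(orientations)
    dt = data.dtype if np.issubdtype(data.dtype, np.floating) else np.float64
    return P.astype(dt) @ data.astype(dt, copy=False)


def reference_gradiometry(
    scalp: np.ndarray, references: np.ndarray
) -> np.ndarray:
    """Regress reference-channel signals out of every scalp channel.

    A single least-squares fit over the full record (zeroth-order synthetic
    gradiometry); the residual is uncorrelated with every reference channel.
    """
    if references.shape[0] == 0:
        raise ValueError("no reference channels supplied")
    dt = np.result_type(scalp.dtype, np.float32)
    R = np.asarray(references, dt)
    S = np.asarray(scalp, dt)
    G = (R @ R.T).astype(float)  # (n_ref, n_ref) normal equations
    coef = (np.linalg.pinv(G) @ (R @ S.T)).astype(dt)  # pinv tolerates dead references
    return (S - coef.T @ R).astype(scalp.dtype)


def design_bandpass(low_hz: float, high_hz: float, rate_hz: float) -> np.ndarray:
    """Linear-phase FIR band-pass taps.

    Transition bandwidths follow the common default rule
    ``min(max(edge/4, 2 Hz), edge)`` on each side, and the filter length is
    6.6 times the reciprocal of the shortest transition band (in samples)
    minus 1, forced odd.
    """
    nyq = rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) invalid for rate {rate_hz}")
    trans_lo = min(max(low_hz / 4.0, 2.0), low_hz)
    trans_hi = min(max(high_hz / 4.0, 2.0), high_hz, nyq - high_hz)
    numtaps = int(round(6.6 / min(trans_lo, trans_hi) * rate_hz)) - 1
    numtaps |= 1
    edges = [max(low_hz - trans_lo / 2.0, 1e-3), min(high_hz + trans_hi / 2.0, nyq - 1e-3)]
    return signal.firwin(numtaps, edges, fs=rate_hz, pass_zero=False, window="hamming")


def bandpass(
    data: np.ndarray, rate_hz: float, low_hz: float, high_hz: float
) -> np.ndarray:
    """Zero-phase FIR band-pass along the last axis.

    The symmetric linear-phase kernel applied with centred convolution has
    exactly zero phase.
    """
    from scipy.fft import rfft, irfft, next_fast_len

    taps = design_bandpass(low_hz, high_hz, rate_hz)
    x = np.asarray(data)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    n = x.shape[-1]
    nfft = next_fast_len(n + len(taps) - 1)
    H = rfft(taps.astype(x.dtype), nfft)
    out = irfft(rfft(x, nfft, axis=-1) * H, nfft, axis=-1)
    delay = (len(taps) - 1) // 2  # symmetric kernel: centred output is zero-phase
    return np.ascontiguousarray(out[..., delay : delay + n]).astype(x.dtype)


def epoch_and_reject(
    data: np.ndarray,
    events: pd.DataFrame,
    rate_hz: float,
    window: tuple[float, float],
    trial_types: list[str] | None = None,
    p2p_limit_fT: float = P2P_LIMIT_FT,
    reject: bool = True,
    band: str = "broadband",
) -> Epochs:
    """Segment continuous data around events and drop high-amplitude trials.

    A trial is rejected when any channel's peak-to-peak amplitude inside
    the window exceeds ``p2p_limit_fT`` (default 4 pT).
    """
    sel = events if trial_types is None else events[events["trial_type"].isin(trial_types)]
    i0 = int(round(window[0] * rate_hz))
    n_win = int(round((window[1] - window[0]) * rate_hz)) + 1
    starts = sel["sample"].to_numpy() + i0
    valid = (starts >= 0) & (starts + n_win <= data.shape[1])
    if not np.all(valid):
        raise ValueError("some events fall outside the record for this window")
    idx = starts[:, None] + np.arange(n_win)[None, :]
    ep = data[:, idx].transpose(1, 0, 2)  # (trial, channel, sample)

    if reject:
        p2p = ep.max(axis=2) - ep.min(axis=2)
        keep = ~(p2p > p2p_limit_fT).any(axis=1)
    else:
        keep = np.ones(len(ep), dtype=bool)
    if not keep.any():
        raise ValueError("all trials rejected by the peak-to-peak rule")
    retained = np.flatnonzero(keep)
    return Epochs(
        data=ep[keep],
        t_start=i0 / rate_hz,
        sampling_rate_hz=rate_hz,
        retained=retained,
        events=sel.iloc[retained].reset_index(drop=True),
        band=band,
    )


def rejection_report(epochs: Epochs, n_events: int) -> pd.DataFrame:
    dropped = sorted(set(range(n_events)) - set(epochs.retained.tolist()))
    rows = [("trial", i, "peak_to_peak_fT", P2P_LIMIT_FT, "removed") for i in dropped]
    rows += [("trial", int(i), "peak_to_peak_fT", P2P_LIMIT_FT, "kept") for i in epochs.retained]
    return pd.DataFrame(rows, columns=["unit", "id", "metric", "threshold", "decision"])
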