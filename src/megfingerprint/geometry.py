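"""Sensor arrays, spherical-conductor forward fields, and lead fields.

Two platforms are modelled:

* ``opm`` — a wearable array of 64 triaxial optically pumped magnetometers
  (192 channels: each site measures three orthogonal field components),
  sampled at 375 Hz, sited a few millimetres off the scalp.
* ``squid`` — a 275-channel cryogenic system of 5 cm-baseline axial
  gradiometers plus 29 distal reference magnetometers, sampled at 600 Hz,
  with the inner pick-up coil ~2 cm from the scalp.

The conductor is a homogeneous sphere, for which the external field of a
current dipole has the Sarvas closed form. Its key physical property —
a purely radial dipole moment produces no external field — carries over to
realistic single-shell head models and is preserved exactly here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensorArray",
    "SourceSpace",
    "LeadField",
    "build_array",
    "build_source_space",
    "sarvas_field",
    "compute_leadfield",
]

MU0_OVER_4PI = 1e-7  # T·m/A

OPM_RATE_HZ = 375.0
SQUID_RATE_HZ = 600.0
OPM_NOISE_FLOOR = 15.0  # fT/sqrt(Hz)
SQUID_NOISE_FLOOR = 5.0
GRADIOMETER_BASELINE_M = 0.05

KIND_MAG = "magnetometer"
KIND_GRAD = "axial_gradiometer"
KIND_REF = "reference"


@dataclass
class SensorArray:
    """Channel geometry and noise description for one MEG platform.

    ``positions`` / ``orientations`` are (n_channels, 3) arrays in metres /
    unit vectors; ``kinds`` labels each channel magnetometer, axial
    gradiometer or reference. Axial gradiometers measure
    B(inner)·axis − B(outer)·axis with the outer coil ``grad_baseline_m``
    further out along the same axis.
    """

    platform: str
    positions: np.ndarray
    orientations: np.ndarray
    kinds: list[str]
    sampling_rate_hz: float
    noise_floor: np.ndarray  # fT/sqrt(Hz) per channel
    sphere_centre: np.ndarray = field(default_factory=lambda: np.zeros(3))
    grad_baseline_m: float = GRADIOMETER_BASELINE_M
    names: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def scalp_mask(self) -> np.ndarray:
        """Boolean mask of non-reference channels."""
        return np.array([k != KIND_REF for k in self.kinds])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "name": self.names or [f"{self.platform}{i:03d}" for i in range(self.n_channels)],
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "ox": self.orientations[:, 0],
                "oy": self.orientations[:, 1],
                "oz": self.orientations[:, 2],
                "kind": self.kinds,
                "noise_floor_fT_sqrtHz": self.noise_floor,
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        sidecar = {
            "platform": self.platform,
            "sampling_rate_hz": self.sampling_rate_hz,
            "sphere_centre_m": self.sphere_centre.tolist(),
            "grad_baseline_m": self.grad_baseline_m,
        }
        Path(str(path)).with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


@dataclass
class SourceSpace:
    """Cubic voxel grid inside the conductor sphere (shared by the cohort)."""

    positions: np.ndarray  # (n_voxels, 3) m
    spacing_m: float
    radius_m: float
    sphere_centre: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]

    def hemisphere_mask(self, side: str) -> np.ndarray:
        """Left/right split by x sign (negative x = left, anatomical axes)."""
        x = self.positions[:, 0] - self.sphere_centre[0]
        if side == "left":
            return x < 0
        if side == "right":
            return x > 0
        raise ValueError(f"unknown side {side!r}")

    def nearest_voxel(self, pos: np.ndarray) -> int:
        return int(np.argmin(np.linalg.norm(self.positions - np.asarray(pos), axis=1)))


@dataclass
class LeadField:
    """Gain tensor: gains[voxel, orientation (x,y,z), channel], fT per nAm."""

    gains: np.ndarray
    source_space: SourceSpace
    array: SensorArray

    @property
    def n_voxels(self) -> int:
        return self.gains.shape[0]

    def gain_for(self, pos: np.ndarray, moment_dir: np.ndarray) -> np.ndarray:
        """Exact per-channel gain for an off-grid dipole (fT per nAm)."""
        g = _channel_gains(np.asarray(pos, float)[None, :], self.array)[0]  # (3, C)
        return np.asarray(moment_dir, float) @ g


def _fibonacci_cap(n: int, radius: float, theta_max: float) -> np.ndarray:
    """Quasi-uniform points on a spherical cap (opening angle theta_max from +z)."""
    i = np.arange(n) + 0.5
    z = 1.0 - (1.0 - np.cos(theta_max)) * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z**2)
    return radius * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _radial_triads(radial: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two tangential unit vectors completing a right-handed triad with radial."""
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(radial), 1))
    ref[np.abs(radial[:, 2]) > 0.9] = [1.0, 0.0, 0.0]
    t1 = np.cross(ref, radial)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(radial, t1)
    return t1, t2


def build_array(
    platform: str,
    head_radius_m: float = 0.09,
    helmet_offset_m: float | None = None,
    seed: int | None = None,
    sphere_centre: np.ndarray | None = None,
    theta_max: float = 2.1,
) -> SensorArray:
    """Construct an OPM or SQUID sensor array on a helmet cap.

    Sensor sites are laid out quasi-uniformly (Fibonacci lattice) on a
    spherical cap of opening angle ``theta_max`` covering the superior head.
    OPM sites carry a right-handed orthonormal triad with one radial axis
    (3 channels/site); SQUID sites carry one radial axial gradiometer.
    ``helmet_offset_m`` defaults to 6.5 mm (OPM, on-scalp) or 20 mm (SQUID
    inner coil inside the dewar).

    The ``seed`` argument is accepted for interface symmetry; the lattice is
    deterministic.
    """
    if head_radius_m <= 0 or (helmet_offset_m is not None and helmet_offset_m <= 0):
        raise ValueError("head radius and helmet offset must be positive")
    centre = np.zeros(3) if sphere_centre is None else np.asarray(sphere_centre, float)

    if platform == "opm":
        offset = 0.0065 if helmet_offset_m is None else helmet_offset_m
        sites = _fibonacci_cap(64, head_radius_m + offset, theta_max)
        radial = sites / np.linalg.norm(sites, axis=1, keepdims=True)
        t1, t2 = _radial_triads(radial)
        positions = np.repeat(sites, 3, axis=0) + centre
        orientations = np.stack([radial, t1, t2], axis=1).reshape(-1, 3)
        kinds = [KIND_MAG] * 192
        noise = np.full(192, OPM_NOISE_FLOOR)
        names = [f"opm{i:02d}-{ax}" for i in range(64) for ax in ("rad", "tan1", "tan2")]
        return SensorArray("opm", positions, orientations, kinds, OPM_RATE_HZ, noise,
                           sphere_centre=centre, names=names)

    if platform == "squid":
        offset = 0.020 if helmet_offset_m is None else helmet_offset_m
        sites = _fibonacci_cap(275, head_radius_m + offset, theta_max)
        radial = sites / np.linalg.norm(sites, axis=1, keepdims=True)
        # distal reference shell 0.4 m above the helmet
        ref_sites = _fibonacci_cap(29, head_radius_m + offset + 0.4, 0.9)
        ref_radial = ref_sites / np.linalg.norm(ref_sites, axis=1, keepdims=True)
        positions = np.vstack([sites, ref_sites]) + centre
        orientations = np.vstack([radial, ref_radial])
        kinds = [KIND_GRAD] * 275 + [KIND_REF] * 29
        noise = np.full(304, SQUID_NOISE_FLOOR)
        names = [f"sq{i:03d}" for i in range(275)] + [f"ref{i:02d}" for i in range(29)]
        return SensorArray("squid", positions, orientations, kinds, SQUID_RATE_HZ, noise,
                           sphere_centre=centre, names=names)

    raise ValueError(f"unknown platform {platform!r}; expected 'opm' or 'squid'")


def build_source_space(
    radius_m: float = 0.08,
    spacing_m: float = 0.005,
    sphere_centre: np.ndarray | None = None,
) -> SourceSpace:
    """Cubic grid of voxels strictly inside a sphere of ``radius_m``."""
    centre = np.zeros(3) if sphere_centre is None else np.asarray(sphere_centre, float)
    half = int(np.floor(radius_m / spacing_m))
    axis = np.arange(-half, half + 1) * spacing_m
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) < radius_m - 1e-12]
    return SourceSpace(pts + centre, spacing_m, radius_m, sphere_centre=centre)


def _sarvas(r0: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorised Sarvas formula.

    Parameters are broadcast: ``r0`` (..., 3) dipole positions, ``q`` (..., 3)
    moments (A·m), ``r`` (..., 3) sensor positions, all relative to the
    sphere centre. Returns B in tesla, shape (..., 3).
    """
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=-1, keepdims=True)
    rn = np.linalg.norm(r, axis=-1, keepdims=True)
    r0_dot_r = np.sum(r0 * r, axis=-1, keepdims=True)
    a_dot_r = np.sum(a_vec * r, axis=-1, keepdims=True)
    F = a * (rn * a + rn**2 - r0_dot_r)
    grad_F = (a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn) * r - (a + 2.0 * rn + a_dot_r / a) * r0
    q_x_r0 = np.cross(q, r0)
    qxr0_dot_r = np.sum(q_x_r0 * r, axis=-1, keepdims=True)
    return MU0_OVER_4PI / F**2 * (F * q_x_r0 - qxr0_dot_r * grad_F)


def sarvas_field(
    dipole_pos: np.ndarray,
    dipole_moment_nAm: np.ndarray,
    sensor_pos: np.ndarray,
    sphere_centre: np.ndarray | None = None,
    conductor_radius_m: float = 0.09,
) -> np.ndarray:
    """External magnetic field of a current dipole in a spherical conductor.

    Returns the 3-vector B at ``sensor_pos`` in fT for a moment in nAm.
    A purely radial moment yields an exactly zero field.

    Raises
    ------
    ValueError
        If the dipole sits at the sphere centre (the formula is singular
        there) or the sensor lies inside the conductor.
    """
    centre = np.zeros(3) if sphere_centre is None else np.asarray(sphere_centre, float)
    r0 = np.asarray(dipole_pos, float) - centre
    r = np.asarray(sensor_pos, float) - centre
    if np.linalg.norm(r0) < 1e-9:
        raise ValueError("dipole at sphere centre: degenerate geometry")
    if np.linalg.norm(r) <= conductor_radius_m:
        raise ValueError("sensor inside conductor sphere: degenerate geometry")
    q = np.asarray(dipole_moment_nAm, float) * 1e-9
    return _sarvas(r0, q, r) * 1e15


def _channel_gains(voxels: np.ndarray, array: SensorArray) -> np.ndarray:
    """Gain tensor (n_vox, 3, n_channels) in fT/nAm for unit x/y/z moments."""
    centre = array.sphere_centre
    r0 = voxels - centre  # (V, 3)
    inner = array.positions - centre  # (C, 3)
    out = np.empty((len(voxels), 3, array.n_channels))
    is_grad = np.array([k == KIND_GRAD for k in array.kinds])
    outer = inner + array.grad_baseline_m * array.orientations  # only used where is_grad
    for ax in range(3):
        q = np.zeros(3)
        q[ax] = 1e-9  # 1 nAm
        B_in = _sarvas(r0[:, None, :], q, inner[None, :, :]) * 1e15
        gains = np.sum(B_in * array.orientations[None, :, :], axis=-1)
        if is_grad.any():
            B_out = _sarvas(r0[:, None, :], q, outer[None, is_grad, :]) * 1e15
            gains[:, is_grad] -= np.sum(B_out * array.orientations[None, is_grad, :], axis=-1)
        out[:, ax, :] = gains
    return out


def compute_leadfield(space: SourceSpace, array: SensorArray) -> LeadField:
    """Lead field for every voxel of ``space`` seen by ``array``.

    Magnetometer gain is B·orientation; axial-gradiometer gain is the
    difference of B·axis between the inner coil and a coaxial coil
    ``grad_baseline_m`` further out. Units fT (or fT difference) per nAm.
    """
    if not np.allclose(space.sphere_centre, array.sphere_centre):
        raise ValueError("source space and array use different sphere centres")
    gains = _channel_gains(space.positions, array)
    if not np.all(np.isfinite(gains)):
        raise ValueError("non-finite lead field entries: degenerate geometry")
    return LeadField(gains, space, array)
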