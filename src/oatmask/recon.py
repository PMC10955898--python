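"""Demultiplexing, virtual-array assembly and universal back-projection.

The multiplexed scan is inverted exactly, P = W^-1 Y, with the
closed-form S-matrix inverse — no regularization is needed because the
cyclic S-matrix is perfectly conditioned for binary codes.  The
recovered per-aperture waveforms are arranged on the interlaced virtual
detector grid, the time axis is moved back to the mask plane
(t_grid = t_sampled - d/c), and the 3D absorption map is formed by
universal back-projection over the planar virtual array:

    v(r) = sum_det w * b(t = |r - r_det| / c),
    b(t) = 2 p(t) - 2 t dp/dt,   w = cos(theta) / |r - r_det|^2

normalized by the sum of weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert, resample

from .codes import CodingMatrix, MaskLayout, apply_inverse
from .simulate import MultiplexedData, ScanConfig

__all__ = [
    "VirtualArrayData",
    "Volume",
    "demultiplex",
    "assemble_grid",
    "correct_time_axis",
    "ubp_reconstruct",
    "ubp_profile",
    "envelope_z",
    "map_projection",
    "measure_fwhm",
    "peak_position",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VirtualArrayData:
    """Demultiplexed per-aperture waveforms on the virtual detector grid.

    ``signals`` has shape (alpha*P, beta*Q, n_t); node (i, j) sits at
    (i * pitch_x, j * pitch_y) on the mask plane (origin = mask cell
    (0, 0)).  ``t_grid`` is the mask-plane time axis.
    """

    signals: np.ndarray = field(repr=False)
    pitch_x: float
    pitch_y: float
    t_grid: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class Volume:
    """Reconstruction on a regular voxel grid.

    ``origin`` is the centre of voxel (0, 0, 0) in mask coordinates
    (mm); the z axis points from the mask plane into the object.
    """

    values: np.ndarray = field(repr=False)
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.values.shape[axis]) * self.voxel_size[axis]


def demultiplex(Y: MultiplexedData | np.ndarray,
                W: CodingMatrix | np.ndarray) -> np.ndarray:
    """Recover per-aperture signals: P = W^-1 Y.

    ``W`` may be the coding matrix (the structured inverse is then
    applied without materializing W^-1) or an explicit dense inverse.
    """
    Ym = Y.Y if isinstance(Y, MultiplexedData) else np.asarray(Y)
    if isinstance(W, CodingMatrix):
        if Ym.shape[0] != W.N:
            raise ValueError(f"Y has {Ym.shape[0]} rows, expected {W.N}")
        return apply_inverse(W, Ym)
    Winv = np.asarray(W, dtype=np.float64)
    if Ym.shape[0] != Winv.shape[1]:
        raise ValueError(
            f"Y has {Ym.shape[0]} rows, inverse expects {Winv.shape[1]}")
    return Winv @ Ym


def correct_time_axis(t_sampled: np.ndarray, d: float, c: float) -> np.ndarray:
    """Move the time axis from the detector plane to the mask plane:
    t_grid = t_sampled - d/c."""
    if d < 0 or c <= 0:
        raise ValueError("need d >= 0 and c > 0")
    return np.asarray(t_sampled) - d / c


def assemble_grid(P: np.ndarray, mask: MaskLayout,
                  scan: ScanConfig,
                  t_sampled: np.ndarray | None = None) -> VirtualArrayData:
    """Arrange demultiplexed rows on the interlaced virtual-array grid.

    Row k of each interlace block is the waveform of mask site
    (k mod P, k mod Q) (the CRT flattening used at multiplexing; the
    shift/row permutation is carried by ``mask``).  Offset (a, b), site
    (i, j) lands at grid element (a + alpha*i, b + beta*j), physical
    position (i*D + a*D/alpha, j*D + b*D/beta).
    """
    if mask is None:
        raise ValueError(
            "mask layout (carrying the shift/row permutation) is required; "
            "regenerate it with fold_to_mask")
    N = mask.P * mask.Q
    n_blocks = scan.alpha * scan.beta
    if P.shape[0] != N or P.shape[1] % n_blocks:
        raise ValueError(
            f"P shape {P.shape} incompatible with N = {N}, "
            f"{n_blocks} interlace blocks")
    n_t = P.shape[1] // n_blocks
    out = np.empty((scan.alpha * mask.P, scan.beta * mask.Q, n_t))
    k = np.arange(N)
    for o, (a, b) in enumerate(scan.offsets):
        block = P[:, o * n_t:(o + 1) * n_t]
        grid = np.empty((mask.P, mask.Q, n_t))
        grid[k % mask.P, k % mask.Q] = block
        out[a::scan.alpha, b::scan.beta] = grid
    if t_sampled is None:
        t_sampled = scan.time_axis + scan.d / scan.c
    t_grid = correct_time_axis(t_sampled, scan.d, scan.c)
    return VirtualArrayData(signals=out, pitch_x=scan.pitch / scan.alpha,
                            pitch_y=scan.pitch / scan.beta, t_grid=t_grid)


def _backprojection_term(data: VirtualArrayData,
                         upsample: int) -> tuple[np.ndarray, np.ndarray]:
    """b = 2p - 2 t dp/dt per detector, optionally Fourier-upsampled."""
    p = data.signals
    t = data.t_grid
    if upsample > 1:
        n = p.shape[-1] * upsample
        p = resample(p, n, axis=-1)
        t = t[0] + np.arange(n) * (t[1] - t[0]) / upsample
    dt = t[1] - t[0]
    dpdt = np.gradient(p, dt, axis=-1)
    return 2.0 * p - 2.0 * t * dpdt, t


def ubp_reconstruct(data: VirtualArrayData,
                    origin: tuple[float, float, float],
                    shape: tuple[int, int, int],
                    voxel_size: float | tuple[float, float, float],
                    c: float,
                    upsample: int = 1) -> Volume:
    """Universal back-projection onto a voxel box.

    Each virtual aperture acts as a point detector at its grid node on
    the mask plane.  The filtered term b = 2p - 2t dp/dt is evaluated
    at the flight time |r - r_det| / c by linear interpolation,
    weighted by the solid-angle factor cos(theta)/|r - r_det|^2
    (theta to the mask normal), summed over detectors and normalized by
    the sum of weights.  Voxels whose flight time falls outside the
    time window receive no contribution; their count is logged.
    """
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    t = data.t_grid
    if not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    b, t = _backprojection_term(data, upsample)
    dt = t[1] - t[0]
    n_t = t.size

    vx = origin[0] + np.arange(shape[0]) * voxel_size[0]
    vy = origin[1] + np.arange(shape[1]) * voxel_size[1]
    vz = origin[2] + np.arange(shape[2]) * voxel_size[2]
    X, Y, Z = np.meshgrid(vx, vy, vz, indexing="ij")
    X, Y, Z = X.ravel(), Y.ravel(), Z.ravel()

    acc = np.zeros(X.size)
    wsum = np.zeros(X.size)
    clipped = 0
    nx, ny = data.signals.shape[:2]
    for i in range(nx):
        dx2 = (X - i * data.pitch_x) ** 2
        for j in range(ny):
            dist = np.sqrt(dx2 + (Y - j * data.pitch_y) ** 2 + Z ** 2)
            pos = (dist / c - t[0]) / dt
            i0 = np.floor(pos).astype(np.int64)
            valid = (i0 >= 0) & (i0 < n_t - 1)
            clipped += int(np.count_nonzero(~valid))
            i0v = np.clip(i0, 0, n_t - 2)
            frac = pos - i0v
            wave = b[i, j]
            bval = (1.0 - frac) * wave[i0v] + frac * wave[i0v + 1]
            w = Z / dist ** 3  # cos(theta) / dist^2
            acc += np.where(valid, w * bval, 0.0)
            wsum += np.where(valid, w, 0.0)
    if clipped:
        logger.info("UBP: %d voxel-detector pairs outside the time window", clipped)
    out = np.divide(acc, wsum, out=np.zeros_like(acc), where=wsum > 0)
    return Volume(values=out.reshape(shape), voxel_size=voxel_size,
                  origin=tuple(float(v) for v in origin))


def ubp_profile(data: VirtualArrayData, center: tuple[float, float, float],
                axis: int, half_extent: float, spacing: float, c: float,
                upsample: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """1D back-projected profile through ``center`` along ``axis``.

    Returns (coordinates, values); a thin wrapper over
    ``ubp_reconstruct`` on a single voxel line, used for resolution
    measurements at finer-than-voxel sampling.
    """
    n = 2 * int(round(half_extent / spacing)) + 1
    shape = [1, 1, 1]
    shape[axis] = n
    origin = list(center)
    origin[axis] -= (n // 2) * spacing
    vol = ubp_reconstruct(data, tuple(origin), tuple(shape), spacing, c,
                          upsample=upsample)
    return vol.axis_coords(axis), vol.values.ravel()


def envelope_z(vol: Volume) -> Volume:
    """Magnitude of the analytic signal along z, per (x, y) line.

    Used for axial width measurements: the band-pass reconstruction is
    bipolar along z (no low frequencies), so the resolution is read off
    the envelope.
    """
    if vol.values.shape[2] < 8:
        raise ValueError("need at least 8 samples along z for the envelope")
    env = np.abs(hilbert(vol.values, axis=2))
    return Volume(values=env, voxel_size=vol.voxel_size, origin=vol.origin)


def map_projection(vol: Volume, axis: str | int) -> np.ndarray:
    """Maximum amplitude projection (per-pixel max along one axis)."""
    names = {"x": 0, "y": 1, "z": 2}
    ax = names[axis] if isinstance(axis, str) else int(axis)
    if ax not in (0, 1, 2):
        raise ValueError("axis must be one of x, y, z")
    return vol.values.max(axis=ax)


def measure_fwhm(profile: np.ndarray, spacing: float) -> float:
    """Full width at half maximum of a single-peaked profile.

    Half-maximum crossings on either side of the global peak are found
    by linear interpolation; the result is in the units of ``spacing``.
    Raises if the peak sits on the boundary or either crossing is
    missing ("peak not resolved").
    """
    y = np.asarray(profile, dtype=np.float64)
    k = int(np.argmax(y))
    if k == 0 or k == y.size - 1:
        raise ValueError("peak not resolved: maximum lies on the profile boundary")
    half = y[k] / 2.0

    left = next((i for i in range(k - 1, -1, -1) if y[i] <= half), None)
    right = next((i for i in range(k + 1, y.size) if y[i] <= half), None)
    if left is None or right is None:
        raise ValueError("peak not resolved: no half-maximum crossing found")
    # linear interpolation between the sub-half sample and its neighbour toward the peak
    xl = left + (half - y[left]) / (y[left + 1] - y[left])
    xr = right - (half - y[right]) / (y[right - 1] - y[right])
    return float((xr - xl) * spacing)


def peak_position(vol: Volume) -> tuple[float, float, float]:
    """Coordinates (mm) of the global-maximum voxel."""
    idx = np.unravel_index(int(np.argmax(vol.values)), vol.values.shape)
    return tuple(vol.origin[a] + idx[a] * vol.voxel_size[a] for a in range(3))
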