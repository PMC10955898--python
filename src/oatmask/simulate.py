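"""Forward simulation of coded-aperture optoacoustic acquisition.

A short laser pulse deposited in an absorber launches a spherical
pressure wave.  On the mask plane the wave from a point absorber at
distance r is a band-limited bipolar transient arriving at t = r/c with
1/r geometric decay.  The masked detector integrates the field over the
open apertures, so each mask position yields one multiplexed waveform

    u_qp(t) = dA * sum_ij p(i*D, j*D, t) * M[i+q, j+p]

and a full 2D scan realizes u_k = W p_k for every time sample.  Scanning
may be interlaced at sub-pitch steps (D/alpha, D/beta) to fill the gaps
between apertures.  Units: mm, us, MHz throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .codes import CodingMatrix, MaskLayout

__all__ = [
    "PointSource",
    "DetectorModel",
    "ScanConfig",
    "MultiplexedData",
    "impulse_response",
    "point_waveform",
    "grid_pressure",
    "multiplex",
    "add_noise",
    "make_phantom",
    "max_adjacent_spacing",
]


@dataclass(frozen=True)
class PointSource:
    """Optoacoustic point absorber at ``position`` (mm), z > 0 measured
    from the mask plane into the object."""

    position: tuple[float, float, float]
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.position[2] > 0:
            raise ValueError("source must sit at z > 0, in front of the mask")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass(frozen=True)
class DetectorModel:
    """Band-pass single-element detector.

    The default band (3 dB edges 3.1-6.5 MHz, 5 MHz centre) matches a
    typical unfocused piezoelectric immersion transducer.
    """

    band_low: float = 3.1
    band_high: float = 6.5
    filter_order: int = 4
    detector_diameter: float = 28.6

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")

    @property
    def center_frequency(self) -> float:
        return 0.5 * (self.band_low + self.band_high)

    @property
    def bandwidth(self) -> float:
        """BW = band_high - band_low, MHz."""
        return self.band_high - self.band_low

    @property
    def envelope_sigma_t(self) -> float:
        """Gaussian envelope width (us) of the impulse response.

        Chosen so the axial point-spread envelope attains the textbook
        limit FWHM_z = 0.88 c / BW, i.e. the Gaussian amplitude
        spectrum has a -6 dB full width equal to BW.
        """
        sigma_f = self.bandwidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return 1.0 / (2.0 * np.pi * sigma_f)

    def axial_resolution_limit(self, c: float) -> float:
        """Diffraction/bandwidth-limited axial FWHM, mm: 0.88 c / BW."""
        return 0.88 * c / self.bandwidth


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition geometry and timing.

    pitch : mask grid step D (mm); alpha, beta : interlace factors
    (sub-pitch scanning at D/alpha, D/beta); d : mask-to-detector
    distance (mm); c : speed of sound (mm/us); fs : sampling rate
    (MHz); n_t : samples per waveform; t0 : start of the mask-plane
    time window (us); noise_sigma : additive noise std; seed : RNG seed.
    """

    pitch: float = 1.0
    alpha: int = 1
    beta: int = 1
    d: float = 2.7
    c: float = 1.49
    fs: float = 50.0
    n_t: int = 1024
    t0: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 1 or self.beta < 1:
            raise ValueError("interlace factors must be >= 1")
        if self.d < 0:
            raise ValueError("mask-to-detector distance must be >= 0")
        if min(self.pitch, self.c, self.fs, self.n_t) <= 0:
            raise ValueError("pitch, c, fs, n_t must be positive")

    @property
    def time_axis(self) -> np.ndarray:
        """Mask-plane time axis (us), length n_t."""
        return self.t0 + np.arange(self.n_t) / self.fs

    @property
    def offsets(self) -> list[tuple[int, int]]:
        """Interlace offsets (a, b), row-major."""
        return [(a, b) for a in range(self.alpha) for b in range(self.beta)]


@dataclass(frozen=True)
class MultiplexedData:
    """Measured matrix Y, shape N x (alpha*beta*n_t): one multiplexed
    waveform per mask shift, column blocks ordered by interlace offset
    then time.  ``t_sampled`` is the detector-plane time axis, i.e. the
    mask-plane axis delayed by d/c."""

    Y: np.ndarray = field(repr=False)
    t_sampled: np.ndarray = field(repr=False)
    offsets: list[tuple[int, int]]
    scan: ScanConfig


def impulse_response(tau: np.ndarray, det: DetectorModel) -> np.ndarray:
    """Band-limited bipolar impulse h(tau), zero-crossing at tau = 0.

    An odd Gabor wavelet, -sin(2 pi f0 tau) * exp(-tau^2 / 2 sigma^2):
    the band-limited form of the N-shaped optoacoustic transient, with
    compression leading, rarefaction trailing, and the arrival time at
    the central zero crossing.  f0 is the detector band centre; sigma
    follows ``DetectorModel.envelope_sigma_t``.
    """
    tau = np.asarray(tau, dtype=np.float64)
    s = det.envelope_sigma_t
    return -np.sin(2.0 * np.pi * det.center_frequency * tau) * np.exp(
        -0.5 * (tau / s) ** 2
    )


def point_waveform(src: PointSource, obs: tuple[float, float],
                   det: DetectorModel, scan: ScanConfig) -> np.ndarray:
    """Pressure waveform from one point source at a mask-plane point.

    p(t) = (A / r) * h(t - r/c) with r the source-observer distance;
    spherical spreading with the detector-band impulse h.
    """
    x0, y0, z0 = src.position
    r = float(np.hypot(np.hypot(obs[0] - x0, obs[1] - y0), z0))
    t = scan.time_axis
    arrival = r / scan.c
    if not (t[0] <= arrival <= t[-1]):
        warnings.warn(
            f"wavefront outside acquisition window: arrival {arrival:.3f} us "
            f"not in [{t[0]:.3f}, {t[-1]:.3f}] us",
            stacklevel=2,
        )
    return (src.amplitude / r) * impulse_response(t - arrival, det)


def _quadrature_points(aperture_diameter: float, n_points: int) -> np.ndarray:
    """Deterministic sub-aperture sample offsets, shape (n, 2).

    n_points = 1: aperture centre only.  n_points = 7: centre plus six
    points at radius 0.4 * diameter, every 60 degrees.
    """
    if n_points == 1:
        return np.zeros((1, 2))
    if n_points == 7:
        ang = np.arange(6) * (np.pi / 3.0)
        ring = 0.4 * aperture_diameter * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        return np.vstack([np.zeros((1, 2)), ring])
    raise ValueError("aperture quadrature supports 1 or 7 points")


def grid_pressure(sources: list[PointSource], mask: MaskLayout,
                  det: DetectorModel, scan: ScanConfig,
                  aperture_points: int = 7) -> np.ndarray:
    """Aperture-averaged pressure on the (possibly interlaced) scan grid.

    Returns an array (alpha*P, beta*Q, n_t); entry (i, j, :) is the
    mean over the aperture quadrature of the point waveforms at the
    disk centred on (i*D/alpha, j*D/beta).  Linear in the source
    amplitudes.
    """
    if not sources:
        raise ValueError("source list is empty")
    nx = scan.alpha * mask.P
    ny = scan.beta * mask.Q
    gx = np.arange(nx) * (scan.pitch / scan.alpha)
    gy = np.arange(ny) * (scan.pitch / scan.beta)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    t = scan.time_axis
    quad = _quadrature_points(mask.aperture_diameter, aperture_points)

    out = np.zeros((nx, ny, scan.n_t))
    f0 = det.center_frequency
    sig = det.envelope_sigma_t
    for src in sources:
        x0, y0, z0 = src.position
        arr_min = z0 / scan.c
        if not (t[0] <= arr_min <= t[-1]):
            warnings.warn(
                f"wavefront outside acquisition window: earliest arrival "
                f"{arr_min:.3f} us not in [{t[0]:.3f}, {t[-1]:.3f}] us",
                stacklevel=2,
            )
        for dx, dy in quad:
            r = np.sqrt((X + dx - x0) ** 2 + (Y + dy - y0) ** 2 + z0 ** 2)
            tau = t[None, None, :] - (r / scan.c)[:, :, None]
            out += (src.amplitude / (quad.shape[0] * r))[:, :, None] * (
                -np.sin(2.0 * np.pi * f0 * tau) * np.exp(-0.5 * (tau / sig) ** 2)
            )
    return out


def multiplex(pressure: np.ndarray, W: CodingMatrix, mask: MaskLayout,
              scan: ScanConfig) -> MultiplexedData:
    """Single-detector multiplexed acquisition: Y rows are W applied to
    the CRT-flattened pressure of each interlace sub-grid, scaled by the
    aperture area dA; the d/c mask-to-detector propagation enters as a
    delay of the recorded time axis."""
    nx, ny = scan.alpha * mask.P, scan.beta * mask.Q
    if pressure.shape[:2] != (nx, ny):
        raise ValueError(
            f"pressure grid {pressure.shape[:2]} does not match "
            f"(alpha*P, beta*Q) = ({nx}, {ny})"
        )
    crt = mask.crt_index
    n_t = pressure.shape[2]
    Wf = W.W.astype(np.float64)
    blocks = []
    for a, b in scan.offsets:
        sub = pressure[a::scan.alpha, b::scan.beta, :]  # (P, Q, n_t)
        flat = np.empty((W.N, n_t))
        flat[crt.ravel()] = sub.reshape(W.N, n_t)
        blocks.append(mask.aperture_area * (Wf @ flat))
    Y = np.concatenate(blocks, axis=1)
    return MultiplexedData(Y=Y, t_sampled=scan.time_axis + scan.d / scan.c,
                           offsets=scan.offsets, scan=scan)


def add_noise(data: MultiplexedData, noise_sigma: float,
              seed: int) -> MultiplexedData:
    """Additive white Gaussian sensor noise, i.i.d. per sample."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return data
    rng = np.random.default_rng(seed)
    return replace(data, Y=data.Y + rng.normal(0.0, noise_sigma, size=data.Y.shape))


def _trefoil(n: int, center: tuple[float, float, float],
             diameter: float) -> np.ndarray:
    """n points on a trefoil knot scaled to the given overall extent."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = np.sin(t) + 2.0 * np.sin(2.0 * t)
    y = np.cos(t) - 2.0 * np.cos(2.0 * t)
    z = -np.sin(3.0 * t)
    pts = np.stack([x, y, z], axis=1)
    extent = np.ptp(pts[:, :2], axis=0).max()
    pts *= diameter / extent
    return pts + np.asarray(center)


def make_phantom(kind: str, params: dict | None = None,
                 seed: int | None = None) -> list[PointSource]:
    """Synthetic absorber distributions.

    kind = "point": one source at ``params['position']``.
    kind = "knot": a closed trefoil curve of overall lateral extent
    ``params['diameter']`` (mm) centred on ``params['center']``,
    discretized into ``params['n']`` equal-amplitude sources — a stand-in
    for a knotted absorbing suture.
    kind = "random_points": ``params['n']`` seeded uniform sources in
    the box ``params['box']`` = (xlim, ylim, zlim).
    """
    params = dict(params or {})
    if kind == "point":
        return [PointSource(position=tuple(params.get("position", (0.0, 0.0, 12.7))),
                            amplitude=float(params.get("amplitude", 1.0)))]
    if kind == "knot":
        n = int(params.get("n", 300))
        center = tuple(params.get("center", (20.0, 21.0, 23.0)))
        diameter = float(params.get("diameter", 10.0))
        pts = _trefoil(n, center, diameter)
        amp = float(params.get("amplitude", 1.0))
        return [PointSource(position=tuple(p), amplitude=amp) for p in pts]
    if kind == "random_points":
        n = int(params.get("n", 10))
        (x0, x1), (y0, y1), (z0, z1) = params.get(
            "box", ((0.0, 41.0), (0.0, 43.0), (10.0, 20.0)))
        rng = np.random.default_rng(seed)
        pos = rng.uniform([x0, y0, z0], [x1, y1, z1], size=(n, 3))
        return [PointSource(position=tuple(p)) for p in pos]
    raise ValueError(
        f"unknown phantom kind {kind!r}; valid kinds: point, knot, random_points"
    )


def max_adjacent_spacing(sources: list[PointSource]) -> float:
    """Largest spacing between consecutive sources (mm), closing the
    loop; compare against c / (2 * band_high) to judge whether a curve
    phantom is sampled below the diffraction-limited resolution."""
    pts = np.array([s.position for s in sources])
    d = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    return float(d.max())
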