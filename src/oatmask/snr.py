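"""Multiplexing SNR advantage of cyclic S-matrix coding.

Multiplexing N apertures through an order-N cyclic S-matrix and
demultiplexing with its exact inverse attenuates additive sensor noise:
every row of W^-1 has Euclidean norm 2 sqrt(N)/(N+1), so the recovered
per-aperture noise std is sigma * 2 sqrt(N)/(N+1) and the SNR gain over
a single-aperture raster scan (W = identity) is

    G = (N+1) / (2 sqrt(N))  ~  sqrt(N)/2.

Random binary masks invert far less gracefully; their pseudo-inverse
row norms are larger and strongly fluctuating, which is quantified here
by Monte-Carlo comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sympy import isprime

from .codes import CodingMatrix, apply_inverse

__all__ = ["GainReport", "theoretical_gain", "analytic_gain",
           "empirical_gain", "random_mask_gain"]


@dataclass(frozen=True)
class GainReport:
    """SNR gain of a multiplexing scheme relative to a direct
    (single-aperture) measurement with identical per-sample noise."""

    N: int
    theoretical_gain: float
    empirical_gain: float
    std_error: float
    trials: int
    seed: int
    redraws: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_twin_prime_order(N: int) -> None:
    """A cyclic S-matrix order from twin primes satisfies N = P(P+2),
    i.e. N + 1 is a perfect square with P = sqrt(N+1) - 1 prime."""
    root = int(round(np.sqrt(N + 1)))
    P = root - 1
    if root * root != N + 1 or not (isprime(P) and isprime(P + 2)):
        raise ValueError(f"N = {N} is not the order of a twin-prime S-matrix")


def theoretical_gain(N: int) -> float:
    """sqrt(N)/2, the nominal multiplex advantage for order N."""
    _validate_twin_prime_order(N)
    return float(np.sqrt(N) / 2.0)


def analytic_gain(N: int) -> float:
    """Exact S-matrix gain (N+1)/(2 sqrt(N)) from the W^-1 row norms."""
    return float((N + 1) / (2.0 * np.sqrt(N)))


def empirical_gain(W: CodingMatrix | np.ndarray, sigma: float = 1.0,
                   trials: int = 10_000, seed: int = 0) -> GainReport:
    """Monte-Carlo SNR gain of demultiplexing through W.

    Pure-noise measurements E ~ N(0, sigma^2) are demultiplexed; the
    gain is sigma over the mean per-element std of W^-1 E.  For the
    identity matrix the gain is 1 (the direct-measurement baseline);
    for a cyclic S-matrix it matches (N+1)/(2 sqrt(N)).
    """
    if trials < 100:
        raise ValueError("need at least 100 trials")
    rng = np.random.default_rng(seed)
    if isinstance(W, CodingMatrix):
        N = W.N
        noise = rng.normal(0.0, sigma, size=(N, trials))
        rec = apply_inverse(W, noise)
        theo = analytic_gain(N)
    else:
        Wm = np.asarray(W, dtype=np.float64)
        N = Wm.shape[0]
        noise = rng.normal(0.0, sigma, size=(N, trials))
        rec = np.linalg.solve(Wm, noise)
        theo = float(np.sqrt(N) / (np.linalg.norm(np.linalg.inv(Wm)) or np.nan))
    per_element_std = rec.std(axis=1, ddof=1)
    gain = sigma / per_element_std.mean()
    stderr = gain * per_element_std.std(ddof=1) / (
        per_element_std.mean() * np.sqrt(N))
    return GainReport(N=N, theoretical_gain=theo, empirical_gain=float(gain),
                      std_error=float(stderr), trials=trials, seed=seed)


def random_mask_gain(N: int, density: float = 0.5, trials: int = 10,
                     seed: int = 0, cyclic: bool = True,
                     max_redraws: int = 50) -> GainReport:
    """SNR gain of a random binary mask ensemble of order N.

    For each trial a random binary multiplexing matrix is drawn and
    pseudo-inverted; the per-trial gain is 1 over the RMS per-element
    reconstruction noise std, i.e. sqrt(N) / ||M^+||_F.  With
    ``cyclic=True`` (default) the draw is a Bernoulli(density) code
    cyclically shifted into a circulant matrix — the ensemble a scanned
    amplitude mask can physically realize, and the like-for-like
    comparison to the cyclic S-matrix; its pseudo-inverse Frobenius
    norm is evaluated exactly through the circulant eigenvalues.  With
    ``cyclic=False`` the matrix is i.i.d. Bernoulli entrywise, which
    inverts far worse (hard-edge smallest singular values).  Singular
    draws are redrawn (counted, capped at ``max_redraws``).  The
    report's ``theoretical_gain`` carries the S-matrix value sqrt(N)/2
    for comparison.
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    gains = []
    redraws = 0
    for _ in range(trials):
        for _attempt in range(max_redraws + 1):
            if cyclic:
                row = (rng.random(N) < density).astype(np.float64)
                lam = np.fft.fft(row)
                if np.abs(lam).min() > 1e-9:
                    fro = float(np.sqrt(np.sum(1.0 / np.abs(lam) ** 2)))
                    break
            else:
                M = (rng.random((N, N)) < density).astype(np.float64)
                if np.linalg.matrix_rank(M) == N:
                    fro = float(np.linalg.norm(np.linalg.pinv(M)))
                    break
            redraws += 1
        else:
            raise RuntimeError(
                f"no invertible Bernoulli({density}) draw of order {N} after "
                f"{max_redraws} redraws")
        gains.append(np.sqrt(N) / fro)
    gains = np.asarray(gains)
    return GainReport(N=N, theoretical_gain=float(np.sqrt(N) / 2.0),
                      empirical_gain=float(gains.mean()),
                      std_error=float(gains.std(ddof=1) / np.sqrt(trials))
                      if trials > 1 else 0.0,
                      trials=trials, seed=seed, redraws=redraws)
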