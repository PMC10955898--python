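"""Cyclic S-matrix code design for coded-aperture acoustic masks.

A single ultrasound detector can be turned into a virtual 2D detector
array by scanning a binary amplitude mask in front of it.  The mask is
built from a cyclic S-matrix: a binary matrix whose every row is a
circular shift of the first, whose rows have weight (N+1)/2, and which
admits an exact closed-form inverse

    W^-1 = 2/(N+1) * (2 W^T - J),    J = all-ones.

The first row is a twin-prime sequence of length N = P*Q (P, Q prime,
Q = P + 2), derived from the classical twin-prime difference set.  The
1D code is folded onto a P x Q grid by Chinese-remainder indexing
k <-> (k mod P, k mod Q), under which 2D shifts of the physical mask
correspond to 1D cyclic shifts of the code, so a 2D raster scan of the
mask realizes every row of W.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sympy import isprime

__all__ = [
    "CyclicSCode",
    "CodingMatrix",
    "MaskLayout",
    "twin_prime_sequence",
    "build_coding_matrix",
    "invert_coding_matrix",
    "apply_inverse",
    "fold_to_mask",
    "pattern_for_shift",
    "shift_to_row",
]


def _legendre(a: int, p: int) -> int:
    """Legendre symbol (a/p) for odd prime p; 0 when p divides a."""
    a %= p
    if a == 0:
        return 0
    return 1 if pow(a, (p - 1) // 2, p) == 1 else -1


def _check_circular_autocorrelation(bits: np.ndarray) -> bool:
    """True iff the cyclic matrix built from ``bits`` satisfies the
    S-matrix identity W W^T = (N+1)/4 * (I + J).

    Equivalent to the circular autocorrelation of ``bits`` being
    (N+1)/2 at lag 0 and (N+1)/4 at every other lag; checked in
    O(N log N) via the FFT rather than by materializing W.
    """
    n = bits.size
    f = np.fft.rfft(bits.astype(np.float64))
    corr = np.fft.irfft(f * np.conj(f), n=n)
    expected = np.full(n, (n + 1) / 4.0)
    expected[0] = (n + 1) / 2.0
    return bool(np.allclose(corr, expected, atol=1e-6))


def twin_prime_sequence(P: int, Q: int) -> np.ndarray:
    """Binary twin-prime code of length N = P*Q with weight (N+1)/2.

    The twin-prime difference set on Z_N,

        D = {multiples of Q} ∪ {k coprime to N : chi_P(k)*chi_Q(k) = +1}

    (chi = Legendre symbol), has size (N-1)/2.  The code is the
    indicator of the *complement* of D, so that the row weight is
    (N+1)/2 and the cyclic matrix it generates is an S-matrix with the
    closed-form inverse.  The identity is verified at construction.

    Parameters
    ----------
    P, Q : int
        Twin primes with Q = P + 2.

    Returns
    -------
    numpy.ndarray of uint8, shape (P*Q,)
        1 = open aperture, 0 = blocked.
    """
    if not isprime(P):
        raise ValueError(f"P = {P} is not prime")
    if not isprime(Q):
        raise ValueError(f"Q = {Q} is not prime")
    if Q - P != 2:
        raise ValueError(f"(P, Q) = ({P}, {Q}) are not twin primes: Q - P = {Q - P} != 2")

    N = P * Q
    in_D = np.zeros(N, dtype=bool)
    in_D[::Q] = True  # multiples of Q, including 0
    k = np.arange(N)
    chi_p = np.array([_legendre(int(v), P) for v in k % P])
    chi_q = np.array([_legendre(int(v), Q) for v in k % Q])
    in_D |= chi_p * chi_q == 1

    bits = (~in_D).astype(np.uint8)
    assert int(bits.sum()) == (N + 1) // 2, "twin-prime code has wrong weight"
    if not _check_circular_autocorrelation(bits):
        raise RuntimeError(
            f"twin-prime code for (P, Q) = ({P}, {Q}) violates the S-matrix identity"
        )
    return bits


@dataclass(frozen=True)
class CyclicSCode:
    """A twin-prime binary code and the order of its cyclic S-matrix."""

    P: int
    Q: int
    bits: np.ndarray = field(repr=False)

    @property
    def N(self) -> int:
        return self.P * self.Q

    @classmethod
    def from_primes(cls, P: int, Q: int) -> "CyclicSCode":
        return cls(P=P, Q=Q, bits=twin_prime_sequence(P, Q))

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.shape != (self.P * self.Q,):
            raise ValueError("bits length must equal P*Q")
        if int(bits.sum()) != (self.P * self.Q + 1) // 2:
            raise ValueError("code weight must be (N+1)/2")
        object.__setattr__(self, "bits", bits)


@dataclass(frozen=True)
class CodingMatrix:
    """Cyclic S-matrix W; row i is row 0 circularly shifted by i,
    i.e. W[i, k] = bits[(k + i) mod N]."""

    N: int
    W: np.ndarray = field(repr=False)

    @classmethod
    def from_code(cls, code: CyclicSCode) -> "CodingMatrix":
        return build_coding_matrix(code)


def build_coding_matrix(code: CyclicSCode) -> CodingMatrix:
    """Stack all N cyclic shifts of the code into the N x N matrix W."""
    bits = code.bits
    N = code.N
    idx = (np.arange(N)[:, None] + np.arange(N)[None, :]) % N
    return CodingMatrix(N=N, W=bits[idx].astype(np.int8))


def _is_s_matrix(W: np.ndarray) -> bool:
    N = W.shape[0]
    if W.shape != (N, N):
        return False
    if not np.isin(W, (0, 1)).all():
        return False
    # row 0 must regenerate every row by cyclic shifting
    idx = (np.arange(N)[:, None] + np.arange(N)[None, :]) % N
    if not np.array_equal(W, W[0][idx]):
        return False
    return _check_circular_autocorrelation(W[0].astype(np.float64))


def invert_coding_matrix(W: CodingMatrix | np.ndarray) -> np.ndarray:
    """Closed-form inverse W^-1 = 2/(N+1) * (2 W^T - J).

    Every entry is +-2/(N+1).  Raises if W is not a valid cyclic
    S-matrix; there is deliberately no numerical-inverse fallback.
    """
    Wm = W.W if isinstance(W, CodingMatrix) else np.asarray(W)
    N = Wm.shape[0]
    if not _is_s_matrix(Wm):
        raise ValueError("not an S-matrix: W fails the cyclic S-matrix identity")
    return (2.0 / (N + 1)) * (2.0 * Wm.T.astype(np.float64) - 1.0)


def apply_inverse(W: CodingMatrix, Y: np.ndarray) -> np.ndarray:
    """Compute W^-1 Y = 2/(N+1) * (2 W^T Y - colsum(Y)) without
    materializing W^-1 or the all-ones matrix."""
    Wm = W.W.astype(np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape[0] != W.N:
        raise ValueError(f"Y has {Y.shape[0]} rows, expected N = {W.N}")
    return (2.0 / (W.N + 1)) * (2.0 * (Wm.T @ Y) - Y.sum(axis=0, keepdims=True))


def _crt_index(P: int, Q: int) -> np.ndarray:
    """crt[r, s] = the unique k in 0..PQ-1 with k = r (mod P), k = s (mod Q)."""
    k = np.arange(P * Q)
    crt = np.empty((P, Q), dtype=np.int64)
    crt[k % P, k % Q] = k
    return crt


@dataclass(frozen=True)
class MaskLayout:
    """The 2D folded code: P x Q unit cell and its (2P-1) x (2Q-1)
    cyclic extension, which is the physical mask.

    Mask cell (0, 0) is the coordinate origin of the whole pipeline;
    cell (i, j) sits at (i*pitch, j*pitch) on the mask plane.  Lengths
    in mm.
    """

    code: CyclicSCode
    pitch: float
    aperture_diameter: float
    unit_cell: np.ndarray = field(repr=False)
    extended: np.ndarray = field(repr=False)

    @property
    def P(self) -> int:
        return self.code.P

    @property
    def Q(self) -> int:
        return self.code.Q

    @property
    def aperture_area(self) -> float:
        """dA, mm^2."""
        return float(np.pi * (self.aperture_diameter / 2.0) ** 2)

    @property
    def crt_index(self) -> np.ndarray:
        return _crt_index(self.P, self.Q)


def fold_to_mask(code: CyclicSCode, pitch: float = 1.0,
                 aperture_diameter: float = 0.5) -> MaskLayout:
    """Fold the 1D code onto the 2D scanning mask.

    Chinese-remainder indexing places bit k at unit cell
    (k mod P, k mod Q); the physical mask is the (2P-1) x (2Q-1)
    cyclic extension so every shift (q, p) with 0 <= q < P,
    0 <= p < Q exposes a full P x Q code window.
    """
    if aperture_diameter > pitch:
        raise ValueError(
            f"aperture diameter {aperture_diameter} mm exceeds grid pitch {pitch} mm: "
            "apertures on adjacent grid points would overlap"
        )
    P, Q = code.P, code.Q
    unit = np.empty((P, Q), dtype=np.uint8)
    k = np.arange(code.N)
    unit[k % P, k % Q] = code.bits
    ii = np.arange(2 * P - 1) % P
    jj = np.arange(2 * Q - 1) % Q
    extended = unit[np.ix_(ii, jj)]
    return MaskLayout(code=code, pitch=float(pitch),
                      aperture_diameter=float(aperture_diameter),
                      unit_cell=unit, extended=extended)


def pattern_for_shift(mask: MaskLayout, q: int, p: int) -> np.ndarray:
    """The P x Q aperture window exposed at mask shift (q, p).

    Flattened by CRT indexing it equals row ``shift_to_row(mask, q, p)``
    of the coding matrix.
    """
    if not (0 <= q < mask.P and 0 <= p < mask.Q):
        raise ValueError(
            f"shift ({q}, {p}) out of range [0, {mask.P}) x [0, {mask.Q})"
        )
    return mask.extended[q:q + mask.P, p:p + mask.Q]


def shift_to_row(mask: MaskLayout, q: int, p: int) -> int:
    """Row index m of W measured at 2D shift (q, p): the unique m with
    m = q (mod P) and m = p (mod Q).  Verified against brute-force
    window enumeration in the test suite."""
    if not (0 <= q < mask.P and 0 <= p < mask.Q):
        raise ValueError(f"shift ({q}, {p}) out of range")
    return int(mask.crt_index[q, p])
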