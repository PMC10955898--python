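# Methods

## Coded-aperture multiplexing model

A binary amplitude mask with apertures of area dA on a Cartesian grid
of pitch Δ is scanned in discrete steps of Δ in front of a single
integrating ("bucket") ultrasound detector. Writing p(x, y, t) for the
incident pressure on the mask plane and M for the binary pattern, each
mask position (q, p) yields

    u_qp(t) = dA · Σ_ij p(iΔ, jΔ, t) · M[i+q, j+p],

i.e. for each time sample a linear multiplexed measurement u = W p,
where W is N×N binary with N = P·Q grid sites. The package restricts W
to cyclic S-matrices: every row a circular shift of the first, row
weight (N+1)/2. These are the SNR-optimal binary multiplexing matrices
and admit the exact inverse

    W⁻¹ = 2/(N+1) · (2Wᵀ − J),

verified here both symbolically (W·W⁻¹ = I follows from the Gram
identity W·Wᵀ = (N+1)/4 · (I + J)) and numerically to 1e−10 at orders
15, 143 and 1763. Demultiplexing is a single matrix product — linear,
regularization-free, applied as 2/(N+1)·(2WᵀY − colsum Y) without
materializing W⁻¹ or J.

### Twin-prime code

The generating row is derived from the twin-prime difference set on
Z_N, N = P·Q with Q = P + 2 both prime:

    D = {multiples of Q} ∪ {k coprime to N : χ_P(k)·χ_Q(k) = +1},

|D| = (N−1)/2 (χ = Legendre symbol). The code is the indicator of the
**complement** of D: the complement is itself a difference set with
parameters (N, (N+1)/2, (N+1)/4), which is exactly the autocorrelation
an S-matrix row requires. The direct indicator of D does *not* satisfy
the S-matrix identity (checked by brute force at all orders up to
1763); the complement does at every order, and the constructor verifies
the identity via the FFT circular autocorrelation and fails loudly if
violated.

### 2D folding and the shift/row correspondence

The 1D code is folded onto the P×Q unit cell by Chinese-remainder
indexing, bit k ↦ cell (k mod P, k mod Q); the physical mask is the
(2P−1)×(2Q−1) cyclic extension (6885 sites for P = 41, Q = 43). CRT
indexing is the unique linear folding for coprime dimensions under
which a 2D mask shift (q, p) acts as a 1D cyclic shift of the code, so
each scan position exposes one row of W: the window at shift (q, p)
flattens to row m with m ≡ q (mod P), m ≡ p (mod Q). This
correspondence is verified by exhaustive window enumeration at orders
15 and 143 in the test suite, and the same indexing is used on the
demultiplexing side, so the mapping can never drift between modules.
Bit 0 sits at mask cell (0, 0), the coordinate origin for the whole
pipeline.

## Forward model

Each point absorber launches a spherically spreading transient:
p(t) = (A/r)·h(t − r/c) at distance r. The band-limited bipolar
impulse h is an odd Gabor wavelet

    h(τ) = −sin(2π f₀ τ) · exp(−τ²/2σ_t²)

with f₀ = 4.8 MHz, the centre of the detector band (3.1–6.5 MHz, a
5 MHz unfocused immersion transducer). The odd phase puts the arrival
time at the central zero crossing — the band-limited form of the
N-shaped thermoacoustic signature, with the source-term time derivative
absorbed into h — and the closed form evaluates exactly at arbitrary
fractional delays, so no waveform interpolation enters the simulator.
The envelope width σ_t is tied to the detector bandwidth through the
textbook axial-resolution identity for Gaussian pulses,
FWHM_axial = 0.88·c/BW: the Gaussian amplitude spectrum has a −6 dB
full width of BW = 3.4 MHz (σ_f = BW/(2√(2 ln 2)) ≈ 1.44 MHz,
σ_t ≈ 0.110 µs). Its −3 dB power band, [3.6, 6.0] MHz, lies inside the
transducer's rated band.

Aperture averaging uses a deterministic 7-point disk quadrature
(centre + 6 points at radius 0.4·diameter, equal weights); a 1-point
mode degenerates to the grid-node waveform for exact tests. The
mask-to-detector propagation over the standoff d is modeled as a pure
delay d/c — the first-order bucket-detector approximation — entering
only the recorded time axis, and is removed in reconstruction by
t_grid = t_sampled − d/c. Sensor noise is i.i.d. additive white
Gaussian per sample, seeded.

Interlaced scanning at sub-pitch steps (Δ/α, Δ/β) is simulated by
evaluating the pressure on the αP × βQ fine grid and multiplexing each
of the α·β coarse sub-grids independently; Y stores the blocks
offset-major, and assembly interleaves the recovered grids at fine
pitch (500 µm for Δ = 1 mm, α = β = 2).

## Reconstruction

Universal back-projection for planar detection: each virtual aperture
is treated as a point detector at its grid node; the filtered term
b(t) = 2p − 2t·∂p/∂t (central finite differences; t is the corrected
mask-plane time) is evaluated at the voxel flight time by linear
interpolation, weighted by cosθ/r² (θ to the mask normal), summed and
normalized by the summed weights. Voxels whose flight time leaves the
acquisition window contribute nothing and are counted in the log. An
optional Fourier ×4 upsampling of b is available for resolution
studies; 1D voxel lines through the peak (the `ubp_profile` helper) are
the cheaper default for FWHM work.

The reconstruction is reported unrectified. Along z it is bipolar —
the band has no low-frequency content — so axial widths are measured on
the envelope (magnitude of the analytic signal along z), lateral widths
on the raw profile, both as interpolated half-maximum crossings through
the global peak.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| P, Q | 41, 43 | twin primes; N = 1763 virtual elements |
| Δ (pitch) | 1.0 mm | aperture grid step; scan step |
| aperture diameter | 0.5 mm | must be ≤ Δ; sets lateral resolution |
| band | 3.1–6.5 MHz | detector −3 dB band; BW = 3.4 MHz |
| d | 2.7 mm | mask-to-detector standoff (pure delay) |
| c | 1.49 mm/µs | speed of sound in water, configurable |
| fs, N_t | 50 MHz, 1024 | sampling (window 20.5 µs ≈ 30 mm depth) |
| α, β | 1, 1 | interlace factors |
| voxel | 0.1 mm | characterization boxes; 0.25 mm for phantoms |

The sampling rate is a package choice (well above the 13 MHz Nyquist
requirement of the band); the characterization geometry (source at
12.7 mm, d = 2.7 mm, 41×43 single-pitch scan) mirrors the physical
setup the design targets.

## SNR analysis

Every row of W⁻¹ has norm 2√N/(N+1), so demultiplexed noise has
per-element std σ·2√N/(N+1) and the gain over a raster scan is
(N+1)/(2√N) ≈ √N/2 — 21.0 for N = 1763. Monte-Carlo estimates
(demultiplexing pure-noise draws) agree with the analytic value within
error bars; the identity matrix reproduces gain 1.

The random-mask comparison draws Bernoulli(0.5) binary *codes* and
cyclically shifts them into circulant multiplexing matrices — the
ensemble a scanned amplitude mask can physically realize, and the
like-for-like comparison to the cyclic S-matrix. The per-draw gain is
√N/‖M⁺‖_F (RMS per-element noise), with the circulant pseudo-inverse
norm evaluated exactly through its FFT eigenvalues; singular draws are
redrawn with a capped, reported count. At N = 1763 this ensemble
reaches a gain of ≈ 6.5–7.6, about one third of the S-matrix value.
A fully i.i.d. entrywise Bernoulli ensemble (`cyclic=False`) is far
worse still — its pseudo-inverse is dominated by near-singular
directions and the RMS gain collapses below 1 — which is why the
structured/random comparison is made within the cyclic family.

## What the synthetic data does and does not emulate

The generator reproduces the geometry and signal structure of a real
planar coded-aperture acquisition: spherical spreading, band-limited
bipolar transients, aperture-area averaging, exact binary multiplexing,
the d/c standoff delay, interlacing, and white sensor noise. It does
not model acoustic diffraction between mask and detector (beyond the
delay), edge-diffracted parasitic signals, the finite detector
footprint, frequency-dependent attenuation, heterogeneous sound speed,
or the transducer's full impulse response — so passing tests validate
the coding/decoding mathematics and the reconstruction geometry, not
hardware-specific effects. Measured axial widths in a real system can
beat the Gaussian-band estimate if the true response has a flatter
passband; lateral widths track the aperture diameter in both.

## Numerical choices and degenerate inputs

- S-matrix identity checked at construction via FFT autocorrelation
  (O(N log N)); `invert_coding_matrix` refuses non-S-matrices rather
  than falling back to a numerical inverse.
- Demultiplexing never forms J; the column-sum broadcast keeps the
  apply step at one GEMM.
- UBP derivative: central differences; linear time interpolation;
  out-of-window flight times contribute zero and are counted.
- FWHM: unique interior maximum required; missing half-maximum
  crossings raise "peak not resolved" instead of returning a width.
- Aperture diameter > pitch, non-twin primes, negative z sources,
  mismatched shapes, and singular random-mask ensembles all raise
  immediately with the failing condition named.

## Problem sizes used in the shipped checks

Full-order (N = 1763) runs are used for code identities, the inverse,
the SNR gain and the point-spread characterization (1024 time samples,
31³ coarse voxels at 100 µm plus 20 µm line profiles); exhaustive
window enumeration and Monte-Carlo agreement run at N = 15 and 143.
These sizes reproduce every headline quantity while keeping the whole
suite interactive.

## Known limitations

- Discrete-step interlacing only; continuous-scan oversampling (finer
  step along one axis with shared code rows) is not simulated.
- The bucket detector is ideal and unbounded: apertures outside a real
  detector's footprint, and the resulting parasitic signals, are not
  modeled.
- Phantom curves are discretized into independent point sources; no
  finite absorber size or optical fluence model.
- Only the twin-prime S-matrix family is implemented (no
  quadratic-residue codes, no ±1 Hadamard masks).
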