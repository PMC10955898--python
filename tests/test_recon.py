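"""Demultiplexing, virtual-array assembly, back-projection, resolution."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oatmask import (CyclicSCode, DetectorModel, PointSource, ScanConfig,
                     Volume, assemble_grid, build_coding_matrix,
                     correct_time_axis, demultiplex, envelope_z, fold_to_mask,
                     grid_pressure, invert_coding_matrix, map_projection,
                     measure_fwhm, multiplex, peak_position, ubp_profile,
                     ubp_reconstruct)


def simulate_point(P, Q, position, n_t=512, alpha=1, beta=1, d=2.7):
    code = CyclicSCode.from_primes(P, Q)
    mask = fold_to_mask(code)
    W = build_coding_matrix(code)
    det = DetectorModel()
    scan = ScanConfig(n_t=n_t, alpha=alpha, beta=beta, d=d)
    src = [PointSource(position=position)]
    p = grid_pressure(src, mask, det, scan)
    data = multiplex(p, W, mask, scan)
    return mask, W, scan, p, data


class TestDemultiplex:
    def test_noiseless_roundtrip_exact(self, W15, mask15, detector,
                                       scan_small):
        src = [PointSource(position=(1.0, 2.0, 12.7))]
        p = grid_pressure(src, mask15, detector, scan_small)
        data = multiplex(p, W15, mask15, scan_small)
        rec = demultiplex(data, W15)
        virt = assemble_grid(rec, mask15, scan_small, t_sampled=data.t_sampled)
        scale = np.abs(p).max() * mask15.aperture_area
        assert np.abs(virt.signals - mask15.aperture_area * p).max() / scale < 1e-9

    def test_dense_inverse_path_agrees(self, W15, mask15, detector,
                                       scan_small):
        src = [PointSource(position=(0.5, 1.5, 11.0))]
        p = grid_pressure(src, mask15, detector, scan_small)
        data = multiplex(p, W15, mask15, scan_small)
        assert np.allclose(demultiplex(data, W15),
                           demultiplex(data, invert_coding_matrix(W15)),
                           atol=1e-12)

    def test_row_count_mismatch(self, W15):
        with pytest.raises(ValueError, match="rows"):
            demultiplex(np.zeros((14, 8)), W15)

    def test_noise_amplification_matches_row_norm(self, W15, rng):
        """Gaussian noise sigma on Y demultiplexes to per-element std
        sigma * 2 sqrt(N)/(N+1)."""
        sigma, trials, N = 1.0, 40_000, 15
        noise = rng.normal(0, sigma, size=(N, trials))
        rec = demultiplex(noise, W15)
        expected = sigma * 2 * np.sqrt(N) / (N + 1)
        assert rec.std(axis=1).mean() == pytest.approx(expected, rel=0.05)


class TestAssembleGrid:
    def test_plain_reshape_alpha_beta_one(self, W15, mask15, detector,
                                          scan_small):
        src = [PointSource(position=(1, 2, 12.7))]
        p = grid_pressure(src, mask15, detector, scan_small)
        data = multiplex(p, W15, mask15, scan_small)
        virt = assemble_grid(demultiplex(data, W15), mask15, scan_small,
                             t_sampled=data.t_sampled)
        assert virt.signals.shape == (3, 5, scan_small.n_t)
        assert virt.pitch_x == 1.0 and virt.pitch_y == 1.0

    def test_interlaced_pitch_500um(self, W15, mask15, detector):
        scan = ScanConfig(n_t=128, alpha=2, beta=2)
        src = [PointSource(position=(1, 2, 3.0))]
        p = grid_pressure(src, mask15, detector, scan)
        data = multiplex(p, W15, mask15, scan)
        virt = assemble_grid(demultiplex(data, W15), mask15, scan,
                             t_sampled=data.t_sampled)
        assert virt.signals.shape == (6, 10, 128)
        assert virt.pitch_x == 0.5 and virt.pitch_y == 0.5
        # interleaved grids recombine to the full fine-pitch pressure
        assert np.allclose(virt.signals, mask15.aperture_area * p, atol=1e-12)

    def test_missing_mask_rejected(self, scan_small):
        with pytest.raises(ValueError, match="fold_to_mask"):
            assemble_grid(np.zeros((15, 512)), None, scan_small)

    def test_earliest_arrival_at_nearest_node(self, W15, mask15, detector):
        scan = ScanConfig(n_t=1024)
        src = [PointSource(position=(2.0, 3.0, 12.7))]
        p = grid_pressure(src, mask15, detector, scan)
        data = multiplex(p, W15, mask15, scan)
        virt = assemble_grid(demultiplex(data, W15), mask15, scan,
                             t_sampled=data.t_sampled)
        from scipy.signal import hilbert
        arrivals = np.argmax(np.abs(hilbert(virt.signals, axis=2)), axis=2)
        i, j = np.unravel_index(np.argmin(arrivals), arrivals.shape)
        assert (i, j) == (2, 3)


class TestTimeAxis:
    def test_zero_distance_identity(self):
        t = np.linspace(0, 10, 11)
        assert np.array_equal(correct_time_axis(t, 0.0, 1.5), t)

    def test_shift_arithmetic(self):
        t = np.linspace(0, 10, 11)
        assert np.allclose(correct_time_axis(t, 3.0, 1.5), t - 2.0)

    def test_roundtrip_restores_arrival(self, W15, mask15, detector):
        """The simulator delays by d/c; time correction restores the
        mask-plane arrival r/c at every aperture within one sample."""
        scan = ScanConfig(n_t=1024, d=2.7)
        src = [PointSource(position=(1.0, 2.0, 12.7))]
        p = grid_pressure(src, mask15, detector, scan)
        data = multiplex(p, W15, mask15, scan)
        virt = assemble_grid(demultiplex(data, W15), mask15, scan,
                             t_sampled=data.t_sampled)
        from scipy.signal import hilbert
        for (i, j) in [(0, 0), (1, 2), (2, 4)]:
            r = np.linalg.norm([i - 1.0, j - 2.0, 12.7])
            k = np.argmax(np.abs(hilbert(virt.signals[i, j])))
            assert abs(virt.t_grid[k] - r / scan.c) <= 1.5 / scan.fs


class TestUBP:
    def test_point_source_localization(self):
        mask, W, scan, p, data = simulate_point(3, 5, (1.0, 2.0, 12.7),
                                                n_t=1024)
        virt = assemble_grid(demultiplex(data, W), mask, scan,
                             t_sampled=data.t_sampled)
        vol = ubp_reconstruct(virt, (0.0, 1.0, 11.7), (21, 21, 21), 0.1,
                              scan.c)
        assert np.allclose(peak_position(vol), (1.0, 2.0, 12.7), atol=0.1)

    def test_amplitude_linearity(self, mask15, W15, detector, scan_small):
        def recon(amp):
            src = [PointSource(position=(1.0, 2.0, 12.7), amplitude=amp)]
            p = grid_pressure(src, mask15, detector, scan_small)
            data = multiplex(p, W15, mask15, scan_small)
            virt = assemble_grid(demultiplex(data, W15), mask15, scan_small,
                                 t_sampled=data.t_sampled)
            return ubp_reconstruct(virt, (0.5, 1.5, 12.2), (11, 11, 11),
                                   0.1, scan_small.c)
        v1, v2 = recon(1.0), recon(2.0)
        assert np.allclose(v2.values, 2 * v1.values, rtol=1e-9, atol=1e-12)

    def test_axial_profile_bipolar(self):
        """The band-pass reconstruction along z has negative lobes
        around the positive peak (no low-frequency content)."""
        mask, W, scan, p, data = simulate_point(3, 5, (1.0, 2.0, 12.7),
                                                n_t=1024)
        virt = assemble_grid(demultiplex(data, W), mask, scan,
                             t_sampled=data.t_sampled)
        _, prof = ubp_profile(virt, (1.0, 2.0, 12.7), 2, 1.5, 0.025, scan.c)
        assert prof.max() > 0 and prof.min() < 0
        assert prof.min() < -0.1 * prof.max()

    def test_nonincreasing_time_axis_rejected(self, mask15, scan_small, W15,
                                              detector):
        src = [PointSource(position=(1, 2, 12.7))]
        p = grid_pressure(src, mask15, detector, scan_small)
        data = multiplex(p, W15, mask15, scan_small)
        virt = assemble_grid(demultiplex(data, W15), mask15, scan_small,
                             t_sampled=data.t_sampled)
        bad = type(virt)(signals=virt.signals, pitch_x=1.0, pitch_y=1.0,
                         t_grid=virt.t_grid[::-1])
        with pytest.raises(ValueError, match="strictly increasing"):
            ubp_reconstruct(bad, (0, 0, 12), (4, 4, 4), 0.2, scan_small.c)

    def test_localization_random_sources(self):
        """Reconstructed peak within one voxel of truth for seeded
        random point-source positions across the field of view."""
        rng = np.random.default_rng(2024)
        code = CyclicSCode.from_primes(11, 13)
        mask = fold_to_mask(code)
        W = build_coding_matrix(code)
        det = DetectorModel()
        scan = ScanConfig(n_t=768)
        for _ in range(8):
            pos = rng.uniform([2.0, 2.0, 9.0], [8.0, 10.0, 14.0])
            src = [PointSource(position=tuple(pos))]
            p = grid_pressure(src, mask, det, scan)
            data = multiplex(p, W, mask, scan)
            virt = assemble_grid(demultiplex(data, W), mask, scan,
                                 t_sampled=data.t_sampled)
            origin = pos - 1.0
            vol = ubp_reconstruct(virt, tuple(origin), (21, 21, 21), 0.1,
                                  scan.c)
            assert np.all(np.abs(np.array(peak_position(vol)) - pos) <= 0.1 + 1e-9)

    def test_noise_only_volume_is_homogeneous(self, W15, mask15):
        """Pure sensor noise reconstructs to a homogeneous near-zero
        volume: mean ~ 0 and no voxel beyond 5 sigma of the voxel
        distribution."""
        scan = ScanConfig(n_t=512)
        rng = np.random.default_rng(7)
        from oatmask import MultiplexedData
        Y = rng.normal(0, 1.0, size=(15, 512))
        data = MultiplexedData(Y=Y, t_sampled=scan.time_axis + scan.d / scan.c,
                               offsets=scan.offsets, scan=scan)
        virt = assemble_grid(demultiplex(data, W15), mask15, scan,
                             t_sampled=data.t_sampled)
        vol = ubp_reconstruct(virt, (0.0, 1.0, 4.0), (15, 15, 15), 0.1,
                              scan.c)
        v = vol.values
        assert abs(v.mean()) < 5 * v.std() / np.sqrt(v.size)
        assert np.abs(v - v.mean()).max() < 5 * v.std()


class TestEnvelopeAndMAP:
    def test_envelope_bounds_signal(self):
        z = np.linspace(0, 4 * np.pi, 64)
        vals = np.cos(z)[None, None, :] * np.ones((3, 3, 1))
        vol = Volume(values=vals, voxel_size=(0.1, 0.1, 0.1),
                     origin=(0, 0, 0))
        env = envelope_z(vol)
        assert np.all(env.values >= 0)
        assert np.all(env.values >= np.abs(vol.values) - 1e-12)

    def test_cosine_envelope_constant(self):
        z = np.arange(256)
        vals = np.cos(2 * np.pi * z / 16.0)[None, None, :] * np.ones((1, 1, 1))
        vol = Volume(values=vals, voxel_size=(0.1, 0.1, 0.1), origin=(0, 0, 0))
        env = envelope_z(vol).values[0, 0, 32:-32]
        assert np.abs(env - 1.0).max() < 0.02

    def test_envelope_needs_depth(self):
        vol = Volume(values=np.zeros((4, 4, 4)), voxel_size=(0.1,) * 3,
                     origin=(0, 0, 0))
        with pytest.raises(ValueError, match="at least 8"):
            envelope_z(vol)

    def test_map_constant_and_single_voxel(self):
        vals = np.zeros((5, 6, 7))
        vals[2, 3, 4] = 2.0
        vol = Volume(values=vals, voxel_size=(0.1,) * 3, origin=(0, 0, 0))
        img = map_projection(vol, "z")
        assert img.shape == (5, 6)
        assert img[2, 3] == 2.0 and np.count_nonzero(img) == 1
        const = Volume(values=np.full((4, 4, 8), 3.0), voxel_size=(0.1,) * 3,
                       origin=(0, 0, 0))
        assert np.all(map_projection(const, "x") == 3.0)


class TestFWHM:
    def test_triangle_half_base(self):
        x = np.linspace(-1, 1, 201)
        tri = np.clip(1 - np.abs(x), 0, None)
        assert measure_fwhm(tri, 0.01) == pytest.approx(1.0, abs=1e-9)

    @given(sigma=st.floats(min_value=0.05, max_value=0.4))
    def test_gaussian_width_property(self, sigma):
        """FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma to within 1%."""
        x = np.linspace(-2, 2, 401)
        y = np.exp(-0.5 * (x / sigma) ** 2)
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert measure_fwhm(y, x[1] - x[0]) == pytest.approx(expected,
                                                             rel=0.01)

    def test_gaussian_100um(self):
        x = np.linspace(-1000, 1000, 2001)  # um
        y = np.exp(-0.5 * (x / 100.0) ** 2)
        assert measure_fwhm(y, 1.0) == pytest.approx(235.48, rel=0.01)

    def test_unresolved_peak_errors(self):
        with pytest.raises(ValueError, match="peak not resolved"):
            measure_fwhm(np.array([0.9, 1.0, 0.9, 0.8, 0.7]), 1.0)
        with pytest.raises(ValueError, match="boundary"):
            measure_fwhm(np.array([1.0, 0.4, 0.1]), 1.0)

    def test_theoretical_axial_limit(self):
        det = DetectorModel()
        assert det.axial_resolution_limit(1.48) * 1e3 == pytest.approx(383,
                                                                       abs=3)
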