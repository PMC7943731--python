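"""Measurement operators: construction, forward/adjoint algebra, RIP."""

import numpy as np
import pytest

from deeppat.errors import (DimensionMismatchError, InvalidArgumentError,
                            InvalidGeometryError)
from deeppat.sensing import (MeasurementMatrix, PATGeometry,
                             build_gaussian_matrix, build_pat_matrix_freq,
                             build_pat_matrix_time, desk_geometry, empirical_rip,
                             measure, proxy)


def identity_matrix(n):
    return MeasurementMatrix(np.eye(n * n), "custom", n, 1.0)


class TestGaussianMatrix:
    def test_shapes(self):
        assert build_gaussian_matrix(8, 0.5, 1).entries.shape == (32, 64)
        assert build_gaussian_matrix(8, 1.0, 1).entries.shape == (64, 64)

    def test_entry_moments(self):
        """Entries are i.i.d. N(0, 1/M): sample mean within 3 standard
        errors of 0 and sample variance within 10% of 1/M."""
        K = build_gaussian_matrix(16, 0.3, 5)
        m, n2 = K.entries.shape
        se = (1.0 / np.sqrt(m)) / np.sqrt(m * n2)
        assert abs(K.entries.mean()) < 3 * se
        assert K.entries.var() == pytest.approx(1.0 / m, rel=0.10)

    def test_ratio_stored_consistently(self):
        for ratio in (0.05, 0.3, 1.0):
            K = build_gaussian_matrix(10, ratio, 0)
            assert K.undersampling_ratio == K.entries.shape[0] / 100

    def test_ratio_validation(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(InvalidArgumentError):
                build_gaussian_matrix(8, bad, 0)


class TestPATTime:
    def test_exact_travel_time_hit(self):
        """A pixel whose distance equals c*s*dt exactly lands amplitude
        1/(2 pi c) in row (h, s)."""
        g = desk_geometry(grid_side=16, num_transducers=4, time_samples=60)
        d = g.distances()
        c = g.sound_speed
        h_idx, px_idx = 2, 37
        s = 5  # force t = s*dt to hit this pixel's travel time exactly
        g2 = PATGeometry(num_transducers=4, grid_side=16, grid_extent=25.0,
                         time_samples=60, dt=float(d[h_idx, px_idx] / c / s))
        K = build_pat_matrix_time(g2)
        row = h_idx * 60 + (s - 1)
        assert K.entries[row, px_idx] == pytest.approx(1.0 / (2 * np.pi * c))

    def test_no_sample_before_first_arrival_gives_zero_matrix(self):
        g = PATGeometry(num_transducers=4, grid_side=16, grid_extent=25.0,
                        time_samples=3, dt=0.001)
        K = build_pat_matrix_time(g)
        assert np.count_nonzero(K.entries) == 0

    def test_rows_match_distance_binning_oracle(self):
        """Every row's support equals an exhaustive enumeration of pixel
        travel times binned to within dt/2 of that row's sample time."""
        g = desk_geometry(grid_side=16, num_transducers=8, time_samples=40)
        K = build_pat_matrix_time(g)
        c, dt = g.sound_speed, g.dt
        amp = 1.0 / (2 * np.pi * c)
        tpos = g.transducer_positions()
        ppos = g.pixel_positions()
        for h in range(8):
            for s in range(1, 41):
                t = s * dt
                expect = np.zeros(256)
                for p in range(256):
                    dist = np.hypot(*(ppos[p] - tpos[h]))
                    if abs(t - dist / c) <= dt / 2:
                        expect[p] = amp
                np.testing.assert_allclose(K.entries[h * 40 + s - 1], expect,
                                           atol=1e-15)

    def test_values_are_zero_or_amplitude(self):
        g = desk_geometry()
        K = build_pat_matrix_time(g)
        vals = np.unique(K.entries)
        assert set(np.round(vals, 12)) <= {0.0, round(1 / (2 * np.pi * g.sound_speed), 12)}


@pytest.fixture(scope="module")
def geom():
    return PATGeometry(num_transducers=4, grid_side=8, grid_extent=25.0,
                       wavenumbers=(0.0, 1.0, 2.5))


class TestPATFreq:

    def test_zero_wavenumber_row_is_zero(self, geom):
        K = build_pat_matrix_freq(geom)
        rows = K.entries.reshape(4, 3, 64)
        assert np.abs(rows[:, 0, :]).max() == 0.0

    def test_modulus_closed_form(self, geom):
        K = build_pat_matrix_freq(geom)
        d = geom.distances()
        rows = K.entries.reshape(4, 3, 64)
        for n_idx, k in enumerate(geom.wavenumbers):
            np.testing.assert_allclose(np.abs(rows[:, n_idx, :]),
                                       geom.sound_speed * k / d, rtol=1e-12)

    def test_phase_direct_evaluation(self, geom):
        """arg(entry) = pi/2 - k*d (mod 2 pi), from i*c*k*exp(-i*k*d)/d."""
        K = build_pat_matrix_freq(geom)
        d = geom.distances()
        rows = K.entries.reshape(4, 3, 64)
        for n_idx, k in enumerate(geom.wavenumbers[1:], start=1):
            expected = np.exp(1j * (np.pi / 2 - k * d))
            np.testing.assert_allclose(rows[:, n_idx, :] / np.abs(rows[:, n_idx, :]),
                                       expected, atol=1e-12)

    def test_geometry_rejects_grid_reaching_ring(self):
        with pytest.raises(InvalidGeometryError):
            PATGeometry(num_transducers=4, grid_side=8, grid_extent=80.0)


class TestMeasureProxy:
    def test_zero_image(self):
        K = build_gaussian_matrix(8, 0.5, 0)
        assert np.all(measure(K, np.zeros((8, 8))).values == 0)

    def test_identity_roundtrip_exact(self, rng):
        K = identity_matrix(8)
        x = rng.uniform(-1, 1, (8, 8))
        v = measure(K, x)
        np.testing.assert_array_equal(v.values, x.ravel())
        np.testing.assert_array_equal(proxy(K, v).pixels, x)

    def test_linearity(self, rng):
        K = build_gaussian_matrix(8, 0.4, 2)
        x1, x2 = rng.uniform(-1, 1, (2, 8, 8))
        a, b = 1.7, -0.3
        lhs = measure(K, a * x1 + b * x2).values
        rhs = a * measure(K, x1).values + b * measure(K, x2).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_proxy_of_zero_vector(self):
        K = build_gaussian_matrix(8, 0.5, 0)
        out = proxy(K, np.zeros(32))
        assert np.all(out.pixels == 0)

    def test_shape_mismatch_errors(self):
        K = build_gaussian_matrix(8, 0.5, 0)
        with pytest.raises(DimensionMismatchError):
            measure(K, np.zeros((7, 7)))
        with pytest.raises(DimensionMismatchError):
            proxy(K, np.zeros(31))

    def test_measurement_noise_seeded(self, rng):
        K = build_gaussian_matrix(8, 0.5, 0)
        x = rng.uniform(-1, 1, (8, 8))
        v1 = measure(K, x, noise_sigma=0.1, seed=4)
        v2 = measure(K, x, noise_sigma=0.1, seed=4)
        np.testing.assert_array_equal(v1.values, v2.values)
        assert not np.array_equal(v1.values, measure(K, x).values)


class TestEmpiricalRIP:
    def test_identity_is_exact_isometry(self):
        rep = empirical_rip(identity_matrix(8), 5, 50, seed=3)
        assert rep.delta_hat == 0.0

    def test_uniform_scaling(self):
        K = MeasurementMatrix(2 * np.eye(64), "custom", 8, 1.0)
        rep = empirical_rip(K, 5, 50, seed=3)
        assert rep.ratio_min == 4.0 and rep.ratio_max == 4.0
        assert rep.delta_hat == 3.0

    def test_sparsity_validation(self):
        K = identity_matrix(4)
        with pytest.raises(InvalidArgumentError):
            empirical_rip(K, 17, 10, seed=0)
        with pytest.raises(InvalidArgumentError):
            empirical_rip(K, 4, 0, seed=0)
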