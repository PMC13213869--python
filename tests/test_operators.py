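"""Encoding machinery: NUFFT accuracy, exact adjoints, coil compression,
sensitivity estimation and density compensation."""

import numpy as np
import pytest

from cineimoco.operators import (
    Nufft2D,
    StackOfSpiralsEncoding,
    compress_coils,
    compute_density_weights,
    estimate_sensitivities,
    inplane_dcf_profile,
    spiral_sample_area,
)
from cineimoco.trajectory import design_vd_spiral


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="module")
def small_spiral():
    return design_vd_spiral(256.0, 16, 4, 2.5, 16.0, 180.0, dwell_us=20)


class TestNufft:
    def test_matches_naive_dft(self, rng):
        n = 16
        k = rng.uniform(-n / 2, n / 2 - 1e-9, size=(60, 2))
        op = Nufft2D((n, n), k)
        x = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        s = op.forward(x)
        ix = np.arange(n) - n // 2
        rx, ry = np.meshgrid(ix, ix, indexing="ij")
        naive = np.array([
            (x * np.exp(-2j * np.pi * (kk[0] * rx + kk[1] * ry) / n)).sum()
            for kk in k
        ])
        assert np.abs(s - naive).max() / np.abs(naive).max() < 1e-3

    def test_adjoint_identity(self, rng):
        n = 16
        k = rng.uniform(-n / 2, n / 2 - 1e-9, size=(60, 2))
        op = Nufft2D((n, n), k)
        x = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        y = rng.normal(size=60) + 1j * rng.normal(size=60)
        s = op.forward(x)
        err = abs(np.vdot(s, y) - np.vdot(x, op.adjoint(y)))
        assert err / (np.linalg.norm(s) * np.linalg.norm(y)) < 1e-6

    def test_zero_maps_to_zero(self, small_spiral):
        op = Nufft2D((16, 16), small_spiral.k_coords)
        assert np.all(op.forward(np.zeros((16, 16), complex)) == 0)
        assert np.all(op.adjoint(np.zeros(small_spiral.n_samples, complex)) == 0)


class TestStackOfSpirals:
    @pytest.fixture(scope="class")
    def op(self, small_spiral):
        rng = np.random.default_rng(0)
        angles = np.arange(7) * 360.0 / 7
        return StackOfSpiralsEncoding(
            (16, 16, 4), small_spiral, angles,
            rng.integers(0, 4, 50), rng.integers(0, 7, 50),
        )

    def test_adjoint_identity(self, op, rng):
        x = rng.normal(size=(16, 16, 4)) + 1j * rng.normal(size=(16, 16, 4))
        y = rng.normal(size=(50, op.n_samples)) + 1j * rng.normal(
            size=(50, op.n_samples))
        d = op.forward(x)
        err = abs(np.vdot(d, y) - np.vdot(x, op.adjoint(y)))
        assert err / (np.linalg.norm(d) * np.linalg.norm(y)) < 1e-6

    def test_linearity(self, op, rng):
        x = rng.normal(size=(16, 16, 4)) + 1j * rng.normal(size=(16, 16, 4))
        y = rng.normal(size=(16, 16, 4)) + 1j * rng.normal(size=(16, 16, 4))
        lhs = op.forward(2.0 * x + (1 - 3j) * y)
        rhs = 2.0 * op.forward(x) + (1 - 3j) * op.forward(y)
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-12)

    def test_batched_leading_dims_match_loop(self, op, rng):
        x = rng.normal(size=(3, 16, 16, 4)) + 1j * rng.normal(size=(3, 16, 16, 4))
        batched = op.forward(x)
        looped = np.stack([op.forward(x[i]) for i in range(3)])
        assert np.allclose(batched, looped, rtol=1e-12, atol=1e-14)

    def test_single_partition_matches_brute_force(self, small_spiral):
        rng = np.random.default_rng(1)
        angles = np.arange(5) * 360.0 / 5
        op = StackOfSpiralsEncoding(
            (16, 16, 1), small_spiral, angles,
            np.zeros(5, int), np.arange(5),
        )
        x = rng.normal(size=(16, 16, 1)) + 1j * rng.normal(size=(16, 16, 1))
        d = op.forward(x)
        ix = np.arange(16) - 8
        rx, ry = np.meshgrid(ix, ix, indexing="ij")
        for a in range(5):
            kk = small_spiral.rotated(angles[a])
            naive = (
                x[:, :, 0][None]
                * np.exp(-2j * np.pi * (kk[:, 0, None, None] * rx
                                        + kk[:, 1, None, None] * ry) / 16)
            ).sum(axis=(1, 2))
            assert np.abs(d[a] - naive).max() / np.abs(naive).max() < 1e-3

    def test_point_object_psf_peaks_at_object(self, small_spiral):
        angles = np.arange(8) * 360.0 / 8
        kz, ang = np.meshgrid(np.arange(4), np.arange(8), indexing="ij")
        op = StackOfSpiralsEncoding((16, 16, 4), small_spiral, angles,
                                    kz.ravel(), ang.ravel())
        w = compute_density_weights(kz.ravel(), ang.ravel(), small_spiral,
                                    n_angles=8).dense()
        x = np.zeros((16, 16, 4), complex)
        x[10, 6, 1] = 1.0
        psf = op.adjoint(w * op.forward(x))
        assert np.unravel_index(np.abs(psf).argmax(), psf.shape) == (10, 6, 1)


class TestCoilCompression:
    def test_full_rank_preserves_gram(self, rng):
        d = rng.normal(size=(5, 200)) + 1j * rng.normal(size=(5, 200))
        comp, T, kept = compress_coils(d, 5)
        g0 = d @ d.conj().T
        g1 = (T.conj().T @ comp) @ (T.conj().T @ comp).conj().T
        assert np.allclose(g0, g1, atol=1e-10 * np.abs(g0).max())
        assert kept == pytest.approx(1.0, abs=1e-12)

    def test_rank2_mixture_kept_by_two_channels(self, rng):
        src = rng.normal(size=(2, 500)) + 1j * rng.normal(size=(2, 500))
        mix = rng.normal(size=(6, 2)) @ src
        _, _, kept = compress_coils(mix, 2)
        assert kept >= 0.999

    def test_retained_energy_monotone(self, rng):
        d = rng.normal(size=(6, 300)) + 1j * rng.normal(size=(6, 300))
        kepts = [compress_coils(d, n)[2] for n in range(1, 7)]
        assert np.all(np.diff(kepts) >= -1e-12)

    def test_rejects_bad_n_keep(self, rng):
        d = rng.normal(size=(4, 10)).astype(complex)
        with pytest.raises(ValueError):
            compress_coils(d, 5)


class TestSensitivities:
    def test_uniform_single_coil_gives_flat_unit_map(self, static_raw):
        import dataclasses

        ph, raw, maps = static_raw
        uni = dataclasses.replace(
            raw,
            readouts=raw.readouts[:, :, :1] / np.abs(maps[0]).mean(),
            n_channels=1,
        )
        # regenerate data with a flat coil: cheaper to just scale one
        # channel is not flat, so simulate directly instead
        from cineimoco.phantom import simulate_acquisition

        flat = np.ones((1,) + tuple(raw.grid_shape), complex)
        uni = simulate_acquisition(ph, raw.schedule, raw.spiral, flat,
                                   noise_sd=0.0, seed=3)
        sm = estimate_sensitivities(uni)
        vals = np.abs(sm.maps[0][sm.mask])
        assert vals.std() < 0.02
        assert vals.mean() == pytest.approx(1.0, abs=0.01)

    def test_known_maps_recovered(self, static_raw):
        ph, raw, maps = static_raw
        sm = estimate_sensitivities(raw)
        rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
        m = sm.mask
        for n in range(maps.shape[0]):
            a = sm.maps[n][m]
            b = (maps[n] / np.maximum(rss, 1e-12))[m]
            corr = abs(np.vdot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert corr >= 0.99

    def test_rss_normalized_inside_mask(self, static_raw):
        _, raw, _ = static_raw
        sm = estimate_sensitivities(raw)
        rss = np.sqrt((np.abs(sm.maps) ** 2).sum(axis=0))
        assert np.abs(rss[sm.mask] - 1.0).max() < 1e-6


class TestDensityWeights:
    def test_duplicated_pair_gets_half_weight(self, small_spiral):
        kz = np.array([0, 0, 1])
        ang = np.array([2, 2, 3])
        w = compute_density_weights(kz, ang, small_spiral, n_angles=5)
        assert w.readout_factor[0] == pytest.approx(w.readout_factor[2] / 2)
        assert w.readout_factor[0] == w.readout_factor[1]

    def test_archimedean_interior_weight_grows_linearly(self):
        sp = design_vd_spiral(256.0, 32, 8, 2.5, 16.0, 180.0,
                              taper_end=1.0, dwell_us=10)
        prof = inplane_dcf_profile(sp, 16)
        r = sp.radius()
        sel = (r > 0.25 * sp.k_max) & (r < 0.85 * sp.k_max)
        coef = np.polyfit(r[sel], prof[sel], 1)
        fit = np.polyval(coef, r[sel])
        resid = np.abs(prof[sel] - fit) / prof[sel].max()
        assert coef[0] > 0
        assert np.median(resid) < 0.05

    def test_weights_close_to_voronoi_areas(self, small_spiral):
        from scipy.spatial import Voronoi
        from shapely.geometry import Polygon

        A = 13
        coords = np.concatenate(
            [small_spiral.rotated(a * 360.0 / A) for a in range(A)], axis=0
        )
        prof = inplane_dcf_profile(small_spiral, A)
        w = np.tile(prof, A)
        vor = Voronoi(coords + 1e-9)
        areas = np.full(len(coords), np.nan)
        for i, reg in enumerate(vor.point_region):
            verts = vor.regions[reg]
            if -1 in verts or len(verts) < 3:
                continue
            areas[i] = Polygon(vor.vertices[verts]).area
        r = np.hypot(*coords.T)
        ok = np.isfinite(areas) & (r > 0.15 * small_spiral.k_max) \
            & (r < 0.85 * small_spiral.k_max)
        ratio = w[ok] / areas[ok]
        ratio /= np.median(ratio)
        assert np.quantile(np.abs(ratio - 1), 0.9) < 0.2

    def test_empty_bin_warns(self, small_spiral):
        with pytest.warns(UserWarning, match="empty bin"):
            w = compute_density_weights(np.array([], int), np.array([], int),
                                        small_spiral)
        assert w.readout_factor.size == 0
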