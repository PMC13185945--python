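import numpy as np
import pytest

from climbfocus.metrics import SharpnessSample
from climbfocus.restore import (
    PsfParams,
    ZStack,
    born_wolf_psf,
    max_projection,
    richardson_lucy_3d,
    rl_iterations,
    zstack_from_trace,
)


@pytest.fixture(scope="module")
def high_na_psf():
    params = PsfParams(na=1.49, wavelength_um=0.52, refr_index=1.515,
                       pixel_um=0.065, z_step_um=0.5, shape=(9, 33, 33))
    return born_wolf_psf(params)


class TestPsfParams:
    def test_na_must_be_below_refr_index(self):
        with pytest.raises(ValueError):
            PsfParams(na=1.6, wavelength_um=0.52, refr_index=1.515,
                      pixel_um=0.065, z_step_um=0.5)

    def test_even_grid_rejected(self):
        with pytest.raises(ValueError):
            PsfParams(na=1.0, wavelength_um=0.52, refr_index=1.515,
                      pixel_um=0.065, z_step_um=0.5, shape=(8, 33, 33))


class TestBornWolfPsf:
    def test_unit_sum(self, high_na_psf):
        assert high_na_psf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_central_plane_radially_symmetric(self, high_na_psf):
        c = high_na_psf[4]
        assert np.allclose(c, c.T, atol=1e-9 * c.max())
        assert np.allclose(c, c[::-1, :], atol=1e-9 * c.max())

    def test_axial_symmetry(self, high_na_psf):
        # aberration-free model is even in defocus
        assert np.allclose(high_na_psf[0], high_na_psf[8], atol=1e-9)
        assert np.allclose(high_na_psf[1], high_na_psf[7], atol=1e-9)

    def test_first_minimum_at_airy_radius(self):
        # fine radial grid so the minimum is resolved
        params = PsfParams(na=1.49, wavelength_um=0.52, refr_index=1.515,
                           pixel_um=0.005, z_step_um=0.5, shape=(1, 201, 201))
        plane = born_wolf_psf(params)[0]
        profile = plane[100, 100:]
        minima = [i for i in range(1, len(profile) - 1)
                  if profile[i] < profile[i - 1] and profile[i] < profile[i + 1]]
        r_min = minima[0] * 0.005
        assert r_min == pytest.approx(0.61 * 0.52 / 1.49, abs=0.01)


class TestRichardsonLucy:
    def test_delta_psf_is_identity(self, rng):
        data = rng.uniform(0, 10, (4, 16, 16))
        delta = np.zeros((3, 3, 3))
        delta[1, 1, 1] = 1.0
        out = richardson_lucy_3d(data, delta, n_iter=5)
        assert np.allclose(out, data, atol=1e-10)

    def test_uniform_stack_is_fixed_point(self):
        data = np.full((4, 12, 12), 3.0)
        psf = np.ones((3, 3, 3)) / 27.0
        out = richardson_lucy_3d(data, psf, n_iter=10)
        assert np.allclose(out, data, atol=1e-9)

    def test_flux_conserved_every_iteration(self, rng):
        data = rng.uniform(0, 100, (4, 24, 24))
        psf = np.ones((3, 5, 5))
        psf /= psf.sum()
        it = rl_iterations(data, psf)
        for _ in range(20):
            est = next(it)
            assert est.sum() == pytest.approx(data.sum(), rel=1e-6)
            assert est.min() >= 0.0

    def test_unnormalised_psf_rejected(self):
        with pytest.raises(ValueError):
            richardson_lucy_3d(np.ones((3, 8, 8)), np.ones((3, 3, 3)))

    def test_oversized_psf_rejected(self):
        psf = np.ones((5, 9, 9))
        psf /= psf.sum()
        with pytest.raises(ValueError):
            richardson_lucy_3d(np.ones((3, 8, 8)), psf)

    def test_matches_skimage_on_interior_object(self, rng):
        # independent cross-check: scikit-image's RL (zero-padded boundary)
        # agrees with the periodic implementation when the blurred object is
        # compactly supported away from the edges
        from scipy.ndimage import gaussian_filter
        from skimage.restoration import richardson_lucy as sk_rl

        obj = np.zeros((48, 48))
        obj[20:28, 22:26] = rng.uniform(5, 10, (8, 4))
        psf1 = np.zeros((11, 11))
        psf1[5, 5] = 1.0
        psf = gaussian_filter(psf1, 1.2)
        psf /= psf.sum()
        from scipy.signal import fftconvolve

        blurred = np.clip(fftconvolve(obj, psf, mode="same"), 0.0, None)
        mine = richardson_lucy_3d(blurred[None], psf[None], n_iter=10)[0]
        theirs = sk_rl(blurred, psf, num_iter=10, clip=False)
        # boundary conventions differ (periodic vs zero-padded), so agreement
        # is checked on the interior at a few percent of the peak intensity
        inner = (slice(12, 36), slice(12, 36))
        assert np.abs(mine[inner] - theirs[inner]).max() < 0.05 * obj.max()

    def test_restoration_reduces_error_against_ground_truth(self, rng, high_na_psf):
        vol = np.zeros((9, 48, 48))
        for zi in (2, 6):
            ys = rng.integers(8, 40, 12)
            xs = rng.integers(8, 40, 12)
            vol[zi, ys, xs] = rng.uniform(50, 100, 12)
        pad = [(0, 0), (0, 48 - 33), (0, 48 - 33)]
        kern = np.roll(np.pad(high_na_psf, pad), (-4, -16, -16), axis=(0, 1, 2))
        otf = np.fft.rfftn(kern)
        blurred = np.clip(np.fft.irfftn(np.fft.rfftn(vol) * otf,
                                        s=vol.shape, axes=(0, 1, 2)), 0, None)
        restored = richardson_lucy_3d(blurred, high_na_psf, n_iter=20)
        assert ((restored - vol) ** 2).mean() < ((blurred - vol) ** 2).mean()


class TestZStack:
    def test_monotone_even_spacing_enforced(self):
        with pytest.raises(ValueError):
            ZStack(planes=np.zeros((3, 4, 4)), z_positions_um=[0.0, 1.0, 1.5])
        with pytest.raises(ValueError):
            ZStack(planes=np.zeros((3, 4, 4)), z_positions_um=[0.0, 1.0, 0.5])

    def test_z_step(self):
        st = ZStack(planes=np.zeros((3, 4, 4)), z_positions_um=[2.0, 1.5, 1.0])
        assert st.z_step_um == pytest.approx(0.5)


class TestMaxProjection:
    def test_single_plane_identity(self, rng):
        plane = rng.uniform(0, 5, (6, 6))
        assert np.array_equal(max_projection(plane[None]), plane)

    def test_zero_plane_ignored(self, rng):
        plane = rng.uniform(1, 5, (6, 6))
        stack = np.stack([plane, np.zeros((6, 6))])
        assert np.array_equal(max_projection(stack), plane)

    def test_disjoint_spots_both_kept(self):
        a = np.zeros((5, 5)); a[1, 1] = 7.0
        b = np.zeros((5, 5)); b[3, 3] = 9.0
        proj = max_projection(np.stack([a, b]))
        assert proj[1, 1] == 7.0 and proj[3, 3] == 9.0

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_projection(np.zeros((0, 4, 4)))


class TestStackAssembly:
    def test_takes_trailing_even_run(self):
        z = [0.0, 1.0, 2.0, 2.5, 3.0, 3.5, 4.0]
        samples = [SharpnessSample(zz, 1.0) for zz in z]
        frames = [np.full((4, 4), float(i)) for i in range(len(z))]
        stack = zstack_from_trace(samples, frames, pixel_um=0.1)
        assert np.allclose(stack.z_positions_um, [2.0, 2.5, 3.0, 3.5, 4.0])

    def test_descending_trace_stored_ascending(self):
        z = [4.0, 3.0, 2.0, 1.0]
        samples = [SharpnessSample(zz, 1.0) for zz in z]
        frames = [np.full((4, 4), float(i)) for i in range(len(z))]
        stack = zstack_from_trace(samples, frames)
        assert np.all(np.diff(stack.z_positions_um) > 0)
        assert stack.planes[0, 0, 0] == 3.0  # frame acquired at z=1.0

    def test_frame_sample_mismatch_rejected(self):
        with pytest.raises(ValueError):
            zstack_from_trace([SharpnessSample(0.0, 1.0)], [])
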