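import numpy as np
import pytest

from pemscat import (ImageGrid, Image3D, siddon_row, snap_in_plane,
                     to_virtual_lors, build_sensitivity, lm_osem,
                     gaussian_post_filter, list_mode_log_likelihood,
                     sample_emissions, run_transport, digitize)
from pemscat.sources import EmissionBatch, make_phantom


@pytest.fixture(scope="module")
def grid():
    return ImageGrid()


def _chord_oracle(a, b, grid, n=200_000):
    """Chord length through the grid box by dense sampling along the LOR."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    t = (np.arange(n) + 0.5) / n
    pts = a[None, :] + t[:, None] * (b - a)[None, :]
    lo = np.asarray(grid.origin)
    hi = lo + np.asarray(grid.extent)
    inside = np.all((pts >= lo) & (pts < hi), axis=1)
    return inside.mean() * np.linalg.norm(b - a)


class TestSiddon:
    def test_axial_lor_crosses_every_slice(self, grid):
        idx, ln = siddon_row((0.05, 0.05, -30.0), (0.05, 0.05, 30.0), grid)
        assert len(idx) == 24
        assert np.allclose(ln, 2.5)

    def test_oblique_chord_length_conserved(self, grid):
        a, b = (-30.0, 0.05, -30.0), (30.0, 0.05, 30.0)
        idx, ln = siddon_row(a, b, grid)
        assert ln.sum() == pytest.approx(np.sqrt(2) * 60.0, rel=1e-9)

    def test_missing_lor_empty(self, grid):
        idx, ln = siddon_row((200.0, 200.0, -30.0), (200.0, 200.0, 30.0), grid)
        assert len(idx) == 0

    def test_random_lors_match_sampling_oracle(self, grid, rng):
        for _ in range(25):
            a = np.append(rng.uniform(-86, 86, 2), -30.0)
            b = np.append(rng.uniform(-86, 86, 2), 30.0)
            idx, ln = siddon_row(a, b, grid)
            assert len(np.unique(idx)) == len(idx)
            assert ln.sum() == pytest.approx(_chord_oracle(a, b, grid),
                                             rel=0.01)

    def test_translation_invariance(self, grid):
        a = np.array([3.3, -7.1, -30.0])
        b = np.array([-12.9, 4.4, 30.0])
        i1, l1 = siddon_row(a, b, grid)
        shift = np.array([grid.voxel[0], 0.0, 0.0])
        i2, l2 = siddon_row(a + shift, b + shift, grid)
        assert np.array_equal(np.sort(i2 - i1), np.ones(len(i1)))
        assert np.allclose(np.sort(l1), np.sort(l2))


class TestVirtualLors:
    def test_snap_to_first_cell_center(self, geom_mono):
        # 0.1 mm inside the lower block edge -> cell 0, center at 0.72 mm
        x = -geom_mono.panel_span / 2 + 0.1
        snapped = snap_in_plane([[x, x]], geom_mono)[0]
        assert snapped[0] == pytest.approx(-geom_mono.panel_span / 2 + 0.72)

    def test_pixel_centers_are_fixed_points(self, geom_pix):
        half = geom_pix.panel_span / 2
        centers = (-half + geom_pix.block_size
                   + (np.arange(40) + 0.5) * geom_pix.pixel_pitch)
        snapped = snap_in_plane(np.column_stack([centers, centers]), geom_pix)
        assert np.allclose(snapped[:, 0], centers, atol=1e-9)

    def test_out_of_span_clamped(self, geom_mono):
        snapped = snap_in_plane([[500.0, -500.0]], geom_mono)[0]
        half = geom_mono.panel_span / 2
        assert abs(snapped[0]) < half and abs(snapped[1]) < half

    def test_si_si_coincidences_identical_in_both_modes(self,
                                                        small_cuboid_mono):
        run = small_cuboid_mono
        si = run.coincidences.coincidence_class == 0
        from pemscat.digitizer import CoincidenceTable
        c = CoincidenceTable(idx_a=run.coincidences.idx_a[si],
                             idx_b=run.coincidences.idx_b[si],
                             coincidence_class=run.coincidences.coincidence_class[si],
                             is_random=run.coincidences.is_random[si])
        fa, fb = to_virtual_lors(run.singles, c, run.geometry, "fhp")
        ea, eb = to_virtual_lors(run.singles, c, run.geometry, "ewp")
        assert np.allclose(fa, ea) and np.allclose(fb, eb)
        assert np.all(fa[:, 2] == -30.0) and np.all(fb[:, 2] == 30.0)


@pytest.fixture(scope="module")
def mini_point_study(grid):
    """A tiny end-to-end acquisition of a point-like source plus a planar
    normalization run, shared across reconstruction tests."""
    from pemscat import build_geometry, build_lyso_table
    geom = build_geometry("monolithic")
    xs = build_lyso_table()
    rng = np.random.default_rng(424242)
    n = 120_000
    origin = np.array([5.3, -3.2, 1.25])
    ct = rng.uniform(-1, 1, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    st = np.sqrt(1 - ct**2)
    batch = EmissionBatch(
        origins=np.tile(origin, (n, 1)),
        directions=np.column_stack([st * np.cos(phi), st * np.sin(phi), ct]),
        times=np.arange(n) * 1e4)
    hits = run_transport(geom, xs, batch, seed=5150)
    singles, coinc = digitize(hits, geom, np.random.default_rng(2))
    la, lb = to_virtual_lors(singles, coinc, geom, "fhp")

    norm = sample_emissions(make_phantom("planar"), 1_000_000,
                            np.random.default_rng(3))
    nh = run_transport(geom, xs, norm, seed=5151)
    ns, nc = digitize(nh, geom, np.random.default_rng(4))
    na, nb = to_virtual_lors(ns, nc, geom, "fhp")
    sens = build_sensitivity(na, nb, grid)
    return origin, la, lb, sens


class TestSensitivity:
    def test_positive_in_central_region(self, mini_point_study, grid):
        """Strictly positive through the interior of the FOV; a few rim
        voxels of the 120 mm box may need more normalization statistics."""
        sens = mini_point_study[3]
        nx, ny, nz = grid.shape
        cx = slice(nx // 2 - 55, nx // 2 + 55)
        assert np.all(sens.voxels[cx, cx, :] > 0)
        wide = slice(nx // 2 - 60, nx // 2 + 60)
        zero_frac = np.mean(sens.voxels[wide, wide, :] == 0)
        assert zero_frac < 1e-4

    def test_corners_weaker_than_center(self, mini_point_study, grid):
        s = mini_point_study[3].voxels
        center = s[87 - 5:87 + 5, 87 - 5:87 + 5, 10:14].mean()
        corner = s[:10, :10, 10:14].mean()
        assert corner < center

    def test_scale_invariance_under_more_statistics(self, mini_point_study,
                                                    grid):
        sens = mini_point_study[3]
        # doubling the LOR list changes nothing after unit-mean rescaling
        from pemscat.recon import build_sensitivity as bs
        la, lb = mini_point_study[1], mini_point_study[2]
        s1 = bs(la, lb, grid).voxels
        s2 = bs(np.vstack([la, la]), np.vstack([lb, lb]), grid).voxels
        assert np.allclose(s1, s2)

    def test_empty_normalization_rejected(self, grid):
        with pytest.raises(ValueError):
            build_sensitivity(np.empty((0, 3)), np.empty((0, 3)), grid)


class TestOsem:
    def test_point_source_localizes(self, mini_point_study, grid):
        origin, la, lb, sens = mini_point_study
        img = lm_osem(la, lb, sens, iterations=2, subsets=8)
        assert np.all(img.voxels >= 0)
        am = np.unravel_index(np.argmax(img.voxels), img.voxels.shape)
        world = [grid.origin[i] + (am[i] + 0.5) * grid.voxel[i]
                 for i in range(3)]
        assert abs(world[0] - origin[0]) <= 1.0
        assert abs(world[1] - origin[1]) <= 1.0
        assert abs(world[2] - origin[2]) <= 2.5

    def test_single_lor_concentrates_on_its_row(self, grid):
        a = np.array([[0.05, 0.05, -30.0]])
        b = np.array([[0.05, 0.05, 30.0]])
        sens = Image3D(voxels=np.ones(grid.shape), grid=grid)
        img = lm_osem(a, b, sens, iterations=1, subsets=1)
        idx, _ = siddon_row(a[0], b[0], grid)
        flat = img.voxels.reshape(-1, order="F")
        on = np.zeros(flat.shape, bool)
        on[idx] = True
        assert flat[on].sum() > 0
        assert np.allclose(flat[~on], 0.0)

    def test_uniform_fixed_point_stays_uniform(self, grid):
        """With sensitivity equal to the backprojection of the event list,
        a uniform image reproduces itself up to a global scale."""
        rng = np.random.default_rng(9)
        a = np.column_stack([rng.uniform(-40, 40, 500),
                             rng.uniform(-40, 40, 500),
                             np.full(500, -30.0)])
        b = a.copy()
        b[:, 2] = 30.0
        sens = build_sensitivity(a, b, grid)
        img = lm_osem(a, b, sens, iterations=1, subsets=1)
        on = sens.voxels > 0
        vals = img.voxels[on]
        assert vals.std() / vals.mean() < 1e-9

    def test_mlem_log_likelihood_non_decreasing(self, mini_point_study, grid):
        origin, la, lb, sens = mini_point_study
        la, lb = la[:400], lb[:400]
        lls = []
        for it in (1, 2, 3):
            img = lm_osem(la, lb, sens, iterations=it, subsets=1)
            lls.append(list_mode_log_likelihood(la, lb, img, sens))
        assert lls[1] >= lls[0] - 1e-6 and lls[2] >= lls[1] - 1e-6

    def test_deterministic(self, mini_point_study):
        origin, la, lb, sens = mini_point_study
        i1 = lm_osem(la[:2000], lb[:2000], sens, 1, 4)
        i2 = lm_osem(la[:2000], lb[:2000], sens, 1, 4)
        assert np.array_equal(i1.voxels, i2.voxels)

    def test_invalid_parameters_rejected(self, mini_point_study):
        origin, la, lb, sens = mini_point_study
        with pytest.raises(ValueError):
            lm_osem(la, lb, sens, iterations=0, subsets=1)


class TestGaussianFilter:
    def test_zero_fwhm_identity(self, grid, rng):
        img = Image3D(voxels=rng.random(grid.shape), grid=grid)
        out = gaussian_post_filter(img, 0.0)
        assert np.array_equal(out.voxels, img.voxels)

    def test_delta_profile_fwhm(self, grid):
        vol = np.zeros(grid.shape)
        vol[87, 87, 12] = 1.0
        out = gaussian_post_filter(Image3D(voxels=vol, grid=grid), 1.5).voxels
        for axis, vsize in ((0, 1.0), (1, 1.0)):
            prof = out[:, 87, 12] if axis == 0 else out[87, :, 12]
            x = (np.arange(174) - 87 + 0.5 - 0.5) * vsize
            sigma = np.sqrt(np.sum(prof * x**2) / prof.sum())
            assert 2.3548 * sigma == pytest.approx(1.5, rel=0.02)

    def test_intensity_conserved(self, grid, rng):
        vol = np.zeros(grid.shape)
        vol[60:110, 60:110, 8:16] = rng.random((50, 50, 8))
        img = Image3D(voxels=vol, grid=grid)
        out = gaussian_post_filter(img, 1.5)
        assert out.voxels.sum() == pytest.approx(vol.sum(), rel=1e-6)

    def test_negative_fwhm_rejected(self, grid):
        img = Image3D(voxels=np.zeros(grid.shape), grid=grid)
        with pytest.raises(ValueError):
            gaussian_post_filter(img, -1.0)
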