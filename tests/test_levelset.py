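import math
from dataclasses import replace

import numpy as np
import pytest

from nightgrape import (
    ChannelImage,
    CvParams,
    InvalidInputError,
    NumericalDivergenceError,
    cv_energy,
    cv_evolve,
    initialize_phi,
    segment,
    segment_pyramid,
    standardize,
    extract_red,
    rotate_channel,
    iou,
    BinaryMask,
    SceneParams,
    generate_scene,
)
from nightgrape.levelset import INTENSITY_SCALE, LevelSetField, upsample_mask

from conftest import disk_channel


# ---------------------------------------------------------------------------
# brute-force oracles: straight per-pixel transcriptions of the energy and
# of one explicit update step, kept free of any vectorized shortcut
# ---------------------------------------------------------------------------

def oracle_energy(values, phi, p):
    H, W = phi.shape
    n_in = n_out = 0
    s_in = s_out = 0.0
    for i in range(H):
        for j in range(W):
            if phi[i, j] > 0:
                n_in += 1
                s_in += values[i, j]
            else:
                n_out += 1
                s_out += values[i, j]
    c_o = s_in / n_in if n_in else 0.0
    c_b = s_out / n_out if n_out else 0.0
    length = 0
    for i in range(H):
        for j in range(W):
            if i + 1 < H and (phi[i, j] > 0) != (phi[i + 1, j] > 0):
                length += 1
            if j + 1 < W and (phi[i, j] > 0) != (phi[i, j + 1] > 0):
                length += 1
    fit_in = fit_out = 0.0
    for i in range(H):
        for j in range(W):
            if phi[i, j] > 0:
                fit_in += (values[i, j] - c_o) ** 2
            else:
                fit_out += (values[i, j] - c_b) ** 2
    return (
        p.mu * length * p.h
        + p.nu * n_in * p.h**2
        + p.lambda_o * fit_in
        + p.lambda_b * fit_out
    )


def _grad_1d(f, k, n, h):
    """np.gradient convention: central interior, one-sided edges."""
    if n == 1:
        return 0.0
    if k == 0:
        return (f(1) - f(0)) / h
    if k == n - 1:
        return (f(n - 1) - f(n - 2)) / h
    return (f(k + 1) - f(k - 1)) / (2 * h)


def oracle_evolve_step(values, phi, p, boundary_row):
    H, W = phi.shape
    n_in = n_out = 0
    s_in = s_out = 0.0
    for i in range(H):
        for j in range(W):
            if phi[i, j] > 0:
                n_in += 1
                s_in += values[i, j]
            else:
                n_out += 1
                s_out += values[i, j]
    sc = INTENSITY_SCALE
    c_o = (s_in / n_in if n_in else 0.0) / sc
    c_b = (s_out / n_out if n_out else 0.0) / sc

    py = np.zeros_like(phi)
    px = np.zeros_like(phi)
    for i in range(H):
        for j in range(W):
            py[i, j] = _grad_1d(lambda k: phi[k, j], i, H, p.h)
            px[i, j] = _grad_1d(lambda k: phi[i, k], j, W, p.h)
    out = np.zeros_like(phi)
    cap0 = max(abs(p.rho_u), abs(p.rho_d))
    sign_rho = math.copysign(1.0, p.rho_u - p.rho_d)
    for i in range(H):
        for j in range(W):
            pyy = _grad_1d(lambda k: py[k, j], i, H, p.h)
            pyx = _grad_1d(lambda k: py[i, k], j, W, p.h)
            pxx = _grad_1d(lambda k: px[i, k], j, W, p.h)
            num = pxx * py[i, j] ** 2 - 2 * px[i, j] * py[i, j] * pyx + pyy * px[i, j] ** 2
            den = (px[i, j] ** 2 + py[i, j] ** 2) ** 1.5 + 1e-8
            v = values[i, j] / sc
            R = (
                (p.mu / sc**2) * (num / den)
                - p.nu / sc**2
                - p.lambda_o * (v - c_o) ** 2
                + p.lambda_b * (v - c_b) ** 2
            )
            if boundary_row is not None and p.u_param > 0:
                if i == boundary_row:
                    R -= (p.u_param / p.h) * sign_rho
                elif i == boundary_row - 1:
                    R += (p.u_param / p.h) * sign_rho
            delta = p.eps / (math.pi * (phi[i, j] ** 2 + p.eps**2))
            new = phi[i, j] + p.dt * delta * R
            cap = max(cap0, abs(phi[i, j]))
            out[i, j] = min(max(new, -cap), cap)
    return out


# ---------------------------------------------------------------------------


class TestInitializePhi:
    def test_step_layout(self):
        p = CvParams(y0=2)
        f = initialize_phi((4, 4), p)
        assert np.all(f.phi[2:] == p.rho_u) and np.all(f.phi[:2] == p.rho_d)
        assert f.iteration == 0 and f.boundary_row == 2

    def test_sign_flip_symmetry(self):
        p = CvParams(y0=2, rho_u=-1.0, rho_d=1.0)
        f = initialize_phi((4, 4), p)
        assert np.all(f.phi[2:] == -1.0) and np.all(f.phi[:2] == 1.0)

    def test_degenerate_boundary_row(self):
        f = initialize_phi((4, 4), CvParams(y0=0))
        assert np.all(f.phi == 1.0)

    def test_y0_out_of_range(self):
        with pytest.raises(InvalidInputError):
            initialize_phi((4, 4), CvParams(y0=4))

    def test_rho_product_constraint(self):
        with pytest.raises(InvalidInputError):
            CvParams(rho_u=1.0, rho_d=1.0)


class TestEnergy:
    def test_perfect_partition_has_zero_fidelity(self):
        values = np.array([[10, 10], [200, 200]], dtype=np.uint8)
        p = CvParams(y0=1)
        f = initialize_phi((2, 2), p)
        # phi>0 on row 1 (values 200): both regions constant
        e = cv_energy(ChannelImage(values), f, p)
        assert e == pytest.approx(p.mu * 2 + p.nu * 2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_3x3(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 256, (3, 3), dtype=np.uint8)
        phi = rng.normal(0, 1, (3, 3))
        p = CvParams(mu=3.0, nu=2.0, lambda_o=1.5, lambda_b=0.5)
        f = LevelSetField(phi.copy())
        expected = oracle_energy(values.astype(float), phi, p)
        assert cv_energy(ChannelImage(values), f, p) == pytest.approx(
            expected, abs=1e-9
        )

    def test_empty_region_flagged(self):
        values = np.array([[10, 20], [30, 40]], dtype=np.uint8)
        f = LevelSetField(np.full((2, 2), -1.0))
        p = CvParams()
        cv_energy(ChannelImage(values), f, p)
        assert f.degenerate


class TestEvolve:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_one_step_matches_bruteforce_on_5x5(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 256, (5, 5), dtype=np.uint8)
        p = CvParams(y0=2, u_param=0.3, dt=1.0)
        f = initialize_phi((5, 5), p)
        f.phi += rng.normal(0, 0.3, (5, 5))  # roughen so curvature is active
        expected = oracle_evolve_step(values.astype(float), f.phi.copy(), p, 2)
        out = cv_evolve(ChannelImage(values), f, p)
        np.testing.assert_allclose(out.phi, expected, atol=1e-9)
        assert out.iteration == 1

    def test_u_zero_collapses_row_cases(self):
        """With u = 0 the three row cases give bitwise-identical updates."""
        rng = np.random.default_rng(9)
        values = rng.integers(0, 256, (6, 6), dtype=np.uint8)
        p = CvParams(y0=3, u_param=0.0)
        f_boundary = initialize_phi((6, 6), p)
        f_plain = LevelSetField(f_boundary.phi.copy(), boundary_row=None)
        a = cv_evolve(ChannelImage(values), f_boundary, p)
        b = cv_evolve(ChannelImage(values), f_plain, p)
        assert np.array_equal(a.phi, b.phi)

    def test_u_positive_touches_only_boundary_rows(self):
        rng = np.random.default_rng(10)
        values = rng.integers(0, 256, (6, 6), dtype=np.uint8)
        p0 = CvParams(y0=3, u_param=0.0, mu=0.0)
        p1 = replace(p0, u_param=0.2)
        a = cv_evolve(ChannelImage(values), initialize_phi((6, 6), p0), p0)
        b = cv_evolve(ChannelImage(values), initialize_phi((6, 6), p1), p1)
        differs = np.any(a.phi != b.phi, axis=1)
        assert differs[2] and differs[3]
        assert not differs[[0, 1, 4, 5]].any()

    def test_vanishing_dirac_leaves_field_unchanged(self):
        values = np.random.default_rng(11).integers(0, 256, (5, 5), dtype=np.uint8)
        phi = np.full((5, 5), 1e200)
        phi[2:] = -1e200
        f = LevelSetField(phi.copy(), boundary_row=None)
        out = cv_evolve(ChannelImage(values), f, CvParams())
        assert np.array_equal(out.phi, phi)

    def test_nonfinite_raises_divergence(self):
        values = np.zeros((4, 4), dtype=np.uint8)
        f = LevelSetField(np.full((4, 4), np.inf), boundary_row=None)
        with pytest.raises(NumericalDivergenceError):
            cv_evolve(ChannelImage(values), f, CvParams())


class TestSegment:
    def test_recovers_bright_disk(self):
        ch, truth = disk_channel()
        mask = segment(ch)
        assert iou(mask, BinaryMask(truth)) >= 0.95

    def test_constant_image_degenerate(self):
        res = segment(
            ChannelImage(np.full((20, 20), 77, dtype=np.uint8)), full_output=True
        )
        assert res.degenerate and not res.mask.labels.any()

    def test_bimodal_equals_midpoint_threshold_up_to_boundary_band(self):
        rng = np.random.default_rng(12)
        ch, region = disk_channel(radius=18)
        values = np.clip(
            ch.values.astype(int) + rng.integers(-8, 9, ch.shape), 0, 255
        ).astype(np.uint8)
        p = replace(CvParams(), nu=0.0, mu=0.0)
        mask = segment(ChannelImage(values), p)
        c_o = values[mask.labels].mean()
        c_b = values[~mask.labels].mean()
        expected = values > (c_o + c_b) / 2
        assert np.mean(mask.labels != expected) < 0.01

    def test_sign_symmetry_on_two_phase_fixture(self):
        """Inverting contrast and swapping rho gives the complementary mask."""
        img = np.full((40, 40), 60, dtype=np.uint8)
        img[10:25, 12:30] = 200
        p = replace(CvParams(), nu=0.0, orient_bright=False)
        m1 = segment(ChannelImage(img), p)
        p_flip = replace(p, rho_u=p.rho_d, rho_d=p.rho_u)
        m2 = segment(ChannelImage((255 - img).astype(np.uint8)), p_flip)
        assert np.array_equal(m1.labels, ~m2.labels)

    def test_energy_descent_end_to_start(self):
        ch, _ = disk_channel()
        p = CvParams()
        f0 = initialize_phi(ch.shape, p)
        e0 = cv_energy(ChannelImage(ch.values), f0, p)
        res = segment(ch, p, full_output=True)
        e1 = cv_energy(ChannelImage(ch.values), res.field, p)
        assert e1 <= e0


class TestPyramid:
    def test_upsample_mask_blocks(self):
        m = BinaryMask(np.array([[True, False], [False, True]]))
        up = upsample_mask(m, 3)
        assert up.labels.shape == (6, 6)
        assert up.labels[0:3, 0:3].all() and not up.labels[0:3, 3:6].any()

    def test_matches_direct_segmentation(self, rotated_channel, noise_free_scene):
        _, truth = noise_free_scene
        pyr = segment_pyramid(rotated_channel, full_output=True)
        direct = segment(rotated_channel, full_output=True)
        assert np.mean(pyr.mask.labels != direct.mask.labels) < 0.02
        assert iou(pyr.mask, truth.fruit_mask) >= 0.95

    def test_refine_is_faster_than_direct(self, rotated_channel):
        pyr = segment_pyramid(rotated_channel, full_output=True)
        direct = segment(rotated_channel, full_output=True)
        assert pyr.iterations < direct.iterations

    def test_all_dark_image_does_not_crash(self):
        ch = ChannelImage(np.full((450, 300), 30, dtype=np.uint8))
        mask = segment_pyramid(ch)
        assert not mask.labels.any()

    def test_requires_standard_size(self):
        with pytest.raises(InvalidInputError):
            segment_pyramid(ChannelImage(np.zeros((100, 100), dtype=np.uint8)))
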