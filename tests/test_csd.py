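import numpy as np
import pytest

from fwlesion.io import DWIVolume
from fwlesion.phantom import simulate_voxel_signal
from fwlesion.shm import n_coeffs, quadrature_grid, sh_basis, sphere_points
from fwlesion import csd as csd_mod
from fwlesion.csd import (
    FODField,
    ResponseSet,
    afd_map,
    average_responses,
    estimate_responses,
    fit_ss3t_csd,
    normalize_fods,
)


def _peaks(fod_coeffs, lmax, min_sep_deg=30.0):
    """Two dominant FOD directions by dense amplitude evaluation."""
    pts = sphere_points(2000, hemisphere=True)
    amp = sh_basis(lmax, pts) @ fod_coeffs
    order = np.argsort(amp)[::-1]
    p1 = pts[order[0]]
    away = np.abs(pts @ p1) < np.cos(np.radians(min_sep_deg))
    second = order[np.isin(order, np.where(away)[0])][0]
    return (p1, amp[order[0]]), (pts[second], amp[second])


class TestSHBasis:
    def test_orthonormal_under_quadrature(self):
        pts, w = quadrature_grid(24, 48)
        b = sh_basis(8, pts)
        gram = (b * w[:, None]).T @ b
        assert np.allclose(gram, np.eye(b.shape[1]), atol=1e-10)

    def test_coefficient_count(self):
        assert n_coeffs(8) == 45
        assert sh_basis(6, np.array([[0.0, 0.0, 1.0]])).shape == (1, 28)


class TestResponses:
    def test_wm_zonal_matches_quadrature_projection(self, calibration60, gtab60):
        vol, masks, (sig_fib, _, _) = calibration60
        resp = estimate_responses(vol, gtab60, masks, lmax=8)
        # oracle: project the analytic single-fiber signal (already aligned
        # with +z after the x->z relabeling of the tensor) onto zonal SH by
        # spherical quadrature
        pts, w = quadrature_grid(24, 48)
        t_z = np.diag([0.3e-3, 0.3e-3, 1.7e-3])  # fiber along z
        sig = 100.0 * np.exp(-1000.0 * np.einsum("ij,jk,ik->i", pts, t_z, pts))
        zonal = sh_basis(8, pts)[:, [0, 3, 10, 21, 36]]
        oracle = (zonal * w[:, None]).T @ sig
        assert np.allclose(resp.wm_shell, oracle, rtol=1e-3, atol=0.5)

    def test_csf_response_is_mean_signal(self, calibration60, gtab60):
        vol, masks, (_, _, sig_csf) = calibration60
        resp = estimate_responses(vol, gtab60, masks, lmax=8)
        assert resp.csf[0] == pytest.approx(100.0, rel=1e-9)
        assert resp.csf[1] == pytest.approx(100.0 * np.exp(-3.0), rel=1e-9)

    def test_no_single_fiber_voxels_errors(self, calibration60, gtab60):
        vol, masks, _ = calibration60
        bad = dict(masks)
        bad["wm"] = masks["gm"]  # isotropic voxels only: FA below threshold
        with pytest.raises(ValueError, match="relax the FA threshold"):
            estimate_responses(vol, gtab60, bad, lmax=8)

    def test_average_identical_is_identity(self, responses60):
        avg = average_responses([responses60, responses60])
        assert np.allclose(avg.wm_shell, responses60.wm_shell)
        assert avg.gm == responses60.gm

    def test_average_is_midpoint_and_linear(self, responses60):
        r = responses60
        other = ResponseSet(
            r.shell_b, 2 * r.wm_b0, 2 * r.wm_shell,
            (2 * r.gm[0], 2 * r.gm[1]), (2 * r.csf[0], 2 * r.csf[1]), r.lmax,
        )
        avg = average_responses([r, other])
        assert np.allclose(avg.wm_shell, 1.5 * r.wm_shell)
        assert avg.wm_b0 == pytest.approx(1.5 * r.wm_b0)
        # linearity: mean of singletons equals one call on the concatenation
        a = average_responses([average_responses([r]), average_responses([other])])
        assert np.allclose(a.wm_shell, avg.wm_shell)

    def test_mismatched_shells_rejected(self, responses60):
        r = responses60
        other = ResponseSet(2000.0, r.wm_b0, r.wm_shell, r.gm, r.csf, r.lmax)
        with pytest.raises(ValueError, match="mismatched"):
            average_responses([r, other])


class TestSS3TCSD:
    def test_single_fiber_peak_and_clean_fractions(self, calibration60, gtab60, responses60):
        _, _, (sig_fib, _, _) = calibration60
        vol = DWIVolume(sig_fib.reshape(1, 1, 1, -1), gtab60)
        fod = fit_ss3t_csd(vol, gtab60, responses60, lmax=8)
        (p1, a1), _ = _peaks(fod.coeffs[0, 0, 0], fod.lmax)
        angle = np.degrees(np.arccos(abs(p1[0])))  # truth along +x
        assert angle <= 5.0
        assert fod.gm_fraction[0, 0, 0] <= 0.02
        assert fod.csf_fraction[0, 0, 0] <= 0.02

    def test_pure_csf_voxel(self, calibration60, gtab60, responses60):
        _, _, (sig_fib, _, sig_csf) = calibration60
        vol = DWIVolume(
            np.stack([sig_fib, sig_csf]).reshape(2, 1, 1, -1), gtab60
        )
        fod = fit_ss3t_csd(vol, gtab60, responses60, lmax=8)
        energy_fib = np.sum(fod.coeffs[0, 0, 0] ** 2)
        energy_csf = np.sum(fod.coeffs[1, 0, 0] ** 2)
        assert fod.csf_fraction[1, 0, 0] == pytest.approx(1.0, abs=0.02)
        assert energy_csf <= 1e-3 * energy_fib

    def test_crossing_fibers_resolved(self, gtab60, responses60):
        b, g = gtab60.bvals, gtab60.bvecs
        tx = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        ty = np.diag([0.3e-3, 1.7e-3, 0.3e-3])
        sig = 100.0 * 0.5 * (
            np.exp(-b * np.einsum("ij,jk,ik->i", g, tx, g))
            + np.exp(-b * np.einsum("ij,jk,ik->i", g, ty, g))
        )
        fod = fit_ss3t_csd(DWIVolume(sig.reshape(1, 1, 1, -1), gtab60),
                           gtab60, responses60, lmax=8)
        (p1, a1), (p2, a2) = _peaks(fod.coeffs[0, 0, 0], fod.lmax)
        ex, ey = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        for p in (p1, p2):
            ang = min(
                np.degrees(np.arccos(min(abs(p @ ex), 1.0))),
                np.degrees(np.arccos(min(abs(p @ ey), 1.0))),
            )
            assert ang <= 10.0
        ratio = a1 / a2
        assert 0.8 <= ratio <= 1.25

    def test_fod_nonnegative_at_constraint_directions(self, calibration60, gtab60, responses60):
        from fwlesion.csd import N_CONSTRAINT_DIRS

        _, _, (sig_fib, sig_gm, sig_csf) = calibration60
        rng = np.random.default_rng(0)
        mixes = []
        for _ in range(20):
            wts = rng.dirichlet([1, 1, 1])
            s = wts[0] * sig_fib + wts[1] * sig_gm + wts[2] * sig_csf
            mixes.append(s + rng.normal(0, 2.0, s.shape))
        vol = DWIVolume(np.abs(np.stack(mixes)).reshape(20, 1, 1, -1), gtab60)
        fod = fit_ss3t_csd(vol, gtab60, responses60, lmax=8)
        dirs = sphere_points(N_CONSTRAINT_DIRS, hemisphere=True)
        amps = fod.coeffs[:, 0, 0] @ sh_basis(fod.lmax, dirs).T
        rel = amps.min(axis=1) / np.maximum(amps.max(axis=1), 1e-12)
        assert rel.min() >= -1e-4

    def test_odd_lmax_rejected(self, calibration60, gtab60, responses60):
        _, _, (sig_fib, _, _) = calibration60
        vol = DWIVolume(sig_fib.reshape(1, 1, 1, -1), gtab60)
        with pytest.raises(ValueError, match="even"):
            fit_ss3t_csd(vol, gtab60, responses60, lmax=7)

    def test_lmax_auto_lowered_when_underdetermined(self, gtab30, responses60, fiber_tensor, caplog):
        sig = simulate_voxel_signal(0.0, fiber_tensor, gtab30)
        vol = DWIVolume(sig.reshape(1, 1, 1, -1), gtab30)
        import logging

        with caplog.at_level(logging.WARNING, logger="fwlesion.csd"):
            fod = fit_ss3t_csd(vol, gtab30, responses60, lmax=8)
        assert fod.lmax == 6
        assert any("lowered" in r.message for r in caplog.records)


class TestNormalizationAndAFD:
    def _fitted(self, calibration60, gtab60, responses60, scale=1.0):
        _, _, (sig_fib, sig_gm, sig_csf) = calibration60
        data = np.stack([sig_fib, 0.5 * sig_fib + 0.5 * sig_gm, sig_csf])
        vol = DWIVolume(scale * data.reshape(3, 1, 1, -1), gtab60)
        return fit_ss3t_csd(vol, gtab60, responses60, lmax=8)

    def test_median_total_is_one_and_idempotent(self, calibration60, gtab60, responses60):
        fod = self._fitted(calibration60, gtab60, responses60)
        norm = normalize_fods(fod)
        total = afd_map(norm) + norm.gm_fraction + norm.csf_fraction
        assert np.nanmedian(total[norm.mask]) == pytest.approx(1.0, abs=1e-9)
        again = normalize_fods(norm)
        assert np.allclose(again.coeffs[norm.mask], norm.coeffs[norm.mask], atol=1e-12)

    def test_normalized_afd_scale_invariant(self, calibration60, gtab60, responses60):
        a = normalize_fods(self._fitted(calibration60, gtab60, responses60, 1.0))
        b = normalize_fods(self._fitted(calibration60, gtab60, responses60, 2.0))
        assert np.allclose(afd_map(a), afd_map(b), atol=1e-8)

    def test_afd_matches_quadrature_integral(self):
        rng = np.random.default_rng(5)
        coeffs = rng.standard_normal((10, 1, 1, n_coeffs(8)))
        fod = FODField(coeffs, np.zeros((10, 1, 1)), np.zeros((10, 1, 1)), 8,
                       np.ones((10, 1, 1), bool))
        pts, w = quadrature_grid(24, 48)
        basis = sh_basis(8, pts)
        oracle = (coeffs.reshape(10, -1) @ basis.T) @ w
        assert np.allclose(afd_map(fod).ravel(), oracle, atol=1e-6)

    def test_afd_zero_and_uniform_identities(self):
        z = np.zeros((1, 1, 1, n_coeffs(4)))
        fod = FODField(z, np.zeros((1, 1, 1)), np.zeros((1, 1, 1)), 4,
                       np.ones((1, 1, 1), bool))
        assert afd_map(fod)[0, 0, 0] == 0.0
        u = z.copy()
        u[..., 0] = 1.0 / (2 * np.sqrt(np.pi))  # unit-integral uniform FOD
        fod_u = FODField(u, np.zeros((1, 1, 1)), np.zeros((1, 1, 1)), 4,
                         np.ones((1, 1, 1), bool))
        assert afd_map(fod_u)[0, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_afd_linear_in_fod(self):
        rng = np.random.default_rng(6)
        c = rng.standard_normal((1, 1, 1, n_coeffs(6)))
        fod = FODField(c, np.zeros((1, 1, 1)), np.zeros((1, 1, 1)), 6,
                       np.ones((1, 1, 1), bool))
        fod3 = FODField(3 * c, np.zeros((1, 1, 1)), np.zeros((1, 1, 1)), 6,
                        np.ones((1, 1, 1), bool))
        assert afd_map(fod3)[0, 0, 0] == pytest.approx(3 * afd_map(fod)[0, 0, 0])

    def test_afd_decreases_with_free_water(self, gtab60, responses60, fiber_tensor):
        sigs = [simulate_voxel_signal(f, fiber_tensor, gtab60) for f in
                np.linspace(0.0, 0.8, 9)]
        vol = DWIVolume(np.stack(sigs).reshape(9, 1, 1, -1), gtab60)
        fod = fit_ss3t_csd(vol, gtab60, responses60, lmax=8)
        afd = afd_map(fod).ravel()
        assert np.all(np.diff(afd) < 0)
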