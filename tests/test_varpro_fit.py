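"""Variable-projection fitting: closed forms, grid search, two-stage fit."""

import numpy as np
import pytest

from facmri.recon import EchoImageSeries
from facmri.triglyceride_model import (
    TriglycerideComposition,
    basis_matrix,
    fac_from_subcomponents,
)
from facmri.varpro_fit import (
    FitConfig,
    confounder_search,
    fac_maps_from_fits,
    fit_image,
    linear_solve,
    optimal_phase,
    refine_confounders,
    residual,
    two_stage_fit,
)


def _synth_voxel(te, comp, x, psi, r2, phi, consts):
    a = basis_matrix(te, comp, r2, consts)
    return np.exp(2j * np.pi * psi * te) * (a @ np.asarray(x)) * np.exp(1j * phi)


@pytest.fixture(scope="module")
def rig(consts, design32):
    te = np.asarray(design32.te_list)
    comp = TriglycerideComposition(17.4, 2.4, 0.624)
    return te, comp


class TestLinearSolve:
    def test_exact_inverse_crime(self, rig, consts):
        te, comp = rig
        x_true = np.array([0.3, 0.2, 0.48, 0.12])
        y = _synth_voxel(te, comp, x_true, 37.0, 55.0, 0.4, consts)
        a = basis_matrix(te, comp, 55.0, consts)
        x = linear_solve(y, a, 37.0, 0.4, te)
        np.testing.assert_allclose(x, x_true, atol=1e-10)

    def test_water_only(self, rig, consts):
        te, comp = rig
        y = 0.8 * np.exp(-30.0 * te)
        a = basis_matrix(te, comp, 30.0, consts)
        x = linear_solve(y, a, 0.0, 0.0, te)
        np.testing.assert_allclose(x, [0.8, 0, 0, 0], atol=1e-8)

    def test_against_generic_lstsq_oracle(self, rig, consts):
        """Matches an independent real-constrained least-squares solve."""
        te, comp = rig
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(50):
            psi = rng.uniform(-200, 200)
            phi = rng.uniform(-1.2, 1.2)
            r2 = rng.uniform(0, 200)
            y = (rng.standard_normal(16) + 1j * rng.standard_normal(16))
            a = basis_matrix(te, comp, r2, consts)
            x = linear_solve(y, a, psi, phi, te)
            # oracle: stack real/imag of Psi A e^{i phi} and solve real LS
            b = np.exp(2j * np.pi * psi * te)[:, None] * a * np.exp(1j * phi)
            m = np.vstack([b.real, b.imag])
            rhs = np.concatenate([y.real, y.imag])
            x_ref, *_ = np.linalg.lstsq(m, rhs, rcond=None)
            worst = max(worst, np.abs(x - x_ref).max())
        assert worst < 1e-9


class TestOptimalPhase:
    def test_forward_inverse_closure(self, rig, consts):
        te, comp = rig
        x_true = np.array([0.1, 0.3, 0.72, 0.18])
        y = _synth_voxel(te, comp, x_true, 55.0, 40.0, 0.4, consts)
        a = basis_matrix(te, comp, 40.0, consts)
        phi = optimal_phase(y, a, 55.0, te)
        # pi-ambiguous branch: canonical when recovered Fntg >= 0
        x = linear_solve(y, a, 55.0, phi, te)
        if x[1] < 0:
            phi += np.pi if phi <= 0 else -np.pi
        assert phi == pytest.approx(0.4, abs=1e-10)

    def test_scale_invariance(self, rig, consts):
        te, comp = rig
        y = _synth_voxel(te, comp, [0.2, 0.2, 0.5, 0.1], 10.0, 30.0, -0.7, consts)
        a = basis_matrix(te, comp, 30.0, consts)
        assert optimal_phase(3.7 * y, a, 10.0, te) == pytest.approx(
            optimal_phase(y, a, 10.0, te), abs=1e-12)

    def test_zero_signal_returns_zero(self, rig, consts):
        te, comp = rig
        a = basis_matrix(te, comp, 30.0, consts)
        assert optimal_phase(np.zeros(16, complex), a, 0.0, te) == 0.0

    def test_against_phase_scan_oracle(self, rig, consts):
        """Analytic phase matches a dense 1-D scan of the residual."""
        te, comp = rig
        rng = np.random.default_rng(7)
        grid = np.linspace(-np.pi / 2, np.pi / 2, 10_000, endpoint=False)
        for _ in range(50):
            psi = rng.uniform(-100, 100)
            r2 = rng.uniform(0, 150)
            y = rng.standard_normal(16) + 1j * rng.standard_normal(16)
            a = basis_matrix(te, comp, r2, consts)
            phi_hat = optimal_phase(y, a, psi, te)
            j_scan = np.array([residual(y, a, psi, p, te) for p in grid])
            phi_best = grid[np.argmin(j_scan)]
            # compare the residuals, not angles (flat minima are possible)
            assert residual(y, a, psi, phi_hat, te) <= j_scan.min() + 1e-9


class TestResidual:
    def test_noiseless_zero(self, rig, consts):
        te, comp = rig
        y = _synth_voxel(te, comp, [0.2, 0.2, 0.5, 0.13], 40.0, 60.0, 0.2, consts)
        a = basis_matrix(te, comp, 60.0, consts)
        phi = optimal_phase(y, a, 40.0, te)
        assert residual(y, a, 40.0, phi, te) < 1e-18

    def test_longhand_identity(self, rig, consts):
        """J equals ||y - Psi A x e^{i phi}||^2 computed from scratch."""
        te, comp = rig
        rng = np.random.default_rng(3)
        y = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        a = basis_matrix(te, comp, 80.0, consts)
        phi, psi = 0.3, -60.0
        x = linear_solve(y, a, psi, phi, te)
        model = np.exp(2j * np.pi * psi * te) * (a @ x) * np.exp(1j * phi)
        assert residual(y, a, psi, phi, te) == pytest.approx(
            np.sum(np.abs(y - model) ** 2), rel=1e-12)

    def test_global_rotation_invariance(self, rig, consts):
        te, comp = rig
        rng = np.random.default_rng(4)
        y = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        a = basis_matrix(te, comp, 20.0, consts)
        phi1 = optimal_phase(y, a, 0.0, te)
        y2 = y * np.exp(0.9j)
        phi2 = optimal_phase(y2, a, 0.0, te)
        assert residual(y, a, 0.0, phi1, te) == pytest.approx(
            residual(y2, a, 0.0, phi2, te), rel=1e-9)


class TestConfounderSearch:
    def test_uniform_on_grid_field_exact(self, small_phantom_images,
                                         small_phantom_truth, consts):
        """Uniform 40 Hz on-grid field is recovered exactly everywhere."""
        cfg = FitConfig()
        psi, r2, j, flags = confounder_search(small_phantom_images, cfg, consts)
        obj = small_phantom_truth["object_mask"]
        err = np.abs(psi - 40.0)[obj]
        assert np.median(err) < 0.05          # essentially exact
        assert err.max() < 2.0                # never off by a grid step

    def test_single_voxel_no_smoothing_equals_exhaustive(self, rig, consts,
                                                         design32):
        te, comp = rig
        cfg = FitConfig(smoothness_weight=0.0,
                        psi_grid=np.arange(-100.0, 102.0, 2.0))
        y = _synth_voxel(te, comp, [0.3, 0.2, 0.48, 0.12], 34.0, 60.0, 0.2,
                         consts)
        imgs = np.tile(y[:, None, None], (1, 2, 2))
        series = EchoImageSeries(images=imgs, stage="denoised", design=design32)
        psi, r2, j, flags = confounder_search(series, cfg, consts, comp)
        # brute force over the same grids
        best = (None, np.inf)
        for p in cfg.psi_grid:
            for r in cfg.r2star_grid:
                a = basis_matrix(te, comp, r, consts)
                jj = residual(y, a, p, optimal_phase(y, a, p, te), te)
                if jj < best[1]:
                    best = ((p, r), jj)
        # sub-grid refinement may move either confounder off its grid
        # point, but never further than one step from the exhaustive optimum
        assert abs(r2[0, 0] - best[0][1]) <= 2.0
        assert abs(psi[0, 0] - best[0][0]) <= 2.0
        assert abs(psi[0, 0] - 34.0) < 0.2
        assert abs(r2[0, 0] - 60.0) < 0.1

    def test_smooth_ramp_no_swaps(self, design32, consts):
        """A +/-100 Hz ramp over a fat/water phantom: no aliased branches."""
        from dataclasses import replace

        from facmri.phantom_sim import (
            PhantomDefinition, Region, builtin_oil_library,
            rasterize_phantom, simulate_echo_images)

        oil = builtin_oil_library()[1]
        regs = (Region("disc", (16, 10, 6), oil=oil, oil_volume_fraction=1.0),
                Region("disc", (16, 24, 6), oil=oil, oil_volume_fraction=0.5))
        defn = PhantomDefinition(
            grid=(32, 32), regions=regs,
            field_map_poly=np.array([[0.0, 100.0]]),   # ramp along x
            phase_map_poly=np.array([[0.2]]))
        truth = rasterize_phantom(defn)
        imgs = simulate_echo_images(truth, design32, consts)
        series = EchoImageSeries(images=imgs, stage="denoised", design=design32)
        psi, r2, j, flags = confounder_search(series, FitConfig(), consts)
        obj = truth["object_mask"]
        err = np.abs(psi - truth["psi_true"])[obj]
        assert np.mean(err <= 2.0) > 0.99
        assert err.max() < 100.0    # nothing lands on an aliased branch


class TestTwoStageFit:
    def test_self_consistent_ratio_unchanged(self, rig, consts):
        """True nmidb/ndb equal to the assumed ratio: stage 2 is a no-op."""
        te, comp = rig
        fntg = 1.0 / (1 + comp.ndb + comp.nmidb)
        x_true = np.array([0.0, fntg, comp.ndb * fntg, comp.nmidb * fntg])
        y = _synth_voxel(te, comp, x_true, 20.0, 40.0, 0.3, consts)
        cfg = FitConfig(cl=comp.cl, nmidb_to_ndb_ratio=comp.nmidb / comp.ndb)
        fit = two_stage_fit(y, 20.0, 40.0, cfg, consts, te, comp)
        np.testing.assert_allclose(fit.x, x_true, atol=1e-8)
        assert not fit.boundary

    def test_ratio_within_bounds_recovered(self, rig, consts):
        """True ratio 0.4 vs assumed 0.26 is reachable within [0.5x, 2x]."""
        te, _ = rig
        comp_true = TriglycerideComposition(17.4, 2.5, 1.0)   # ratio 0.4
        fntg = 1.0 / (1 + 2.5 + 1.0)
        x_true = np.array([0.1, fntg, 2.5 * fntg, 1.0 * fntg])
        y = _synth_voxel(te, comp_true, x_true, -15.0, 30.0, -0.2, consts)
        cfg = FitConfig(cl=17.4, nmidb_to_ndb_ratio=0.26)
        fit = two_stage_fit(y, -15.0, 30.0, cfg, consts, te, comp_true)
        ndb, nmidb, _, _ = fac_from_subcomponents(fit.x)
        assert ndb == pytest.approx(2.5, abs=1e-3)
        assert nmidb == pytest.approx(1.0, abs=1e-3)

    def test_unreachable_ratio_pins_at_bound(self, rig, consts):
        """True ratio far outside [0.5x, 2x] of the assumed: boundary flag."""
        te, _ = rig
        comp_true = TriglycerideComposition(17.4, 2.0, 1.8)   # ratio 0.9
        fntg = 1.0 / (1 + 2.0 + 1.8)
        x_true = np.array([0.1, fntg, 2.0 * fntg, 1.8 * fntg])
        y = _synth_voxel(te, comp_true, x_true, 0.0, 20.0, 0.0, consts)
        cfg = FitConfig(cl=17.4, nmidb_to_ndb_ratio=0.2)
        fit = two_stage_fit(y, 0.0, 20.0, cfg, consts, te, comp_true)
        assert fit.boundary

    def test_zero_voxel_masked(self, rig, consts):
        te, comp = rig
        fit = two_stage_fit(np.zeros(16, complex), 0.0, 0.0, FitConfig(),
                            consts, te, comp)
        assert fit.masked


class TestFitImage:
    def test_noiseless_phantom_closure(self, small_phantom_images,
                                       small_phantom_truth, consts):
        """Rasterise -> simulate -> fit recovers composition and PDFF.

        With matched per-oil assumptions the pure-oil ndb error is below
        1e-3 and the PDFF map error below half a percentage point.
        """
        truth = small_phantom_truth
        series = small_phantom_images
        cfg = FitConfig()
        psi_map, r2_map, _, _ = confounder_search(series, cfg, consts)
        lab = truth["region_labels"]
        worst_ndb, worst_pdff = 0.0, 0.0
        for idx in np.unique(lab[lab >= 0]):
            m = lab == idx
            comp_o = TriglycerideComposition(
                truth["cl"][m].max(), truth["ndb_true"][m].max(),
                truth["nmidb_true"][m].max())
            cfg_o = FitConfig(cl=comp_o.cl,
                              nmidb_to_ndb_ratio=comp_o.nmidb / comp_o.ndb)
            psi_o, r2_o = refine_confounders(series, psi_map, cfg_o, consts,
                                             comp_o, mask=m)
            part = fit_image(series, cfg_o, consts, comp_assumed=comp_o,
                             mask=m, confounders=(psi_o, r2_o))
            maps = fac_maps_from_fits(part)
            worst_pdff = max(worst_pdff,
                             np.abs(maps["pdff"] - truth["pdff_true"])[m].max())
            if np.isclose(truth["pdff_true"][m].mean(), 1.0):
                worst_ndb = max(worst_ndb,
                                np.abs(maps["ndb"][m] - comp_o.ndb).max())
        assert worst_ndb < 1e-3
        assert worst_pdff < 0.005

    def test_water_and_fat_calibration_voxels(self, rig, consts, design32):
        """Pure-water and pure-fat voxels give PDFF 0 and 1."""
        te, comp = rig
        fntg = 1.0 / (1 + comp.ndb + comp.nmidb)
        xf = np.array([0.0, fntg, comp.ndb * fntg, comp.nmidb * fntg])
        yw = 1.0 * np.exp((2j * np.pi * 20.0 - 20.0) * te)
        yf = _synth_voxel(te, comp, xf, 20.0, 20.0, 0.1, consts)
        imgs = np.zeros((16, 2, 2), complex)
        imgs[:, 0, 0] = yw
        imgs[:, 1, 1] = yf
        imgs[:, 0, 1] = yw
        imgs[:, 1, 0] = yf
        series = EchoImageSeries(images=imgs, stage="denoised", design=design32)
        cfg = FitConfig(psi_grid=np.arange(-100.0, 102.0, 2.0))
        fit = fit_image(series, cfg, consts, comp_assumed=comp)
        maps = fac_maps_from_fits(fit)
        assert maps["pdff"][0, 0] == pytest.approx(0.0, abs=1e-3)
        assert maps["pdff"][1, 1] == pytest.approx(1.0, abs=1e-3)

    def test_repeat_run_bit_identical(self, small_phantom_images, consts):
        cfg = FitConfig()
        mask = np.zeros((32, 32), bool)
        mask[10:16, 10:16] = True
        a = fit_image(small_phantom_images, cfg, consts, mask=mask)
        b = fit_image(small_phantom_images, cfg, consts, mask=mask)
        for key in ("x", "psi", "r2star", "phi", "residual"):
            assert np.array_equal(a[key], b[key])


class TestVarproVsJointFit:
    def test_equivalence_on_noiseless_voxels(self, rig, consts):
        """VARPRO solution matches a generic 7-parameter joint fit."""
        from scipy.optimize import least_squares

        te, comp = rig
        rng = np.random.default_rng(17)
        cfg = FitConfig(smoothness_weight=0.0)
        n_checked = 0
        for _ in range(30):
            x_true = np.abs(rng.standard_normal(4)) * [0.5, 0.3, 0.6, 0.1]
            psi_true = rng.uniform(-150, 150)
            r2_true = 2.0 * rng.integers(0, 100)
            phi_true = rng.uniform(-1.2, 1.2)
            y = _synth_voxel(te, comp, x_true, psi_true, r2_true, phi_true,
                             consts)

            def model_resid(p):
                x, psi, r2, phi = p[:4], p[4], p[5], p[6]
                a = basis_matrix(te, comp, max(r2, 0.0), consts)
                m = (np.exp(2j * np.pi * psi * te) * (a @ x)
                     * np.exp(1j * phi))
                return np.concatenate([(y - m).real, (y - m).imag])

            # joint nonlinear fit, multi-start around decoys
            best = None
            for psi0 in (psi_true, psi_true + 30, psi_true - 30):
                p0 = np.concatenate([x_true * 1.3, [psi0, r2_true + 20, 0.0]])
                sol = least_squares(model_resid, p0, gtol=1e-14, xtol=1e-14,
                                    ftol=1e-14)
                if best is None or sol.cost < best.cost:
                    best = sol
            # VARPRO grid solution (sub-grid refined) for the same voxel
            imgs = np.tile(y[:, None, None], (1, 2, 2))
            from facmri.sequence_design import default_cardiac_design

            design = default_cardiac_design(matrix_size=32)
            series = EchoImageSeries(images=imgs, stage="denoised",
                                     design=design)
            psi_m, r2_m, _, _ = confounder_search(series, cfg, consts, comp)
            psi_hat, r2_hat = psi_m[0, 0], r2_m[0, 0]
            r2_joint = max(best.x[5], 0.0)   # the joint fit clamps R2* at 0
            assert abs(psi_hat - best.x[4]) <= 2.0       # psi grid step
            assert abs(r2_hat - r2_joint) <= 2.0         # r2 grid step
            a = basis_matrix(te, comp, r2_hat, consts)
            phi_hat = optimal_phase(y, a, psi_hat, te)
            x_hat = linear_solve(y, a, psi_hat, phi_hat, te)
            if x_hat[1] < 0:
                x_hat = -x_hat
            xb = best.x[:4] if best.x[1] >= 0 else -best.x[:4]
            denom = max(np.abs(xb).max(), 1e-12)
            assert np.abs(x_hat - xb).max() / denom < 5e-3
            n_checked += 1
        assert n_checked == 30
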