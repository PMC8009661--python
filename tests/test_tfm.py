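"""TFM: PIV tracking, Boussinesq forward map, L1 inversion, strain energy."""

import numpy as np
import pytest
from scipy.optimize import minimize

from na_dynamics import synthetic as syn, tfm
from na_dynamics.config import ImagingConfig


def _render_beads(beads_um, field_um, config, shift_px=(0.0, 0.0)):
    px = config.pixel_size_um
    shape = (int(field_um[1] / px), int(field_um[0] / px))
    pos = beads_um / px + np.asarray(shift_px)
    return syn.render_gaussian_spots(shape, pos,
                                     np.full(len(pos), 300.0), 2.1) + 50.0


class TestTrackBeads:
    def test_identity_displacement(self, config):
        beads = syn.generate_bead_field(0.5, (12, 12), 0.4, seed=1)
        ref = _render_beads(beads, (12, 12), config)
        fld = tfm.track_beads(ref, ref, template_px=17, max_disp_px=10)
        assert len(fld) > 10
        # zero displacement up to the subpixel-fit resolution (neighboring
        # beads skew the 3-point fit by a few hundredths of a pixel)
        assert np.abs(fld.vectors[fld.valid]).max() < 0.1

    def test_rigid_shift_recovered(self, config):
        beads = syn.generate_bead_field(0.5, (16, 16), 0.4, seed=2)
        ref = _render_beads(beads, (16, 16), config)
        moved = _render_beads(beads, (16, 16), config, shift_px=(3.0, -2.0))
        fld = tfm.track_beads(moved, ref, template_px=19, max_disp_px=10)
        med = np.median(fld.vectors[fld.valid], axis=0)
        assert med[0] == pytest.approx(3.0, abs=0.1)
        assert med[1] == pytest.approx(-2.0, abs=0.1)

    def test_template_validation(self, config):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError, match="odd"):
            tfm.track_beads(img, img, template_px=18)
        with pytest.raises(ValueError, match="larger than image"):
            tfm.track_beads(img, img, template_px=33)

    def test_planted_patch_displacements(self, single_patch_recovery, config):
        """Noise-free single-patch scenario: per-bead PIV vectors match the
        forward-model displacements with RMS error < 0.15 px."""
        from scipy.spatial import cKDTree
        d = single_patch_recovery
        beads_um = d["truth"].bead_positions_um
        tree = cKDTree(beads_um / config.pixel_size_um)
        _, idx = tree.query(d["field"].positions)
        u_true = syn.displacement_from_patches(
            beads_um, [d["patch"]], 0.0, config.youngs_modulus_pa,
            config.poisson_ratio) / config.pixel_size_um
        err = np.linalg.norm(d["field"].vectors - u_true[idx], axis=1)
        rms = np.sqrt((err[d["field"].valid] ** 2).mean())
        assert rms < 0.15


class TestRemoveOutliers:
    def test_perturbed_bead_invalidated(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 100, (60, 2))
        vec = np.tile([1.0, 0.5], (60, 1))
        vec[17] += [10.0, 0.0]
        fld = tfm.DisplacementField(pos, vec, np.ones(60, bool), np.ones(60))
        out = tfm.remove_outliers(fld)
        assert not out.valid[17]
        assert out.valid.sum() == 59
        # vector values untouched
        assert np.array_equal(out.vectors, vec)

    def test_all_zero_nothing_invalidated(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 50, (30, 2))
        fld = tfm.DisplacementField(pos, np.zeros((30, 2)),
                                    np.ones(30, bool), np.ones(30))
        assert tfm.remove_outliers(fld).valid.all()

    def test_too_few_beads_unchanged_with_warning(self):
        fld = tfm.DisplacementField(np.array([[0, 0], [5, 5.0]]),
                                    np.zeros((2, 2)), np.ones(2, bool),
                                    np.ones(2))
        with pytest.warns(UserWarning, match="too few"):
            out = tfm.remove_outliers(fld)
        assert out.valid.all()


class TestForwardMap:
    def test_closed_form_point_force(self):
        """Unit tangential point force: displacement along/perpendicular to
        the force axis matches the Boussinesq-Cerruti closed form."""
        E, nu = 5000.0, 0.5
        r = 3.0
        for theta in (0.0, np.pi / 2, np.pi / 4):
            dx, dy = r * np.cos(theta), r * np.sin(theta)
            G = tfm.greens_tensor(np.array(dx), np.array(dy), E, nu, 0.01)
            expected = (1e3 * (1 + nu) / (np.pi * E * r)
                        * ((1 - nu) + nu * np.cos(theta) ** 2))
            assert G[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_angular_ratio_incompressible(self):
        # nu = 0.5: perpendicular/parallel displacement ratio = (1-nu)/1
        E, nu = 5000.0, 0.5
        along = tfm.greens_tensor(np.array(4.0), np.array(0.0), E, nu, 0.01)
        perp = tfm.greens_tensor(np.array(0.0), np.array(4.0), E, nu, 0.01)
        assert perp[0, 0] / along[0, 0] == pytest.approx((1 - nu), rel=1e-12)

    def test_linearity(self):
        beads = syn.generate_bead_field(1.0, (8, 8), 0.3, seed=5)
        fmap = tfm.build_forward_map(beads, (0, 0, 8, 8), 1.0, 5000.0, 0.5)
        f = np.zeros(fmap.matrix.shape[1])
        f[10] = 1.0
        assert np.allclose(fmap.matrix @ (2 * f), 2 * (fmap.matrix @ f))

    def test_mesh_width_from_density(self):
        beads = syn.generate_bead_field(1.0, (8, 8), 0.3, seed=5)
        fmap = tfm.build_forward_map(beads, (0, 0, 8, 8), 4.0, 5000.0, 0.5)
        assert fmap.mesh_width_um == pytest.approx(0.5)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="no beads"):
            tfm.build_forward_map(np.zeros((0, 2)), None, 1.0, 5000.0, 0.5)


class TestSolveL1:
    def test_zero_data_zero_solution(self):
        beads = syn.generate_bead_field(1.0, (8, 8), 0.3, seed=6)
        fmap = tfm.build_forward_map(beads, (0, 0, 8, 8), 1.0, 5000.0, 0.5)
        fld = tfm.DisplacementField(beads / 0.08, np.zeros((len(beads), 2)),
                                    np.ones(len(beads), bool),
                                    np.ones(len(beads)))
        sol = tfm.solve_l1(fmap, fld, 1e-3, 0.08)
        assert np.all(sol.tractions == 0.0)

    def test_point_force_recovery_vs_qp_oracle(self):
        """Noise-free single nodal force inverted with small lambda: center
        within one cell, magnitude within 10%; FISTA solution matches an
        independent split-variable bound-constrained QP solve."""
        beads = syn.generate_bead_field(1.5, (6, 6), 0.2, seed=7)
        fmap = tfm.build_forward_map(beads, (0, 0, 6, 6), 1.0, 5000.0, 0.5)
        nn = len(fmap.mesh_nodes)
        assert nn <= 100
        f_true = np.zeros(2 * nn)
        j = 2 * (nn // 2)   # x-component of a central node
        f_true[j] = 0.05    # nN
        u = fmap.matrix @ f_true
        fld = tfm.DisplacementField(beads / 0.08,
                                    (u.reshape(-1, 2)) / 0.08,
                                    np.ones(len(beads), bool),
                                    np.ones(len(beads)))
        lam = 1e-7
        sol = tfm.solve_l1(fmap, fld, lam, 0.08)
        mag = sol.magnitude()
        i = np.argmax(mag)
        true_node = fmap.mesh_nodes[nn // 2]
        assert np.linalg.norm(sol.mesh_nodes[i] - true_node) <= fmap.mesh_width_um
        w2 = fmap.mesh_width_um ** 2
        rec = mag[i] * w2 / 1e3  # back to nN
        assert rec == pytest.approx(0.05, rel=0.10)

        # independent oracle: minimize ||Mf-u||^2 + lam*sum(fp+fm), f=fp-fm
        M = fmap.matrix

        def obj(z):
            fp, fm = z[:2 * nn], z[2 * nn:]
            f = fp - fm
            r = M @ f - u
            g = 2 * M.T @ r
            return r @ r + lam * z.sum(), np.concatenate([g + lam, -g + lam])

        res = minimize(obj, np.zeros(4 * nn), jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * (4 * nn),
                       options={"maxiter": 20_000, "maxfun": 100_000,
                                "ftol": 1e-18, "gtol": 1e-14})
        f_oracle = res.x[:2 * nn] - res.x[2 * nn:]
        f_fista = sol.tractions.ravel() * w2 / 1e3
        assert np.abs(f_fista - f_oracle).max() < 0.05 * np.abs(f_true).max()

    def test_l1_norm_monotone_in_lambda(self):
        beads = syn.generate_bead_field(1.0, (8, 8), 0.3, seed=8)
        fmap = tfm.build_forward_map(beads, (0, 0, 8, 8), 1.0, 5000.0, 0.5)
        rng = np.random.default_rng(0)
        fld = tfm.DisplacementField(beads / 0.08,
                                    rng.normal(0, 0.5, (len(beads), 2)),
                                    np.ones(len(beads), bool),
                                    np.ones(len(beads)))
        lams = np.logspace(-6, -2, 6)
        norms = [tfm.solve_l1(fmap, fld, l, 0.08).l1_norm for l in lams]
        for a, b in zip(norms, norms[1:]):
            assert a >= b - 1e-9 * max(abs(a), 1.0)

    def test_negative_lambda_rejected(self):
        beads = syn.generate_bead_field(1.0, (6, 6), 0.3, seed=9)
        fmap = tfm.build_forward_map(beads, (0, 0, 6, 6), 1.0, 5000.0, 0.5)
        fld = tfm.DisplacementField(beads / 0.08, np.zeros((len(beads), 2)),
                                    np.ones(len(beads), bool),
                                    np.ones(len(beads)))
        with pytest.raises(ValueError):
            tfm.solve_l1(fmap, fld, -1.0, 0.08)


class TestLCurve:
    def test_lambda_interior_and_deterministic(self, single_patch_recovery):
        d = single_patch_recovery
        grid = d["lcurve"]["lambdas"]
        assert grid[0] < d["lam"] < grid[-1]
        lam2, _ = tfm.select_lambda_lcurve(d["fmap"], d["field"], grid, 0.08)
        assert lam2 == d["lam"]

    def test_pure_noise_selects_sparse_end(self):
        beads = syn.generate_bead_field(1.0, (10, 10), 0.3, seed=10)
        fmap = tfm.build_forward_map(beads, (0, 0, 10, 10), 1.0, 5000.0, 0.5)
        rng = np.random.default_rng(3)
        fld = tfm.DisplacementField(beads / 0.08,
                                    rng.normal(0, 0.05, (len(beads), 2)),
                                    np.ones(len(beads), bool),
                                    np.ones(len(beads)))
        grid = np.logspace(-6, -1, 11)
        lam, _ = tfm.select_lambda_lcurve(fmap, fld, grid, 0.08)
        sol = tfm.solve_l1(fmap, fld, lam, 0.08)
        # reconstruction approximately zero: below the traction noise floor
        assert np.median(sol.magnitude()) < 20.0

    def test_short_grid_rejected(self, single_patch_recovery):
        d = single_patch_recovery
        with pytest.raises(ValueError, match="10"):
            tfm.select_lambda_lcurve(d["fmap"], d["field"],
                                     np.logspace(-5, -2, 5), 0.08)


class TestStrainEnergy:
    def test_zero_displacement_zero_energy(self, single_patch_recovery):
        d = single_patch_recovery
        fld = d["field"]
        zero = tfm.DisplacementField(fld.positions,
                                     np.zeros_like(fld.vectors),
                                     fld.valid, fld.scores)
        assert tfm.strain_energy(zero, d["solution"],
                                 pixel_size_um=0.08) == 0.0

    def test_hand_arithmetic_uniform_fields(self):
        # uniform T = 100 Pa, u = 0.1 µm over 100 µm² -> 0.5 fJ
        n = 10
        xs = np.arange(n) + 0.5
        nodes = np.array([[x, y] for y in xs for x in xs])
        tr = tfm.TractionField(nodes, 1.0,
                               np.tile([100.0, 0.0], (n * n, 1)),
                               1e-3, 0.0, 0.0, mesh_shape=(n, n))
        pos_um = nodes  # beads at the mesh nodes
        fld = tfm.DisplacementField(pos_um, np.tile([0.1, 0.0], (n * n, 1)),
                                    np.ones(n * n, bool), np.ones(n * n))
        # pixel size 1 so px == µm
        e = tfm.strain_energy(fld, tr, pixel_size_um=1.0)
        assert e == pytest.approx(0.5, rel=0.02)

    def test_quadrature_agreement_gaussian_patch(self):
        """Planted analytic u and T fields: node-sum integral matches direct
        numerical quadrature of ½ u·T within 2%."""
        n = 40
        w = 0.5
        xs = (np.arange(n) + 0.5) * w
        nodes = np.array([[x, y] for y in xs for x in xs])
        c = np.array([10.0, 10.0])
        r2 = ((nodes - c) ** 2).sum(axis=1)
        tmag = 200.0 * np.exp(-r2 / (2 * 2.0 ** 2))
        umag = 0.05 * np.exp(-r2 / (2 * 3.0 ** 2))
        tr = tfm.TractionField(nodes, w,
                               np.column_stack([tmag, np.zeros(n * n)]),
                               1e-3, 0.0, 0.0, mesh_shape=(n, n))
        fld = tfm.DisplacementField(nodes,
                                    np.column_stack([umag, np.zeros(n * n)]),
                                    np.ones(n * n, bool), np.ones(n * n))
        e = tfm.strain_energy(fld, tr, pixel_size_um=1.0)
        # oracle: dense quadrature of the closed-form integrand
        from scipy.integrate import dblquad
        integrand = lambda y, x: (0.5 * 200.0 * 0.05
                                  * np.exp(-((x - 10) ** 2 + (y - 10) ** 2)
                                           / (2 * 2.0 ** 2))
                                  * np.exp(-((x - 10) ** 2 + (y - 10) ** 2)
                                           / (2 * 3.0 ** 2)))
        ref, _ = dblquad(integrand, 0, 20, 0, 20, epsabs=1e-9)
        assert e == pytest.approx(ref * 1e-3, rel=0.02)

    def test_empty_mask_warns_zero(self, single_patch_recovery):
        d = single_patch_recovery
        with pytest.warns(UserWarning, match="empty"):
            e = tfm.strain_energy(d["field"], d["solution"],
                                  cell_mask_nodes=np.zeros(
                                      len(d["solution"].mesh_nodes), bool),
                                  pixel_size_um=0.08)
        assert e == 0.0


class TestReadTractionAt:
    def _grid_field(self):
        xs = np.arange(4) * 1.0
        nodes = np.array([[x, y] for y in xs for x in xs])
        mags = np.zeros((4, 4))
        mags[2:, :] = 100.0   # rows y>=2 at 100 Pa
        tr = np.zeros((16, 2))
        tr[:, 0] = mags.ravel()
        return tfm.TractionField(nodes, 1.0, tr, 1e-3, 0.0, 0.0,
                                 mesh_shape=(4, 4))

    def test_node_value_exact(self):
        t = self._grid_field()
        v, out = tfm.read_traction_at(t, np.array([[1.0, 2.0]]))
        assert v[0] == pytest.approx(100.0)
        assert not out[0]

    def test_bilinear_midpoint(self):
        t = self._grid_field()
        v, _ = tfm.read_traction_at(t, np.array([[1.5, 1.5]]))
        assert v[0] == pytest.approx(50.0)

    def test_out_of_field_clamped_and_flagged(self):
        t = self._grid_field()
        v, out = tfm.read_traction_at(t, np.array([[10.0, 10.0]]))
        assert out[0]
        assert v[0] == pytest.approx(100.0)
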