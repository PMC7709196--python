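"""Kernel, convolution, per-voxel regression, interpolation, shift application."""

import numpy as np
import pytest
from scipy import ndimage

from shiftfield import Atom, AtomicModel, UnitCell
from shiftfield.density import (
    DensityGrid,
    GridSpec,
    calc_structure_factors,
    choose_grid,
    gradient_maps,
    synthesize_from_coefficients,
)
from shiftfield.field import (
    ShiftField,
    apply_shifts,
    build_kernel,
    build_regression_fields,
    convolve,
    interpolate_shift,
    interpolate_trilinear,
    shift_field_cycle,
    solve_shift_field,
)
from shiftfield.likelihood import difference_coefficients
from shiftfield.reflections import ReflectionSet
from shiftfield.synthetic import enumerate_unique_hkl


def _grid(shape, d=3.0):
    return GridSpec(tuple(shape), d_min=d, oversample=1.5)


class TestKernel:
    def test_profile_values(self):
        """w(0) = 1 before normalization; w = 0 exactly beyond r0."""
        cell = UnitCell(40, 40, 40)
        grid = _grid((40, 40, 40))
        kern = build_kernel(grid, cell, 12.0, normalize=False)
        assert kern.values[0, 0, 0] == pytest.approx(1.0)
        fu = np.fft.fftfreq(40)
        du = np.stack(np.meshgrid(fu, fu, fu, indexing="ij"), axis=-1)
        r = np.linalg.norm(du @ cell.orth_matrix.T, axis=-1)
        assert np.all(kern.values[r >= 12.0 + 1e-9] == 0.0)
        # nonincreasing along the +u axis within the sphere
        axis_vals = kern.values[:13, 0, 0]
        assert (np.diff(axis_vals) <= 1e-12).all()

    def test_sphere_point_count_exceeds_5000(self):
        """A 12 Å kernel on a 1 Å grid contains > 5000 grid points."""
        cell = UnitCell(40, 40, 40)
        kern = build_kernel(_grid((40, 40, 40)), cell, 12.0, normalize=False)
        assert np.count_nonzero(kern.values) > 5000

    def test_oblique_cell_uses_orthogonal_distance(self):
        """In a 60-degree cell the kernel support is a sphere, not an ellipsoid."""
        cell = UnitCell(40, 40, 40, 90, 90, 60)
        kern = build_kernel(_grid((40, 40, 40)), cell, 10.0, normalize=False)
        fu = np.fft.fftfreq(40)
        du = np.stack(np.meshgrid(fu, fu, fu, indexing="ij"), axis=-1)
        r = np.linalg.norm(du @ cell.orth_matrix.T, axis=-1)
        inside = kern.values > 0
        assert np.all(r[inside] < 10.0)
        assert np.all(kern.values[(r > 0.5) & (r < 9.0)] > 0)

    def test_invalid_radius(self):
        cell = UnitCell(40, 40, 40)
        with pytest.raises(ValueError):
            build_kernel(_grid((40, 40, 40)), cell, -1.0)
        with pytest.raises(ValueError):
            build_kernel(_grid((40, 40, 40)), cell, 0.5)  # below grid spacing


class TestConvolve:
    def test_delta_reproduces_kernel(self):
        cell = UnitCell(16, 16, 16)
        kern = build_kernel(_grid((16, 16, 16)), cell, 5.0)
        delta = np.zeros((16, 16, 16))
        delta[0, 0, 0] = 1.0
        out = convolve(DensityGrid(cell, delta), kern)
        assert np.allclose(out.values, kern.values, atol=1e-12)

    def test_constant_preserved_by_unit_kernel(self):
        cell = UnitCell(16, 16, 16)
        kern = build_kernel(_grid((16, 16, 16)), cell, 5.0)
        out = convolve(DensityGrid(cell, np.full((16, 16, 16), 3.7)), kern)
        assert np.allclose(out.values, 3.7, atol=1e-10)

    def test_matches_direct_space_triple_loop(self, rng):
        """FFT circular convolution equals brute-force direct summation."""
        cell = UnitCell(16, 16, 16)
        a = rng.normal(size=(16, 16, 16))
        kern = build_kernel(_grid((16, 16, 16)), cell, 4.0)
        fast = convolve(DensityGrid(cell, a), kern).values
        slow = np.zeros_like(a)
        kv = kern.values
        nz = np.argwhere(kv != 0)
        for i, j, k in nz:
            slow += kv[i, j, k] * np.roll(a, (i, j, k), axis=(0, 1, 2))
        assert np.abs(fast - slow).max() < 1e-8 * np.abs(slow).max()

    def test_shape_mismatch(self):
        cell = UnitCell(16, 16, 16)
        with pytest.raises(ValueError):
            convolve(DensityGrid(cell, np.zeros((16, 16, 16))),
                     DensityGrid(cell, np.zeros((8, 8, 8))))


class TestRegressionFields:
    def test_zero_difference_zero_residual(self, rng):
        cell = UnitCell(16, 16, 16)
        kern = build_kernel(_grid((16, 16, 16)), cell, 5.0)
        grads = [DensityGrid(cell, rng.normal(size=(16, 16, 16))) for _ in range(3)]
        fields = build_regression_fields(DensityGrid(cell, np.zeros((16, 16, 16))), grads, kern)
        for r in fields.residual:
            assert np.allclose(r.values, 0.0)

    def test_constant_predictor_limit(self, rng):
        """With only the constant predictor: normal = 1, residual = smoothed diff."""
        cell = UnitCell(16, 16, 16)
        kern = build_kernel(_grid((16, 16, 16)), cell, 5.0)
        diff = DensityGrid(cell, rng.normal(size=(16, 16, 16)))
        fields = build_regression_fields(diff, [], kern, include_const=True, labels=())
        assert fields.labels == ("const",)
        assert np.allclose(fields.normal[(0, 0)].values, 1.0, atol=1e-10)
        assert np.allclose(fields.residual[0].values, convolve(diff, kern).values, atol=1e-12)

    def test_spot_check_against_direct_sum(self, rng):
        """normal_uv at one voxel equals the kernel-weighted sum over offsets."""
        cell = UnitCell(16, 16, 16)
        kern = build_kernel(_grid((16, 16, 16)), cell, 5.0)
        gu = DensityGrid(cell, rng.normal(size=(16, 16, 16)))
        gv = DensityGrid(cell, rng.normal(size=(16, 16, 16)))
        diff = DensityGrid(cell, rng.normal(size=(16, 16, 16)))
        fields = build_regression_fields(diff, [gu, gv], kern, labels=("u", "v"))
        p = (3, 11, 7)
        kv = kern.values
        nz = np.argwhere(kv != 0)
        total = 0.0
        for i, j, k in nz:
            q = ((p[0] - i) % 16, (p[1] - j) % 16, (p[2] - k) % 16)
            total += kv[i, j, k] * gu.values[q] * gv.values[q]
        assert fields.normal[(0, 1)].values[p] == pytest.approx(total, rel=1e-10)

    def test_normal_diag_nonnegative_and_symmetric_storage(self, rng):
        cell = UnitCell(16, 16, 16)
        kern = build_kernel(_grid((16, 16, 16)), cell, 5.0)
        grads = [DensityGrid(cell, rng.normal(size=(16, 16, 16))) for _ in range(3)]
        diff = DensityGrid(cell, rng.normal(size=(16, 16, 16)))
        fields = build_regression_fields(diff, grads, kern)
        for i in range(3):
            assert fields.normal[(i, i)].values.min() > -1e-10
        assert set(fields.normal) == {(i, j) for i in range(3) for j in range(i, 3)}


class TestSolve:
    def test_zero_residual_zero_field(self, rng):
        cell = UnitCell(8, 8, 8)
        kern = build_kernel(_grid((8, 8, 8)), cell, 3.0)
        grads = [DensityGrid(cell, rng.normal(size=(8, 8, 8))) for _ in range(3)]
        fields = build_regression_fields(DensityGrid(cell, np.zeros((8, 8, 8))), grads, kern)
        sf = solve_shift_field(fields)
        for c in sf.components:
            assert np.allclose(c.values, 0.0)

    def test_identity_normal_matrix(self):
        """N = I, r = (0.1, 0, -0.2) solves to exactly that vector at lambda = 0."""
        cell = UnitCell(8, 8, 8)
        shape = (8, 8, 8)
        import shiftfield.field as ff

        ones = DensityGrid(cell, np.ones(shape))
        zeros = DensityGrid(cell, np.zeros(shape))
        fields = ff.RegressionFields(
            ("u", "v", "w"),
            [DensityGrid(cell, np.full(shape, 0.1)), zeros.copy(),
             DensityGrid(cell, np.full(shape, -0.2))],
            {(0, 0): ones.copy(), (1, 1): ones.copy(), (2, 2): ones.copy(),
             (0, 1): zeros.copy(), (0, 2): zeros.copy(), (1, 2): zeros.copy()},
        )
        sf = solve_shift_field(fields, ridge_fraction=0.0)
        assert np.allclose(sf.components[0].values, 0.1, atol=1e-14)
        assert np.allclose(sf.components[1].values, 0.0, atol=1e-14)
        assert np.allclose(sf.components[2].values, -0.2, atol=1e-14)

    def test_random_spd_systems_match_dense_solver(self, rng):
        """Planted SPD 3x3 systems reproduce scipy's dense solve to 1e-10."""
        from scipy import linalg
        import shiftfield.field as ff

        cell = UnitCell(4, 4, 4)
        shape = (4, 4, 4)
        npts = 64
        mats = np.empty((npts, 3, 3))
        for p in range(npts):
            a = rng.normal(size=(3, 3))
            mats[p] = a @ a.T + 0.5 * np.eye(3)
        rhs = rng.normal(size=(npts, 3))
        normal = {}
        for i in range(3):
            for j in range(i, 3):
                normal[(i, j)] = DensityGrid(cell, mats[:, i, j].reshape(shape))
        residual = [DensityGrid(cell, rhs[:, i].reshape(shape)) for i in range(3)]
        fields = ff.RegressionFields(("u", "v", "w"), residual, normal)
        sf = solve_shift_field(fields, ridge_fraction=0.0)
        got = np.stack([c.values.reshape(-1) for c in sf.components], axis=1)
        for p in range(npts):
            expect = linalg.solve(mats[p], rhs[p], assume_a="sym")
            assert np.allclose(got[p], expect, atol=1e-10)

    def test_singular_voxels_get_zero(self):
        import shiftfield.field as ff

        cell = UnitCell(4, 4, 4)
        shape = (4, 4, 4)
        zeros = DensityGrid(cell, np.zeros(shape))
        fields = ff.RegressionFields(
            ("u",), [DensityGrid(cell, np.ones(shape))], {(0, 0): zeros}
        )
        sf = solve_shift_field(fields)
        assert np.allclose(sf.components[0].values, 0.0)
        assert np.isfinite(sf.components[0].values).all()


class TestInterpolation:
    def test_grid_node_exact(self, rng):
        cell = UnitCell(10, 10, 10)
        vals = rng.normal(size=(8, 10, 12))
        g = DensityGrid(cell, vals)
        assert interpolate_trilinear(g, np.array([[3 / 8, 7 / 10, 5 / 12]]))[0] == pytest.approx(
            vals[3, 7, 5]
        )

    def test_linear_ramp_exact_at_midpoints(self):
        """Trilinear interpolation is exact on fields linear in u."""
        cell = UnitCell(10, 10, 10)
        n = 8
        ramp = np.broadcast_to(np.arange(n)[:, None, None], (n, n, n)).astype(float)
        g = DensityGrid(cell, ramp.copy())
        for i in range(n - 1):
            u = (i + 0.5) / n
            assert interpolate_trilinear(g, np.array([[u, 0.3, 0.6]]))[0] == pytest.approx(i + 0.5)

    def test_against_scipy_oracle(self, rng):
        """1000 random points vs scipy's periodic spline-order-1 interpolator."""
        cell = UnitCell(10, 10, 10)
        vals = rng.normal(size=(9, 11, 13))
        g = DensityGrid(cell, vals)
        pts = rng.uniform(-1, 2, size=(1000, 3))
        ours = interpolate_trilinear(g, pts)
        coords = (pts % 1.0).T * np.array(vals.shape)[:, None]
        ref = ndimage.map_coordinates(vals, coords, order=1, mode="grid-wrap")
        assert np.abs(ours - ref).max() < 1e-12


class TestApplyShifts:
    def _uniform_field(self, cell, shape, vec):
        comps = [DensityGrid(cell, np.full(shape, v)) for v in vec]
        return ShiftField(("u", "v", "w"), comps)

    def test_zero_field_identity(self, helix10):
        sf = self._uniform_field(helix10.cell, (8, 8, 8), (0.0, 0.0, 0.0))
        out = apply_shifts(helix10, sf)
        assert np.allclose(out.frac_coords(), helix10.frac_coords())

    def test_uniform_shift_and_wrap(self, cubic_cell):
        model = AtomicModel(cubic_cell, [Atom("C", [0.995, 0.5, 0.5])])
        sf = self._uniform_field(cubic_cell, (8, 8, 8), (0.01, 0.0, 0.0))
        out = apply_shifts(model, sf, scale=1.0)
        assert out.atoms[0].frac[0] == pytest.approx(0.005)

    def test_biso_mode_floor(self, cubic_cell):
        model = AtomicModel(cubic_cell, [Atom("C", [0.5, 0.5, 0.5], b_iso=5.0)])
        sf = ShiftField(("biso",), [DensityGrid(cubic_cell, np.full((8, 8, 8), -100.0))])
        out = apply_shifts(model, sf, mode="biso")
        assert out.atoms[0].b_iso == pytest.approx(2.0)  # floored

    def test_constant_component_never_applied(self, cubic_cell):
        model = AtomicModel(cubic_cell, [Atom("C", [0.5, 0.5, 0.5])])
        comps = [DensityGrid(cubic_cell, np.full((8, 8, 8), v)) for v in (0.01, 0.02, 0.03, 99.0)]
        sf = ShiftField(("u", "v", "w", "const"), comps)
        out = apply_shifts(model, sf)
        assert np.allclose(out.atoms[0].frac, [0.51, 0.52, 0.53])


class TestRegressionOracle:
    def _cycle_fields(self, helix10, helix10_refl, include_const=False):
        """One toy-cycle's difference map, gradients and kernel at 4 Å."""
        from shiftfield.density import apply_scale, scale_fobs_fcalc
        from shiftfield.likelihood import (
            estimate_sigma_a, figures_of_merit, make_binning, normalize_amplitudes,
        )
        from shiftfield.reflections import truncate_resolution

        refl = truncate_resolution(helix10_refl, 4.0)
        fc = calc_structure_factors(helix10, refl)
        k, b = scale_fobs_fcalc(refl, fc)
        fc = apply_scale(fc, k, b)
        binning = make_binning(refl, 8)
        eo, ec = normalize_amplitudes(refl, fc, binning)
        sa = estimate_sigma_a(eo, ec, refl.free, binning, refl, fc)
        m, dlk = figures_of_merit(sa, eo, ec)
        # perturb fobs slightly so the difference map is non-trivial
        coeff = difference_coefficients(refl, fc, m * 0.95, dlk)
        grid = choose_grid(helix10.cell, 4.0)
        diff = synthesize_from_coefficients(refl, coeff, grid, helix10.cell)
        grads = gradient_maps(fc, grid, "coords")
        kern = build_kernel(grid, helix10.cell, 8.0)
        return diff, grads, kern

    def test_smoothed_solve_equals_explicit_wls(self, helix10, helix10_refl, rng):
        """Per-voxel solution equals an explicit weighted least squares over
        the kernel sphere, computed by direct summation, at 20 random voxels."""
        diff, grads, kern = self._cycle_fields(helix10, helix10_refl)
        fields = build_regression_fields(diff, grads, kern)
        sf = solve_shift_field(fields, ridge_fraction=0.0)
        shape = diff.shape
        kv = kern.values
        nz = np.argwhere(kv != 0)
        w = kv[nz[:, 0], nz[:, 1], nz[:, 2]]
        gvals = np.stack([g.values for g in grads])
        got = np.stack([c.values for c in sf.components])
        picks = rng.integers(0, np.array(shape), size=(20, 3))
        for p in picks:
            q = (p[None, :] - nz) % np.array(shape)
            gq = gvals[:, q[:, 0], q[:, 1], q[:, 2]]  # (3, npts)
            dq = diff.values[q[:, 0], q[:, 1], q[:, 2]]
            nmat = (gq * w) @ gq.T
            rvec = (gq * w) @ dq
            expect = np.linalg.solve(nmat, rvec)
            assert np.allclose(got[:, p[0], p[1], p[2]], expect, rtol=1e-6, atol=1e-9)

    def test_constant_term_absorbs_offset(self, helix10, helix10_refl):
        """Adding a constant to the difference map leaves coordinate shifts
        unchanged when the constant predictor is included."""
        diff, grads, kern = self._cycle_fields(helix10, helix10_refl)
        f1 = build_regression_fields(diff, grads, kern, include_const=True)
        sf1 = solve_shift_field(f1, ridge_fraction=0.0)
        shifted = DensityGrid(diff.cell, diff.values + 0.37)
        f2 = build_regression_fields(shifted, grads, kern, include_const=True)
        sf2 = solve_shift_field(f2, ridge_fraction=0.0)
        for c1, c2 in zip(sf1.components[:3], sf2.components[:3]):
            assert np.abs(c1.values - c2.values).max() < 1e-8

    def test_large_kernel_approaches_uniform_field(self, helix10, helix10_refl):
        """As r0 grows toward the cell size the shift field flattens."""
        diff, grads, _ = self._cycle_fields(helix10, helix10_refl)
        grid = GridSpec(diff.shape, 4.0, 1.5)
        spreads = []
        for r0 in (6.0, 24.0):
            kern = build_kernel(grid, helix10.cell, r0)
            sf = solve_shift_field(build_regression_fields(diff, grads, kern))
            spreads.append(
                max(float(c.values.max() - c.values.min()) for c in sf.components)
            )
        assert spreads[1] < 0.3 * spreads[0]


class TestCycle:
    def test_self_consistent_data_give_tiny_shifts(self, helix10_sym, helix10_sym_refl):
        """Data generated from the model itself: one cycle moves atoms < 0.05 Å."""
        _, stats = shift_field_cycle(helix10_sym, helix10_sym_refl, 6.0, 24.0)
        assert stats.max_shift < 0.05
        assert stats.r_work < 1e-6

    def test_no_data_after_truncation(self, helix10_sym, helix10_sym_refl):
        with pytest.raises(ValueError, match="no data"):
            shift_field_cycle(helix10_sym, helix10_sym_refl, 200.0, 800.0)

    def test_one_cycle_recovers_translation_from_ideal_difference_map(self, helix10):
        """The regression machinery alone (ideal complex difference map
        F_truth - F_model) recovers a planted 1 Å translation within 30%
        in a single 6 Å cycle with r0 = 24 Å."""
        from shiftfield.synthetic import (
            PerturbationSpec, SimulationSpec, perturb_model, simulate_observations,
        )

        start = perturb_model(
            helix10, PerturbationSpec("rigid_translation", 1.0, direction=(1, 0, 0))
        )
        refl = simulate_observations(helix10, SimulationSpec(d_min=6.0, seed=2))
        fc_truth = calc_structure_factors(helix10, refl)
        fc_model = calc_structure_factors(start, refl)
        grid = choose_grid(helix10.cell, 6.0)
        diff = synthesize_from_coefficients(
            refl, fc_truth.f_calc - fc_model.f_calc, grid, helix10.cell
        )
        grads = gradient_maps(fc_model, grid, "coords")
        kern = build_kernel(grid, helix10.cell, 24.0)
        sf = solve_shift_field(build_regression_fields(diff, grads, kern))
        mean_vec = interpolate_shift(sf, start.frac_coords()).mean(axis=0)
        mean_orth = helix10.cell.orth_matrix @ mean_vec
        assert np.linalg.norm(mean_orth - np.array([-1.0, 0, 0])) < 0.3

    def test_biso_cycle_runs(self, helix10_sym, helix10_sym_refl):
        bumped = helix10_sym.copy()
        bumped.set_b_values(helix10_sym.b_values() + 15.0)
        out, stats = shift_field_cycle(bumped, helix10_sym_refl, 4.0, 16.0, mode="biso")
        # B refinement moves B values back toward the truth
        assert out.b_values().mean() < bumped.b_values().mean()
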