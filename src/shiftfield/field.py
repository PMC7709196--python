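"""The shift-field regression: kernel smoothing, per-voxel solve, shift application.

At every grid point the likelihood-weighted difference map D is regressed
onto the gradient maps g_i of the calculated density over a surrounding
sphere, with weight w(r) = 1 - (r/r0)^2 falling to zero at the regression
radius r0.  Because the weight depends only on the offset between points,
both sides of the weighted normal equations

    [ sum_j w_j g_i(j) g_k(j) ] dx_k = sum_j w_j g_i(j) D(j)

are plain convolutions of pointwise product maps with the kernel, evaluated
for all voxels at once by FFT.  Solving the small (n x n) system per voxel
yields the shift field; atoms pick up their update by trilinear
interpolation at their fractional position.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .cell import UnitCell
from .density import (
    DensityGrid,
    GridSpec,
    apply_bulk_solvent,
    apply_scale,
    calc_structure_factors,
    choose_grid,
    gradient_maps,
    scale_fobs_fcalc,
    synthesize_from_coefficients,
)
from .likelihood import (
    difference_coefficients,
    estimate_sigma_a,
    figures_of_merit,
    make_binning,
    normalize_amplitudes,
    r_factors,
)
from .model import AtomicModel
from .reflections import ReflectionSet, truncate_resolution

__all__ = [
    "KernelSpec",
    "RegressionFields",
    "ShiftField",
    "build_kernel",
    "convolve",
    "build_regression_fields",
    "solve_shift_field",
    "interpolate_shift",
    "apply_shifts",
    "shift_field_cycle",
    "CycleStats",
]

log = logging.getLogger(__name__)

B_MIN = 2.0  # floor for refined isotropic B (Å^2)


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """Regression-sphere radius and its parabolic weight profile."""

    r0: float

    def weight(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return np.where(r < self.r0, 1.0 - (r / self.r0) ** 2, 0.0)


def build_kernel(grid: GridSpec, cell: UnitCell, r0: float, normalize: bool = True) -> DensityGrid:
    """Kernel map w(r) = 1 - (r/r0)^2 centred on the origin, periodically wrapped.

    r is the orthogonal (Å) distance of each grid point from the origin via
    the shortest periodic image, so the kernel is correct in oblique cells.
    Normalized to unit sum by default (the normalization cancels in the
    per-voxel solve but keeps logged field magnitudes interpretable).
    """
    if r0 <= 0:
        raise ValueError("kernel radius must be positive")
    nu, nv, nw = grid.shape
    spacing = max(
        np.linalg.norm(cell.orth_matrix[:, k]) / n for k, n in enumerate(grid.shape)
    )
    if r0 <= spacing:
        raise ValueError(f"kernel radius {r0} Å below grid spacing {spacing:.2f} Å")
    if 2.0 * r0 >= min(cell.lengths):
        log.warning("kernel diameter %.1f Å exceeds shortest cell edge: kernel wraps", 2 * r0)
    fu = np.fft.fftfreq(nu)  # signed fractional offsets, shortest image
    fv = np.fft.fftfreq(nv)
    fw = np.fft.fftfreq(nw)
    du = np.stack(np.meshgrid(fu, fv, fw, indexing="ij"), axis=-1)
    orth = du @ cell.orth_matrix.T
    r = np.sqrt(np.einsum("...i,...i->...", orth, orth))
    spec = KernelSpec(r0)
    w = spec.weight(r)
    if normalize:
        w /= w.sum()
    return DensityGrid(cell, w)


def convolve(map_: DensityGrid, kernel: DensityGrid) -> DensityGrid:
    """Periodic (circular) convolution of two maps on the same grid, via FFT."""
    if map_.shape != kernel.shape:
        raise ValueError("map and kernel grids differ")
    out = np.fft.irfftn(
        np.fft.rfftn(map_.values) * np.fft.rfftn(kernel.values),
        s=map_.shape, axes=(0, 1, 2),
    )
    return DensityGrid(map_.cell, out)


@dataclasses.dataclass
class RegressionFields:
    """Kernel-smoothed residual-vector and normal-matrix maps.

    labels: predictor names in order (subset of u, v, w, biso, const).
    residual[i] = convolve(D * g_i, kernel)
    normal[(i, j)] = convolve(g_i * g_j, kernel), stored for i <= j.
    """

    labels: tuple[str, ...]
    residual: list[DensityGrid]
    normal: dict[tuple[int, int], DensityGrid]

    @property
    def n(self) -> int:
        return len(self.labels)


def build_regression_fields(
    diff: DensityGrid,
    gradients: list[DensityGrid],
    kernel: DensityGrid,
    include_const: bool = False,
    labels: tuple[str, ...] | None = None,
) -> RegressionFields:
    """Smoothed product maps for the per-voxel weighted least squares."""
    preds = list(gradients)
    if labels is None:
        labels = ("u", "v", "w")[: len(gradients)] if len(gradients) == 3 else ("biso",)
    labels = tuple(labels)
    if include_const:
        preds = preds + [DensityGrid(diff.cell, np.ones(diff.shape))]
        labels = labels + ("const",)
    residual = [convolve(DensityGrid(diff.cell, diff.values * g.values), kernel) for g in preds]
    normal: dict[tuple[int, int], DensityGrid] = {}
    for i in range(len(preds)):
        for j in range(i, len(preds)):
            normal[(i, j)] = convolve(
                DensityGrid(diff.cell, preds[i].values * preds[j].values), kernel
            )
    return RegressionFields(labels, residual, normal)


@dataclasses.dataclass
class ShiftField:
    """Per-voxel parameter shifts, one 3D grid per predictor label."""

    labels: tuple[str, ...]
    components: list[DensityGrid]

    @property
    def cell(self) -> UnitCell:
        return self.components[0].cell

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components[0].shape


def solve_shift_field(
    fields: RegressionFields,
    ridge_fraction: float = 1e-6,
    abs_floor_fraction: float = 1e-12,
) -> ShiftField:
    """Solve (N + lambda I) dx = r at every grid point.

    lambda = ridge_fraction * max(diag N) per point keeps near-singular
    voxels (flat solvent) finite; points whose largest diagonal entry falls
    below ``abs_floor_fraction`` of the global maximum get zero shift.
    """
    n = fields.n
    shape = fields.residual[0].shape
    npts = int(np.prod(shape))
    nm = np.empty((npts, n, n))
    for i in range(n):
        for j in range(i, n):
            v = fields.normal[(i, j)].values.reshape(-1)
            nm[:, i, j] = v
            nm[:, j, i] = v
    rv = np.stack([r.values.reshape(-1) for r in fields.residual], axis=1)
    diag_max = np.max(np.einsum("pii->pi", nm), axis=1)
    floor = abs_floor_fraction * max(diag_max.max(), 0.0)
    ok = diag_max > max(floor, 0.0)
    lam = ridge_fraction * diag_max
    nm[:, np.arange(n), np.arange(n)] += lam[:, None]
    sol = np.zeros((npts, n))
    if ok.any():
        try:
            sol[ok] = np.linalg.solve(nm[ok], rv[ok, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            # last-resort per-point fallback; ridge should normally prevent this
            for p in np.nonzero(ok)[0]:
                sol[p] = np.linalg.lstsq(nm[p], rv[p], rcond=None)[0]
    sol[~np.isfinite(sol).all(axis=1)] = 0.0
    cell = fields.residual[0].cell
    comps = [DensityGrid(cell, sol[:, k].reshape(shape)) for k in range(n)]
    return ShiftField(fields.labels, comps)


def interpolate_trilinear(grid: DensityGrid, frac: np.ndarray) -> np.ndarray:
    """Periodic trilinear interpolation of a map at fractional positions (n, 3)."""
    frac = np.atleast_2d(np.asarray(frac, dtype=float))
    shape = np.array(grid.shape)
    g = frac * shape
    i0 = np.floor(g).astype(int)
    t = g - i0
    out = np.zeros(len(frac))
    for du in (0, 1):
        for dv in (0, 1):
            for dw in (0, 1):
                w = (
                    (t[:, 0] if du else 1 - t[:, 0])
                    * (t[:, 1] if dv else 1 - t[:, 1])
                    * (t[:, 2] if dw else 1 - t[:, 2])
                )
                idx = (i0 + np.array([du, dv, dw])) % shape
                out += w * grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out


def interpolate_shift(sf: ShiftField, frac: np.ndarray) -> np.ndarray:
    """Shift vector(s) at fractional position(s); (n, len(labels)) for (n, 3) input."""
    frac2 = np.atleast_2d(np.asarray(frac, dtype=float))
    out = np.stack([interpolate_trilinear(c, frac2) for c in sf.components], axis=1)
    return out[0] if np.asarray(frac).ndim == 1 else out


def apply_shifts(
    model: AtomicModel, sf: ShiftField, scale: float = 1.0, mode: str = "coords"
) -> AtomicModel:
    """Apply interpolated shift-field values to every atom.

    coords: fractional coordinates += scale * (du, dv, dw), wrapped.
    biso:   B += scale * dB, floored at B_MIN.  The constant component, if
    present, is a regression nuisance term and is never applied to atoms.
    """
    out = model.copy()
    if not out.atoms:
        return out
    frac = out.frac_coords()
    shifts = interpolate_shift(sf, frac)
    if mode == "coords":
        for k, lab in enumerate(("u", "v", "w")):
            if lab not in sf.labels:
                raise ValueError(f"shift field lacks component {lab!r} for coords mode")
        cols = [sf.labels.index(lab) for lab in ("u", "v", "w")]
        out.set_frac_coords(frac + scale * shifts[:, cols])
    elif mode == "biso":
        if "biso" not in sf.labels:
            raise ValueError("shift field lacks a biso component")
        col = sf.labels.index("biso")
        out.set_b_values(np.maximum(B_MIN, out.b_values() + scale * shifts[:, col]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


@dataclasses.dataclass
class CycleStats:
    """Per-cycle diagnostics logged by the refinement driver."""

    d: float
    r0: float
    n_refl: int
    r_work: float
    r_free: float
    mean_shift: float  # Å, orthogonal
    max_shift: float  # Å, orthogonal
    sigma_a: np.ndarray | None = None


def shift_field_cycle(
    model: AtomicModel,
    refl: ReflectionSet,
    d_cycle: float,
    r0: float,
    mode: str = "coords",
    include_const: bool = False,
    ridge_fraction: float = 1e-6,
    shift_scale: float = 1.0,
    solvent: bool = False,
    k_sol: float = 0.35,
    b_sol: float = 46.0,
    n_bins: int = 12,
    oversample: float = 1.5,
    include_free_in_diff: bool = False,
    include_hydrogens: bool = False,
) -> tuple[AtomicModel, CycleStats]:
    """One complete shift-field refinement cycle at resolution ``d_cycle``.

    Truncates the data, computes scaled structure factors and the sigma_A
    difference map, regresses it onto the gradient maps over spheres of
    radius ``r0``, and applies the interpolated shifts to the atoms.
    """
    refl_d = truncate_resolution(refl, d_cycle)
    if len(refl_d) == 0:
        raise ValueError(f"no data at {d_cycle:.2f} Å resolution")
    fc = calc_structure_factors(model, refl_d, include_hydrogens=include_hydrogens)
    if solvent:
        fc = apply_bulk_solvent(fc, k_sol, b_sol)
    k, b_overall = scale_fobs_fcalc(refl_d, fc)
    fc = apply_scale(fc, k, b_overall)
    r_work, r_free = r_factors(refl_d, fc)

    binning = make_binning(refl_d, n_bins=n_bins)
    e_obs, e_calc = normalize_amplitudes(refl_d, fc, binning)
    sa = estimate_sigma_a(e_obs, e_calc, refl_d.free, binning, refl_d, fc)
    centric = refl_d.sym.is_centric(refl_d.hkl)
    m, d_lk = figures_of_merit(sa, e_obs, e_calc, centric)
    coeff = difference_coefficients(refl_d, fc, m, d_lk, include_free=include_free_in_diff)
    # The m|Fo|-D|Fc| synthesis shows acentric errors at half height; the
    # Gauss-Newton gradient coefficients are 2(m|Fo|-D|Fc|) for acentric
    # reflections and 1x for centric, so double the acentrics here.
    coeff = np.where(centric, coeff, 2.0 * coeff)

    grid = choose_grid(model.cell, d_cycle, oversample=oversample)
    diff = synthesize_from_coefficients(refl_d, coeff, grid, model.cell)
    grads = gradient_maps(fc, grid, mode="coords" if mode == "coords" else "biso")
    kernel = build_kernel(grid, model.cell, r0)
    fields = build_regression_fields(diff, grads, kernel, include_const=include_const)
    sf = solve_shift_field(fields, ridge_fraction=ridge_fraction)
    new_model = apply_shifts(model, sf, scale=shift_scale, mode=mode)

    if mode == "coords":
        cols = [sf.labels.index(lab) for lab in ("u", "v", "w")]
        shifts = interpolate_shift(sf, model.frac_coords())[:, cols] * shift_scale
        orth = shifts @ model.cell.orth_matrix.T
        mags = np.linalg.norm(orth, axis=1)
    else:
        col = sf.labels.index("biso")
        mags = np.abs(interpolate_shift(sf, model.frac_coords())[:, col]) * shift_scale
    stats = CycleStats(
        d=d_cycle,
        r0=r0,
        n_refl=len(refl_d),
        r_work=r_work,
        r_free=r_free,
        mean_shift=float(mags.mean()) if len(mags) else 0.0,
        max_shift=float(mags.max()) if len(mags) else 0.0,
        sigma_a=sa.sigma_a.copy(),
    )
    log.info(
        "cycle d=%.2f r0=%.1f nrefl=%d r_work=%.4f r_free=%.4f mean_shift=%.4f max_shift=%.4f",
        d_cycle, r0, len(refl_d), r_work, r_free, stats.mean_shift, stats.max_shift,
    )
    return new_model, stats
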