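"""Structure factors, electron-density synthesis and Lifchitz gradient maps.

Conventions used throughout (and pinned by the test suite):

* density synthesis  rho(x) = (1/V) * sum_h F(h) exp(-2*pi*i h.x)
* structure factors  F(h) = sum_atoms occ * f(s) * exp(-B s^2/4) * exp(+2*pi*i h.x)
* coordinate gradient maps g_k are the density change per unit *positive*
  fractional shift of the atoms along axis k, i.e. the synthesis of
  (+2*pi*i h_k) F(h) under the convention above.  Translating the model by a
  small delta changes the map by ~ sum_k g_k * delta_k; this orientation is
  what makes the shift-field regression return shifts that move atoms toward
  positive difference density.

Atomic scattering factors are the standard International Tables 4-Gaussian
parameterizations (taken from gemmi's element tables):
f(s) = sum_i a_i exp(-b_i s^2/4) + c, with s = 1/d.
"""

from __future__ import annotations

import dataclasses
import logging
from functools import lru_cache

import gemmi
import numpy as np

from .cell import UnitCell
from .model import AtomicModel
from .reflections import ReflectionSet

__all__ = [
    "FormFactorModel",
    "ComplexStructureFactors",
    "GridSpec",
    "DensityGrid",
    "choose_grid",
    "calc_structure_factors",
    "calc_structure_factors_fft",
    "apply_bulk_solvent",
    "scale_fobs_fcalc",
    "apply_scale",
    "synthesize_map",
    "synthesize_from_coefficients",
    "gradient_maps",
    "sample_density",
    "write_ccp4_map",
]

log = logging.getLogger(__name__)

# Direct summation up to this many atom images; density-sampling + FFT beyond.
DIRECT_SUM_ATOM_LIMIT = 2000


class FormFactorModel:
    """Sum-of-Gaussians X-ray scattering factors per element."""

    @staticmethod
    @lru_cache(maxsize=None)
    def coefficients(element: str) -> tuple[np.ndarray, np.ndarray, float]:
        el = gemmi.Element(element)
        if el.atomic_number == 0:
            raise ValueError(f"no scattering factors for element {element!r}")
        it92 = el.it92
        return np.array(it92.a), np.array(it92.b), float(it92.c)

    @classmethod
    def evaluate(cls, element: str, s2: np.ndarray) -> np.ndarray:
        """f(s) at s^2 = 1/d^2 (Å⁻²); vectorized over s2."""
        a, b, c = cls.coefficients(element)
        s2 = np.asarray(s2, dtype=float)
        return np.exp(-b * s2[..., None] / 4.0) @ a + c


@dataclasses.dataclass
class ComplexStructureFactors:
    """Calculated structure factors aligned with a ReflectionSet.

    ``scale_k``/``scale_b`` record the overall scale applied to ``f_calc``
    (identity 1.0/0.0 until :func:`apply_scale` runs).
    """

    refl: ReflectionSet
    f_calc: np.ndarray  # complex, len(refl)
    scale_k: float = 1.0
    scale_b: float = 0.0

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.f_calc)

    @property
    def phases(self) -> np.ndarray:
        return np.angle(self.f_calc)


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """FFT grid sampling for a cell at a working resolution."""

    shape: tuple[int, int, int]
    d_min: float
    oversample: float

    @property
    def size(self) -> int:
        n = self.shape
        return n[0] * n[1] * n[2]


@dataclasses.dataclass
class DensityGrid:
    """Periodic real-valued density over the unit cell.

    ``values[i, j, k]`` sits at fractional position (i/nu, j/nv, k/nw).
    """

    cell: UnitCell
    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.cell, self.values.copy())


def _fft_friendly(n: int) -> int:
    """Smallest integer >= n whose prime factors are all in {2, 3, 5, 7}."""
    m = max(int(n), 2)
    while True:
        k = m
        for p in (2, 3, 5, 7):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += 1


def choose_grid(cell: UnitCell, d: float, oversample: float = 1.5) -> GridSpec:
    """Pick grid dimensions so spacing <= d / (2 * oversample) on every axis.

    The default oversampling of 1.5 gives ~d/3 spacing (a 1 Å grid for 3 Å
    data), rounded up to FFT-efficient sizes.
    """
    if d <= 0:
        raise ValueError("resolution must be positive")
    dims = []
    for edge in cell.lengths:
        n_min = int(np.ceil(2.0 * oversample * edge / d))
        dims.append(_fft_friendly(n_min))
    return GridSpec(tuple(dims), d_min=d, oversample=oversample)


def _atom_arrays(model: AtomicModel, include_hydrogens: bool):
    model = model.expand_to_p1()
    atoms = [a for a in model.atoms if include_hydrogens or a.element.upper() != "H"]
    if not atoms:
        raise ValueError("no scattering atoms in model")
    frac = np.array([a.frac for a in atoms])
    occ = np.array([a.occ for a in atoms])
    b_iso = np.array([a.b_iso for a in atoms])
    elements = np.array([a.element for a in atoms])
    return frac, occ, b_iso, elements


def calc_structure_factors(
    model: AtomicModel,
    refl: ReflectionSet,
    include_hydrogens: bool = False,
    method: str = "auto",
) -> ComplexStructureFactors:
    """F_calc for every reflection of `refl` from the (symmetry-expanded) model.

    ``method`` is "direct", "fft" or "auto" (direct summation up to
    ``DIRECT_SUM_ATOM_LIMIT`` atom images, density sampling + FFT beyond).
    """
    frac, occ, b_iso, elements = _atom_arrays(model, include_hydrogens)
    if method == "auto":
        method = "direct" if len(frac) <= DIRECT_SUM_ATOM_LIMIT else "fft"
    if method == "fft":
        return calc_structure_factors_fft(model, refl, include_hydrogens=include_hydrogens)
    s2 = refl.inv_d2
    f_calc = np.zeros(len(refl), dtype=complex)
    phase = np.exp(2j * np.pi * (refl.hkl @ frac.T))  # (n_refl, n_atoms)
    for element in np.unique(elements):
        sel = elements == element
        f0 = FormFactorModel.evaluate(element, s2)  # (n_refl,)
        debye = np.exp(-np.outer(s2 / 4.0, b_iso[sel]))  # (n_refl, n_sel)
        f_calc += f0 * ((phase[:, sel] * debye) @ occ[sel])
    return ComplexStructureFactors(refl, f_calc)


def sample_density(
    model: AtomicModel,
    grid: GridSpec,
    include_hydrogens: bool = False,
    b_extra: float = 0.0,
) -> DensityGrid:
    """Real-space Gaussian density of the model sampled on the grid.

    ``b_extra`` adds uniform Gaussian smearing (deconvolved again by the FFT
    structure-factor path); it keeps sharp zero-B atoms representable on a
    finite grid.
    """
    frac, occ, b_iso, elements = _atom_arrays(model, include_hydrogens)
    nu, nv, nw = grid.shape
    rho = np.zeros(grid.shape)
    orth = model.cell.orth_matrix
    spacing = float(min(np.linalg.norm(orth[:, k]) / n for k, n in enumerate(grid.shape)))
    for x, q, b, element in zip(frac, occ, b_iso, elements):
        a_coef, b_coef, c_coef = FormFactorModel.coefficients(element)
        # include the constant term as a Gaussian of width given by B alone
        aa = np.append(a_coef, c_coef)
        bb = np.append(b_coef, 0.0) + b + b_extra
        if np.any(bb <= 0):
            raise ValueError("zero-width atomic Gaussian; increase b_extra")
        # cutoff where the widest Gaussian falls to 1e-7 of its peak
        r_cut = float(np.sqrt(bb.max() * np.log(1e7)) / (2.0 * np.pi)) + spacing
        # local box of grid points within r_cut of the atom (per-axis extent)
        ext = np.ceil(r_cut / (np.linalg.norm(orth, axis=0) / np.array(grid.shape))).astype(int)
        centre = np.round(x * np.array(grid.shape)).astype(int)
        iu = np.arange(centre[0] - ext[0], centre[0] + ext[0] + 1)
        iv = np.arange(centre[1] - ext[1], centre[1] + ext[1] + 1)
        iw = np.arange(centre[2] - ext[2], centre[2] + ext[2] + 1)
        fu = iu / nu - x[0]
        fv = iv / nv - x[1]
        fw = iw / nw - x[2]
        du = np.stack(np.meshgrid(fu, fv, fw, indexing="ij"), axis=-1)
        r2 = np.einsum("...i,...i->...", du @ orth.T, du @ orth.T)
        dens = np.zeros(r2.shape)
        for ai, bi in zip(aa, bb):
            dens += q * ai * (4.0 * np.pi / bi) ** 1.5 * np.exp(-4.0 * np.pi**2 * r2 / bi)
        np.add.at(
            rho,
            (
                np.mod(iu, nu)[:, None, None],
                np.mod(iv, nv)[None, :, None],
                np.mod(iw, nw)[None, None, :],
            ),
            dens,
        )
    return DensityGrid(model.cell, rho)


def calc_structure_factors_fft(
    model: AtomicModel,
    refl: ReflectionSet,
    include_hydrogens: bool = False,
    b_extra: float = 15.0,
    oversample: float = 2.5,
) -> ComplexStructureFactors:
    """Structure factors by density sampling and forward FFT.

    Production path for large models; must agree with direct summation to
    ~1e-3 relative (asserted in the tests).
    """
    grid = choose_grid(model.cell, refl.d_min, oversample=oversample)
    rho = sample_density(model, grid, include_hydrogens, b_extra=b_extra)
    coeff = np.fft.ifftn(rho.values) * model.cell.volume
    nu, nv, nw = grid.shape
    h = refl.hkl
    f = coeff[np.mod(h[:, 0], nu), np.mod(h[:, 1], nv), np.mod(h[:, 2], nw)]
    # undo the b_extra smearing
    f = f * np.exp(b_extra * refl.inv_d2 / 4.0)
    return ComplexStructureFactors(refl, f)


def apply_bulk_solvent(
    fc: ComplexStructureFactors, k_sol: float = 0.35, b_sol: float = 46.0
) -> ComplexStructureFactors:
    """Babinet-style bulk-solvent attenuation F <- F (1 - k_sol exp(-b_sol s^2/4))."""
    if k_sol < 0 or b_sol < 0:
        raise ValueError("solvent parameters must be non-negative")
    s2 = fc.refl.inv_d2
    factor = 1.0 - k_sol * np.exp(-b_sol * s2 / 4.0)
    return ComplexStructureFactors(fc.refl, fc.f_calc * factor, fc.scale_k, fc.scale_b)


def scale_fobs_fcalc(refl: ReflectionSet, fc: ComplexStructureFactors) -> tuple[float, float]:
    """Overall (k, B) putting |Fc| on the |Fo| scale.

    Least-squares fit of log(|Fo|/|Fc|) against s^2/4 over work reflections:
    |Fo| ~ k exp(-B s^2/4) |Fc|.
    """
    amp = fc.amplitudes
    work = ~refl.free
    ok = work & (amp > 0) & (refl.f_obs > 0)
    if ok.sum() < 2:
        raise ValueError("not enough reflections with non-zero |Fc| for scaling")
    y = np.log(refl.f_obs[ok] / amp[ok])
    x = refl.inv_d2[ok] / 4.0
    slope, intercept = np.polyfit(x, y, 1)
    return float(np.exp(intercept)), float(-slope)


def apply_scale(fc: ComplexStructureFactors, k: float, b_overall: float) -> ComplexStructureFactors:
    """Return structure factors with |Fc| <- k exp(-B s^2/4) |Fc|."""
    s2 = fc.refl.inv_d2
    return ComplexStructureFactors(
        fc.refl, fc.f_calc * k * np.exp(-b_overall * s2 / 4.0), k, b_overall
    )


def _coefficient_grid(refl: ReflectionSet, coeff: np.ndarray, shape: tuple[int, int, int]):
    nu, nv, nw = shape
    h = refl.hkl
    if np.any(np.abs(h) >= np.array(shape) / 2.0):
        raise ValueError("grid below Nyquist for these reflections")
    grid = np.zeros(shape, dtype=complex)
    iu, iv, iw = np.mod(h[:, 0], nu), np.mod(h[:, 1], nv), np.mod(h[:, 2], nw)
    grid[iu, iv, iw] = coeff
    # Friedel completion: coefficient at -h is the conjugate
    ju, jv, jw = np.mod(-h[:, 0], nu), np.mod(-h[:, 1], nv), np.mod(-h[:, 2], nw)
    grid[ju, jv, jw] = np.conj(coeff)
    return grid


def synthesize_from_coefficients(
    refl: ReflectionSet, coeff: np.ndarray, grid: GridSpec, cell: UnitCell
) -> DensityGrid:
    """Real Fourier synthesis (1/V) sum_h c(h) e^{-2 pi i h.x} with Friedel completion."""
    cgrid = _coefficient_grid(refl, np.asarray(coeff, dtype=complex), grid.shape)
    rho = np.fft.fftn(cgrid) / cell.volume
    return DensityGrid(cell, np.ascontiguousarray(rho.real))


def synthesize_map(fc: ComplexStructureFactors, grid: GridSpec) -> DensityGrid:
    """Electron-density map from calculated structure factors."""
    return synthesize_from_coefficients(fc.refl, fc.f_calc, grid, fc.refl.cell)


def gradient_maps(
    fc: ComplexStructureFactors, grid: GridSpec, mode: str = "coords"
) -> list[DensityGrid]:
    """Derivative maps of the calculated density w.r.t. model parameters.

    coords: three maps g_u, g_v, g_w from coefficients (+2 pi i h_k) F(h);
    g_k is the density change per unit positive fractional shift along axis k.
    biso: one map from (-s^2/4) F(h), the density change per unit B increase.
    """
    refl = fc.refl
    if mode == "coords":
        return [
            synthesize_from_coefficients(
                refl, 2j * np.pi * refl.hkl[:, k] * fc.f_calc, grid, refl.cell
            )
            for k in range(3)
        ]
    if mode == "biso":
        return [
            synthesize_from_coefficients(
                refl, -(refl.inv_d2 / 4.0) * fc.f_calc, grid, refl.cell
            )
        ]
    raise ValueError(f"unknown gradient mode {mode!r}")


def write_ccp4_map(grid: DensityGrid, path: str) -> None:
    """Dump a density grid as a CCP4 map for visual inspection."""
    g = gemmi.FloatGrid(np.asarray(grid.values, dtype=np.float32))
    g.set_unit_cell(grid.cell.to_gemmi())
    g.spacegroup = gemmi.SpaceGroup("P 1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(path)
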