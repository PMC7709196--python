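"""Synthetic ground-truth structures, perturbations and simulated observations.

Everything needed to validate the refinement by parameter recovery without
external data: ideal-geometry polyalanine backbones in P1 cells, rigid and
hinge perturbations emulating molecular-replacement errors (misplaced or
rotated domains), error-free or noisy simulated amplitude data with a free-R
partition, and the matched-r.m.s.d. scoring metrics.

All randomness flows through explicit integer seeds; fixtures are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .cell import SymmetryOps, UnitCell
from .density import calc_structure_factors
from .model import Atom, AtomicModel
from .reflections import ReflectionSet

__all__ = [
    "PerturbationSpec",
    "SimulationSpec",
    "make_toy_structure",
    "perturb_model",
    "simulate_observations",
    "enumerate_unique_hkl",
    "matched_rmsd",
    "align_residue_pairs",
    "needleman_wunsch",
]

# ideal backbone internal coordinates (lengths Å, angles deg)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_CA_C_O = 120.8
_HELIX_PHI, _HELIX_PSI, _OMEGA = -57.0, -47.0, 180.0

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural extension reference frame: position of atom d from a-b-c chain."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(n_residues: int, phi_psi) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O per residue) in orthogonal Å from torsion angles."""
    residues: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    c = ca + np.array([-_BOND_CA_C * math.cos(ang), _BOND_CA_C * math.sin(ang), 0.0])
    for i in range(n_residues):
        phi, psi = phi_psi(i)
        if i > 0:
            n_new = _place_atom(residues[-1]["N"], residues[-1]["CA"], residues[-1]["C"],
                                _BOND_C_N, _ANG_CA_C_N, psi_prev)
            ca = _place_atom(residues[-1]["CA"], residues[-1]["C"], n_new,
                             _BOND_N_CA, _ANG_C_N_CA, _OMEGA)
            c = _place_atom(residues[-1]["C"], n_new, ca, _BOND_CA_C, _ANG_N_CA_C, phi)
            n = n_new
        o = _place_atom(n, ca, c, _BOND_C_O, _ANG_CA_C_O, psi + 180.0)
        residues.append({"N": n, "CA": ca, "C": c, "O": o})
        psi_prev = psi
    return residues


def make_toy_structure(
    style: str = "poly_ala_helix",
    n_residues: int = 10,
    cell_padding: float = 8.0,
    angles: tuple[float, float, float] = (90.0, 90.0, 90.0),
    b_iso: float = 20.0,
    spacegroup: str = "P 1",
    seed: int = 0,
) -> AtomicModel:
    """Ideal-geometry polyalanine backbone in a triclinic cell.

    Styles: ``poly_ala_helix`` (one alpha-helix), ``two_domain_helix_pair``
    (two helices offset by >10 Å, consecutive residue numbering, one chain),
    ``random_coil`` (seeded random torsions).  The cell encloses the model
    with ``cell_padding`` Å on every side.

    A non-P1 ``spacegroup`` (e.g. "P 21 21 21", which requires the default
    90-degree angles) populates the cell with symmetry mates; this pins the
    origin, which amplitude data in P1 cannot do, and is therefore the
    setting for whole-model translation-recovery studies.  Self-contact of
    symmetry images closer than 3 Å raises an error.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    if style == "poly_ala_helix":
        residues = _build_backbone(n_residues, lambda i: (_HELIX_PHI, _HELIX_PSI))
    elif style == "random_coil":
        tors = rng.uniform([-160.0, -80.0], [-50.0, 160.0], size=(n_residues, 2))
        residues = _build_backbone(n_residues, lambda i: tuple(tors[i]))
    elif style == "two_domain_helix_pair":
        n1 = n_residues // 2
        dom1 = _build_backbone(n1, lambda i: (_HELIX_PHI, _HELIX_PSI))
        dom2 = _build_backbone(n_residues - n1, lambda i: (_HELIX_PHI, _HELIX_PSI))
        offset = np.array([0.0, 18.0, 0.0])
        for res in dom2:
            for k in res:
                res[k] = res[k] + offset
        residues = dom1 + dom2
    else:
        raise ValueError(f"unknown style {style!r}")

    coords = np.array([res[name] for res in residues for name in ("N", "CA", "C", "O")])
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    if 2.0 * cell_padding < 3.0:
        raise ValueError("cell padding too small: periodic images would be in contact")
    edges = (hi - lo) + 2.0 * cell_padding
    cell = UnitCell(float(edges[0]), float(edges[1]), float(edges[2]), *angles)
    sym = SymmetryOps.p1() if spacegroup in ("P 1", "P1") else SymmetryOps.from_spacegroup(spacegroup)
    # place the model with `cell_padding` clearance from the cell origin;
    # for oblique cells convert through the orthogonalization matrix
    frac_all = cell.fractionalize(coords - lo + cell_padding)
    if not sym.is_p1:
        # centre the molecule in its asymmetric-unit quadrant and check
        # that no symmetry image comes within contact distance
        images = sym.apply(frac_all)
        for img in images[1:]:
            dmin = min(
                cell.min_image_distance(frac_all, np.tile(x, (len(frac_all), 1))).min()
                for x in img
            )
            if dmin < 3.0:
                raise ValueError(
                    f"symmetry images clash ({dmin:.1f} Å); increase cell_padding"
                )
    atoms: list[Atom] = []
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    i = 0
    for resnum, res in enumerate(residues, start=1):
        for name in ("N", "CA", "C", "O"):
            atoms.append(
                Atom(
                    element=elements[name],
                    frac=frac_all[i],
                    occ=1.0,
                    b_iso=b_iso,
                    chain="A",
                    resnum=resnum,
                    resname="ALA",
                    name=name,
                )
            )
            i += 1
    return AtomicModel(cell, atoms, sym)


@dataclasses.dataclass
class PerturbationSpec:
    """How to damage a ground-truth model before attempting recovery.

    kind: rigid_translation | hinge_rotation | random_jitter.
    magnitude: Å for translation/jitter (r.m.s. for jitter), degrees for rotation.
    selection: None for all atoms, or (first_resnum, last_resnum) inclusive.
    axis/pivot: rotation axis direction and pivot point, orthogonal Å
    (pivot defaults to the selection centroid).
    """

    kind: str
    magnitude: float
    selection: tuple[int, int] | None = None
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    pivot: tuple[float, float, float] | None = None
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("perturbation magnitude must be non-negative")
        if self.kind not in ("rigid_translation", "hinge_rotation", "random_jitter"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


def perturb_model(model: AtomicModel, spec: PerturbationSpec) -> AtomicModel:
    """Apply a rigid translation, hinge rotation or random jitter to a selection."""
    out = model.copy()
    if spec.selection is None:
        mask = np.ones(len(out), dtype=bool)
    else:
        lo, hi = spec.selection
        mask = np.array([lo <= a.resnum <= hi for a in out.atoms])
    if not mask.any():
        raise ValueError("perturbation selection is empty")
    orth = out.orth_coords()
    sel = orth[mask]
    if spec.kind == "rigid_translation":
        direction = np.asarray(spec.direction, dtype=float)
        direction /= np.linalg.norm(direction)
        sel = sel + spec.magnitude * direction
    elif spec.kind == "hinge_rotation":
        axis = np.asarray(spec.axis, dtype=float)
        axis /= np.linalg.norm(axis)
        pivot = (
            sel.mean(axis=0) if spec.pivot is None else np.asarray(spec.pivot, dtype=float)
        )
        theta = math.radians(spec.magnitude)
        k = axis
        v = sel - pivot
        # Rodrigues rotation
        sel = (
            pivot
            + v * math.cos(theta)
            + np.cross(k, v) * math.sin(theta)
            + np.outer(v @ k, k) * (1.0 - math.cos(theta))
        )
    else:  # random_jitter
        rng = np.random.default_rng(spec.seed)
        disp = rng.normal(size=sel.shape)
        disp *= spec.magnitude / max(np.sqrt(np.mean(np.sum(disp**2, axis=1))), 1e-30)
        sel = sel + disp
    orth[mask] = sel
    out.set_frac_coords(model.cell.fractionalize(orth))
    return out


@dataclasses.dataclass
class SimulationSpec:
    """Conditions for simulated amplitude data from a ground-truth model."""

    d_min: float = 3.0
    noise_fraction: float = 0.0
    free_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be non-negative")
        if not 0.0 <= self.free_fraction <= 0.5:
            raise ValueError("free fraction must be in [0, 0.5]")


def enumerate_unique_hkl(cell: UnitCell, d_min: float) -> np.ndarray:
    """All unique Miller indices (one per Friedel pair, P1) with d >= d_min."""
    hmax = [int(np.floor(edge / d_min)) + 1 for edge in cell.lengths]
    ranges = [np.arange(-m, m + 1) for m in hmax]
    h, k, l = np.meshgrid(*ranges, indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacing(hkl)
    hkl = hkl[d >= d_min]
    # keep one hemisphere: h > 0, or h == 0 and k > 0, or h == k == 0 and l > 0
    h, k, l = hkl.T
    keep = (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l > 0))
    return hkl[keep]


def simulate_observations(truth: AtomicModel, spec: SimulationSpec) -> ReflectionSet:
    """Simulated amplitude data: |Fo| = |Fc(truth)| (1 + eps), seeded free flags.

    eps ~ Normal(0, noise_fraction) clipped at -0.9; sigma(|Fo|) is set to
    noise_fraction * |Fo|.
    """
    hkl = enumerate_unique_hkl(truth.cell, spec.d_min)
    if len(hkl) < 10:
        raise ValueError(f"only {len(hkl)} reflections to {spec.d_min} Å; cell too small")
    placeholder = ReflectionSet(truth.cell, hkl, np.ones(len(hkl)))
    fc = calc_structure_factors(truth, placeholder)
    amp = fc.amplitudes
    rng = np.random.default_rng(spec.seed)
    eps = np.clip(rng.normal(0.0, spec.noise_fraction, size=len(hkl)), -0.9, None) \
        if spec.noise_fraction > 0 else np.zeros(len(hkl))
    f_obs = amp * (1.0 + eps)
    free = rng.uniform(size=len(hkl)) < spec.free_fraction
    return ReflectionSet(truth.cell, hkl, f_obs, spec.noise_fraction * f_obs, free, truth.sym)


def _matched_pairs(model_a: AtomicModel, model_b: AtomicModel):
    index_b = {(a.chain, a.resnum, a.name): a for a in model_b.atoms}
    pairs = []
    for a in model_a.atoms:
        b = index_b.get((a.chain, a.resnum, a.name))
        if b is not None:
            pairs.append((a, b))
    return pairs


def matched_rmsd(
    model_a: AtomicModel, model_b: AtomicModel, selection_rule: str = "all_atoms"
) -> float:
    """R.m.s.d. (Å, minimum-image) over atoms matched by chain/residue/name.

    selection_rule:
      * ``all_atoms`` — every matched atom;
      * ``ca_only`` — matched CA atoms;
      * ``ca_within_3A`` — matched CA atoms excluding pairs more than 3 Å
        apart, which removes outlier residues that would otherwise dominate.
    """
    pairs = _matched_pairs(model_a, model_b)
    if selection_rule in ("ca_only", "ca_within_3A"):
        pairs = [(a, b) for a, b in pairs if a.name == "CA"]
    if not pairs:
        raise ValueError("no matched atoms between the two models")
    fa = np.array([a.frac for a, _ in pairs])
    fb = np.array([b.frac for _, b in pairs])
    dist = model_a.cell.min_image_distance(fa, fb)
    if selection_rule == "ca_within_3A":
        keep = dist <= 3.0
        if not keep.any():
            raise ValueError("no matched CA pairs within 3 Å")
        dist = dist[keep]
    return float(np.sqrt(np.mean(dist**2)))


def needleman_wunsch(
    seq_a: str, seq_b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[int, list[tuple[int, int]]]:
    """Global alignment; returns (score, aligned index pairs excluding gaps)."""
    na, nb = len(seq_a), len(seq_b)
    score = np.zeros((na + 1, nb + 1), dtype=int)
    score[:, 0] = gap * np.arange(na + 1)
    score[0, :] = gap * np.arange(nb + 1)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            diag = score[i - 1, j - 1] + (match if seq_a[i - 1] == seq_b[j - 1] else mismatch)
            score[i, j] = max(diag, score[i - 1, j] + gap, score[i, j - 1] + gap)
    pairs: list[tuple[int, int]] = []
    i, j = na, nb
    while i > 0 and j > 0:
        sub = match if seq_a[i - 1] == seq_b[j - 1] else mismatch
        if score[i, j] == score[i - 1, j - 1] + sub:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif score[i, j] == score[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return int(score[na, nb]), pairs


def _chain_sequences(model: AtomicModel) -> dict[str, list[tuple[int, str]]]:
    seqs: dict[str, dict[int, str]] = {}
    for a in model.atoms:
        seqs.setdefault(a.chain, {})[a.resnum] = THREE_TO_ONE.get(a.resname, "X")
    return {ch: sorted(res.items()) for ch, res in seqs.items()}


def align_residue_pairs(
    model_a: AtomicModel, model_b: AtomicModel
) -> list[tuple[str, int, int]]:
    """Aligned residue pairs (chain, resnum_a, resnum_b) by per-chain global alignment."""
    seqs_a = _chain_sequences(model_a)
    seqs_b = _chain_sequences(model_b)
    common = sorted(set(seqs_a) & set(seqs_b))
    if not common:
        raise ValueError("models share no chain identifiers")
    out: list[tuple[str, int, int]] = []
    for ch in common:
        res_a, res_b = seqs_a[ch], seqs_b[ch]
        sa = "".join(code for _, code in res_a)
        sb = "".join(code for _, code in res_b)
        _, pairs = needleman_wunsch(sa, sb)
        out.extend((ch, res_a[i][0], res_b[j][0]) for i, j in pairs)
    return out
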