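"""Reflection data: Miller indices, amplitudes, sigmas and free-R flags.

Two on-disk formats are supported behind one reader interface:

* MTZ (binary, the CCP4 standard), read with gemmi.  The free set is
  selected by an integer equals-value test on the flag column; by CCP4
  convention the default is ``flag == 0`` -> free.
* A plain-text CSV dialect defined by this project so that fixtures stay
  text-only: header ``h,k,l,fobs,sigfobs,free`` with ``free`` in {0, 1}
  and ``1`` meaning free.  One unique reflection per row.
"""

from __future__ import annotations

import logging
import os

import gemmi
import numpy as np
import pandas as pd

from .cell import SymmetryOps, UnitCell

__all__ = [
    "ReflectionSet",
    "read_reflections",
    "write_reflections_csv",
    "truncate_resolution",
]

log = logging.getLogger(__name__)

CSV_COLUMNS = ["h", "k", "l", "fobs", "sigfobs", "free"]


class ReflectionSet:
    """Unique structure-factor amplitudes with their cell and free partition.

    Attributes
    ----------
    hkl : (n, 3) int array of Miller indices, (0,0,0) excluded.
    f_obs, sig_f : (n,) float arrays (amplitude scale arbitrary).
    free : (n,) bool array; True marks cross-validation reflections.
    """

    def __init__(
        self,
        cell: UnitCell,
        hkl: np.ndarray,
        f_obs: np.ndarray,
        sig_f: np.ndarray | None = None,
        free: np.ndarray | None = None,
        sym: SymmetryOps | None = None,
    ):
        hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
        keep = np.any(hkl != 0, axis=1)
        if not np.all(keep):
            log.warning("discarding %d (0,0,0) reflection(s)", int((~keep).sum()))
        self.hkl = hkl[keep]
        self.f_obs = np.asarray(f_obs, dtype=float)[keep]
        if np.any(self.f_obs < 0):
            raise ValueError("negative amplitude in reflection data")
        self.sig_f = (
            np.zeros(len(self.hkl)) if sig_f is None else np.asarray(sig_f, dtype=float)[keep]
        )
        self.free = (
            np.zeros(len(self.hkl), dtype=bool)
            if free is None
            else np.asarray(free, dtype=bool)[keep]
        )
        self.cell = cell
        self.sym = sym if sym is not None else SymmetryOps.p1()
        uniq = {tuple(h) for h in self.hkl}
        if len(uniq) != len(self.hkl):
            raise ValueError("duplicate Miller indices in reflection set")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        """Resolution (Å) per reflection, from the cell's reciprocal metric."""
        return self.cell.d_spacing(self.hkl)

    @property
    def inv_d2(self) -> np.ndarray:
        """1/d² = s² per reflection (Å⁻²)."""
        return 1.0 / self.d**2

    @property
    def d_min(self) -> float:
        return float(self.d.min())

    @property
    def d_max(self) -> float:
        return float(self.d.max())

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(
            self.cell, self.hkl[mask], self.f_obs[mask], self.sig_f[mask],
            self.free[mask], self.sym,
        )


def truncate_resolution(refl: ReflectionSet, d: float) -> ReflectionSet:
    """Keep exactly the reflections with d(hkl) >= d."""
    if d <= 0:
        raise ValueError("resolution limit must be positive")
    mask = refl.d >= d
    if not mask.any():
        log.warning("no reflections at or below %.2f Å resolution limit", d)
    log.debug("truncate %.2f Å: %d of %d reflections kept", d, int(mask.sum()), len(refl))
    return refl.select(mask)


def read_reflections(
    path: str | os.PathLike,
    cell: UnitCell | None = None,
    amplitude_column: str | None = None,
    free_column: str | None = None,
    free_value: int = 0,
) -> ReflectionSet:
    """Read reflections from MTZ or the project CSV dialect.

    For MTZ the cell comes from the file; `amplitude_column` may name the
    F column (otherwise the first F/sigF pair found is used) and
    ``free_value`` sets the integer meaning "free" (CCP4 default 0).
    For CSV a `cell` must be supplied by the caller.
    """
    path = os.fspath(path)
    if path.lower().endswith(".mtz"):
        return _read_mtz(path, amplitude_column, free_column, free_value)
    if cell is None:
        raise ValueError("reading CSV reflections requires an explicit unit cell")
    return _read_csv(path, cell)


def _read_csv(path: str, cell: UnitCell) -> ReflectionSet:
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("h", "k", "l", "fobs") if c not in df.columns]
    if missing:
        raise ValueError(
            f"reflection CSV missing column(s) {missing}; available: {list(df.columns)}"
        )
    if "sigfobs" not in df.columns:
        df["sigfobs"] = 0.0
    if "free" not in df.columns:
        log.warning("no free column in %s: all reflections assigned to the work set", path)
        df["free"] = 0
    return ReflectionSet(
        cell,
        df[["h", "k", "l"]].to_numpy(dtype=int),
        df["fobs"].to_numpy(dtype=float),
        df["sigfobs"].to_numpy(dtype=float),
        df["free"].to_numpy(dtype=int) == 1,
    )


def _read_mtz(
    path: str, amplitude_column: str | None, free_column: str | None, free_value: int
) -> ReflectionSet:
    mtz = gemmi.read_mtz_file(path)
    cell = UnitCell.from_gemmi(mtz.cell)
    try:
        sym = SymmetryOps.from_spacegroup(mtz.spacegroup.hm)
    except Exception:
        sym = SymmetryOps.p1()
    cols = {c.label: c for c in mtz.columns}
    f_col = None
    if amplitude_column is not None:
        if amplitude_column not in cols:
            raise ValueError(
                f"amplitude column {amplitude_column!r} not in MTZ; available: {list(cols)}"
            )
        f_col = amplitude_column
    else:
        for c in mtz.columns:
            if c.type == "F":
                f_col = c.label
                break
    if f_col is None:
        raise ValueError(f"no amplitude (type F) column in MTZ; available: {list(cols)}")
    data = np.asarray(mtz, dtype=float)
    labels = [c.label for c in mtz.columns]
    hkl = data[:, [labels.index("H"), labels.index("K"), labels.index("L")]].astype(int)
    f_obs = data[:, labels.index(f_col)]
    sig_label = "SIG" + f_col
    sig = data[:, labels.index(sig_label)] if sig_label in labels else np.zeros(len(hkl))
    if free_column is None:
        free_column = next(
            (c.label for c in mtz.columns if c.type == "I" and "free" in c.label.lower()), None
        )
    if free_column is not None:
        free = data[:, labels.index(free_column)].astype(int) == free_value
    else:
        log.warning("no free-flag column in %s: all reflections in the work set", path)
        free = np.zeros(len(hkl), dtype=bool)
    ok = np.isfinite(f_obs)
    return ReflectionSet(cell, hkl[ok], f_obs[ok], sig[ok], free[ok], sym)


def write_reflections_csv(refl: ReflectionSet, path: str | os.PathLike) -> None:
    """Write the project CSV dialect (free: 1 = free, 0 = work)."""
    df = pd.DataFrame(
        {
            "h": refl.hkl[:, 0],
            "k": refl.hkl[:, 1],
            "l": refl.hkl[:, 2],
            "fobs": refl.f_obs,
            "sigfobs": refl.sig_f,
            "free": refl.free.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write("# shiftfield reflection CSV: free column uses 1 = free reflection\n")
        df.to_csv(fh, index=False)
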