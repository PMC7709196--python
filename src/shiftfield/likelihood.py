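"""Sigma-A likelihood weighting and difference-map coefficients.

sigma_A is the resolution-dependent correlation between normalized observed
and calculated structure factors (Read's formalism).  It is estimated here
per resolution bin by maximizing the Rice (acentric) log-likelihood of the
normalized observed amplitudes given the calculated ones, using the free
reflections so the estimate is cross-validated against refinement bias.
From sigma_A follow the per-reflection figure of merit m (the expected
cosine of the phase error) and the amplitude scale D, which combine into
the likelihood-weighted difference-map coefficients (m|Fo| - D|Fc|) e^{i phi_c}.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import optimize, special

from .density import ComplexStructureFactors
from .reflections import ReflectionSet

__all__ = [
    "ResolutionBinning",
    "SigmaAModel",
    "make_binning",
    "normalize_amplitudes",
    "estimate_sigma_a",
    "figures_of_merit",
    "difference_coefficients",
    "r_factors",
]

log = logging.getLogger(__name__)

SIGMA_A_MIN = 0.01
SIGMA_A_MAX = 0.99


@dataclasses.dataclass
class ResolutionBinning:
    """Equal-population resolution bins over a reflection set."""

    n_bins: int
    bin_index: np.ndarray  # per reflection, 0..n_bins-1
    counts: np.ndarray
    mean_inv_d2: np.ndarray

    def bin_mean(self, values: np.ndarray) -> np.ndarray:
        """Per-bin mean of a per-reflection quantity."""
        sums = np.bincount(self.bin_index, weights=values, minlength=self.n_bins)
        return sums / self.counts


def make_binning(refl: ReflectionSet, n_bins: int = 12, min_per_bin: int = 3) -> ResolutionBinning:
    """Partition reflections into equal-population bins of increasing 1/d^2."""
    n = len(refl)
    n_bins = max(1, min(n_bins, n // max(min_per_bin, 1)))
    order = np.argsort(refl.inv_d2, kind="stable")
    idx = np.empty(n, dtype=int)
    idx[order] = np.minimum((np.arange(n) * n_bins) // n, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        raise ValueError("empty resolution bin; use fewer bins")
    mean_inv_d2 = np.bincount(idx, weights=refl.inv_d2, minlength=n_bins) / counts
    return ResolutionBinning(n_bins, idx, counts, mean_inv_d2)


def normalize_amplitudes(
    refl: ReflectionSet, fc: ComplexStructureFactors, binning: ResolutionBinning
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized amplitudes E = F / sqrt(<F^2>_bin), observed and calculated.

    Each kind is normalized by its own per-bin mean square, so <E^2> = 1 per
    bin per kind.
    """
    if np.any(binning.counts < 3):
        raise ValueError("bins with <3 reflections; use fewer bins")
    eo2 = binning.bin_mean(refl.f_obs**2)
    ec2 = binning.bin_mean(fc.amplitudes**2)
    if np.any(ec2 <= 0):
        raise ValueError("bin with all-zero calculated amplitudes")
    e_obs = refl.f_obs / np.sqrt(eo2[binning.bin_index])
    e_calc = fc.amplitudes / np.sqrt(ec2[binning.bin_index])
    return e_obs, e_calc


@dataclasses.dataclass
class SigmaAModel:
    """Per-bin sigma_A with the normalizers needed to rescale to amplitudes."""

    binning: ResolutionBinning
    sigma_a: np.ndarray  # per bin, clamped to [SIGMA_A_MIN, SIGMA_A_MAX]
    mean_fo2: np.ndarray  # per bin <|Fo|^2>
    mean_fc2: np.ndarray  # per bin <|Fc|^2>

    @property
    def sigma_a_per_reflection(self) -> np.ndarray:
        return self.sigma_a[self.binning.bin_index]


def _rice_neg_loglik(sigma_a: float, eo: np.ndarray, ec: np.ndarray) -> float:
    """Negative acentric Rice log-likelihood of Eo given sigma_a * Ec.

    p(Eo|Ec) = 2 Eo / (1-s^2) * exp(-(Eo^2 + s^2 Ec^2)/(1-s^2)) * I0(2 s Eo Ec/(1-s^2))
    """
    s2 = sigma_a * sigma_a
    var = 1.0 - s2
    x = 2.0 * sigma_a * eo * ec / var
    # log I0(x) = x + log(i0e(x)) stays finite for large x
    log_i0 = x + np.log(special.i0e(x))
    ll = (
        np.log(2.0 * np.maximum(eo, 1e-30) / var)
        - (eo**2 + s2 * ec**2) / var
        + log_i0
    )
    return -float(np.sum(ll))


def estimate_sigma_a(
    e_obs: np.ndarray,
    e_calc: np.ndarray,
    free: np.ndarray,
    binning: ResolutionBinning,
    refl: ReflectionSet | None = None,
    fc: ComplexStructureFactors | None = None,
) -> SigmaAModel:
    """Maximum-likelihood sigma_A per resolution bin.

    Uses free reflections when every bin has at least one; otherwise falls
    back to all reflections with a logged warning.  The 1-D likelihood is
    maximized by bounded Brent search on [SIGMA_A_MIN, SIGMA_A_MAX].
    """
    if binning.n_bins < 2:
        raise ValueError("sigma_A estimation needs at least 2 resolution bins")
    free = np.asarray(free, dtype=bool)
    free_counts = np.bincount(binning.bin_index[free], minlength=binning.n_bins)
    if np.all(free_counts >= 1):
        use = free
    else:
        log.warning("bins without free reflections: estimating sigma_A from all reflections")
        use = np.ones(len(e_obs), dtype=bool)
    sigma_a = np.empty(binning.n_bins)
    for b in range(binning.n_bins):
        sel = use & (binning.bin_index == b)
        res = optimize.minimize_scalar(
            _rice_neg_loglik,
            bounds=(SIGMA_A_MIN, SIGMA_A_MAX),
            args=(e_obs[sel], e_calc[sel]),
            method="bounded",
            options={"xatol": 1e-5},
        )
        sigma_a[b] = float(np.clip(res.x, SIGMA_A_MIN, SIGMA_A_MAX))
    if refl is not None and fc is not None:
        mean_fo2 = binning.bin_mean(refl.f_obs**2)
        mean_fc2 = binning.bin_mean(fc.amplitudes**2)
    else:
        mean_fo2 = np.ones(binning.n_bins)
        mean_fc2 = np.ones(binning.n_bins)
    return SigmaAModel(binning, sigma_a, mean_fo2, mean_fc2)


def figures_of_merit(
    sa: SigmaAModel,
    e_obs: np.ndarray,
    e_calc: np.ndarray,
    centric: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-reflection figure of merit m and amplitude scale D.

    Acentric: X = 2 sigma_A Eo Ec / (1 - sigma_A^2), m = I1(X)/I0(X).
    Centric:  m = tanh(X/2).
    D converts the sigma_A correlation to the |Fo| amplitude scale:
    D = sigma_A * sqrt(<Fo^2>_bin / <Fc^2>_bin).
    """
    s = sa.sigma_a_per_reflection
    x = 2.0 * s * e_obs * e_calc / (1.0 - s * s)
    m = special.i1e(x) / special.i0e(x)
    if centric is not None and np.any(centric):
        m = np.where(centric, np.tanh(x / 2.0), m)
    d_lk = s * np.sqrt(sa.mean_fo2 / sa.mean_fc2)[sa.binning.bin_index]
    return m, d_lk


def difference_coefficients(
    refl: ReflectionSet,
    fc: ComplexStructureFactors,
    m: np.ndarray,
    d_lk: np.ndarray,
    include_free: bool = False,
) -> np.ndarray:
    """Complex coefficients (m|Fo| - D|Fc|) e^{i phi_calc}.

    Free reflections (and any with missing |Fo|) get zero coefficient by
    default so the difference map never sees the cross-validation set.
    """
    amp = fc.amplitudes
    phase = np.where(amp > 0, fc.f_calc / np.where(amp > 0, amp, 1.0), 0.0)
    weight = m * refl.f_obs - d_lk * amp
    coeff = weight * phase
    ok = np.isfinite(refl.f_obs)
    if not include_free:
        ok &= ~refl.free
    return np.where(ok, coeff, 0.0)


def r_factors(refl: ReflectionSet, fc: ComplexStructureFactors) -> tuple[float, float]:
    """(R_work, R_free) = sum ||Fo|-|Fc|| / sum |Fo| over each partition.

    R_free is NaN (undefined), not 0, when the free set is empty.
    """
    amp = fc.amplitudes

    def _r(mask: np.ndarray) -> float:
        if not mask.any():
            return float("nan")
        denom = refl.f_obs[mask].sum()
        if denom == 0:
            return float("nan")
        return float(np.abs(refl.f_obs[mask] - amp[mask]).sum() / denom)

    return _r(~refl.free), _r(refl.free)
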