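# Methods

## Model and target

The refinement minimizes the disagreement between observed structure-factor
amplitudes |Fo| and amplitudes |Fc| calculated from an atomic model, working
in real space through a likelihood-weighted difference map. In the Lifchitz
formulation the calculated density map is differentiated with respect to the
parameters being refined; a positive correlation between a gradient map and
the difference map at some location means the local agreement improves by
moving the corresponding parameter. Shift-field refinement turns this into a
*local linear regression*: at every grid point the difference map is
regressed onto the gradient maps over a surrounding spherical region, and
the per-voxel solution is a field of parameter shifts. Atoms are updated by
trilinear interpolation of that field at their positions.

The regression weight is w(r) = 1 − (r/r₀)² inside radius r₀ and zero
outside. Because the weight depends only on the offset between the voxel
being solved and the contributing voxel, the weighted normal equations are
exactly kernel convolutions of pointwise product maps:

    residual_i(x) = [w * (Δ · g_i)](x)
    normal_ij(x)  = [w * (g_i · g_j)](x)
    (N(x) + λ diag-scaled I) δ(x) = r(x)   at every voxel x

computed with FFTs — one forward/inverse pair per product map. No second
weighting scheme exists; the kernel *is* the weighted least squares.

## Structure factors and maps

F(h) = Σ_atoms occ·f(s)·exp(−B s²/4)·exp(2πi h·x) over the symmetry-expanded
model, with the International Tables 4-Gaussian form factors (coefficients
from gemmi's element tables; hydrogens excluded by default). Direct
summation is used up to ~2000 atom images; beyond that, Gaussian density
sampling plus forward FFT (the two paths agree to 1e-3 relative and are
cross-checked against gemmi's independent calculator in the tests). Maps use
the convention ρ(x) = (1/V) Σ_h F(h) e^(−2πi h·x), on grids with spacing
≤ d/3 (oversampling 1.5) rounded up to 2,3,5,7-smooth FFT sizes. Under this
convention the coordinate gradient maps are the syntheses of (+2πi h_k)F(h),
oriented so that translating the model by +δ changes ρ by ≈ Σ g_k δ_k — the
orientation is pinned by a finite-difference test, not by convention. In
B-factor mode the single gradient map is the synthesis of −(s²/4)F(h).

An overall scale k·exp(−B_overall s²/4) fitted by least squares on
log(|Fo|/|Fc|) puts |Fc| on the observed scale before any difference
coefficients are formed. An optional Babinet bulk-solvent factor
(1 − k_sol·e^(−b_sol s²/4), defaults 0.35/46 Å², off for synthetic data)
models disordered solvent; a mask-based solvent model is out of scope.

## Likelihood weighting

σ_A per resolution bin is the maximizer of the acentric Rice log-likelihood
of the normalized observed amplitudes Eo given σ_A·Ec, found by bounded
Brent search on [0.01, 0.99] over the free reflections (equal-population
bins, default 12; the estimator falls back to all reflections with a warning
when a bin has no free data, as happens for small fixtures). Normalization
uses per-bin mean squares so ⟨E²⟩ = 1 per bin per kind. From σ_A follow
X = 2σ_A·Eo·Ec/(1−σ_A²), the figure of merit m = I₁(X)/I₀(X) (tanh(X/2) for
centric reflections, detected from the symmetry operators), and
D = σ_A·(⟨Fo²⟩/⟨Fc²⟩)^(1/2), which converts the correlation to the observed
amplitude scale.

The difference map uses coefficients (m|Fo| − D|Fc|)e^(iφc), with free
reflections and missing observations given zero weight so the
cross-validation set never drives shifts. For the regression the acentric
coefficients are doubled: an acentric m|Fo|−D|Fc| synthesis shows model
errors at half height, and 2(m|Fo|−D|Fc|) (1× centric) is the standard
Gauss–Newton gradient weighting. Without the factor the per-cycle shifts are
half the proper step; with it, a single regression against an ideal complex
difference map recovers 94% of a planted 1 Å translation.

## Cycle schedule and defaults

| parameter | default | meaning |
| --- | --- | --- |
| n_cycles | 12 | refinement cycles; convergence is cycle-count-based |
| d_start → d_end | 6.0 → 3.0 Å | working resolution, linear in d per cycle |
| radius_factor | 4.0 | regression radius r₀ = 4·d of the cycle |
| ridge_fraction | 1e-6 | per-voxel Tikhonov λ relative to max diag(N) |
| shift_scale | 1.0 | fraction of the solved shift applied |
| include_const | off | extra constant regression predictor |
| n_bins | 12 | equal-population σ_A bins |
| oversample | 1.5 | grid spacing ≤ d/(2·oversample) |

Early low-resolution, large-radius cycles give a large radius of convergence
(whole-domain moves); later cycles refine detail. The constant predictor can
absorb an additive offset between the maps (it does so exactly — adding a
constant to the difference map changes no coordinate shift by more than
1e-8) but brings no benefit on well-scaled data and costs extra transforms,
so it defaults off. Voxels whose normal matrix is near-singular (flat
solvent) get λ-regularized solves; voxels whose largest diagonal entry is
below 1e-12 of the global maximum get zero shift. Both choices make the
solve total without measurably biasing shifts at atoms.

The kernel is normalized to unit sum (the normalization cancels in the
solve but keeps logged field magnitudes interpretable) and measures r as
*orthogonal* distance via the orthogonalization matrix, so it remains
spherical in oblique cells. When 2r₀ exceeds the shortest cell edge the
kernel wraps onto itself; this is logged as a warning and degrades locality
gracefully (early cycles of small-cell fixtures operate in this regime).

## Synthetic validation harness

The generator builds ideal-geometry polyalanine backbones (N, CA, C, O;
helices from standard φ/ψ = −57°/−47° internal coordinates) in cells that
enclose the model with a chosen padding, simulates observations as
|Fo| = |Fc(truth)|·(1+ε) with ε ~ N(0, noise), assigns free flags by a
seeded Bernoulli draw (default 5%), and perturbs models by rigid
translation, hinge rotation or random jitter. Scoring uses minimum-image
matched-atom r.m.s.d. with the selection rules all-atoms, Cα-only, or
Cα-pairs-within-3 Å (which excludes outlier residues); models with
differing sequences are first matched by per-chain global alignment
(match +1, mismatch −1, gap −2).

Two physical facts shaped the recovery studies and are worth recording:

* **Origin invariance.** In P1, translating *all* atoms multiplies every
  F(h) by a pure phase; amplitudes are exactly unchanged, so a whole-model
  offset is unrecoverable from amplitude data by any method. Recovery
  fixtures therefore carry P 2₁ 2₁ 2₁ symmetry — the symmetry mates pin the
  origin, as they do for essentially all real protein crystals.
* **Centre-of-density conservation.** A phaseless difference map contains,
  besides the true difference ΔF/2, a conjugate ghost term of equal power
  with model-biased phases. For subset perturbations in P1 the ghost pulls
  the stationary part of the structure opposite to the mobile part, so the
  common-mode error component is conserved and absolute r.m.s.d. stalls at
  it. This is a property of amplitude-only refinement generally, not of the
  shift-field formulation; symmetry removes it.

What passing these tests does *not* show: the harness has no solvent
contribution, no missing atoms or sequence errors, no experimental-intensity
error model (French–Wilson), and backbone-only scattering. Real
molecular-replacement cases add all of these; the harness validates the
estimator and the convergence machinery, not performance on deposited data.

## Measured behaviour (recomputed by `scripts/acceptance.py` and the test suite)

Under the default schedule on the standard fixtures (10-residue helix or
40-residue two-domain pair, P 2₁ 2₁ 2₁, error-free 3 Å data): a 1.5 Å
whole-model translation refines to ~0.2 Å matched r.m.s.d. with R_work and
R_free both falling; an 8° domain rotation (main-chain displacement up to
~3.8 Å) is reduced by ~2/3 in r.m.s.d.; refining an already-correct model
moves no atom more than ~0.02 Å; and σ_A = 0.7 is recovered to ±0.05 at
2000 reflections per bin. With 5% amplitude noise the translation recovery
is essentially unchanged. Problem sizes (cells of 30–60 Å, 2000–9000
reflections) were chosen so each full 12-cycle run completes in seconds;
the algorithm itself is O(n_FFT · N log N) per cycle and scales to real
unit cells.

## Known limitations

* No stereochemical restraints: geometry drifts with cycle count
  (visible in the bond_rmsd column); follow with conventional restrained
  refinement. Running far beyond 12 cycles distorts geometry faster than a
  finishing refinement can restore it.
* A single smooth field cannot express discontinuous shifts across close
  molecular boundaries (e.g. a surface helix that must move while a
  packing neighbour stays); restraint-based methods can.
* Isotropic B only; no anisotropic ADPs, alternate conformers (beyond
  occupancy pass-through), twinning or anomalous data.
* Coordinate and B-factor modes are separate runs, not a joint regression.
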