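# shiftfield

Restraint-free **shift-field refinement** of macromolecular atomic models
against structure-factor amplitudes.

## The problem

After molecular replacement, parts of a model are often displaced by
angstroms from their true positions — whole domains shifted or rotated.
Conventional reciprocal-space refinement, with its stereochemical restraints
and rugged target landscape, converges slowly or not at all from such
starting points. Shift-field refinement attacks exactly this regime: instead
of refining each atom's parameters, it computes a smooth *spatial field* of
parameter shifts over the whole unit cell and lets every atom read its
update from that field. Coarse-scale errors are corrected quickly, at low
resolution, without restraints, and local geometry rides along largely
intact.

## The method

Each cycle, at working resolution *d* (ramped linearly from 6 Å to 3 Å over
12 cycles by default):

1. Calculate structure factors **F**<sub>c</sub> from the current model and
   put them on the observed scale (overall *k*, *B*).
2. Estimate σ<sub>A</sub> per resolution bin from the free reflections
   (maximum-likelihood fit of the Rice distribution of normalized
   amplitudes), giving per-reflection figures of merit
   *m* = I₁(X)/I₀(X) and the amplitude scale *D*.
3. Synthesize the calculated density ρ and the likelihood-weighted
   difference map Δ from coefficients (*m*|F<sub>o</sub>| − *D*|F<sub>c</sub>|)e<sup>iφc</sup>
   (work reflections only; acentric terms doubled for the regression,
   the standard Gauss–Newton gradient weighting).
4. Synthesize the gradient (Lifchitz) maps g<sub>k</sub> = ∂ρ/∂u<sub>k</sub>
   with respect to the fractional coordinates (or one map ∂ρ/∂B in
   B-factor mode).
5. At every grid point **x**, regress Δ onto the g<sub>k</sub> over a
   surrounding sphere of radius r₀ = 4*d* with weight
   w(r) = 1 − (r/r₀)². Because the weight depends only on the offset,
   both sides of the weighted normal equations
   (Σ w g<sub>i</sub>g<sub>j</sub>) Δ**x** = Σ w g<sub>i</sub>Δ are plain
   FFT convolutions of product maps with the kernel; one small linear solve
   per voxel yields the **shift field**.
6. Interpolate the field at each atom and apply the shifts.

All map algebra runs on the full-cell P1 grid with the model expanded over
its symmetry operators; the maps then carry the space-group symmetry, so the
solved field is automatically covariant and asymmetric-unit atoms read
correct shifts.

There are no stereochemical restraints, so geometry drifts slowly with cycle
count (the per-cycle statistics include a backbone bond-length r.m.s.d.
reporter to make this visible); in production use the refined model should
be finished with a cycle of conventional restrained refinement.

## Worked example

The package carries its own synthetic harness: ideal-geometry polyalanine
fixtures in P 2₁ 2₁ 2₁ cells, simulated error-free or noisy amplitudes with
a free-R partition, and parameter-recovery metrics. Displace a ground-truth
helix by 1.5 Å and watch the default schedule pull it back:

```python
from shiftfield import (ShiftFieldRefinement, SimulationSpec, PerturbationSpec,
                        make_toy_structure, simulate_observations, perturb_model,
                        matched_rmsd)

truth = make_toy_structure("poly_ala_helix", 10, cell_padding=10.0,
                           spacegroup="P 21 21 21")
refl = simulate_observations(truth, SimulationSpec(d_min=3.0, seed=11))
start = perturb_model(truth, PerturbationSpec("rigid_translation", 1.5,
                                              direction=(1, 0.3, 0.2)))
results = ShiftFieldRefinement(start, refl).fit()
print(results.summary())
print("final r.m.s.d. vs truth: %.2f A" % matched_rmsd(results.model_refined, truth))
```

```
Shift-field refinement results
==============================
atoms: 40   reflections: 2266   mode: coords   const term: off
schedule: 12 cycles, 6.0 -> 3.0 Å, r0 = 4.0 x d

 cycle    d   r0  n_refl r_work r_free mean_shift max_shift bond_rmsd
     1 6.00 24.0     285 0.3563 0.4823     0.1006    0.1271    0.0050
     2 5.73 22.9     327 0.2889 0.3392     0.1249    0.1562    0.0109
     ...
    11 3.27 13.1    1745 0.1074 0.0932     0.0218    0.0518    0.0687
    12 3.00 12.0    2266 0.1106 0.0974     0.0116    0.0511    0.0653

R_work 0.3563 -> 0.1106   R_free 0.4823 -> 0.0974
final r.m.s.d. vs truth: 0.21 A
```

The 1.5 Å offset is recovered to 0.21 Å; R<sub>free</sub> falls alongside
R<sub>work</sub>, so the improvement is not overfitting. Each table row
reports the cycle resolution `d`, regression radius `r0`, reflections used,
R factors *before* that cycle's shifts, and the mean/max atom shift applied
(orthogonal Å).

The same run from a shell:

```sh
shiftfield make-fixture --residues 10 --d-min 3.0 \
    --perturb rigid_translation --magnitude 1.5 --prefix fix
shiftfield refine --model fix_start.pdb --hklin fix_refl.csv \
    --output refined.pdb --table stats.csv
```

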