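# Methods

## Model and procedure

`mapfit` performs density-guided flexible fitting: Langevin dynamics of a
coarse-grained bead model under

    U_total = U_MD + U_EM + U_SS

* **U_EM** — each coupled bead i contributes wᵢ·V(rᵢ), where V is the fitting
  potential derived from the density map,
  V(r) = ζ[1 − (Φ(r) − Φ_thr)/(Φ_max − Φ_thr)] above the noise threshold and
  the constant ζ below it.  V is evaluated by trilinear interpolation; map
  forces are the exact gradient of the interpolant.  The form is inverted
  relative to the raw density — density maxima are energy minima — and is
  continuous at the threshold, so sub-threshold noise exerts no force.  The
  printed form of this potential in some descriptions omits the "1 −" term;
  that variant rises with density and is discontinuous at the threshold, so
  the inverted, threshold-continuous form is implemented.
* **U_MD** — a structure-based (Gō-like) Cα surrogate built from a reference
  conformation: harmonic bonds/angles/dihedrals at reference values, native
  contacts (Gaussian wells) for sequence-distant pairs within a cutoff, and a
  soft excluded-volume repulsion for every non-local pair.  This is the
  central scale-down of the package: an all-atom force field is replaced by a
  model that preserves the method's logic (internal energy resists the
  deformation that the map potential drives) at ~1000× lower cost.
* **U_SS** — harmonic restraints on pseudo-dihedrals and 1-4 distances inside
  helix/strand segments, assigned at the search model's geometry.  The
  published restraint form is delegated to earlier method papers; harmonic
  restraints on these internal coordinates are the stand-in used here.

Topology is always built from the **search** conformation, so fitting
genuinely deforms the model against its own internal energy.

**Cascade fitting** blurs the map with a strictly decreasing ladder of
Gaussian half-widths (default σ = 5…0 Å in 1 Å steps; σ means the standard
deviation of the blur kernel).  Each stage rebuilds the potential from the
blurred map (same ζ; threshold recomputed as the 5th percentile of the
blurred map's positive voxels), runs dynamics until stationary, and seeds the
next stage; velocities are re-drawn at the stage temperature.  After the
unblurred stage the model is annealed: coupling rescaled to ζ = 1, 300 K → 0 K
linear ramp, 0 K hold, and a quasi-Newton quench.

**Resolution-exchange fitting** runs one replica per rung; every
`exchange_interval` steps (default 500), alternating even/odd neighbor pairs
attempt a Metropolis swap of their *maps* (coordinates stay with their
trajectory — physically equivalent to swapping coordinates and cheaper to
book-keep).  Internal and restraint energies cancel in the exchange
difference, so Δ reduces to the map-coupling terms; this identity is tested.
The run ends when the σ = 0 holder's recent snapshots are stationary; the
best σ = 0 snapshot by global map correlation is annealed into the final
model.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| ζ (coupling scale) | 0.3 (1.0 during final anneal) | kcal/mol | standard coupling strength for this family of methods |
| wᵢ (coupling weight) | bead mass (110 amu) | amu | per-residue mass, matching mass-weighted coupling of all heavy atoms |
| bond / angle / dihedral k | 100 / 20 / 2 | kcal/mol/Å², kcal/mol/rad² | chain geometry essentially rigid against map forces |
| contact ε, width, cutoff | 8.0, 1.5, 8.0 | kcal/mol, Å, Å | sets domain rigidity; see below |
| excluded-volume radius, k | min(4.5, 0.9·r_ref), 20 | Å, kcal/mol/Å² | Cα packing distance; per-pair onset keeps the reference an exact stationary point |
| SS restraint k | 5 | kcal/mol | protects helices from strong map forces |
| timestep / friction / T | 10 fs / 5 ps⁻¹ / 300 K | | stable for the stiffest bond mode (period ≈ 320 fs) |
| stationarity | 200-frame window, range < 0.1 Å | | RMSD-to-window-mean criterion |
| stage step cap | 5000 | steps | stages typically converge in 2000–5000 steps |
| threshold percentile | 5 % of positive voxels | | recomputed per blurred map |

The contact well depth (8 kcal/mol per residue-level contact, Gaussian width
1.5 Å) is deliberately at the stiff end for a Cα model.  The map coupling is
mass-weighted, so a bead feels the full ζ·m ≈ 33 kcal/mol depth that an
all-atom residue would accumulate over its atoms — but a minimal Cα model has
far less internal stiffness than an all-atom force field.  The deep, finite
contacts restore that balance: domains behave as quasi-rigid bodies that can
still yield under sustained force, which is how folded domains respond in
all-atom fitting.  With weak contacts (ε ≈ 1–2) the blurred-map stages
visibly squeeze and shear the domains.

Units: Å, fs, amu, kcal/mol; k_B = 0.0019872 kcal/mol/K.  BAOAB Langevin
splitting (velocity Verlet at zero friction; energy drift < 1e-4 relative
over 10⁴ NVE steps is tested).  Trilinear map forces are discontinuous across
voxel faces; force/finite-difference agreement is tested away from faces.
An excluded-volume neighbor list (2 Å skin, rebuilt every 20 steps) leaves
energies exactly unchanged.

## Synthetic fixture

`make_fixture` builds the study system: two compact three-helix-bundle
domains (60 residues each, unequal helix lengths so the blurred blob still
determines orientation) joined by a 4-residue linker — 124 beads, ≈ 70 Å
long.  The map is rendered at 3 Å nominal resolution (bead width = resolution
/ 2.355, i.e. FWHM = nominal resolution; any consistent convention works and
this one is used everywhere) on a 1 Å grid with 14 Å padding so a 5 Å blur
conserves mass.

The search model is a second clean conformer of the same fold: domain B is
slid along its own bundle axis (a register shift) and swung about the linker
hinge, calibrated to 7.0 ± 0.2 Å RMSD overall.  The slide is what makes the
fixture a faithful analog of the hard fitting problem: displaced helices lie
over neighboring turns of their own density track, so the unblurred potential
has deep competing minima along the return path (measured barriers of tens of
kcal/mol), while a 5 Å blur leaves a smooth funnel.  Purely transverse hinge
swings turn out to be too easy — direct fitting then succeeds from 7 Å —
because the displaced domain returns through empty space into its own
density.

Generators for half-map pairs (shared signal, independent seeded noise),
spatially varying resolution (sharp core, blurred periphery, with the
per-voxel nominal resolution in a companion volume), and hinge/heated/local
displaced conformers are deterministic functions of (spec, seed).

What the fixture does **not** emulate: side-chain density, non-uniform
solvent background, map anisotropy, and the atomic-scale spectral content of
real maps (see the sharpening caveat below).  Passing tests demonstrate the
method's mechanics — funnel versus trap, exchange bookkeeping, validation
arithmetic — not performance on experimental reconstructions.

## Validation machinery

* **GCC/LCC** — Pearson correlation between the map and the model rendered on
  its grid, over the union of above-threshold voxels (LCC: additionally
  within 5 Å spheres of the residue; the local mask radius is a local choice).
* **FSC/iFSC** — per-shell normalized cross-correlation of the half-spectrum
  (one shell per integer reciprocal-grid radius); iFSC integrates the curve
  over the resolution axis d in a stated range, so its maximum is the range
  width in Å; this reading is the only one consistent with reported values
  of order 4–5 Å on a 3.4–10 Å range.
* **Half-map cross-validation** — iFSC of the fitted model against its
  fitting half-map (direct) and the held-out one (cross); direct − cross is
  the overfitting indicator.
* **RMSF** — per-bead RMS deviation from the window-mean positions over the
  trailing 80 % of frames, with no superposition (the map fixes the frame);
  overall RMSF is the RMS of the per-bead values.  B = 8π²/3·RMSF² with the
  exact constant 26.319 Å² per Å² (some printed worked examples imply ≈ 26.0;
  the exact constant is used).
* **Guinier analysis** — least-squares slope of ln(spherically averaged
  amplitude) against s² over shells in a resolution window, B = −4·slope;
  applying `sharpen` (amplitudes × exp(−B·s²/4)) with −B flattens the
  falloff.
* **Sharpening scan** — for each B on a grid: sharpen, run a short fixed-seed
  fitting simulation of the prefitted model, record overall RMSF over the
  equilibrated second half.  The argmin names the sharpening of maximum
  contrast.

**Sharpening-scan caveat.**  On a bead-level map the rendering width s_b
(1.27 Å at 3 Å resolution) sets an intrinsic deconvolution scale
8π²s_b² ≈ 130 Å².  In the noise-free blur-restore experiment the RMSF minimum
sits between the blur-equivalent B = −8π²σ*² and the full deconvolution point
−8π²(σ*² + s_b²): past the restoration point, sharpening keeps deepening the
(noise-free) bead wells until ringing sets in.  The scan therefore cannot
localize the optimum more finely than ~130 Å², and the blur-equivalence
experiments use a blur large enough (σ* = 2.5 Å, optimum ≈ −493 Å²) that a
proportionate grid step (125 Å², ~25 % of the optimum) absorbs that scale.
On real maps the noise floor supplies the penalty for over-sharpening
instead; with added synthetic noise the scan minimum becomes a function of
the assumed noise spectrum, which the fixture deliberately does not try to
pin down.

## Numerical choices and degenerate inputs

* Blur: FFT/separable convolution with zero-padding handled by a 6σ-truncated
  kernel; mass conservation holds when the map carries an empty border, which
  the renderers guarantee (pad ≥ 10 Å).  Blurring and sharpening commute in
  the interior; boundary handling differs (zero-padded versus periodic).
* Potential from a flat map (Φ_max = Φ_thr) is rejected; beads outside the
  grid sit on the V = ζ plateau with zero force.
* Dihedral gradients are zeroed at exactly collinear geometries (the angle is
  undefined there); fixture geometries keep all bends far from collinearity.
* `make_schedule` descends arithmetically and always terminates at exactly 0.
* Minimization is steepest descent with backtracking (monotone, deterministic);
  the post-anneal quench uses L-BFGS and keeps the result only if it lowers
  the energy.
* Stage re-seeding, replica seeds, and fixture noise all derive from named
  seed streams; identical configurations reproduce bitwise.
* Single-bin local-resolution tables report a degenerate fit (slope `None`)
  rather than extrapolating.

## Known limitations

* The Cα surrogate cannot express side-chain placement, rotamers, or
  Ramachandran statistics; external model-geometry scores are out of scope.
* Orthogonal unit cells only; no map symmetry handling.
* Trajectory step counts are calibrated by the stationarity detector, not by
  wall-clock times quoted for all-atom protocols; published per-stage
  durations presume all-atom timesteps and do not transfer.
* The radius-of-convergence and convergence-RMSD numbers produced by
  `scripts/acceptance.py` are properties of the packaged fixture at its
  stated conditions (3 Å-equivalent map, ζ = 0.3, 300 K), not of any
  experimental system.
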