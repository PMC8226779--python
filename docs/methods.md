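# Methods

This note records the models implemented in `maostraj`, their assumptions,
the defaults that matter, and what the synthetic fixtures do and do not
demonstrate.

## Scope and conventions

The package analyses protein/solvent trajectories from micro-aqueous organic
solvent (MAOS) simulations: an organic solvent (n-heptane or toluene) with a
small water fraction in which a lipase keeps a partial hydration layer.
Lengths are Å, times ps, surface areas are reported in nm², diffusion
coefficients in cm²/s (1 cm²/s = 10⁴ Å²/ps, asserted once in
`synthetic.CM2S_TO_A2PS`). Atom indices are 0-based. Boxes are orthorhombic
with the minimum-image convention; triclinic cells are out of scope.

Topology classification: backbone atoms are exactly the atoms named C, CA, N
of protein residues. Residue hydropathy follows the sign of the
Kyte–Doolittle scale (phobic: ALA VAL LEU ILE PRO PHE MET TRP GLY CYS;
philic: the remaining standard residues), overridable per residue in the
config since hydropathy dictionaries differ between laboratories. Van der
Waals radii are the Bondi set with a 1.7 Å fallback. Unrecognised residues
are classified `organic` and logged rather than rejected, because MAOS boxes
routinely contain parameterised solvent residues with nonstandard names.
The water volume fraction helper defaults to molar volumes from 25 °C liquid
densities (water 0.997, n-heptane 0.6795, toluene 0.8669 g/cm³); the
reference temperature of a reported v/v composition is rarely stated, so the
volumes are configurable.

## Flexibility metrics

RMSD and RMSF remove rigid-body motion by Kabsch superposition (SVD with the
reflection case corrected by a sign flip of the smallest singular vector;
unweighted by default, mass weights optional). RMSF fits every frame onto
frame 0 over the same selection before measuring fluctuations about the
time-average position — the fit reference is a genuine choice since only
"translations and rotations removed" is specified by common practice, and
frame 0 makes the result reproducible from the trajectory alone. A
consequence worth knowing: the fit itself absorbs a 1/N share of any single
atom's displacement, which the test suite verifies exactly on a symmetric
fixture.

## Surface analysis

SASA uses the Shrake–Rupley rolling-probe construction with a deterministic
golden-spiral point set (default 960 points, probe 1.4 Å). The golden spiral
makes areas bit-reproducible; 960 vs 4000 points agree within 1 % on the toy
peptide, and isolated-sphere and two-sphere closed forms are matched within
1 % and 0.5 %. Slice-based SASA algorithms (as in DSSP) measure the same
quantity; exact parity with any particular implementation is a non-goal.
Per-atom areas are attributed to hydrophilic/hydrophobic classes by residue
(not per-atom polarity), matching how surface composition is discussed for
proteins, and SA_catalytic sums all atoms of the triad residues (side-chain
restriction is configurable; exposure of the catalytic Ser is the
functionally meaningful signal).

## Water structure and dynamics

**Proximal RDF.** g(r) bins each water oxygen's minimum-image distance to the
*nearest* reference atom. Shell radii of a few Å only make sense as
surface-proximal distances, so for multi-atom references the per-bin
reference volume is estimated by Monte Carlo (uniform probe points binned by
their own proximal distance, 2×10⁵ points by default); a single-atom
reference reduces to the spherical-shell volume. Normalisation is fixed by
the box-average water density, so a uniform ideal gas gives g ≈ 1 and
∫ g ρ dV over r ≤ r_max recovers the mean water count (tested to 1 %).
Shell maxima are local maxima of the Gaussian-smoothed profile (σ = 1 bin,
prominence ≥ 0.05) refined to sub-bin precision by parabolic interpolation.
Note that g(r) divides the radial density by the shell volume, which shifts
a Gaussian shell's maximum down by ≈ 2σ²/µ (≈ 0.05 Å for the 3.75 Å shell) —
within the tolerance used everywhere, but visible in reported radii.

**Hydrogen bonds.** Geometric criterion: donor–acceptor ≤ 3.5 Å and
hydrogen–donor–acceptor angle ≤ 30°, the de facto defaults; both are
configurable. Candidate pairs are pruned with a periodic grid/KD-tree
neighbour search, which the suite verifies against an all-pairs evaluation
by exact set equality. Lifetimes come in both flavours: *continuous* (mean
uninterrupted on-run, edge-censored runs excluded, plus an exponential fit
of the run survival function) and *intermittent* (existence autocorrelation
c(t) = ⟨h(0)h(t)⟩/⟨h⟩ with a direct exponential fit). Continuous is the
default reported number because it is the quantity comparable to
sub-picosecond relaxation measurements. In a two-state fixture at
reformation equilibrium c(t) plateaus at ⟨h⟩, so the intermittent fit reads
much longer than the continuous one; that ordering is expected and is
asserted as an invariant rather than "fixed". The z-profile assigns each
bond to the 2 Å slab of its hydrogen's z coordinate and by default counts
all bonds passed in; callers filter donor/acceptor roles upstream.

**Diffusion.** MSD is averaged over particles and all time origins (FFT
algorithm) on unwrapped coordinates; D = slope/6 from a least-squares line
over lags in [10 %, 50 %] of the maximum lag (excludes ballistic onset and
the noisy tail). A fit with r² < 0.9 or a log–log MSD slope outside 1 ± 0.2
is flagged non-diffusive instead of silently reported.

**Rotational relaxation.** C_l(t) = ⟨P_l(u(t)·u(t+τ))⟩ for l = 1, 2, with τ
from a log-linear fit over C ∈ (0.05, 1]. Rank 1 is the default output and
rank 2 is always available, since either Legendre rank is common in the
water-reorientation literature.

## Synthetic generators

Each generator is a pure function of (spec, seed) and reproduces bit-exactly.

* `gen_brownian`: independent Gaussian walks, per-step variance 2·D·dt per
  dimension; wrapped and unwrapped coordinates both carried. A sampled step
  beyond box/2 is a hard error (the wrapped walk would be unrecoverable).
* `gen_shell_waters`: radial distances from a Gaussian mixture (negative
  draws rejected), directions uniform on the sphere, independent frames.
  Defaults elsewhere in the package use the two hydration shells at 3.75 and
  8.5 Å with σ = 0.3 Å and equal weights: the σ and weights are this
  package's choice of a realistic shell width and occupancy, made once, as
  the stated radii are the only published anchors.
* `gen_cv_samples`: Metropolis chain targeting exp(−V) with V in kT units;
  step auto-tuned to 0.3–0.5 acceptance during a 10 % burn-in; an overall
  acceptance outside [0.05, 0.95] is an error rather than a silent bad chain.
* `gen_hb_telegraph`: per-frame break probability 1 − exp(−dt/τ_on),
  reformation likewise from τ_off (default τ_on); all bonds start formed.
* `gen_rotational_diffusion`: per step, a random rotation whose rotation
  vector has i.i.d. N(0, 2·D_r·dt) components — the small-step propagator of
  isotropic rotational diffusion, chosen because it yields the closed form
  C_l(t) = exp(−l(l+1)·D_r·t) exactly; a single-axis Gaussian-angle step
  would decorrelate three times more slowly than its nominal D_r. Steps with
  D_r·dt > 0.1 are rejected as outside the small-angle regime.

What the fixtures do *not* emulate: protein geometry, force fields, solvent
packing, coupling between translational and rotational motion, or
non-exponential hydrogen-bond kinetics. Passing tests therefore demonstrate
estimator correctness on known statistics, not fidelity of any particular
MD system.

## Energy landscapes and minimum energy paths

E(x) = −ln(P(x)/P_max) in kT units (T default 313 K) on a default 50×50 grid
over the sampled range padded 2 %, with optional Gaussian smoothing of the
histogram (σ = 1 bin) to stabilise finite-difference gradients. Bins without
samples are masked (E = +∞); the probability is normalised over unmasked
bins and the minimum unmasked energy is exactly 0. For conversions, 1 kT at
313 K ≈ 0.622 kcal/mol (`KT_TO_KCAL_AT`).

Basins are 8-neighbourhood local minima of E, masked bins excluded, greedily
deduplicated within a 3-bin window with a deterministic lowest-x-then-y
tie-break, sorted by energy.

The string method runs in fractional bin-index coordinates so the two
collective variables — with incommensurate units (Å vs nm²) — are treated on
an equal footing. Images start on the straight segment, descend the
bilinearly interpolated gradient (centred differences, half-bin stencil;
endpoints fixed; displacement capped at half a bin per iteration) and are
reparametrised to equal arc length each iteration. Masked bins act as a soft
wall 5 kT above the highest sampled energy; a final path through the wall is
a hard error (no finite-energy detour exists). Convergence is declared when
the maximum image displacement falls below tol; the default tol is 10⁻³ of
the grid extent *scaled by the descent step*, so it measures gradient
smallness independently of the step size — a fixed displacement threshold
alone would declare victory on the first iteration of a shallow landscape.
The transition state is the highest-energy image of a converged path; the
saddle check builds a finite-difference Hessian from the (smoothed) grid at
the nearest bin and requires exactly one negative eigenvalue, and an
endpoint maximum is never reported as a saddle. The pipeline reports all
pairwise paths between basins within 2 kT of the global minimum (fringe
minima from histogram noise sit higher and are skipped); blocked or
unconverged paths are recorded as such rather than failing the run.

Verified behaviour: on the analytic double-well (x²−1)² + y² the relaxed
string finds the saddle at the origin within one bin with the 1 kT barrier
within 5 %, agrees with a Dijkstra minimax-cost grid oracle, and is
invariant to the image count (16/32/64); sampled landscapes converge
monotonically to the generating potential as the sample count doubles.

## Pipeline and problem sizes

The demo pipeline (toy-peptide metrics and SASA, shell RDF, Brownian
diffusion, telegraph lifetimes, rotational relaxation, double-well landscape
and MEP) uses deliberately modest sizes — hundreds of frames, tens of
thousands of CV samples — chosen so a complete run takes seconds on one
core while every recovery tolerance in the test suite is still met with
margin. All stage seeds derive from the single run seed via stage-name
offsets, outputs embed the config hash, and identical config + seed
reproduce every JSON summary byte-for-byte.

## Known limitations

* No reproduction of system-specific published values (RMSF profiles,
  lipase landscapes, water D in MAOS, picosecond HB lifetimes): those
  require the original 200 ns explicit-solvent trajectories, which are not
  deposited. The composition arithmetic and the crystal-structure surface
  ratio are the only directly reproducible worked numbers.
* Orthorhombic boxes only; no protonation assignment; no secondary-structure
  analysis; no finite-temperature string method; 2D landscapes only.
* The proximal-RDF Monte-Carlo normalisation uses the first frame's
  reference coordinates; for a flexible reference the shell volumes are
  approximate at the level of the reference's conformational spread.
* Lid regions are named per lipase in the literature, not algorithmically
  defined, so no automatic lid segmentation is attempted.
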