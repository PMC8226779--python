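# maostraj

Trajectory analysis of lipase hydration in **micro-aqueous organic solvent
(MAOS)** media — organic solvents (n-heptane, toluene) carrying a small water
fraction (≈ 3.5 % v/v) in which lipases retain the hydration layer their
structure and catalysis depend on.

The package implements, as a tested and reusable pipeline, the analysis chain
used to characterise lipase conformation and hydration in molecular-dynamics
trajectories of such systems:

* **Flexibility metrics** — Kabsch-superposed backbone RMSD and RMSF
  (backbone = C, CA, N of each residue).
* **Surface analysis** — Shrake–Rupley solvent-accessible surface area,
  partitioned into hydrophilic/hydrophobic residue classes
  (SA_philic, SA_phobic, their ratio R) and over the Ser–His–Asp catalytic
  triad (SA_catalytic, a proxy for open/closed lid states).
* **Water structure and dynamics** — proximal water–protein radial
  distribution function g(r) with hydration-shell detection; geometric
  hydrogen-bond detection (D–A ≤ 3.5 Å, H–D–A ≤ 30°) with continuous and
  intermittent lifetime estimators and z-axis bond profiles; translational
  diffusion D from the Einstein relation (D = slope of MSD / 6); rank-1/2
  rotational correlation functions C_l(t) = ⟨P_l(u(0)·u(t))⟩.
* **Energy landscapes and paths** — Boltzmann inversion
  E(x) = −kT ln(P(x)/P_max) over two collective variables
  (x = backbone RMSD, y = SA_catalytic) at T = 313 K, basin detection, and
  zero-temperature **string-method** minimum energy paths whose
  highest-energy image is the transition state, verified as a first-order
  saddle (exactly one negative Hessian eigenvalue).
* **Synthetic generators** — Brownian particles at a stated D, Gaussian
  hydration shells, Metropolis sampling of known 2D potentials, telegraph
  hydrogen-bond processes with exponential lifetimes, and rotational
  diffusion of unit vectors — so every analysis stage is verifiable against
  exact ground truth without running MD.

## Worked example

```python
import numpy as np
from maostraj import (CompositionSpec, water_volume_fraction, ShellSpec,
                      gen_shell_waters, proximal_rdf, find_shells,
                      PotentialSpec, gen_cv_samples, boltzmann_landscape,
                      find_minima, string_mep, transition_state)

# 1. composition of the micro-aqueous n-heptane box
print("water content: %.1f %% v/v"
      % water_volume_fraction(CompositionSpec(600, 2039)))

# 2. hydration shells recovered from a synthetic two-shell water ensemble
traj = gen_shell_waters(ShellSpec((3.75, 8.5), (0.3, 0.3), (0.5, 0.5),
                                  n_waters=500, n_frames=200, seed=42))
prof = proximal_rdf(traj, np.arange(1, traj.n_atoms), np.array([0]), 0.1, 12.0)
for r, g in find_shells(prof):
    print("shell at %.2f A  (g = %.1f)" % (r, g))

# 3. energy landscape and minimum energy path of a two-state system
samples = gen_cv_samples(PotentialSpec(form="double_well"), 40000, 42)
land = boltzmann_landscape(samples, (50, 50), smooth_sigma=1.0)
minima = find_minima(land)[:2]
path = string_mep(land, minima[0][:2], minima[1][:2])
ts, e_ts, saddle = transition_state(path, land)
print("TS at (%.2f, %.2f), barrier %.2f kT, first-order saddle: %s"
      % (ts[0], ts[1], e_ts - minima[0][2], saddle))
```

prints

```
water content: 3.5 % v/v
shell at 3.70 A  (g = 106.5)
shell at 8.47 A  (g = 20.9)
TS at (0.05, -0.10), barrier 1.12 kT, first-order saddle: True
```

The water content reproduces the 3.5 % v/v micro-aqueous composition of a
600-water / 2039-heptane box; the two g(r) maxima recover the construction
radii of the first and second hydration shells (3.75 and 8.5 Å) within a
tenth of an Å; and on a sampled double-well landscape the string method
relaxes to the analytic saddle between the two conformational basins.

A command-line interface mirrors the library:

```sh
maostraj run --seed 7 --out demo_out          # full synthetic pipeline
maostraj simulate shells --seed 42            # fixture trajectories
maostraj composition --n-water 600 --n-organic 2039
```

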