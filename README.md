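# smtrack

Single-molecule tracking and kinetics analysis for protein–DNA interactions
on stretched DNA, built around the workflows used to study how the damage
sensor UV-DDB stimulates and displaces the glycosylase AAG on damaged DNA:
kymograph particle tracking, mean-squared-displacement (MSD) diffusion
analysis, binding-lifetime estimation with photobleaching correction,
dual-color colocalization against damage-site fiducials, and gel-based
equilibrium/excision quantification.

Because raw movies and gels for such experiments are rarely deposited, the
package ships a first-class synthetic-data module (`smtrack.simkit`) that
generates trajectories, kymographs, dwell tables, damage-site layouts and
binding isotherms with known ground truth, so every analysis stage can be
validated closed-loop.

## The models

**Diffusion on DNA.** For each motile phase of a track, the time-averaged MSD

```
MSD(nΔt) = 1/(N−n) Σᵢ (x_{i+n} − x_i)²
```

is fit with the 1D anomalous-diffusion model `MSD(nΔt) = 2D(nΔt)^α + y`,
where `D` is the diffusion coefficient (μm²/s), `α` the anomalous exponent
(α = 1 Brownian, α = 2 ballistic) and `y` an intercept absorbing localization
noise. Fits with R² < 0.8 or covering < 10% of the MSD curve are rejected.

**Binding lifetimes.** Dwell times are fit with a single exponential either
via the Kaplan–Meier survival curve (`S(t) = e^{−t/τ}`, censoring-aware) or
via the cumulative residence time distribution (CRTD) of completed events.
Fluorophore photobleaching is an independent competing exponential, so the
true off-rate is recovered by rate subtraction:
`k_off = 1/τ_obs − 1/τ_bleach`.

**Equilibrium binding.** When the probe DNA concentration is comparable to
Kd, the % bound follows the ligand-depletion ("quadratic") isotherm

```
% bound = 100 · [(D + P + Kd) − √((D + P + Kd)² − 4DP)] / (2D)
```

with `P` total protein and `D` total DNA concentration; `fit_kd` estimates
Kd by nonlinear least squares.

## Worked example

```python
import numpy as np
from smtrack.simkit import simulate_dwell_times, simulate_isotherm
from smtrack.kinetics import fit_survival, correct_for_photobleaching, LifetimeFit
from smtrack.equilibria import fit_kd

# 1000 binding events with a 2.8 s off-lifetime competing with 40.4 s bleaching
dwells = simulate_dwell_times(2.8, 40.4, 300.0, 1000, rng=42)
obs = fit_survival(dwells, method="crtd")
bleach = LifetimeFit(40.4, 6.3, 1.0, 120, 0, 1.0)
corr = correct_for_photobleaching(obs, bleach)
print(f"observed lifetime: {obs.tau_s:.2f} +/- {obs.tau_se_s:.2f} s (n={obs.n_events})")
print(f"bleach-corrected:  {corr.tau_s:.2f} s")

# a 10-point titration at 8 nM DNA, true Kd = 6 nM, 2 percentage-point noise
pts = simulate_isotherm(6.0, 8.0, np.geomspace(0.25, 256, 10), noise_sd=2.0, rng=7)
fit = fit_kd(pts)
print(f"Kd = {fit.kd_nM:.2f} +/- {fit.se_nM:.2f} nM (R^2 = {fit.r_squared:.4f})")
```

prints

```
observed lifetime: 2.59 +/- 0.08 s (n=1000)
bleach-corrected:  2.77 s
Kd = 6.25 +/- 0.26 nM (R^2 = 0.9988)
```

The observed lifetime (2.59 s) is shorter than the planted 2.8 s because
fluorophore death truncates dwells; rate subtraction recovers the true
off-lifetime within sampling error. The Kd estimate recovers the planted
6 nM within its standard error.

A command-line interface mirrors the library:

```sh
smtrack simulate kymo --seed 1 --n 10 --out sim/
smtrack track --kymo sim/kymograph.tiff --threshold 5 --out tracks.csv
smtrack motion --tracks tracks.csv --fps 10 --out phases.csv
smtrack kinetics --dwells dwells.csv --method crtd --out fit.json
smtrack kd --points points.csv --dna-nm 8 --out kd.json
smtrack pipeline --seed 1 --out run/
```

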