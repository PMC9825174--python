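# Methods

This note documents the models implemented in `smtrack`, the assumptions
behind them, the defaults of the synthetic generator, and the numerical
choices made where the design was genuinely open.

## Synthetic data model (`simkit`)

The generator emulates two single-molecule imaging geometries: DNA
"tightropes" (long tandem-ligated substrates with one abasic-site analogue
per 2 kb repeat, suspended between beads and imaged at ~10 fps for 5 min)
and optically trapped lambda DNA (48.5 kb) scanned in kymograph mode at
10–30 fps, with lesion positions marked by fluorescent fiducials.

Each simulated particle is either **bound** at a damage site (stationary) or
**diffusing** in 1D along the DNA. Motile particles move with stationary
power-law increments, `Var[x(t+Δ) − x(t)] = 2D·Δ^α`:

- For α = 1 the increments are i.i.d. Gaussian (Brownian sliding).
- For α ≠ 1 the increments are exact-covariance fractional Gaussian noise
  generated by Davies–Harte circulant embedding (Cholesky fallback for the
  rare embeddings with negative eigenvalues). This matches the MSD fit model
  `2D(nΔt)^α + y`, which presumes stationary power-law increments.
- α = 2 is treated as the ballistic degenerate case (one Gaussian velocity).

Presence ends at the first of exponential dissociation (`bind_lifetime`),
exponential photobleaching (`bleach_lifetime`) or the movie end
(right-censored). Blinking is a two-state on/off telegraph process
independent of motion; only the downstream merging rule (< 2 s gaps) is
constrained by the experimental procedure, so the photophysics is the
simplest renewal model consistent with it. Localization error is i.i.d.
Gaussian per frame. Kymographs are rendered as sums of Gaussian line
profiles (sd `psf_sigma` pixels) scaled to `photon_rate·Δt` expected photons
per emitter, with Poisson shot noise and a constant camera offset; photon
counts are nonnegative integers before the offset is added.

Key defaults (all configurable):

| parameter | default | why |
| --- | --- | --- |
| `frame_interval` | 0.1 s | 10 fps, the tightrope/C-trap acquisition rate |
| `n_frames` | 3000 | 5-minute movies |
| `diffusion_coefficient` | 2.11×10⁻² μm²/s | measured glycosylase sliding coefficient |
| `alpha` | 1.0 | Brownian baseline; observed values span ~1–1.3 |
| `localization_sigma` | 0.02 μm | sub-pixel localization at moderate SNR |
| `bind_lifetime` | 2.8 s | GFP-tagged glycosylase lifetime in nuclear extract |
| `bleach_lifetime` | 40.4 s | measured GFP photobleaching lifetime |
| `blink_off_lifetime` | 0.5 s | gaps well under the 2 s merge rule |
| `photon_rate` | 5000 /s | ~500 photons/frame, SNR ≈ 5–20 over offset noise |
| `pixel_size` | 0.1 μm | typical EMCCD/confocal sampling; not asserted as an instrument value |
| `dna_length` | 48.5 kb | lambda DNA |
| `site_spacing` | 2.0 kb | one lesion per tightrope repeat |
| `kb_to_um` | 0.34 | B-form helical rise |
| `motile_fraction` | 0.11 | motile-event fraction observed for GFP-AAG in extracts |

The published lambda-DNA nick-site coordinates are not available, so
`lambda_fiducial_layout()` uses a **synthetic** 10-site layout constructed so
that one pair falls below the optical resolution limit and one site sits
inside the bead-exclusion margin, leaving 8 observable sites — the same
10 → 8 reduction as the real substrate.

What the generator does **not** emulate: bead/trap mechanics and DNA
force-extension, flow stretching, 2D/3D imaging, spectral bleed-through,
non-Gaussian localization error, heterogeneous photophysics (Qdot power-law
blinking), or crossing-trajectory identity swaps. Passing closed-loop tests
therefore demonstrates correctness of the estimators under the stated noise
model, not robustness to every artifact of real data.

## Tracking (`tracking`)

Per frame, the background is the column median (robust to neighboring
particles) and the noise scale is 1.4826×MAD. Pixels above
`background + threshold·sd` seed 1D Gaussian fits (center, amplitude,
width); failed fits fall back to an intensity-weighted centroid. Centers are
linked frame-to-frame by nearest neighbor within 3 pixels, ties broken by
smaller displacement; a track ends on its first unmatched frame. Tracks
shorter than 10 frames are discarded as noise at these frame rates.

Blink merging re-joins segment pairs with a dark gap strictly shorter than
2 s ("<2 s" is treated as a strict inequality) whose junction positions
differ by at most 0.5 μm (≈1.5 kb at 0.34 μm/kb); the experimental rule
says "same position" without quantifying it, so the gate is explicit and
configurable. Merging picks the smallest eligible gap first, applies
transitively, and is idempotent. Limitation: no multi-emitter
deconvolution — crossing trajectories may swap identities.

## Motion analysis (`motion`)

`compute_msd` implements the time-averaged (single-trajectory) MSD exactly;
gaps break phases rather than being interpolated across. The diffusion fit
uses nonlinear least squares with `D ≥ 0`, `α ∈ (0, 2]` (boundary hits
flagged) and free intercept. Weighting: the sd of an MSD point scales with
its magnitude and with 1/√(N−n) averaged pairs, so points are weighted by
`√(N−n)/MSD(n)`. With uniform or (N−n)-only weights the long-lag points —
few, large and mutually correlated — dominate and single-trajectory D
estimates acquire a heavy right tail from the α–D trade-off; the
relative-error weighting removes that bias (mean recovered D within ~10% at
50 phases × 300 frames). Fits are summarized over the standard rejection
filter, R² ≥ 0.8 and ≥ 10% curve coverage; by default the MSD is fit over
the first 25% of lags, which always satisfies the coverage rule.

Phase segmentation is not prescribed by the experimental procedure, so the
package uses a sliding-window displacement test: a window is motile when its
mean MSD at lags 1–3 exceeds the localization-noise floor `4σ_loc²` by a
configurable factor (default 3; the floor is deliberately conservative —
the static-particle expectation is `2σ_loc²`). Frames take the majority
label of covering windows. Phases are treated independently in summaries
(matching per-phase reporting), with per-particle aggregation available in
`classify_behavior`, where a particle is motile if any phase has an accepted
motile fit and dissociated if its track ends before the observation window.

## Kinetics (`kinetics`)

Dwells run from first to last detected frame of a blink-merged track;
single-frame detections are excluded as indistinguishable from noise;
tracks reaching the movie end are right-censored. Two lifetime estimators:

- `survival_decay`: fits `S(t) = e^{−t/τ}` to the Kaplan–Meier survival
  estimate (product-limit; censored events contribute while observed).
- `crtd`: fits `A(1 − e^{−t/τ})` to cumulative counts of completed events.

Both report τ, its SE, and t½ = τ·ln 2. Because residuals of empirical
survival curves are strongly correlated, covariance-based SEs are floored at
the exponential information bound τ/√n. Photobleaching lifetimes come from
`A·e^{−t/τ}+c` fits to per-second photon bins; traces whose fitted τ exceeds
10× the trace span are flagged `no_bleaching`, and R² < 0.9 flags
`poor_fit` (e.g. multi-component decays). The bleach correction assumes
independent competing exponentials (rate subtraction) and requires
τ_obs < τ_bleach; SEs propagate to first order. Lifetimes extrapolated
beyond the observation window are whatever the fit supports — the package
fits the window it is given.

## Colocalization (`colocalization`)

A pair is colocalized when two channels' particles co-exist within 0.5 μm
for ≥ 1 s (defaults; the experimental calls were by overlapping signals
without numeric thresholds). Pairing is greedy by overlap duration, ties by
mean distance, one pair per particle; an exhaustive-search oracle bounds the
difference from optimal assignment on small instances in the tests. Reports
emit both particle- and per-channel event denominators. On-target
classification uses a ±1 kb window by default (half the 2 kb array spacing).

## Equilibria (`equilibria`)

Lane fractions divide background-subtracted band intensities by the lane
total; subtraction is per band with clipping at zero (warned). The quadratic
isotherm is evaluated as the physical root of
`x² − (D+P+Kd)x + DP = 0`, clipped to [0, 100]%; `fit_kd` seeds the search
at the protein concentration of half-maximal binding and refuses data
without a transition. Fold stimulation is summarized at the earliest
timepoint where the unstimulated fraction reaches 0.05, avoiding 0/0
instability at early times.

## Problem sizes

The test suite and `scripts/acceptance.py` run at desk scale by design:
50 phases × 300 frames for diffusion recovery, 1000–2000 dwells per lifetime
condition, 50 replicate 10-point titrations per Kd, 500 particle pairs for
colocalization, 10⁴ events for the on-target null, 100-frame kymographs for
tracking accuracy. These sizes put sampling error well inside the asserted
tolerances while keeping a full run in the tens of seconds.
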