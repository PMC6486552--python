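# Methods

`ssb_recycling` simulates the turnover of single-stranded DNA-binding protein
(SSB) at an *E. coli* replication fork and re-implements the analysis chain
used to quantify that turnover from single-molecule and live-cell imaging:
kymograph rate analysis, FRAP (fluorescence recovery after photobleaching)
exchange-time fits with photobleaching handling, censoring-aware
Okazaki-fragment length estimation, and the recycling arithmetic that combines
them. This note records the model, its assumptions, the tunable parameters,
and the design choices made where the underlying experiments leave the
mechanism open.

## The fork/exchange model

A replisome synthesizes DNA at a per-replisome rate `v ~ N(v_mean, v_sd)`
(truncated positive; defaults 750 ± 73 bp/s). Lagging-strand synthesis is
discontinuous: Okazaki-fragment lengths are i.i.d. exponential with a
concentration-dependent mean `L(c)`, tabulated from gel densitometry of
rolling-circle products (1.4, 1.5, 2.0, 2.8 knt at 2, 10, 20, 100 nM SSB
tetramer) and interpolated log-linearly in concentration. The exponential
choice follows the single-exponential shape of the measured length
distributions. The source material reports the top concentration
inconsistently as 100 or 200 nM; we follow the figure caption (100 nM).

Within a cycle the helicase exposes ssDNA linearly in time and the
lagging-strand polymerase consumes it at the cycle boundary; this sawtooth,
tiled at one tetramer per `footprint_nt` (default 35 nt, the SSB₃₅ binding
mode; SSB₆₅ interconversion is abstracted away), is recorded in the
`ForkTrajectory`, and `steady_state_tetramers` reports its time-averaged
coverage. For exponential fragment lengths the duration-weighted time average
of the sawtooth equals `L_mean`, i.e. ~40 tetramers at 2 nM — consistent with
the ~35 tetramers measured on product ends by intensity calibration.

**Mean-field fork complement.** The tetramer ledger does not track the
instantaneous tiling. A diffraction-limited fork spot integrates SSB over the
whole loop region (~0.5 µm ≈ 1.8 kb), so the observed spot intensity reflects
the fork's steady-state complement, which is experimentally near-constant in
time. The ledger therefore carries a fixed complement of
`round(L_mean / footprint_nt)` tetramers (configurable via
`initial_tetramers`), and the site-level tiling invariant holds in time
average rather than frame by frame. We adopted this after finding that
explicit site-queue bookkeeping makes bright-tetramer influx bursty (solution
binding happens only when a fragment out-sizes the hand-off queue), which
distorts the recovery kinetics of a typical finite-size experiment away from
the per-tetramer exchange law the model is meant to embody.

**Exchange channels.** Each fork-bound tetramer is replaced by solution SSB
through two routes:

1. *Facilitated exchange in place*, a Poisson process while bound.
2. *Boundary competition*: when the polymerase displaces the tetramers at a
   cycle boundary, each independently transfers internally to the new ssDNA
   behind the helicase with probability
   `p_int = p_int_scale / (p_int_scale + c)`, or is competed out by a
   solution tetramer that takes its place.

The total per-tetramer replacement rate is the effective exchange rate

    k_ex(c) = k_intr + k_fac · c

(pseudo-first-order facilitated exchange). The boundary channel contributes
`r_b = (1 − p_int(c)) · v / L_mean(c)`; the in-place Poisson intensity is set
to `k_ex − r_b` (floored at zero with a warning) so the two channels together
realize `k_ex` exactly. Because cycle durations are exponential, boundary
replacements are Poisson too, and a tetramer's replacement time is exponential
with rate `k_ex`; after a FRAP pulse the expected bright fraction recovers as
`1 − exp(−k_ex t)`. The ground truth `tau_true = 1/k_ex` is recorded per run.

`k_intr` and `k_fac` default to a least-squares calibration of `1/τ` against
`c` over the three measured exchange times (20 s at 2 nM, 10 s at 10 nM,
2.9 s at 100 nM), giving `k_intr ≈ 0.057 s⁻¹`, `k_fac ≈ 0.0029 nM⁻¹s⁻¹`
(`calibrate_exchange_constants`). These reproduce the measured values within
their quoted errors and are exposed in the config.

`p_int_scale` defaults to 200 nM. Two considerations fix the scale: at the
estimated in-vivo SSB concentration (300–600 nM) roughly half of the
fork-bound SSB should be recycled internally per fragment cycle, and the
boundary channel alone must not exceed the calibrated total exchange rate at
any in-vitro concentration (at 20 nM the boundary rate would already exceed
`k_ex(10 nM)`). With 200 nM, `p_int` runs from ~0.99 at 2 nM to ~0.3–0.4 in
the in-vivo-equivalent regime. Whether exchange is per-tetramer or
cooperative is not established; per-tetramer replacement is assumed.

**Chase conditions** (`c = 0`, `k_intr = 0`, a pre-assembled labelled
complement): `p_int = 1` and `k_ex = 0`, so the complement is conserved —
every tetramer ends as `internal_transfer` or `retained_at_end`, reproducing
retention of the original SSB complement when free SSB is removed.

**Photophysics.** A labelled tetramer carries 1 or 2 dyes (probability set so
the mean is `dyes_mean`, default 1.5). Each dye bleaches independently under
imaging with lifetime `tau_b`; a FRAP pulse instantly bleaches every dye on
fork-associated tetramers, while the flowed solution pool stays bright
in vitro. Dye clocks start when imaging starts (`warmup_s` lets replication
run unilluminated before acquisition).

Imaging bleach lifetimes are per illumination scheme: 9.5 s under continuous
full-power imaging (the chase templates), and 400 s in the in-vitro FRAP
template, representing strongly attenuated/low-duty recovery-phase
acquisition between pulses. The attenuated value is a modelling choice — the
recovery-phase illumination of the original experiments is not quantified —
chosen so that bleaching contributes only a small decaying component over a
recovery window (which the combined fit's `a·exp(−t/τ_b)` term absorbs)
rather than dominating the recovery rate; with the continuous-imaging
lifetime, in-vitro "recovery" would measure `k_ex + 1/τ_b` instead of the
exchange rate at low concentration.

## In-vivo mode

`simulate_in_vivo_scene` builds a field of rod-shaped cells (capsules,
~1.1 × 4.5–6 µm) each holding a finite cytosolic pool (~600 tetramers,
Poisson-distributed) and 1–4 replisome foci (≥ 0.8 µm apart, i.e.
resolvable) of `focus_tetramers` (default 12) tetramers. Whole-cell
illumination bleaches every dye with lifetime `tau_b` (default 10 s for the
fluorescent-protein label), so the pool's bright fraction decays as
`exp(−t/τ_b)`. Focus occupants are replaced from their cell's pool at rate
`k_ex`; an arriving tetramer is bright with the pool's current bright
fraction. The FRAP pulse is a Gaussian dose (FWHM 500 nm, peak dose 3.0, so a
centred focus retains `e⁻³ ≈ 5%`) that also bleaches the cytosol by its
area-integral (~9% for these cell sizes — the pulse is specific). The focus
bright count then follows `exp(−t/τ_b)·(1 − exp(−k_ex t))` in expectation:
the two-step analysis (divide by the control-cell decay, then fit
`I₀(1 − exp(−t/τ))`) is exact for this model, which is why the in-vivo
procedure differs from the in-vitro combined fit — in vivo the *reservoir
itself* bleaches, making the bleach factor multiplicative.

## Analysis chain

**FRAP, in vitro.** Each replisome trace is scaled by the ensemble pre-pulse
mean (one shared constant per experiment; per-trace normalization by a short
pre-pulse window injects a time-correlated ratio bias under fork-intensity
fluctuations, biasing τ upward). The first three recovery phases per
replisome are re-zeroed at their pulses, averaged pointwise across
replisomes, and fit by nonlinear least squares to

    I(t) = a·exp(−t/τ_b) + I₀·(1 − exp(−t/τ))

with all parameters bounded positive. Initialization: τ from
time-to-half-recovery/ln 2, τ_b from the tail log-slope, `a = I(0)`, `I₀`
from the plateau. Standard errors come from the fit Jacobian; a bootstrap
over traces is available (`bootstrap_tau`, 200 resamples). Fits where τ and
τ_b agree within 20% are flagged `near_degenerate_exponentials`; a vanishing
`a` flags τ_b as unidentifiable; τ at its bounds is flagged. Weighting is
unweighted by default (per-point SEMs can be passed as weights).

**FRAP, in vivo.** Unpulsed control cells in the same field are normalized,
averaged, and fit with a single exponential to get the imaging-bleach
lifetime (a rising control is rejected; a flat one returns τ_b = ∞,
making the correction the identity). The averaged pulsed-focus trace is
divided pointwise by the fitted decay — truncated with a warning where the
correction would amplify more than 10× — and fit with
`I₀·(1 − exp(−t/τ))`.

**Kymographs and rates.** Rendering uses 160 nm pixels, a 120 nm Gaussian
PSF, 3.6 bp/nm stretched-DNA conversion (from 500 nm ≈ 1800 bp), Poisson
shot noise and Gaussian read noise — all configurable; photon flux is
conserved exactly in noise-free mode. Tracking detects per-row maxima above
median + 5·MAD with centroid refinement, seeds at the globally brightest
detection, and links outward with a 3 px/frame step limit. Rates come from
piecewise-linear least squares with a dynamic-programming changepoint search
(penalty `3·σ̂²·ln n` per extra segment, σ̂ from robust first differences;
minimum segment 5 s). Pooled segment rates are summarized by a least-squares
Gaussian fit to their histogram (falling back to moment estimates when the
histogram is degenerate), reported as mean ± SEM. Co-localization counts the
fraction of reference foci with a partner focus within 250 nm (≈ the
diffraction limit), returning an explicit no-data marker for empty inputs.

**Okazaki-fragment lengths.** Single-molecule route: adjacent SSB-spot
spacings along stretched pre-assembly products sample fragment lengths,
left-censored at 0.5 knt (two spots inside the diffraction limit merge; from
the 500 nm ≈ 1.8 kb scale, conservatively rounded). For exponential lengths
the truncation correction is analytic (memorylessness:
`mean = mean(observed) − threshold`); this truncated MLE is the default, a
histogram single-exponential fit is provided for comparison, and CIs are
percentile bootstrap. The estimator is unbiased to <3% for thresholds up to
half the mean. Ensemble route: gel densitometry is emulated with migration
monotone in log-length, calibrated against a synthetic ladder
{0.5, 1, 2, 3, 5, 10} knt; each fragment contributes stain intensity
proportional to its length, so the raw profile is length-biased (mean
`E[L²]/E[L]`, 2× the mean for exponentials) and dividing by length recovers
the number distribution.

**Recycling metrics.** With exchange time τ, fragment length `L_of` and rate
`v`: one cycle takes `t_of = L_of/v`, the pool supports
`n_cycles = τ/t_of` cycles, and the per-cycle retained fraction is
`exp(−t_of/τ) = exp(−1/n_cycles)` (asserted as an identity). The shared-rate
default is 750 bp/s (the measured rate shows no significant concentration
dependence), overridable per concentration. The 20 nM exchange time was
never measured; the report carries it as an explicit missing value rather
than interpolating. Stoichiometry divides spot intensity by a calibrated
single-tetramer intensity; footprint is tetramers × 35 nt.

## What the generator does and does not emulate

The synthetic data reproduce the statistical structure the analyses rely on:
exchange-driven recovery with photobleaching, per-replisome rate dispersion,
exponential fragment lengths with diffraction censoring, length-proportional
gel staining, finite-pool bleaching in vivo with pulsed and control cells.
They do not emulate stage drift, uneven illumination, camera gain
nonlinearity (gain/offset of the original cameras are unpublished; noise
defaults are generic EMCCD-like), SSB diffusion along ssDNA, leading-strand
or primase kinetics, or cooperative whole-cluster exchange. Passing
parameter-recovery tests therefore shows the inference chain is correct and
well-calibrated for this generative model, not that it is robust to every
artefact of real movies — real-data entry points (TIFF + sidecar, CSV
traces) exist precisely so the same chain can be run on measured data.

## Numerical choices and problem sizes

Event simulation uses one seeded generator per run (`numpy` PCG64 via
`SeedSequence`); identical configs are bitwise-reproducible, and all file
writes are atomic (temp + rename). Fits use `lmfit` (trust-region least
squares) with positivity bounds. Frame interval defaults to 0.5 s, resolving
the 2.5–20 s exchange times. Default experiment sizes mirror the measured
ones: 24/20/18 replisomes for FRAP at 10/2/100 nM with three recovery phases
each and windows of ≥3.5 expected exchange times; 29 pulsed foci + 40
control cells in vivo; 71 kymographs for rates; 500 fragments per
concentration for length estimation. Parameter-recovery summaries use the
median over 100 independent seeds; the bundled recovery tests and the
reproduction script run these sizes in a few minutes on one core.

## Known limitations

- The mean-field fork complement holds the tetramer count fixed per run;
  intensity fluctuations from instantaneous coverage changes are not
  simulated (only dye-count and detector noise).
- The exchange-rate law is linear in concentration over the calibrated range;
  saturation at high concentration is not modelled.
- The in-vivo pulse model bleaches by a 2-D Gaussian dose; axial structure
  and diffusion during the pulse are ignored.
- The combined recovery fit and the two-step fit estimate the same τ only
  when imaging bleaching is weak or properly corrected; on strongly bleached
  in-vivo-style data the combined fit is structurally misspecified (this is
  by design — it mirrors the two distinct published procedures).
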