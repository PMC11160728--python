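# Methods

`extruderquant` implements the quantitative measurement chain used to follow
SMC loop extruders (Condensin I/II, Cohesin-STAG1/2) and their boundary
factor CTCF through mitotic exit, plus a stochastic model of the resulting
loop architecture. This note describes the models, the assumptions behind
them, the defaults and the numerical choices; it is the reference for what
the synthetic-data tests do and do not demonstrate about real data.

## FCS-calibrated copy numbers (`extruderquant.fcs`)

Fluorescence fluctuations of a diffusing species in a 3D Gaussian confocal
volume autocorrelate as

    G(tau) = (1/N) (1 + tau/tauD)^-1 (1 + tau/(kappa^2 tauD))^-1/2 + offset

with `N` the mean particle number in the effective volume, `tauD` the
diffusion time and `kappa` the axial elongation of the volume. `fit_acf`
estimates `N`, `tauD` and the offset by trust-region least squares
(`scipy.optimize.curve_fit`), with `kappa` fixed to 5 by default — a typical
confocal value; it can be freed or set per instrument. No triplet/blinking
term is included: the fit target is `N`, and the synthetic curves are
generated from the same diffusion-only model, so a photophysics term would
be unidentifiable here. A reference dye of known concentration `C` gives the
effective volume `V_eff = N/(C N_A)`; absolute volumes are
instrument-specific (the choice of reference dye alone shifts them by tens
of percent), so only the arithmetic is meaningful, not any particular
printed volume.

Image intensities are converted to concentrations through an OLS regression
of FCS-derived concentration on measured intensity; the slope is the
calibration factor and the zero-concentration intercept the background.
Per-voxel concentrations `factor * (I - background)` are clipped at zero
before integration so copy numbers stay nonnegative; total copies over a
mask are `sum(C * V_voxel * N_A)`. The operation is linear in
background-corrected intensity and additive over disjoint masks, both
asserted in tests.

## Photobleaching kinetics (`extruderquant.kinetics`)

Half-nucleus FRAP is summarised by the normalized difference
`D(t) = (F_ub(t) - F_b(t)) / (F_ub(0) - F_b(0))` between the unbleached and
bleached region means, with t = 0 at the first post-bleach frame (frames
during the bleach train are excluded). The module accepts per-region mean
series directly; aggregating raw images into weighted 1D chromatin profiles
is upstream image processing and out of scope here. `D(t)` is fitted with

    D(t) = a + (1 - a) exp(-koff t)

where `a` is the stably bound ("immobile") fraction over the observation
window and `1/koff` the residence time of the dynamically exchanging pool.
The fit is bounded (`a` in [0,1], `koff` > 0), initialised deterministically
at `a = D(t_end)` and `koff = ln2 / t_half`, and reports 95% confidence
half-widths from the parameter covariance. Degenerate inputs (flat or
monotonically increasing curves) set `fit_ok = False` with a diagnostic
instead of raising.

The spot-bleach assay depletes the chromatin-bound pool by continuous point
illumination; the raw bound fraction is
`100 * (pre - post)/pre` over the first and last 500 ms window means. The
window mean includes early decay, so for fast bleach rates the raw value
undershoots the true bound fraction slightly; this mirrors the real assay
and is removed by the affine calibration against a ~100% bound (H2B) and a
0% bound (free fluorophore) reference, which maps the references exactly to
0 and 100% and clips to that range. After repeated half-nucleus bleaching of
the soluble pool, the bound fraction is read from the unbleached half as
`1 - (1 - post_ub/pre_ub)`: the soluble pool equilibrates across the
nucleus while bound molecules in the unbleached half are untouched. This
convention is the module's own choice of estimator for a stated goal.

## Occupancy arithmetic (`extruderquant.occupancy`)

Bound copies are `nuclear copies x bound fraction`, with the FRAP-derived
fraction taking precedence and the spot-bleach fraction as fallback when no
exponential fit exists (the Condensin II kleisin in early G1 is the case
that fixes this rule). Per-megabase densities divide by
`genome_mb_per_copy x n_genome_copies`; the packaged summary tables
reproduce with 2 x 7,900 Mb in BOTH cell-cycle stages, so that is the
default even though the later stage nominally describes a single nucleus —
the divisor is configurable and the inconsistency is deliberately
reproduced, not resolved. Display rounding is half-up at one decimal, the
printed precision. Rows without any bound fraction are flagged, never
dropped.

Loop arithmetic: a complex extruding at total rate `v` (kb/s) for its
residence time `T` makes a loop of `vT` kb (1 kb/s x 120 s = 120 kb). The
closed-form encounter probability under Poisson placement of `d` complexes
per Mb with loop span `L` kb is `1 - exp(-d L / 1000)`; it is the analytic
companion to the simulator's pairing statistics (0.302 at 3/Mb vs 0.617 at
8/Mb for 120 kb loops).

## Loop-extrusion simulator (`extruderquant.simulation`)

A fixed-timestep (default dt = 0.1 s) two-arm extruder model on an integer
lattice of 1 kb sites, the standard 1D loop-extruding-factor scheme. Per
step and species, `Poisson(loading_rate x lattice_Mb x dt)` extruders load
at uniform random unoccupied sites (attempts on occupied sites are skipped;
occupancy is far below 1% under all study conditions). Each unstalled arm
advances one site with probability `(speed/2) dt` — `speed` is the TOTAL
loop-growth rate split over both arms, so that 1 kb/s for 120 s yields
120 kb loops. An arm stepping onto a CTCF site whose orientation faces it
('+' sites stall left-moving arms, '-' sites right-moving ones, i.e. a
convergent pair captures a loop) stalls permanently with the species'
`ctcf_stall_prob`. Arms are blocked by the pre-step occupancy and
simultaneous claims to a site resolve in favour of the lowest id, which
makes anchor crossing impossible by construction — loop intervals are
nested or disjoint at every step (assertable along whole trajectories with
`check_invariants=True`). Blocked encounters stall but do not unload; with
`pair_on_encounter` both extruders are marked as a pair. Whether paired
complexes remain associated or continue extruding as a unit is left open
biologically; here they simply remain mutually blocked while adjacent.
Unloading removes an extruder with probability `koff dt` and records its
completed loop size.

Closed forms used for validation: mean completed loop size `speed/koff` and
steady-state density `loading_rate/koff` per Mb in the sparse,
boundary-free limit. Completed-loop samples from a finite window are
length-biased against long-lived extruders; the bias is of order
`(1/koff)/duration`, so validation runs use durations of 100 lifetimes
(12,000 s for a 120 s residence time), leaving ~1% bias against a 3%
tolerance. `paired_fraction` is the fraction of surviving extruders that
are adjacent-stalled against another extruder's anchor or flagged as
paired. `loops_to_distance_map` converts a loop configuration to an
expected ideal-chain distance matrix: a kb covered by `d` loops contributes
`compaction^d` (default 0.25) of effective contour, and the expected
distance is `step_nm_per_sqrt_kb * sqrt(contour)`.

## STED spot analysis (`extruderquant.sted`)

Segmentation follows the operator sequence: mild Gaussian blur (sigma 1) ->
Otsu threshold computed within the nuclear mask (a fixed common threshold
across images of one experiment can be supplied instead) -> binary erosion
(disk radius 1) and removal of objects below `min_size` (4 px) -> dilation
-> cluster splitting by local maxima (minimum distance 4 px) and watershed.
Erosion/size/peak defaults are this package's choices; the operator
sequence itself is fixed. Per-spot statistics come from the original
background-subtracted image. Background subtraction is a flat greyscale
opening with a separable square structuring element of half-width 50 px —
the same envelope idea as rolling-ball subtraction, but O(n) via moving
min/max. Colocalization is the Pearson correlation over masked pixels
(undefined and flagged for constant channels). Spot density assumes a
500 nm optical-section depth; labeling efficiency is the ratio of observed
to copy-number-expected density.

Dimer inference fixes a two-component Gaussian mixture at means `mu` and
`2 mu` (mu = median of a monomer reference, shared variance estimated
robustly from the reference via MAD) and estimates only the mixing weight
by EM. Fixing the means keeps the model identifiable on small spot samples
and encodes the doubled-intensity interpretation of unresolvable pairs;
the median intensity ratio is reported alongside.

## Chromatin traces (`extruderquant.traces`)

Trace tables are long-format (trace id, 0-based genomic bin, x/y/z nm, SNR,
fit sd, barcode distance). QC drops points failing per-point thresholds,
then traces with fewer than 20 surviving points; exact numeric per-point
thresholds are not anchored to any published values and are configurable.
Distance matrices take the median over traces (having both bins) of the
Euclidean 3D distance; contact maps the fraction of such traces below a
threshold (120 nm default). Difference matrices subtract elementwise with
NaN propagation. Scaling curves key every pairwise distance by genomic
separation; the power-law exponent is fit by OLS on log-log medians.
`detect_contact_block` scores every contiguous bin interval by the summed
off-diagonal enrichment of its contact sub-block over the distance-decay
expectation (mean contact per separation) using 2D prefix sums, and returns
the maximising interval — used to recover planted loop domains.

## Synthetic data (`extruderquant.synthetic`)

All generators take explicit seeds (never global state) and are
bit-reproducible. Noise is additive Gaussian throughout — the simplest
model sufficient for recovery testing; real photon-counting data is
Poisson-dominated, so absolute noise magnitudes should not be compared to
real acquisitions.

- FRAP curves sample the exponential-with-immobile-fraction model on a
  uniform frame grid (defaults 30 frames at 20 s, the live-imaging
  protocol).
- Spot-bleach traces follow
  `(1 - f) + f exp(-bleach_rate t)` for 30 s at 50 ms sampling.
- FCS curves sample the diffusion ACF on a log-spaced lag grid with
  relative Gaussian noise.
- STED fields place single-pixel impulses uniformly at random (optionally
  with a minimum mutual separation for well-separated benchmarks) in a
  field of 200 um^2 at 18.88 nm pixels, blur with sigma 2.6 px, and scale
  so the blurred peak sits 6-fold over the mean background; dimers are
  single impulses of doubled amplitude, reflecting pairs below the ~60 nm
  resolution limit. The background is constant plus Gaussian noise (mean
  10, sd 2 by default) — its level is a free parameter of the simulation.
  Blurring uses zero-padding, so spots at the field edge lose flux rather
  than artificially gaining it.
- Traces are cumulative 3D Gaussian walks (per-axis step sd 50 nm per
  12 kb bin, giving ~0.9 um spans over 1.2 Mb), with steps inside planted
  loop intervals multiplied by the loop's compaction factor (nested loops
  multiply; crossing intervals are rejected before any output), 20 nm
  localization noise and 10% missing points by default. A Gaussian chain
  has no excluded volume or confinement, so real scaling exponents below
  0.5 at long separations are not expected to reproduce; the generator is
  designed to carry the distance/contact signatures the analysis must
  detect, not polymer physics.
- Calibration cells invert the calibration line exactly plus noise.

## Problem sizes and tolerances

Validation workloads are sized so closed-form comparisons are limited by
the statistics being tested, not by runtime choices: the simulator's
closed-form check uses a 2,000 Mb lattice for 12,000 s (~20,000 unload
events; sampling error ~1%, censoring bias ~1%, checked against a 3%
tolerance); the density comparison discards the first half of each run as
burn-in. Pairing comparisons run 50 independent seed pairs of 1,200 s on
25 Mb. FRAP recovery uses 200 replicates per parameter set. Trace analyses
use 500 traces of 100 bins. Exact arithmetic (occupancy tables, bound
fractions, calibrations) is tested to printed rounding with half-up
rounding at one decimal.

## Known limitations

- The simulator is 1D: no 3D polymer dynamics, no Hi-C map generation, no
  sister-chromatid cohesion, and mitotic Condensin behaviour is covered
  only by parameterization, not by mitosis-specific features.
- The FCS model omits photophysics and detector artefacts; the FRAP model
  is a single-exponential reaction-dominant approximation without
  diffusion coupling.
- STED simulation uses an isotropic Gaussian blur, not a vectorial or
  depletion-shaped PSF, and no camera-noise physics.
- Trace analysis starts from fitted spot tables; drift correction,
  deconvolution and 3D super-localization are upstream and out of scope.
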