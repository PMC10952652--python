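# Methods

`capria` simulates and reconstructs combined 4D ASL angiography and perfusion
MRI: a pseudo-continuous arterial spin labeling (PCASL) preparation followed
by a continuous 3D golden-means radial ("koosh-ball") spoiled gradient-echo
readout, from which both high spatio-temporal-resolution angiograms and
low-resolution perfusion images are reconstructed retrospectively from the
same raw k-space. This note documents the models, the numerical choices, and
what the synthetic data do and do not establish.

## Acquisition model

Spoke `m` of the radial readout points along polar/azimuthal angles

    theta = arccos({m phi1}),   phi = 2 pi {m phi2},

where `phi2` is the real root of `x^3 + x - 1 = 0` (0.6823...),
`phi1 = phi2^2` (0.4656...), and `{.}` is the fractional part (computed by
explicit floor subtraction; no incremental angle accumulation, so there is no
drift at large `m`). The direction of every odd-numbered spoke is reversed
(cosine negated, azimuth advanced half a turn) so that the asymmetric-echo
readout — partial Fourier factor 0.79, sampling radial coordinate
`-(2 pf - 1) k_max .. +k_max` — still covers k-space evenly. The counter for
spoke `i` of preparation `n` is `m = i - 1 + (n - 1) M`, with `M` the spoke
count of the maximum temporal window `t_max`; any contiguous run of spokes
then covers the sphere near-uniformly, so the reconstruction window (hence
temporal resolution, undersampling factor and post-labeling delay) is a free
retrospective choice.

Timing: the default protocol uses labeling duration `tau = 1.4 s`, 216 spokes
in 1.9397 s of readout per preparation, and 88 label/control pairs at a
160^3 matrix over a 183 mm FOV. The printed repetition time of 9.0 ms is
treated as a rounded value; the authoritative spoke interval is
`1.9397 s / 216 = 8.98 ms`. Pairs are interleaved label-preparation then
control-preparation (configurable), minimizing the time between acquisitions
of the same spoke in the two conditions. The dead time between the end of
labeling and the first excitation is not specified by the protocol; it
defaults to 0 s and is a config field. Frame post-labeling delays use the
window-center convention `PLD_k = (k - 1/2) W dt`, which reproduces the
protocol's printed multi-PLD list to within 1 ms. Readout samples are spaced
`1/FOV` for a full echo; for fractional partial-Fourier counts the span
endpoints are kept exact and the spacing deviates by <1%.

## Signal models

Both ASL difference signals are scaled by `sin(alpha_i)` at excitation `i`
and attenuated by the cumulative factor `R_i = prod_{j<i} cos(alpha_j)`,
because every non-selective pulse consumes longitudinal magnetization of the
labeled blood.

* **Angiographic (macrovascular):** a non-dispersed bolus occupying a voxel
  with blood-volume fraction `v` between arrival `delta_t` and washout
  `delta_t + tau`, relaxed by blood T1:
  `S = 2 M0b alpha_inv v sin(alpha_i) exp(-delta_t/T1b) R_i` inside the
  bolus window, zero outside. Dispersion is deliberately excluded.
* **Perfusion (tissue):** the standard single-compartment continuous-labeling
  kinetic model with tissue arrival `Delta_t` and apparent relaxation
  `1/T1' = 1/T1t + f/lambda`, times `R_i sin(alpha_i)`. The closed form is
  verified against a Runge-Kutta integration of the underlying
  inflow/clearance ODE to 1e-6 relative.

The protocol does not fix tissue constants; literature-standard 3 T defaults
are used and config-overridable: `T1b = 1.65 s`, `T1t = 1.3 s`,
`lambda = 0.9`, `f = 50 ml/100g/min` (0.00833 s^-1), `alpha_inv = 0.85`,
`M0b = 1`. Flip angles are degrees at every interface, radians internally.
Note the perfusion signal is linear in `f` only to first order (the `f/lambda`
clearance term perturbs `T1'` at the percent level) — exactly the
approximation under which flow need not be searched during optimization.

## Flip-angle optimization

Candidate schedules are constant (CFA) or quadratically increasing (VFA),
`alpha_i = alpha_1 + (alpha_N - alpha_1)((i-1)/(N-1))^2`. The angiographic
metric averages the signal over pulses while labeled blood is present
(`delta_t <= t_i < tau + delta_t`), then over arterial transit times
`delta_t` uniform on [0.2, 1.0] s (9 points); the perfusion metric averages
over pulses after all blood has arrived (`t_i >= tau + Delta_t`), then over
`Delta_t` uniform on [0.5, 2.0] s (7 points). Transit times beyond the
readout contribute zero with a warning (they do so identically for every
schedule, leaving the argmax unchanged). Each surface is normalized to its
grid maximum; the combined surface is `1/2 S_angio + S_perf`, renormalized —
the half-weight reflects the much lower SNR of the perfusion signal. The CFA
choice is the diagonal argmax; the VFA choice is the grid point within 95% of
the combined peak closest to the origin in Euclidean `(alpha_1, alpha_N)`
distance (ties toward smaller `alpha_N`, then `alpha_1`), minimizing
attenuation of late-arriving blood. With a 1-degree grid over 1–20 degrees
these rules select CFA 6 deg and VFA (2, 9) deg; the default grid step is
0.5 deg, where the selections move by at most one coarse step (5.5 deg and
(2.5, 8.5) deg). The physiological grid densities are assumptions (only the
ranges are given); the selections are insensitive to halving them.

## Synthetic data generator

The phantom is the package's definition of the study conditions, not a dial:

* geometry: an ellipsoidal head of static tissue (intensity 1), three vessel
  segments (a trunk feeding two branches) with arterial transit times
  0.3 / 0.6 / 0.9 s and blood-volume fractions 1.0 / 0.8 / 0.8, and two
  tissue regions (hemisphere-filling, f = 60 ml/100g/min, `Delta_t` = 1.1 s;
  deep, f = 36 ml/100g/min, `Delta_t` = 1.6 s);
* boundaries are partial-volume smooth (Gaussian, sigma = 1 voxel). In vivo
  objects are not voxel-sharp, and a binary mask at desk matrix sizes
  carries >15% of its energy outside the sampled k-space ball — an error
  floor no acquisition of that nominal resolution could beat;
* each spoke samples the object at its own pulse time with that pulse's
  `R_i sin(alpha_i)` weighting, so the object is non-stationary within a
  reconstruction window, as in the real sequence;
* label/control are synthesized as `static -+ dM/2`, so their subtraction is
  exactly the modeled difference; the static anatomy (weighted by
  `sin(alpha_i)`) exercises sensitivity estimation and phase alignment;
* 8 Gaussian-lobe complex coil sensitivities with smooth random phase ramps
  (seeded); strictly positive root-sum-of-squares over the head;
* i.i.d. complex Gaussian noise, std 0.2 per component per sample at the
  desk scale. This puts single-frame perfusion difference images near unit
  SNR — the regime the method actually operates in, where CFA late-PLD
  frames are marginal and the VFA/LLR advantages are visible — while
  angiographic frames remain clearly above the noise;
* an optional linear per-preparation phase drift (default 5 mrad/prep)
  applied to the control condition, emulating scanner drift;
* noise and drift are drawn from a generator keyed on
  `(seed, preparation index)`, which makes discarding later preparations
  bit-identical to a prospectively shorter scan — the property the
  split-scan analyses rely on.

The forward simulator uses a finer NUFFT (kernel width 6, oversampling 2.0)
than the reconstruction operators (width 4, oversampling 1.5), so the data
are not generated by the discretization the solvers invert.

What the phantom does **not** emulate: realistic anatomy, B0 inhomogeneity
and flow dephasing, motion, dispersion, physiological noise. Passing tests
therefore establish correctness of the pipeline under the stated statistical
model — not in vivo image quality.

## Reconstruction

Preprocessing: (1) SVD coil compression to 4 virtual channels at desk scale
(computed from the data covariance, applied to data and any stored truth
sensitivities; retained energy logged); (2) coil-sensitivity estimation from
the label/control mean of all spokes, radially Hann-tapered to the target
band, reconstructed per coil by 10 CG iterations and normalized by the
root-sum-of-squares, masked at 10% of the peak RSS; (3) per-spoke-pair phase
alignment: the control spoke is rotated by the magnitude-weighted average
phase of `control * conj(label)` over the 5 most central readout samples,
then complex-subtracted. With zero drift this rotation is bounded by the
ASL-difference perturbation (~1e-3 rad) rather than exactly zero; with drift
it recovers the applied rotation to the same bound.

Solvers (complex difference frames throughout; magnitude only at export):

* **CG-SENSE:** `min ||Ex - y||^2 + lambda_s ||D_s x||^2 + lambda_t ||D_t x||^2`
  by conjugate gradients on the normal equations, with zero-padded forward
  differences in space and time. No density compensation inside the solver
  (the normal-equation formulation absorbs sampling density; a
  density-compensated adjoint exists for quick-look gridding only). CG
  monotonically decreases the quadratic objective, which is what the solver
  tracks and guards (five consecutive rises abort with diagnostics); the
  normal-equation residual itself is not monotone in CG.
* **LLR:** `min 1/2||Ex - y||^2 + lambda sum_p ||P_p x||_*` over space x time
  patch matrices (default 8^3 voxels x all frames), solved with POGM (FISTA
  available by flag and recorded in provenance); the prox is patch-wise
  singular-value soft-thresholding, the patch grid is cycle-spun by a seeded
  random shift each iteration, and the step size comes from a power-method
  estimate of `||E||^2`. `lambda` is specified relative to `max|E^H y|` so
  one default (0.01) transfers across matrix sizes and noise scales. If the
  final iterate is not the best observed, the best iterate is returned with
  a warning.

The encoding operator is a Kaiser-Bessel gridding NUFFT (written in-package;
kernel width 4, oversampling 1.5, Beatty beta, analytic sinh deapodization)
with an exact-transpose adjoint, so the adjoint dot-product identity holds to
machine precision while the transform itself is accurate to ~3e-3 (one-sided)
against a direct DFT — ~1e-4 at the simulator settings. Image convention:
cell-centered grid, DC at the center voxel, k-space in cycles/mm.

Perfusion series are reconstructed directly at a lower matrix (fraction
52/160 of the acquisition matrix) from the central k-space samples
(`|k| <= matrix_low / (2 FOV)`) at the broadest window; the resulting
undersampling factor (`(pi matrix^2/2)` diameter-spoke Nyquist count over
acquired spokes) is logged and recorded in provenance — 19.0 for the
full-protocol angiogram (24-spoke window) and 1.3 for its perfusion series.

The acquisition protocol does not fix regularization weights (they are
chosen empirically in practice); the defaults here (`lambda_s = 1e-3`, `lambda_t = 1e-2`,
`lambda_llr = 0.01` relative) were fixed by the shipped `sweep-lambda`
utility on the desk phantom and are recorded in every output's JSON sidecar.

## Repeatability assessment

The acquisition is split by preparation order into halves, each reconstructed
independently; per-frame Pearson correlations of voxel magnitudes inside a
mask (whole-head for perfusion; for angiography the temporal-mean image
thresholded at 0.7 x the 99.9th-percentile intensity and dilated by a
3.5 mm spherical element) are Fisher-transformed (`z = atanh r`) for any
averaging. Frames with a constant half are reported missing (NaN), never
zero. The in vivo brain-mask route (structural segmentation + registration)
is out of scope; the phantom's known support is the brain mask here.

`epi_split_correction` applies the reference quadratic mapping
(`-0.2231 r^2 + 1.2221 r + 0.0004`) from 4-of-5-pair EPI repeatability to its
full-scan equivalent. `refit_split_correction` regenerates such a mapping by
simulating kinetic-model timecourses (the original signal family is
unspecified; this package draws mixed macrovascular/perfusion voxels over the
phantom's parameter ranges) at paired noise levels (reduced scan time 4/5 ->
noise x 5/4) and fitting a quadratic. Its coefficients reproduce the
reference mapping qualitatively, not numerically: monotone, near-zero intercept,
`f(r) >= r` over [0.01, 0.97]. (Strict `f(r) >= r` fails above r = 0.997
even for the reference coefficients.)

## Problem sizes

The shipped tests run the full physics at a workstation scale chosen as the
package's standard desk conditions: 48^3 phantom grid, 8 physical / 4 virtual
coils, 16 label/control pairs, the full 216-spoke timing, perfusion at 16^3.
At this scale split-half perfusion repeatability spans r ~ 0.36-0.99 across
schedules and PLDs, giving the comparisons room on both sides. Solver unit
tests use 16-24^3 grids with Nyquist or near-Nyquist spoke counts. The
full-protocol geometry (160^3, 88 pairs) is exercised for its analytic
quantities (schedules, undersampling factors, metric optimization) and
available end-to-end via `--scale 1.0`.

## Known limitations

* No B0/off-resonance, motion, or dispersion modeling; no trajectory-error
  correction — the trajectory is assumed exact.
* Partial-Fourier recovery relies on the solvers' implicit regularization
  only; no homodyne/POCS step.
* The LLR prior can bias timecourses if over-weighted; the default weight
  keeps vessel time-to-peak bias at zero frames on the phantom, but the
  appropriate weight is application-dependent (the sweep utility exists for
  this reason).
* The repeatability statistics are image-quality surrogates; they are not an
  SNR measurement and inherit the mask definition.
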