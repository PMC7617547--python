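# Methods

This note documents the models, estimators and numerical choices behind
tremornet, what the synthetic cohort generator does and does not emulate,
and where the design was genuinely open.

## Task and data model

A trial consists of five epochs in fixed order: eyes-open **rest** (3 s),
**postural** raise (3 s), directional **cue** (2.5 ± 1 s, uniform jitter per
trial), centre-out **reach** (2 s), and a sustained **hold** (1.5 s). Trials
follow a 2 × 2 design (high/low cue uncertainty × large/small target),
balanced within subject. Each trial carries a triaxial accelerometer trace
(m/s²) and source-level time series for a fixed set of 10 motor ROIs
(ipsi/contralateral dorsolateral prefrontal cortex, SMA, sensorimotor
cortex, posterior parietal cortex, cerebellum lobule VI). The default
sampling rate is 256 Hz — comfortably above 4 × the highest analysed
frequency (45 Hz) — and configurable.

## Synthetic cohort generator

The generator exists so that every estimator in the chain can be validated
against known ground truth, and so that the permutation statistics can be
calibrated on cohorts whose null is true by construction.

**Tremor.** A subject-fixed frequency is drawn from N(5.8, 1.6²) Hz,
clipped to the 4-12 Hz tremor band, and a subject-fixed random unit vector
defines the dominant sensor axis. The oscillation is a carrier with Wiener
phase noise (1.5 rad²/s, i.e. a sub-Hz linewidth — a deterministic
fixed-phase sinusoid is both unphysiological and degenerate for coherence
analysis) under slow (0.2-1.4 Hz) amplitude modulation of configurable
depth (default 0.3; single-trial burst structure is deliberately exposed as
a parameter rather than fixed). The burst is gated to posture→hold with
raised-cosine ramps ≤ 200 ms and scaled so its RMS over those epochs equals
the configured amplitude exactly: 0.85 m/s² for patients, 0.19 m/s²
(physiological tremor) for controls, with mean-one lognormal trial-to-trial
variation (σ = 0.1).

**Tremor-coherent sources.** Inside the 4-12 Hz band and the tremor epochs,
a target ROI's band content is replaced by a power-matched mixture
√c·r̂ + √(1-c)·ŝ of the band-filtered tremor reference r̂ and an
independent surrogate ŝ with the same (1 Hz-smoothed) amplitude spectrum.
Because the two parts share a spectral shape, the magnitude-squared
coherence with the reference approaches the mixing fraction c at every
in-band frequency; measured targets {0, 0.5, 1} come out near
{0.02, 0.45, 0.97}. Default targets: contralateral SMA 0.6, contralateral
dlPFC 0.3, contralateral PPC 0.25, cerebellar ROIs 0.2, all others 0;
patients only.

**Motor networks.** Four spatial-spectral networks modulate band-limited
power multiplicatively: variance in the band is scaled by
(1-depth)^a(t), where a(t) is the network's per-epoch activation profile
smoothed with ≤ 250 ms ramps and the band split is an exact FFT brick-wall
(so the realized in-band variance ratio matches the configured depth):

| network | band (Hz) | ROIs | activation (per epoch) | depth ctrl / ET |
|---|---|---|---|---|
| low-beta frontoparietal | 14-21 | SMA, sensorimotor, PPC (both) | cue 1.0, reach 0.3, hold 0.1 | 0.30 / 0.45 |
| gamma sensorimotor | 30-45 | sensorimotor (both) | reach 1.0 | -0.40 (power burst) |
| mu prefrontal | 8-16 | dlPFC (both) | posture 1.0, cue 0.4, reach 0.4, hold 0.45 | 0.28 |
| upper-beta premotor (SMA) | 18-30 | SMA (both) | hold -1.0 (rebound) | 0.15 / 0.22 |

The 15-point patient-control difference in low-beta depth is the study
condition of interest; per-trial depths jitter with SD 0.12 (single-trial
ERD is highly variable in practice), and that realized low-beta depth is
coupled into the trial's mean velocity with slope -1.2 units/s per unit
depth, so deeper planning-network engagement means slower reaches.

The four activation profiles and ROI assignments were designed jointly for
*identifiability*: PCA can only recover components whose spatial-spectral
footprints are near-orthogonal and whose latent variances are distinct, so
the networks use disjoint ROI × band combinations (up to unavoidable
time-frequency smearing), pairwise profile correlations ≤ 0.2, and a graded
variance ladder (realized explained-variance shares ≈ 54/25/13/7 %). This
mirrors real group decompositions, whose reported components are orthogonal
by construction and carry a similar descending variance split.

**Kinematics** are generated directly as table values (reaction time, mean
velocity, path length, hold variability) with additive condition and group
offsets; full trajectories are not synthesized except for a minimum-jerk
1-D speed profile (`build_trial_trajectory`) used to validate onset
detection and the kinematic summaries.

**Background activity** is 1/f Gaussian noise, independent across channels
apart from the injected couplings. Volume conduction, sensor-level physics,
artifacts (blinks, cable noise) and head tremor are deliberately not
modelled: the ROI inputs represent already-beamformed virtual channels.
Consequently, passing round trips show that the estimators are correct and
calibrated under the assumed signal model — not that they are robust to
sensor artifacts, source leakage, or non-Gaussian noise.

## Estimators

**Tremor chain.** FIR filters are windowed-sinc (Hamming), order 3·fs/f_low
(shortened on segments too short for the default), applied
forward-backward for zero phase. The principal axis is the leading
eigenvector of the 3 × 3 covariance of the band-filtered axes, sign-fixed so
its largest-magnitude element is positive. The peak frequency is the argmax
of a Slepian multitaper spectrum with round(1.5 × duration_s) tapers —
"1.5 tapers per Hz of spectral resolution"; the alternative reading (per Hz
of signal band) is available through the `taper_density` parameter.
Amplitude is the RMS of the dominant-axis signal re-filtered to peak ± 3 Hz.
Epochs shorter than 2 s borrow neighbouring samples symmetrically so the
spectral estimate stays defined (the cue epoch can be 1.5 s at minimal
jitter). Known bias: the ± 3 Hz band clips the tails of the tremor line
shape and the onset ramp sits inside the posture epoch, together ≈ -2 %.

**Time-frequency maps.** At frequency f the window spans 4 cycles (4/f s)
and the taper count is max(1, ⌊2·T·W - 1⌋) with W = 0.4 Hz of half-bandwidth
smoothing — which forces a single Slepian above 1.6 Hz, so most rows use
one taper. Power is evaluated by direct projection onto tapered complex
exponentials at exactly the requested frequencies; this is the limit of
dense zero-padded FFT interpolation and avoids padding artifacts. Maps live
on a fixed 50 ms hop grid aligned to absolute sample indices (time-shift
equivariant within one hop); grid points whose window overruns the signal
are NaN. PSD scaling is one-sided (a flat white-noise spectrum comes out at
2σ²/fs). The 4-cycle windows imply ~f/4 Hz resolution, so band edges smear;
ERD **percent change** (100·(P - P̄_rest)/P̄_rest per row) inherits that
smearing. For unbiased band-power round trips the package also provides
`band_power_change`, which brick-wall filters once and forms the epoch /
rest variance ratio directly, pooling power across trials before the ratio
(averaging per-trial ratios carries an upward Jensen bias of ≈ +6 % at
these epoch lengths).

**Coherence.** Magnitude-squared coherence uses pooled multitaper cross-
and auto-spectra (2 s segments, 3 tapers, NW = 2) over all segments and
trials; at least 4 segments are required (fewer make the estimate trivially
1). The in-band average is weighted by the reference auto-spectrum so a
narrowband tremor reference is read where it has power rather than diluted
across the whole 4-12 Hz band. Per-trial coherence (for trial ranking)
pools only within-trial segments. The auxiliary procedure keeps the top
fraction (default 0.5) of trials by reference-ROI coherence, regresses the
reference channel out of every other ROI by unlagged least squares
(coefficient + intercept; lag structure left open), and recomputes
coherence on the residuals; a channel fully explained by the reference
(residual power < 1e-10 of the original) reports zero rather than the
coherence of numerical noise, and the reference ROI itself is reported as
missing. Trial ranking uses the reference ROI's coherence; ranking by each
target ROI is available via the same per-trial values.

**tfPCA.** Power is floored at (smallest positive value × 1e-3) before the
log; per-subject Z uses the pooled mean/SD over all entries (SD floor
1e-12), retained on the tensor so trials project into the same space; a
per-(frequency, ROI) normalization alternative exists behind
`build_tensor`'s interface by normalizing maps beforehand. The fit is an
SVD of the column-centered unfolding (time × frequency·ROI,
frequency-major); NaN cells are replaced by column means, i.e. they
contribute nothing to the covariance. Component signs put the
largest-magnitude loading positive. Back-projection centers with the
*group-fit* column means — per-trial centering would destroy cross-trial
comparability. The number of components is a parameter (default 4); no
automatic selection rule is implemented.

**Cluster permutation.** Pointwise two-sided t (Welch for unpaired
contrasts, since group sizes are typically unequal; one-sample on
differences with sign flipping for paired), cluster-forming threshold at
the two-sided p = 0.1 critical value (per-point Welch df), clusters are
contiguous same-sign suprathreshold runs scored by summed t, and the null
is the maximum |mass| over label exchanges / sign flips, vectorized across
permutations. p = (1 + #{null ≥ observed}) / (1 + n_perm) — never exactly
zero. The cluster-forming threshold is not the significance level; cluster
significance is α = 0.05. Calibration: family-wise error 0.05 within the
binomial CI over 500 null simulations; an injected 1.5-SD offset over 30 %
of the axis at n = 12/11 is detected in ≥ 90 % of replicates.

**Quartile splits.** Per subject, trials with covariate ≤ Q1 and ≥ Q3
(inclusive bounds keep quartiles non-empty at 8 trials; ties resolve through
the inclusive threshold in stable trial order) are averaged and compared
with the paired cluster test. The generator's velocity coupling acts through
the planning network, whose engagement peaks in the cue epoch, so that is
where the power experiment looks for the effect.

**Outlier screens.** The kinematic |Z| > 1.96 filter computes each value's
Z against the *other* values (leave-one-out): with an inclusive SD the
largest attainable |Z| in n values is (n-1)/√n < 1.96 for n ≤ 4, which
would make the screen vacuous exactly where it matters. Cook's-distance
screening removes points above 3 × the mean distance and refits once;
perfect fits (residual sum of squares at rounding level) skip screening,
because the distances are then ratios of float noise.

**Condition ANOVA** averages trials per subject × condition cell, subtracts
the subject mean (only within-subject condition variance is tested), and
fits an ordinary two-way OLS ANOVA (type II). It is deliberately not a
mixed model; degrees of freedom are reported as computed.

## Problem sizes

The tfPCA recovery experiment runs at 23 subjects × 150 trials: residual
estimator noise in the group tensor falls as 1/(subjects × trials), and
roughly 2,800+ trials are needed before the four-network structure carries
> 90 % of tensor variance, matching the scale of real group analyses.
Round-trip experiments use 100 trials per subject (Monte-Carlo error ≈ 1-2 %
of the target quantities); the ERD round trips disable trial-level depth
jitter so the configured depth is the exact truth being estimated.
Permutation calibration uses 500 replicate null datasets at 500
permutations each. The example scripts use deliberately small cohorts and
say so where estimates are visibly noisy.

## Known limitations

- Estimator validation is within-model: no artifacts, no source leakage,
  no volume conduction, no non-stationary backgrounds.
- The TF transform's 4-cycle windows trade frequency resolution for
  temporal locality; narrow-band effects at low frequencies smear, and the
  map-based ERD is accordingly attenuated relative to the band-variance
  route.
- The auxiliary regression is unlagged; a lagged or frequency-domain
  variant could remove more of a delayed shared component.
- ANOVA df conventions follow the OLS fit on cell means and are not meant
  to reproduce any particular mixed-model notation.
- Epoch-locked tensor windows truncate the cue epoch at its minimum
  duration, discarding late-cue data on long-cue trials.
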