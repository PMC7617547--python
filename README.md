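# tremornet

Analysis chain for studying how pathological tremor interacts with
movement-locked brain rhythms during naturalistic reaching — aimed at
researchers working with Essential Tremor (ET) or similar movement
disorders who record source-level M/EEG ("virtual electrode") time series
alongside triaxial accelerometry in a structured reach-to-target task.

The package covers five analysis layers plus a matched synthetic cohort
generator:

- **Tremor quantification** (`tremornet.tremor`): zero-phase FIR bandpass to
  the 4-12 Hz tremor band, principal-axis projection of the three
  accelerometer axes, multitaper peak-frequency estimation (1.5 tapers per
  second of data), and RMS amplitude after re-filtering around the peak
  ± 3 Hz — per task epoch.
- **Kinematics** (`tremornet.kinematics`): posture-onset detection by
  thresholding the Z-normalized rectified accelerometer sum at Z = 3,
  per-trial reaction time / mean velocity / path length / hold variability,
  a leave-one-out |Z| > 1.96 outlier screen, and condition ANOVAs on
  subject-demeaned cell means.
- **Spectral analysis** (`tremornet.spectral`): movement-locked multitaper
  time-frequency maps (4 cycles per frequency, ± 0.4 Hz Slepian smoothing,
  power evaluated at the exact requested frequencies), percent change from a
  rest baseline (event-related desynchronization, ERD), band-averaged
  magnitude-squared coherence between ROI channels and the tremor signal
  pooled over trials, and an auxiliary procedure that ranks trials by
  reference-channel coherence, regresses the reference out, and re-maps the
  residual coherence.
- **Time-frequency PCA** (`tremornet.tfpca`): group-level SVD of the
  log-scaled, per-subject Z-normalized time × frequency × ROI tensor,
  giving spatial-spectral components with latent temporal dynamics,
  single-trial back-projection through the group loadings, and rank-k
  reconstruction with the usual explained-variance identity.
- **Group statistics** (`tremornet.stats`): cluster-based permutation tests
  on time courses (cluster-forming p = 0.1, mass statistic, max-statistic
  null, α = 0.05), exact binomial subject-overlap probabilities
  B(k ≥ n; N, p), quartile splits of trial latents by kinematic covariates,
  Benjamini-Hochberg FDR, and Cook's-distance-screened correlation.

The synthetic generator (`tremornet.synth`) produces whole cohorts with the
statistical structure these analyses assume — a five-epoch trial (rest 3 s,
postural raise 3 s, jittered cue 2.5 ± 1 s, reach, hold), 4-12 Hz tremor
bursts (patient mean 5.8 Hz, 0.85 m/s² RMS at posture vs ~0.19 m/s²
physiological tremor in controls), tremor-coherent cortical sources
strongest over contralateral SMA, and four movement-locked band-power
networks with a deeper low-beta response in patients — so every estimator
can be validated against known ground truth.

## The core statistic

For ROI r and frequency f, trial-averaged power P(t, f, r) is mapped to a
subject tensor X = Z(log P) (pooled per-subject Z), epochs concatenated
along time. tfPCA solves the SVD of the column-centered unfolding
X̃ ∈ ℝ^{T×(F·R)},

    X̃ = U S Vᵀ,   coefficients = rows of Vᵀ,   latents = X̃ V,

so component k has unit-norm spatial-spectral loadings v_k over (f, r) and
latent dynamics x̃(t)·v_k; explained variance is s_k² / Σ s². Trials are
projected through the group V and column means, which keeps single-trial
latents comparable across subjects, and quartile splits of those latents by
per-trial kinematics are tested with paired cluster permutation.

## Worked example

`examples/tremor_quantification.py` embeds a 5.8 Hz, 0.85 m/s² tremor burst
from posture onset into sensor noise and runs the estimation chain per
epoch:

```
   epoch  peak (Hz)  RMS (m/s^2)
    rest       9.00        0.008
 posture       5.67        0.819
     cue       5.60        0.867
    hold       6.00        0.788
```

Rest contains only sensor noise (the "peak" is noise in an empty band, with
amplitude at the noise floor); the tremor epochs recover the embedded
frequency to within the spectral resolution of a 3 s epoch and the embedded
amplitude to within a few percent. The other scripts in `examples/` walk
through cohort simulation, ERD measurement, source-tremor coherence with
overlap statistics, tfPCA, group statistics, and the end-to-end pipeline.

A thin CLI wraps the pipeline for on-disk runs:

```bash
tremornet simulate --out run/cohort --seed 8
tremornet analyze --cohort run/cohort --out run/results --seed 8
tremornet report --results run/results
```

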