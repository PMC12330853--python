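# Methods

## Signal model

A breath hold (BH) raises arterial CO2, which dilates cerebral vessels and
raises the BOLD signal. Per voxel i the fitted model is

    y_i(t) = β_i · x(t − Lag_i) + C(t) γ_i + ε_i(t)

where x is the normalized stimulus regressor, C the confounds, and Lag_i a
voxel-specific latency. CVR is the response amplitude per unit CO2 change,

    CVR_i [%/mmHg] = β_i / (μ_i · ΔPetCO2) × 100,

with μ_i the voxel's temporal mean signal and ΔPetCO2 the subject's mean
BH-induced end-tidal CO2 rise. The optimal-lag map is reported relative to
its in-brain median (Lag_rel); positive values mean a later-than-typical
response (white matter, venous territories).

### Regressors

Two stimulus encodings × three convolution models give six candidate
families:

* **PetCO2** — the end-tidal CO2 course, the physiological driver;
* **Block** — a unit boxcar over the holds, a fallback for poor CO2
  recordings;

each used raw (WoC) or convolved with a single-gamma (CSg) or double-gamma
(CDb) kernel. Kernels are gamma densities parametrized by time-to-peak p1
(3–11 s in 1 s steps), dispersion p3 = p1/6 (so the shape index p1/p3 = 6
is constant), with the double form subtracting a 1/6-amplitude undershoot
gamma at p2 = (8/3)p1, p4 = p3. The gamma convention is shape =
delay/dispersion, scale = dispersion (seconds); the positive-lobe mode
therefore sits at p1 − p3 even though p1 is labeled "time to peak".
Kernels are sampled at dt = 0.1 s over 32 s and normalized to unit sum so
that convolution preserves the regressor's amplitude scale and β stays
comparable across delays (the source convention does not state a kernel
scaling; unit sum is our choice).

Each candidate design column is the high-resolution source delayed by the
candidate lag (positive lag = later response), sampled at the volume times
k·TR, and min–max normalized to [0, 1] *per candidate* (whether
normalization precedes or follows the shift is unstated in the source; we
normalize after, keeping β's meaning fixed across lags). High-res sources
are built on a window padded by 24 s (= 15 s bulk search + 9 s sweep) on
both sides. PetCO2 sources get an additional 40 s of edge-held *warm-up*
history before convolution: the resting CO2 level is non-zero, so a causal
convolution from zero history would inject an onset ramp into the scan
window that can dominate the min–max normalization. Block sources are zero
before the first hold, where zero history is exact.

### Lag optimization

The **bulk lag** maximizes the Pearson correlation between the mean
gray-matter BOLD series and the TR-sampled regressor over ±15 s in 1 s
steps (ties → smaller |lag|; boundary hits are warned about). The
voxelwise sweep then refits the GLM with the regressor at bulk − 9 … bulk
+ 9 s (19 candidates) and keeps, per voxel, the lag whose regressor attains
the highest **partial F** — the F of the regressor of interest alone
(reduced model = confounds + intercept), not of the full model. Exact F
ties (possible in noiseless synthetic data) resolve to the smallest
|offset| from the bulk lag, then the more negative lag — preferring the
least-shifted explanation; the step is 1 s (a finer 0.3 s grid changes
results negligibly and triples the cost).

The joint voxelwise (HRF delay, lag) search is implemented
(`optimize_delay_and_lag`) but not recommended: the two parameters
interact so strongly that at realistic SNR the estimated delays pile up at
the extremes of the tested range (reproduced in the acceptance suite as a
>2/9 mass at 3 s and 11 s when the truth is 6 s); delay selection belongs
at the ROI level.

### Estimation

OLS via the Frisch–Waugh decomposition: the confounds-plus-intercept block
is orthonormalized once, data and candidate columns are residualized
against it, and the 19 candidate fits reduce to per-candidate rank-one
updates — algebraically identical to refitting the full design per lag
(verified against an explicit lstsq loop to 1e-8). Collinear confound
columns are dropped by pivoted QR with a warning (zero-motion simulations
make this path routine). An optional single-pass Cochrane–Orcutt AR(1)
pre-whitening with a pooled autocorrelation is available
(`prewhiten=True`) but off by default: the source pipeline used its
package's standard pre-whitening, but OLS is deterministic and sufficient
at synthetic scale; the flag records the gap.

Voxels with an exact fit (zero residuals) get partial F = +inf, which the
argmax handles naturally; all-zero (degenerate) voxels get F = 0.

## PetCO2 processing

1. **Tube delay** — timestamps shifted by −delay (gas transit to the
   capnograph); samples before t = 0 dropped.
2. **Peak detection** — local maxima with prominence ≥ 25% of the trace's
   interquartile range (robust to cardiogenic ripples), thinned to a
   minimum 2 s separation keeping the higher peak. Apneas produce no peaks
   (the trace decays monotonically with no airflow).
3. **Interpolation + detrending** — PCHIP through the peaks onto a 0.1 s
   grid (a published resampling rate of 0.027 Hz is below any plausible
   breathing rate and treated as a typo), then a second-order Butterworth
   high-pass at 1/100 Hz applied forward–backward with the mean re-added
   (absolute mmHg are needed for ΔPetCO2).
4. **ΔPetCO2** — per hold: first end-tidal peak within 20 s after the hold
   minus the mean end-tidal value over the preceding cued-breathing
   baseline; averaged over holds. The baseline window *excludes* the first
   20 s after the previous hold, so the elevated recovery breaths of one
   trial cannot contaminate the next trial's baseline (with the full-gap
   window the per-trial values would be systematically biased low).
   Missing post-hold peaks are warned about and excluded from the mean.

## BOLD preprocessing (in scope)

Motion correction, distortion correction, registration and segmentation
are consumed, not performed — masks and motion tables are inputs, assumed
voxel-aligned (the simulator guarantees this). In scope:

* **Detrending** — projection onto the orthogonal complement of a slow
  drift basis (linear term + discrete cosines with frequency < 1/100 Hz),
  mean preserved. Unlike a recursive filter this is exactly idempotent,
  and the *same projection is applied to the design and confound columns*,
  so filtering cannot bias β — this is what makes the noiseless
  forward/inverse round trip exact. The ~0.02 Hz task frequency passes
  with <2% attenuation.
* **Smoothing** — per-volume Gaussian, σ = FWHM/2.3548 per axis converted
  to voxels, reflect boundary (mass-preserving in the interior). Default
  FWHM 3.5 mm; recovery tests run unsmoothed because the synthetic truth
  is voxelwise.
* **Confounds** — 24 extended motion parameters (6 rigid-body, backward-
  difference derivatives with zero first row, squares of both) plus one
  unit spike column per motion outlier. Outliers: RMS difference of each
  volume from the middle volume over the brain mask, threshold
  Q75 + 1.5·IQR. On task-dominated synthetic data this rule flags more
  volumes than real motion would (the metric sees the task), which costs
  degrees of freedom but nothing else.

## Maps and summaries

CVR and Lag_rel as above; the Lag_rel median is taken over the whole brain
mask before any thresholding (GM-only is configurable). μ_i defaults to
the whole-time-course mean; a baseline-only mean (excluding holds + 20 s)
is behind a flag — the two differ negligibly by construction of the small
BH perturbation. Percentile thresholds — CVR (1, 90), Lag_rel (1, 99) —
use linear interpolation over in-mask finite values with inclusive bounds,
and only invalidate voxels, never alter values. ROI summaries are
arithmetic means over valid voxels per tissue.

## Model comparison statistics

Friedman's rank test with average ranks and the standard tie correction;
Conover's post-hoc pairwise test in the squared-rank (tie-robust) form
with (n−1)(k−1) df — when every subject ranks the conditions identically
the statistic diverges and the pairwise p is 0 (or 1 for tied rank sums).
Bonferroni correction: adjusted p = min(1, p·m), significance at raw
p < α/m (α = 0.05: thresholds 0.0083 for six comparisons, 0.0167 for
three). The paired sign-flip permutation test (exact enumeration when
2^n ≤ n_perm, else seeded Monte Carlo with the add-one estimator) is a
desk-scale stand-in for voxelwise permutation inference, which is out of
scope.

## Synthetic data: what it emulates and what it does not

The generator emulates: a four-trial end-expiration BH paradigm (15 s
holds, 30 s cued baselines, 269 s / 213 volumes at TR 1.26 s; the 59 s
lead-in is a tuned constant — the source states only the total); a
capnograph trace with end-tidal peaks at the breathing rate (0.25 Hz
default), decay to the inspired level during holds, a first post-hold peak
elevated by ΔPetCO2 (default 8 mmHg over a 38 mmHg baseline — plausible
values, not measured ones; the source reports neither) relaxing over ~3
breaths; slow cosine drift (128 s period, removed by the 100 s detrend);
motion-coupled nuisance as a random linear mix of the 6 simulated motion
columns; white Gaussian noise scaled to the voxel mean. Tissue defaults —
GM 0.45 %/mmHg at lag −0.2 s, WM 0.20 %/mmHg at +0.2 s, voxel lags from
truncated Gaussians in ±3 s (snappable to the 1 s grid) — sit inside
reported healthy-adult ranges and are reference points, not oracles.

Forward model per voxel: y = μ·(1 + c·(x − mean(x))) + drift + motion +
noise, with c = CVR·ΔPetCO2/100 and x built *exactly* like a fitted
candidate column (shifted, TR-sampled, min–max normalized). Centering x
keeps the temporal mean equal to μ, so the mean-normalized CVR definition
inverts the forward model exactly — the uncentered form would bias CVR
recovery by c·mean(x) ≈ 1% and make the machine-precision round-trip test
impossible.

Not emulated: EPI/k-space physics, vascular transit and dispersion,
physiological noise spectra (cardiac/respiratory harmonics), spatial
autocorrelation of noise, multi-echo acquisition, real motion artifacts
(the motion table moves nothing — it only couples into intensities). A
green recovery test therefore establishes the *estimator's* correctness
and noise robustness, not performance on real scanner data.

## Known limitations

* Pre-whitening is optional and single-pass; with the default OLS the
  partial-F values on strongly autocorrelated data are optimistic. Lag
  and CVR estimates (the quantities of interest) are unbiased either way.
* The bulk lag is estimated from GM, so WM lags sit near the sweep's
  upper range; widening `lag_halfwidth` is the remedy if boundary
  fractions (reported in QC) are high.
* The lag sweep's multiple-comparisons problem is acknowledged, not
  corrected: maps are trimmed by amplitude percentiles, not by inference.
* `read_events` reconstructs baseline duration from trial spacing and
  needs the run length supplied (events files do not record it).
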