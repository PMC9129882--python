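# Methods

## The detection model

`bsdetect` treats burst-suppression detection as a low-rank signal problem.
During burst-suppression the cortical BOLD signal is dominated by one
shared slow fluctuation — the hemodynamic echo of the burst/suppression
alternation — riding on spatially independent noise. In a z-scored
voxel × frame matrix that shared fluctuation is (approximately) the leading
right singular vector, and its defining property is not explained variance
but **asymmetry**: the distribution of Pearson correlations between the
component and the individual voxel rows is shifted toward +1 rather than
centred on zero. The median of those cortex-wide correlations ("median r")
is the detection statistic. Structured noise components (motion residuals,
vascular or ventilation effects) load positively on some voxels and
negatively on others, so their correlation histograms stay symmetric and
their median r near zero even when their explained variance is large.

The thresholds on median r (human 0.45, macaque 0.15, marmoset 0.22, rat
0.20) are deliberately species-specific constants, not fitted quantities:
the appropriate value depends on species, anesthetic and acquisition, and
the method is a screening heuristic, not an automated classifier. Rats
additionally use an exclusion rule — if a second PC's median r comes within
0.15 of the top one the run is rejected as ambiguous — encoded as
`m1 − m2 ≥ 0.15` accepts, i.e. a gap of exactly 0.15 is still accepted.
For the other species "a single prominent asymmetric PC" is encoded by the
threshold alone (no gap rule), which presets express as
`exclusion_delta = None`.

Sign conventions: PCs are unit-norm right singular vectors; SVD sign is
arbitrary, so any PC whose median voxel correlation is negative is flipped
together with its correlation vector. Classification is therefore invariant
to a global sign change of the data, and to any permutation of voxel rows.
Exact ties in ranking PCs by median r resolve to the lower PC rank (stable
sort).

## Conditioning as one orthogonal projection

Detrending and bandpassing are implemented jointly: each voxel row is
replaced by its least-squares residual against Legendre polynomials of
degree 0..3 (on the frame index mapped to [−1, 1]) together with
sine/cosine regressors at every discrete Fourier frequency outside the
passband (0.005–0.12 Hz; 0.008–0.15 Hz for rats; band edges inclusive).
Fitting both bases in a single projection avoids any order dependence
between detrending and filtering, produces no filter transient, and makes
two properties exact rather than approximate: idempotence (the operator is
a projection) and annihilation of anything in the removed span. The QR
factorization of the regressor matrix is cached per (n_frames, TR, band,
order), so repeated runs with a common geometry share it.

All standard deviations in the package — tSNR, z-scoring, ROI amplitude —
use the population convention (denominator *n*) for mutual consistency.
Voxels with zero temporal variance get tSNR +inf and are excluded as
"constant"; non-finite input voxels are zeroed, flagged and likewise
excluded. The tSNR floor omits voxels *strictly below* 15; a voxel at
exactly 15 is retained. Voxel enumeration is C-scan order over ascending
(x, y, z), making every selection deterministic.

Optional Gaussian smoothing (FWHM in mm, converted per axis to voxel units
via the affine) uses constant-zero padding at the volume boundary; when a
mask is supplied the smoothed data are renormalized by the smoothed mask so
in-mask voxels average only in-mask neighbors. Zero padding was chosen over
reflective modes because masked fMRI data have no meaningful values outside
the brain; the renormalization removes the resulting edge attenuation
inside the mask.

## EEG segmentation and the hemodynamic model

For each fMRI frame, the EEG segment of 6 s centred on the volume's
acquisition time is Hann-windowed and its PSD (Welch with that single
window, density scaling) integrated over 0.5–8 Hz by the trapezoid rule;
frames below 100 µV² are suppressions (0), the rest bursts (1). The
envelope is frame-locked — one state per volume — because the downstream
comparison target (a PC) is frame-locked too. EEG/scan alignment is taken
from the trace's `t0`; correcting misalignment is the caller's
responsibility.

The hemodynamic response function is the widely used double-gamma form
`g(t; 6, 1) − (1/6)·g(t; 16, 1)` (gamma densities; peak near 5 s,
undershoot near 15 s), sampled at the frame rate and scaled to peak 1. The
literature's "canonical" parameterization varies slightly between software
packages, so every parameter is exposed in `HrfParams`. The kernel can be
evaluated with a continuous-time delay, so fractional-frame hemodynamic
lags are represented exactly in the phantom.

Before convolution the envelope is extended backwards in time with its
first observed state for one kernel length: the subject's pre-scan state is
assumed to continue the first observed state. This removes the spurious
onset transient a zero-padded convolution would inject into every model —
in particular, a constant envelope maps to an exactly constant convolution,
which the DC-removing bandpass then annihilates exactly. The convolution
output passes through the same spectral projection used for fMRI
conditioning (degree-0 detrend + bandpass), so model and data live in the
same subspace.

Lagged correlation uses integer multiples of TR only (the PC has no
sub-frame information), overlapping segments without padding (n − |k|
points at lag k), a default search range of ±30 s, and smallest-|lag|
tie-breaking. The maximum over lags necessarily bounds the zero-lag value
from above.

## Maps and ROI metrics

Single-run maps are Pearson correlation maps with Fisher-Z scores
`atanh(r)·√(n−3)`, capped at |Z| = 40 so perfect correlations stay finite;
voxels outside the retained set are NaN. This replaces a prewhitened GLM
deliberately: for a single regressor, OLS correlation and GLM t are
monotonically equivalent, and group-level permutation inference is outside
this package's scope.

Map-to-map similarity is the mean over masked voxels of the local Pearson
correlation in a cubic neighborhood of half-width 4 voxels (clipped at
edges; neighborhoods with fewer than 5 valid voxels or zero variance are
skipped). The radius is configurable since comparison tools differ in their
window conventions; numerical identity with any external tool's metric is
not claimed.

ROI series are the spatial mean over mask voxels converted to
percent-signal-change about the temporal mean. Spectral summaries use
Welch's method with 100-timepoint Hann segments and 50-point overlap;
band-integrated log10 PSD is reported for 0.005–0.05 Hz and 0.05–0.12 Hz,
with near-zero bins (power < 1e-300) excluded from the log and counted in a
diagnostics field.

## The synthetic phantom

The phantom is the forward model run in reverse, and its defaults define
the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| grid | 10×10×10 | cortex = central 8×8×8 box (512 voxels) |
| n_frames / TR | 300 / 2 s | a 10-minute run |
| burst_dur_s / supp_dur_s | 15 ± 5 s each | human-like timescale, ~50% suppression |
| engaged_fraction | 0.6 | fraction of cortex carrying the response |
| amplitude_pct | 1.0 | response SD, % of the 100-unit baseline |
| noise_sd_pct | 1.0 | white-noise SD, % of baseline (SNR 1 per voxel) |
| drift_order / drift_pct | 3 / 1.0 | random Legendre drift per voxel |
| hemo_lag_s | 0 | injected hemodynamic delay |

The envelope is an alternating renewal process with uniformly jittered
epoch durations quantized to frames — the simplest process with
controllable mean durations. Engaged voxels carry the standardized
HRF-convolved envelope at `amplitude_pct`; non-engaged voxels carry noise
of the same SD. Noise is temporally white at the voxel level; the bandpass
step imposes realistic smoothness downstream. All randomness flows from one
seed through named sub-streams (envelope, engagement mask, noise, drift,
EEG), so outputs are bitwise reproducible on one platform given the config.

The matched EEG is unit-variance Gaussian noise spectrally confined to
0.5–8 Hz, amplitude-modulated so integrated band power is 300 µV² in bursts
and 20 µV² in suppressions, with 0.5 s raised-cosine cross-fades at
transitions and a 3 s pre/post pad so edge analysis windows are covered.

What the phantom does **not** emulate: motion, physiological
(cardiac/respiratory) noise, spatial autocorrelation of noise, multi-coil
or Rician noise statistics, susceptibility dropout, vascular territories or
balloon-model nonlinearity. Passing the phantom tests therefore shows that
the algorithmic chain is correct and self-consistent at realistic SNR — not
that the thresholds are optimal for any particular scanner or species.

## Numerical choices and degenerate inputs

- Band edges are inclusive in the passband; a band reaching Nyquist is a
  configuration error.
- Correlation vectors are clipped to [−1, 1] against rounding before
  histogramming; the 50-bin histogram over [−1, 1] is right-inclusive on
  the last bin only, so r = 1 is counted.
- Rank-deficient matrices return the available PCs with a warning rather
  than failing.
- Empty voxel selections, constant rows/regressors/series, ROI means ≤ 0
  and unresolvable EEG bands raise typed errors that the CLI maps to exit
  codes (2 input, 3 degenerate data, 4 configuration).
- Problem sizes in the test and acceptance suites (512-voxel cortex, 300
  frames, 100 phantom replicates) were chosen so the whole chain — ~500
  full pipeline executions — completes in well under a minute while leaving
  detection and false-positive rates statistically meaningful.

## Known limitations

- Thresholds are heuristics inherited from specific datasets; new
  anesthetics, species or acquisition protocols need their own calibration.
- Single-run maps are correlation maps, not prewhitened GLM estimates;
  autocorrelated noise inflates |Z| somewhat, uniformly across voxels.
- The EEG segmentation assumes a single artifact-free channel; gradient and
  ballistocardiogram denoising must happen upstream.
- The lag estimate is quantized to the TR; sub-frame lags bias toward the
  nearest frame.
- Runs in near-constant suppression with a single short burst produce no
  asymmetric PC (the fluctuation is not quasi-periodic within the band) and
  are reported as not-detected — a real limitation of the statistic, not a
  bug.
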