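# bsdetect

Detection and mapping of anesthesia-induced **burst-suppression** directly
from BOLD fMRI, without concurrent EEG.

During deep anesthesia the brain's electrical activity alternates between
high-amplitude bursts and quasi-isoelectric suppressions. Through
neurovascular coupling this bistable alternation leaves a hemodynamic
footprint: a slow, near-global fluctuation of the cortical BOLD signal.
`bsdetect` identifies that footprint with a simple, data-driven statistic
and is aimed at animal-fMRI and clinical researchers who need to know
whether a run was acquired during burst-suppression — and which voxels took
part — when no EEG was recorded.

## The method

Given a preprocessed 4D run and a cortical mask:

1. **Voxel selection** — drop voxels with temporal SNR below 15, keep
   cortical voxels, reshape to a voxel × frame matrix.
2. **Conditioning** — remove polynomial trends (degree ≤ 3) and bandpass to
   0.005–0.12 Hz (0.008–0.15 Hz for rats) in one exact spectral projection;
   z-score each voxel row.
3. **Carpet + PCA** — order rows by correlation with the mean cortical
   signal (the carpet plot), then take the first five temporal principal
   components by SVD.
4. **Asymmetry score** — correlate each PC with every retained voxel
   (Pearson *r*, sign-fixed so the median is non-negative). The median
   cortex-wide *r* measures how *asymmetric* the PC's correlation histogram
   is: a symmetric, zero-centred histogram is ordinary structured noise,
   while a histogram shifted toward +1 marks a component that the whole
   cortex follows.
5. **Classification** — a run is burst-suppression when its top median *r*
   exceeds a species threshold (human 0.45, macaque 0.15, marmoset 0.22,
   rat 0.20); for rats, runs whose second PC comes within *r* = 0.15 of the
   top one are excluded as ambiguous.

When EEG **is** available, the package also derives the classical
hemodynamic reference: frames whose 0.5–8 Hz EEG power (6 s Hann window
centred on each volume) falls below 100 µV² are labelled suppressions, the
resulting boxcar is convolved with a two-gamma HRF and bandpassed, and the
model is cross-correlated with the detected PC to quantify agreement and
hemodynamic lag. Voxelwise correlation/Fisher-Z maps, neighborhood
cross-correlation between maps, and ROI amplitude/spectral metrics complete
the toolbox. A ground-truthed synthetic phantom generator (BOLD + matched
EEG) makes the whole chain testable without any data download.

## Worked example

```python
import bsdetect as bs

# a seeded phantom: 300 frames at TR 2 s, 60% of cortex engaged,
# response amplitude = noise SD = 1% of baseline, hemodynamic lag 4 s
cfg = bs.PhantomConfig(seed=1, hemo_lag_s=4.0)
run, truth = bs.simulate_bold(cfg)

res = bs.detect_run(run, truth.cortex_mask, species="human")
print(res.decision.is_burst_suppression)   # True
print(round(res.pcs[0].median_r, 3))       # 0.805

trace = bs.simulate_eeg(truth.envelope, seed=1)
_, env, model, xc = bs.validate_against_eeg(
    run, truth.cortex_mask, trace, species="human")
print(round(xc.r_zero_lag, 3), round(xc.r_max, 3), xc.lag_at_max)
# 0.653 0.997 4.0
```

The first PC correlates with the median cortical voxel at *r* = 0.81 — far
above the strictest (human) threshold — so the run is flagged as
burst-suppression. Against the EEG-derived model the PC reaches *r* = 0.997
at a lag of 4.0 s: the cross-correlation recovers the injected hemodynamic
delay exactly, while the zero-lag correlation (0.65) shows what is lost by
ignoring the lag.

The same pipelines are scriptable from the shell:

```bash
bsdetect simulate --seed 1 -o phantom.nii.gz --truth truth.json --eeg eeg.csv
bsdetect detect phantom.nii.gz --mask phantom_cortex.nii.gz \
    --species human --tr-override 2.0
bsdetect validate phantom.nii.gz --mask phantom_cortex.nii.gz --eeg eeg.csv \
    --species human
```

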