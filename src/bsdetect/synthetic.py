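"""Ground-truthed burst-suppression phantoms: BOLD volumes plus matched EEG.

The phantom is the forward model of the detector run in reverse. A binary
burst/suppression envelope (alternating renewal process with uniform
duration jitter) is convolved with the two-gamma HRF — optionally delayed by
a controllable hemodynamic lag — to produce the clean response. "Engaged"
cortex voxels carry that response at a configurable percent amplitude on top
of white noise and a random polynomial drift; non-engaged voxels carry the
same noise and drift without the response. A matched EEG trace is
band-limited (0.5-8 Hz) Gaussian noise whose integrated band power tracks
the envelope state, so the segmentation rule can recover the envelope.

All randomness derives from a single seed through named, deterministic
sub-streams (envelope, engagement mask, noise, drift, EEG), so every output
is reproducible from the config alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bold_io import BoldRun, VolumeMap
from .eeg import BurstEnvelope, EEGTrace, HrfParams, two_gamma_hrf
from .errors import ConfigError

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "simulate_envelope",
    "simulate_bold",
    "simulate_eeg",
]

_BASELINE = 100.0  # scanner-unit baseline intensity

# named sub-stream indices off the root seed
_STREAMS = {"envelope": 0, "mask": 1, "noise": 2, "drift": 3, "eeg": 4}


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one phantom run.

    Defaults emulate a human-timescale burst-suppression run: 300 frames at
    TR 2 s (10 min), epochs averaging 15 s per state (suppression roughly
    half the time), 60% of cortex engaged, and response amplitude equal to
    the voxel noise SD (1% of baseline each, i.e. SNR 1 per voxel).
    """

    grid: tuple[int, int, int] = (10, 10, 10)
    n_frames: int = 300
    tr: float = 2.0
    burst_dur_s: tuple[float, float] = (15.0, 5.0)  # (mean, jitter)
    supp_dur_s: tuple[float, float] = (15.0, 5.0)
    engaged_fraction: float = 0.6
    amplitude_pct: float = 1.0
    noise_sd_pct: float = 1.0
    drift_order: int = 3
    drift_pct: float = 1.0  # SD of each random drift coefficient, % of baseline
    hemo_lag_s: float = 0.0
    hrf_params: HrfParams = field(default_factory=HrfParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.engaged_fraction <= 1:
            raise ConfigError("engaged_fraction must be in [0, 1]")
        for mean, _ in (self.burst_dur_s, self.supp_dur_s):
            if mean < 2 * self.tr:
                raise ConfigError("mean epoch durations must be >= 2 * tr")
        if self.n_frames < 2 or self.tr <= 0:
            raise ConfigError("n_frames >= 2 and tr > 0 required")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a simulated run."""

    envelope: BurstEnvelope
    engaged_mask: VolumeMap
    cortex_mask: VolumeMap
    clean_signal: np.ndarray  # frame-length, zero mean, unit SD
    lag_s: float


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[_STREAMS[stream]])


def simulate_envelope(cfg: PhantomConfig) -> BurstEnvelope:
    """Alternating burst/suppression epochs with uniform duration jitter.

    Epoch durations are drawn uniformly from ``mean +/- jitter`` (per state),
    quantized to whole frames (minimum one); the starting state is random.
    Fully reproducible from ``cfg.seed``.
    """
    rng = _rng(cfg.seed, "envelope")
    state = int(rng.integers(2))
    states: list[int] = []
    while len(states) < cfg.n_frames:
        mean, jitter = cfg.burst_dur_s if state == 1 else cfg.supp_dur_s
        dur = rng.uniform(mean - jitter, mean + jitter)
        n = max(1, int(round(dur / cfg.tr)))
        states.extend([state] * n)
        state = 1 - state
    return BurstEnvelope(states=np.array(states[: cfg.n_frames]), tr=cfg.tr)


def _cortex_box(grid: tuple[int, int, int]) -> np.ndarray:
    """Central box mask: one-voxel border stripped on every axis (where possible)."""
    mask = np.zeros(grid, dtype=bool)
    sl = tuple(slice(1, s - 1) if s > 2 else slice(None) for s in grid)
    mask[sl] = True
    return mask


def clean_response(cfg: PhantomConfig, envelope: BurstEnvelope) -> np.ndarray:
    """Envelope convolved with the (lagged) HRF, standardized to zero mean/unit SD."""
    kernel = two_gamma_hrf(cfg.tr, params=cfg.hrf_params, lag_s=cfg.hemo_lag_s)
    states = envelope.states.astype(float)
    # continue the first observed state backwards so the run starts in
    # hemodynamic steady state (same convention as envelope_to_model)
    pad = np.full(len(kernel) - 1, states[0])
    conv = np.convolve(np.concatenate([pad, states]), kernel)[
        len(pad) : len(pad) + cfg.n_frames
    ]
    sd = conv.std()
    if sd == 0:
        return np.zeros(cfg.n_frames)
    return (conv - conv.mean()) / sd


def simulate_bold(cfg: PhantomConfig) -> tuple[BoldRun, PhantomTruth]:
    """Generate a phantom BOLD run and its ground truth.

    Cortex is the central box of the grid; a random ``engaged_fraction`` of
    its voxels carry the clean hemodynamic response at ``amplitude_pct`` of
    baseline, on top of iid Gaussian noise (``noise_sd_pct`` of baseline,
    matched in engaged and non-engaged voxels) and a per-voxel random
    Legendre drift of degree ``drift_order``.
    """
    envelope = simulate_envelope(cfg)
    clean = clean_response(cfg, envelope)

    cortex = _cortex_box(cfg.grid)
    cortex_idx = np.argwhere(cortex)
    n_engaged = int(round(cfg.engaged_fraction * len(cortex_idx)))
    pick = _rng(cfg.seed, "mask").choice(len(cortex_idx), size=n_engaged, replace=False)
    engaged = np.zeros(cfg.grid, dtype=bool)
    engaged[tuple(cortex_idx[np.sort(pick)].T)] = True

    n_vox = int(np.prod(cfg.grid))
    noise = _rng(cfg.seed, "noise").standard_normal((n_vox, cfg.n_frames))
    rel = 1.0 + (cfg.noise_sd_pct / 100.0) * noise
    rel = rel.reshape(cfg.grid + (cfg.n_frames,))
    rel[engaged] += (cfg.amplitude_pct / 100.0) * clean

    data = _BASELINE * rel
    if cfg.drift_order > 0:
        x = np.linspace(-1.0, 1.0, cfg.n_frames)
        basis = np.polynomial.legendre.legvander(x, cfg.drift_order)[:, 1:]  # skip DC
        coef = _rng(cfg.seed, "drift").standard_normal((n_vox, cfg.drift_order))
        drift = (coef @ basis.T) * (_BASELINE * cfg.drift_pct / 100.0)
        data += drift.reshape(cfg.grid + (cfg.n_frames,))

    run = BoldRun(data=data, tr=cfg.tr, affine=np.eye(4))
    truth = PhantomTruth(
        envelope=envelope,
        engaged_mask=VolumeMap(engaged.astype(float), label="mask"),
        cortex_mask=VolumeMap(cortex.astype(float), label="mask"),
        clean_signal=clean,
        lag_s=cfg.hemo_lag_s,
    )
    return run, truth


def simulate_eeg(
    envelope: BurstEnvelope,
    fs: float = 256.0,
    burst_power_uv2: float = 300.0,
    supp_power_uv2: float = 20.0,
    seed: int = 0,
    pad_s: float = 3.0,
    crossfade_s: float = 0.5,
) -> EEGTrace:
    """Amplitude-modulated band-limited EEG whose band power tracks the envelope.

    The carrier is Gaussian noise spectrally confined to 0.5-8 Hz and
    normalized to unit variance, so its integrated band power equals its
    variance. Each sample is scaled by the square root of the target power of
    the frame it falls in (burst vs suppression), with a ``crossfade_s``
    raised-cosine smoothing of the gain at epoch transitions. The trace
    starts ``pad_s`` seconds before the first volume (``t0 = -pad_s``) so
    that edge analysis windows are covered.
    """
    if fs < 64:
        raise ConfigError("EEG simulation requires fs >= 64 Hz")
    n_frames = envelope.n_frames
    if n_frames == 0:
        return EEGTrace(samples=np.empty(0), fs=fs, t0=0.0)
    tr = envelope.tr
    duration = n_frames * tr + 2 * pad_s
    n_samp = int(round(duration * fs))
    rng = _rng(seed, "eeg")

    white = rng.standard_normal(n_samp)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    spectrum[(freqs < 0.5) | (freqs > 8.0)] = 0.0
    carrier = np.fft.irfft(spectrum, n=n_samp)
    carrier /= carrier.std()

    t = np.arange(n_samp) / fs - pad_s
    frame = np.clip(np.round(t / tr).astype(int), 0, n_frames - 1)
    power = np.where(envelope.states[frame] == 1, burst_power_uv2, supp_power_uv2)
    gain = np.sqrt(power.astype(float))
    n_fade = max(1, int(round(crossfade_s * fs)))
    hann = np.hanning(2 * n_fade + 1)
    gain = np.convolve(gain, hann / hann.sum(), mode="same")

    return EEGTrace(samples=carrier * gain, fs=fs, t0=-pad_s)
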