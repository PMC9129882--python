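"""EEG segmentation, hemodynamic modelling and lag analysis.

Burst/suppression epochs are read off a single EEG channel by thresholding
band power: for every fMRI frame, the power spectral density of a 6 s
Hann-windowed EEG segment centered on that frame is integrated over
0.5-8 Hz; frames below 100 uV^2 are suppressions (0), the rest bursts (1).
The resulting boxcar envelope, convolved with a two-gamma hemodynamic
response function and passed through the same bandpass used for fMRI
preprocessing, yields the hemodynamic model that an asymmetric PC should
follow — up to an anesthesia-dependent lag recovered by cross-correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from . import bold_io
from .bold_io import TimeSeriesMatrix, VoxelSet
from .errors import ConfigError, ConstantSeriesError, DegenerateDataError, SamplingError

logger = logging.getLogger(__name__)

__all__ = [
    "EEGTrace",
    "BurstEnvelope",
    "HrfParams",
    "HemodynamicModel",
    "CrossCorrResult",
    "segment_eeg",
    "two_gamma_hrf",
    "envelope_to_model",
    "crosscorrelate",
]

#: defaults of the EEG segmentation rule
DEFAULT_WINDOW_S = 6.0
DEFAULT_EEG_BAND = (0.5, 8.0)
DEFAULT_POWER_THRESHOLD_UV2 = 100.0


@dataclass
class EEGTrace:
    """A single-channel EEG recording in microvolts.

    ``t0`` is the time of the first sample relative to the first fMRI
    volume (seconds); negative values mean the EEG starts before the scan.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float).ravel()


@dataclass
class BurstEnvelope:
    """Per-frame burst(1)/suppression(0) states at the fMRI frame rate."""

    states: np.ndarray
    tr: float
    band_powers: np.ndarray | None = None  # integrated band power per frame, uV^2

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int).ravel()

    @property
    def n_frames(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class HrfParams:
    """Two-gamma HRF kernel parameters.

    The kernel is ``g(t; peak_delay/peak_disp, peak_disp) -
    undershoot_ratio * g(t; under_delay/under_disp, under_disp)`` with
    gamma-density ``g``; the defaults place the peak near 5 s and the
    undershoot near 15 s and are all exposed so alternates are one config
    away.
    """

    peak_delay: float = 6.0  # s, mean of the positive lobe
    peak_disp: float = 1.0  # s, scale of the positive lobe
    under_delay: float = 16.0  # s, mean of the undershoot
    under_disp: float = 1.0  # s, scale of the undershoot
    under_ratio: float = 1.0 / 6.0  # undershoot amplitude relative to peak lobe


DEFAULT_HRF = HrfParams()


@dataclass
class HemodynamicModel:
    """Frame-rate hemodynamic prediction derived from a burst envelope."""

    timeseries: np.ndarray
    tr: float
    band: tuple[float, float]
    hrf_params: HrfParams = field(default_factory=HrfParams)


@dataclass
class CrossCorrResult:
    """Lagged-correlation summary between a model and a PC.

    A positive ``lag_at_max`` means the second series is delayed relative to
    the first.
    """

    r_zero_lag: float
    r_max: float
    lag_at_max: float  # seconds


def segment_eeg(
    eeg: EEGTrace,
    n_frames: int,
    tr: float,
    window_s: float = DEFAULT_WINDOW_S,
    band: tuple[float, float] = DEFAULT_EEG_BAND,
    power_threshold: float = DEFAULT_POWER_THRESHOLD_UV2,
) -> BurstEnvelope:
    """Threshold per-frame EEG band power into a burst/suppression envelope.

    For frame ``k`` the EEG segment of length ``window_s`` centered at time
    ``k * tr`` is Hann-windowed, its PSD estimated (Welch with that single
    window, density scaling) and integrated over ``band`` by the trapezoid
    rule. Frames with integrated power below ``power_threshold`` (uV^2) are
    suppressions. Windows reaching past the recording edges are clipped,
    with a logged warning.
    """
    if eeg.fs < 2 * band[1]:
        raise SamplingError(
            f"fs={eeg.fs} Hz cannot resolve the {band[1]} Hz band edge"
        )
    half = window_s / 2.0
    n_samples = len(eeg.samples)
    if n_samples < int(round(window_s * eeg.fs)) // 2:
        raise DegenerateDataError("EEG shorter than one analysis window")
    clipped = 0
    powers = np.empty(n_frames)
    for k in range(n_frames):
        t = k * tr
        i0 = int(round((t - half - eeg.t0) * eeg.fs))
        i1 = int(round((t + half - eeg.t0) * eeg.fs))
        if i0 < 0 or i1 > n_samples:
            clipped += 1
            i0, i1 = max(i0, 0), min(i1, n_samples)
        seg = eeg.samples[i0:i1]
        if len(seg) < 8:
            powers[k] = 0.0
            continue
        freqs, psd = signal.welch(
            seg,
            fs=eeg.fs,
            window="hann",
            nperseg=len(seg),
            noverlap=0,
            scaling="density",
            detrend="constant",
        )
        sel = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
        powers[k] = float(np.trapezoid(psd[sel], freqs[sel]))
    if clipped:
        logger.warning("%d EEG analysis windows clipped at recording edges", clipped)
    states = (powers >= power_threshold).astype(int)
    return BurstEnvelope(states=states, tr=tr, band_powers=powers)


def two_gamma_hrf(
    tr: float,
    duration_s: float = 32.0,
    params: HrfParams = DEFAULT_HRF,
    lag_s: float = 0.0,
) -> np.ndarray:
    """Sample the canonical two-gamma HRF at the frame rate, peak scaled to 1.

    ``lag_s`` delays the whole kernel (evaluated in continuous time, so
    fractional-frame lags are exact); the kernel is causal: it is zero for
    ``t < lag_s``.
    """
    if not tr > 0:
        raise ConfigError("tr must be positive")
    t = np.arange(0.0, duration_s + lag_s + tr / 2, tr) - lag_s
    p = params
    h = stats.gamma.pdf(t, p.peak_delay / p.peak_disp, scale=p.peak_disp)
    if p.under_ratio != 0:
        h = h - p.under_ratio * stats.gamma.pdf(
            t, p.under_delay / p.under_disp, scale=p.under_disp
        )
    h[t < 0] = 0.0
    peak = np.max(h)
    if peak <= 0:
        raise ConfigError("HRF kernel has non-positive peak; check parameters")
    return h / peak


def envelope_to_model(
    envelope: BurstEnvelope,
    band: tuple[float, float] = (0.005, 0.12),
    hrf_params: HrfParams = DEFAULT_HRF,
    lag_s: float = 0.0,
) -> HemodynamicModel:
    """Convolve a burst envelope with the HRF and bandpass the result.

    The envelope is treated as frame-rate samples. Before the causal linear
    convolution, the envelope is extended backwards in time with its initial
    state for one kernel length (the pre-scan state is assumed to continue
    the first observed state), which removes the spurious onset transient —
    in particular, a constant envelope maps to an exactly constant
    convolution. The result is truncated to the frame grid and passed
    through the same spectral projection used for fMRI preprocessing
    (degree-0 detrend + bandpass), so the output is zero-mean with spectrum
    confined to ``band``.
    """
    n = envelope.n_frames
    if n < 10:
        raise DegenerateDataError("envelope_to_model needs >= 10 frames")
    kernel = two_gamma_hrf(envelope.tr, params=hrf_params, lag_s=lag_s)
    states = envelope.states.astype(float)
    pad = np.full(len(kernel) - 1, states[0])
    conv = np.convolve(np.concatenate([pad, states]), kernel)[len(pad) : len(pad) + n]
    filtered = _bandpass_vector(conv, envelope.tr, band)
    return HemodynamicModel(
        timeseries=filtered, tr=envelope.tr, band=band, hrf_params=hrf_params
    )


def _bandpass_vector(x: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Apply the shared detrend+bandpass projection to a single series."""
    dummy = VoxelSet(indices=np.zeros((1, 3), dtype=int), shape=(1, 1, 1))
    mat = TimeSeriesMatrix(values=x[None, :].astype(float), voxel_index=dummy, tr=tr)
    return bold_io.detrend_and_bandpass(mat, poly_order=0, band=band).values[0]


def crosscorrelate(
    model: HemodynamicModel | np.ndarray,
    pc: np.ndarray,
    tr: float | None = None,
    max_lag_s: float = 30.0,
) -> CrossCorrResult:
    """Lagged Pearson correlation between a model and a PC time series.

    For integer lags ``k`` with ``|k * tr| <= max_lag_s``, the correlation is
    computed over the overlapping segments ``model[:n-k]`` and ``pc[k:]``
    (positive ``k`` = PC delayed relative to the model; no padding). Returns
    the correlation at zero lag, the maximum, and the lag at the maximum in
    seconds; exact ties go to the smallest ``|lag|``.
    """
    if isinstance(model, HemodynamicModel):
        x = np.asarray(model.timeseries, dtype=float)
        tr = model.tr if tr is None else tr
    else:
        x = np.asarray(model, dtype=float)
        if tr is None:
            raise ConfigError("tr is required when the model is a bare array")
    y = np.asarray(pc, dtype=float)
    if len(x) != len(y):
        raise ConfigError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if not max_lag_s < n * tr / 2:
        raise ConfigError("max_lag_s must be below half the run duration")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError("cross-correlation of a constant series is undefined")
    max_k = int(np.floor(max_lag_s / tr))
    r_zero = np.nan
    r_max = -np.inf
    best_k = 0
    # visit lags by increasing |k| so the smallest |lag| wins exact ties
    for k in sorted(range(-max_k, max_k + 1), key=lambda k: (abs(k), k)):
        if k >= 0:
            a, b = x[: n - k] if k else x, y[k:]
        else:
            a, b = x[-k:], y[: n + k]
        if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if k == 0:
            r_zero = r
        if r > r_max:
            r_max = r
            best_k = k
    return CrossCorrResult(r_zero_lag=r_zero, r_max=r_max, lag_at_max=best_k * tr)
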