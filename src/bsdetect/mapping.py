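"""Voxelwise regressor maps, map comparison, and ROI amplitude/spectral metrics.

Single-run maps are correlation maps: each voxel's time series is correlated
with a regressor (asymmetric PC, EEG-derived model, or ROI seed) and the
Pearson r is Fisher-transformed and scaled by ``sqrt(n - 3)`` into an
approximate Z score. This is a deliberate simplification of a prewhitened
GLM: for a single regressor the two are monotonically equivalent, and the
group-level permutation machinery is out of scope here.

Two maps are compared with a neighborhood cross-correlation: the mean over
masked voxels of the local Pearson correlation computed in a cubic window
around each voxel.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .bold_io import BoldRun, TimeSeriesMatrix, VolumeMap
from .carpet import _rows_vs_vector_r
from .errors import ConfigError, ConstantSeriesError, DegenerateDataError

__all__ = [
    "StatMap",
    "RoiSeries",
    "RoiMetrics",
    "FISHER_Z_CAP",
    "voxelwise_regression",
    "neighborhood_cross_correlation",
    "roi_signal",
    "roi_metrics",
    "minmax_scale",
]

#: |z| cap keeping Fisher-transformed volumes finite at |r| = 1
FISHER_Z_CAP = 40.0

DEFAULT_PSD_BANDS = {"low": (0.005, 0.05), "high": (0.05, 0.12)}


class StatMap:
    """Voxelwise correlation (r) and Fisher-Z volumes for one regressor."""

    def __init__(
        self,
        r: VolumeMap,
        z: VolumeMap,
        regressor_name: str,
        n_frames: int,
        voxel_r: np.ndarray,
    ) -> None:
        self.r = r
        self.z = z
        self.regressor_name = regressor_name
        self.n_frames = n_frames
        #: flat per-voxel r in the voxel-set order (convenience for tests/IO)
        self.voxel_r = voxel_r


class RoiSeries:
    """Mean ROI BOLD time series in percent-signal-change units (zero mean)."""

    def __init__(self, timeseries: np.ndarray, roi_name: str, tr: float) -> None:
        self.timeseries = np.asarray(timeseries, dtype=float)
        self.roi_name = roi_name
        self.tr = tr


class RoiMetrics:
    """Amplitude (SD) and Welch-PSD summaries of one ROI series."""

    def __init__(
        self,
        sd: float,
        frequencies: np.ndarray,
        psd: np.ndarray,
        band_logpsd: dict[str, float],
        excluded_bins: dict[str, int],
    ) -> None:
        self.sd = sd
        self.frequencies = frequencies
        self.psd = psd
        self.band_logpsd = band_logpsd
        #: per band, number of near-zero PSD bins excluded from log10 integration
        self.excluded_bins = excluded_bins


def voxelwise_regression(
    matrix: TimeSeriesMatrix, regressor: np.ndarray, regressor_name: str = "regressor"
) -> StatMap:
    """Correlate every retained voxel with a regressor and Fisher-transform.

    ``z = atanh(r) * sqrt(n_frames - 3)``, capped at |z| = 40 so perfect
    correlations stay finite. Voxels outside the voxel set are NaN in both
    output volumes.
    """
    reg = np.asarray(regressor, dtype=float).ravel()
    if len(reg) != matrix.n_frames:
        raise ConfigError(
            f"regressor length {len(reg)} != n_frames {matrix.n_frames}"
        )
    if np.ptp(reg) == 0:
        raise ConstantSeriesError("constant regressor")
    r = _rows_vs_vector_r(matrix.values, reg)
    with np.errstate(divide="ignore"):
        z = np.arctanh(r) * np.sqrt(max(matrix.n_frames - 3, 1))
    z = np.clip(z, -FISHER_Z_CAP, FISHER_Z_CAP)
    shape = matrix.voxel_index.shape
    r_vol = np.full(shape, np.nan)
    z_vol = np.full(shape, np.nan)
    idx = matrix.voxel_index.as_tuple()
    r_vol[idx] = r
    z_vol[idx] = z
    return StatMap(
        r=VolumeMap(r_vol, label="r"),
        z=VolumeMap(z_vol, label="Z"),
        regressor_name=regressor_name,
        n_frames=matrix.n_frames,
        voxel_r=r,
    )


def neighborhood_cross_correlation(
    map_a: VolumeMap,
    map_b: VolumeMap,
    mask: VolumeMap,
    radius_vox: int = 4,
) -> float:
    """Mean local Pearson correlation between two maps within a mask.

    For every masked voxel, the two maps are correlated over the cubic
    neighborhood of half-width ``radius_vox`` (clipped at the volume edges),
    using masked, finite voxels only. Neighborhoods with fewer than 5 valid
    voxels or zero variance in either map are skipped; the returned value is
    the mean over contributing voxels.
    """
    a, b, m = map_a.values, map_b.values, mask.values
    if a.shape != b.shape or a.shape != m.shape:
        raise ConfigError("maps and mask must share one grid")
    valid = (m > 0) & np.isfinite(a) & np.isfinite(b)
    if not valid.any():
        raise DegenerateDataError("mask selects no finite voxels")
    centers = np.argwhere(m > 0)
    total = 0.0
    count = 0
    shape = a.shape
    for x, y, z in centers:
        sl = tuple(
            slice(max(c - radius_vox, 0), min(c + radius_vox + 1, s))
            for c, s in zip((x, y, z), shape)
        )
        v = valid[sl]
        if int(v.sum()) < 5:
            continue
        av = a[sl][v]
        bv = b[sl][v]
        sa = av.std()
        sb = bv.std()
        if sa == 0 or sb == 0:
            continue
        total += float(np.mean((av - av.mean()) * (bv - bv.mean())) / (sa * sb))
        count += 1
    if count == 0:
        raise DegenerateDataError("no neighborhood had enough valid voxels")
    return total / count


def roi_signal(run: BoldRun, roi_mask: VolumeMap, roi_name: str = "roi") -> RoiSeries:
    """Mean ROI time series as percent-signal-change about the temporal mean."""
    if roi_mask.shape != run.spatial_shape:
        raise ConfigError("ROI mask grid does not match the run")
    sel = (roi_mask.values > 0) & ~run.nonfinite_mask
    if not sel.any():
        raise DegenerateDataError("ROI mask selects no usable voxels")
    ts = run.data[sel].mean(axis=0)
    mean_t = float(ts.mean())
    if mean_t <= 0:
        raise DegenerateDataError(
            f"ROI temporal mean {mean_t:g} <= 0; percent change undefined"
        )
    return RoiSeries(100.0 * (ts - mean_t) / mean_t, roi_name=roi_name, tr=run.tr)


def roi_metrics(
    series: RoiSeries,
    segment_len: int = 100,
    overlap: int = 50,
    bands: dict[str, tuple[float, float]] | None = None,
) -> RoiMetrics:
    """Amplitude (population SD) and Welch PSD of an ROI series.

    The PSD uses Hann windows of ``segment_len`` timepoints with ``overlap``
    overlapping points (density scaling). Band summaries integrate
    ``log10(PSD)`` over each band's frequency bins by the trapezoid rule;
    near-zero bins (power < 1e-300) are excluded and counted.
    """
    if bands is None:
        bands = DEFAULT_PSD_BANDS
    x = series.timeseries
    if len(x) < segment_len:
        raise DegenerateDataError(
            f"series length {len(x)} < segment length {segment_len}"
        )
    sd = float(x.std())  # population SD
    freqs, psd = signal.welch(
        x,
        fs=1.0 / series.tr,
        window="hann",
        nperseg=segment_len,
        noverlap=overlap,
        scaling="density",
    )
    band_logpsd: dict[str, float] = {}
    excluded: dict[str, int] = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
        ok = sel & (psd >= 1e-300)
        excluded[name] = int(sel.sum() - ok.sum())
        if int(ok.sum()) < 2:
            band_logpsd[name] = float("nan")
        else:
            band_logpsd[name] = float(np.trapezoid(np.log10(psd[ok]), freqs[ok]))
    return RoiMetrics(
        sd=sd,
        frequencies=freqs,
        psd=psd,
        band_logpsd=band_logpsd,
        excluded_bins=excluded,
    )


def minmax_scale(series: np.ndarray) -> np.ndarray:
    """Map a series linearly onto [0, 1] (min to 0, max to 1)."""
    x = np.asarray(series, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ConstantSeriesError("min-max scaling of a constant series is undefined")
    return (x - lo) / (hi - lo)
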