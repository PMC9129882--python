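"""Volumetric I/O and time-series conditioning for BOLD runs.

This module owns everything between a 4D NIfTI file on disk and the
voxel-by-frame matrix that the carpet/PCA detector consumes: loading with
repetition-time handling, temporal SNR computation, voxel selection
(cortical mask + tSNR floor), joint polynomial detrend + bandpass as a
single orthogonal projection, optional Gaussian smoothing, and row-wise
z-scoring.

Conventions used throughout:

* the frame axis is always the last (4th) axis of the volume;
* standard deviations are population SDs (denominator ``n``), so that tSNR,
  z-scores and ROI amplitudes are mutually consistent;
* voxel sets are enumerated in C order over ascending (x, y, z), which makes
  every selection step deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import nibabel as nib
import numpy as np
from numpy.polynomial import legendre
from scipy import ndimage

from .errors import (
    BandError,
    ConfigError,
    ConstantSeriesError,
    DimensionalityError,
    EmptySelectionError,
    MetadataError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BoldRun",
    "VolumeMap",
    "VoxelSet",
    "TimeSeriesMatrix",
    "load_bold",
    "save_volume",
    "compute_tsnr",
    "build_voxel_set",
    "extract_matrix",
    "detrend_and_bandpass",
    "smooth_gaussian",
    "zscore_rows",
]


@dataclass
class BoldRun:
    """A 4D BOLD acquisition: ``data[x, y, z, frame]`` plus timing/geometry.

    ``nonfinite_mask`` flags voxels whose series contained NaN/Inf on load;
    those values are zeroed in ``data`` and the voxels are excluded from any
    downstream :class:`VoxelSet`.
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray
    nonfinite_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise DimensionalityError(
                f"BoldRun requires 4D data, got {self.data.ndim}D"
            )
        if self.n_frames < 2:
            raise MetadataError("BoldRun requires at least 2 frames")
        if not self.tr > 0:
            raise MetadataError(f"repetition time must be positive, got {self.tr}")
        if self.nonfinite_mask is None:
            bad = ~np.isfinite(self.data).all(axis=-1)
            if bad.any():
                logger.warning(
                    "%d voxels contain non-finite values; zeroed and flagged",
                    int(bad.sum()),
                )
                self.data = np.where(bad[..., None], 0.0, self.data)
            self.nonfinite_mask = bad

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.asarray(nib.affines.voxel_sizes(self.affine), dtype=float)


@dataclass
class VolumeMap:
    """A 3D scalar map aligned to a run's spatial grid.

    ``label`` is a semantic tag (``tsnr``, ``mask``, ``r``, ``Z``...).
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise DimensionalityError(
                f"VolumeMap requires 3D values, got {self.values.ndim}D"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class VoxelSet:
    """An ordered, unique list of 3D voxel coordinates with provenance."""

    indices: np.ndarray  # (n, 3) int array, C-scan order
    shape: tuple[int, int, int]
    provenance: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.indices)

    def as_tuple(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Index tuple usable for fancy indexing into the parent grid."""
        return tuple(self.indices.T)


@dataclass
class TimeSeriesMatrix:
    """2D voxel-by-frame matrix carrying its voxel index map and TR."""

    values: np.ndarray  # (n_voxels, n_frames)
    voxel_index: VoxelSet
    tr: float

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise DimensionalityError("TimeSeriesMatrix values must be 2D")
        if len(self.voxel_index) != self.values.shape[0]:
            raise MetadataError(
                "row count does not match the voxel index "
                f"({self.values.shape[0]} vs {len(self.voxel_index)})"
            )

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def load_bold(path, tr_override: float | None = None) -> BoldRun:
    """Load a 4D NIfTI image into a :class:`BoldRun`.

    TR is read from the header (``pixdim[4]``) unless ``tr_override`` is
    given. Non-4D images raise :class:`DimensionalityError`; a non-positive
    header TR without an override raises :class:`MetadataError`.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise DimensionalityError(f"{path}: expected a 4D image, got {img.ndim}D")
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()
    tr = float(tr_override) if tr_override is not None else float(zooms[3])
    if not tr > 0:
        raise MetadataError(
            f"{path}: header TR is {zooms[3]!r}; pass tr_override to set it"
        )
    return BoldRun(data=data, tr=tr, affine=np.asarray(img.affine, dtype=float))


def load_mask(path, label: str = "mask") -> VolumeMap:
    """Load a 3D NIfTI volume as a mask/map (any numeric type accepted)."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D image, got {img.ndim}D")
    return VolumeMap(values=np.asarray(img.dataobj, dtype=np.float64), label=label)


def save_volume(values: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D or 4D array as NIfTI-1."""
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def compute_tsnr(run: BoldRun) -> VolumeMap:
    """Temporal signal-to-noise ratio: temporal mean / temporal SD per voxel.

    The SD is the population SD. Constant voxels (SD exactly zero) get
    tSNR ``+inf`` and are thereby flagged; voxel selection treats non-finite
    tSNR as "constant" and drops them.
    """
    mean = run.data.mean(axis=-1)
    sd = run.data.std(axis=-1)  # population SD (ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    tsnr = np.where(run.nonfinite_mask, np.inf, tsnr)
    return VolumeMap(values=tsnr, label="tsnr")


def build_voxel_set(
    run: BoldRun,
    cortical_mask: VolumeMap,
    tsnr: VolumeMap,
    tsnr_min: float = 15.0,
) -> VoxelSet:
    """Select analyzable voxels: in-mask, tSNR at or above the floor, non-constant.

    A voxel survives iff ``mask > 0`` and ``tsnr >= tsnr_min`` and it is not
    flagged constant/non-finite. The tSNR comparison keeps voxels exactly at
    the floor (only strictly-below values are omitted). Order is C-scan order
    over ascending (x, y, z), which is deterministic by construction.
    """
    shape = run.spatial_shape
    if cortical_mask.shape != shape or tsnr.shape != shape:
        raise DimensionalityError("mask/tsnr grids do not match the run")
    in_mask = cortical_mask.values > 0
    constant = ~np.isfinite(tsnr.values)
    keep = in_mask & ~constant & (tsnr.values >= tsnr_min)
    if not keep.any():
        if not in_mask.any():
            culprit = "the cortical mask is empty"
        elif not (in_mask & ~constant).any():
            culprit = "every masked voxel is constant or non-finite"
        else:
            culprit = f"every masked voxel has tSNR < {tsnr_min}"
        raise EmptySelectionError(f"no voxels survive selection: {culprit}")
    indices = np.argwhere(keep)  # C order: ascending (x, y, z)
    n_mask = int(in_mask.sum())
    logger.info(
        "voxel selection: %d in mask -> %d retained (tsnr_min=%g)",
        n_mask,
        len(indices),
        tsnr_min,
    )
    return VoxelSet(
        indices=indices,
        shape=shape,
        provenance=(
            f"mask>0 ({n_mask})",
            f"tsnr>={tsnr_min} & non-constant ({len(indices)})",
        ),
    )


def extract_matrix(run: BoldRun, voxels: VoxelSet) -> TimeSeriesMatrix:
    """Reshape the 4D run into a 2D (voxel x frame) matrix for the voxel set."""
    return TimeSeriesMatrix(
        values=run.data[voxels.as_tuple()].astype(np.float64, copy=True),
        voxel_index=voxels,
        tr=run.tr,
    )


@lru_cache(maxsize=8)
def _nuisance_basis(
    n_frames: int, tr: float, poly_order: int, low: float, high: float
) -> np.ndarray:
    """Orthonormal basis (Q of a QR) spanning the removed subspace.

    The removed subspace is the span of Legendre polynomials of degree
    0..poly_order (on frame index mapped to [-1, 1]) together with the
    discrete Fourier sine/cosine pairs at frequencies strictly outside
    [low, high]. Projecting data onto the orthogonal complement implements
    detrending and bandpassing jointly, with no order dependence and exact
    idempotence.
    """
    x = np.linspace(-1.0, 1.0, n_frames)
    cols = [legendre.legvander(x, poly_order)]
    t = np.arange(n_frames)
    for k in range(1, n_frames // 2 + 1):
        f = k / (n_frames * tr)
        # band edges are inclusive in the passband
        if low - 1e-12 <= f <= high + 1e-12:
            continue
        phase = 2.0 * np.pi * k * t / n_frames
        cos = np.cos(phase)[:, None]
        if 2 * k == n_frames:  # Nyquist bin has no sine partner
            cols.append(cos)
        else:
            cols.append(np.hstack([cos, np.sin(phase)[:, None]]))
    X = np.hstack(cols)
    q, r = np.linalg.qr(X)
    # drop numerically dependent columns
    keep = np.abs(np.diag(r)) > 1e-10 * np.abs(np.diag(r)).max()
    return np.ascontiguousarray(q[:, keep])


def detrend_and_bandpass(
    matrix: TimeSeriesMatrix,
    poly_order: int = 3,
    band: tuple[float, float] = (0.005, 0.12),
) -> TimeSeriesMatrix:
    """Remove polynomial trends and out-of-band Fourier components per row.

    Implemented as a single least-squares projection: each row is replaced by
    its residual against Legendre polynomials of degree 0..``poly_order``
    jointly with sine/cosine regressors at every discrete Fourier frequency
    outside ``band`` (edges inclusive in the passband). Being an orthogonal
    projection, the operation is idempotent, introduces no filter transient,
    and leaves every row with exactly zero mean.
    """
    low, high = band
    nyquist = 1.0 / (2.0 * matrix.tr)
    if not (0 <= low < high):
        raise BandError(f"invalid band {band}")
    if high >= nyquist:
        raise BandError(
            f"band high {high} Hz reaches the Nyquist frequency {nyquist} Hz"
        )
    q = _nuisance_basis(matrix.n_frames, float(matrix.tr), int(poly_order), low, high)
    vals = matrix.values
    out = vals - (vals @ q) @ q.T
    return TimeSeriesMatrix(values=out, voxel_index=matrix.voxel_index, tr=matrix.tr)


def smooth_gaussian(
    run: BoldRun, fwhm_mm: float, mask: VolumeMap | None = None
) -> BoldRun:
    """Per-frame 3D Gaussian smoothing with a kernel specified by FWHM in mm.

    Sigma per axis is ``fwhm / (2 * sqrt(2 ln 2))`` converted to voxel units
    via the affine. ``fwhm_mm = 0`` returns the input unchanged. Outside-mask
    (and outside-volume) values are treated as zero; when a mask is supplied
    the smoothed data are renormalized by the smoothed mask so that in-mask
    values are a weighted average of in-mask neighbors only.
    """
    if fwhm_mm < 0:
        raise ConfigError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return run
    sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / run.voxel_sizes
    data = run.data
    if mask is not None:
        m = (mask.values > 0).astype(np.float64)
        data = data * m[..., None]
        norm = ndimage.gaussian_filter(m, sigma=sigma_vox, mode="constant")
    out = np.empty_like(data)
    for f in range(run.n_frames):
        out[..., f] = ndimage.gaussian_filter(
            data[..., f], sigma=sigma_vox, mode="constant"
        )
    if mask is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where((norm > 1e-12)[..., None], out / norm[..., None], 0.0)
        out *= (mask.values > 0)[..., None]
    return BoldRun(
        data=out,
        tr=run.tr,
        affine=run.affine,
        nonfinite_mask=run.nonfinite_mask,
    )


def zscore_rows(matrix: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Normalize every row to zero mean and unit population SD."""
    vals = matrix.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population SD
    flat = sd[:, 0] <= 0
    if flat.any():
        raise ConstantSeriesError(
            f"{int(flat.sum())} constant rows cannot be z-scored; "
            "voxel selection should have removed them"
        )
    return TimeSeriesMatrix(
        values=(vals - mean) / sd, voxel_index=matrix.voxel_index, tr=matrix.tr
    )
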