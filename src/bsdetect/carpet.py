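"""Carpet-plot construction, temporal PCA and the asymmetric-PC classifier.

The detector rests on a simple observation: during burst-suppression the
whole cortex fluctuates together, so one temporal principal component of the
z-scored voxel-by-frame matrix correlates positively with almost every
voxel. The median of the cortex-wide Pearson correlations ("median r")
measures this asymmetry; a run is classified as burst-suppression when the
most asymmetric PC exceeds a species-specific threshold, optionally with an
exclusion rule for runs where a second PC is nearly as asymmetric.

Species presets (threshold on median r, exclusion gap, preprocessing band):

========  =========  =============  ================
species   threshold  exclusion gap  bandpass (Hz)
========  =========  =============  ================
human     0.45       --             0.005 - 0.12
macaque   0.15       --             0.005 - 0.12
marmoset  0.22       --             0.005 - 0.12
rat       0.20       0.15           0.008 - 0.15
========  =========  =============  ================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bold_io import TimeSeriesMatrix, VoxelSet
from .errors import ConfigError, DegenerateDataError

__all__ = [
    "CarpetMatrix",
    "PcProfile",
    "AsymmetryDecision",
    "SpeciesPreset",
    "SPECIES_PRESETS",
    "N_HISTOGRAM_BINS",
    "order_by_mean_correlation",
    "temporal_pca",
    "pc_voxel_correlations",
    "classify_run",
]

#: number of equal-width histogram bins over [-1, 1] for per-PC correlations
N_HISTOGRAM_BINS = 50


@dataclass(frozen=True)
class SpeciesPreset:
    """Detection constants for one species."""

    threshold: float
    exclusion_delta: float | None
    band: tuple[float, float]


SPECIES_PRESETS: dict[str, SpeciesPreset] = {
    "human": SpeciesPreset(0.45, None, (0.005, 0.12)),
    "macaque": SpeciesPreset(0.15, None, (0.005, 0.12)),
    "marmoset": SpeciesPreset(0.22, None, (0.005, 0.12)),
    "rat": SpeciesPreset(0.20, 0.15, (0.008, 0.15)),
}


@dataclass
class CarpetMatrix:
    """A z-scored voxel-by-frame matrix plus a display row ordering.

    The ordering is a view: ``values`` keeps the original storage order and
    ``display_order`` is the permutation that sorts rows for plotting.
    """

    values: np.ndarray
    voxel_index: VoxelSet
    display_order: np.ndarray
    tr: float

    def ordered_values(self) -> np.ndarray:
        return self.values[self.display_order]


@dataclass
class PcProfile:
    """One temporal principal component and its cortex-wide correlation profile.

    ``timeseries`` is the unit-norm right singular vector (sign-fixed so that
    ``median_r >= 0``); ``voxel_r`` holds its Pearson correlation with every
    retained voxel; ``histogram`` counts those correlations in 50 equal bins
    spanning [-1, 1].
    """

    index: int  # 1-based PC rank
    timeseries: np.ndarray
    explained_variance_ratio: float
    voxel_r: np.ndarray | None = None
    median_r: float | None = None
    histogram: np.ndarray | None = None
    sign_flipped: bool = False


@dataclass
class AsymmetryDecision:
    """Outcome of the asymmetric-PC classification for one run."""

    is_burst_suppression: bool
    selected_pc: int | None
    threshold_used: float
    second_pc_margin: float
    exclusion_applied: bool
    reason: str
    median_r_values: tuple[float, ...] = field(default_factory=tuple)


def order_by_mean_correlation(matrix: TimeSeriesMatrix) -> CarpetMatrix:
    """Order carpet rows by decreasing correlation with the mean time series.

    The mean is taken over all rows of ``matrix``; ties keep the original
    (stable) order. The returned object shares the underlying row storage.
    """
    vals = matrix.values
    if vals.shape[0] < 2 or vals.shape[1] < 3:
        raise DegenerateDataError("carpet ordering needs >= 2 rows and >= 3 frames")
    mean_ts = vals.mean(axis=0)
    r = _rows_vs_vector_r(vals, mean_ts)
    order = np.argsort(-r, kind="stable")
    return CarpetMatrix(
        values=vals,
        voxel_index=matrix.voxel_index,
        display_order=order,
        tr=matrix.tr,
    )


def temporal_pca(matrix: TimeSeriesMatrix, n_components: int = 5) -> list[PcProfile]:
    """Temporal principal components of the (row-z-scored) carpet matrix.

    Computed by singular value decomposition: the PCs are the right singular
    vectors (frame-length, unit Euclidean norm) ordered by decreasing
    singular value, with ``explained_variance_ratio_k = s_k^2 / sum(s^2)``.
    If the matrix rank is below ``n_components`` only the available
    components are returned, with a warning.
    """
    vals = matrix.values
    if n_components > min(vals.shape):
        raise ConfigError(
            f"n_components={n_components} exceeds min(voxels, frames)={min(vals.shape)}"
        )
    _, s, vt = np.linalg.svd(vals, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise DegenerateDataError("all-zero matrix has no principal components")
    rank = int(np.sum(s > s[0] * 1e-12))
    if rank < n_components:
        warnings.warn(
            f"matrix rank {rank} < requested {n_components} components; "
            "returning the available ones",
            stacklevel=2,
        )
        n_components = rank
    return [
        PcProfile(
            index=k + 1,
            timeseries=vt[k].copy(),
            explained_variance_ratio=float(s[k] ** 2 / total),
        )
        for k in range(n_components)
    ]


def pc_voxel_correlations(
    pcs: list[PcProfile], matrix: TimeSeriesMatrix
) -> list[PcProfile]:
    """Complete PC profiles with voxelwise Pearson correlations.

    For each PC, every voxel row is correlated with the PC time series. If
    the median correlation is negative, the PC and its correlations are
    sign-flipped so that the PC polarity matches the majority of voxels.
    The histogram uses 50 equal bins on [-1, 1] (right edge inclusive on the
    last bin only).
    """
    vals = matrix.values
    for pc in pcs:
        r = _rows_vs_vector_r(vals, pc.timeseries)
        med = float(np.median(r))
        if med < 0:
            pc.timeseries = -pc.timeseries
            r = -r
            med = -med
            pc.sign_flipped = True
        pc.voxel_r = r
        pc.median_r = med
        pc.histogram, _ = np.histogram(r, bins=N_HISTOGRAM_BINS, range=(-1.0, 1.0))
    return pcs


def classify_run(
    pcs: list[PcProfile],
    threshold: float,
    exclusion_delta: float | None = None,
) -> AsymmetryDecision:
    """Classify a run as burst-suppression from its completed PC profiles.

    Let ``m1 >= m2`` be the two largest median-r values (ties broken by lower
    PC rank). The run is burst-suppression iff ``m1 > threshold`` and, when
    an exclusion gap is configured, ``m1 - m2 >= exclusion_delta`` (a second
    PC strictly within the gap disqualifies the run).
    """
    if not pcs or any(pc.median_r is None for pc in pcs):
        raise DegenerateDataError("classify_run needs completed PC profiles")
    medians = [float(pc.median_r) for pc in pcs]
    order = sorted(range(len(pcs)), key=lambda i: (-medians[i], i))
    top = order[0]
    m1 = medians[top]
    m2 = medians[order[1]] if len(order) > 1 else -np.inf
    margin = m1 - m2
    exclusion_applied = False
    if m1 <= threshold:
        is_bs = False
        reason = f"max median r {m1:.3f} <= threshold {threshold:g}"
    elif exclusion_delta is not None and margin < exclusion_delta:
        is_bs = False
        exclusion_applied = True
        reason = (
            f"second PC within {exclusion_delta:g} of the most asymmetric PC "
            f"(gap {margin:.3f})"
        )
    else:
        is_bs = True
        reason = f"median r {m1:.3f} > threshold {threshold:g}"
        if exclusion_delta is not None:
            reason += f"; gap {margin:.3f} >= {exclusion_delta:g}"
    return AsymmetryDecision(
        is_burst_suppression=is_bs,
        selected_pc=pcs[top].index if is_bs else None,
        threshold_used=float(threshold),
        second_pc_margin=float(margin),
        exclusion_applied=exclusion_applied,
        reason=reason,
        median_r_values=tuple(medians),
    )


def _rows_vs_vector_r(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Pearson r between each row and a vector, clipped to [-1, 1]."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    denom = np.linalg.norm(rc, axis=1) * np.linalg.norm(vc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, rc @ vc / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)
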