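"""End-to-end detection and EEG-validation pipelines with reproducible reports.

Two layers: in-memory pipeline functions (:func:`detect_run`,
:func:`validate_against_eeg`) that operate on loaded objects and return
result bundles, and file-driven workflow entry points
(:func:`run_detect_workflow`, :func:`run_eeg_validation_workflow`) that read
inputs from a config mapping, run the pipeline and assemble a
:class:`RunReport` that serializes to JSON. Reports are pure functions of
(inputs, config): re-running with identical inputs reproduces every numeric
field, and input files are content-hashed for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any

import numpy as np

from . import __version__, bold_io, carpet, eeg, mapping
from .bold_io import BoldRun, TimeSeriesMatrix, VolumeMap
from .carpet import SPECIES_PRESETS, AsymmetryDecision, CarpetMatrix, PcProfile
from .eeg import BurstEnvelope, CrossCorrResult, EEGTrace, HemodynamicModel
from .errors import ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionResult",
    "RunReport",
    "detect_run",
    "validate_against_eeg",
    "run_detect_workflow",
    "run_eeg_validation_workflow",
]


@dataclass
class DetectionResult:
    """Everything the detection pipeline computes for one run."""

    matrix: TimeSeriesMatrix  # detrended, bandpassed, z-scored
    carpet: CarpetMatrix
    pcs: list[PcProfile]
    decision: AsymmetryDecision
    tsnr: VolumeMap
    n_voxels: int

    @property
    def selected_pc(self) -> PcProfile | None:
        if self.decision.selected_pc is None:
            return None
        return self.pcs[self.decision.selected_pc - 1]


@dataclass
class RunReport:
    """Machine-readable record of one workflow execution."""

    workflow: str
    inputs: dict[str, str]  # path -> sha256
    config: dict[str, Any]
    pc_table: list[dict[str, Any]]
    decision: dict[str, Any]
    crosscorr: dict[str, Any] | None = None
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.__dict__, indent=indent)


def detect_run(
    run: BoldRun,
    cortical_mask: VolumeMap,
    *,
    species: str | None = None,
    threshold: float | None = None,
    exclusion_delta: float | None = None,
    band: tuple[float, float] | None = None,
    poly_order: int = 3,
    tsnr_min: float = 15.0,
    n_pcs: int = 5,
    smooth_fwhm_mm: float = 0.0,
) -> DetectionResult:
    """Run the full asymmetric-PC detection pipeline on a loaded run.

    Stages: optional smoothing -> tSNR -> voxel selection -> joint
    detrend/bandpass -> row z-scoring -> carpet ordering -> temporal PCA ->
    voxelwise correlations -> classification. Either ``species`` (preset
    threshold/exclusion/band) or an explicit ``threshold`` must be given;
    explicit values override the preset.
    """
    preset = None
    if species is not None:
        try:
            preset = SPECIES_PRESETS[species]
        except KeyError:
            raise ConfigError(
                f"unknown species {species!r}; choose from {sorted(SPECIES_PRESETS)}"
            ) from None
    if threshold is None:
        if preset is None:
            raise ConfigError("either species or threshold must be provided")
        threshold = preset.threshold
    if exclusion_delta is None and preset is not None:
        exclusion_delta = preset.exclusion_delta
    if band is None:
        band = preset.band if preset is not None else (0.005, 0.12)

    if smooth_fwhm_mm > 0:
        run = bold_io.smooth_gaussian(run, smooth_fwhm_mm, mask=cortical_mask)
    tsnr = bold_io.compute_tsnr(run)
    voxels = bold_io.build_voxel_set(run, cortical_mask, tsnr, tsnr_min=tsnr_min)
    matrix = bold_io.extract_matrix(run, voxels)
    matrix = bold_io.detrend_and_bandpass(matrix, poly_order=poly_order, band=band)
    matrix = bold_io.zscore_rows(matrix)
    carpet_matrix = carpet.order_by_mean_correlation(matrix)
    pcs = carpet.temporal_pca(matrix, n_components=min(n_pcs, min(matrix.values.shape)))
    pcs = carpet.pc_voxel_correlations(pcs, matrix)
    decision = carpet.classify_run(pcs, threshold, exclusion_delta)
    logger.info("detection: %s", decision.reason)
    return DetectionResult(
        matrix=matrix,
        carpet=carpet_matrix,
        pcs=pcs,
        decision=decision,
        tsnr=tsnr,
        n_voxels=len(voxels),
    )


def validate_against_eeg(
    run: BoldRun,
    cortical_mask: VolumeMap,
    eeg_trace: EEGTrace,
    *,
    window_s: float = eeg.DEFAULT_WINDOW_S,
    eeg_band: tuple[float, float] = eeg.DEFAULT_EEG_BAND,
    power_threshold: float = eeg.DEFAULT_POWER_THRESHOLD_UV2,
    max_lag_s: float = 30.0,
    **detect_kwargs,
) -> tuple[DetectionResult, BurstEnvelope, HemodynamicModel, CrossCorrResult | None]:
    """Detect the asymmetric PC and compare it with the EEG-derived model.

    The EEG is segmented into a burst envelope, converted into the
    hemodynamic model, and cross-correlated against the detected asymmetric
    PC. If the run has no asymmetric PC, the cross-correlation is skipped
    (result ``None``), mirroring the exclusion of such runs from the
    EEG comparison.
    """
    detection = detect_run(run, cortical_mask, **detect_kwargs)
    envelope = eeg.segment_eeg(
        eeg_trace,
        n_frames=run.n_frames,
        tr=run.tr,
        window_s=window_s,
        band=eeg_band,
        power_threshold=power_threshold,
    )
    band = detect_kwargs.get("band")
    if band is None:
        species = detect_kwargs.get("species")
        band = SPECIES_PRESETS[species].band if species else (0.005, 0.12)
    model = eeg.envelope_to_model(envelope, band=band)
    selected = detection.selected_pc
    xcorr = None
    if selected is not None:
        xcorr = eeg.crosscorrelate(model, selected.timeseries, max_lag_s=max_lag_s)
    else:
        logger.info("no asymmetric PC found; skipping EEG cross-correlation")
    return detection, envelope, model, xcorr


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _pc_table(pcs: list[PcProfile]) -> list[dict[str, Any]]:
    return [
        {
            "rank": pc.index,
            "explained_variance_ratio": round(pc.explained_variance_ratio, 10),
            "median_r": round(float(pc.median_r), 10),
            "sign_flipped": pc.sign_flipped,
        }
        for pc in pcs
    ]


def _decision_dict(decision: AsymmetryDecision) -> dict[str, Any]:
    return {
        "is_burst_suppression": decision.is_burst_suppression,
        "selected_pc": decision.selected_pc,
        "threshold_used": decision.threshold_used,
        "second_pc_margin": round(decision.second_pc_margin, 10),
        "exclusion_applied": decision.exclusion_applied,
        "reason": decision.reason,
    }


def _load_inputs(config: dict[str, Any]) -> tuple[BoldRun, VolumeMap, dict[str, str]]:
    bold_path = config["bold"]
    mask_path = config["mask"]
    run = bold_io.load_bold(bold_path, tr_override=config.get("tr_override"))
    mask = bold_io.load_mask(mask_path)
    hashes = {str(bold_path): _sha256(bold_path), str(mask_path): _sha256(mask_path)}
    return run, mask, hashes


def _detect_kwargs(config: dict[str, Any]) -> dict[str, Any]:
    kwargs: dict[str, Any] = {}
    for key in ("species", "threshold", "exclusion_delta", "poly_order",
                "tsnr_min", "n_pcs", "smooth_fwhm_mm"):
        if config.get(key) is not None:
            kwargs[key] = config[key]
    if config.get("band_low_hz") is not None and config.get("band_high_hz") is not None:
        kwargs["band"] = (config["band_low_hz"], config["band_high_hz"])
    return kwargs


def run_detect_workflow(config: dict[str, Any]) -> RunReport:
    """File-driven detection workflow: load inputs, detect, report."""
    run, mask, hashes = _load_inputs(config)
    result = detect_run(run, mask, **_detect_kwargs(config))
    return RunReport(
        workflow="detect",
        inputs=hashes,
        config={k: v for k, v in config.items() if k not in ("bold", "mask")},
        pc_table=_pc_table(result.pcs),
        decision=_decision_dict(result.decision),
    )


def run_eeg_validation_workflow(config: dict[str, Any]) -> RunReport:
    """File-driven EEG-validation workflow: detect, segment EEG, cross-correlate."""
    run, mask, hashes = _load_inputs(config)
    eeg_path = config["eeg"]
    trace = load_eeg_csv(eeg_path)
    hashes[str(eeg_path)] = _sha256(eeg_path)
    detection, envelope, model, xcorr = validate_against_eeg(
        run,
        mask,
        trace,
        window_s=config.get("window_s", eeg.DEFAULT_WINDOW_S),
        power_threshold=config.get(
            "threshold_uv2", eeg.DEFAULT_POWER_THRESHOLD_UV2
        ),
        max_lag_s=config.get("max_lag_s", 30.0),
        **_detect_kwargs(config),
    )
    xcorr_block = None
    if xcorr is not None:
        xcorr_block = {
            "r_zero_lag": round(xcorr.r_zero_lag, 10),
            "r_max": round(xcorr.r_max, 10),
            "lag_at_max_s": xcorr.lag_at_max,
            "n_burst_frames": int(envelope.states.sum()),
        }
    return RunReport(
        workflow="validate",
        inputs=hashes,
        config={k: v for k, v in config.items() if k not in ("bold", "mask", "eeg")},
        pc_table=_pc_table(detection.pcs),
        decision=_decision_dict(detection.decision),
        crosscorr=xcorr_block,
    )


def load_eeg_csv(path) -> EEGTrace:
    """Read a single-column CSV/TSV of uV samples with a JSON sidecar.

    The sidecar ``<stem>.json`` must provide ``fs_hz`` and may provide
    ``t0_s`` (default 0).
    """
    import pandas as pd
    from pathlib import Path

    p = Path(path)
    samples = pd.read_csv(p, header=None).iloc[:, 0].to_numpy(dtype=float)
    sidecar = p.with_suffix(".json")
    if not sidecar.exists():
        raise ConfigError(f"EEG sidecar {sidecar} not found (needs fs_hz)")
    meta = json.loads(sidecar.read_text())
    return EEGTrace(samples=samples, fs=float(meta["fs_hz"]), t0=float(meta.get("t0_s", 0.0)))


def save_eeg_csv(trace: EEGTrace, path) -> None:
    """Write an EEG trace as CSV plus JSON sidecar."""
    from pathlib import Path

    p = Path(path)
    np.savetxt(p, trace.samples, fmt="%.6f")
    p.with_suffix(".json").write_text(
        json.dumps({"fs_hz": trace.fs, "t0_s": trace.t0})
    )
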