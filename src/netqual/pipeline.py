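"""Post-registration BOLD signal processing.

The pipeline assumes spatially registered data (realignment, slice timing and
normalisation are upstream concerns) and covers the temporal steps: frame
trimming, motion quality control, regional mean extraction over a parcellation,
nuisance regression against the extracranial (air) background signal, band-pass
filtering, and ALFF (low-frequency band power).

Fixed processing order: trim -> motion QC -> extract -> background regression
-> bandpass.  Each step is a pure function; :func:`preprocess_subject` chains
them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import signal as spsignal

logger = logging.getLogger(__name__)

__all__ = [
    "BoldVolume",
    "ParcellationLabels",
    "MotionTrace",
    "RegionalSignalMatrix",
    "MotionQCResult",
    "PipelineConfig",
    "PreprocessedSubject",
    "trim_frames",
    "motion_qc",
    "extract_regional_means",
    "regress_background",
    "bandpass",
    "alff",
    "preprocess_subject",
]


@dataclass
class BoldVolume:
    """4D voxel time-series with repetition time.

    ``data`` is indexed ``(x, y, z, t)`` in arbitrary scanner units; ``tr`` is
    the repetition time in seconds.
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got ndim={self.data.ndim}")
        if self.data.shape[-1] < 1:
            raise ValueError("BOLD volume must contain at least one frame")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @classmethod
    def from_nifti(cls, path) -> "BoldVolume":
        img = nib.load(str(path))
        tr = float(img.header["pixdim"][4])
        return cls(data=np.asanyarray(img.dataobj).astype(np.float64),
                   tr=tr, affine=np.asarray(img.affine))

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = self.tr
        img.header.set_zooms(tuple(zooms))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, str(path))


@dataclass
class ParcellationLabels:
    """3D integer label volume; 0 means unlabelled."""

    labels: np.ndarray
    region_ids: list[int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("parcellation labels must be a 3D volume")
        self.region_ids = [int(r) for r in self.region_ids]
        if any(r <= 0 for r in self.region_ids):
            raise ValueError("region ids must be positive integers")
        present = set(np.unique(self.labels).tolist())
        missing = [r for r in self.region_ids if r not in present]
        if missing:
            raise ValueError(f"region ids absent from label volume: {missing}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @classmethod
    def from_nifti(cls, path, region_ids=None) -> "ParcellationLabels":
        img = nib.load(str(path))
        labels = np.asanyarray(img.dataobj).astype(np.int64)
        if region_ids is None:
            region_ids = sorted(int(v) for v in np.unique(labels) if v > 0)
        return cls(labels=labels, region_ids=list(region_ids))

    def to_nifti(self, path, affine=None) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int16),
                              np.eye(4) if affine is None else affine)
        nib.save(img, str(path))


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters per frame.

    ``translations``: frames x 3, millimetres.  ``rotations``: frames x 3,
    radians.  Stored/loaded as the common whitespace-delimited 6-column text
    format (tx ty tz rx ry rz).
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape[1] != 3 or self.rotations.shape[1] != 3:
            raise ValueError(
                "motion trace needs 3 translation and 3 rotation columns, got "
                f"{self.translations.shape[1]} and {self.rotations.shape[1]}")
        if self.translations.shape[0] != self.rotations.shape[0]:
            raise ValueError("translation and rotation frame counts differ")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]

    @classmethod
    def from_text(cls, path) -> "MotionTrace":
        arr = np.loadtxt(str(path))
        arr = np.atleast_2d(arr)
        if arr.shape[1] != 6:
            raise ValueError(f"expected 6 columns in motion file, got {arr.shape[1]}")
        return cls(translations=arr[:, :3], rotations=arr[:, 3:])

    def to_text(self, path) -> None:
        np.savetxt(str(path), np.hstack([self.translations, self.rotations]),
                   fmt="%.6f")


@dataclass
class RegionalSignalMatrix:
    """Regions x time matrix of mean regional signals."""

    signals: np.ndarray
    tr: float
    region_ids: list[int]

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] != len(self.region_ids):
            raise ValueError("row count does not match number of region ids")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("regional signals contain non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_regions(self) -> int:
        return self.signals.shape[0]

    @property
    def n_frames(self) -> int:
        return self.signals.shape[1]

    def temporal_mean(self) -> np.ndarray:
        """Per-region temporal mean (S-bar)."""
        return self.signals.mean(axis=1)

    def temporal_sd(self, ddof: int = 0) -> np.ndarray:
        """Per-region temporal standard deviation (sigma_S)."""
        return self.signals.std(axis=1, ddof=ddof)

    def amplitude(self) -> np.ndarray:
        """Per-region |max - mean| (A, the peak excursion)."""
        return np.abs(self.signals.max(axis=1) - self.signals.mean(axis=1))


@dataclass
class MotionQCResult:
    passed: bool
    first_bad_frame: int | None
    max_translation: float
    max_rotation: float


def trim_frames(vol: BoldVolume, n_head: int = 10, n_tail: int = 10) -> BoldVolume:
    """Drop the first ``n_head`` and last ``n_tail`` frames.

    Removes scanner start-up / transition frames.  Raises if nothing would be
    left.
    """
    if n_head < 0 or n_tail < 0:
        raise ValueError("n_head and n_tail must be non-negative")
    if vol.n_frames <= n_head + n_tail:
        raise ValueError(
            f"cannot trim {n_head}+{n_tail} frames from a {vol.n_frames}-frame volume")
    data = vol.data[..., n_head: vol.n_frames - n_tail]
    return BoldVolume(data=data, tr=vol.tr, affine=vol.affine)


def motion_qc(trace: MotionTrace, trans_max: float = 1.0,
              rot_max: float = 0.0125) -> MotionQCResult:
    """Flag subjects whose realignment exceeds the motion limits.

    A subject is excluded iff any frame's maximum absolute translation is
    strictly above ``trans_max`` (mm) or rotation strictly above ``rot_max``
    (radians) — values exactly at the limit pass.
    """
    if trace.n_frames == 0:
        raise ValueError("empty motion trace")
    t = np.abs(trace.translations).max(axis=1)
    r = np.abs(trace.rotations).max(axis=1)
    bad = (t > trans_max) | (r > rot_max)
    first_bad = int(np.argmax(bad)) if bad.any() else None
    return MotionQCResult(passed=not bad.any(), first_bad_frame=first_bad,
                          max_translation=float(t.max()), max_rotation=float(r.max()))


def extract_regional_means(vol: BoldVolume,
                           parc: ParcellationLabels) -> RegionalSignalMatrix:
    """Average the voxel time-series within each parcellation region."""
    if vol.data.shape[:3] != parc.labels.shape:
        raise ValueError(
            f"volume shape {vol.data.shape[:3]} does not match labels {parc.labels.shape}")
    flat = vol.data.reshape(-1, vol.n_frames)
    lab = parc.labels.reshape(-1)
    rows = np.empty((parc.n_regions, vol.n_frames), dtype=float)
    empty = []
    for i, rid in enumerate(parc.region_ids):
        mask = lab == rid
        if not mask.any():
            empty.append(rid)
            continue
        rows[i] = flat[mask].mean(axis=0)
    if empty:
        raise ValueError(f"regions with zero voxels: {empty}")
    return RegionalSignalMatrix(signals=rows, tr=vol.tr,
                                region_ids=list(parc.region_ids))


def regress_background(regional: RegionalSignalMatrix,
                       background: np.ndarray) -> RegionalSignalMatrix:
    """Remove the extracranial background signal from every region.

    Each row is replaced by its ordinary-least-squares residual on
    ``[intercept, background]``; the row's temporal mean is restored afterwards
    so that downstream mean-based quality metrics remain defined.  A constant
    background degenerates to an intercept-only regression (rows unchanged),
    with a warning.
    """
    bg = np.asarray(background, dtype=float).ravel()
    if bg.shape[0] != regional.n_frames:
        raise ValueError(
            f"background length {bg.shape[0]} != frame count {regional.n_frames}")
    y = regional.signals
    means = y.mean(axis=1, keepdims=True)
    if np.std(bg) == 0:
        warnings.warn("background regressor is constant; intercept-only "
                      "regression leaves signals unchanged", stacklevel=2)
        return replace(regional, signals=y.copy())
    x = np.column_stack([np.ones_like(bg), bg])
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y - (x @ beta).T
    return replace(regional, signals=resid + means)


def _butter_band(low: float, high: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyq:
        raise ValueError(
            f"high cutoff {high} Hz is not below the Nyquist frequency {nyq} Hz")
    return spsignal.butter(order, [low, high], btype="band", fs=fs, output="sos")


def bandpass(regional: RegionalSignalMatrix, low: float = 0.009,
             high: float = 0.08, order: int = 4) -> RegionalSignalMatrix:
    """Zero-phase Butterworth band-pass of every regional signal.

    Applied forward-backward (``sosfiltfilt``) so the filter introduces no
    time shift and therefore does not perturb inter-regional correlation
    structure.  Removes the DC component (the temporal mean).
    """
    sos = _butter_band(low, high, fs=1.0 / regional.tr, order=order)
    padlen = min(3 * (2 * sos.shape[0] + 1) * 2, regional.n_frames - 1)
    filtered = spsignal.sosfiltfilt(sos, regional.signals, axis=-1, padlen=padlen)
    return replace(regional, signals=np.ascontiguousarray(filtered))


def alff(regional: RegionalSignalMatrix, low: float = 0.01,
         high: float = 0.08) -> np.ndarray:
    """Amplitude of low-frequency fluctuations per region.

    Summed periodogram power in ``[low, high]`` Hz (DC bin excluded by the
    positive lower edge).
    """
    fs = 1.0 / regional.tr
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= fs / 2.0 and not np.isclose(high, fs / 2.0):
        raise ValueError(f"high cutoff {high} Hz exceeds Nyquist {fs / 2.0} Hz")
    freqs, pxx = spsignal.periodogram(regional.signals, fs=fs, axis=-1)
    band = (freqs >= low) & (freqs <= high)
    return pxx[:, band].sum(axis=1)


@dataclass
class PipelineConfig:
    """Knobs for :func:`preprocess_subject` (defaults follow the study design)."""

    n_head: int = 10
    n_tail: int = 10
    trans_max: float = 1.0          # mm
    rot_max: float = 0.0125         # radians
    air_cutoff: float = 0.5         # air-probability threshold for the nuisance mask
    band_low: float = 0.009         # Hz
    band_high: float = 0.08         # Hz
    restore_mean: bool = True       # re-add S-bar after band-passing


@dataclass
class PreprocessedSubject:
    signals: RegionalSignalMatrix
    qc: MotionQCResult | None
    trimmed: BoldVolume
    background: np.ndarray


def preprocess_subject(vol: BoldVolume, parc: ParcellationLabels,
                       air_probabilities: np.ndarray,
                       motion: MotionTrace | None = None,
                       config: PipelineConfig | None = None) -> PreprocessedSubject:
    """Run the full temporal pipeline for one subject.

    Order: trim -> motion QC -> regional extraction -> background regression
    -> band-pass.  The pre-filter temporal means are restored at the end (when
    ``restore_mean``) so tSNR/SNR stay defined on the output.  Motion QC is
    evaluated on the trimmed frame range; a failing subject is still processed
    — the caller decides on exclusion via ``qc.passed``.
    """
    cfg = config or PipelineConfig()
    trimmed = trim_frames(vol, cfg.n_head, cfg.n_tail)
    logger.info("trimmed %d+%d frames -> %d frames", cfg.n_head, cfg.n_tail,
                trimmed.n_frames)
    qc = None
    if motion is not None:
        sl = slice(cfg.n_head, motion.n_frames - cfg.n_tail)
        qc = motion_qc(MotionTrace(motion.translations[sl], motion.rotations[sl]),
                       cfg.trans_max, cfg.rot_max)
        if not qc.passed:
            logger.warning("motion QC failed at frame %s (trans %.3f mm, rot %.5f rad)",
                           qc.first_bad_frame, qc.max_translation, qc.max_rotation)
    regional = extract_regional_means(trimmed, parc)
    air_mask = np.asarray(air_probabilities) > cfg.air_cutoff
    if not air_mask.any():
        raise ValueError("no voxels above the air-probability cutoff")
    background = trimmed.data[air_mask].mean(axis=0)
    regional = regress_background(regional, background)
    means = regional.temporal_mean()
    regional = bandpass(regional, cfg.band_low, cfg.band_high)
    if cfg.restore_mean:
        regional = replace(regional,
                           signals=regional.signals + means[:, None])
    return PreprocessedSubject(signals=regional, qc=qc, trimmed=trimmed,
                               background=background)
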