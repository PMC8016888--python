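"""fMRI quality metrics: SNR, temporal SNR (tSNR) and contrast-to-noise (CNR).

Definitions (all dimensionless ratios):

* SNR   = mean brain signal / sigma_N                (scanning quality)
* tSNR  = temporal mean / temporal sd of a signal    (signal stability)
* CNR   = |max(signal) - mean(signal)| / sigma_N     (fluctuation detectability)

where sigma_N is the standard deviation of the background noise, estimated
from voxels with high air/background probability — the part of the field of
view containing no anatomy.  Standard deviations are population (ddof=0) by
default; this is an arbitrary but fixed convention, switchable everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pipeline import BoldVolume, RegionalSignalMatrix

__all__ = [
    "AirProbabilityMap",
    "QualityMetrics",
    "background_sd",
    "snr",
    "tsnr",
    "cnr",
    "subject_quality",
    "tsnr_map",
]


@dataclass
class AirProbabilityMap:
    """3D map of the probability that a voxel contains air/background."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 3:
            raise ValueError("air probability map must be 3D")
        if self.probabilities.min() < 0 or self.probabilities.max() > 1:
            raise ValueError("air probabilities must lie in [0, 1]")

    def mask(self, cutoff: float = 0.5) -> np.ndarray:
        return self.probabilities > cutoff


@dataclass
class QualityMetrics:
    """Per-subject quality summary; scalars are means over regions."""

    snr: float
    tsnr: float
    cnr: float
    sigma_n: float
    per_region_tsnr: np.ndarray
    per_region_cnr: np.ndarray


def background_sd(vol: BoldVolume, air: AirProbabilityMap,
                  cutoff: float = 0.5, ddof: int = 0) -> float:
    """Pooled standard deviation over all (air voxel, frame) samples."""
    mask = air.mask(cutoff)
    if vol.data.shape[:3] != mask.shape:
        raise ValueError("volume and air map shapes differ")
    if not mask.any():
        raise ValueError(f"no voxels with air probability above {cutoff}")
    samples = vol.data[mask]
    sd = float(samples.std(ddof=ddof))
    if sd == 0:
        warnings.warn("background voxels are constant (sigma_N = 0); "
                      "SNR and CNR are undefined downstream", stacklevel=2)
    return sd


def snr(vol: BoldVolume, brain_mask: np.ndarray, sigma_n: float) -> float:
    """Mean intensity over brain voxels and frames divided by sigma_N."""
    if sigma_n <= 0:
        raise ValueError("sigma_N must be positive (see background_sd); "
                         f"got {sigma_n}")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if vol.data.shape[:3] != brain_mask.shape:
        raise ValueError("volume and brain mask shapes differ")
    if not brain_mask.any():
        raise ValueError("empty brain mask")
    return float(vol.data[brain_mask].mean() / sigma_n)


def tsnr(signal: np.ndarray, ddof: int = 0) -> float:
    """Temporal mean divided by temporal standard deviation of one signal."""
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("tSNR needs at least two frames")
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("constant signal: temporal sd is zero, tSNR undefined")
    return float(x.mean() / sd)


def cnr(signal: np.ndarray, sigma_n: float) -> float:
    """|max - mean| of the signal divided by the background noise sd."""
    if sigma_n <= 0:
        raise ValueError(f"sigma_N must be positive, got {sigma_n}")
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("empty signal")
    return float(abs(x.max() - x.mean()) / sigma_n)


def subject_quality(regional: RegionalSignalMatrix, vol: BoldVolume,
                    air: AirProbabilityMap, brain_mask: np.ndarray | None = None,
                    cutoff: float = 0.5, ddof: int = 0) -> QualityMetrics:
    """All three quality metrics for one subject.

    tSNR and CNR are computed per region on the (processed) regional signals
    and averaged, unweighted, into the subject scalar; SNR is computed on the
    volume over ``brain_mask`` (default: the complement of the air mask)
    against the pooled background sd.
    """
    sigma_n = background_sd(vol, air, cutoff=cutoff, ddof=ddof)
    means = regional.temporal_mean()
    sds = regional.temporal_sd(ddof=ddof)
    if np.any(sds == 0):
        bad = [regional.region_ids[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant regional signal(s), tSNR undefined: {bad}")
    per_tsnr = means / sds
    if sigma_n == 0:
        raise ValueError("sigma_N is zero; SNR and CNR undefined")
    per_cnr = regional.amplitude() / sigma_n
    if brain_mask is None:
        brain_mask = ~air.mask(cutoff)
    return QualityMetrics(
        snr=snr(vol, brain_mask, sigma_n),
        tsnr=float(per_tsnr.mean()),
        cnr=float(per_cnr.mean()),
        sigma_n=sigma_n,
        per_region_tsnr=per_tsnr,
        per_region_cnr=per_cnr,
    )


def tsnr_map(vol: BoldVolume, ddof: int = 0) -> np.ndarray:
    """Voxel-wise tSNR map (mean/sd over time; 0 where the sd is 0)."""
    mean = vol.data.mean(axis=-1)
    sd = vol.data.std(axis=-1, ddof=ddof)
    out = np.zeros_like(mean)
    np.divide(mean, sd, out=out, where=sd > 0)
    return out
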