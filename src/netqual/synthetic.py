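"""Synthetic resting-state BOLD cohort generator.

Emulates a two-group study (a healthy-like and a patient-like cohort) in
which the *latent* inter-regional coupling is identical across groups while
the BOLD fluctuation amplitude differs.  Because the additive scanner noise is
fixed, a lower fluctuation amplitude simultaneously lowers the
contrast-to-noise ratio, raises the temporal SNR, and attenuates every
pairwise Pearson correlation — the mechanism by which signal quality can
masquerade as network reorganisation.

Generative model for region i of one subject (amplitude ``a`` drawn once per
subject):

    x_i(t) = baseline_mean + a * ( sum_j coupling[i, j] * shared_j(t) + unique_i(t) )

with ``shared_j`` and ``unique_i`` independent unit-variance band-limited
(0.01-0.08 Hz) Gaussian processes.  Every voxel of region i carries ``x_i``
plus independent white scanner noise; air voxels carry pure scanner noise.
Analytically, the single-voxel tSNR is

    baseline_mean / sqrt(a^2 * (sum_j coupling[i, j]^2 + 1) + scanner_noise_sd^2)

and pairwise correlation grows with the coupling rows' inner product,
attenuated by the noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as spsignal

from .pipeline import (BoldVolume, MotionTrace, ParcellationLabels,
                       _butter_band)
from .quality import AirProbabilityMap

__all__ = [
    "LatentNetwork",
    "GroupSpec",
    "VolumeLayout",
    "SubjectData",
    "CohortBundle",
    "band_limited_noise",
    "generate_subject",
    "generate_cohort",
    "iter_cohort",
    "hs_like_spec",
    "ms_like_spec",
    "default_cohort_specs",
    "write_subject",
    "write_cohort",
]

COHORT_COLUMNS = ("subject_id", "group", "age", "education_years", "sdmt",
                  "cvlt", "bvmt", "cowat", "fsmc", "bicams_scaled", "bicams_z")

#: cognition score (mean, sd) per group flavour; means/sds follow the kind of
#: values reported for MS vs healthy cohorts, used as configurable placeholders
COGNITION_HS = {"sdmt": (53.6, 9.0), "cvlt": (68.1, 6.3), "bvmt": (29.6, 4.2),
                "cowat": (35.0, 9.8), "fsmc": (37.6, 10.0),
                "bicams_scaled": (100.0, 12.0), "bicams_z": (0.0, 0.8)}
COGNITION_MS = {"sdmt": (53.7, 12.3), "cvlt": (61.4, 11.1), "bvmt": (25.9, 6.7),
                "cowat": (32.2, 11.1), "fsmc": (63.8, 18.2),
                "bicams_scaled": (90.0, 15.0), "bicams_z": (-0.45, 1.0)}


@dataclass
class LatentNetwork:
    """Shared-signal loading matrix defining the true coupling structure.

    ``coupling`` is symmetric with zero diagonal and entries in [0, 1]; entry
    (i, j) is region i's loading on region j's shared band-limited drive.
    Both study groups use the same latent network — by construction there is
    no group difference in brain organisation.
    """

    coupling: np.ndarray
    block_structure: list[int] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coupling, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("coupling must be square")
        if c.shape[0] < 1:
            raise ValueError("latent network needs at least one region")
        if not np.allclose(c, c.T):
            raise ValueError("coupling must be symmetric")
        if np.any(np.diag(c) != 0):
            raise ValueError("coupling diagonal must be zero")
        if c.min() < 0 or c.max() > 1:
            raise ValueError("coupling values must lie in [0, 1]")
        self.coupling = c

    @property
    def n_regions(self) -> int:
        return self.coupling.shape[0]

    @classmethod
    def default(cls, n_regions: int = 94, n_blocks: int = 8,
                within: float = 0.30, between: float = 0.07) -> "LatentNetwork":
        """Block-modular coupling: stronger loading within modules.

        The defaults give broad positive functional connectivity with a
        visible community structure, in the range typical of resting-state
        correlation matrices.
        """
        blocks = np.array_split(np.arange(n_regions), n_blocks)
        assign = np.empty(n_regions, dtype=int)
        for b, idx in enumerate(blocks):
            assign[idx] = b
        c = np.full((n_regions, n_regions), between)
        same = assign[:, None] == assign[None, :]
        c[same] = within
        np.fill_diagonal(c, 0.0)
        return cls(coupling=c, block_structure=assign.tolist())


@dataclass
class GroupSpec:
    """Acquisition and signal parameters for one study group.

    ``fluct_amplitude`` scales the BOLD fluctuation (driving sigma_S and the
    peak amplitude A); ``amplitude_cv`` is the coefficient of variation of the
    per-subject lognormal amplitude multiplier (inter-subject variability of
    BOLD amplitude); ``scanner_noise_sd`` is the fixed additive noise (the
    source of sigma_N).  Units are arbitrary scanner units; ``tr`` in seconds.
    """

    label: str
    n_subjects: int
    baseline_mean: float = 1000.0
    fluct_amplitude: float = 10.0
    amplitude_cv: float = 0.2
    scanner_noise_sd: float = 100.0
    n_frames: int = 200
    tr: float = 3.0
    cognition: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.fluct_amplitude < 0:
            raise ValueError("fluct_amplitude must be non-negative")
        if self.scanner_noise_sd <= 0:
            raise ValueError("scanner_noise_sd must be positive")
        if self.n_frames <= 20:
            raise ValueError("n_frames must exceed 20 (frame trimming removes 20)")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be non-negative")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


def hs_like_spec(n_subjects: int = 25, **overrides) -> GroupSpec:
    """Healthy-like group: full fluctuation amplitude."""
    kw = dict(label="HS-like", n_subjects=n_subjects, fluct_amplitude=10.0,
              cognition=COGNITION_HS)
    kw.update(overrides)
    return GroupSpec(**kw)


def ms_like_spec(n_subjects: int = 49, **overrides) -> GroupSpec:
    """Patient-like group: fluctuation amplitude reduced by 20%."""
    kw = dict(label="MS-like", n_subjects=n_subjects, fluct_amplitude=8.0,
              cognition=COGNITION_MS)
    kw.update(overrides)
    return GroupSpec(**kw)


def default_cohort_specs() -> list[GroupSpec]:
    """The default two-group study design (25 healthy-like, 49 patient-like)."""
    return [hs_like_spec(), ms_like_spec()]


@dataclass
class VolumeLayout:
    """Geometry of the synthetic volume.

    A margin of ``air_margin`` voxels on every face is pure-noise air
    (probability 1.0); the interior is partitioned into ``n_regions``
    contiguous, equally sized slabs.  Geometry carries no signal content —
    only mask membership matters downstream.
    """

    shape: tuple[int, int, int] = (48, 48, 24)
    air_margin: int = 10

    def interior_slices(self) -> tuple[slice, slice, slice]:
        m = self.air_margin
        return tuple(slice(m, s - m) for s in self.shape)

    def n_interior_voxels(self) -> int:
        return int(np.prod([s - 2 * self.air_margin for s in self.shape]))

    def air_map(self) -> AirProbabilityMap:
        p = np.ones(self.shape)
        p[self.interior_slices()] = 0.0
        return AirProbabilityMap(probabilities=p)

    def parcellation(self, n_regions: int) -> ParcellationLabels:
        """Split the interior into n_regions contiguous voxel runs (C-order)."""
        nvox = self.n_interior_voxels()
        if nvox < n_regions:
            raise ValueError(
                f"layout has {nvox} interior voxels, cannot host {n_regions} regions")
        labels = np.zeros(self.shape, dtype=np.int64)
        interior = np.zeros([s - 2 * self.air_margin for s in self.shape],
                            dtype=np.int64)
        bounds = np.linspace(0, nvox, n_regions + 1).astype(int)
        flat = interior.reshape(-1)
        for i in range(n_regions):
            flat[bounds[i]:bounds[i + 1]] = i + 1
        labels[self.interior_slices()] = interior
        return ParcellationLabels(labels=labels,
                                  region_ids=list(range(1, n_regions + 1)))


@dataclass
class SubjectData:
    """One generated subject: volumes, masks, motion and realized parameters."""

    subject_id: str
    group: str
    bold: BoldVolume
    parcellation: ParcellationLabels
    air: AirProbabilityMap
    motion: MotionTrace
    amplitude: float                 # realized fluctuation amplitude
    regional_drive: np.ndarray       # noiseless regional signals (regions x T)


@dataclass
class CohortBundle:
    subjects: list[SubjectData]
    table: pd.DataFrame
    latent: LatentNetwork
    specs: list[GroupSpec]


def band_limited_noise(rng: np.random.Generator, n_series: int, n_frames: int,
                       tr: float, low: float = 0.01, high: float = 0.08,
                       order: int = 4) -> np.ndarray:
    """Unit-variance Gaussian processes band-limited to [low, high] Hz.

    White noise filtered with the same zero-phase Butterworth band-pass used
    by the analysis pipeline, then standardized to zero mean and unit sample
    variance, so the generator's spectrum matches the analysis band and the
    realized latent variance is exactly 1.
    """
    white = rng.standard_normal((n_series, n_frames))
    sos = _butter_band(low, high, fs=1.0 / tr, order=order)
    padlen = min(3 * (2 * sos.shape[0] + 1) * 2, n_frames - 1)
    x = spsignal.sosfiltfilt(sos, white, axis=-1, padlen=padlen)
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("degenerate band-limited process (zero variance)")
    return np.ascontiguousarray(x / sd)


def _regional_drive(latent: LatentNetwork, spec: GroupSpec, amplitude: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Noiseless regional signals: baseline + amplitude * (coupled + unique)."""
    n = latent.n_regions
    shared = band_limited_noise(rng, n, spec.n_frames, spec.tr)
    unique = band_limited_noise(rng, n, spec.n_frames, spec.tr)
    return spec.baseline_mean + amplitude * (latent.coupling @ shared + unique)


def _motion_trace(rng: np.random.Generator, n_frames: int) -> MotionTrace:
    """Small bounded random-walk realignment parameters (passes motion QC)."""
    trans = np.clip(np.cumsum(rng.normal(0, 0.02, (n_frames, 3)), axis=0),
                    -0.8, 0.8)
    rot = np.clip(np.cumsum(rng.normal(0, 2e-4, (n_frames, 3)), axis=0),
                  -0.01, 0.01)
    return MotionTrace(translations=trans, rotations=rot)


def generate_subject(latent: LatentNetwork, spec: GroupSpec, seed: int,
                     layout: VolumeLayout | None = None,
                     subject_id: str | None = None) -> SubjectData:
    """Generate one subject's 4D BOLD volume, masks and motion trace.

    Deterministic in (latent, spec, seed, layout).  The realized amplitude is
    ``spec.fluct_amplitude`` times a lognormal multiplier with unit mean and
    coefficient of variation ``spec.amplitude_cv``.
    """
    layout = layout or VolumeLayout()
    if latent.n_regions < 1:
        raise ValueError("latent network has no regions")
    rng = np.random.default_rng(seed)
    cv = spec.amplitude_cv
    mult = float(rng.lognormal(mean=-0.5 * np.log(1 + cv**2),
                               sigma=np.sqrt(np.log(1 + cv**2)))) if cv > 0 else 1.0
    amplitude = spec.fluct_amplitude * mult

    drive = _regional_drive(latent, spec, amplitude, rng)
    parc = layout.parcellation(latent.n_regions)

    data = rng.standard_normal(layout.shape + (spec.n_frames,),
                               dtype=np.float32)
    data *= np.float32(spec.scanner_noise_sd)
    flat = data.reshape(-1, spec.n_frames)
    lab = parc.labels.reshape(-1)
    for i, rid in enumerate(parc.region_ids):
        flat[lab == rid] += drive[i].astype(np.float32)

    motion = _motion_trace(rng, spec.n_frames)
    bold = BoldVolume(data=data, tr=spec.tr)
    return SubjectData(subject_id=subject_id or f"{spec.label}-{seed}",
                       group=spec.label, bold=bold, parcellation=parc,
                       air=layout.air_map(), motion=motion,
                       amplitude=amplitude, regional_drive=drive)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    while True:
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())


def _cohort_rows(spec: GroupSpec, ids: list[str], rng) -> pd.DataFrame:
    n = len(ids)
    rows = {"subject_id": ids, "group": spec.label,
            "age": _truncated_normal(rng, 44.0, 11.0, 18.0, 65.0, n),
            "education_years": rng.normal(14.5, 2.6, n)}
    cog = spec.cognition or COGNITION_HS
    for score, (mu, sd) in cog.items():
        rows[score] = rng.normal(mu, sd, n)
    return pd.DataFrame(rows)


def iter_cohort(latent: LatentNetwork, specs: list[GroupSpec], seed: int,
                layout: VolumeLayout | None = None):
    """Yield (SubjectData, table_row_index) one subject at a time.

    Streaming counterpart of :func:`generate_cohort` for workflows that do not
    need all volumes in memory at once.  Subject seeds are spawned from
    ``seed`` with a SeedSequence, so the cohort is bit-reproducible.
    """
    if not specs:
        raise ValueError("need at least one group spec")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(sum(s.n_subjects for s in specs))
    k = 0
    for spec in specs:
        for i in range(spec.n_subjects):
            sid = f"{spec.label}-{i:03d}"
            sub = generate_subject(latent, spec,
                                   seed=children[k].generate_state(1)[0] % (2**31),
                                   layout=layout, subject_id=sid)
            yield sub
            k += 1


def cohort_table(specs: list[GroupSpec], seed: int) -> pd.DataFrame:
    """Demographics and placeholder cognition scores for the cohort."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    frames = []
    for spec in specs:
        ids = [f"{spec.label}-{i:03d}" for i in range(spec.n_subjects)]
        frames.append(_cohort_rows(spec, ids, rng))
    table = pd.concat(frames, ignore_index=True)
    if table["subject_id"].duplicated().any():
        dups = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject identifiers: {dups}")
    return table[list(COHORT_COLUMNS)]


def generate_cohort(latent: LatentNetwork, specs: list[GroupSpec], seed: int,
                    layout: VolumeLayout | None = None) -> CohortBundle:
    """Generate a full synthetic cohort (volumes held in memory).

    For large cohorts prefer :func:`iter_cohort` plus :func:`cohort_table`.
    """
    table = cohort_table(specs, seed)
    subjects = list(iter_cohort(latent, specs, seed, layout))
    return CohortBundle(subjects=subjects, table=table, latent=latent,
                        specs=list(specs))


def write_subject(sub: SubjectData, out_dir) -> None:
    """Write one subject as NIfTI volumes + motion text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sub.bold.to_nifti(out / f"{sub.subject_id}_bold.nii.gz")
    sub.parcellation.to_nifti(out / f"{sub.subject_id}_labels.nii.gz")
    img_air = sub.air.probabilities.astype(np.float32)
    import nibabel as nib
    nib.save(nib.Nifti1Image(img_air, np.eye(4)),
             str(out / f"{sub.subject_id}_air.nii.gz"))
    sub.motion.to_text(out / f"{sub.subject_id}_motion.txt")


def write_cohort(bundle: CohortBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in bundle.subjects:
        write_subject(sub, out)
    bundle.table.to_csv(out / "cohort.tsv", sep="\t", index=False)
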