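"""Synthetic percept-fMRI cohort generation.

Emulates the data structure of a continuous pain-rating ("percept-related")
fMRI experiment in trigeminal neuralgia: each subject contributes a pain
tracking run during which a 0-100 VAS rating trace is recorded, a resting
run, and optionally a motion tracking control run in which the subject
re-tracks a replay of their own earlier rating cursor while the BOLD signal
carries no pain coupling.

BOLD voxels inside a configurable set of "planted" atlas regions carry an
HRF-convolved copy of the rating trace; every voxel additionally carries
AR(1) temporal noise, a slow sinusoidal drift, and a leak of six synthetic
head-motion courses, so that nuisance regression and bandpass filtering have
realistic structure to remove.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "PainTrace",
    "BoldRun",
    "Atlas",
    "SubjectRecord",
    "CohortConfig",
    "DEFAULT_REGION_NAMES",
    "make_block_atlas",
    "generate_trace",
    "generate_subject",
    "generate_cohort",
    "volume_times",
]

# Hemisphere-free names in the style of a Lausanne-type cortical/subcortical
# parcellation; used cyclically (with numeric suffixes) for larger atlases.
DEFAULT_REGION_NAMES = [
    "superior_frontal",
    "precentral",
    "superior_temporal",
    "fusiform",
    "supramarginal",
    "insula",
    "lateral_orbitofrontal",
    "thalamus",
    "rostral_middle_frontal",
    "lateral_occipital",
    "lingual",
    "inferior_temporal",
    "parahippocampal",
    "precuneus",
    "dacc",
    "postcentral",
]


@dataclass(frozen=True)
class PainTrace:
    """A subject's continuous 0-100 VAS pain rating time course."""

    subject_id: str
    times: np.ndarray  # seconds, strictly increasing
    ratings: np.ndarray  # VAS units in [0, 100]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ratings = np.asarray(self.ratings, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ratings", ratings)
        if times.ndim != 1 or ratings.shape != times.shape:
            raise ValueError("times and ratings must be 1-D and equal length")
        if len(times) < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(ratings < 0) or np.any(ratings > 100):
            raise ValueError("ratings must lie in [0, 100]")

    def resample(self, at_times: np.ndarray) -> np.ndarray:
        """Linear interpolation of the rating trace at arbitrary times."""
        return np.interp(np.asarray(at_times, dtype=float), self.times, self.ratings)


SESSIONS = ("tracking", "resting", "motion_tracking")


@dataclass
class BoldRun:
    """One 4D functional run (x, y, z, t) with TR, affine and session kind."""

    data: np.ndarray
    tr: float
    affine: np.ndarray
    session: str
    nuisance: np.ndarray | None = None  # (t, 6) motion courses, if simulated/known

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[3] < 2:
            raise ValueError("data must be 4-D with at least 2 time points")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 voxel->mm map")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD intensities must be finite")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(data=data, tr=self.tr, affine=self.affine.copy(),
                       session=self.session, nuisance=self.nuisance)


def volume_times(run: BoldRun) -> np.ndarray:
    """Acquisition mid-times (s) of each volume: (i + 1/2) * TR."""
    return (np.arange(run.n_volumes) + 0.5) * run.tr


@dataclass
class Atlas:
    """Integer-labelled parcellation: 0 = background, 1..R named regions."""

    labels: np.ndarray
    names: dict[int, str]
    affine: np.ndarray = field(default_factory=lambda: np.diag([3.0, 3.0, 3.0, 1.0]))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3-D integer grid")
        codes = self.codes
        missing = [c for c in codes if c not in self.names]
        if missing:
            raise ValueError(f"atlas codes without names: {missing}")
        vals = [self.names[c] for c in codes]
        if len(set(vals)) != len(vals):
            raise ValueError("region names must be unique")

    @property
    def codes(self) -> list[int]:
        return [int(c) for c in np.unique(self.labels) if c != 0]

    @property
    def n_regions(self) -> int:
        return len(self.codes)

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def name_of(self, code: int) -> str:
        return self.names.get(int(code), "background")


@dataclass
class SubjectRecord:
    """One synthetic subject: metadata, pain trace, and functional runs."""

    id: str
    sex: str  # "female" | "male"
    surgery: bool
    trace: PainTrace
    runs: list[BoldRun]
    motion_trace: PainTrace | None = None  # replayed cursor during motion tracking

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        kinds = [r.session for r in self.runs]
        if kinds.count("tracking") != 1:
            raise ValueError("exactly one tracking run required")
        if kinds.count("resting") > 1 or kinds.count("motion_tracking") > 1:
            raise ValueError("at most one resting and one motion_tracking run")

    def run(self, session: str) -> BoldRun:
        for r in self.runs:
            if r.session == session:
                return r
        raise KeyError(f"subject {self.id} has no {session} run")

    def has_run(self, session: str) -> bool:
        return any(r.session == session for r in self.runs)


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults are the desk-scale conditions used throughout the test suite:
    a 26x12x12 grid at 3 mm isotropic holding 16 disjoint 4x4x4 ROI blocks
    separated by background, TR 1.98 s, a 480 s tracking run, a 300 s
    resting run, and 12 subjects with signal planted in three regions.
    """

    n_subjects: int = 12
    shape: tuple[int, int, int] = (26, 12, 12)
    n_regions: int = 16
    tr: float = 1.98
    tracking_s: float = 480.0
    resting_s: float = 300.0
    motion_s: float = 480.0
    include_motion: bool = True
    planted_rois: tuple[int, ...] = (3, 8, 13)
    # planted coupling in noise-SD units per 10 VAS. The default keeps the
    # decoders on the steep part of their accuracy-vs-SNR curve (where the
    # occlusion analysis is informative); a planted voxel then correlates
    # with the HRF-convolved ratings at r ~ 0.2-0.3, a moderately
    # pain-correlated voxel by the standards of published percept-fMRI maps
    amplitude: float = 0.25
    ar1: float = 0.4                # AR(1) coefficient of temporal noise
    noise_sigma: float = 1.0
    drift_amplitude: float = 0.5    # low-frequency (<0.01 Hz) sinusoidal drift
    motion_amplitude: float = 0.3   # leak of the 6 motion courses into voxels
    female_fraction: float = 25 / 39
    surgery_fraction: float = 20 / 39
    resting_rho: float = 0.7        # corr(latent resting pain, tracking mean)
    # rating-trace dynamics: pain fluctuations are paroxysm-driven, so that
    # threshold crossings happen on 10-100 s timescales (inside the analysis
    # band) rather than through very slow baseline drift
    paroxysm_rate_low: float = 0.015   # events / s, per-subject uniform draw
    paroxysm_rate_high: float = 0.030
    spike_amp_low: float = 25.0        # VAS, per-subject uniform draw of the
    spike_amp_high: float = 45.0       # mean paroxysm amplitude
    walk_sigma: float = 0.15        # baseline random-walk step SD (VAS units)
    spike_amp_mean: float = 35.0
    spike_tau_s: float = 12.0
    baseline_low: float = 6.0
    baseline_high: float = 9.0
    seed: int = 0

    def validate(self, atlas: Atlas | None = None) -> None:
        if self.n_subjects < 8:
            raise ValueError("n_subjects must be >= 8 (fold construction needs >= 8)")
        if self.tr <= 0 or self.tracking_s <= 0 or self.resting_s <= 0:
            raise ValueError("tr and run durations must be positive")
        if atlas is not None:
            bad = set(self.planted_rois) - set(atlas.codes)
            if bad:
                raise ValueError(f"planted region codes absent from atlas: {sorted(bad)}")


def make_block_atlas(
    shape: tuple[int, int, int] = (26, 12, 12),
    n_regions: int = 16,
    block: int = 4,
    gap: int = 3,
    names: Sequence[str] | None = None,
    voxel_mm: float = 3.0,
) -> Atlas:
    """Lay out ``n_regions`` cubic ROI blocks on a lattice inside ``shape``.

    Blocks are separated by ``gap`` background voxels so that regions are
    never face/edge/corner adjacent; with the default 2-voxel gap a
    connected-component labelling cannot merge clusters across regions even
    through a single stray suprathreshold background voxel.
    """
    pitch = block + gap
    cap = [max(1, (s + gap) // pitch) for s in shape]
    # choose lattice dims (nx, ny, nz) covering n_regions, greedy along x
    nx = min(cap[0], n_regions)
    ny = min(cap[1], int(np.ceil(n_regions / nx)))
    nz = int(np.ceil(n_regions / (nx * ny)))
    if nz > cap[2]:
        raise ValueError(f"cannot fit {n_regions} blocks of {block}^3 into grid {shape}")
    labels = np.zeros(shape, dtype=np.int32)
    # even origins: every block then occupies the same phase of a stride-2
    # downsampling grid, so no region is systematically attenuated by the
    # decoder's pooling geometry
    offs = [(s - (n * pitch - gap)) // 2 for s, n in zip(shape, (nx, ny, nz))]
    offs = [o - o % 2 for o in offs]
    code = 0
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                if code >= n_regions:
                    break
                code += 1
                x0 = offs[0] + i * pitch
                y0 = offs[1] + j * pitch
                z0 = offs[2] + k * pitch
                labels[x0:x0 + block, y0:y0 + block, z0:z0 + block] = code
    base = list(names) if names is not None else DEFAULT_REGION_NAMES
    table = {}
    for c in range(1, n_regions + 1):
        nm = base[(c - 1) % len(base)]
        if n_regions > len(base):
            nm = f"{nm}_{(c - 1) // len(base) + 1}"
        table[c] = nm
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return Atlas(labels=labels, names=table, affine=affine)


def generate_trace(
    duration_s: float,
    tr: float,
    paroxysm_rate: float = 0.02,
    seed: int | np.random.Generator = 0,
    *,
    baseline_start: float | None = None,
    walk_sigma: float = 1.0,
    spike_amp_mean: float = 35.0,
    spike_tau_s: float = 12.0,
    subject_id: str = "sim",
) -> PainTrace:
    """Simulate a spontaneous pain rating trace.

    The model is a reflected random walk (slow baseline drift on the 0-100
    scale) plus paroxysms: sharp transients decaying with time constant
    ``spike_tau_s``, whose onsets follow a regularized renewal process
    (Gamma-distributed inter-event intervals with mean 1/rate) and whose
    amplitudes are Gamma distributed with mean ``spike_amp_mean``. The
    renewal regularity keeps the fraction of time spent in high pain from
    varying wildly between runs of equal length.
    """
    if duration_s <= 0 or tr <= 0:
        raise ValueError("duration_s and tr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(np.floor(duration_s / tr)) + 1
    times = np.arange(n) * tr
    if baseline_start is None:
        baseline_start = rng.uniform(5.0, 15.0)
    # reflected random walk in [0, 100]
    steps = rng.normal(0.0, walk_sigma, size=n - 1) if walk_sigma > 0 else np.zeros(n - 1)
    base = np.empty(n)
    base[0] = float(np.clip(baseline_start, 0.0, 100.0))
    for i in range(1, n):
        v = base[i - 1] + steps[i - 1]
        v = abs(v)  # reflect at 0
        if v > 100:
            v = 200 - v  # reflect at 100
        base[i] = float(np.clip(v, 0.0, 100.0))
    # paroxysm onsets: Gamma(shape=4) renewal intervals, mean 1/rate
    events = np.zeros(n)
    if paroxysm_rate > 0:
        shape = 4.0
        t = rng.gamma(shape, 1.0 / (paroxysm_rate * shape))
        while t < duration_s:
            idx = int(t / tr)
            if idx < n:
                events[idx] += rng.gamma(shape, spike_amp_mean / shape)
            t += rng.gamma(shape, 1.0 / (paroxysm_rate * shape))
    decay = np.exp(-tr / spike_tau_s)
    spikes = lfilter([1.0], [1.0, -decay], events)
    ratings = np.clip(base + spikes, 0.0, 100.0)
    return PainTrace(subject_id=subject_id, times=times, ratings=ratings)


def _ar1_noise(rng: np.random.Generator, phi: float, sigma: float,
               shape: tuple[int, ...]) -> np.ndarray:
    """AR(1) noise along the last axis with stationary SD ``sigma``."""
    e = rng.standard_normal(shape).astype(np.float32)
    if phi != 0.0:
        e = lfilter([1.0], [1.0, -phi], e, axis=-1).astype(np.float32)
        e *= np.sqrt(1.0 - phi**2)
    return e * sigma


def _motion_courses(rng: np.random.Generator, n_t: int) -> np.ndarray:
    """Six standardized random-walk head-motion courses (3 transl, 3 rot)."""
    m = np.cumsum(rng.standard_normal((n_t, 6)), axis=0)
    m -= m.mean(axis=0)
    m /= m.std(axis=0) + 1e-12
    return m


def _hrf_regressor(trace: PainTrace, tr: float, n_t: int) -> np.ndarray:
    """HRF-convolved rating in units of 10 VAS (kernel normalized to sum 1),
    so the planted coupling preserves the subject's physical rating scale."""
    # local import: correlation module owns the canonical HRF
    from .correlation import canonical_hrf

    t = (np.arange(n_t) + 0.5) * tr
    resampled = trace.resample(t)
    kernel = canonical_hrf(tr).kernel
    reg = np.convolve(resampled, kernel / kernel.sum())[:n_t]
    return reg / 10.0


def _synth_run(
    rng: np.random.Generator,
    cfg: CohortConfig,
    atlas: Atlas,
    session: str,
    n_t: int,
    coupled_trace: PainTrace | None,
) -> BoldRun:
    """Simulate one run. Voxels outside the brain mask stay at zero, as in
    skull-stripped normalized data; brain voxels carry AR(1) noise, slow
    drift, a leak of the motion courses, and (in coupled sessions) the
    HRF-convolved rating signal inside the planted regions."""
    shape = tuple(cfg.shape)
    brain = atlas.brain_mask()
    n_vox = int(brain.sum())
    vox = _ar1_noise(rng, cfg.ar1, cfg.noise_sigma, (n_vox, n_t))
    # slow sinusoidal drift, frequency < 0.01 Hz, random phase per voxel
    t = np.arange(n_t) * cfg.tr
    f = rng.uniform(0.002, 0.008, size=n_vox)
    phase = rng.uniform(0, 2 * np.pi, size=n_vox)
    vox += (cfg.drift_amplitude *
            np.sin(2 * np.pi * f[:, None] * t[None, :] + phase[:, None])).astype(np.float32)
    # motion leak
    motion = _motion_courses(rng, n_t)
    loadings = rng.normal(0.0, cfg.motion_amplitude / np.sqrt(6), size=(n_vox, 6))
    vox += (loadings @ motion.T).astype(np.float32)
    if coupled_trace is not None and cfg.amplitude != 0.0:
        reg = _hrf_regressor(coupled_trace, cfg.tr, n_t).astype(np.float32)
        planted = np.isin(atlas.labels[brain], list(cfg.planted_rois))
        vox[planted] += cfg.amplitude * reg
    vox += 100.0  # mean BOLD level inside the brain
    data = np.zeros(shape + (n_t,), dtype=np.float32)
    data[brain] = vox
    return BoldRun(data=data, tr=cfg.tr, affine=atlas.affine.copy(),
                   session=session, nuisance=motion)


def generate_subject(
    config: CohortConfig,
    atlas: Atlas,
    subject_id: str,
    seed: int | np.random.Generator,
    *,
    sex: str = "female",
    surgery: bool = False,
    include_motion: bool | None = None,
) -> SubjectRecord:
    """Generate one subject: trace, tracking/resting(/motion) runs.

    The resting run is driven by a latent "ongoing pain" trace whose baseline
    is correlated (``config.resting_rho``) with the subject's mean tracking
    rating; the motion-tracking run replays the tracking cursor but its BOLD
    has zero planted coupling.
    """
    config.validate(atlas)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if include_motion is None:
        include_motion = config.include_motion

    # subject-specific paroxysm rate and amplitude: the between-subject
    # drivers of mean pain level (and of the high-pain time fraction)
    rate = rng.uniform(config.paroxysm_rate_low, config.paroxysm_rate_high)
    amp = rng.uniform(config.spike_amp_low, config.spike_amp_high)
    trace = generate_trace(
        config.tracking_s, config.tr, rate, rng,
        walk_sigma=config.walk_sigma, spike_amp_mean=amp,
        spike_tau_s=config.spike_tau_s, subject_id=subject_id,
        baseline_start=rng.uniform(config.baseline_low, config.baseline_high),
    )
    n_track = int(np.floor(config.tracking_s / config.tr))
    n_rest = int(np.floor(config.resting_s / config.tr))
    runs = [_synth_run(rng, config, atlas, "tracking", n_track, trace)]

    # latent resting ("ongoing") pain: a paroxysm rate correlated with the
    # subject's tracking-session rate, so that resting pain predicted by a
    # decoder should correlate with tracking pain across subjects
    mu_r = 0.5 * (config.paroxysm_rate_low + config.paroxysm_rate_high)
    sd_r = (config.paroxysm_rate_high - config.paroxysm_rate_low) / np.sqrt(12.0)
    rho = config.resting_rho
    latent_rate = (mu_r + rho * (rate - mu_r)
                   + np.sqrt(max(0.0, 1 - rho**2)) * sd_r * rng.standard_normal())
    latent_rate = float(np.clip(latent_rate, 0.0, 2 * config.paroxysm_rate_high))
    rest_trace = generate_trace(
        config.resting_s, config.tr, latent_rate, rng,
        walk_sigma=config.walk_sigma, spike_amp_mean=amp,
        spike_tau_s=config.spike_tau_s, subject_id=subject_id,
        baseline_start=rng.uniform(config.baseline_low, config.baseline_high),
    )
    runs.append(_synth_run(rng, config, atlas, "resting", n_rest, rest_trace))

    motion_trace = None
    if include_motion:
        n_mot = int(np.floor(config.motion_s / config.tr))
        # replayed cursor: the subject's own earlier rating trace
        n_keep = min(len(trace.times), int(np.floor(config.motion_s / config.tr)) + 1)
        motion_trace = PainTrace(subject_id=subject_id,
                                 times=trace.times[:n_keep].copy(),
                                 ratings=trace.ratings[:n_keep].copy())
        runs.append(_synth_run(rng, config, atlas, "motion_tracking", n_mot, None))

    return SubjectRecord(id=subject_id, sex=sex, surgery=surgery, trace=trace,
                         runs=runs, motion_trace=motion_trace)


def generate_cohort(config: CohortConfig) -> tuple[list[SubjectRecord], Atlas]:
    """Generate the full cohort with randomized sex / prior-surgery labels.

    Counts follow the configured proportions (defaults reproduce 25 female /
    14 male and 20 surgery / 19 non-surgery at n=39).
    """
    config.validate()
    atlas = make_block_atlas(tuple(config.shape), config.n_regions)
    config.validate(atlas)
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_female = int(round(n * config.female_fraction))
    n_surgery = int(round(n * config.surgery_fraction))
    sex = np.array(["female"] * n_female + ["male"] * (n - n_female))
    surgery = np.array([True] * n_surgery + [False] * (n - n_surgery))
    rng.shuffle(sex)
    rng.shuffle(surgery)
    subjects = []
    for i in range(n):
        sid = f"sub-{i + 1:03d}"
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        subjects.append(generate_subject(config, atlas, sid, sub_rng,
                                         sex=str(sex[i]), surgery=bool(surgery[i])))
    return subjects, atlas


def config_from_dict(d: dict) -> CohortConfig:
    """Build a CohortConfig from a plain dict (e.g. parsed YAML)."""
    fields = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("shape", "planted_rois"):
        if key in d:
            d[key] = tuple(d[key])
    return CohortConfig(**d)
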