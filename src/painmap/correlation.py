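"""HRF-convolved correlation mapping of continuous pain ratings.

The percept-related branch of the pipeline: the subject's 0-100 rating trace
is convolved with a canonical double-gamma hemodynamic response function,
correlated with every voxel's BOLD time course, Fisher-transformed, and the
per-subject z maps are combined with a voxelwise one-sample t test. Signed
suprathreshold clusters (p < alpha, >= min_voxels, 26-connected by default)
are reported as region-named rows with peak coordinates and volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.special import gammaln

from .cohort import Atlas, BoldRun, PainTrace, volume_times

__all__ = [
    "Hrf", "CorrelationMap", "GroupMap", "ClusterRow",
    "canonical_hrf", "convolve_trace", "subject_correlation_map",
    "fisher_z", "group_map", "extract_clusters", "distinct_regions",
    "PainCorrelationAnalysis",
]


@dataclass(frozen=True)
class Hrf:
    """Sampled hemodynamic response kernel with its shape parameters."""

    kernel: np.ndarray
    tr: float
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        object.__setattr__(self, "kernel", k)
        if k.ndim != 1 or len(k) < 1 or not np.all(np.isfinite(k)):
            raise ValueError("kernel must be a finite 1-D array")
        if k.sum() <= 0:
            raise ValueError("kernel must sum to a positive value")


def _gamma_pdf(t: np.ndarray, shape: float, scale: float = 1.0) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos] / scale
    out[pos] = np.exp((shape - 1) * np.log(tp) - tp - gammaln(shape)) / scale
    return out


def canonical_hrf(tr: float, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  undershoot_ratio: float = 1.0 / 6.0, length_s: float = 32.0) -> Hrf:
    """Canonical double-gamma HRF sampled at the repetition time.

    h(t) = Gamma(peak_delay, 1).pdf(t) - ratio * Gamma(undershoot_delay, 1).pdf(t),
    over t in [0, length_s). With the defaults the positive lobe peaks near
    5-6 s and a shallow undershoot follows around 16 s.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, length_s, tr)
    kernel = _gamma_pdf(t, peak_delay) - undershoot_ratio * _gamma_pdf(t, undershoot_delay)
    return Hrf(kernel=kernel, tr=tr, peak_delay=peak_delay,
               undershoot_delay=undershoot_delay,
               undershoot_ratio=undershoot_ratio, length_s=length_s)


def convolve_trace(trace: PainTrace, hrf: Hrf, run: BoldRun) -> np.ndarray:
    """HRF-convolved rating regressor sampled at the run's volume times.

    The trace is first linearly resampled at the volume acquisition
    mid-times, then causally convolved with the kernel and truncated to the
    run length.
    """
    t = volume_times(run)
    if trace.times[-1] < t[-1] - run.tr:
        raise ValueError(
            f"trace ends at {trace.times[-1]:.2f} s but run extends to {t[-1]:.2f} s")
    resampled = trace.resample(t)
    return np.convolve(resampled, hrf.kernel)[: run.n_volumes]


@dataclass
class CorrelationMap:
    """Per-voxel Pearson r (and Fisher z) for one subject."""

    r: np.ndarray
    subject_id: str
    flat_voxels: np.ndarray = field(default=None)  # zero-variance voxel mask

    def __post_init__(self) -> None:
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("|r| must not exceed 1")
        if self.flat_voxels is None:
            self.flat_voxels = np.zeros(self.r.shape, dtype=bool)

    @property
    def z(self) -> np.ndarray:
        return fisher_z(self.r)


def subject_correlation_map(run: BoldRun, regressor: np.ndarray,
                            subject_id: str = "") -> CorrelationMap:
    """Pearson correlation of the regressor with every voxel's time course.

    Voxels with zero temporal variance get r = 0 and are flagged.
    """
    reg = np.asarray(regressor, dtype=float)
    if reg.ndim != 1 or len(reg) != run.n_volumes:
        raise ValueError("regressor length must match the run's t-dimension")
    sr = reg.std()
    if sr == 0:
        raise ValueError("regressor has zero variance")
    n_t = run.n_volumes
    flat = run.data.reshape(-1, n_t).astype(float)
    xc = flat - flat.mean(axis=1, keepdims=True)
    yc = reg - reg.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    flatmask = sx == 0
    denom = np.where(flatmask, 1.0, sx * sy)
    r = (xc @ yc) / denom
    r[flatmask] = 0.0
    r = np.clip(r, -1.0, 1.0).reshape(run.spatial_shape)
    return CorrelationMap(r=r, subject_id=subject_id,
                          flat_voxels=flatmask.reshape(run.spatial_shape))


_R_CLAMP = 1.0 - 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher transform z = atanh(r); |r| = 1 is clamped to atanh(1 - 1e-7)."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise ValueError("|r| must not exceed 1")
    z = np.arctanh(np.clip(arr, -_R_CLAMP, _R_CLAMP))
    return float(z) if np.isscalar(r) else z


@dataclass
class GroupMap:
    """Voxelwise one-sample t statistics of Fisher z across subjects."""

    t: np.ndarray
    p: np.ndarray
    n_subjects: int
    degenerate: np.ndarray = field(default=None)  # zero-variance voxels, p forced to 1

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(self.t.shape, dtype=bool)


def group_map(maps: list[CorrelationMap]) -> GroupMap:
    """One-sample t test of per-subject Fisher z against zero, per voxel."""
    if len(maps) < 3:
        raise ValueError("group analysis needs at least 3 subjects")
    shapes = {m.r.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("all subject maps must share one grid")
    z = np.stack([m.z for m in maps])  # (n, x, y, z)
    n = z.shape[0]
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    # zero between-subject variance: identical nonzero z is overwhelming
    # evidence (t -> inf); identical zero z carries none (p = 1)
    null_deg = degenerate & (mean == 0)
    t[null_deg] = 0.0
    p[null_deg] = 1.0
    t[degenerate & ~null_deg] = np.sign(mean[degenerate & ~null_deg]) * np.inf
    p[degenerate & ~null_deg] = 0.0
    return GroupMap(t=t, p=p, n_subjects=n, degenerate=degenerate)


@dataclass
class ClusterRow:
    """One suprathreshold cluster, in the style of a published cluster table."""

    region: str
    peak_mm: tuple[float, float, float]
    volume_voxels: int
    volume_mm3: float
    peak_t: float
    sign: str  # "positive" | "negative"


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_clusters(group: GroupMap, atlas: Atlas, alpha: float = 0.05,
                     min_voxels: int = 10, sign: str = "positive",
                     connectivity: int = 26) -> list[ClusterRow]:
    """Signed suprathreshold clusters with peak location and region name.

    Voxels with p < alpha and the requested t sign are grouped by
    26-connected (configurable) component labelling; components smaller than
    ``min_voxels`` are discarded. Each surviving cluster is reported at its
    max-|t| voxel, mapped to mm via the atlas affine and named by the atlas
    code at the peak.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    mask = (group.p < alpha) & ((group.t > 0) if sign == "positive" else (group.t < 0))
    labelled, n_comp = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    voxel_mm3 = float(abs(np.linalg.det(atlas.affine[:3, :3])))
    rows: list[ClusterRow] = []
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labelled == comp)
        if len(idx) < min_voxels:
            continue
        tvals = np.abs(group.t[tuple(idx.T)])
        peak = idx[int(np.argmax(tvals))]
        peak_t = float(group.t[tuple(peak)])
        mm = atlas.affine @ np.append(peak, 1.0)
        code = int(atlas.labels[tuple(peak)])
        rows.append(ClusterRow(
            region=atlas.name_of(code),
            peak_mm=tuple(float(v) for v in mm[:3]),
            volume_voxels=int(len(idx)),
            volume_mm3=len(idx) * voxel_mm3,
            peak_t=peak_t,
            sign=sign,
        ))
    rows.sort(key=lambda r: -abs(r.peak_t))
    return rows


def distinct_regions(pos: list[ClusterRow], neg: list[ClusterRow]) -> set[str]:
    """Union of region names across both signs; a region counts once."""
    return {row.region for row in pos} | {row.region for row in neg}


class PainCorrelationAnalysis:
    """Full correlation branch: convolve, correlate, Fisher, group test, clusters.

    Parameters
    ----------
    alpha : voxelwise two-sided p threshold (uncorrected by default).
    min_voxels : minimum cluster extent.
    connectivity : 6, 18 or 26 for cluster component labelling.
    fdr : if True, apply Benjamini-Hochberg across brain voxels instead of
        the uncorrected threshold (off by default).
    """

    def __init__(self, alpha: float = 0.05, min_voxels: int = 10,
                 connectivity: int = 26, fdr: bool = False):
        self.alpha = alpha
        self.min_voxels = min_voxels
        self.connectivity = connectivity
        self.fdr = fdr

    def fit(self, runs: list[BoldRun], traces: list[PainTrace], atlas: Atlas):
        if len(runs) != len(traces):
            raise ValueError("one trace per run required")
        maps = []
        for run, trace in zip(runs, traces):
            hrf = canonical_hrf(run.tr)
            reg = convolve_trace(trace, hrf, run)
            maps.append(subject_correlation_map(run, reg, subject_id=trace.subject_id))
        self.subject_maps_ = maps
        gm = group_map(maps)
        if self.fdr:
            from statsmodels.stats.multitest import multipletests

            brain = atlas.brain_mask()
            pvec = gm.p[brain]
            adj = multipletests(pvec, method="fdr_bh")[1]
            padj = np.ones_like(gm.p)
            padj[brain] = adj
            gm = GroupMap(t=gm.t, p=padj, n_subjects=gm.n_subjects,
                          degenerate=gm.degenerate)
        self.group_map_ = gm
        self.positive_clusters_ = extract_clusters(
            gm, atlas, self.alpha, self.min_voxels, "positive", self.connectivity)
        self.negative_clusters_ = extract_clusters(
            gm, atlas, self.alpha, self.min_voxels, "negative", self.connectivity)
        self.regions_ = distinct_regions(self.positive_clusters_,
                                         self.negative_clusters_)
        return self
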