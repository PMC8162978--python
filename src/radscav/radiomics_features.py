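"""Radiomic feature extraction from a segmented tumor volume.

Implements the feature families used throughout the pipeline —
histogram order statistics, grey-level size-zone (GLSZM) and run-length
(GLRLM) texture, Laws and wavelet energies, and eigenvalue-based shape
descriptors — with community-standard (IBSI-style) formulas stated in
the docstrings. Feature names are stable, so repeated extraction of the
same volume yields identical :class:`FeatureVector` rows.

Grey levels are discretized inside the mask with equal-width bins
(default 32 levels) before any texture matrix is built, which makes all
texture features invariant to intensity shifts.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pywt
from scipy.ndimage import correlate1d
from skimage import measure

from .datatypes import TumorVolume

__all__ = [
    "TextureMatrix",
    "quantize",
    "glszm",
    "glszm_features",
    "glrlm",
    "glrlm_gln",
    "laws_energy_3d",
    "wavelet_energy_3d",
    "shape_features",
    "histogram_features",
    "extract_all",
    "FEATURE_FAMILIES",
]

#: the five 1D Laws kernels (level, edge, spot, ripple, wave)
LAWS_KERNELS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
}


@dataclasses.dataclass
class TextureMatrix:
    """Grey level x (zone size | run length) count matrix.

    Row index ``g-1`` holds grey level ``g``; column index ``s-1``
    holds zone size / run length ``s``.
    """

    counts: np.ndarray  # (n_levels, max size/length), nonnegative ints
    n_levels: int
    kind: str  # "GLSZM" | "GLRLM"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.min() < 0 or self.counts.sum() < 1:
            raise ValueError("texture matrix must be nonnegative with total >= 1")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def quantize(volume: TumorVolume, n_levels: int = 32) -> np.ndarray:
    """Equal-width discretization of masked intensities into 1..n_levels.

    Bins cover ``[min, max]`` inside the mask; a constant region maps
    entirely to level 1. Voxels outside the mask are 0.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    vals = volume.intensities[volume.mask]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(volume.intensities.shape, dtype=np.int64)
    if hi == lo:
        q[volume.mask] = 1
        return q
    levels = np.floor(n_levels * (vals - lo) / (hi - lo)).astype(np.int64) + 1
    q[volume.mask] = np.minimum(levels, n_levels)
    return q


def _connectivity_rank(connectivity: int, ndim: int) -> int:
    if ndim == 2 and connectivity == 8:
        return 2
    if ndim == 3 and connectivity == 26:
        return 3
    raise ValueError(f"connectivity {connectivity} invalid for {ndim}D (use 8/2D or 26/3D)")


def glszm(quantized: np.ndarray, mask: np.ndarray, connectivity: int | None = None) -> TextureMatrix:
    """Grey-level size-zone matrix.

    Entry ``(g, s)`` counts the connected zones (8-connected in 2D,
    26-connected in 3D) of grey level ``g`` and size ``s`` voxels; the
    matrix total is the number of zones.
    """
    quantized = np.asarray(quantized)
    mask = np.asarray(mask, bool)
    if quantized.shape != mask.shape:
        raise ValueError("quantized grid and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    if connectivity is None:
        connectivity = 8 if quantized.ndim == 2 else 26
    rank = _connectivity_rank(connectivity, quantized.ndim)
    n_levels = int(quantized[mask].max())
    zones: list[tuple[int, int]] = []
    for g in range(1, n_levels + 1):
        lab, n_comp = measure.label(
            (quantized == g) & mask, connectivity=rank, return_num=True
        )
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    counts = np.zeros((n_levels, max_size), dtype=np.int64)
    for g, s in zones:
        counts[g - 1, s - 1] += 1
    return TextureMatrix(counts, n_levels, "GLSZM")


def glszm_features(m: TextureMatrix) -> dict[str, float]:
    """Grey-level variance, small-zone low-grey-level emphasis, GLN.

    With ``p(g,s) = counts(g,s) / N_z``:

    * ``GLV   = sum p(g,s) (g - mu)^2`` with ``mu = sum p(g,s) g``
    * ``SZLGE = sum p(g,s) / (g^2 s^2)``
    * ``GLN   = sum_g (sum_s counts(g,s))^2 / N_z``
    """
    n_z = m.total
    g = np.arange(1, m.counts.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, m.counts.shape[1] + 1, dtype=float)[None, :]
    p = m.counts / n_z
    mu = float((p * g).sum())
    return {
        "glszm_grey_level_variance": float((p * (g - mu) ** 2).sum()),
        "glszm_small_zone_low_grey_level_emphasis": float((p / (g**2 * s**2)).sum()),
        "glszm_grey_level_non_uniformity": float((m.counts.sum(axis=1).astype(float) ** 2).sum() / n_z),
    }


def _directions(ndim: int) -> list[tuple[int, ...]]:
    """Unique run directions up to sign: 4 in 2D, 13 in 3D."""
    dirs = []
    for d in itertools.product((-1, 0, 1), repeat=ndim):
        if d == (0,) * ndim:
            continue
        if d > (0,) * ndim:  # keep one representative of each +/- pair
            dirs.append(d)
    return dirs


def glrlm(quantized: np.ndarray, mask: np.ndarray, direction: tuple[int, ...]) -> TextureMatrix:
    """Grey-level run-length matrix for one direction.

    A run is a maximal straight sequence of masked voxels sharing one
    grey level; gaps in the mask break runs.
    """
    quantized = np.asarray(quantized)
    mask = np.asarray(mask, bool)
    if quantized.shape != mask.shape:
        raise ValueError("quantized grid and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    d = np.asarray(direction, int)
    shape = np.asarray(quantized.shape)

    coords = np.argwhere(mask)
    prev = coords - d
    inb = np.all((prev >= 0) & (prev < shape), axis=1)
    prev_same = np.zeros(len(coords), bool)
    if inb.any():
        pt = tuple(prev[inb].T)
        ct = tuple(coords[inb].T)
        prev_same[inb] = mask[pt] & (quantized[pt] == quantized[ct])
    starts = coords[~prev_same]
    levels = quantized[tuple(starts.T)]

    lengths = np.ones(len(starts), dtype=np.int64)
    cur = starts.copy()
    active = np.arange(len(starts))
    while active.size:
        nxt = cur[active] + d
        inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
        goes_on = np.zeros(active.size, bool)
        if inb.any():
            nt = tuple(nxt[inb].T)
            goes_on[inb] = mask[nt] & (quantized[nt] == levels[active[inb]])
        cont = active[goes_on]
        lengths[cont] += 1
        cur[cont] = nxt[goes_on]
        active = cont

    n_levels = int(quantized[mask].max())
    counts = np.zeros((n_levels, int(lengths.max())), dtype=np.int64)
    np.add.at(counts, (levels - 1, lengths - 1), 1)
    return TextureMatrix(counts, n_levels, "GLRLM")


def glrlm_gln(quantized: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Run-length grey-level non-uniformity, averaged over directions.

    Per direction ``GLN = sum_g (sum_r counts(g,r))^2 / N_runs``; the
    feature is the mean over the 4 (2D) or 13 (3D) unique directions.
    """
    glns = []
    for d in _directions(np.asarray(quantized).ndim):
        m = glrlm(quantized, mask, d)
        per_level = m.counts.sum(axis=1).astype(float)
        glns.append((per_level**2).sum() / m.total)
    return {"glrlm_avg_gln": float(np.mean(glns))}


def laws_energy_3d(volume: TumorVolume) -> dict[str, float]:
    """All 125 separable 5x5x5 Laws texture energies.

    Each energy is the mean absolute response over masked voxels of one
    outer product of the 1D kernels {L5, E5, S5, R5, W5}, applied
    separably with reflective boundaries.
    """
    if any(s < 5 for s in volume.intensities.shape):
        raise ValueError("volume must be at least 5 voxels per axis")
    out: dict[str, float] = {}
    mask = volume.mask
    # cache single-axis passes to avoid recomputing shared prefixes
    pass0 = {k: correlate1d(volume.intensities, v, axis=0, mode="reflect") for k, v in LAWS_KERNELS.items()}
    for ka, a0 in pass0.items():
        pass1 = {k: correlate1d(a0, v, axis=1, mode="reflect") for k, v in LAWS_KERNELS.items()}
        for kb, a1 in pass1.items():
            for kc, vc in LAWS_KERNELS.items():
                resp = correlate1d(a1, vc, axis=2, mode="reflect")
                out[f"laws_{ka}{kb}{kc}"] = float(np.abs(resp[mask]).mean())
    return out


def _downsample_mask(mask: np.ndarray) -> np.ndarray:
    """Logical-OR 2x2x2 block reduction, padding odd axes with False."""
    pad = [(0, s % 2) for s in mask.shape]
    m = np.pad(mask, pad, constant_values=False)
    sx, sy, sz = (s // 2 for s in m.shape)
    return m.reshape(sx, 2, sy, 2, sz, 2).any(axis=(1, 3, 5))


def wavelet_energy_3d(volume: TumorVolume, wavelet: str = "haar") -> dict[str, float]:
    """One-level separable 3D wavelet decomposition, 8 subband energies.

    Subbands are named LLL..HHH (low/high per axis); the energy of a
    subband is the mean squared coefficient over the mask-covered
    region (mask block-reduced by the decimation factor).
    """
    if any(s < 2 for s in volume.intensities.shape):
        raise ValueError("every axis must span at least 2 voxels")
    coeffs = pywt.dwtn(volume.intensities, wavelet, mode="periodization")
    mask_ds = _downsample_mask(volume.mask)
    out: dict[str, float] = {}
    for key in sorted(coeffs):  # 'aaa', 'aad', ..., 'ddd'
        band = key.replace("a", "L").replace("d", "H")
        c = coeffs[key]
        region = c[mask_ds] if mask_ds.any() else c.ravel()
        out[f"wavelet_{band}_energy"] = float(np.mean(region**2))
    return out


def shape_features(volume: TumorVolume) -> dict[str, float]:
    """Eigenvalue shape descriptors of the segmented region.

    From the covariance eigenvalues l1 >= l2 >= l3 of the
    spacing-weighted voxel coordinates:

    * ``flatness = sqrt(l3 / l1)`` (1 for a sphere, -> 0 for a pancake)
    * ``asymmetry = 1 - sqrt(l2 / l1)`` computed on the 2D covariance of
      the largest-area axial slice (0 for a circular cross-section)
    * ``orientation_deg`` = angle in [0, 90] degrees between the major
      eigenvector and the z axis
    * ``surface_to_volume`` = mesh surface area (marching cubes) over
      mask volume, in physical units
    """
    mask = volume.mask
    if mask.sum() < 4:
        raise ValueError("mask must contain >= 4 voxels")
    spacing = np.asarray(volume.spacing)
    coords = np.argwhere(mask) * spacing
    cov = np.cov(coords.T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[-1] <= 0 or evals[0] < -1e-9:
        raise ValueError("degenerate mask: covariance is not positive")
    evals = np.clip(evals, 0.0, None)
    flatness = float(np.sqrt(evals[0] / evals[2]))
    major = evecs[:, 2]
    orientation = float(np.degrees(np.arccos(np.clip(abs(major[2]), 0.0, 1.0))))

    areas = mask.sum(axis=(0, 1))
    z_best = int(np.argmax(areas))
    sl = np.argwhere(mask[:, :, z_best]) * spacing[:2]
    if len(sl) < 2:
        asymmetry = 0.0
    else:
        ev2 = np.clip(np.linalg.eigvalsh(np.cov(sl.T)), 0.0, None)
        asymmetry = 0.0 if ev2[1] == 0 else float(1.0 - np.sqrt(ev2[0] / ev2[1]))

    padded = np.pad(mask, 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=volume.spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    vol = float(mask.sum()) * volume.voxel_volume
    return {
        "shape_flatness": flatness,
        "shape_asymmetry": asymmetry,
        "shape_orientation_deg": orientation,
        "shape_surface_to_volume": area / vol,
    }


def histogram_features(volume: TumorVolume) -> dict[str, float]:
    """Order statistics of the masked intensities.

    Percentiles use linear interpolation between closest ranks; the
    standard deviation is the population sd.
    """
    vals = volume.intensities[volume.mask]
    p10, p50, p90 = np.percentile(vals, [10, 50, 90])
    return {
        "hist_mean": float(vals.mean()),
        "hist_sd": float(vals.std()),
        "hist_p10": float(p10),
        "hist_p50": float(p50),
        "hist_p90": float(p90),
    }


FEATURE_FAMILIES = ("histogram", "glszm", "glrlm", "laws", "wavelet", "shape")


def extract_all(
    volume: TumorVolume, n_levels: int = 32, families: tuple[str, ...] = FEATURE_FAMILIES
) -> dict[str, float]:
    """One feature-table row: concatenation of all requested families."""
    unknown = set(families) - set(FEATURE_FAMILIES)
    if unknown:
        raise ValueError(f"unknown feature families {sorted(unknown)}")
    out: dict[str, float] = {}
    if "histogram" in families:
        out.update(histogram_features(volume))
    if "glszm" in families or "glrlm" in families:
        q = quantize(volume, n_levels)
        if "glszm" in families:
            out.update(glszm_features(glszm(q, volume.mask, 26)))
        if "glrlm" in families:
            out.update(glrlm_gln(q, volume.mask))
    if "laws" in families:
        out.update(laws_energy_3d(volume))
    if "wavelet" in families:
        out.update(wavelet_energy_3d(volume))
    if "shape" in families:
        out.update(shape_features(volume))
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values for {bad}")
    return out
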