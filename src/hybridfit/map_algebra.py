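"""Map arithmetic and comparison: scaling, difference and overlap maps,
threshold masks, real-space correlation, FSC, and mask elimination.

These are the primitives behind the three density-assignment approaches:
subunit deletion (difference maps), shared-subunit overlap, and assignment
of leftover density by elimination.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.fft
from scipy import ndimage

from .grids_io import DensityMap

__all__ = [
    "Mask",
    "FSCCurve",
    "scale_factor",
    "difference_map",
    "overlap_map",
    "threshold_mask",
    "real_space_cc",
    "fsc",
    "resolution_at",
    "eliminate",
    "jaccard",
]


class CongruenceError(ValueError):
    """Grids differ in shape, voxel size or origin."""


class UndefinedStatisticError(ValueError):
    """A scale or correlation is undefined (zero variance input)."""


def _check_congruent(a: DensityMap, b: DensityMap) -> None:
    if not a.congruent(b):
        raise CongruenceError(
            f"grids not congruent: {a.shape}/{b.shape}, "
            f"voxel {a.voxel_size}/{b.voxel_size}, origin {a.origin}/{b.origin}"
        )


@dataclasses.dataclass
class Mask:
    """Boolean field congruent with a parent map grid, with provenance."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def empty(self) -> bool:
        return not self.values.any()

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def __and__(self, other: "Mask") -> "Mask":
        return Mask(self.values & other.values, f"({self.provenance})&({other.provenance})")

    def __or__(self, other: "Mask") -> "Mask":
        return Mask(self.values | other.values, f"({self.provenance})|({other.provenance})")


def jaccard(a: Mask, b: Mask) -> float:
    """Jaccard index |a∩b| / |a∪b| of two congruent masks."""
    union = (a.values | b.values).sum()
    if union == 0:
        return 1.0
    return float((a.values & b.values).sum() / union)


@dataclasses.dataclass
class FSCCurve:
    """Fourier shell correlation: per-shell frequency, correlation, count."""

    frequency: np.ndarray  # shell centres, 1/Å, strictly increasing
    correlation: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")


def scale_factor(a: DensityMap, b: DensityMap) -> float:
    """Least-squares scale k minimizing ||k·a − b||²: k = Σab / Σa²."""
    _check_congruent(a, b)
    denom = float((a.values.astype(float) ** 2).sum())
    if denom == 0:
        raise UndefinedStatisticError("scale undefined for identically zero map")
    return float((a.values.astype(float) * b.values).sum() / denom)


def difference_map(holo: DensityMap, sub: DensityMap, scale: bool = True) -> DensityMap:
    """holo − k·sub with k the least-squares scale of sub onto holo.

    Scaling makes subunit-deletion differences robust to global intensity
    differences between independent reconstructions; pass ``scale=False``
    for maps already on a common scale.
    """
    _check_congruent(holo, sub)
    k = scale_factor(sub, holo) if scale else 1.0
    return holo.copy(values=holo.values - k * sub.values)


def overlap_map(a: DensityMap, b: DensityMap) -> DensityMap:
    """Voxelwise minimum of the sigma-normalized, nonnegativity-clipped maps.

    The minimum keeps density units and reads directly as the envelope the
    two reconstructions share — the density attributable to a common subunit.
    Symmetric in its arguments.
    """
    _check_congruent(a, b)
    an = np.clip(a.sigma_normalized().values, 0.0, None)
    bn = np.clip(b.sigma_normalized().values, 0.0, None)
    return a.copy(values=np.minimum(an, bn))


def threshold_mask(dmap: DensityMap, level_sigma: float = 1.0) -> Mask:
    """Mask of voxels whose sigma-normalized density exceeds ``level_sigma``."""
    if not np.isfinite(level_sigma):
        raise ValueError("level_sigma must be finite")
    norm = dmap.sigma_normalized().values
    return Mask(norm > level_sigma, provenance=f"threshold@{level_sigma}sigma")


def real_space_cc(a: DensityMap, b: DensityMap, mask: Mask | None = None) -> float:
    """Pearson correlation of two maps over masked voxels."""
    _check_congruent(a, b)
    if mask is None:
        sel = np.ones(a.shape, dtype=bool)
    else:
        if mask.values.shape != a.shape:
            raise CongruenceError("mask shape does not match maps")
        if mask.empty:
            raise ValueError("mask is empty")
        sel = mask.values
    x = a.values[sel].astype(float)
    y = b.values[sel].astype(float)
    x -= x.mean()
    y -= y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise UndefinedStatisticError("correlation undefined for constant map under mask")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def fsc(a: DensityMap, b: DensityMap, shell_width: float | None = None) -> FSCCurve:
    """Fourier shell correlation between two maps on congruent cubic grids.

    Per shell: Re(Σ F_a conj(F_b)) / sqrt(Σ|F_a|² Σ|F_b|²).  Shells are
    ``shell_width`` wide in spatial frequency (default: one Fourier voxel);
    shells with no reflections are skipped.
    """
    _check_congruent(a, b)
    if len(set(a.shape)) != 1 or len(set(np.round(a.voxel_size, 9))) != 1:
        raise ValueError("FSC requires a cubic grid with isotropic voxels")
    n = a.shape[0]
    vs = float(a.voxel_size[0])
    fa = scipy.fft.fftn(a.values.astype(float))
    fb = scipy.fft.fftn(b.values.astype(float))
    freq = scipy.fft.fftfreq(n, d=vs)
    s = np.sqrt(
        freq[:, None, None] ** 2 + freq[None, :, None] ** 2 + freq[None, None, :] ** 2
    )
    if shell_width is None:
        shell_width = 1.0 / (n * vs)
    nyquist = 0.5 / vs
    edges = np.arange(0.0, nyquist + shell_width, shell_width)
    which = np.digitize(s.ravel(), edges) - 1
    num = np.real(fa.conj() * fb).ravel()
    pa = np.abs(fa.ravel()) ** 2
    pb = np.abs(fb.ravel()) ** 2
    freqs, corr, count = [], [], []
    for i in range(len(edges) - 1):
        sel = which == i
        cnt = int(sel.sum())
        if cnt == 0:
            continue
        denom = np.sqrt(pa[sel].sum() * pb[sel].sum())
        c = 1.0 if denom == 0 else float(num[sel].sum() / denom)
        freqs.append(0.5 * (edges[i] + edges[i + 1]))
        corr.append(np.clip(c, -1.0, 1.0))
        count.append(cnt)
    return FSCCurve(np.array(freqs), np.array(corr), np.array(count))


def pad_to_cube(dmap: DensityMap) -> DensityMap:
    """Zero-pad a map symmetrically to a cubic box (for shell statistics)."""
    if len(set(np.round(dmap.voxel_size, 9))) != 1:
        raise ValueError("anisotropic voxels cannot be padded to a cube")
    n = max(dmap.shape)
    start = (np.array([n, n, n]) - dmap.shape) // 2
    values = np.zeros((n, n, n), dtype=dmap.values.dtype)
    values[
        start[0] : start[0] + dmap.shape[0],
        start[1] : start[1] + dmap.shape[1],
        start[2] : start[2] + dmap.shape[2],
    ] = dmap.values
    return DensityMap(
        values,
        dmap.voxel_size.copy(),
        dmap.origin - start * dmap.voxel_size,
        dmap.resolution,
    )


def resolution_at(curve: FSCCurve, threshold: float = 0.5) -> float:
    """Resolution d (Å) where the FSC first crosses below ``threshold``,
    linearly interpolated in frequency; inf if it never does at s=0 end,
    Nyquist shell resolution if it never drops."""
    f, c = curve.frequency, curve.correlation
    below = np.flatnonzero(c < threshold)
    if len(below) == 0:
        return float(1.0 / f[-1])
    i = below[0]
    if i == 0:
        return float(np.inf)
    # interpolate between shell i-1 (above) and i (below)
    f0, f1, c0, c1 = f[i - 1], f[i], c[i - 1], c[i]
    s_cross = f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1)
    return float(1.0 / s_cross)


def eliminate(holo_mask: Mask, assigned: list[Mask]) -> Mask:
    """Holo envelope minus the union of already-assigned masks."""
    left = holo_mask.values.copy()
    for m in assigned:
        if m.values.shape != left.shape:
            raise CongruenceError("assigned mask shape differs from holo mask")
        left &= ~m.values
    return Mask(left, provenance=f"eliminate({len(assigned)} assigned)")


def largest_component(mask: Mask) -> Mask:
    """Largest 6-connected component of a mask (empty stays empty)."""
    if mask.empty:
        return Mask(mask.values.copy(), provenance=mask.provenance + "|largest")
    lab, n = ndimage.label(mask.values)
    sizes = ndimage.sum_labels(mask.values, lab, index=np.arange(1, n + 1))
    best = 1 + int(np.argmax(sizes))
    return Mask(lab == best, provenance=mask.provenance + "|largest")
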