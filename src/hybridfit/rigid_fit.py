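"""Rigid-body placement of atomic models (or maps) into density.

A fit is scored by the masked real-space correlation between the map and a
density simulated from the transformed model at the map's nominal
resolution, over the model's own 1-sigma envelope (so empty regions do not
dilute the score).  The global search enumerates a deterministic
quasi-uniform rotation grid and finds the best translation per rotation by
FFT cross-correlation; a derivative-free simplex then refines the six
rigid-body degrees of freedom.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.fft
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .grids_io import AtomicModel, DensityMap
from .map_algebra import Mask, real_space_cc, threshold_mask
from .synth import SimulationSpec, simulate_map

__all__ = [
    "RigidTransform",
    "FitResult",
    "score_fit",
    "global_search",
    "local_refine",
    "align_maps",
    "resample_map",
    "coverage_report",
    "CoverageReport",
    "so3_grid",
]


class OutOfBoundsError(ValueError):
    """The transformed model does not lie inside the map box."""


@dataclasses.dataclass
class RigidTransform:
    """Rotation (unit quaternion, scalar-first) plus translation in Å.

    Acts on points as x' = R x + t.
    """

    quaternion: np.ndarray  # (w, x, y, z)
    translation: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternion, dtype=float).reshape(4)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-6:
            if n == 0:
                raise ValueError("zero quaternion")
            q = q / n
        self.quaternion = q
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]), np.zeros(3))

    @classmethod
    def from_rotation(cls, rot: Rotation, translation=np.zeros(3)) -> "RigidTransform":
        x, y, z, w = rot.as_quat()
        return cls(np.array([w, x, y, z]), translation)

    @classmethod
    def from_rotvec(cls, rotvec, translation=np.zeros(3)) -> "RigidTransform":
        return cls.from_rotation(Rotation.from_rotvec(rotvec), translation)

    # -- algebra ------------------------------------------------------
    @property
    def rotation(self) -> Rotation:
        w, x, y, z = self.quaternion
        return Rotation.from_quat([x, y, z, w])

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.matrix.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        r = self.rotation * other.rotation
        t = self.matrix @ other.translation + self.translation
        return RigidTransform.from_rotation(r, t)

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.inv()
        return RigidTransform.from_rotation(rinv, -rinv.as_matrix() @ self.translation)

    def angle_to(self, other: "RigidTransform") -> float:
        """Rotation-angle distance to another transform, degrees."""
        return float(np.degrees((self.rotation.inv() * other.rotation).magnitude()))

    def apply_model(self, model: AtomicModel) -> AtomicModel:
        return model.transformed(self.matrix, self.translation)


@dataclasses.dataclass
class FitResult:
    """One placement with its masked real-space CC and rank."""

    transform: RigidTransform
    score: float
    rank: int = 1
    converged: bool = True


# ---------------------------------------------------------------------------
# rotation sampling

def _sphere_points(spacing_rad: float) -> np.ndarray:
    """Deterministic quasi-uniform directions with mean spacing <= spacing."""
    n = max(int(np.ceil(4.0 * np.pi / spacing_rad**2)), 6)
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    th = golden * i
    return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)


def so3_grid(angular_step_deg: float) -> list[Rotation]:
    """Quasi-uniform rotation grid with spacing <= the requested step.

    Layered Hopf-style construction: a spherical Fibonacci set of axis
    directions (where the body z-axis is sent) times an evenly spaced
    in-plane spin.  Deterministic: the list order is fixed for a given step.
    """
    step = np.radians(angular_step_deg)
    dirs = _sphere_points(step)
    n_spin = max(int(np.ceil(2.0 * np.pi / step)), 2)
    spins = np.arange(n_spin) * (2.0 * np.pi / n_spin)
    # the Fibonacci sphere never hits the pole exactly, so the null rotation
    # would otherwise be missing from the grid; planted-identity problems
    # (and pure translations) must be recoverable exactly
    out: list[Rotation] = [Rotation.identity()]
    z = np.array([0.0, 0.0, 1.0])
    for u in dirs:
        # minimal rotation sending z to u
        v = np.cross(z, u)
        c = float(z @ u)
        if np.linalg.norm(v) < 1e-12:
            r_dir = Rotation.identity() if c > 0 else Rotation.from_rotvec([np.pi, 0, 0])
        else:
            angle = np.arctan2(np.linalg.norm(v), c)
            r_dir = Rotation.from_rotvec(v / np.linalg.norm(v) * angle)
        for psi in spins:
            out.append(r_dir * Rotation.from_rotvec(z * psi))
    return out


# ---------------------------------------------------------------------------
# rendering helpers (un-low-passed Gaussian splat, used for FFT search)

def _render(model: AtomicModel, dmap: DensityMap, sigma: float) -> np.ndarray:
    from .synth import atom_weights

    shape = dmap.shape
    voxel = dmap.voxel_size
    origin = dmap.origin
    values = np.zeros(shape, dtype=float)
    axes = [origin[a] + np.arange(shape[a]) * voxel[a] for a in range(3)]
    cutoff = 4.5 * sigma
    norm = 1.0 / ((2.0 * np.pi) ** 1.5 * sigma**3)
    for w, p in zip(atom_weights(model), model.positions):
        lo = np.maximum(np.floor((p - cutoff - origin) / voxel).astype(int), 0)
        hi = np.minimum(np.ceil((p + cutoff - origin) / voxel).astype(int) + 1, shape)
        if np.any(hi <= lo):
            continue
        dx = axes[0][lo[0] : hi[0]] - p[0]
        dy = axes[1][lo[1] : hi[1]] - p[1]
        dz = axes[2][lo[2] : hi[2]] - p[2]
        r2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (w * norm) * np.exp(
            -r2 / (2.0 * sigma**2)
        )
    return values


def _map_resolution(dmap: DensityMap, resolution: float | None) -> float:
    if resolution is not None:
        return float(resolution)
    if dmap.resolution is not None:
        return float(dmap.resolution)
    raise ValueError(
        "map has no nominal resolution recorded; pass resolution= explicitly"
    )


# ---------------------------------------------------------------------------
# scoring

def score_fit(
    model: AtomicModel,
    dmap: DensityMap,
    transform: RigidTransform,
    resolution: float | None = None,
) -> float:
    """Masked real-space CC of the transformed model against the map.

    The model is simulated on the map grid at the map's nominal resolution
    and correlated with the map over the model's own 1-sigma envelope.
    """
    d = _map_resolution(dmap, resolution)
    moved = transform.apply_model(model)
    lo = dmap.origin
    hi = dmap.origin + (np.array(dmap.shape) - 1) * dmap.voxel_size
    if np.any(moved.positions < lo - dmap.voxel_size) or np.any(
        moved.positions > hi + dmap.voxel_size
    ):
        raise OutOfBoundsError("transformed model lies outside the map box")
    spec = SimulationSpec(resolution=d, voxel_size=float(np.max(dmap.voxel_size)))
    sim = simulate_map(moved, spec, origin=dmap.origin, shape=dmap.shape)
    mask = threshold_mask(sim, 1.0)
    return real_space_cc(sim, dmap, mask)


# ---------------------------------------------------------------------------
# global search

def global_search(
    model: AtomicModel,
    dmap: DensityMap,
    angular_step_deg: float = 15.0,
    top_k: int = 10,
    resolution: float | None = None,
) -> list[FitResult]:
    """Exhaustive rotation grid + FFT translation search.

    For every rotation on the quasi-uniform grid the model (rotated about
    its centroid at the box centre) is splatted onto the map grid and the
    best integer-voxel translation found by FFT cross-correlation; the best
    candidates are re-scored with the masked CC and returned ranked.
    Deterministic: ties are broken by lower rotation index.
    """
    if not 5.0 <= angular_step_deg <= 60.0:
        raise ValueError("angular_step_deg must lie in [5, 60]")
    d = _map_resolution(dmap, resolution)
    sigma = 0.225 * d
    shape = np.array(dmap.shape)
    extent = model.positions.max(axis=0) - model.positions.min(axis=0)
    if np.any(extent >= shape * dmap.voxel_size):
        raise ValueError("map box smaller than the model footprint")
    center = dmap.origin + shape * dmap.voxel_size / 2.0
    c0 = model.centroid
    f_map = scipy.fft.fftn(dmap.values.astype(float))

    rotations = so3_grid(angular_step_deg)
    candidates: list[tuple[float, int, RigidTransform]] = []
    for ridx, rot in enumerate(rotations):
        R = rot.as_matrix()
        moved = model.transformed(R, center - R @ c0)
        g = _render(moved, dmap, sigma)
        corr = scipy.fft.ifftn(f_map * np.conj(scipy.fft.fftn(g))).real
        flat = int(np.argmax(corr))
        idx = np.array(np.unravel_index(flat, dmap.shape))
        idx = np.where(idx > shape // 2, idx - shape, idx)  # signed cyclic shift
        t = center - R @ c0 + idx * dmap.voxel_size
        candidates.append(
            (float(corr.flat[flat]), ridx, RigidTransform.from_rotation(rot, t))
        )

    candidates.sort(key=lambda c: (-c[0], c[1]))
    results: list[FitResult] = []
    for raw, ridx, tr in candidates[: max(3 * top_k, top_k)]:
        try:
            cc = score_fit(model, dmap, tr, resolution=d)
        except (OutOfBoundsError, ValueError):
            continue
        results.append(FitResult(tr, cc, rank=ridx))
    results.sort(key=lambda r: (-r.score, r.rank))
    for i, r in enumerate(results[:top_k]):
        r.rank = i + 1
    return results[:top_k]


# ---------------------------------------------------------------------------
# local refinement

def local_refine(
    model: AtomicModel,
    dmap: DensityMap,
    start: RigidTransform,
    resolution: float | None = None,
    max_cycles: int = 4,
) -> FitResult:
    """Derivative-free 6-DoF refinement of a placement.

    Nelder–Mead over a rotation-vector/translation perturbation applied
    about the current model position; cycles repeat until the score improves
    by less than 1e-5 over a full cycle.  The refined score never drops
    below the starting score; non-convergence returns the best-so-far with
    ``converged=False``.
    """
    d = _map_resolution(dmap, resolution)
    pivot = start.apply(model.centroid)[0]

    def build(p: np.ndarray, base: RigidTransform) -> RigidTransform:
        delta_r = Rotation.from_rotvec(p[:3])
        # rotate about the model's current position, then shift
        q = RigidTransform.from_rotation(
            delta_r, pivot - delta_r.as_matrix() @ pivot + p[3:]
        )
        return q.compose(base)

    def objective(p: np.ndarray, base: RigidTransform) -> float:
        try:
            return -score_fit(model, dmap, build(p, base), resolution=d)
        except OutOfBoundsError:
            return 1.0  # worse than any correlation

    current = start
    best = score_fit(model, dmap, current, resolution=d)
    start_score = best
    converged = False
    for _ in range(max_cycles):
        p0 = np.zeros(6)
        simplex = [p0]
        for i, h in enumerate([0.05, 0.05, 0.05, 1.0, 1.0, 1.0]):
            e = np.zeros(6)
            e[i] = h
            simplex.append(e)
        res = minimize(
            objective,
            p0,
            args=(current,),
            method="Nelder-Mead",
            options={
                "initial_simplex": np.array(simplex),
                "xatol": 1e-4,
                "fatol": 1e-7,
                "maxiter": 600,
            },
        )
        new_score = -res.fun
        if new_score > best:
            current = build(res.x, current)
            pivot = current.apply(model.centroid)[0]
        if new_score - best < 1e-5:
            converged = True
            best = max(best, new_score)
            break
        best = new_score
    if best < start_score:  # never degrade the starting placement
        current, best = start, start_score
    return FitResult(current, best, rank=1, converged=converged)


# ---------------------------------------------------------------------------
# map-to-map alignment

def resample_map(
    moving: DensityMap, transform: RigidTransform, like: DensityMap
) -> DensityMap:
    """Resample ``moving`` under ``transform`` onto the grid of ``like``.

    The returned map holds, at each grid point x of ``like``, the trilinear
    sample of ``moving`` at transform⁻¹(x).
    """
    inv = transform.inverse()
    ax = like.grid_coords()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    vals = moving.interpolate(inv.apply(pts)).reshape(like.shape)
    return like.copy(values=vals)


def align_maps(
    moving: DensityMap,
    fixed: DensityMap,
    angular_step_deg: float = 15.0,
) -> RigidTransform:
    """Find the rigid transform taking ``moving`` onto ``fixed``.

    Same machinery as the model search, with the moving map resampled
    (trilinear) instead of a model being splatted: every rotation about the
    moving map's centre gets its best integer-voxel shift from FFT
    cross-correlation, and the leading candidates are re-ranked by the
    Pearson CC over the moving map's transformed 1-sigma envelope (raw
    cross-correlation alone would reward burying a small map in the densest
    region of the fixed map under a wrong rotation).
    """
    if not 5.0 <= angular_step_deg <= 60.0:
        raise ValueError("angular_step_deg must lie in [5, 60]")
    shape = np.array(fixed.shape)
    f_fixed = scipy.fft.fftn(fixed.values.astype(float))
    center = moving.origin + np.array(moving.shape) * moving.voxel_size / 2.0
    mov_sigma = threshold_mask(moving, 1.0)
    mov_support = moving.copy(values=mov_sigma.values.astype(float))

    candidates: list[tuple[float, int, RigidTransform]] = []
    for ridx, rot in enumerate(so3_grid(angular_step_deg)):
        R = rot.as_matrix()
        tr = RigidTransform.from_rotation(rot, center - R @ center)
        rotated = resample_map(moving, tr, fixed)
        corr = scipy.fft.ifftn(f_fixed * np.conj(scipy.fft.fftn(rotated.values))).real
        flat = int(np.argmax(corr))
        idx = np.array(np.unravel_index(flat, fixed.shape))
        idx = np.where(idx > shape // 2, idx - shape, idx)
        full = RigidTransform.from_rotation(
            rot, center - R @ center + idx * fixed.voxel_size
        )
        candidates.append((float(corr.flat[flat]), ridx, full))
    candidates.sort(key=lambda c: (-c[0], c[1]))

    best: tuple[float, int, RigidTransform] | None = None
    for _raw, ridx, tr in candidates[:20]:
        aligned = resample_map(moving, tr, fixed)
        mask = Mask(resample_map(mov_support, tr, fixed).values > 0.5)
        if mask.empty:
            continue
        try:
            cc = real_space_cc(aligned, fixed, mask)
        except ValueError:
            continue
        if best is None or cc > best[0] or (cc == best[0] and ridx < best[1]):
            best = (cc, ridx, tr)
    if best is None:
        raise ValueError("no overlapping content between the maps")
    return best[2]


# ---------------------------------------------------------------------------
# coverage

@dataclasses.dataclass
class CoverageReport:
    """Fraction of residues placed in the density, with per-subunit detail."""

    fraction: float
    per_subunit: dict[str, int]
    total_residues: int


def coverage_report(
    fitted: list[tuple[AtomicModel, FitResult]], total_residue_count: int
) -> CoverageReport:
    """Fraction of the complex's residues accounted for by fitted models."""
    if total_residue_count <= 0:
        raise ValueError("total residue count must be positive")
    per: dict[str, int] = {}
    placed = 0
    for model, _fit in fitted:
        n = model.n_residues
        placed += n
        for s in model.subunits:
            sub = model.select(np.array([x == s for x in model.subunit_ids]))
            per[s] = per.get(s, 0) + sub.n_residues
    if placed > total_residue_count:
        raise ValueError("fitted residues exceed the stated total")
    return CoverageReport(placed / total_residue_count, per, total_residue_count)
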