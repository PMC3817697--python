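"""Synthetic fixtures: Gaussian-atom density simulation, subcomplexes and
toy crystals.

The simulator stands in for experimental reconstructions: every atom
contributes an isotropic Gaussian of weight Z·occupancy and width
``sigma_atom = 0.225 d`` (so the atom's Fourier falloff reaches ~e^-2 at
spatial frequency 1/d), and the finished map is hard-truncated in Fourier
space at 1/d.  Holo/subcomplex map pairs built from one toy model emulate
subunit-deletion experiments; :func:`make_crystal` builds amplitude-only
reflection sets from a symmetry-expanded model, the way a small crystal of
a known complex provides molecular-replacement test data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.fft

from .grids_io import AtomicModel, DensityMap, EmptyModelError

__all__ = [
    "SimulationSpec",
    "simulate_map",
    "add_noise",
    "make_subcomplex",
    "make_crystal",
    "SyntheticCrystal",
    "toy_complex",
    "default_spec",
]

# approximate atomic numbers for the elements that occur in practice
_ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16,
    "MG": 12, "ZN": 30, "FE": 26, "X": 6,
}

SIGMA_PER_RESOLUTION = 0.225  # sigma_atom = 0.225 * d


@dataclasses.dataclass
class SimulationSpec:
    """Parameters of a simulated reconstruction.

    resolution : nominal resolution d in Å (all Fourier content beyond 1/d
        is removed); must satisfy d >= 2·max(voxel_size) (Nyquist).
    voxel_size : Å per grid step (isotropic scalar or 3-vector).
    padding : Å added around the model extent when the box is auto-sized.
    noise_sigma_frac : noise standard deviation as a fraction of map sigma.
    seed : RNG seed for the noise.
    """

    resolution: float = 12.0
    voxel_size: float = 3.0
    padding: float = 12.0
    noise_sigma_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        vs = np.max(np.asarray(self.voxel_size, dtype=float))
        if self.resolution < 2.0 * vs:
            raise ValueError(
                f"resolution {self.resolution} below Nyquist limit "
                f"{2.0 * vs} for voxel {vs}"
            )
        if self.padding < 0:
            raise ValueError("padding must be >= 0")
        if self.noise_sigma_frac < 0:
            raise ValueError("noise_sigma_frac must be >= 0")


def default_spec(**overrides) -> SimulationSpec:
    """The package's standard fixture conditions: d = 12 Å on a 3 Å grid,
    echoing ~11-12 Å single-particle reconstructions of a large complex."""
    return SimulationSpec(**overrides)


def atom_weights(model: AtomicModel) -> np.ndarray:
    z = np.array(
        [_ATOMIC_NUMBER.get(e.upper(), 6) for e in model.elements], dtype=float
    )
    return z * model.occupancies


def lowpass(values: np.ndarray, voxel_size: np.ndarray, d: float) -> np.ndarray:
    """Hard spherical truncation at spatial frequency 1/d."""
    freqs = [
        scipy.fft.fftfreq(n, d=vs)
        for n, vs in zip(values.shape, np.broadcast_to(voxel_size, (3,)))
    ]
    s2 = (
        freqs[0][:, None, None] ** 2
        + freqs[1][None, :, None] ** 2
        + freqs[2][None, None, :] ** 2
    )
    ft = scipy.fft.fftn(values)
    ft[s2 > 1.0 / d**2] = 0.0
    return scipy.fft.ifftn(ft).real


def simulate_map(
    model: AtomicModel,
    spec: SimulationSpec,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> DensityMap:
    """Simulate a density map from an atomic model at nominal resolution d.

    The box is auto-sized to the model bounding box plus ``spec.padding``,
    rounded up to even grid dimensions, unless an explicit grid (``origin``
    and ``shape``) is given — holo/subcomplex pairs and linearity oracles
    need congruent grids.  Deterministic for fixed inputs.
    """
    voxel = np.broadcast_to(np.asarray(spec.voxel_size, dtype=float), (3,))
    if (origin is None) != (shape is None):
        raise ValueError("origin and shape must be given together")
    if origin is None:
        lo = model.positions.min(axis=0) - spec.padding
        hi = model.positions.max(axis=0) + spec.padding
        n = np.ceil((hi - lo) / voxel).astype(int)
        n += n % 2  # even dimensions
        origin = lo
        shape = tuple(int(x) for x in n)
    else:
        origin = np.asarray(origin, dtype=float)
        shape = tuple(int(x) for x in shape)

    sigma = SIGMA_PER_RESOLUTION * spec.resolution
    values = np.zeros(shape, dtype=float)
    weights = atom_weights(model)
    norm = 1.0 / ((2.0 * np.pi) ** 1.5 * sigma**3)
    cutoff = 4.5 * sigma  # beyond this a Gaussian is < 4e-5 of its peak
    axes = [origin[a] + np.arange(shape[a]) * voxel[a] for a in range(3)]
    for w, p in zip(weights, model.positions):
        idx_lo = np.floor((p - cutoff - origin) / voxel).astype(int)
        idx_hi = np.ceil((p + cutoff - origin) / voxel).astype(int) + 1
        if np.any(idx_hi <= 0) or np.any(idx_lo >= shape):
            raise RuntimeError("atom outside simulation box (auto-sizing bug)")
        idx_lo = np.maximum(idx_lo, 0)
        idx_hi = np.minimum(idx_hi, shape)
        dx = axes[0][idx_lo[0] : idx_hi[0]] - p[0]
        dy = axes[1][idx_lo[1] : idx_hi[1]] - p[1]
        dz = axes[2][idx_lo[2] : idx_hi[2]] - p[2]
        r2 = (
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        values[
            idx_lo[0] : idx_hi[0], idx_lo[1] : idx_hi[1], idx_lo[2] : idx_hi[2]
        ] += (w * norm) * np.exp(-r2 / (2.0 * sigma**2))

    values = lowpass(values, voxel, spec.resolution)
    return DensityMap(values, voxel.copy(), origin, resolution=spec.resolution)


def add_noise(dmap: DensityMap, noise_sigma_frac: float, seed: int) -> DensityMap:
    """Add i.i.d. zero-mean Gaussian noise with sd = frac · sigma(map)."""
    if noise_sigma_frac < 0:
        raise ValueError("noise_sigma_frac must be >= 0")
    if noise_sigma_frac == 0:
        return dmap.copy()
    rng = np.random.default_rng(seed)
    sd = noise_sigma_frac * dmap.values.std()
    return dmap.copy(values=dmap.values + rng.normal(0.0, sd, dmap.shape))


def make_subcomplex(model: AtomicModel, exclude: set[str]) -> AtomicModel:
    """Model restricted to atoms whose subunit is not in ``exclude``."""
    present = set(model.subunit_ids)
    unknown = set(exclude) - present
    if unknown:
        raise ValueError(f"exclude lists unknown subunits: {sorted(unknown)}")
    keep = np.array([s not in exclude for s in model.subunit_ids])
    if not keep.any():
        raise EmptyModelError("excluding every subunit leaves an empty model")
    return model.select(keep)


# ---------------------------------------------------------------------------
# synthetic crystals

# symmetry operators as (rotation on fractional coords, fractional shift);
# the dyad of P2/P21 is along b
_SPACEGROUP_OPS = {
    "P1": [(np.eye(3), np.zeros(3))],
    "P2": [
        (np.eye(3), np.zeros(3)),
        (np.diag([-1.0, 1.0, -1.0]), np.zeros(3)),
    ],
    "P21": [
        (np.eye(3), np.zeros(3)),
        (np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.5, 0.0])),
    ],
}


@dataclasses.dataclass
class SyntheticCrystal:
    """An amplitude-only observed reflection set plus the withheld truth.

    ``observed`` mimics measured diffraction (amplitudes, no phases);
    ``truth`` carries the phased set and ``shift_frac`` the planted
    fractional position of the model, for test harnesses only.
    """

    observed: "StructureFactorSet"
    truth: "StructureFactorSet"
    shift_frac: np.ndarray
    spacegroup: str
    cell: np.ndarray


def structure_factors_direct(
    model: AtomicModel,
    cell: np.ndarray,
    d_min: float,
    spacegroup: str = "P1",
    shift_frac: np.ndarray | None = None,
    sigma: float | None = None,
    friedel_full: bool = False,
) -> "StructureFactorSet":
    """Closed-form structure factors of a Gaussian-atom model in a cell.

    F(h) = G(s) Σ_ops Σ_atoms w e^{+2πi h·(R x_frac + τ + t)} with
    G(s) = exp(-2π² σ² s²), the transform of the unit-weight Gaussian atom.
    Exact (no grid); the oracle counterpart of FFT-based routines.
    """
    from .em_mr import StructureFactorSet

    cell = np.asarray(cell, dtype=float)
    if spacegroup not in _SPACEGROUP_OPS:
        raise ValueError(f"unsupported spacegroup {spacegroup}")
    if sigma is None:
        sigma = SIGMA_PER_RESOLUTION * d_min
    shift = np.zeros(3) if shift_frac is None else np.asarray(shift_frac, float)

    hmax = np.floor(cell / d_min).astype(int)
    h, k, l = np.meshgrid(
        np.arange(-hmax[0], hmax[0] + 1),
        np.arange(-hmax[1], hmax[1] + 1),
        np.arange(-hmax[2], hmax[2] + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    s2 = ((hkl / cell) ** 2).sum(axis=1)
    keep = s2 <= 1.0 / d_min**2
    if not friedel_full:
        # unique hemisphere: h > 0, or h = 0 and k > 0, or h = k = 0 and l >= 0
        hh, kk, ll = hkl.T
        hemi = (hh > 0) | ((hh == 0) & (kk > 0)) | ((hh == 0) & (kk == 0) & (ll >= 0))
        keep &= hemi
    hkl = hkl[keep]
    s2 = s2[keep]

    frac = model.positions / cell
    w = atom_weights(model)
    F = np.zeros(len(hkl), dtype=complex)
    for rot, tau in _SPACEGROUP_OPS[spacegroup]:
        # the model is placed at ``shift`` first; symmetry acts on the placed copy
        x = (frac + shift) @ rot.T + tau
        phase = 2.0j * np.pi * (hkl @ x.T)  # (n_refl, n_atoms)
        F += np.exp(phase) @ w
    F *= np.exp(-2.0 * np.pi**2 * sigma**2 * s2)

    with np.errstate(divide="ignore"):
        d = 1.0 / np.sqrt(s2)
    return StructureFactorSet(
        cell=cell,
        spacegroup=spacegroup,
        hkl=hkl,
        amplitude=np.abs(F),
        phase=np.degrees(np.angle(F)),
    )


def make_crystal(
    model: AtomicModel,
    spacegroup: str,
    cell: np.ndarray,
    d: float,
    shift_frac: np.ndarray | None = None,
) -> SyntheticCrystal:
    """Build a synthetic crystal of ``model`` and return amplitudes only.

    The model (in Å, with its own coordinates taken as the zero placement)
    is optionally shifted by ``shift_frac`` (fractional), symmetry-expanded,
    and transformed to resolution ``d``.  Phases are withheld from the
    observed set; the phased truth and the planted shift ride alongside.
    """
    cell = np.asarray(cell, dtype=float)
    frac = model.positions / cell
    if frac.min() < 0 or frac.max() > 1:
        raise ValueError("model does not fit inside the cell")
    truth = structure_factors_direct(
        model, cell, d, spacegroup=spacegroup, shift_frac=shift_frac
    )
    observed = truth.amplitudes_only()
    return SyntheticCrystal(
        observed=observed,
        truth=truth,
        shift_frac=np.zeros(3) if shift_frac is None else np.asarray(shift_frac, float),
        spacegroup=spacegroup,
        cell=cell,
    )


# ---------------------------------------------------------------------------
# the standard three-subunit toy complex

def toy_complex(
    seed: int = 7,
    n_atoms: tuple[int, int, int] = (50, 40, 55),
    centers: np.ndarray | None = None,
    radii: np.ndarray | None = None,
) -> AtomicModel:
    """A three-subunit pseudo-atomic complex ("A", "B", "C").

    Each subunit is a compact blob of carbon pseudo-atoms drawn inside an
    ellipsoid; the three blobs touch but have distinct envelopes, the way
    subunits of a multi-subunit assembly pack side by side.
    """
    rng = np.random.default_rng(seed)
    if centers is None:
        centers = np.array(
            [[0.0, 0.0, 0.0], [26.0, 2.0, 4.0], [12.0, 24.0, -2.0]]
        )
    if radii is None:
        radii = np.array([[12.0, 9.0, 8.0], [9.0, 12.0, 8.0], [8.0, 9.0, 12.0]])
    elements, positions, sub = [], [], []
    for sid, n, c, r in zip("ABC", n_atoms, centers, radii):
        pts = []
        while len(pts) < n:
            u = rng.uniform(-1.0, 1.0, size=3)
            if (u**2).sum() <= 1.0:
                pts.append(c + u * r)
        positions.extend(pts)
        elements.extend(["C"] * n)
        sub.extend([sid] * n)
    n_tot = len(positions)
    return AtomicModel(
        elements,
        np.array(positions),
        np.zeros(n_tot),
        np.ones(n_tot),
        sub,
    )
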