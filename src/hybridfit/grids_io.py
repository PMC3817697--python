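"""Density maps, atomic models and subunit tables: containers and file I/O.

Conventions used throughout the package:

* Maps live on axis-aligned orthogonal grids. ``values[i, j, k]`` is the
  density at physical position ``origin + (i, j, k) * voxel_size`` in
  ångströms, with ``i`` along x, ``j`` along y and ``k`` along z.
* Grid indexing is 0-based; coordinates are continuous Å, never fractional.
* Off-grid sampling anywhere in the package is trilinear.
* On disk, maps are MRC/CCP4-2014 mode-2 (32-bit float); the reader permutes
  any MCRS axis dialect to the canonical x-fastest order.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "DensityMap",
    "AtomicModel",
    "SubunitTable",
    "read_map",
    "write_map",
    "read_model",
    "write_model",
    "read_subunit_table",
    "complex_mass",
]

MAPPING_APPROACHES = frozenset(
    {"subunit_deletion", "overlap", "docking", "elimination", "fab_em", "nd"}
)


class UnsupportedFormatError(ValueError):
    """Raised for maps on non-orthogonal cells or unexpected on-disk modes."""


class EmptyModelError(ValueError):
    """Raised when a model file contains no atoms, or all atoms were removed."""


@dataclasses.dataclass
class DensityMap:
    """A 3-D scalar field on a regular orthogonal grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Density in arbitrary units, finite everywhere.
    voxel_size : ndarray, shape (3,)
        Å per grid step along x, y, z; strictly positive.
    origin : ndarray, shape (3,)
        Å position of grid point (0, 0, 0).
    resolution : float or None
        Nominal resolution d (Å) when known (set by the simulator); metadata
        only, not stored in the file header.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if not np.all(self.voxel_size > 0):
            raise ValueError("voxel_size must be strictly positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self, values: np.ndarray | None = None) -> "DensityMap":
        return DensityMap(
            self.values.copy() if values is None else values,
            self.voxel_size.copy(),
            self.origin.copy(),
            self.resolution,
        )

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical Å coordinates along each axis (1-D arrays)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.voxel_size[a]
            for a in range(3)
        )

    def sigma_normalized(self) -> "DensityMap":
        """Copy with mean 0 and standard deviation 1. Idempotent."""
        v = self.values.astype(float)
        sd = v.std()
        if sd == 0:
            raise ValueError("cannot sigma-normalize a constant map")
        return self.copy(values=(v - v.mean()) / sd)

    def congruent(self, other: "DensityMap", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear sample at Å positions ``points`` (N, 3); 0 outside."""
        from scipy.ndimage import map_coordinates

        idx = (np.atleast_2d(points) - self.origin) / self.voxel_size
        return map_coordinates(
            self.values.astype(float), idx.T, order=1, mode="constant", cval=0.0
        )


@dataclasses.dataclass
class AtomicModel:
    """Atoms with coordinates, element, B-factor, occupancy and subunit label.

    ``subunit_ids`` maps to PDB chain identifiers.  ``residue_ids`` (optional)
    keeps (chain, residue-number) identity for residue counting; pseudo-atom
    models may omit it, in which case each atom counts as one residue.
    """

    elements: list[str]
    positions: np.ndarray
    b_factors: np.ndarray
    occupancies: np.ndarray
    subunit_ids: list[str]
    residue_ids: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        if n == 0:
            raise EmptyModelError("model has no atoms")
        self.b_factors = np.asarray(self.b_factors, dtype=float).reshape(n)
        self.occupancies = np.asarray(self.occupancies, dtype=float).reshape(n)
        if np.any(self.b_factors < 0):
            raise ValueError("negative B-factor")
        if np.any((self.occupancies < 0) | (self.occupancies > 1)):
            raise ValueError("occupancy outside [0, 1]")
        if len(self.elements) != n or len(self.subunit_ids) != n:
            raise ValueError("field lengths disagree")
        if any(not s for s in self.subunit_ids):
            raise ValueError("empty subunit_id")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def subunits(self) -> list[str]:
        """Distinct subunit ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.subunit_ids:
            seen.setdefault(s)
        return list(seen)

    @property
    def n_residues(self) -> int:
        if self.residue_ids is None:
            return len(self)
        return len(set(self.residue_ids))

    def select(self, keep: np.ndarray) -> "AtomicModel":
        keep = np.asarray(keep)
        if not keep.any():
            raise EmptyModelError("selection removes every atom")
        idx = np.flatnonzero(keep)
        return AtomicModel(
            [self.elements[i] for i in idx],
            self.positions[idx],
            self.b_factors[idx],
            self.occupancies[idx],
            [self.subunit_ids[i] for i in idx],
            None
            if self.residue_ids is None
            else [self.residue_ids[i] for i in idx],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        """Apply x' = R x + t to every atom position."""
        out = dataclasses.replace(self)
        out.positions = self.positions @ np.asarray(rotation).T + np.asarray(
            translation, dtype=float
        )
        return out

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclasses.dataclass
class SubunitTable:
    """Per-subunit stoichiometry ledger: name, mass (kDa), copy number N and
    the mapping approach used to place it in the density."""

    frame: pd.DataFrame  # columns: name, mass_kda, n, approach

    def __post_init__(self) -> None:
        required = {"name", "mass_kda", "n", "approach"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"subunit table missing columns: {sorted(missing)}")
        if len(self.frame) == 0:
            raise ValueError("subunit table is empty")
        if (self.frame["mass_kda"] <= 0).any():
            raise ValueError("non-positive subunit mass")
        if (self.frame["n"] < 1).any():
            raise ValueError("copy number must be >= 1")
        bad = set(self.frame["approach"]) - MAPPING_APPROACHES
        if bad:
            raise ValueError(f"unknown mapping approach(es): {sorted(bad)}")


# ---------------------------------------------------------------------------
# map I/O

def read_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4-2014 map; canonicalizes axis order to x-fastest."""
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise UnsupportedFormatError(f"cannot parse map file {path}: {exc}") from exc
    cell = ccp4.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise UnsupportedFormatError("non-orthogonal cell is not supported")
    # setup() regrids to standard X-Y-Z axis order covering the whole cell
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(ccp4.grid, copy=True)
    if not np.all(np.isfinite(values)):
        raise UnsupportedFormatError("map does not cover its grid or has NaNs")
    shape = values.shape
    voxel = np.array([cell.a, cell.b, cell.c]) / np.array(shape)
    origin = np.array(
        [ccp4.header_float(w) for w in (50, 51, 52)], dtype=float
    )
    if np.allclose(origin, 0.0):
        # fall back to the start-index convention used by CCP4-style files
        nstart = np.array(
            [ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float
        )
        origin = nstart * voxel
    return DensityMap(values, voxel, origin)


def write_map(dmap: DensityMap, path: str | Path) -> None:
    """Write mode-2 (float32) MRC-2014 with the ORIGIN header set in Å."""
    ccp4 = gemmi.Ccp4Map()
    nx, ny, nz = dmap.shape
    cell_len = np.array(dmap.shape) * dmap.voxel_size
    ccp4.grid = gemmi.FloatGrid(
        np.ascontiguousarray(dmap.values, dtype=np.float32),
        gemmi.UnitCell(*cell_len, 90.0, 90.0, 90.0),
        gemmi.SpaceGroup("P1"),
    )
    ccp4.update_ccp4_header(2, True)
    for w, v in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# model I/O

def read_model(path: str | Path) -> AtomicModel:
    """Read ATOM/HETATM records from a PDB file; chain ID becomes subunit_id."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    elements, pos, b, occ, chains, resids = [], [], [], [], [], []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    elements.append(atom.element.name)
                    pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    b.append(atom.b_iso)
                    occ.append(atom.occ)
                    chains.append(chain.name)
                    resids.append((chain.name, res.seqid.num))
        break  # first model only
    if not pos:
        raise EmptyModelError(f"no ATOM records in {path}")
    return AtomicModel(elements, np.array(pos), np.array(b), np.array(occ), chains, resids)


def write_model(model: AtomicModel, path: str | Path) -> None:
    """Write a minimal PDB; one chain per subunit, coordinates to 3 decimals."""
    st = gemmi.Structure()
    st.name = "model"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    counters: dict[str, int] = {}
    for i in range(len(model)):
        cid = model.subunit_ids[i]
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
            counters[cid] = 0
        if model.residue_ids is not None:
            seq = model.residue_ids[i][1]
        else:
            counters[cid] += 1
            seq = counters[cid]
        chain = chains[cid]
        if len(chain) == 0 or chain[-1].seqid.num != seq:
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(seq, " ")
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = model.elements[i].upper()
        atom.element = gemmi.Element(model.elements[i])
        atom.pos = gemmi.Position(*model.positions[i])
        atom.b_iso = float(model.b_factors[i])
        atom.occ = float(model.occupancies[i])
        chain[-1].add_atom(atom)
    for chain in chains.values():
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# subunit table

def read_subunit_table(path: str | Path) -> SubunitTable:
    """Read a delimited text table with header (name, mass_kda, n, approach)."""
    frame = pd.read_csv(path, sep=None, engine="python")
    frame.columns = [c.strip().lower() for c in frame.columns]
    return SubunitTable(frame)


def complex_mass(table: SubunitTable) -> float:
    """Total complex mass in kDa: Σ mass × copy-number over subunits."""
    return float((table.frame["mass_kda"] * table.frame["n"]).sum())


def apc_subunit_table() -> SubunitTable:
    """Published human APC/C subunit inventory (masses in kDa, copy numbers,
    and the approach by which each subunit was mapped into the density).

    Several subunits are present in two copies, which is why the whole
    assembly reaches roughly 1.3 MDa.
    """
    from importlib.resources import files

    with (files("hybridfit") / "data" / "apc_subunits.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    return SubunitTable(frame)
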