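"""Orchestrate subunit assignment into an auditable per-subunit ledger.

Three complementary approaches localize subunits of a multi-subunit complex
in a reconstruction: compare a pair of reconstructions that differ by one
subunit (the difference density is the missing subunit), intersect two
reconstructions that share a subunit (the overlap density is the shared
subunit), and, once everything else is placed, attribute the leftover
envelope to the remaining subunit by elimination.  Each step records its
evidence — masks, fitted placements, correlation scores and input
provenance — in an :class:`AssignmentLedger`, finalized to pairwise-disjoint
per-subunit masks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from .grids_io import AtomicModel, DensityMap, write_map
from .map_algebra import (
    Mask,
    difference_map,
    eliminate,
    largest_component,
    overlap_map,
    real_space_cc,
    threshold_mask,
)
from .rigid_fit import FitResult, align_maps, global_search, local_refine, resample_map

__all__ = [
    "LedgerEntry",
    "AssignmentLedger",
    "NoSignalError",
    "assign_by_deletion",
    "assign_by_overlap",
    "assign_by_elimination",
    "finalize",
]


class NoSignalError(ValueError):
    """A difference/overlap computation produced no significant density."""


@dataclasses.dataclass
class LedgerEntry:
    subunit_id: str
    approach: str  # subunit_deletion | overlap | docking | elimination | fab_em | nd
    mask: Mask
    fit: FitResult | None = None
    cc: float | None = None
    provenance: list[str] = dataclasses.field(default_factory=list)
    flagged_empty: bool = False
    evidence: DensityMap | None = None  # density backing the claim, holo grid


@dataclasses.dataclass
class AssignmentLedger:
    """Per-subunit record of how each density region was assigned."""

    holo: DensityMap
    entries: list[LedgerEntry] = dataclasses.field(default_factory=list)
    finalized: bool = False

    def add(self, entry: LedgerEntry) -> None:
        if any(e.subunit_id == entry.subunit_id for e in self.entries):
            raise ValueError(f"subunit {entry.subunit_id} already in ledger")
        self.entries.append(entry)
        self.finalized = False

    def masks(self) -> list[Mask]:
        return [e.mask for e in self.entries]

    def entry(self, subunit_id: str) -> LedgerEntry:
        for e in self.entries:
            if e.subunit_id == subunit_id:
                return e
        raise KeyError(subunit_id)

    def save(self, directory: str | Path) -> Path:
        """Serialize to JSON with mask maps referenced by path + checksum."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        doc = {"finalized": self.finalized, "entries": []}
        for e in self.entries:
            mask_path = directory / f"mask_{e.subunit_id}.mrc"
            mask_map = DensityMap(
                e.mask.values.astype(np.float32),
                self.holo.voxel_size,
                self.holo.origin,
            )
            write_map(mask_map, mask_path)
            digest = hashlib.sha256(mask_path.read_bytes()).hexdigest()
            rec = {
                "subunit_id": e.subunit_id,
                "approach": e.approach,
                "mask_file": mask_path.name,
                "mask_sha256": digest,
                "mask_voxels": e.mask.n_voxels,
                "cc": None if e.cc is None else round(float(e.cc), 6),
                "flagged_empty": e.flagged_empty,
                "provenance": e.provenance,
            }
            if e.fit is not None:
                rec["fit"] = {
                    "quaternion": [round(float(q), 9) for q in e.fit.transform.quaternion],
                    "translation": [round(float(t), 6) for t in e.fit.transform.translation],
                    "score": round(float(e.fit.score), 6),
                }
            doc["entries"].append(rec)
        out = directory / "ledger.json"
        out.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        return out


def _fit_into(
    model: AtomicModel,
    density: DensityMap,
    angular_step_deg: float,
    resolution: float | None,
) -> FitResult:
    hits = global_search(
        model, density, angular_step_deg=angular_step_deg, top_k=3, resolution=resolution
    )
    if not hits:
        raise NoSignalError("no valid placement found")
    return local_refine(model, density, hits[0].transform, resolution=resolution)


def _aligned_onto(moving: DensityMap, fixed: DensityMap) -> DensityMap:
    if moving.congruent(fixed):
        # already on the target grid; alignment machinery would return identity
        return moving
    tr = align_maps(moving, fixed)
    out = resample_map(moving, tr, fixed)
    out.resolution = moving.resolution
    return out


def assign_by_deletion(
    holo: DensityMap,
    sub: DensityMap,
    model: AtomicModel,
    subunit_id: str | None = None,
    level_sigma: float = 1.0,
    angular_step_deg: float = 20.0,
    resolution: float | None = None,
) -> LedgerEntry:
    """Assign a subunit from a holo/subcomplex difference density.

    The subcomplex map is aligned onto the holo map, the scaled difference
    computed, its envelope masked, and the subunit's atomic model fitted
    into the difference density.
    """
    sub_aligned = _aligned_onto(sub, holo)
    diff = difference_map(holo, sub_aligned, scale=True)
    if diff.values.std() < 1e-6 * max(holo.values.std(), 1e-30):
        raise NoSignalError("difference map carries no signal (sub == holo?)")
    mask = largest_component(threshold_mask(diff, level_sigma))
    if mask.empty:
        raise NoSignalError("difference density below threshold everywhere")
    fit = _fit_into(model, diff, angular_step_deg, resolution)
    sid = subunit_id or model.subunits[0]
    return LedgerEntry(
        subunit_id=sid,
        approach="subunit_deletion",
        mask=mask,
        fit=fit,
        cc=fit.score,
        provenance=["difference(holo, subcomplex)", f"mask@{level_sigma}sigma"],
        evidence=diff,
    )


def assign_by_overlap(
    map1: DensityMap,
    map2: DensityMap,
    model: AtomicModel,
    subunit_id: str | None = None,
    level_sigma: float = 1.0,
    angular_step_deg: float = 20.0,
    resolution: float | None = None,
) -> LedgerEntry:
    """Assign the subunit two subcomplex reconstructions share.

    Both maps are brought to a common frame; the voxelwise minimum of their
    clipped, sigma-normalized densities is the shared envelope, into which
    the shared subunit's model is fitted.
    """
    m2 = _aligned_onto(map2, map1)
    ov = overlap_map(map1, m2)
    ov.resolution = map1.resolution if resolution is None else resolution
    if ov.values.std() < 1e-12 * max(map1.values.std(), 1e-30):
        raise NoSignalError("maps share no density (disjoint supports)")
    mask = largest_component(threshold_mask(ov, level_sigma))
    if mask.empty:
        raise NoSignalError("maps share no density above threshold")
    fit = _fit_into(model, ov, angular_step_deg, resolution)
    sid = subunit_id or model.subunits[0]
    return LedgerEntry(
        subunit_id=sid,
        approach="overlap",
        mask=mask,
        fit=fit,
        cc=fit.score,
        provenance=["overlap(map1, map2)", f"mask@{level_sigma}sigma"],
        evidence=ov,
    )


def assign_by_elimination(
    holo: DensityMap,
    ledger: AssignmentLedger,
    subunit_id: str,
    level_sigma: float = 1.0,
) -> LedgerEntry:
    """Attribute the not-yet-assigned holo envelope to a remaining subunit.

    No atomic model is required — the approach exists precisely for
    subunits that lack one.  A fully assigned map yields a flagged empty
    entry rather than an error.
    """
    holo_mask = threshold_mask(holo, level_sigma)
    leftover = eliminate(holo_mask, ledger.masks())
    return LedgerEntry(
        subunit_id=subunit_id,
        approach="elimination",
        mask=leftover,
        fit=None,
        cc=None,
        provenance=[f"eliminate(holo@{level_sigma}sigma, {len(ledger.entries)} assigned)"],
        flagged_empty=leftover.empty,
        evidence=None,
    )


def finalize(ledger: AssignmentLedger, level_sigma: float = 1.0) -> AssignmentLedger:
    """Resolve voxel conflicts and clip every mask to the holo envelope.

    A voxel claimed by several entries goes to the entry with the higher
    evidence density there (the density backing its claim: the
    difference/overlap map holding its fitted model, or the holo density
    itself for elimination entries); ties go to the earlier entry.
    Afterwards the masks are pairwise disjoint and each is a subset of the
    holo ``level_sigma`` mask.
    """
    holo_mask = threshold_mask(ledger.holo, level_sigma)
    n = len(ledger.entries)
    if n == 0:
        raise ValueError("ledger has no entries")
    evidence = np.zeros((n,) + ledger.holo.shape)
    claims = np.zeros((n,) + ledger.holo.shape, dtype=bool)
    for i, e in enumerate(ledger.entries):
        claims[i] = e.mask.values & holo_mask.values
        if e.evidence is not None:
            evidence[i] = e.evidence.values
        else:
            evidence[i] = ledger.holo.values  # elimination: holo density itself

    # winner per voxel: highest evidence among claimants, earlier entry on ties
    neg_inf = -np.inf
    ev = np.where(claims, evidence, neg_inf)
    winner = np.argmax(ev, axis=0)  # argmax returns the first (earliest) max
    any_claim = claims.any(axis=0)
    for i, e in enumerate(ledger.entries):
        final = any_claim & (winner == i) & claims[i]
        e.mask = Mask(final, provenance=e.mask.provenance + "|finalized")
        e.flagged_empty = e.mask.empty
        if e.evidence is not None and e.fit is not None:
            try:
                e.cc = real_space_cc(e.evidence, ledger.holo, e.mask)
            except ValueError:
                pass
    ledger.finalized = True
    return ledger
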