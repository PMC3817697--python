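# Methods

## Scope and model

`hybridfit` implements the computational core of hybrid model building for
multi-subunit complexes: segmenting an intermediate-resolution (∼10–12 Å)
single-particle reconstruction into per-subunit regions, fitting atomic
models rigidly into density, and using segmented EM density as a
molecular-replacement (MR) search model against crystal amplitudes. All
stages operate on axis-aligned orthogonal grids; positions are continuous
ångströms with 0-based grid indexing, and every off-grid sample is
trilinear. Skewed cells, mmCIF, flexible fitting, and image processing
(classification, reconstruction, antibody-labelling analysis) are out of
scope.

## Density simulation

Experimental reconstructions are emulated by a Gaussian-atom model: each
atom contributes an isotropic Gaussian of weight Z·occupancy and width
σ_atom = 0.225·d, after which the map is hard-truncated in Fourier space at
spatial frequency 1/d. The width constant makes a single atom's Fourier
falloff reach ≈e⁻² at 1/d, so the nominal resolution d is the only
resolution parameter; any smooth monotone map from d to width would do, and
this one is simple and documented. The simulation box is auto-sized to the
model bounding box plus padding (default 12 Å), rounded up to even
dimensions for clean FFT bookkeeping; an explicit grid can be supplied so
holo/subcomplex pairs share one lattice. Noise, when requested, is i.i.d.
Gaussian per voxel with standard deviation expressed as a fraction of the
map σ — the simplest stand-in for reconstruction noise; no CTF, no
projection geometry, no sharpening or B-factor weighting is modelled.
Consequences: passing tests demonstrate the *procedures* (difference
arithmetic, search machinery, phasing cycles) are correct, not that the
package would segment a map whose noise is correlated or whose two input
reconstructions differ in magnification or hand.

The standard fixture is a three-subunit complex ("A", "B", "C") of 30–60
carbon pseudo-atoms per subunit drawn inside touching ellipsoids, simulated
at d = 12 Å on 3 Å voxels — echoing the 11–12 Å maps such hybrid studies
typically start from. Pseudo-atom counts stand in for residue counts in
coverage bookkeeping.

## Map algebra and assignment

Difference maps are computed after least-squares scaling of the subtrahend
onto the minuend (k = Σab/Σa²), with a flag to disable scaling for maps
already on a common scale. Overlap density is the voxelwise minimum of the
two sigma-normalized, nonnegativity-clipped maps: the minimum keeps density
units and reads directly as the shared envelope; a product would not.
Envelopes are thresholded at 1.0 σ by default (common EM practice) and
reduced to their largest 6-connected component before downstream use.
Map-to-map agreement is Pearson correlation over a mask; resolution
estimates use FSC with a 0.5 threshold and one-Fourier-voxel shells,
linearly interpolated at the crossing.

The assignment pipeline records one ledger entry per subunit (approach,
mask, fitted placement, CC, provenance) and finalizes by resolving voxel
conflicts: a voxel claimed by several entries goes to the entry with the
higher evidence density at that voxel (its difference/overlap map, or the
holo density for elimination entries), ties to the earlier entry. Visual
boundary judgement in the original practice is thus replaced by a
deterministic rule. Finalized masks are pairwise disjoint subsets of the
holo 1 σ envelope. Fab-labelling assignments enter the ledger only as an
externally supplied mask with the `fab_em` tag — computing them from class
averages is out of scope. Ledgers serialize to JSON with mask files
referenced by path and SHA-256 checksum.

## Rigid-body search

Rotations are enumerated on a deterministic quasi-uniform grid: spherical
Fibonacci directions (spacing ≤ step) × evenly spaced in-plane spins, with
the identity prepended so null problems are recovered exactly. For each
rotation the model is splatted on the map grid and the best integer-voxel
translation found by FFT cross-correlation; the leading candidates are
re-scored by the masked real-space CC (the model's own 1 σ envelope masks
the correlation so empty density does not dilute it) and ranked, ties
broken by grid order. Map-to-map alignment uses the same machinery with
trilinear resampling in place of splatting, and the same re-ranking —
unnormalized correlation alone would bury a small map in the densest region
of the target under a wrong rotation.

Local refinement is Nelder–Mead over a 6-vector (rotation-vector
perturbation about the model's current position, plus a shift), initial
simplex 0.05 rad / 1 Å, cycling until the score improves by < 1e-5 per
cycle (max 4 cycles, 600 iterations each); the refined score never drops
below the start, and non-convergence returns best-so-far with a flag. The
score surface is analytic in the transform (Gaussian splats move
continuously), so no gradient of the interpolant is needed. On noise-free
fixtures, 15° grid + refinement recovers 20 random planted transforms to
≤ 2° and ≤ 0.5 voxel (the packaged acceptance run measures ≈0.002° and
< 0.001 voxel worst case).

## EM-map molecular replacement

The map is embedded centred in a P1 supercell, by default 5× each box
dimension. Centring maximizes the distance to periodic images, which is the
point of the large cell: self-Patterson vectors of the model must exceed
the rotation function's radius of integration before cross-Patterson
vectors from neighbouring images intrude; `rotation_search` enforces radius
< half the smallest supercell edge. Structure factors are the FFT of the
box (convention F(h) = Σ ρ e^{+2πi h·x/N}, fixed so independent
implementations can compare phases; F(000) = Σρ), with no amplitude
rescaling of the EM density. The working band defaults to 4–30 Å.

The rotation function correlates the observed Patterson (inverse transform
of |F|²) with the rotated model Patterson over grid points in the shell
r_min < r ≤ radius (origin peak excluded; r_min defaults to the data
resolution limit), on the same deterministic SO(3) grid as the real-space
search; the top grid rotations are polished by a simplex on the continuous
Patterson overlap. Because any Patterson is centrosymmetric the score
cannot distinguish a rotation from its centrosymmetric image; consumers
must treat R and its inverse-through-the-origin as equivalent. The
translation function scores a fractional-shift grid (default 20×20 over
(t_x, t_z); the dyad-axis component is amplitude-invariant in P2/P2₁ and
fixed at 0) by Pearson correlation between observed and
symmetry-expanded calculated amplitudes. P1 translation is degenerate and
returns the zero shift flagged as such. Supported space groups are P1, P2
and P2₁ with explicit operator lists — enough to make translation
non-degenerate at desk scale; recovered shifts are reported modulo the
space group's permissible origin shifts ((½, ·, ½) for P2₁).

## Phase extension

Phases are extended from d_start (default 10 Å) to the amplitude limit
(default 5 Å) by cyclic solvent flattening: synthesize a map from observed
amplitudes + current phases, set everything outside the protein mask (the
densest 1 − solvent_fraction of voxels, recomputed every cycle) to the
solvent mean, back-transform, adopt the calculated phases, and admit one
new resolution shell per cycle (equal steps in 1/d). Observed amplitudes
pass through bit-exactly. The solvent fraction should reflect the actual
solvent content of the cell; for the sparse pseudo-atom fixture that is
≈0.9 (measured from the ground-truth map's 1 σ envelope and rounded down,
since over-assigning protein is the safe direction), much higher than the
≈0.5 of a typical protein crystal. On the noise-free fixture, 20 cycles
leave the newly phased 10–5 Å shells at a mean phase error of ≈43° versus
ground truth — well below the 90° random expectation — and raise the map
correlation to the true 5 Å map relative to the 10 Å start.

## Numerical choices and degenerate inputs

- Map I/O is MRC/CCP4-2014 mode 2 via gemmi; any on-disk axis order is
  permuted to x-fastest on read; non-orthogonal cells are rejected. The
  ORIGIN header carries the Å origin; files written by the package round
  values to float32, and round trips are bit-exact at that precision.
- Sigma normalization of a constant map, correlation under a constant
  masked region, and scaling by an identically zero map raise typed errors
  rather than returning NaN.
- Difference of a map with itself carries no signal and raises a no-signal
  error in the assignment layer (an all-zero map cannot be thresholded).
- Empty masks are allowed and flagged, never silently dropped; eliminating
  from a fully assigned envelope yields a flagged empty entry.
- All searches are deterministic for fixed inputs: fixed grids, stable
  sorts, ties broken by enumeration order; noise takes an explicit seed.

## Problem sizes

Tests and the acceptance script run on 24–40³ grids (3 Å voxels), 40–145
pseudo-atom models, 15–30° rotation grids, 5× supercells of single-subunit
maps, and reflection sets of 10³–10⁵. These sizes keep a full run in
minutes on one CPU while leaving every search non-trivial (thousands of
rotations, 400-point translation grids, 20-cycle extensions).

## Known limitations

- The Gaussian-atom simulator ignores electron scattering form factors,
  B-factors, CTF and projection artefacts; results on real maps depend on
  factors the fixtures do not model.
- Rigid fitting only; conformational differences between the model and the
  density are not absorbed.
- The MR layer is desk-scale: no likelihood targets, no general space-group
  handling, no anisotropy or twinning treatment, no experimental scaling.
- Subcomplex alignment assumes substantial shared content; reconstructions
  that differ in hand or magnification are not handled.
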