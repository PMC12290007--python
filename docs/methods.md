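# Methods

This note documents the models, conventions and numerical choices behind
`tibind`, and what the synthetic validation does and does not establish.

## Observables and binding classification

**SSD.** The surface separation distance is the z-distance from the
mass-weighted centre of mass of the whole peptide (no atom exclusions) to
the mean z of the outermost Ti layer, taken as the minimum over the two
slab faces with periodic wrapping in z. Both faces of the slab are
crystallographically equivalent, and a peptide drifting across the box
midplane simply engages the other face; the maximum attainable SSD is half
the box height minus the slab thickness. The outer Ti layer is defined
geometrically as all Ti within `layer_tolerance` (default 0.05 nm) of the
extreme Ti z on that face — with the anatase (101) stacking (Ti sub-planes
0.088 nm apart) this selects exactly one atomic plane per face.

**EED.** Euclidean distance between the Cα atoms of residues 1 and 6,
computed on unwrapped coordinates.

**Bound state.** A frame is bound iff SSD < 1 nm (strict inequality;
SSD ≥ 1 nm is desorbed). `percent_bound` is the bound fraction of the
production window. State-conditioned EED means use population SDs
(divide by N, configurable): they are descriptive statistics over dense,
strongly autocorrelated time series, not standard errors. An optional
debounce (`min_dwell_frames`) merges state runs shorter than a dwell
minimum into the surrounding state; the default (1) applies no debounce,
since threshold flicker is part of the raw observable.

**Unwrapping.** Peptides are made whole by a breadth-first traversal of
the heavy-atom bond graph (residue templates plus inter-residue C–N
bonds), placing each atom at its minimum image relative to its parent. A
post-unwrap bond above 0.25 nm aborts the analysis as a broken molecule.
Coordinates are stored wrapped as read; unwrapping is always explicit.

## Atom classification

Surface classes are geometric, not name-based (the slab has no standard
residue nomenclature): hydroxyl oxygens (OF) are surface O within the O–H
bond cutoff (0.12 nm) of a surface H; bridging/exposed oxygens (OB) are
the remaining surface O within `exposure_depth` (0.25 nm) of an outer Ti
plane; deeper lattice O are retained but excluded from OB reporting.
Peptide roles come from residue topology: one Cα per residue, the backbone
N of residue 1 as the N-terminal amine, both carboxylate O of residue 6
(zwitterionic, uncapped termini), sidechain N sets (Arg: NE/NH1/NH2,
Lys: NZ) and sidechain O sets (Asp: OD1/OD2). "Peptide oxygen" in the
bridging filter means every peptide O — backbone carbonyls, the C-terminal
carboxylate and sidechain oxygens.

## Clustering

Pairwise RMSD after Kabsch least-squares superposition (proper rotations
only, determinant +1; mirror images are not superposable). The default
selection is peptide heavy atoms — hydrogen positions under
constraint-based MD add noise without information — with an all-atom and a
mass-weighted switch. The RMSD after fitting is not a metric (no triangle
inequality), so clustering operates on the explicit pairwise matrix: the
GROMOS procedure repeatedly seeds a cluster at the frame with the most
neighbours within the cutoff (0.15 nm over the whole peptide, following
common practice for peptides of this size), removing each cluster as it
forms. Ties in neighbour count go to the lowest frame index, which makes
the output invariant to frame ordering. Cluster sizes are provably
non-increasing in formation order. Frames may be strided before the O(F²)
matrix; the reported populations refer to the clustered subset.

The batched matrix path computes per-pair 3×3 cross-covariances and a
batched SVD using the e₀ − 2Σσ identity (adequate at 1e-8 for matrix
entries); the scalar `kabsch_rmsd` evaluates the explicit residual after
applying the fitted rotation, so exact rigid transforms return zero at
machine precision.

## Radial distribution functions

g(r) = ⟨counts in shell⟩ / (N_A · V_shell(r) · ρ_B) with ρ_B the whole-box
density of the B selection and exact shell volumes
(4π/3)(r₊³ − r₋³); distances are minimum-image in orthorhombic boxes,
identical indices excluded pairwise, defaults r_max = 1.2 nm and
Δr = 0.002 nm. In slab geometry the density is inhomogeneous, so peak
*heights* are normalisation-convention-dependent; raw pair counts are kept
in `RDFResult` so any other convention can be applied afterwards. Peak
*positions* — the quantity the analysis actually interprets — are
convention-independent; `first_peak` reports the global maximum within
(0, 0.4 nm] and flags profiles whose true maximum lies beyond the window.

**Conditional (bridging) RDF.** The reference set is recomputed every
frame: Na⁺ within 3 Å of at least one surface oxygen (OB ∪ OF) *and*
3 Å of at least one peptide oxygen — an instantaneous geometric
criterion. The default normalisation pools counts over frames and divides
by the summed per-frame filtered ion count, so frames with no bridging ion
contribute zero counts and zero reference particles; a per-frame-mean
variant is exposed. With a filter that accepts every ion, the conditional
RDF is bin-for-bin identical to the plain RDF — a tested identity.

## Anatase (101) slab

The slab is cut from the tetragonal anatase lattice (I4₁/amd,
a = b = 0.3785 nm, c = 0.9514 nm, oxygen parameter u = 0.2081) in the
rotated frame whose x/y axes are the (101) in-plane lattice vectors
([10-1]-projected, 1.0239 nm, and [010], 0.3785 nm) and whose z is the
(101) normal (d₁₀₁ = 0.3517 nm). Sites are enumerated exactly (no
numerical dedup), and the cleavage plane is the midpoint of the widest
inter-plane gap — the stoichiometric termination exposing two-coordinated
bridging O above five-coordinated Ti on both inversion-related faces.
`n_layers` counts (101) stacking periods (two Ti planes each). With
n1 = 5, n2 = 13, n_layers = 9 the builder yields 2340 Ti / 4680 O, lateral
5.12 × 4.92 nm, thickness 3.05 nm and 260 Ti₅c — the reference-scale system
(note that thickness and composition correspond to nine stacking periods,
i.e. eighteen Ti planes; "Ti layer" counts in the literature are often
ambiguous between periods and planes).

Hydroxylation draws exactly round(f · N₅c) sites (round-half-to-even, for
determinism) uniformly without replacement from the 5-coordinated Ti of
the selected face(s), both faces by default. The OH geometry (Ti–O
0.18 nm, O–H 0.098 nm along the surface normal) only needs to support
OF/HF classification and RDF geometry — no energetics are computed. The
per-hydroxyl effective charge is an input, not a constant: the 30%
coverage matches a measured
nanoparticle surface charge of −0.62 e/nm², but the mapping depends on the
force field's partial charges, so the builder reports σ = q·N_OH/A per
face rather than hard-coding it.

## Synthetic data: what it emulates, and what it does not

The generator plants a known truth with the statistical
structure: a discrete-time two-state Markov chain per frame (defaults
p_bind = 0.08, p_unbind = 0.02, stationary bound probability 0.8, chosen
to emulate a predominantly bound strong binder with an integrated
autocorrelation time of ~19 frames); bound-state SSD from a truncated
normal on (0, 1 nm) (μ 0.7, σ 0.1), unbound SSD uniform between the
threshold and the geometric maximum; rigid all-heavy-atom conformer
templates with exact planted EEDs (Cα on a circular arc with 0.38 nm
virtual bonds; idealised, not force-field, internal geometry) mixed 70/30
in the bound state and jittered isotropically (σ 0.01 nm); an anchor
contact (first basic residue's terminal sidechain N placed at exactly
0.28 nm from a randomly chosen hydroxyl O whenever the sampled geometry
permits); and, with probability 0.9 per bound frame, one Na⁺ placed to
satisfy the dual bridging criterion exactly while all other ions stay
≥ 0.5 nm from every surface and peptide oxygen. The lower slab face is
reached by a proper 180° rotation, never a mirror, so all frames remain
superposable. Frames are emitted wrapped, which forces the unwrapping path
in every analysis.

Passing on this benchmark establishes that the analysis chain recovers
planted kinetics, conformer mixtures and contact geometry exactly or
within quantified sampling error. It does *not* establish force-field
realism: there is no solvent, no energetics, no correlated conformational
drift, and transition kinetics are frame-discrete. Quantities that depend
on those features (free energies, rates in physical time, peak heights)
are out of scope by design.

## Problem sizes and determinism

The test suite and the acceptance script use a 2000-frame benchmark
(~600-atom system), cluster at a stride capping the matrix at ≲450 frames,
and verify binding-fraction recovery within three effective-sample
standard deviations (binomial variance inflated by the chain's
autocorrelation time, √(p(1−p)·τ/N)). All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
trajectories and pipeline artifacts (the run manifest records the SHA-256
of every output). Sequence/motif operations are exact combinatorics and
are cross-checked against brute-force window scans; clustering is checked
against a literal transcription of the neighbour-count procedure; the
Kabsch RMSD against a quaternion-eigenvalue implementation and
MDAnalysis; the RDF against the ideal-gas limit and delta-placed pairs.

## Known limitations

- Orthorhombic boxes only; triclinic inputs are rejected at the boundary.
- The slab builder produces the ideal stoichiometric (101) termination;
  no relaxation, defects, steps or other facets.
- GRO/PDB/XTC/DCD cover the supported formats; multi-frame GRO is parsed
  natively (trajectory libraries do not read it for non-standard slabs).
- The conditional RDF's reference count can be zero in sparse systems;
  such frames contribute nothing, which is the documented convention.
- Motif statistics are raw counts; no enrichment testing is performed.
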