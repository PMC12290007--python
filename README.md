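# tibind

Analysis toolkit for studying **sequence effects in titanium-binding peptide
adsorption on TiO₂** from unbiased molecular-dynamics trajectories.

Short solid-binding peptides such as the titanium binder RKLPDA (min TBP-1)
attach to titania surfaces through a mix of electrostatics, hydrogen bonding
to surface hydroxyls, and ion-mediated contacts. Reordering the same six
residues changes the binding strength substantially, and quantifying that
requires a reproducible chain of trajectory analyses. `tibind` implements
that chain for hexapeptides on the hydroxylated anatase (101) surface:

- **Sequence space** — enumerate all 720 orderings of the {R, K, L, P, D, A}
  multiset, collapse reverse pairs into one composition class (360
  directionally distinct sequences), select strong binders by binding
  fraction, and tally pair/triplet motifs, optionally position-resolved.
- **Binding observables** — per frame, the *surface separation distance*
  SSD (mass-weighted peptide COM to the mean plane of the outermost Ti
  layer, minimised over the two slab faces under periodic boundaries) and
  the *end-to-end distance* EED (Cα₁–Cα₆). A frame is **bound** when
  SSD < 1 nm; the per-sequence binding fraction is
  `percent_bound = 100 · #bound / #frames`, and EED is summarised
  separately over bound (EED_a ± std_a) and unbound (EED_d ± std_d) frames.
- **Conformational clustering** — Kabsch least-squares superposition RMSD
  over peptide heavy atoms, clustered with the iterative GROMOS
  neighbour-count algorithm (cutoff 0.15 nm): the frame with the most
  neighbours seeds a cluster, it and its neighbours are removed, repeat.
- **Radial distribution functions** — g(r) between typed peptide atoms
  (sidechain N of Arg/Lys, N-terminal amine, Asp/C-terminal oxygens, Cα of
  apolar residues) and the two surface oxygen types: bridging oxygens (OB)
  and hydroxyl oxygens (OF), with sub-0.4 nm peak extraction.
- **Na⁺ bridging** — a conditional RDF restricted to ions simultaneously
  within 3 Å of a surface oxygen *and* 3 Å of a peptide oxygen, the
  geometry of an ion bridging the peptide to the surface.
- **Surface builder** — a stoichiometric anatase (101) slab cut from the
  tetragonal lattice (a = 0.3785 nm, c = 0.9514 nm, u = 0.2081), with
  random hydroxylation of the 5-coordinated surface Ti and a surface-charge
  report. The defaults reproduce the reference-scale slab: 2340 Ti, 4680 O,
  3.05 nm thick, 260 Ti₅c, 78 OH at 30% coverage.
- **Synthetic data** — a generator that emits wrapped GRO/XTC trajectories
  with *planted ground truth* (two-state Markov binding kinetics, rigid
  conformer templates with exact EEDs, exact anchor contacts and Na⁺
  bridges), so every stage of the pipeline is validated without external
  downloads.

## Worked example

```python
from tibind import (SyntheticSpec, binding_profile, classify_atoms,
                    compute_rdf, first_peak, generate_trajectory,
                    resolve_selection)

spec = SyntheticSpec(n_frames=800, p_bind=0.08, p_unbind=0.02)
topo, frames, truth = generate_trajectory(spec, seed=11)
profile = binding_profile(frames, topo)
print(f"percent bound: {profile.percent_bound:.2f}%")
print(f"EED bound {profile.eed_a:.3f} nm, unbound {profile.eed_d:.3f} nm")

classes = classify_atoms(topo, frames[0])
rdf = compute_rdf(frames, resolve_selection("sidechain-N pos 1", topo, classes),
                  resolve_selection("surface OF", topo, classes))
print(f"Arg1 N - hydroxyl O peak: {first_peak(rdf)[0]:.3f} nm")
```

prints

```
percent bound: 70.62%
EED bound 0.865 nm, unbound 1.399 nm
Arg1 N - hydroxyl O peak: 0.281 nm
```

The binding fraction equals the generator's realised state occupancy; the
bound-state EED is lower than the unbound one because the bound state mixes
in the compact conformer (adsorption-induced compaction); and the RDF peak
sits at the planted 0.28 nm guanidinium–hydroxyl contact. The scripts in
`examples/` walk through each capability (sequence library, surface
builder, observables, clustering, RDF/bridging) the same way, and the
`tibind` command exposes them as thin subcommands
(`permute`, `build-surface`, `synth`, `analyze`, `cluster`, `rdf`, `rank`,
`motifs`, `report`).

Per-peptide SSD/EED time series stored as 3-column text files (time_ps,
ssd_nm, eed_nm) can be ranked directly with
`tibind rank --series-dir DIR --out OUT`, which also writes the
strong-binder subset and all motif tables.

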