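"""Typed RDFs against surface oxygens and the Na+ bridging analysis.

In the synthetic benchmark the arginine guanidinium N is planted at
0.28 nm from a surface hydroxyl O in bound frames, and a Na+ ion bridges
a peptide oxygen to the surface at 0.23 nm.  The RDF peak positions
recover both planted distances; the conditional RDF uses only ions that
satisfy the dual 3 A (surface O AND peptide O) criterion, re-evaluated
every frame.
"""

from tibind import (SyntheticSpec, bridging_na_filter, classify_atoms,
                    compute_rdf, conditional_rdf, first_peak,
                    generate_trajectory, resolve_selection)

spec = SyntheticSpec(n_frames=600, contact_distance=0.28, bridge_distance=0.23)
topo, frames, truth = generate_trajectory(spec, seed=11)
classes = classify_atoms(topo, frames[0])

sel_n1 = resolve_selection("sidechain-N pos 1", topo, classes)
sel_of = resolve_selection("surface OF", topo, classes)
rdf = compute_rdf(frames, sel_n1, sel_of, r_max=1.2, bin_width=0.002)
r_peak, g_peak, outside = first_peak(rdf, window_max=0.4)
print(f"Arg1 sidechain N - hydroxyl O: peak at {r_peak:.3f} nm "
      f"(planted {truth.contact_distance} nm)")

n_bridging = sum(bridging_na_filter(fr, classes).size for fr in frames)
print(f"bridging Na+ occurrences over {len(frames)} frames: {n_bridging}")

cond = conditional_rdf(frames, classes,
                       resolve_selection("peptide-O", topo, classes),
                       r_max=1.2, bin_width=0.002)
r_b, _, _ = first_peak(cond, window_max=0.4)
print(f"bridging Na+ - peptide O: peak at {r_b:.3f} nm "
      f"(planted {truth.bridge_distance} nm)")
# Sub-0.4 nm peak positions are the binding evidence: they are independent
# of the g(r) normalisation convention, unlike peak heights.
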