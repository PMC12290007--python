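"""Per-frame adsorption observables on a synthetic trajectory.

Generates a trajectory whose bound/unbound kinetics follow a two-state
Markov chain with stationary bound probability 0.8, then recomputes the
surface separation distance (SSD, peptide COM to the outer Ti plane) and
end-to-end distance (EED, C-alpha 1 to C-alpha 6) per frame and derives
the binding fraction and state-conditioned EED statistics.
"""

from tibind import (AnalysisParams, SyntheticSpec, binding_profile,
                    generate_trajectory, rank_peptides)

spec = SyntheticSpec(n_frames=800, p_bind=0.08, p_unbind=0.02)
print(f"planted stationary bound probability: "
      f"{spec.stationary_bound_probability:.2f}")

topo, frames, truth = generate_trajectory(spec, seed=11)
profile = binding_profile(frames, topo, AnalysisParams(bound_threshold=1.0))

print(f"frames: {profile.n_frames}, percent bound: {profile.percent_bound:.2f}%"
      f" (truth: {100 * truth.states.mean():.2f}%)")
print(f"EED bound   {profile.eed_a:.3f} +- {profile.std_a:.3f} nm")
print(f"EED unbound {profile.eed_d:.3f} +- {profile.std_d:.3f} nm")
print(f"adsorption/desorption events: {len(profile.events)}")

table = rank_peptides({topo.peptide_sequence: profile})
print(table.round(2).to_string(index=False))
# A lower bound-state EED than unbound-state EED indicates compaction on
# adsorption, the signature seen for many strongly binding sequences.
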