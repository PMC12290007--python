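"""SSD/EED observables, bound-state classification and ranking."""

import numpy as np
import pytest

from tibind.observables import (AnalysisParams, binding_profile, compute_eed,
                                compute_ssd, profile_from_series, rank_peptides,
                                unwrap_peptide, write_ranking_tsv)
from tibind.topology import TrajectoryFrame, classify_atoms, peptide_bond_list


class TestUnwrap:
    def test_already_whole_peptide_unchanged(self, small_system):
        _, topo, frames, _ = small_system
        coords = unwrap_peptide(frames[0], topo)
        once_more = unwrap_peptide(
            TrajectoryFrame(frames[0].time, frames[0].box, coords), topo)
        assert np.allclose(once_more, coords)

    def test_split_across_boundary_reunited(self, small_system):
        _, topo, frames, _ = small_system
        fr = frames[0]
        pep = topo.peptide_indices
        whole = unwrap_peptide(fr, topo)
        # drag the whole peptide across the x boundary, then wrap
        shifted = whole.copy()
        shifted[pep, 0] += fr.box[0] - shifted[pep, 0].mean()
        wrapped = shifted % fr.box
        rewhole = unwrap_peptide(TrajectoryFrame(fr.time, fr.box, wrapped), topo)
        bonds = peptide_bond_list(topo)
        b1 = sorted(np.linalg.norm(whole[b] - whole[a]) for a, b in bonds)
        b2 = sorted(np.linalg.norm(rewhole[b] - rewhole[a]) for a, b in bonds)
        assert np.allclose(b1, b2, atol=1e-9)

    def test_bond_spectrum_matches_template(self):
        from tibind.synthetic import SyntheticSpec, generate_trajectory
        spec = SyntheticSpec(n_frames=3, jitter_sigma=0.0, template_eeds=(0.65,),
                             bound_weights=(1.0,), unbound_weights=(1.0,))
        topo, frames, _ = generate_trajectory(spec, seed=3)
        template = spec_template_bonds(spec, topo)
        bonds = peptide_bond_list(topo)
        for fr in frames:
            coords = unwrap_peptide(fr, topo)
            got = sorted(float(np.linalg.norm(coords[b] - coords[a]))
                         for a, b in bonds)
            assert np.allclose(got, template, atol=1e-9)

    def test_broken_molecule_rejected(self, small_system):
        _, topo, frames, _ = small_system
        fr = frames[0]
        corrupted = fr.coords.copy()
        corrupted[topo.peptide_indices[5]] += 1.0  # tear one atom away
        with pytest.raises(ValueError, match="broken"):
            unwrap_peptide(TrajectoryFrame(fr.time, fr.box, corrupted), topo)


def spec_template_bonds(spec, topo):
    from tibind.synthetic import build_conformer
    _, _, coords, _ = build_conformer(spec.sequence, spec.template_eeds[0])
    bonds = peptide_bond_list(topo)
    start = topo.peptide_indices[0]
    return sorted(float(np.linalg.norm(coords[b - start] - coords[a - start]))
                  for a, b in bonds)


class TestSsdEed:
    def test_ssd_matches_planted_truth(self, benchmark, benchmark_classes):
        _, topo, frames, truth = benchmark
        cls = benchmark_classes
        for i in range(0, 200, 7):
            coords = unwrap_peptide(frames[i], topo)
            assert compute_ssd(frames[i], cls, topo, coords=coords) == \
                pytest.approx(truth.true_ssd[i], abs=1e-6)

    def test_ssd_invariant_under_xy_translation_and_rewrap(
            self, benchmark, benchmark_classes):
        _, topo, frames, _ = benchmark
        fr = frames[0]
        cls = benchmark_classes
        ref = compute_ssd(fr, cls, topo, coords=unwrap_peptide(fr, topo))
        moved = (fr.coords + np.array([1.3, -0.7, 0.0])) % fr.box
        fr2 = TrajectoryFrame(fr.time, fr.box, moved)
        assert compute_ssd(fr2, cls, topo, coords=unwrap_peptide(fr2, topo)) == \
            pytest.approx(ref, abs=1e-9)

    def test_ssd_symmetric_under_z_mirror(self, benchmark, benchmark_classes):
        _, topo, frames, _ = benchmark
        fr = frames[0]
        ref = compute_ssd(fr, benchmark_classes, topo,
                          coords=unwrap_peptide(fr, topo))
        mirrored = fr.coords.copy()
        mirrored[:, 2] = (fr.box[2] - mirrored[:, 2]) % fr.box[2]
        fr2 = TrajectoryFrame(fr.time, fr.box, mirrored)
        cls2 = classify_atoms(topo, fr2)
        assert compute_ssd(fr2, cls2, topo, coords=unwrap_peptide(fr2, topo)) == \
            pytest.approx(ref, abs=1e-9)

    def test_eed_from_known_calpha_positions(self, small_system):
        _, topo, frames, _ = small_system
        cls = classify_atoms(topo, frames[0])
        coords = frames[0].coords.copy()
        coords[cls.peptide_CA[1]] = [0.0, 0.0, 0.0]
        coords[cls.peptide_CA[6]] = [0.0, 0.0, 1.2]
        assert compute_eed(frames[0], cls, coords=coords) == pytest.approx(1.2)

    def test_eed_bounded_by_extended_chain(self, benchmark, benchmark_classes):
        _, topo, frames, _ = benchmark
        for fr in frames[:100]:
            coords = unwrap_peptide(fr, topo)
            assert compute_eed(fr, benchmark_classes, coords=coords) <= 5 * 0.40


class TestBindingProfile:
    def test_always_bound_series(self):
        t = np.arange(10.0)
        prof = profile_from_series(t, np.full(10, 0.5), np.full(10, 1.0))
        assert prof.percent_bound == 100.0
        assert prof.eed_d is None and prof.std_d is None
        assert len(prof.events) == 1 and prof.events[0][2] == "bound"

    def test_alternating_series_is_half_bound(self):
        t = np.arange(10.0)
        ssd = np.where(np.arange(10) % 2 == 0, 0.5, 1.5)
        prof = profile_from_series(t, ssd, np.ones(10))
        assert prof.percent_bound == pytest.approx(50.0)
        assert len(prof.events) == 10

    def test_threshold_is_strict(self):
        prof = profile_from_series([0.0, 1.0], [1.0, 0.999], [1.0, 1.0])
        # SSD exactly at the threshold counts as desorbed
        assert prof.percent_bound == pytest.approx(50.0)

    def test_events_partition_frames(self, benchmark_profile):
        prof = benchmark_profile
        n_from_events = 0
        for t0, t1, _ in prof.events:
            i0 = np.searchsorted(prof.times, t0)
            i1 = np.searchsorted(prof.times, t1)
            n_from_events += i1 - i0 + 1
        assert n_from_events == prof.n_frames
        assert int(prof.bound.sum()) + int((~prof.bound).sum()) == prof.n_frames

    def test_state_conditioned_eed_uses_population_sd(self):
        t = np.arange(4.0)
        eed = np.array([1.0, 2.0, 1.0, 2.0])
        prof = profile_from_series(t, np.full(4, 0.5), eed)
        assert prof.eed_a == pytest.approx(1.5)
        assert prof.std_a == pytest.approx(0.5)  # divide-by-N convention

    def test_debounce_merges_flicker(self):
        ssd = np.array([0.5] * 5 + [1.5] + [0.5] * 5)
        prof = profile_from_series(np.arange(11.0), ssd, np.ones(11),
                                   AnalysisParams(min_dwell_frames=2))
        assert prof.percent_bound == 100.0
        assert len(prof.events) == 1

    def test_empty_production_window_rejected(self):
        with pytest.raises(ValueError, match="production"):
            profile_from_series([0.0, 1.0], [0.5, 0.5], [1.0, 1.0],
                                AnalysisParams(production_start=10.0))

    def test_trajectory_and_series_paths_agree(self, benchmark, benchmark_classes,
                                               benchmark_profile):
        _, topo, frames, _ = benchmark
        p1 = benchmark_profile
        p2 = profile_from_series(p1.times, p1.ssd, p1.eed)
        assert p2.percent_bound == pytest.approx(p1.percent_bound)
        assert p2.eed_a == pytest.approx(p1.eed_a)

    def test_percent_bound_tracks_markov_truth(self, benchmark, benchmark_profile):
        _, _, _, truth = benchmark
        assert benchmark_profile.percent_bound == \
            pytest.approx(100.0 * truth.states.mean(), abs=1e-9)


class TestRanking:
    @staticmethod
    def _profile(percent):
        n = 100
        n_bound = int(round(n * percent / 100))
        ssd = np.concatenate([np.full(n_bound, 0.5), np.full(n - n_bound, 1.5)])
        return profile_from_series(np.arange(n, dtype=float), ssd, np.ones(n))

    def test_sorted_by_percent_then_label(self):
        profs = {"RKLPDA": self._profile(96.0), "PLARKD": self._profile(100.0),
                 "AAAAAA": self._profile(96.0)}
        df = rank_peptides(profs)
        assert df["sequence"].tolist() == ["PLARKD", "AAAAAA", "RKLPDA"]
        assert df["percent_bound"].is_monotonic_decreasing

    def test_ranking_tsv_report_rounding(self, tmp_path):
        df = rank_peptides({"ABCDEF": self._profile(100.0)})
        out = tmp_path / "ranking.tsv"
        write_ranking_tsv(df, out)
        lines = out.read_text().splitlines()
        assert lines[1].split("\t")[1] == "100.00"
        assert lines[1].split("\t")[-1] == "-"  # never desorbed: no std_d

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_peptides({})
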