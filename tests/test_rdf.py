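"""Radial distribution functions, selections and the Na+ bridging filter."""

import numpy as np
import pytest

from tibind.rdf import (RDFResult, SelectionError, bridging_na_filter,
                        compute_rdf, conditional_rdf, first_peak,
                        resolve_selection, write_rdf)
from tibind.topology import TrajectoryFrame


class TestSelections:
    def test_guanidinium_nitrogens_of_position_1(self, benchmark, benchmark_classes):
        _, topo, _, _ = benchmark
        sel = resolve_selection("sidechain-N pos 1", topo, benchmark_classes)
        assert sel.size == 3
        assert all(topo.names[i] in ("NE", "NH1", "NH2") for i in sel)

    def test_single_calpha(self, benchmark, benchmark_classes):
        _, topo, _, _ = benchmark
        sel = resolve_selection("CA pos 3", topo, benchmark_classes)
        assert sel.size == 1
        assert topo.names[sel[0]] == "CA"

    def test_residue_letter_qualifier(self, benchmark, benchmark_classes):
        _, topo, _, _ = benchmark
        sel = resolve_selection("CA res A,L,P", topo, benchmark_classes)
        assert sel.size == 3  # L3, P4, A6 of RKLPDA

    def test_surface_of_empty_without_hydroxyls(self):
        from tibind.synthetic import SyntheticSpec, generate_synthetic_system
        topo, _, cls, _ = generate_synthetic_system(
            SyntheticSpec(hydroxyl_fraction=0.0), seed=2)
        assert resolve_selection("surface OF", topo, cls).size == 0
        assert resolve_selection("surface OB", topo, cls).size > 0

    def test_cterm_and_nterm(self, benchmark, benchmark_classes):
        _, topo, _, _ = benchmark
        assert resolve_selection("CTERM-O", topo, benchmark_classes).size == 2
        assert resolve_selection("NTERM-N", topo, benchmark_classes).size == 1

    @pytest.mark.parametrize("expr, msg", [
        ("bogus", "token 1"),
        ("surface XY", "token 2"),
        ("CA pos notanumber", "token 3"),
        ("sidechain-N wat 1", "token 2"),
    ])
    def test_parse_errors_report_position(self, benchmark, benchmark_classes,
                                          expr, msg):
        _, topo, _, _ = benchmark
        with pytest.raises(SelectionError, match=msg):
            resolve_selection(expr, topo, benchmark_classes)


def _frame(coords, box=(4.0, 4.0, 4.0)):
    return TrajectoryFrame(time=0.0, box=np.asarray(box, dtype=float),
                           coords=np.asarray(coords, dtype=float))


class TestComputeRdf:
    def test_ideal_gas_is_unity(self):
        rng = np.random.default_rng(11)
        box = np.array([4.0, 4.0, 4.0])
        a = rng.uniform(0, 4, size=(2500, 3))
        b = rng.uniform(0, 4, size=(2500, 3))
        fr = _frame(np.vstack([a, b]), box)
        res = compute_rdf([fr], np.arange(2500), np.arange(2500, 5000),
                          r_max=0.6, bin_width=0.02)
        window = (res.bin_centers >= 0.3) & (res.bin_centers <= 0.5)
        assert np.all(np.abs(res.g[window] - 1.0) < 0.05)
        assert abs(res.g[window].mean() - 1.0) < 0.02

    def test_delta_pair_lands_in_one_bin(self):
        fr = _frame([[1.0, 1.0, 1.0], [1.25, 1.0, 1.0]])
        res = compute_rdf([fr], np.array([0]), np.array([1]),
                          r_max=0.6, bin_width=0.002)
        assert res.counts.sum() == 1
        assert res.counts[int(0.25 / 0.002)] == 1

    def test_minimum_image_distance_used(self):
        # atoms 0.2 nm apart across the x boundary
        fr = _frame([[0.05, 2.0, 2.0], [3.85, 2.0, 2.0]])
        res = compute_rdf([fr], np.array([0]), np.array([1]),
                          r_max=0.6, bin_width=0.002)
        assert res.counts.sum() == 1
        hit = int(np.flatnonzero(res.counts)[0])
        assert res.bin_centers[hit] == pytest.approx(0.2, abs=0.003)

    def test_count_conservation(self, benchmark, benchmark_classes):
        _, topo, frames, _ = benchmark
        sel_a = benchmark_classes.peptide_O
        sel_b = np.concatenate([benchmark_classes.OB, benchmark_classes.OF])
        sub = frames[:40]
        res = compute_rdf(sub, sel_a, sel_b, r_max=0.8, bin_width=0.01)
        total = 0
        from tibind.topology import min_image
        for fr in sub:
            d = min_image(fr.coords[sel_a][:, None] - fr.coords[sel_b][None],
                          fr.box)
            total += int((np.linalg.norm(d, axis=-1) < 0.8).sum())
        assert res.counts.sum() == total

    def test_self_pairs_excluded(self):
        fr = _frame([[1.0, 1.0, 1.0], [1.2, 1.0, 1.0]])
        res = compute_rdf([fr], np.array([0, 1]), np.array([0, 1]),
                          r_max=0.6, bin_width=0.01)
        assert res.counts.sum() == 2  # the 0-1 pair both ways, no 0-0/1-1

    def test_r_max_beyond_half_box_rejected(self):
        fr = _frame([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]], box=(2.0, 2.0, 2.0))
        with pytest.raises(ValueError, match="half"):
            compute_rdf([fr], np.array([0]), np.array([1]), r_max=1.2)

    def test_empty_selection_rejected(self):
        fr = _frame([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="empty"):
            compute_rdf([fr], np.array([], dtype=int), np.array([0]))


class TestFirstPeak:
    @staticmethod
    def _rdf_from_g(g, bin_width=0.01):
        g = np.asarray(g, dtype=float)
        edges = np.arange(len(g) + 1) * bin_width
        return RDFResult(bin_edges=edges, g=g, counts=np.zeros(len(g), dtype=int),
                         frames_used=1, mean_n_a=1.0, n_b=1, normalization="test")

    def test_two_peak_histogram_returns_short_range_peak(self):
        centers = np.arange(120) * 0.01 + 0.005
        g = np.exp(-((centers - 0.28) / 0.02) ** 2) * 5 + \
            np.exp(-((centers - 0.55) / 0.02) ** 2) * 3
        r, gp, flag = first_peak(self._rdf_from_g(g))
        assert r == pytest.approx(0.285, abs=0.011)
        assert not flag

    def test_monotone_increase_flagged(self):
        g = np.linspace(0, 2, 120)
        r, gp, flag = first_peak(self._rdf_from_g(g))
        assert flag

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            first_peak(self._rdf_from_g(np.zeros(120)))

    def test_peak_stable_under_bin_halving(self, benchmark, benchmark_classes):
        _, topo, frames, _ = benchmark
        sel_a = resolve_selection("sidechain-N pos 1", topo, benchmark_classes)
        sel_b = benchmark_classes.OF
        sub = frames[:150]
        r1 = first_peak(compute_rdf(sub, sel_a, sel_b, bin_width=0.004))[0]
        r2 = first_peak(compute_rdf(sub, sel_a, sel_b, bin_width=0.002))[0]
        assert abs(r1 - r2) <= 0.004


class TestBridgingFilter:
    def test_dual_criterion_geometry(self, benchmark, benchmark_classes):
        _, topo, frames, _ = benchmark
        cls = benchmark_classes
        fr = frames[0]
        of_atom = fr.coords[cls.OF[0]]
        pep_o = fr.coords[cls.peptide_O[0]]
        coords = fr.coords.copy()
        # ion 1: near a hydroxyl O only -> excluded
        coords[cls.NA[1]] = of_atom + [0.0, 0.0, 0.25]
        # ion 2: near a peptide O only -> excluded
        coords[cls.NA[2]] = pep_o + [0.0, 0.25, 0.0]
        # ion 3: far from everything -> excluded
        coords[cls.NA[3]] = [0.1, 0.1, fr.box[2] - 1.0]
        fr2 = TrajectoryFrame(fr.time, fr.box, coords % fr.box)
        got = set(bridging_na_filter(fr2, cls).tolist())
        assert cls.NA[1] not in got and cls.NA[2] not in got and cls.NA[3] not in got

    def test_satisfying_both_criteria_selected(self, benchmark, benchmark_classes):
        _, topo, frames, _ = benchmark
        cls = benchmark_classes
        fr = frames[0]
        coords = fr.coords.copy()
        of_atom = coords[cls.OF[0]]
        # put a peptide O 0.5 nm above the hydroxyl and the ion midway
        coords[cls.peptide_O[0]] = of_atom + [0.0, 0.0, 0.5]
        coords[cls.NA[0]] = of_atom + [0.0, 0.0, 0.25]
        fr2 = TrajectoryFrame(fr.time, fr.box, coords % fr.box)
        assert cls.NA[0] in bridging_na_filter(fr2, cls).tolist()

    def test_planted_bridges_recovered_exactly(self, benchmark, benchmark_classes):
        _, topo, frames, truth = benchmark
        for i in range(0, len(frames), 13):
            got = bridging_na_filter(frames[i], benchmark_classes)
            assert got.tolist() == truth.bridge_na[i].tolist()

    def test_no_ions_empty(self, benchmark, benchmark_classes):
        from dataclasses import replace
        _, topo, frames, _ = benchmark
        cls = replace(benchmark_classes, NA=np.array([], dtype=int))
        assert bridging_na_filter(frames[0], cls).size == 0


class TestConditionalRdf:
    def test_always_true_filter_equals_plain_rdf(self, benchmark, benchmark_classes):
        _, topo, frames, _ = benchmark
        cls = benchmark_classes
        fr = frames[0]
        coords = fr.coords.copy()
        of_atom = coords[cls.OF[0]]
        # park every Na+ in bridging geometry around one hydroxyl
        coords[cls.peptide_O[0]] = of_atom + [0.0, 0.0, 0.5]
        for k, na in enumerate(cls.NA):
            coords[na] = of_atom + [0.02 * k, 0.0, 0.25]
        fr2 = TrajectoryFrame(fr.time, fr.box, coords % fr.box)
        assert bridging_na_filter(fr2, cls).size == cls.NA.size
        sel_b = cls.peptide_O
        cond = conditional_rdf([fr2], cls, sel_b, r_max=0.8, bin_width=0.01)
        plain = compute_rdf([fr2], cls.NA, sel_b, r_max=0.8, bin_width=0.01)
        assert np.allclose(cond.g, plain.g)
        assert np.array_equal(cond.counts, plain.counts)

    def test_no_bridging_ions_zero_g(self, benchmark, benchmark_classes):
        _, topo, frames, truth = benchmark
        empty = [i for i in range(300) if truth.bridge_na[i].size == 0][:5]
        sub = [frames[i] for i in empty]
        res = conditional_rdf(sub, benchmark_classes, benchmark_classes.peptide_O,
                              r_max=0.8, bin_width=0.01)
        assert np.all(res.g == 0.0)
        assert res.mean_n_a == 0.0

    def test_frame_mean_mode_runs(self, benchmark, benchmark_classes):
        _, topo, frames, _ = benchmark
        res = conditional_rdf(frames[:50], benchmark_classes,
                              benchmark_classes.peptide_O, r_max=0.8,
                              bin_width=0.01, mode="frame_mean")
        assert res.g.shape == res.counts.shape


def test_write_rdf_header_and_columns(tmp_path):
    res = RDFResult(bin_edges=np.array([0.0, 0.1, 0.2]), g=np.array([0.0, 2.0]),
                    counts=np.array([0, 4]), frames_used=2, mean_n_a=1.0, n_b=3,
                    normalization="test")
    p = tmp_path / "out.tsv"
    write_rdf(res, p, label_a="N1", label_b="OF")
    lines = p.read_text().splitlines()
    assert lines[0].startswith("# RDF N1 - OF")
    assert len(lines[4].split()) == 2
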