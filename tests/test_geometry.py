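import numpy as np
import pytest
from hypothesis import given, strategies as st

from g4annotate import (
    GeometryConstants,
    SyntheticSpec,
    build_g4,
    diagonal_feasibility,
    loop_span_model,
    stem_height,
    successive_c5_distances,
    tetrad_planarity,
)
from g4annotate.geometry import fit_plane, rise_and_twist
from g4annotate.structure_io import Nucleotide, StructureModel
from g4annotate.tetrads import assemble_stem, detect_tetrads


def _stem_for(topology, n_tetrads=3, **kw):
    model = build_g4(SyntheticSpec(topology=topology, n_tetrads=n_tetrads, **kw))
    tetrads = detect_tetrads(model)
    return assemble_stem(tetrads, model), model


class TestLoopSpanModel:
    def test_printed_values(self):
        assert loop_span_model(1) == pytest.approx(12.5)
        assert loop_span_model(2) == pytest.approx(18.75)
        assert loop_span_model(3) == pytest.approx(25.0)

    def test_n0(self):
        assert loop_span_model(0) == pytest.approx(6.25)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            loop_span_model(-1)

    @given(st.integers(min_value=0, max_value=100))
    def test_strictly_increasing(self, n):
        assert loop_span_model(n + 1) > loop_span_model(n)


class TestDiagonalFeasibility:
    def test_threshold_identity(self):
        res = diagonal_feasibility(3)
        assert res.threshold == pytest.approx(21.0 + 2 * 3.42)
        assert res.threshold == pytest.approx(27.84)

    def test_three_nt_infeasible(self):
        res = diagonal_feasibility(3)
        assert not res.feasible
        assert res.modeled_length == pytest.approx(25.0)

    def test_four_nt_feasible(self):
        res = diagonal_feasibility(4)
        assert res.feasible
        assert res.modeled_length > 31.0

    def test_large_n_feasible(self):
        assert diagonal_feasibility(100).feasible

    @given(st.integers(min_value=0, max_value=60))
    def test_monotone(self, n):
        if diagonal_feasibility(n).feasible:
            assert diagonal_feasibility(n + 1).feasible

    def test_constants_propagate(self):
        c = GeometryConstants(mean_c5_step=7.0, diagonal_c5=20.0, mean_rise=3.0)
        res = diagonal_feasibility(3, c)
        assert res.threshold == pytest.approx(26.0)
        assert res.modeled_length == pytest.approx(loop_span_model(3, c)) == pytest.approx(28.0)

    def test_constants_validated(self):
        with pytest.raises(ValueError):
            GeometryConstants(mean_rise=-1.0)


class TestSuccessiveC5:
    def test_single_pair_direct_distance(self):
        a = Nucleotide("A", 1, "T", False, "T", atoms={"C5'": np.zeros(3)})
        b = Nucleotide("A", 2, "T", False, "T", atoms={"C5'": np.array([6.25, 0, 0])})
        model = StructureModel(chains=[[a, b]])
        dists, mean, skipped = successive_c5_distances(model)
        assert dists == [pytest.approx(6.25)]
        assert mean == pytest.approx(6.25)
        assert skipped == 0

    def test_22nt_parallel_mean_in_range(self):
        model = build_g4(
            SyntheticSpec(topology="parallel", loop_lengths=(1, 2, 1), fn5=3, fn3=3)
        )
        assert model.n_residues == 22
        _, mean, _ = successive_c5_distances(model)
        assert 5.5 <= mean <= 7.0

    def test_22nt_mean_against_text_scan_oracle(self, tmp_path):
        # independent oracle: re-extract C5' coordinates from the PDB text
        from g4annotate.synthetic import write_pdb

        model = build_g4(
            SyntheticSpec(topology="parallel", loop_lengths=(1, 2, 1), fn5=3, fn3=3)
        )
        p = tmp_path / "m.pdb"
        write_pdb(model, p)
        coords = []
        for line in p.read_text().splitlines():
            if line.startswith("ATOM") and line[12:16].strip() == "C5'":
                coords.append(
                    (int(line[22:26]), np.array([float(line[30 + 8 * k:38 + 8 * k]) for k in range(3)]))
                )
        coords.sort()
        oracle = [
            float(np.linalg.norm(b - a))
            for (ra, a), (rb, b) in zip(coords, coords[1:])
            if rb == ra + 1
        ]
        _, mean, _ = successive_c5_distances(model)
        assert mean == pytest.approx(float(np.mean(oracle)), abs=1e-3)

    def test_missing_atoms_skipped(self):
        a = Nucleotide("A", 1, "T", False, "T", atoms={"C5'": np.zeros(3)})
        b = Nucleotide("A", 2, "T", False, "T", atoms={})
        model = StructureModel(chains=[[a, b]])
        dists, mean, skipped = successive_c5_distances(model)
        assert dists == [] and mean is None and skipped == 1


class TestStemHeight:
    def test_three_tetrad(self):
        stem, _ = _stem_for("parallel", 3)
        h, _ = stem_height(stem)
        assert h == pytest.approx(12.0, abs=1.5)

    def test_four_tetrad(self):
        stem, _ = _stem_for("parallel", 4)
        h, _ = stem_height(stem)
        assert h == pytest.approx(18.0, abs=1.5)

    def test_single_tetrad_zero(self):
        model = build_g4(SyntheticSpec(topology="parallel", n_tetrads=3))
        tetrads = detect_tetrads(model)[:1]
        stem = assemble_stem(tetrads, model)
        h, _ = stem_height(stem)
        assert h == 0.0

    def test_scales_linearly_with_tetrad_count(self):
        heights = []
        for n in (2, 3, 4):
            stem, _ = _stem_for("parallel", n)
            heights.append(stem_height(stem)[0])
        d1 = heights[1] - heights[0]
        d2 = heights[2] - heights[1]
        assert d1 == pytest.approx(d2, abs=0.8)


class TestRiseAndTwist:
    def test_round_trip_against_generator(self):
        stem, _ = _stem_for("antiparallel-chair", 3)
        rises, twists = rise_and_twist(stem)
        assert all(r == pytest.approx(3.42, abs=0.05) for r in rises)
        assert all(t == pytest.approx(30.0, abs=1.0) for t in twists)

    def test_left_handed_negative_twist(self):
        stem, _ = _stem_for("parallel", 3, twist=-30.0)
        _, twists = rise_and_twist(stem)
        assert all(t == pytest.approx(-30.0, abs=1.0) for t in twists)

    def test_single_tetrad_empty(self):
        model = build_g4(SyntheticSpec(topology="parallel"))
        stem = assemble_stem(detect_tetrads(model)[:1], model)
        assert rise_and_twist(stem) == ([], [])


class TestPlanarity:
    def test_coplanar_points_zero(self):
        pts = [np.array([x, y, 0.0]) for x in (0, 1) for y in (0, 1)]
        _, _, rms = fit_plane(pts)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_ideal_tetrad_planar(self):
        stem, _ = _stem_for("parallel", 3)
        for tet in stem.tetrads:
            assert tetrad_planarity(tet) < 0.2


class TestRigidMotionInvariance:
    def test_geometry_invariant(self):
        from scipy.spatial.transform import Rotation as R

        model = build_g4(SyntheticSpec(topology="antiparallel-basket", n_tetrads=3))
        stem = assemble_stem(detect_tetrads(model), model)
        h0, _ = stem_height(stem)
        r0, t0 = rise_and_twist(stem)
        _, mean0, _ = successive_c5_distances(model)

        rot = R.from_euler("xyz", [31.0, -57.0, 111.0], degrees=True)
        shift = np.array([13.0, -44.0, 91.0])
        import copy

        moved = copy.deepcopy(model)
        for nt in moved.residues():
            for name in nt.atoms:
                nt.atoms[name] = rot.apply(nt.atoms[name]) + shift
        stem2 = assemble_stem(detect_tetrads(moved), moved)
        h1, _ = stem_height(stem2)
        r1, t1 = rise_and_twist(stem2)
        _, mean1, _ = successive_c5_distances(moved)
        assert h1 == pytest.approx(h0, abs=1e-6)
        assert np.allclose(r1, r0, atol=1e-6)
        assert np.allclose(t1, t0, atol=1e-6)
        assert mean1 == pytest.approx(mean0, abs=1e-9)
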