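import numpy as np
import pytest

from g4annotate import (
    BuildError,
    SyntheticSpec,
    build_g4,
    perturb,
    read_structure,
)
from g4annotate.pipeline import annotate_structure
from g4annotate.rules import RuleQuery, allowed_topologies
from g4annotate.synthetic import DEFAULT_LOOPS, write_pdb
from g4annotate.geometry import stem_height
from g4annotate.tetrads import assemble_stem, detect_tetrads

from conftest import ALL_TOPOLOGIES, TABLE1_GROOVES, TABLE4_SIDES


class TestBuild:
    def test_parallel_round_trip(self):
        ann = annotate_structure(build_g4(SyntheticSpec(topology="parallel", loop_lengths=(1, 2, 1))))
        assert ann.topology == "parallel"
        assert ann.loop_combination == "-p-p-p"

    def test_chair_round_trip_with_groove(self):
        ann = annotate_structure(
            build_g4(SyntheticSpec(topology="antiparallel-chair", n_tetrads=2, loop_lengths=(2, 3, 2)))
        )
        assert ann.topology == "antiparallel-chair"
        assert ann.groove["letters"] == "wnwn"

    def test_short_diagonal_rejected(self):
        with pytest.raises(BuildError, match="diagonal"):
            build_g4(SyntheticSpec(topology="antiparallel-basket", loop_lengths=(2, 2, 2)))

    def test_short_diagonal_forced_builds(self):
        model = build_g4(
            SyntheticSpec(topology="antiparallel-basket", loop_lengths=(2, 3, 2), force=True)
        )
        assert model.n_residues > 0

    def test_unknown_topology(self):
        with pytest.raises(BuildError):
            build_g4(SyntheticSpec(topology="sideways"))

    def test_bad_tetrad_count(self):
        with pytest.raises(BuildError):
            build_g4(SyntheticSpec(topology="parallel", n_tetrads=5))

    def test_hoogsteen_distances_within_cutoff(self, parallel_model):
        gs = {g.residue_number: g for g in parallel_model.guanines()}
        tetrads = detect_tetrads(parallel_model)
        for tet in tetrads:
            ring = tet.guanines
            for k in range(4):
                donor, acceptor = ring[k], ring[(k + 1) % 4]
                assert np.linalg.norm(donor.atoms["N1"] - acceptor.atoms["O6"]) <= 3.5
                assert np.linalg.norm(donor.atoms["N2"] - acceptor.atoms["N7"]) <= 3.5

    def test_seed_determinism(self):
        spec = SyntheticSpec(topology="hybrid2", noise_sigma=0.2, seed=5)
        a, b = build_g4(spec), build_g4(spec)
        for x, y in zip(a.residues(), b.residues()):
            for name in x.atoms:
                assert np.array_equal(x.atoms[name], y.atoms[name])

    def test_stem_height_scales_with_tetrads(self):
        hs = []
        for n in (2, 3, 4):
            model = build_g4(SyntheticSpec(topology="parallel", n_tetrads=n))
            stem = assemble_stem(detect_tetrads(model), model)
            hs.append(stem_height(stem)[0])
        assert hs[0] < hs[1] < hs[2]


class TestGroundTruthRoundTrip:
    @pytest.mark.parametrize("topology", ALL_TOPOLOGIES)
    @pytest.mark.parametrize("n_tetrads", [2, 3, 4])
    def test_full_recovery(self, topology, n_tetrads, grid_annotations):
        model, ann = grid_annotations[(topology, n_tetrads)]
        gt = model.metadata["ground_truth"]
        assert ann.topology == gt["topology"]
        assert ann.strand_pattern == gt["strand_pattern"]
        assert ann.n_tetrads == gt["n_tetrads"]
        assert ann.gc_pattern == gt["gc_pattern"]
        assert [lp["kind"] for lp in ann.loops] == gt["loop_kinds"]
        assert [lp["length_nt"] for lp in ann.loops] == gt["loop_lengths"]
        assert ann.groove["letters"] == TABLE1_GROOVES[topology]
        assert ann.extremity_sides == TABLE4_SIDES[topology]

    @pytest.mark.parametrize("topology", ALL_TOPOLOGIES)
    def test_cross_module_rule_consistency(self, topology, grid_annotations):
        # the annotated topology is allowed by the rule engine for its own
        # default loop lengths (defaults were chosen to be rule-consistent)
        _, ann = grid_annotations[(topology, 3)]
        L1, L2, L3 = DEFAULT_LOOPS[topology]
        pred = allowed_topologies(RuleQuery(L1, L2, L3))
        assert topology in pred.allowed_topologies() or pred.caveats


class TestPerturb:
    def test_sigma_zero_identity(self, parallel_model):
        out = perturb(parallel_model, 0.0, seed=1)
        for a, b in zip(out.residues(), parallel_model.residues()):
            for name in a.atoms:
                assert np.array_equal(a.atoms[name], b.atoms[name])

    def test_same_seed_identical(self, parallel_model):
        a = perturb(parallel_model, 0.3, seed=9)
        b = perturb(parallel_model, 0.3, seed=9)
        for x, y in zip(a.residues(), b.residues()):
            for name in x.atoms:
                assert np.array_equal(x.atoms[name], y.atoms[name])

    def test_negative_sigma_rejected(self, parallel_model):
        with pytest.raises(ValueError):
            perturb(parallel_model, -0.1)

    @pytest.mark.parametrize("topology", ALL_TOPOLOGIES)
    def test_topology_invariant_at_sigma_03(self, topology, grid_annotations):
        model, _ = grid_annotations[(topology, 3)]
        for seed in (1, 2):
            assert annotate_structure(perturb(model, 0.3, seed=seed)).topology == topology


class TestWritePdb:
    def test_build_write_read_annotate_identity(self, tmp_path):
        model = build_g4(SyntheticSpec(topology="hybrid3", n_tetrads=3))
        direct = annotate_structure(model)
        p = tmp_path / "h3.pdb"
        write_pdb(model, p)
        reread = annotate_structure(read_structure(p))
        d1, d2 = direct.to_dict(), reread.to_dict()
        d1.pop("source_id"), d2.pop("source_id")
        assert d1 == d2

    def test_two_block_round_trip(self, tmp_path):
        model = build_g4(SyntheticSpec(topology="two-block:parallel/parallel"))
        p = tmp_path / "tb.pdb"
        write_pdb(model, p)
        ann = annotate_structure(read_structure(p))
        assert ann.n_blocks == 2
        assert ann.blocks == [[1, 2], [3, 4]]
        assert ann.topology == "two-block:parallel/parallel"

    def test_four_tetrad_short_loops_build_but_warn(self, tmp_path):
        model = build_g4(SyntheticSpec(topology="parallel", n_tetrads=4, loop_lengths=(1, 2, 1)))
        ann = annotate_structure(model)
        assert ann.topology == "parallel"
        assert any("propeller" in w for w in ann.warnings)


class TestGcOverrides:
    def test_all_syn_parallel(self):
        model = build_g4(SyntheticSpec(topology="parallel", gc_pattern=("ssss", "ssss", "ssss")))
        ann = annotate_structure(model)
        assert ann.topology == "parallel"
        assert ann.gc_pattern == ["ssss", "ssss", "ssss"]

    def test_inconsistent_gc_rejected(self):
        with pytest.raises(BuildError, match="polarit"):
            build_g4(SyntheticSpec(topology="parallel", gc_pattern=("ssaa", "aaaa", "aaaa")))
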