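"""Superposition, regional RMSD, and the substitution screen."""

import numpy as np
import pytest

from _oracles import quaternion_grid_rmsd
from olfevo.structure import (
    RegionAnnotation,
    StructureModel,
    confidence_mask,
    diff_positions,
    kabsch_superpose,
    read_structure,
    region_rmsd,
    run_screen,
    write_structure,
)
from olfevo.synthetic import MockPredictor, StructSimSpec, gen_structure_pair


def _random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.normal(scale=10.0, size=3)


class TestPDBRoundTrip:
    def test_write_read_identity(self, structure_pair, tmp_path):
        bg, _ = structure_pair
        path = tmp_path / "bg.pdb"
        write_structure(bg, path)
        back = read_structure(path)
        assert back.sequence == bg.sequence
        # PDB stores coordinates to 3 decimals
        np.testing.assert_allclose(back.coords, bg.coords, atol=5.1e-4)
        np.testing.assert_allclose(back.plddt, bg.plddt, atol=0.01)

    def test_no_calpha_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text(
            "ATOM      1  CB  ALA A   1       0.000   0.000   0.000  1.00 90.00           C\n"
            "END\n"
        )
        with pytest.raises(ValueError, match="C-alpha"):
            read_structure(path)

    def test_chain_break_rejected(self, tmp_path):
        lines = []
        for i, rid in enumerate([1, 2, 5], 1):
            lines.append(
                f"ATOM  {i:5d}  CA  ALA A{rid:4d}    {float(i):8.3f}{0.0:8.3f}{0.0:8.3f}"
                f"  1.00 90.00           C"
            )
        path = tmp_path / "gap.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        with pytest.raises(ValueError, match="chain break"):
            read_structure(path)
        assert read_structure(path, allow_gaps=True).n_residues == 3


class TestConfidenceMask:
    def test_uniform_high_confidence_full(self):
        m = StructureModel("AAAA", np.zeros((4, 3)), np.full(4, 90.0))
        assert confidence_mask(m).all()

    def test_threshold_is_strict(self):
        m = StructureModel("AAA", np.zeros((3, 3)), np.array([69.9, 70.0, 70.1]))
        assert list(confidence_mask(m)) == [False, False, True]

    def test_terminal_residues_masked(self, struct_spec, structure_pair):
        bg, _ = structure_pair
        mask = confidence_mask(bg)
        assert not mask[:10].any() and not mask[-10:].any()
        assert mask[150:250].all()


class TestKabsch:
    def test_identical_zero(self, rng):
        pts = rng.normal(size=(30, 3))
        _, _, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_recovered(self, rng):
        pts = rng.normal(size=(40, 3))
        rot, trans = _random_rigid(rng)
        moved = pts @ rot.T + trans
        _, _, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_search_oracle(self, rng):
        for case in range(3):
            a = rng.normal(size=(50, 3)) * 5.0
            b = a + rng.normal(size=(50, 3)) * 1.0
            _, _, rmsd = kabsch_superpose(a, b)
            oracle = quaternion_grid_rmsd(a, b, seed=case)
            assert abs(rmsd - oracle) <= 1e-6
            assert rmsd <= oracle + 1e-9  # Kabsch attains the optimum

    def test_invariant_under_rigid_pretransform(self, rng):
        a = rng.normal(size=(25, 3))
        b = a + rng.normal(size=(25, 3)) * 0.5
        _, _, base = kabsch_superpose(a, b)
        rot, trans = _random_rigid(rng)
        _, _, moved = kabsch_superpose(a @ rot.T + trans, b)
        assert moved == pytest.approx(base, abs=1e-9)

    def test_proper_rotation(self, rng):
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3))
        rot, _, _ = kabsch_superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_degenerate_raises(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRegionRMSD:
    def test_identical_models_all_zero(self, structure_pair, struct_spec):
        bg, _ = structure_pair
        per_region, _, global_rmsd = region_rmsd(bg, bg, struct_spec.annotation)
        assert global_rmsd == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in per_region.values())

    def test_planted_divergence_confined_to_s5_s6(self):
        spec = StructSimSpec(seed=5, perturb_amplitude=2.0)
        bg, tg = gen_structure_pair(spec)
        per_region, dev, _ = region_rmsd(bg, tg, spec.annotation)
        target = max(per_region["S5"], per_region["S6"])
        others = [v for k, v in per_region.items() if k not in ("S5", "S6")]
        assert target > 5 * max(others)

    def test_deviation_profile_peaks_at_causal_sites(self):
        spec = StructSimSpec(seed=6)
        bg, tg = gen_structure_pair(spec)
        _, dev, _ = region_rmsd(bg, tg, spec.annotation)
        dev = np.nan_to_num(dev)
        order = np.argsort(dev)[::-1] + 1  # residue numbering
        top = set(order[:8])
        assert any(abs(p - 181) <= 1 for p in top)
        assert any(abs(p - 307) <= 1 for p in top)

    def test_empty_region_after_masking_raises(self, structure_pair):
        bg, tg = structure_pair
        ann = RegionAnnotation({"tip": (1, 3)})  # low-confidence N-terminus
        with pytest.raises(ValueError, match="tip"):
            region_rmsd(bg, tg, ann)


class TestDiffPositions:
    def test_identical_sequences_empty(self):
        assert diff_positions("ACDEF", "ACDEF") == []

    def test_two_differences_labeled(self):
        seq_a = "A" * 400
        seq_a = seq_a[:180] + "A" + seq_a[181:]
        seq_b = seq_a[:180] + "D" + seq_a[181:306] + "P" + seq_a[307:]
        seq_a = seq_a[:306] + "S" + seq_a[307:]
        cands = diff_positions(seq_a, seq_b)
        assert [c.label for c in cands] == ["A181D", "S307P"]

    def test_generator_plants_32_candidates(self, struct_spec, structure_pair):
        bg, tg = structure_pair
        assert len(diff_positions(bg.sequence, tg.sequence)) == 32

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            diff_positions("AA", "AAA")


class TestScreen:
    def test_recovers_planted_pair_among_decoys(self, struct_spec, structure_pair,
                                                mock_predictor):
        bg, tg = structure_pair
        target_model = mock_predictor(tg.sequence)
        res = run_screen(bg.sequence, tg.sequence, target_model, mock_predictor,
                         struct_spec.annotation)
        assert sorted(c.label for c in res.accepted) == ["A181D", "S307P"]
        assert res.converged
        assert res.initial_rmsd == pytest.approx(1.7, abs=0.25)
        assert res.final_rmsd < 0.15

    def test_trajectory_non_increasing(self, struct_spec, structure_pair, mock_predictor):
        bg, tg = structure_pair
        res = run_screen(bg.sequence, tg.sequence, mock_predictor(tg.sequence),
                         mock_predictor, struct_spec.annotation)
        traj = [res.initial_rmsd] + res.trajectory
        assert all(b < a for a, b in zip(traj, traj[1:]))

    def test_zero_candidates_trivially_converged(self, struct_spec, mock_predictor):
        spec = struct_spec
        bg_seq = None
        bg, _ = gen_structure_pair(spec)
        bg_seq = bg.sequence
        target_model = mock_predictor(bg_seq)
        res = run_screen(bg_seq, bg_seq, target_model, mock_predictor, spec.annotation)
        assert res.accepted == [] and res.converged

    def test_single_planted_site_single_round(self):
        spec = StructSimSpec(seed=21, causal_substitutions={190: ("L", "F")},
                             n_decoys=10, prediction_noise_sd=0.02)
        bg, tg = gen_structure_pair(spec)
        pred = MockPredictor(spec)
        res = run_screen(bg.sequence, tg.sequence, pred(tg.sequence), pred, spec.annotation)
        assert [c.label for c in res.accepted] == ["L190F"]
        assert len(res.trajectory) == 1

    @pytest.mark.parametrize("n_causal", [1, 2, 3])
    def test_recovery_across_planted_set_sizes(self, n_causal):
        positions = [175, 195, 310][:n_causal]
        for seed in range(5):
            subs = {p: ("A", "V") for p in positions}
            spec = StructSimSpec(seed=100 + seed, causal_substitutions=subs,
                                 n_decoys=20, prediction_noise_sd=0.04)
            bg, tg = gen_structure_pair(spec)
            pred = MockPredictor(spec)
            res = run_screen(bg.sequence, tg.sequence, pred(tg.sequence), pred,
                             spec.annotation)
            assert sorted(c.position for c in res.accepted) == positions

    def test_summary_reports_accepted_set(self, struct_spec, structure_pair, mock_predictor):
        bg, tg = structure_pair
        res = run_screen(bg.sequence, tg.sequence, mock_predictor(tg.sequence),
                         mock_predictor, struct_spec.annotation)
        text = res.summary()
        assert "A181D" in text and "S307P" in text and "converged" in text
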