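"""Coarse model construction, surrogate energy, hinge refinement and the
superposition metrics."""

import numpy as np
import pytest

from cirperm.fixtures import make_ideal_chain, make_two_domain_model
from cirperm.refine import (AXIAL_ANGLES, PLANE_ANGLES, Junction,
                            alignment_ratio, build_coarse_model, hinge_refine,
                            kabsch_rmsd, split_by_hinge, surrogate_energy)
from cirperm.seqalign import Alignment
from cirperm.structure import StructureError, structure_from_ca


def rodrigues(axis, angle_deg):
    """Independent rotation-matrix construction (Rodrigues formula)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


class TestCoarseModel:
    def test_identity_alignment_copies_template(self):
        tpl = make_ideal_chain(10, "helix")
        aln = Alignment((tpl.sequence, tpl.sequence), 0.0)
        model, energy = build_coarse_model(aln, tpl)
        np.testing.assert_allclose(model.ca_coords(), tpl.ca_coords())
        rmsd, _ = kabsch_rmsd(model.ca_coords(), tpl.ca_coords())
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert energy == pytest.approx(surrogate_energy(tpl))

    @pytest.mark.parametrize("anchor_gap", [15.2, 10.0, 7.0])
    def test_linker_spacing_near_ideal(self, anchor_gap):
        # template: two residues anchor_gap apart; target inserts GGG
        tpl = structure_from_ca(
            "AK", np.array([[0.0, 0, 0], [anchor_gap, 0, 0]]))
        aln = Alignment(("AGGGK", "A---K"), 0.0)
        model, _ = build_coarse_model(aln, tpl, linker="GGG")
        d = np.linalg.norm(np.diff(model.ca_coords(), axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) < 0.4)

    def test_template_mismatch_rejected(self):
        tpl = make_ideal_chain(5, "straight")
        aln = Alignment(("AAAAA", "AAAAA"), 0.0)
        with pytest.raises(StructureError, match="mismatch"):
            build_coarse_model(aln, tpl)

    def test_deterministic(self):
        tpl = make_ideal_chain(8, "helix")
        aln = Alignment((tpl.sequence[:4] + "GG" + tpl.sequence[4:],
                         tpl.sequence[:4] + "--" + tpl.sequence[4:]), 0.0)
        m1, e1 = build_coarse_model(aln, tpl, "GG")
        m2, e2 = build_coarse_model(aln, tpl, "GG")
        assert e1 == e2
        np.testing.assert_array_equal(m1.ca_coords(), m2.ca_coords())


class TestSurrogateEnergy:
    def test_ideal_chain_scores_zero(self):
        assert surrogate_energy(make_ideal_chain(10, "straight")) == \
            pytest.approx(0.0, abs=1e-20)

    def test_single_clash_adds_ten(self):
        base = make_ideal_chain(10, "straight")
        coords = np.vstack([base.ca_coords(), [[0.0, 2.0, 0.0]]])
        s = structure_from_ca(base.sequence + "A", coords)
        bond = (np.linalg.norm(coords[-1] - coords[-2]) - 3.8) ** 2
        assert surrogate_energy(s) == pytest.approx(bond + 10.0)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        s, _ = make_two_domain_model(seed=4)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.7])
        moved = structure_from_ca(s.sequence,
                                  rot.apply(s.ca_coords()) + [3, 4, 5])
        assert abs(surrogate_energy(moved) - surrogate_energy(s)) < 1e-9


class TestSplitByHinge:
    def test_smaller_proportion_selected(self):
        model, junction = make_two_domain_model(n1=40, n2=60, linker_len=3)
        frame = split_by_hinge(model, junction)
        assert not frame.small_is_cterm
        assert len(frame.small_serials) == 40

    def test_tie_takes_c_terminal_proportion(self):
        model, junction = make_two_domain_model(n1=50, n2=50, linker_len=3)
        frame = split_by_hinge(model, junction)
        assert frame.small_is_cterm
        assert frame.small_serials[0] == 54

    def test_hinge_is_middle_linker_residue(self):
        model, junction = make_two_domain_model(n1=10, n2=8, linker_len=3)
        frame = split_by_hinge(model, junction)
        np.testing.assert_allclose(frame.hinge, model.residues[11].ca)

    def test_direct_join_uses_termini_midpoint(self):
        model, _ = make_two_domain_model(n1=6, n2=6, linker_len=0)
        frame = split_by_hinge(model, Junction(joined_at=6))
        coords = model.ca_coords()
        np.testing.assert_allclose(frame.hinge,
                                   0.5 * (coords[5] + coords[6]))

    def test_axis_equivariance_under_rotation(self):
        from scipy.spatial.transform import Rotation
        model, junction = make_two_domain_model(seed=2)
        frame = split_by_hinge(model, junction)
        rot = Rotation.from_rotvec([0.4, 0.9, -0.3])
        moved = structure_from_ca(model.sequence, rot.apply(model.ca_coords()))
        frame2 = split_by_hinge(moved, junction)
        np.testing.assert_allclose(frame2.axis_r, rot.apply(frame.axis_r),
                                   atol=1e-9)


class TestHingeRefine:
    def test_exactly_162_snapshots(self):
        model, junction = make_two_domain_model(seed=0)
        frame = split_by_hinge(model, junction)
        rr = hinge_refine(model, frame)
        assert rr.n_snapshots == 162
        assert len({(t, p) for t, p, _ in rr.energies}) == 162

    def test_refined_energy_never_worse(self):
        for seed in range(5):
            model, junction = make_two_domain_model(seed=seed)
            frame = split_by_hinge(model, junction)
            rr = hinge_refine(model, frame)
            assert rr.best_energy <= surrogate_energy(model)

    def test_planted_optimum_found(self):
        model, junction = make_two_domain_model(seed=9)
        frame = split_by_hinge(model, junction)
        # build the target pose with an independent rotation implementation
        R = rodrigues(frame.axis_r, 120.0) @ rodrigues(frame.plane_normal,
                                                       40.0)
        target = model.ca_coords().copy()
        for serial in frame.small_serials:
            target[serial - 1] = R @ (target[serial - 1] - frame.hinge) + \
                frame.hinge

        def rigged(s):
            return float(np.sum((s.ca_coords() - target) ** 2))

        rr = hinge_refine(model, frame, energy_fn=rigged)
        assert rr.best_pose == (40, 120)
        assert rr.best_energy == pytest.approx(0.0, abs=1e-12)

    def test_rigid_body_contract(self):
        model, junction = make_two_domain_model(seed=3)
        frame = split_by_hinge(model, junction)
        rr = hinge_refine(
            model, frame,
            energy_fn=lambda s: float(s.ca_coords()[-1, 0]))  # arbitrary
        before, after = model.ca_coords(), rr.structure.ca_coords()
        small = [i - 1 for i in frame.small_serials]
        large = [i for i in range(len(model)) if i not in small]
        # large proportion and linker untouched
        np.testing.assert_array_equal(after[large], before[large])
        # intra-proportion distances preserved
        d0 = np.linalg.norm(before[small][:, None] - before[small], axis=2)
        d1 = np.linalg.norm(after[small][:, None] - after[small], axis=2)
        np.testing.assert_allclose(d1, d0, atol=1e-6)

    def test_matches_exhaustive_grid_oracle(self):
        model, junction = make_two_domain_model(seed=6)
        frame = split_by_hinge(model, junction)
        rr = hinge_refine(model, frame)
        # independent exhaustive evaluation
        oracle = []
        for theta in PLANE_ANGLES:
            for phi in AXIAL_ANGLES:
                R = rodrigues(frame.axis_r, phi) @ \
                    rodrigues(frame.plane_normal, theta)
                coords = model.ca_coords().copy()
                if (theta, phi) != (0, 0):
                    for serial in frame.small_serials:
                        coords[serial - 1] = R @ (coords[serial - 1] -
                                                  frame.hinge) + frame.hinge
                s = structure_from_ca(model.sequence, coords)
                oracle.append(((theta, phi), surrogate_energy(s)))
        best_pose, best_e = min(oracle, key=lambda x: (x[1], x[0]))
        assert rr.best_pose == best_pose
        assert rr.best_energy == pytest.approx(best_e, abs=1e-6)


def quaternion_rmsd(A, B):
    """Horn's closed-form quaternion superposition (independent oracle)."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    Sxx = A.T @ B
    N = np.array([
        [Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2], Sxx[1, 2] - Sxx[2, 1],
         Sxx[2, 0] - Sxx[0, 2], Sxx[0, 1] - Sxx[1, 0]],
        [Sxx[1, 2] - Sxx[2, 1], Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2],
         Sxx[0, 1] + Sxx[1, 0], Sxx[2, 0] + Sxx[0, 2]],
        [Sxx[2, 0] - Sxx[0, 2], Sxx[0, 1] + Sxx[1, 0],
         -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2], Sxx[1, 2] + Sxx[2, 1]],
        [Sxx[0, 1] - Sxx[1, 0], Sxx[2, 0] + Sxx[0, 2],
         Sxx[1, 2] + Sxx[2, 1], -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]],
    ])
    lam = np.linalg.eigvalsh(N)[-1]
    msd = (np.sum(A ** 2) + np.sum(B ** 2) - 2 * lam) / len(A)
    return np.sqrt(max(msd, 0.0))


class TestKabsch:
    def test_identical_sets(self):
        A = np.random.default_rng(0).normal(size=(6, 3))
        rmsd, _ = kabsch_rmsd(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_recovered(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(1)
        A = rng.normal(size=(8, 3)) * 5
        B = Rotation.from_rotvec([0.5, -0.2, 1.4]).apply(A) + [10, -4, 2]
        rmsd, (R, t) = kabsch_rmsd(A, B)
        assert rmsd < 1e-9
        np.testing.assert_allclose(A @ R.T + t, B, atol=1e-9)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A = rng.normal(size=(5, 3)) * 4
            B = rng.normal(size=(5, 3)) * 4
            rmsd, _ = kabsch_rmsd(A, B)
            assert rmsd == pytest.approx(quaternion_rmsd(A, B), abs=1e-9)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestAlignmentRatio:
    @pytest.mark.parametrize("n,size,expected", [
        (214, 214, 100.0), (0, 100, 0.0), (53, 106, 50.0),
    ])
    def test_values(self, n, size, expected):
        assert alignment_ratio(n, size) == expected

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            alignment_ratio(0, 0)
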