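import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from foldpool import fixtures
from foldpool.metrics import (
    DegenerateCoordinatesError,
    InsufficientCorrespondenceError,
    correspond,
    gdt_ts,
    kabsch_superpose,
    lddt_ca,
    similarity_matrix,
    tm_d0,
    tm_score,
)

from oracles import euler_grid_rmsd


def rigid(model, rotation=None, translation=(0.0, 0.0, 0.0)):
    coords = model.ca_coords
    if rotation is not None:
        coords = coords @ np.asarray(rotation).T
    return model.with_(ca_coords=coords + np.asarray(translation, float))


class TestCorrespond:
    def test_full_overlap(self, helix20):
        other = fixtures.perturb_model(helix20, 0.1, seed=0)
        P, Q, nums = correspond(helix20, other)
        assert len(P) == len(Q) == 20
        np.testing.assert_array_equal(nums, np.arange(1, 21))

    def test_partial_overlap_by_residue_number(self, helix20):
        # residues 1..10 vs 6..15 share exactly 5
        a = helix20.with_(
            sequence=helix20.sequence[:10],
            residue_numbers=helix20.residue_numbers[:10],
            ca_coords=helix20.ca_coords[:10],
            plddt=helix20.plddt[:10],
        )
        b = helix20.with_(
            sequence=helix20.sequence[5:15],
            residue_numbers=helix20.residue_numbers[5:15],
            ca_coords=helix20.ca_coords[5:15],
            plddt=helix20.plddt[5:15],
        )
        P, Q, nums = correspond(a, b)
        assert len(P) == 5
        np.testing.assert_array_equal(nums, [6, 7, 8, 9, 10])

    def test_disjoint_sets_error(self, helix20):
        b = helix20.with_(residue_numbers=helix20.residue_numbers + 100)
        with pytest.raises(InsufficientCorrespondenceError):
            correspond(helix20, b)

    def test_different_targets_rejected(self, helix20):
        with pytest.raises(ValueError):
            correspond(helix20, helix20.with_(target_id="other"))


class TestKabsch:
    def test_identity(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        sup = kabsch_superpose(P, P)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_pure_translation(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        sup = kabsch_superpose(P, P + np.array([5.0, 0.0, 0.0]))
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(sup.translation, [5, 0, 0], atol=1e-12)

    def test_recovers_z_rotation_against_grid_oracle(self):
        helix = fixtures.make_helix(5)
        P = helix.ca_coords
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ Rz.T
        sup = kabsch_superpose(P, Q)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, Rz, atol=1e-6)
        # coarse full-grid: no rotation anywhere beats the Kabsch optimum
        best_rmsd_grid, _ = euler_grid_rmsd(P, Q, step_deg=10.0)
        assert sup.rmsd <= best_rmsd_grid + 1e-9
        # fine sweep about the known axis locates the optimum at 90 deg
        best_rmsd_z, best_R = euler_grid_rmsd(P, Q, step_deg=1.0, z_only=True)
        np.testing.assert_allclose(best_R, Rz, atol=1e-6)

    def test_degenerate_collinear_rejected(self):
        P = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateCoordinatesError):
            kabsch_superpose(P, P)

    def test_reflection_excluded(self, rng):
        P = rng.normal(size=(6, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirrored target
        sup = kabsch_superpose(P, Q)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)


class TestTmScore:
    def test_identical_is_one(self, helix20):
        assert tm_score(helix20, helix20) == pytest.approx(1.0, abs=1e-9)

    def test_d0_floor_applies_at_l20(self):
        # 1.24 * 5^(1/3) - 1.8 ~ 0.3204 < 0.5, so the floor engages
        assert tm_d0(20) == pytest.approx(0.5)
        assert tm_d0(50) == pytest.approx(1.24 * np.cbrt(35.0) - 1.8)

    def test_rigid_transform_of_either_side_is_invariant(self, helix20):
        model = fixtures.perturb_model(helix20, 0.8, seed=2)
        base = tm_score(model, helix20)
        R = Rotation.from_euler("xyz", [31, -12, 77], degrees=True).as_matrix()
        assert tm_score(rigid(model, R, (4, -2, 9)), helix20) == pytest.approx(base, abs=1e-6)
        assert tm_score(model, rigid(helix20, R, (1, 2, 3))) == pytest.approx(base, abs=1e-6)

    def test_displaced_half_scores_partial(self):
        native = fixtures.make_helix(8)
        coords = native.ca_coords.copy()
        coords[4:] += np.array([50.0, 0.0, 0.0])
        model = native.with_(model_id="split", ca_coords=coords)
        s = tm_score(model, native)
        assert 0.0 < s < 1.0
        # the intact half contributes ~4 residues at zero distance
        assert s == pytest.approx(4.0 / 8.0, abs=0.01)


class TestGdtTs:
    def test_identical_is_one(self, helix20):
        assert gdt_ts(helix20, helix20) == pytest.approx(1.0)

    def test_uniform_translation_is_removed(self, helix20):
        assert gdt_ts(rigid(helix20, None, (7.0, -3.0, 2.0)), helix20) == pytest.approx(1.0)

    def test_rigid_split_half_scores_half(self):
        native = fixtures.make_helix(10)
        coords = native.ca_coords.copy()
        coords[5:] += np.array([50.0, 0.0, 0.0])
        model = native.with_(model_id="split", ca_coords=coords)
        assert gdt_ts(model, native) == pytest.approx(0.5)

    def test_monotone_in_noise_scale(self, helix30):
        # averaged over seeds, larger sigma cannot raise GDT-TS
        sigmas = [0.2, 0.8, 2.0, 4.0]
        means = []
        for sigma in sigmas:
            vals = [
                gdt_ts(fixtures.perturb_model(helix30, sigma, seed=s), helix30)
                for s in range(20)
            ]
            means.append(np.mean(vals))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestLddtCa:
    def test_identical_is_one(self, helix20):
        assert lddt_ca(helix20, helix20) == pytest.approx(1.0)

    def test_inflated_distances_score_zero(self, helix20):
        # uniform x5 scaling inflates every CA distance well past 4 A
        model = helix20.with_(ca_coords=helix20.ca_coords * 5.0)
        assert lddt_ca(model, helix20) == pytest.approx(0.0)

    def test_superposition_free(self, helix20):
        model = fixtures.perturb_model(helix20, 0.5, seed=9)
        R = Rotation.from_euler("zyx", [120, 30, -45], degrees=True).as_matrix()
        assert lddt_ca(rigid(model, R, (10, 10, 10)), helix20) == pytest.approx(
            lddt_ca(model, helix20), abs=1e-12
        )

    def test_hand_enumerated_four_residue_toy(self):
        # square of side 3; qualifying pairs (residue-number separation
        # >= 2, d_ref < 15 A) are, zero-based, (0,2), (0,3) and (1,3)
        ref_coords = np.array(
            [[0, 0, 0], [3, 0, 0], [3, 3, 0], [0, 3, 0]], float
        )
        native = fixtures.make_helix(4).with_(ca_coords=ref_coords)
        moved = ref_coords.copy()
        # push residue 2 radially away from residue 0: pair (0,2) is
        # stretched by exactly 1.5 A, pairs (0,3) and (1,3) untouched
        moved[2] += np.array([1.5 / np.sqrt(2), 1.5 / np.sqrt(2), 0.0])
        model = native.with_(model_id="toy", ca_coords=moved)
        # pass table over thresholds {0.5,1,2,4}: (0,2) passes only 2 and
        # 4; the other two pairs pass everything -> per-threshold
        # fractions (2/3, 2/3, 1, 1)
        expected = np.mean([2 / 3, 2 / 3, 1.0, 1.0])
        assert lddt_ca(model, native) == pytest.approx(expected)


class TestSimilarityMatrix:
    def test_identical_pool_all_ones(self, helix20):
        models = [helix20.with_(model_id=f"m{i}") for i in range(3)]
        sim = similarity_matrix(models)
        np.testing.assert_allclose(sim.to_numpy(), 1.0, atol=1e-9)

    def test_symmetric_and_matches_pairwise_recomputation(self, helix20):
        models = [
            fixtures.perturb_model(helix20, s, seed=i)
            for i, s in enumerate([0.3, 1.0, 2.5])
        ]
        sim = similarity_matrix(models)
        np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T)
        np.testing.assert_allclose(np.diag(sim.to_numpy()), 1.0)
        l_target = 20
        for i in range(3):
            for j in range(i + 1, 3):
                expected = 0.5 * (
                    tm_score(models[i], models[j], l_ref=l_target)
                    + tm_score(models[j], models[i], l_ref=l_target)
                )
                assert sim.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_single_model_rejected(self, helix20):
        with pytest.raises(ValueError):
            similarity_matrix([helix20])
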