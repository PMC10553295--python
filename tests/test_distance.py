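"""Hamming trajectories, the stationary summary, and pairwise matrices."""

import numpy as np
import pytest
from scipy import stats

from capdist.ca_engine import AutomatonImage, evolve
from capdist.distance import (
    ComparabilityError,
    DistanceMatrix,
    hamming_trajectory,
    p_distance_matrix,
    pairwise_shd_matrix,
    stationary_value,
)
from capdist.encoding import AlignedProteinSet, encode_sequence
from capdist.fixtures import SimulationSpec, simulate_alignment


def image_from_rows(rows):
    return AutomatonImage(np.array(rows, dtype=np.uint8), rule_number=84)


class TestHammingTrajectory:
    def test_identical_images_give_zero_trajectory(self, rng):
        img = evolve(rng.integers(0, 2, size=16, dtype=np.uint8), 84, steps=30)
        traj = hamming_trajectory(img, img, window=10)
        assert traj.values.tolist() == [0.0] * 31
        assert traj.shd == 0.0 and traj.saturated

    def test_complementary_rows_give_distance_one(self):
        a = image_from_rows([[0, 1, 0], [0, 1, 0]])
        b = image_from_rows([[1, 0, 1], [1, 0, 1]])
        traj = hamming_trajectory(a, b, window=2)
        assert traj.values.tolist() == [1.0, 1.0]

    def test_quarter_distance_row(self):
        a = image_from_rows([[0, 0, 1, 1]])
        b = image_from_rows([[0, 1, 1, 1]])
        traj = hamming_trajectory(a, b, window=1)
        assert traj.values.tolist() == [0.25]

    def test_matches_brute_force_recount(self, rng):
        for _ in range(5):
            m = int(rng.integers(4, 17))
            steps = int(rng.integers(2, 21))
            img_a = evolve(rng.integers(0, 2, size=m, dtype=np.uint8), 84, steps)
            img_b = evolve(rng.integers(0, 2, size=m, dtype=np.uint8), 84, steps)
            traj = hamming_trajectory(img_a, img_b, window=2)
            for t in range(steps + 1):
                expected = sum(
                    abs(int(img_a.rows[t, i]) - int(img_b.rows[t, i]))
                    for i in range(m)
                ) / m
                assert traj.values[t] == pytest.approx(expected)

    def test_symmetry_in_arguments(self, rng):
        img_a = evolve(rng.integers(0, 2, size=12, dtype=np.uint8), 84, 15)
        img_b = evolve(rng.integers(0, 2, size=12, dtype=np.uint8), 84, 15)
        ab = hamming_trajectory(img_a, img_b, window=5)
        ba = hamming_trajectory(img_b, img_a, window=5)
        assert np.array_equal(ab.values, ba.values)

    def test_mismatched_images_rejected(self, rng):
        a = evolve(rng.integers(0, 2, size=8, dtype=np.uint8), 84, 5)
        b = evolve(rng.integers(0, 2, size=9, dtype=np.uint8), 84, 5)
        with pytest.raises(ComparabilityError):
            hamming_trajectory(a, b, window=2)
        c = evolve(rng.integers(0, 2, size=8, dtype=np.uint8), 30, 5)
        with pytest.raises(ComparabilityError):
            hamming_trajectory(a, c, window=2)


class TestStationaryValue:
    def test_constant_tail(self):
        shd, saturated = stationary_value(np.full(50, 0.3), window=10, tol=0.01)
        assert shd == pytest.approx(0.3) and saturated

    def test_all_zero(self):
        shd, saturated = stationary_value(np.zeros(20), window=10, tol=0.0)
        assert shd == 0.0 and saturated

    def test_steep_ramp_is_not_saturated(self):
        values = np.linspace(0, 1, 50)
        shd, saturated = stationary_value(values, window=20, tol=0.01)
        assert not saturated
        assert shd == pytest.approx(values[-20:].mean())

    def test_window_longer_than_trajectory_rejected(self):
        with pytest.raises(ValueError, match="window"):
            stationary_value(np.zeros(5), window=6)


class TestPairwiseShdMatrix:
    def test_identical_sequences_give_zero_matrix(self):
        aln = AlignedProteinSet(("x", "y"), ("GARY", "GARY"))
        mat = pairwise_shd_matrix(aln, steps=20, window=5)
        assert mat.values.tolist() == [[0, 0], [0, 0]]

    def test_duplicate_taxon_equidistant_from_third(self):
        aln = AlignedProteinSet(("a", "b", "c"), ("GARY", "GARY", "WHYS"))
        mat = pairwise_shd_matrix(aln, steps=50, window=10)
        assert mat[("a", "b")] == 0.0
        assert mat[("a", "c")] == pytest.approx(mat[("b", "c")])

    def test_matrix_properties_and_permutation_consistency(self):
        aln = simulate_alignment(SimulationSpec(ancestor_length=30, seed=7))
        mat = pairwise_shd_matrix(aln, steps=60, window=10)
        v = mat.values
        assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)
        assert v.min() >= 0 and v.max() <= 1
        perm = aln.labels[::-1]
        seqs = dict(zip(aln.labels, aln.sequences))
        aln_perm = AlignedProteinSet(perm, tuple(seqs[l] for l in perm))
        mat_perm = pairwise_shd_matrix(aln_perm, steps=60, window=10)
        assert np.allclose(mat_perm.values, mat.reorder(perm).values)

    def test_mean_shd_grows_with_divergence(self):
        # two-leaf trees at increasing substitution counts; Spearman over
        # replicate means must be positive
        counts = [2, 10, 40, 90]
        means = []
        for k in counts:
            vals = [
                pairwise_shd_matrix(
                    simulate_alignment(SimulationSpec(
                        tree=f"(A:{k},B:0);", ancestor_length=120, seed=seed)),
                    steps=120, window=20,
                )[("A", "B")]
                for seed in range(5)
            ]
            means.append(np.mean(vals))
        rho, _ = stats.spearmanr(counts, means)
        assert rho > 0


class TestPDistance:
    def test_single_difference(self):
        aln = AlignedProteinSet(("x", "y"), ("AAAA", "AAAT"))
        assert p_distance_matrix(aln)[("x", "y")] == pytest.approx(0.25)

    def test_identical_sequences(self):
        aln = AlignedProteinSet(("x", "y"), ("GARY", "GARY"))
        assert p_distance_matrix(aln)[("x", "y")] == 0.0

    def test_pairwise_deletion_skips_gap_sites(self):
        aln = AlignedProteinSet(("x", "y"), ("AA-A", "AAAA"))
        assert p_distance_matrix(aln)[("x", "y")] == 0.0

    def test_complete_vs_pairwise_deletion(self):
        # site 2 has a gap in z only: complete deletion drops it for all pairs
        aln = AlignedProteinSet(("x", "y", "z"), ("AACA", "AATA", "AA-A"))
        pairwise = p_distance_matrix(aln, deletion="pairwise")
        complete = p_distance_matrix(aln, deletion="complete")
        assert pairwise[("x", "y")] == pytest.approx(0.25)
        assert complete[("x", "y")] == 0.0

    def test_no_comparable_sites_warns_and_zeroes(self, caplog):
        aln = AlignedProteinSet(("x", "y"), ("A--", "-AA"))
        with caplog.at_level("WARNING"):
            mat = p_distance_matrix(aln)
        assert mat[("x", "y")] == 0.0
        assert "no comparable sites" in caplog.text


class TestDistanceMatrixIO:
    def test_phylip_round_trip(self, tmp_path, rng):
        v = rng.random((4, 4)) / 2
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        mat = DistanceMatrix(("a", "b", "c", "d"), v, "shd")
        path = tmp_path / "m.phylip"
        mat.write_phylip(path)
        back = DistanceMatrix.read_phylip(path)
        assert back.labels == mat.labels
        assert np.allclose(back.values, mat.values, atol=1e-6)

    def test_tsv_round_trip(self, tmp_path):
        mat = DistanceMatrix(("a", "b"), np.array([[0, 0.125], [0.125, 0]]), "shd")
        path = tmp_path / "m.tsv"
        mat.write_tsv(path)
        back = DistanceMatrix.read_tsv(path)
        assert back.labels == mat.labels
        assert np.array_equal(back.values, mat.values)

    @pytest.mark.parametrize("bad", [
        np.array([[0, 0.2], [0.3, 0]]),           # asymmetric
        np.array([[0.1, 0.2], [0.2, 0]]),         # nonzero diagonal
        np.array([[0, 1.5], [1.5, 0]]),           # out of [0, 1] for shd
        np.array([[0, np.nan], [np.nan, 0]]),     # NaN
    ])
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), bad, "shd")
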