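"""Frame clustering, boost reweighting, and representative selection."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from glynmr.cluster import (
    UNCLUSTERED,
    ConformerFrame,
    FrameSeries,
    pairwise_rmsd,
    representatives,
    reweight_clusters,
    subsample,
    ward_cluster,
)
from glynmr.constants import KB_KCAL_MOL
from glynmr.synthetic import make_boosted_frames


def series_of(coords, energy=None, boost=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return FrameSeries(
        coords=coords,
        energy=np.zeros(n) if energy is None else np.asarray(energy, float),
        boost=np.zeros(n) if boost is None else np.asarray(boost, float),
    )


class TestSubsample:
    def test_paper_scale_counts(self):
        # every tenth of 500,000 saved frames -> 50,000
        s = series_of(np.zeros((500_000, 1, 3)))
        assert len(subsample(s, 10)) == 50_000

    def test_identity_and_arithmetic(self):
        s = series_of(np.arange(25 * 3).reshape(25, 1, 3))
        assert len(subsample(s, 1)) == 25
        sub = subsample(s, 10)
        assert list(sub.indices) == [0, 10, 20]

    def test_stride_validation(self):
        s = series_of(np.zeros((4, 1, 3)))
        with pytest.raises(ValueError):
            subsample(s, 0)


class TestPairwiseRmsd:
    def test_identical_frames_zero(self):
        s = series_of(np.tile(np.arange(12.0).reshape(4, 3), (3, 1, 1)))
        assert np.allclose(pairwise_rmsd(s), 0.0)

    def test_rigid_translation(self):
        base = np.arange(12.0).reshape(4, 3)
        t = np.array([1.0, -2.0, 2.0])
        s = series_of(np.stack([base, base + t]))
        assert pairwise_rmsd(s, superpose=False)[0] == pytest.approx(np.linalg.norm(t))
        assert pairwise_rmsd(s, superpose=True)[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_sum_of_squares(self, rng):
        a, b = rng.normal(size=(2, 7, 3))
        s = series_of(np.stack([a, b]))
        direct = math.sqrt(np.sum((a - b) ** 2) / 7)
        assert pairwise_rmsd(s)[0] == pytest.approx(direct, rel=1e-12)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            pairwise_rmsd(series_of(np.zeros((1, 4, 3))))


class TestWardCluster:
    def test_two_separated_blobs_recovered_exactly(self):
        centers = np.stack([np.zeros((5, 3)), np.full((5, 3), 6.0)])
        series, truth = make_boosted_frames(
            centers, [0.5, 0.5], 1200, seed=5, coord_sd=0.3
        )
        cs = ward_cluster(pairwise_rmsd(series), min_size=500)
        assert cs.n_clusters == 2
        assert adjusted_rand_score(truth, cs.labels) == 1.0

    def test_single_blob_one_cluster(self):
        rng = np.random.default_rng(0)
        s = series_of(rng.normal(scale=0.3, size=(800, 5, 3)))
        cs = ward_cluster(pairwise_rmsd(s), min_size=500)
        assert cs.n_clusters == 1
        assert np.all(cs.labels == 1)

    def test_thirty_well_fixture_count(self):
        """Scaled-down planted-well ensemble (5,000 frames, 30 wells,
        min size 50): the tuned cutoff recovers the well count to +/-3."""
        rng = np.random.default_rng(42)
        centers = rng.normal(scale=8.0, size=(30, 11, 3))
        series, truth = make_boosted_frames(
            centers, np.full(30, 1 / 30), 5000, seed=3, coord_sd=0.5
        )
        cs = ward_cluster(pairwise_rmsd(series), min_size=50)
        assert abs(cs.n_clusters - 30) <= 3
        mask = cs.labels != UNCLUSTERED
        assert adjusted_rand_score(truth[mask], cs.labels[mask]) > 0.9

    def test_all_unclustered_is_error(self):
        rng = np.random.default_rng(1)
        s = series_of(rng.normal(size=(40, 2, 3)))
        with pytest.raises(ValueError, match="min_size"):
            ward_cluster(pairwise_rmsd(s), min_size=1000)


class TestReweight:
    def test_zero_boosts_give_raw_occupancies(self):
        coords = np.zeros((300, 2, 3))
        labels = np.r_[np.zeros(100, int), np.ones(200, int)]
        cs = reweight_clusters(series_of(coords), labels)
        p = cs.probabilities()
        assert p[0] == pytest.approx(1 / 3)
        assert p[1] == pytest.approx(2 / 3)

    def test_constant_boost_closed_form(self):
        """Equal occupancy, constant boosts 2 and 0 kcal/mol at 300 K:
        p1/p2 = exp(beta * 2) exactly (variance terms vanish)."""
        n = 400
        boost = np.r_[np.full(n, 2.0), np.zeros(n)]
        labels = np.r_[np.zeros(n, int), np.ones(n, int)]
        cs = reweight_clusters(
            series_of(np.zeros((2 * n, 1, 3)), boost=boost), labels, temperature=300.0
        )
        p = cs.probabilities()
        assert p[0] / p[1] == pytest.approx(math.exp(2.0 / (KB_KCAL_MOL * 300.0)), rel=1e-12)
        fes = {c["id"]: c["free_energy_kcal_mol"] for c in cs.clusters}
        assert fes[0] == pytest.approx(0.0)
        assert fes[1] == pytest.approx(2.0, rel=1e-12)

    def test_uniform_constant_boost_cancels(self):
        boost = np.full(500, 7.5)
        labels = np.r_[np.zeros(150, int), np.ones(350, int)]
        cs = reweight_clusters(series_of(np.zeros((500, 1, 3)), boost=boost), labels)
        assert cs.probabilities()[1] == pytest.approx(0.7)

    def test_gaussian_boost_population_recovery(self):
        """Planted ensemble with per-cluster Gaussian boosts (sd 8
        kcal/mol): cumulant reweighting recovers target populations within
        2x the delta-method Monte-Carlo SE of the log-weights."""
        centers = np.stack([np.zeros((3, 3)), np.full((3, 3), 8.0)])
        target = np.array([0.65, 0.35])
        series, labels = make_boosted_frames(
            centers, target, 40_000, seed=11,
            boost_mean=[45.5, 45.0], boost_sd=[8.0, 8.0], coord_sd=0.2,
        )
        cs = reweight_clusters(series, labels, temperature=300.0)
        beta = 1.0 / (KB_KCAL_MOL * 300.0)
        # SE of each cluster's log-weight (Gaussian delta method)
        se2 = []
        for c in cs.clusters:
            n, var = c["size"], c["boost_var"]
            se2.append(beta**2 * var / n + beta**4 * var**2 / (2 * (n - 1)))
        se_diff = math.sqrt(sum(se2))
        p = cs.probabilities()
        dlog = math.log(p[0] / p[1]) - math.log(target[0] / target[1])
        assert abs(dlog) < 2.0 * se_diff

    def test_second_order_cumulant_matches_exact_gaussian_average(self):
        rng = np.random.default_rng(9)
        mu, sd, beta = 3.0, 0.8, 1.2
        x = rng.normal(mu, sd, size=10_000)
        exact = beta * mu + beta**2 * sd**2 / 2
        est = beta * x.mean() + beta**2 * x.var(ddof=1) / 2
        se = beta * sd / math.sqrt(len(x)) + beta**2 * sd**2 / math.sqrt(2 * len(x))
        assert abs(est - exact) < 4 * se

    def test_single_member_cluster_warns(self):
        labels = np.r_[np.zeros(1, int), np.ones(10, int)]
        s = series_of(np.zeros((11, 1, 3)), boost=np.ones(11))
        with pytest.warns(UserWarning, match="single member"):
            reweight_clusters(s, labels)

    def test_probabilities_sum_to_one_and_permutation_invariance(self, rng):
        n = 600
        boost = rng.uniform(0, 5, size=n)
        labels = rng.integers(0, 3, size=n)
        s = series_of(rng.normal(size=(n, 2, 3)), boost=boost)
        cs = reweight_clusters(s, labels)
        assert sum(cs.probabilities().values()) == pytest.approx(1.0, abs=1e-9)
        perm = rng.permutation(n)
        s2 = FrameSeries(coords=s.coords[perm], energy=s.energy[perm],
                         boost=s.boost[perm], indices=s.indices[perm])
        cs2 = reweight_clusters(s2, labels[perm])
        for cid, p in cs.probabilities().items():
            assert cs2.probabilities()[cid] == pytest.approx(p, rel=1e-12)


class TestRepresentatives:
    def test_minimum_energy_member(self):
        s = series_of(np.zeros((3, 1, 3)), energy=[3.0, 1.0, 2.0])
        assert representatives(s, np.zeros(3, int)) == {0: 1}

    def test_tie_broken_by_lowest_frame_index(self):
        s = series_of(np.zeros((2, 1, 3)), energy=[1.0, 1.0])
        assert representatives(s, np.zeros(2, int)) == {0: 0}

    def test_planted_minimum_recovered(self, rng):
        n = 500
        energy = rng.normal(size=n)
        labels = rng.integers(0, 4, size=n)
        s = series_of(np.zeros((n, 1, 3)), energy=energy)
        reps = representatives(s, labels)
        for cid, fidx in reps.items():
            members = np.nonzero(labels == cid)[0]
            assert energy[fidx] == energy[members].min()

    def test_missing_energies_rejected(self):
        s = series_of(np.zeros((3, 1, 3)), energy=[1.0, np.nan, 2.0])
        with pytest.raises(ValueError, match="energies"):
            representatives(s, np.zeros(3, int))


def test_conformer_frame_validation():
    with pytest.raises(ValueError):
        ConformerFrame(index=0, coords=np.zeros((2, 3)), energy=0.0, boost=-1.0)
    f = ConformerFrame(index=3, coords=np.zeros((2, 3)), energy=-10.0, boost=0.5)
    s = FrameSeries.from_frames([f, f])
    assert len(s) == 2 and list(s.indices) == [3, 3]
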