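"""State discovery: rank-correlation MDS, PAM, consensus, replication rule."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform, pdist
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from scgxe.states import (ClusterAssignment, ConsensusMatrix, ConsensusStateClusterer,
                          UNASSIGNED, consensus_cluster, drop_unreplicated_clusters,
                          mds_embed, pam, rank_correlation_distance,
                          recluster_consensus)


class TestRankCorrelationDistance:
    def test_duplicate_and_reversed_cells(self, rng):
        base = rng.normal(size=20)
        expr = pd.DataFrame({"c0": base, "c1": base, "c2": -base})
        d = rank_correlation_distance(expr)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_scipy_spearman(self, rng):
        expr = pd.DataFrame(rng.poisson(5, size=(40, 8)).astype(float),
                            columns=[f"c{i}" for i in range(8)])
        expr.iloc[0] += 0.5  # avoid all-constant rows; ties remain in the data
        d = rank_correlation_distance(expr)
        rho, _ = spearmanr(expr.to_numpy())
        assert np.allclose(d, 1 - rho, atol=1e-12)

    def test_constant_cell_named_in_error(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "flat"])
        expr["flat"] = 7.0
        with pytest.raises(ValueError, match="flat"):
            rank_correlation_distance(expr)


class TestMDS:
    def test_collinear_points_recover_spacing(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        emb = mds_embed(D, dims=1)
        x = emb.coords[:, 0]
        spacing = np.abs(np.diff(np.sort(x)))
        assert spacing == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_duplicate_point_identical_coordinates(self):
        D = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.warns(UserWarning):
            emb = mds_embed(D, dims=2)
        assert np.allclose(emb.coords[0], emb.coords[1], atol=1e-9)

    def test_euclidean_round_trip(self, rng):
        X = rng.normal(size=(30, 5))
        D = squareform(pdist(X))
        emb = mds_embed(D, dims=5)
        D2 = squareform(pdist(emb.coords))
        assert np.max(np.abs(D - D2)) < 1e-8

    def test_requests_beyond_rank_warn(self, rng):
        X = rng.normal(size=(10, 2))
        D = squareform(pdist(X))
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            emb = mds_embed(D, dims=9)
        assert emb.coords.shape[1] < 9


class TestPAM:
    def test_recovers_separated_groups(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(5, 0.3, (12, 2))])
        D = squareform(pdist(X))
        labels, medoids = pam(D, 2)
        truth = np.array([0] * 10 + [1] * 12)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert len(set(medoids)) == 2

    def test_deterministic(self, rng):
        D = squareform(pdist(rng.normal(size=(25, 3))))
        out1 = pam(D, 4)
        out2 = pam(D, 4)
        assert np.array_equal(out1[0], out2[0]) and out1[1] == out2[1]


def block_consensus(sizes, noise=0.0, rng=None):
    n = sum(sizes)
    C = np.zeros((n, n))
    start = 0
    for s in sizes:
        C[start:start + s, start:start + s] = 1.0
        start += s
    if noise and rng is not None:
        jitter = rng.uniform(0, noise, size=(n, n))
        C = np.clip(C - jitter * (C > 0.5) + jitter * (C <= 0.5), 0, 1)
        C = (C + C.T) / 2
    np.fill_diagonal(C, 1.0)
    return C


class TestConsensus:
    def test_two_separated_blobs(self, rng):
        chips = np.repeat(np.arange(5), 12)
        labels_true = np.tile(np.array([0] * 6 + [1] * 6), 5)
        X = np.where(labels_true[:, None] == 0, 0.0, 8.0) + rng.normal(0, 0.4, (60, 2))
        C = consensus_cluster(X, chips, k_range=range(1, 6), random_state=0)
        same = labels_true[:, None] == labels_true[None, :]
        off = ~np.eye(60, dtype=bool)
        assert C.values[same & off].min() >= 0.95
        assert C.values[~same].max() <= 0.05
        assert np.allclose(np.diag(C.values), 1.0)
        assert np.all((C.values >= 0) & (C.values <= 1))

    def test_single_chip_rejected(self, rng):
        with pytest.raises(ValueError, match="2 replicate chips"):
            consensus_cluster(rng.normal(size=(10, 2)), np.zeros(10, dtype=int))

    def test_identical_cells_form_single_full_consensus(self):
        X = np.zeros((20, 2))
        chips = np.repeat(np.arange(4), 5)
        C = consensus_cluster(X, chips, k_range=range(1, 4), random_state=1)
        assert np.allclose(C.values, 1.0)

    def test_empty_k_range_rejected(self, rng):
        with pytest.raises(ValueError, match="k_range"):
            consensus_cluster(rng.normal(size=(10, 2)),
                              np.repeat([0, 1], 5), k_range=[])


class TestReclusterAndReplication:
    def _consensus(self, C, chips):
        n = C.shape[0]
        return ConsensusMatrix(values=C, n_iterations=len(set(chips)),
                               copresence=np.full((n, n), 1.0),
                               cell_ids=list(range(n)))

    def test_three_replicated_blocks_selected(self, rng):
        sizes = [40, 30, 30]
        chips = np.tile(np.arange(10), 10)    # every block spread over all chips
        C = block_consensus(sizes, noise=0.05, rng=rng)
        a = recluster_consensus(self._consensus(C, chips), chips, k_max=6)
        truth = np.repeat(np.arange(3), sizes)
        assert a.k == 3
        assert adjusted_rand_score(truth, a.labels) >= 0.99

    def test_single_chip_block_not_retained(self, rng):
        # 3 replicated blocks + a 12-cell block living on one chip only
        sizes = [30, 30, 30, 12]
        chips = np.concatenate([np.tile(np.arange(10), 9), np.full(12, 0)])
        C = block_consensus(sizes, noise=0.05, rng=rng)
        a = recluster_consensus(self._consensus(C, chips), chips, k_max=6)
        rogue_cells = np.arange(90, 102)
        rogue_labels = set(a.labels[rogue_cells].tolist())
        retained = set(a.labels.tolist()) - {UNASSIGNED}
        for lab in rogue_labels & retained:
            members = np.flatnonzero(a.labels == lab)
            # the rogue cells may only survive inside a replicated mixed cluster
            assert len(set(members) - set(rogue_cells)) > 0

    @pytest.mark.parametrize("n_chips_with_3,expected_kept", [
        (6, True),    # >= 3 cells on 6 of 10 chips -> 4 deficient <= 5: kept
        (4, False),   # 6 deficient > 5: dropped
        (5, True),    # exactly half deficient: kept (strict 'more than half')
    ])
    def test_replication_rule_arithmetic(self, n_chips_with_3, expected_kept):
        labels = np.zeros(3 * n_chips_with_3, dtype=int)
        chips = np.repeat(np.arange(n_chips_with_3), 3)
        # pad the chip universe to 10 chips with cells of another cluster
        pad_chips = np.arange(10)
        labels = np.concatenate([labels, np.ones(40, dtype=int)])
        chips = np.concatenate([chips, np.tile(pad_chips, 4)])
        assignment = ClusterAssignment(labels=labels, k=2, medoids=[0, 1],
                                       replication_table=pd.DataFrame(),
                                       cell_ids=list(range(len(labels))))
        out = drop_unreplicated_clusters(assignment, chips)
        kept = (out.labels[:3 * n_chips_with_3] == 0).all()
        assert kept == expected_kept

    def test_one_chip_counts_as_its_own_majority(self):
        labels = np.zeros(5, dtype=int)
        chips = np.zeros(5, dtype=int)
        assignment = ClusterAssignment(labels=labels, k=1, medoids=[0],
                                       replication_table=pd.DataFrame(),
                                       cell_ids=list(range(5)))
        out = drop_unreplicated_clusters(assignment, chips)
        assert (out.labels == 0).all()


class TestEstimator:
    def test_sklearn_get_set_params_roundtrip(self):
        est = ConsensusStateClusterer(k_max=4, random_state=3)
        params = est.get_params()
        est2 = ConsensusStateClusterer().set_params(**params)
        assert est2.get_params() == params

    def test_cell_order_permutation_invariance(self, rng):
        chips = np.repeat(np.arange(5), 12)
        labels_true = np.tile(np.array([0] * 6 + [1] * 6), 5)
        X = np.where(labels_true[:, None] == 0, 0.0, 8.0) + rng.normal(0, 0.4, (60, 2))
        est = ConsensusStateClusterer(random_state=0).fit(X, chips=chips)
        perm = np.random.default_rng(0).permutation(60)
        est_p = ConsensusStateClusterer(random_state=0).fit(X[perm], chips=chips[perm])
        assert adjusted_rand_score(est.labels_[perm], est_p.labels_) == 1.0
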