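"""Replicable cell-state discovery.

Cells are embedded by classical multidimensional scaling of their pairwise
Spearman-correlation dissimilarities (1 - rho, all genes weighted equally,
five dimensions by default, one embedding per culture time point).  States are
extracted with a hybrid of model-driven and non-parametric clustering:
Gaussian mixtures are fitted repeatedly with one replicate chip omitted per
iteration (model and k selected by BIC), accumulating a consensus matrix of
the proportion of iterations in which two cells share a cluster; the
consensus is then re-clustered with partitioning around medoids (PAM) on
1 - consensus, selecting the maximum number of clusters for which
experimental replication is strongly represented in every cluster.  A cluster
with fewer than ``min_cells`` cells in more than ``replicate_fraction`` of
the replicate chips is not considered in downstream modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.mixture import GaussianMixture

__all__ = [
    "EmbeddingMatrix",
    "ConsensusMatrix",
    "ClusterAssignment",
    "rank_correlation_distance",
    "mds_embed",
    "pam",
    "consensus_cluster",
    "recluster_consensus",
    "drop_unreplicated_clusters",
    "ConsensusStateClusterer",
    "discover_states",
    "match_clusters_across_time",
]

UNASSIGNED = -1


@dataclass
class EmbeddingMatrix:
    coords: np.ndarray            # cells x dims
    cell_ids: list
    eigenvalues: np.ndarray


@dataclass
class ConsensusMatrix:
    values: np.ndarray            # cells x cells in [0, 1]
    n_iterations: int
    copresence: np.ndarray        # iteration counts both cells retained
    cell_ids: list


@dataclass
class ClusterAssignment:
    labels: np.ndarray            # per-cell cluster id; UNASSIGNED = -1
    k: int
    medoids: list                 # cell ids
    replication_table: pd.DataFrame   # cluster x chip cell counts
    cell_ids: list

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cell_ids, name="cluster")


def rank_correlation_distance(expr: pd.DataFrame) -> np.ndarray:
    """D_ij = 1 - Spearman rho between cell columns; all genes equal weight.

    Rank correlation is invariant to monotone transforms, so the expression
    scale (TPM vs log TPM) does not matter.  A constant cell profile has no
    defined rank correlation and raises, naming the cell.
    """
    values = expr.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    const = values.std(axis=0) == 0
    if const.any():
        bad = [expr.columns[i] for i in np.flatnonzero(const)[:5]]
        raise ValueError(f"constant expression profile for cell(s) {bad}")
    ranks = np.apply_along_axis(rankdata, 0, values)
    rho = np.corrcoef(ranks, rowvar=False)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2


def mds_embed(D: np.ndarray, dims: int = 5, cell_ids=None) -> EmbeddingMatrix:
    """Classical (Torgerson) MDS: double-centre -D^2/2, top eigenpairs.

    Negative eigenvalues are truncated to zero with a warning; if fewer than
    ``dims`` positive eigenvalues exist the available dimensions are returned
    with a warning.  Axis signs are fixed so each axis' largest-magnitude
    loading is positive (determinism up to that convention).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if (eigval < -1e-8 * max(1.0, abs(eigval[0]))).any():
        warnings.warn("negative eigenvalues truncated to zero (non-Euclidean input)")
    n_pos = int((eigval > 1e-12).sum())
    use = min(dims, n_pos)
    if use < dims:
        warnings.warn(f"only {use} positive eigenvalues; returning {use} dimensions")
    coords = eigvec[:, :use] * np.sqrt(eigval[:use])[None, :]
    for j in range(use):
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    return EmbeddingMatrix(coords=coords,
                           cell_ids=list(cell_ids) if cell_ids is not None else list(range(n)),
                           eigenvalues=eigval[:use])


# ---------------------------------------------------------------------------
# PAM: deterministic build + swap k-medoids on a dissimilarity matrix
# ---------------------------------------------------------------------------

def pam(D: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, list[int]]:
    """Classic PAM on a precomputed dissimilarity; returns (labels, medoids).

    Fully deterministic: ties in the build step, the swap step and the final
    assignment are broken by the lowest cell index.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_near[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
        d_near = np.minimum(d_near, D[medoids[-1]])
    # SWAP
    for _ in range(max_iter):
        medoids.sort()
        med = np.array(medoids)
        dmat = D[med]                       # k x n
        nearest_pos = np.argmin(dmat, axis=0)
        d1 = dmat[nearest_pos, np.arange(n)]
        dmat_inf = dmat.copy()
        dmat_inf[nearest_pos, np.arange(n)] = np.inf
        d2 = dmat_inf.min(axis=0)
        best_delta = -1e-12
        best_swap = None
        for mi in range(len(medoids)):
            mine = nearest_pos == mi
            if mine.any():
                part1 = (np.minimum(D[:, mine], d2[mine][None, :]) - d1[mine][None, :]).sum(axis=1)
            else:
                part1 = np.zeros(n)
            others = ~mine
            part2 = np.minimum(D[:, others] - d1[others][None, :], 0).sum(axis=1)
            delta = part1 + part2
            delta[med] = np.inf
            ci = int(np.argmin(delta))
            if delta[ci] < best_delta:
                best_delta = float(delta[ci])
                best_swap = (mi, ci)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    medoids.sort()
    labels = np.argmin(D[np.array(medoids)], axis=0)
    return labels, medoids


# ---------------------------------------------------------------------------
# consensus clustering with the replication constraint
# ---------------------------------------------------------------------------

def _replication_table(labels, chip_ids, cell_ids) -> pd.DataFrame:
    df = pd.DataFrame({"cluster": labels, "chip": chip_ids})
    table = df[df["cluster"] != UNASSIGNED].groupby(["cluster", "chip"]).size().unstack(fill_value=0)
    table = table.reindex(columns=sorted(set(chip_ids)), fill_value=0)
    return table


def _cluster_passes(row: pd.Series, n_chips: int, min_cells: int, replicate_fraction: float) -> bool:
    deficient = int((row < min_cells).sum())
    return deficient <= replicate_fraction * n_chips


class ConsensusStateClusterer(BaseEstimator, ClusterMixin):
    """Leave-one-chip-out Gaussian-mixture consensus clustering, re-clustered
    with PAM under the experimental replication constraint.

    Parameters
    ----------
    k_range : iterable of int
        Mixture component counts searched by BIC in each iteration.
    covariance_types : tuple of str
        Covariance families searched by BIC.
    k_max : int
        Largest PAM cluster count tried on the consensus matrix.
    min_cells, replicate_fraction : int, float
        A cluster passes replication iff the number of chips carrying fewer
        than ``min_cells`` of its cells is at most ``replicate_fraction`` of
        all chips.
    random_state : int
        Seeds the mixture initialisations.

    Attributes (after ``fit(X, chips=...)``)
    ----------------------------------------
    consensus_matrix_ : ConsensusMatrix
    labels_ : ndarray of cluster ids (UNASSIGNED = -1)
    k_ : selected number of clusters
    medoids_ : medoid indices
    replication_table_ : DataFrame cluster x chip
    """

    def __init__(self, k_range=tuple(range(1, 7)),
                 covariance_types=("spherical", "diag", "full"),
                 k_max: int = 6, min_cells: int = 3, replicate_fraction: float = 0.5,
                 reg_covar: float = 1e-6, random_state: int = 0):
        self.k_range = k_range
        self.covariance_types = covariance_types
        self.k_max = k_max
        self.min_cells = min_cells
        self.replicate_fraction = replicate_fraction
        self.reg_covar = reg_covar
        self.random_state = random_state

    # -- consensus accumulation ------------------------------------------
    def _consensus(self, X, chips, cell_ids) -> ConsensusMatrix:
        if len(self.k_range) == 0:
            raise ValueError("k_range must not be empty")
        chips = np.asarray(chips)
        uniq = sorted(set(chips.tolist()))
        if len(uniq) < 2:
            raise ValueError("need at least 2 replicate chips")
        counts = pd.Series(chips).value_counts()
        if (counts < 2).any():
            raise ValueError("every chip must carry at least 2 cells")
        n = X.shape[0]
        co = np.zeros((n, n))
        pres = np.zeros((n, n))
        seeds = np.random.default_rng(self.random_state).integers(2 ** 31, size=len(uniq))
        for it, chip in enumerate(uniq):
            keep = np.flatnonzero(chips != chip)
            sub = X[keep]
            best = None
            for k in self.k_range:
                if k > len(keep):
                    continue
                for cov in self.covariance_types:
                    gm = GaussianMixture(
                        n_components=k, covariance_type=cov,
                        reg_covar=self.reg_covar, random_state=int(seeds[it]),
                        n_init=1, max_iter=200,
                    )
                    try:
                        gm.fit(sub)
                    except Exception:
                        try:
                            gm.set_params(reg_covar=self.reg_covar * 1e4)
                            gm.fit(sub)
                        except Exception:
                            warnings.warn(f"mixture fit failed (k={k}, {cov}); skipped")
                            continue
                    bic = gm.bic(sub)
                    if best is None or bic < best[0]:
                        best = (bic, gm)
            if best is None:
                warnings.warn(f"no mixture converged with chip {chip} omitted; iteration skipped")
                continue
            labels = best[1].predict(sub)
            same = labels[:, None] == labels[None, :]
            co[np.ix_(keep, keep)] += same
            pres[np.ix_(keep, keep)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(pres > 0, co / np.where(pres > 0, pres, 1.0), 0.5)
        if (pres == 0).sum() > n:  # any uncovered off-diagonal pair
            warnings.warn("some cell pairs never co-present (need >= 3 chips); "
                          "their consensus is set to the uninformative 0.5")
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2
        return ConsensusMatrix(values=consensus, n_iterations=len(uniq),
                               copresence=pres, cell_ids=list(cell_ids))

    # -- replication-constrained re-clustering ---------------------------
    def _recluster(self, C: ConsensusMatrix, chips) -> ClusterAssignment:
        D = 1.0 - C.values
        n_chips = len(set(np.asarray(chips).tolist()))
        chosen = None
        for k in range(min(self.k_max, len(C.cell_ids)), 0, -1):
            labels, medoids = pam(D, k)
            # every one of the k requested clusters must be replicated; a
            # cluster left empty by assignment ties is deficient everywhere
            table = _replication_table(labels, chips, C.cell_ids).reindex(
                range(k), fill_value=0)
            ok = all(
                _cluster_passes(table.loc[c], n_chips, self.min_cells, self.replicate_fraction)
                for c in table.index
            )
            if ok:
                chosen = (labels, medoids, table, k)
                break
        if chosen is None:  # pathological; fall back to one cluster for audit
            labels, medoids = pam(D, 1)
            table = _replication_table(labels, chips, C.cell_ids)
            warnings.warn("no cluster count satisfied replication; returning k=1")
            chosen = (labels, medoids, table, 1)
        labels, medoids, table, k = chosen
        return ClusterAssignment(
            labels=np.asarray(labels), k=k,
            medoids=[C.cell_ids[m] for m in medoids],
            replication_table=table, cell_ids=list(C.cell_ids),
        )

    def fit(self, X, y=None, chips=None, cell_ids=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or not np.all(np.isfinite(X)):
            raise ValueError("X must be a finite 2-D array")
        if chips is None:
            raise ValueError("chips (per-cell replicate ids) are required")
        cell_ids = list(cell_ids) if cell_ids is not None else list(range(X.shape[0]))
        self.consensus_matrix_ = self._consensus(X, chips, cell_ids)
        assignment = self._recluster(self.consensus_matrix_, chips)
        assignment = drop_unreplicated_clusters(
            assignment, chips, self.min_cells, self.replicate_fraction)
        self.assignment_ = assignment
        self.labels_ = assignment.labels
        self.k_ = assignment.k
        self.medoids_ = assignment.medoids
        self.replication_table_ = assignment.replication_table
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, y, **kwargs).labels_


def consensus_cluster(embedding, chip_ids, k_range=tuple(range(1, 7)),
                      gmm_config: dict | None = None, random_state: int = 0) -> ConsensusMatrix:
    """Leave-one-chip-out mixture consensus matrix (BIC model selection)."""
    coords = embedding.coords if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding)
    cell_ids = (embedding.cell_ids if isinstance(embedding, EmbeddingMatrix)
                else list(range(len(coords))))
    est = ConsensusStateClusterer(k_range=tuple(k_range), random_state=random_state,
                                  **(gmm_config or {}))
    return est._consensus(coords, chip_ids, cell_ids)


def recluster_consensus(C: ConsensusMatrix, chip_ids, min_cells: int = 3,
                        replicate_fraction: float = 0.5, k_max: int = 6) -> ClusterAssignment:
    """PAM on 1 - consensus for k = k_max..1; keep the largest replicable k."""
    est = ConsensusStateClusterer(k_max=k_max, min_cells=min_cells,
                                  replicate_fraction=replicate_fraction)
    return est._recluster(C, chip_ids)


def drop_unreplicated_clusters(assignment: ClusterAssignment, chip_ids,
                               min_cells: int = 3,
                               replicate_fraction: float = 0.5) -> ClusterAssignment:
    """Mark clusters violating the replication rule as UNASSIGNED.

    A cluster is dropped iff the number of chips carrying fewer than
    ``min_cells`` of its cells exceeds ``replicate_fraction`` of all chips
    (strict inequality: exactly half is retained).
    """
    chips = np.asarray(chip_ids)
    n_chips = len(set(chips.tolist()))
    table = _replication_table(assignment.labels, chips, assignment.cell_ids)
    labels = assignment.labels.copy()
    kept = []
    for c in table.index:
        deficient = int((table.loc[c] < min_cells).sum())
        if deficient > replicate_fraction * n_chips:
            labels[labels == c] = UNASSIGNED
        else:
            kept.append(c)
    return ClusterAssignment(
        labels=labels, k=len(kept),
        medoids=assignment.medoids,
        replication_table=table.loc[kept] if kept else table.iloc[:0],
        cell_ids=assignment.cell_ids,
    )


# ---------------------------------------------------------------------------
# per-time-point orchestration
# ---------------------------------------------------------------------------

def discover_states(tpm: pd.DataFrame, meta: pd.DataFrame, dims: int = 5,
                    k_max: int = 6, min_cells: int = 3, replicate_fraction: float = 0.5,
                    random_state: int = 0) -> dict:
    """Embed and cluster cells separately per time point; match clusters across.

    Returns {"assignments": {time: ClusterAssignment}, "embeddings": {...},
    "labels": Series over all cells (8 h cluster ids; 1 h ids mapped through
    nearest-medoid matching), "matching": DataFrame}.
    """
    meta = meta.loc[tpm.columns]
    out = {"assignments": {}, "embeddings": {}, "consensus": {}}
    for t in sorted(meta["time_h"].unique()):
        cells = meta.index[meta["time_h"] == t]
        sub = tpm[cells]
        D = rank_correlation_distance(sub)
        emb = mds_embed(D, dims=dims, cell_ids=list(cells))
        est = ConsensusStateClusterer(k_max=k_max, min_cells=min_cells,
                                      replicate_fraction=replicate_fraction,
                                      random_state=random_state)
        est.fit(emb.coords, chips=meta.loc[cells, "chip"].to_numpy(), cell_ids=list(cells))
        out["embeddings"][t] = emb
        out["consensus"][t] = est.consensus_matrix_
        out["assignments"][t] = est.assignment_
    times = sorted(out["assignments"])
    labels = pd.Series(UNASSIGNED, index=tpm.columns, name="cluster", dtype=int)
    ref_t = times[-1]
    for cell_id, lab in zip(out["assignments"][ref_t].cell_ids, out["assignments"][ref_t].labels):
        labels[cell_id] = lab
    if len(times) == 2:
        matching = match_clusters_across_time(tpm, out["assignments"][times[0]],
                                              out["assignments"][ref_t])
        mapping = dict(zip(matching["cluster_from"], matching["cluster_to"]))
        for cell_id, lab in zip(out["assignments"][times[0]].cell_ids,
                                out["assignments"][times[0]].labels):
            labels[cell_id] = mapping.get(lab, UNASSIGNED) if lab != UNASSIGNED else UNASSIGNED
        out["matching"] = matching
    out["labels"] = labels
    return out


def match_clusters_across_time(tpm: pd.DataFrame, a: ClusterAssignment,
                               b: ClusterAssignment) -> pd.DataFrame:
    """Nearest-medoid matching of clusters in ``a`` to clusters in ``b``.

    Similarity is the Spearman correlation of medoid expression profiles in
    the shared gene space; each cluster of ``a`` maps to its most similar
    cluster of ``b`` (reported, not assumed, to be the same state).
    """
    rows = []
    # medoids are indexed by original cluster id (PAM labels follow sorted medoids)
    b_meds = {int(lab): b.medoids[int(lab)]
              for lab in sorted(set(b.labels.tolist())) if lab != UNASSIGNED}
    a_meds = {int(lab): a.medoids[int(lab)]
              for lab in sorted(set(a.labels.tolist())) if lab != UNASSIGNED}
    for lab_a, med_a in a_meds.items():
        best = None
        ra = rankdata(tpm[med_a].to_numpy())
        for lab_b, med_b in b_meds.items():
            rb = rankdata(tpm[med_b].to_numpy())
            rho = np.corrcoef(ra, rb)[0, 1]
            if best is None or rho > best[1]:
                best = (lab_b, rho)
        rows.append({"cluster_from": lab_a, "cluster_to": best[0], "medoid_spearman": best[1]})
    return pd.DataFrame(rows, columns=["cluster_from", "cluster_to", "medoid_spearman"])
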