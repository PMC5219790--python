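"""Canonical verification experiments at the study's design scale.

These functions regenerate synthetic experiments under the frozen study
conditions (10 replicate chips x 48 chambers x 2,000 genes) and measure the
pipeline's operating characteristics: null calibration of the rank-product
tests, recovery of planted global and heterogeneous effects, clustering
recovery under the replication constraint, imaging detection quality, and
interval coverage.  The rank-statistic experiments use the generator's
exchangeable-gene configuration (equal baseline abundance) because the
rank-product null assumes independent uniform ranks, which presumes gene
exchangeability; see docs/methods.md.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from .imaging import circularity, detect_blobs
from .qc import tpm_normalize
from .rankprod import (geometric_mean_p, mu_mad, rank_product, rank_within_library,
                       rp_pvalue_bounds, qvalues, subtype_deltas)
from .simulate import random_chambers, simulate_experiment, study_config
from .states import (ConsensusStateClusterer, UNASSIGNED, mds_embed,
                     rank_correlation_distance)

__all__ = [
    "null_type1_rates",
    "effect_recovery_ranks",
    "clustering_recovery",
    "imaging_detection_metrics",
    "ci_coverage",
]


def _log_tpm(sim):
    tpm = tpm_normalize(sim.expression, sim.gene_lengths)
    return np.log2(tpm.to_frame() + 1.0)


def _two_sided_p(stat, n, k):
    ps = {}
    for direction in ("up", "down"):
        rp = rank_product(rank_within_library(stat, direction))
        ps[direction] = np.array(
            [geometric_mean_p(*rp_pvalue_bounds(min(r, float(n) ** k), n, k))
             for r in rp])
    return np.minimum(np.minimum(ps["up"], ps["down"]) * 2, 1.0)


def null_type1_rates(seed: int = 11, alphas=(0.01, 0.05)) -> dict:
    """Fraction of genes reaching p <= alpha / q <= 0.05 on a fully null design."""
    sim = simulate_experiment(study_config(seed=seed, with_states=False,
                                           abundance_sigma=0.0))
    frame = _log_tpm(sim)
    delta = subtype_deltas(frame, sim.metadata, ("genotype", ("WT", "KO")),
                           subtype_col="env")
    stats = mu_mad(delta)
    n, k = len(stats.genes), len(stats.libraries)
    out = {"n_genes": n, "n_libraries": k}
    for test, stat in (("mu", stats.mu), ("mad", stats.mad)):
        p2 = _two_sided_p(stat, n, k)
        q = qvalues(np.maximum(p2, 1e-300))
        for alpha in alphas:
            out[f"{test}_frac_p_le_{alpha}"] = float((p2 <= alpha).mean())
        out[f"{test}_frac_q_le_0.05"] = float((q <= 0.05).mean())
    return out


def effect_recovery_ranks(seeds=range(20)) -> dict:
    """Median significance ranks of planted global and heterogeneous genes.

    Global genes carry a +1.5 log2 KO shift in every state; heterogeneous
    genes alternate +-1.5 across the three states.  Ranks are positions in
    the relevant test's significance ordering: the up direction for the test
    that should detect the gene class, and the more favourable of the two
    directions for the mu-test rank of heterogeneous genes (a conservative
    choice for asserting that they do NOT look like global shifts).
    """
    glob_meds, het_mad_meds, het_mu_meds = [], [], []
    for seed in seeds:
        sim = simulate_experiment(study_config(seed=seed, with_effects=True,
                                               single_time=True, abundance_sigma=0.0))
        frame = _log_tpm(sim)
        meta = sim.metadata.assign(state=sim.truth.true_state)
        delta = subtype_deltas(frame, meta, ("genotype", ("WT", "KO")),
                               subtype_col="state")
        stats = mu_mad(delta)

        def rp_rank(stat, direction):
            return rankdata(rank_product(rank_within_library(stat, direction)))

        mu_up = rp_rank(stats.mu, "up")
        mu_dn = rp_rank(stats.mu, "down")
        mad_up = rp_rank(stats.mad, "up")
        gid = {g: i for i, g in enumerate(stats.genes)}
        glob = [gid[g] for g in sim.truth.true_global_de]
        het = [gid[g] for g in sim.truth.true_het_de]
        glob_meds.append(float(np.median(mu_up[glob])))
        het_mad_meds.append(float(np.median(mad_up[het])))
        het_mu_meds.append(float(np.median(np.minimum(mu_up, mu_dn)[het])))
    return {
        "n_seeds": len(glob_meds),
        "global_median_mu_rank": float(np.median(glob_meds)),
        "het_median_mad_rank": float(np.median(het_mad_meds)),
        "het_median_mu_rank": float(np.median(het_mu_meds)),
        "per_seed_global_mu": glob_meds,
        "per_seed_het_mad": het_mad_meds,
        "per_seed_het_mu": het_mu_meds,
    }


def _cluster_once(seed: int, rogue: bool):
    sim = simulate_experiment(study_config(seed=seed, single_time=True, rogue=rogue))
    tpm = tpm_normalize(sim.expression, sim.gene_lengths).to_frame()
    emb = mds_embed(rank_correlation_distance(tpm), 5, cell_ids=list(tpm.columns))
    est = ConsensusStateClusterer(random_state=seed).fit(
        emb.coords, chips=sim.metadata["chip"].to_numpy(), cell_ids=list(tpm.columns))
    truth = sim.truth.true_state.to_numpy()
    return truth, est.labels_


def clustering_recovery(seeds=range(20)) -> dict:
    """End-to-end ARI on 3 planted states; retention rate of a 1-chip rogue state."""
    aris, rogue_retained = [], 0
    for seed in seeds:
        truth, labels = _cluster_once(seed, rogue=False)
        aris.append(float(adjusted_rand_score(truth, labels)))
        truth_r, labels_r = _cluster_once(seed, rogue=True)
        nonrogue = truth_r != "rogue"
        for c in set(labels_r[labels_r != UNASSIGNED].tolist()):
            members = truth_r[labels_r == c]
            if (members == "rogue").mean() > 0.5:
                rogue_retained += 1
                break
    return {
        "n_seeds": len(aris),
        "median_ari": float(np.median(aris)),
        "per_seed_ari": aris,
        "rogue_retained_runs": rogue_retained,
    }


def imaging_detection_metrics(n_chambers: int = 100, seed: int = 5,
                              match_tolerance_px: float = 3.0) -> dict:
    """Detection recall/precision on random single-cell chambers and the
    worst circularity disagreement with the brute-force oracle."""
    chambers = random_chambers(n_chambers, seed=seed, cells_range=(1, 1))
    tp = fp = fn = 0
    max_circ_err = 0.0
    for img, centers in chambers:
        blobs = detect_blobs(img)
        matched = set()
        for blob in blobs:
            hit = None
            for ci, center in enumerate(centers):
                if ci not in matched and math.dist(blob.centroid, center) <= match_tolerance_px:
                    hit = ci
                    break
            if hit is None:
                fp += 1
            else:
                matched.add(hit)
                tp += 1
            max_circ_err = max(max_circ_err,
                               abs(circularity(blob) - _circularity_oracle(blob.pixel_set)))
        fn += len(centers) - len(matched)
    recall = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    return {"n_chambers": n_chambers, "recall": recall, "precision": precision,
            "max_circularity_error": max_circ_err}


def _circularity_oracle(pixels) -> float:
    """Brute-force minimum enclosing circle + exhaustive pixel-in-circle count."""
    import itertools

    pts = sorted((float(r), float(c)) for r, c in pixels)

    def covers(circ):
        return all(math.dist((circ[0], circ[1]), p) <= circ[2] + 1e-9 for p in pts)

    if len(pts) == 1:
        best = (pts[0][0], pts[0][1], 0.0)
    else:
        cands = []
        for a, b in itertools.combinations(pts, 2):
            cands.append(((a[0] + b[0]) / 2, (a[1] + b[1]) / 2, math.dist(a, b) / 2))
        for a, b, c in itertools.combinations(pts, 3):
            ax, ay = a
            bx, by = b
            cx, cy = c
            d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
            if abs(d) < 1e-12:
                continue
            ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
                  + (cx * cx + cy * cy) * (ay - by)) / d
            uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
                  + (cx * cx + cy * cy) * (bx - ax)) / d
            cands.append((ux, uy, math.dist((ux, uy), a)))
        best = min((c for c in cands if covers(c)), key=lambda c: c[2])
    cy, cx, r = best
    n_in = n_blob = 0
    pset = set(pixels)
    for rr in range(math.floor(cy - r - 1), math.ceil(cy + r + 1) + 1):
        for cc in range(math.floor(cx - r - 1), math.ceil(cx + r + 1) + 1):
            if (rr - cy) ** 2 + (cc - cx) ** 2 <= (r + 1e-9) ** 2:
                n_in += 1
                if (rr, cc) in pset:
                    n_blob += 1
    return n_blob / n_in


def ci_coverage(n_draws: int = 10_000, n: int = 40, p: float = 0.3,
                seed: int = 8) -> dict:
    """Empirical coverage of the Newcombe interval for a null difference."""
    from .association import proportion_change_ci

    rng = np.random.default_rng([seed, 61])
    x1 = rng.binomial(n, p, n_draws)
    x2 = rng.binomial(n, p, n_draws)
    _, lo, hi = proportion_change_ci(x1, np.full(n_draws, n), x2, np.full(n_draws, n))
    return {"n_draws": n_draws, "coverage": float(((lo <= 0) & (hi >= 0)).mean())}
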