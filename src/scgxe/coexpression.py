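"""Focal-gene coexpression, differential coexpression and preranked enrichment.

Gene co-expression with a focal gene (e.g. SOD1) is estimated by Spearman
rank correlation across a declared cell subset.  Knockout-vs-wild-type
differential coexpression ranks genes by the change in that correlation,
``delta_rho = rho_KO - rho_WT``; the ranked list feeds a minimal preranked
gene-set enrichment: the weighted Kolmogorov-Smirnov running-sum enrichment
score with a gene-label permutation null,
``p = (1 + #{|ES*| >= |ES|}) / (n_perm + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CoexpressionProfile",
    "EnrichmentResult",
    "focal_coexpression",
    "delta_coexpression",
    "enrichment_score",
    "preranked_enrichment",
    "read_gmt",
    "write_gmt",
]


@dataclass
class CoexpressionProfile:
    focal_gene: str
    rho: pd.Series                # per gene; NaN where undefined (constant gene)
    n_cells: int


@dataclass
class EnrichmentResult:
    gene_set: str
    es: float
    p: float
    n_perm: int
    n_overlap: int
    seed: int


def focal_coexpression(expr: pd.DataFrame, cells, focal_gene: str,
                       min_cells: int = 10) -> CoexpressionProfile:
    """Spearman rho of every gene with the focal gene over the given cells."""
    if focal_gene not in expr.index:
        raise ValueError(f"focal gene {focal_gene!r} absent")
    cells = list(cells)
    if len(cells) < min_cells:
        raise ValueError(f"need at least {min_cells} cells, got {len(cells)}")
    sub = expr[cells].to_numpy(dtype=float)
    focal = sub[expr.index.get_loc(focal_gene)]
    if np.all(focal == focal[0]):
        raise ValueError(f"focal gene {focal_gene!r} is constant over the subset")
    focal_r = rankdata(focal)
    focal_r = (focal_r - focal_r.mean()) / focal_r.std()
    ranks = np.apply_along_axis(rankdata, 1, sub)
    sds = ranks.std(axis=1)
    means = ranks.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (ranks - means[:, None]) / sds[:, None]
        rho = (z * focal_r[None, :]).mean(axis=1)
    rho[sds == 0] = np.nan
    return CoexpressionProfile(
        focal_gene=focal_gene,
        rho=pd.Series(rho, index=expr.index, name="rho"),
        n_cells=len(cells),
    )


def delta_coexpression(profile_ko: CoexpressionProfile,
                       profile_wt: CoexpressionProfile) -> pd.Series:
    """Genes ranked by delta_rho = rho_KO - rho_WT, descending.

    Genes with an undefined correlation in either profile are excluded (a
    warning records how many).
    """
    if profile_ko.focal_gene != profile_wt.focal_gene:
        raise ValueError("profiles have different focal genes")
    if not profile_ko.rho.index.equals(profile_wt.rho.index):
        raise ValueError("profiles must share a gene universe")
    delta = profile_ko.rho - profile_wt.rho
    n_missing = int(delta.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} gene(s) dropped (undefined rho in one profile)")
    delta = delta.dropna()
    delta = delta.drop(index=profile_ko.focal_gene, errors="ignore")
    return delta.sort_values(ascending=False, kind="mergesort")


def enrichment_score(scores: pd.Series, gene_set, weight_exponent: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score on a descending ranking."""
    genes = scores.index.to_numpy()
    vals = scores.to_numpy(dtype=float)
    hits = np.isin(genes, list(gene_set))
    return _es_from_hits(vals, hits, weight_exponent)


def _es_from_hits(vals: np.ndarray, hits: np.ndarray, weight_exponent: float) -> float:
    n = vals.size
    nh = int(hits.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must hit a strict subset of the ranking")
    w = np.abs(vals) ** weight_exponent
    wh = np.where(hits, w, 0.0)
    denom = wh.sum()
    if denom == 0:
        # all hit weights zero (e.g. scores of 0); fall back to unweighted
        wh = hits.astype(float)
        denom = wh.sum()
    p_hit = np.cumsum(wh) / denom
    p_miss = np.cumsum(~hits) / (n - nh)
    run = p_hit - p_miss
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def preranked_enrichment(scores: pd.Series, gene_set, set_name: str = "set",
                         weight_exponent: float = 1.0, n_perm: int = 1000,
                         seed: int = 0, min_overlap: int = 5) -> EnrichmentResult | None:
    """Minimal preranked GSEA with a gene-label permutation null.

    ``scores`` is sorted descending internally (stable; ties then by gene id
    for determinism).  Returns None (with a warning) when the overlap with
    the ranking is below ``min_overlap``.
    """
    scores = scores.copy()
    order = pd.DataFrame({"s": scores, "g": scores.index}).sort_values(
        ["s", "g"], ascending=[False, True], kind="mergesort")
    scores = scores[order.index]
    genes = scores.index.to_numpy()
    hits = np.isin(genes, list(gene_set))
    nh = int(hits.sum())
    if nh < min_overlap:
        warnings.warn(f"gene set {set_name!r}: overlap {nh} < {min_overlap}; skipped")
        return None
    if nh == genes.size:
        raise ValueError("gene set covers the whole ranking")
    vals = scores.to_numpy(dtype=float)
    es = _es_from_hits(vals, hits, weight_exponent)
    rng = np.random.default_rng([seed, 41])
    exceed = 0
    n = genes.size
    for _ in range(n_perm):
        perm_hits = np.zeros(n, dtype=bool)
        perm_hits[rng.choice(n, size=nh, replace=False)] = True
        if abs(_es_from_hits(vals, perm_hits, weight_exponent)) >= abs(es):
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return EnrichmentResult(gene_set=set_name, es=es, p=p, n_perm=n_perm,
                            n_overlap=nh, seed=seed)


def read_gmt(path) -> dict:
    """GMT: one gene set per line — name, description, member genes (tab-sep)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict, path, description: str = "na"):
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
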