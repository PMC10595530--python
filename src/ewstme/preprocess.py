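"""From raw counts to labeled cell populations.

QC filtering, normalization (log counts-per-10k or analytic Pearson
residuals), PCA/kNN graph Louvain clustering, marker-based cluster
annotation, per-gene Wilcoxon rank-sum differential expression with
Bonferroni correction, and exact-depth downsampling.
"""

from __future__ import annotations

import random
import warnings

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._utils import substream
from .containers import CountMatrix, NormMatrix
from .signatures import SignatureSet, module_score


class EmptyResultError(RuntimeError):
    """Raised when a filter removes every cell."""


def qc_filter(
    counts: CountMatrix,
    cells: pd.DataFrame,
    min_genes_per_cell: int = 200,
    min_cells_per_sample: int = 20,
) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Remove low-complexity cells, then under-populated samples.

    Cells with fewer than ``min_genes_per_cell`` detected genes are
    dropped; samples whose surviving cell count falls below
    ``min_cells_per_sample`` are excluded entirely (the fate of a
    sample sequenced to only a handful of usable cells).  The report
    lists every removal with its reason.
    """
    if min_genes_per_cell < 0 or min_cells_per_sample < 0:
        raise ValueError("thresholds must be >= 0")
    meta = cells.loc[counts.cells]
    detected = pd.Series(counts.genes_detected(), index=counts.cells)
    low = detected.index[detected < min_genes_per_cell]
    keep = detected.index.difference(low, sort=False)

    report = {
        "removed_cells": [
            {"cell_id": c, "reason": f"{detected[c]} genes detected < {min_genes_per_cell}"}
            for c in low
        ],
        "removed_samples": [],
    }
    surviving = meta.loc[keep, "sample_id"].value_counts()
    for s in meta["sample_id"].unique():
        n = int(surviving.get(s, 0))
        if n < min_cells_per_sample:
            report["removed_samples"].append(
                {"sample_id": s, "reason": f"{n} cells after QC < {min_cells_per_sample}"}
            )
    bad_samples = {r["sample_id"] for r in report["removed_samples"]}
    keep = [c for c in counts.cells if c in set(keep) and meta.loc[c, "sample_id"] not in bad_samples]
    if not keep:
        raise EmptyResultError("QC filtering removed every cell")
    return counts.subset(cells=keep), meta.loc[keep], report


def normalize(counts: CountMatrix, method: str = "log1p_cp10k", theta: float = 100.0) -> NormMatrix:
    """Normalize counts for downstream scoring and clustering.

    ``log1p_cp10k``: x -> log(1 + 1e4 * x / depth).

    ``pearson_residual``: analytic Pearson residuals of a fixed-theta
    negative binomial null, (x - mu) / sqrt(mu + mu^2/theta) with
    mu = depth * gene_total / grand_total, clipped to +-sqrt(n_cells);
    this approximates regression-based variance stabilization with a
    closed form.  All-zero genes get residual 0.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    depth = counts.depth().astype(float)
    zero = depth == 0
    if zero.any():
        names = counts.cells[zero].tolist()
        raise ValueError(f"zero-depth cell(s): {names[:5]}")
    X = counts.to_dense().astype(float)
    if method == "log1p_cp10k":
        vals = np.log1p(1e4 * X / depth[None, :])
    elif method == "pearson_residual":
        gene_tot = X.sum(axis=1)
        total = gene_tot.sum()
        mu = np.outer(gene_tot, depth) / total
        with np.errstate(divide="ignore", invalid="ignore"):
            res = (X - mu) / np.sqrt(mu + mu**2 / theta)
        res[gene_tot == 0, :] = 0.0
        lim = np.sqrt(counts.shape[1])
        vals = np.clip(res, -lim, lim)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return NormMatrix(vals, counts.genes, counts.cells, method=method)


def pca_embed(norm: NormMatrix, n_pcs: int = 30, seed: int = 0) -> np.ndarray:
    """Cells x components embedding of the cell-centered matrix."""
    n_pcs = min(n_pcs, norm.shape[1] - 1, norm.shape[0])
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=int(seed))
    return pca.fit_transform(norm.X.T)


def cluster(
    norm: NormMatrix,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    n_pcs: int = 30,
    seed: int = 0,
) -> pd.Series:
    """Louvain community detection on a kNN graph of the PC embedding.

    Every cell is assigned a cluster id; the assignment is deterministic
    given the seed.
    """
    n_cells = norm.shape[1]
    if n_cells < n_neighbors + 1:
        raise ValueError(f"{n_cells} cells but n_neighbors={n_neighbors}; need n_neighbors+1")
    emb = pca_embed(norm, n_pcs=n_pcs, seed=seed)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = igraph.Graph(n=n_cells, edges=sorted(edges))
    igraph.set_random_number_generator(random.Random(int(seed)))
    try:
        part = g.community_multilevel(resolution=resolution)
    finally:
        igraph.set_random_number_generator(random)
    return pd.Series(part.membership, index=norm.cells, name="cluster_id")


def annotate_clusters(
    norm: NormMatrix,
    cluster_ids: pd.Series,
    marker_sets: dict[str, SignatureSet],
    n_bins: int = 25,
    n_ctrl: int | str = 100,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Label each cluster by its best-scoring marker program.

    Every cluster receives the label whose marker module score has the
    highest cluster mean; the returned table reports all scores and the
    margin between best and runner-up.  Exact ties are broken by the
    listed label order, with a warning.
    """
    if not marker_sets:
        raise ValueError("no marker sets given")
    labels = list(marker_sets)
    scores = pd.DataFrame(
        {name: module_score(norm, marker_sets[name], n_bins=n_bins, n_ctrl=n_ctrl, seed=seed) for name in labels}
    )
    by_cluster = scores.groupby(cluster_ids.loc[scores.index]).mean()
    assignment = {}
    for cid, row in by_cluster.iterrows():
        best = row.max()
        winners = [l for l in labels if row[l] == best]
        if len(winners) > 1:
            warnings.warn(f"cluster {cid}: tie between {winners}; using {winners[0]}")
        assignment[cid] = winners[0]
    by_cluster["label"] = pd.Series(assignment)
    ordered = np.sort(by_cluster[labels].to_numpy(), axis=1)
    by_cluster["margin"] = ordered[:, -1] - ordered[:, -2] if len(labels) > 1 else np.inf
    return pd.Series(assignment, name="cell_type"), by_cluster


def de_wilcoxon(norm: NormMatrix, group_a, group_b) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test between cell groups.

    Uses exact enumeration when both groups have <= 10 cells and the
    tie-corrected normal approximation (with continuity correction)
    otherwise.  P-values carry a Bonferroni correction over all tested
    genes; rows are sorted by p.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    A = norm.X[:, norm.cells.get_indexer(group_a)]
    B = norm.X[:, norm.cells.get_indexer(group_b)]
    method = "exact" if (len(group_a) <= 10 and len(group_b) <= 10) else "asymptotic"
    if method == "exact":
        # exact enumeration breaks under ties; scipy falls back per gene
        res = st.mannwhitneyu(A, B, axis=1, alternative="two-sided", method="auto")
    else:
        res = st.mannwhitneyu(A, B, axis=1, alternative="two-sided", method="asymptotic")
    n = norm.shape[0]
    out = pd.DataFrame(
        {
            "gene": norm.genes,
            "mean_diff": A.mean(axis=1) - B.mean(axis=1),
            "statistic": np.asarray(res.statistic, dtype=float),
            "p": np.asarray(res.pvalue, dtype=float),
        }
    )
    out["p_bonferroni"] = np.minimum(out["p"] * n, 1.0)
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def downsample_counts(
    counts: CountMatrix, target_depth: int, seed: int = 0, policy: str = "strict"
) -> CountMatrix:
    """Downsample every cell to exactly ``target_depth`` transcripts.

    Transcripts are drawn without replacement from each cell's observed
    counts (multivariate hypergeometric), so column sums equal the
    target exactly.  Cells already at the target are returned unchanged.
    ``policy="strict"`` raises if any cell is below the target;
    ``policy="skip"`` leaves such cells at their native depth.
    """
    if policy not in ("strict", "skip"):
        raise ValueError(f"unknown policy {policy!r}")
    depth = counts.depth()
    shallow = counts.cells[depth < target_depth]
    if len(shallow) and policy == "strict":
        raise ValueError(
            f"{len(shallow)} cell(s) below target depth {target_depth}: {shallow[:5].tolist()}"
        )
    rng = substream(seed, "downsample")
    X = counts.to_dense()
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if depth[j] <= target_depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, target_depth)
    return CountMatrix(sp.csr_matrix(out), counts.genes, counts.cells)
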