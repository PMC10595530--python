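"""Arm-level copy-number inference from expression.

Single-cell expression carries a faint copy-number signal: genes on a
gained arm are, on average, proportionally over-expressed.  Smoothing
depth-normalized expression along genomic position within each
chromosome and comparing against a reference of non-malignant cells
recovers arm-level gains and losses well enough to confirm tumor-cell
identity, which is how it is used here (not for breakpoint mapping).

Per cell and gene window the statistic is::

    log2( MA_w( expr_cell / ref_level ) )

where ref_level is the per-gene reference expression level, the ratio is
winsorized so one extreme gene cannot dominate, and MA_w is a centered
moving average over ``window_size`` genes ordered by position (never
crossing an arm boundary), followed by centering each cell at the
genome-wide median of its per-arm means and clipping.  Averaging the
ratio on the linear scale before the log keeps a planted fold change
from being shrunk by low per-gene counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NormMatrix


@dataclass
class CNVMatrix:
    """Cells x genomic-window matrix of smoothed log2 relative expression."""

    values: pd.DataFrame  # index: cells, columns: window ids
    windows: pd.DataFrame  # per window: gene, chromosome, arm, start_bp
    clip: float


def _moving_average(arr: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 with edge truncation."""
    n = arr.shape[0]
    if n == 0:
        return arr
    window = min(window, n)
    half = window // 2
    csum = np.cumsum(arr, axis=0)
    csum = np.vstack([np.zeros((1,) + arr.shape[1:]), csum])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)[:, None]


def infer_cnv(
    norm: NormMatrix,
    gene_table: pd.DataFrame,
    reference_cells,
    window_size: int = 101,
    clip: float = 3.0,
    reference_groups: pd.Series | None = None,
    winsor_cap: float = 8.0,
    min_ref_level: float = 1.0,
) -> CNVMatrix:
    """Smoothed log2 relative expression versus a reference cell set.

    ``reference_cells`` should be cells assumed diploid (here: immune
    and endothelial compartments).  The per-gene reference level is the
    pooled reference mean, or -- when ``reference_groups`` labels the
    reference cells (cell types or clusters) -- the median across group
    means, which keeps a marker gene of one reference population from
    inflating the reference level of its neighborhood.  Per gene and
    cell, relative expression (cell / reference level, capped at
    ``winsor_cap`` so a single highly expressed gene cannot dominate a
    window) is averaged over ``window_size`` genes ordered by genomic
    position within each chromosome arm, log2-transformed, centered per
    cell at the genome-wide median of its per-arm means, and clipped to
    ``+-clip``.

    ``window_size`` must be odd; an arm with fewer genes is smoothed
    with a shrunk window (with a warning).  Genes undetected in the
    reference are excluded from windows.  Requires a ``log1p_cp10k``
    normalized matrix (the statistic is defined on the linear
    counts-per-10k scale).
    """
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise ValueError("reference cell set is empty")
    if window_size % 2 == 0:
        raise ValueError("window_size must be odd")
    if norm.method != "log1p_cp10k":
        raise ValueError(f"infer_cnv needs a log1p_cp10k matrix, got {norm.method!r}")
    missing = set(reference_cells) - set(norm.cells)
    if missing:
        raise KeyError(f"unknown reference cells: {sorted(missing)[:5]}")

    genes = gene_table.loc[gene_table.index.intersection(norm.genes)]
    genes = genes.sort_values(["chromosome", "start_bp"], kind="stable")
    expr = np.expm1(norm.gene_values(genes.index))  # linear cp10k, genomic order

    if reference_groups is None:
        ref_idx = norm.cells.get_indexer(reference_cells)
        ref_level = expr[:, ref_idx].mean(axis=1)
    else:
        groups = pd.Series(reference_groups).loc[reference_cells]
        means = []
        for _, idx in groups.groupby(groups).groups.items():
            means.append(expr[:, norm.cells.get_indexer(idx)].mean(axis=1))
        ref_level = np.median(np.stack(means), axis=0)

    # genes expressed too weakly in the reference carry almost no
    # copy-number information but a lot of ratio noise; drop them
    detected = ref_level >= max(min_ref_level, np.finfo(float).tiny)
    genes = genes[detected]
    expr = expr[detected]
    ref_level = ref_level[detected]
    if len(genes) == 0:
        raise ValueError("no gene is sufficiently expressed in the reference cells")

    rel = np.minimum(expr / ref_level[:, None], winsor_cap)
    sm_parts, keep_rows, arm_of = [], [], []
    for arm, sub in genes.groupby("arm", sort=False):
        rows = genes.index.get_indexer(sub.index)
        if len(rows) < window_size:
            warnings.warn(f"arm {arm}: {len(rows)} genes < window {window_size}; window shrunk")
        w = min(window_size, len(rows))
        w = w if w % 2 else w - 1
        sm_parts.append(_moving_average(rel[rows], max(w, 1)))
        keep_rows.append(sub.index)
        arm_of += [arm] * len(rows)

    idx = pd.Index(np.concatenate([k.to_numpy() for k in keep_rows]), name="gene")
    with np.errstate(divide="ignore"):
        vals = np.log2(np.vstack(sm_parts))
    vals[np.isneginf(vals)] = -clip  # windows with zero expression bottom out at the clip
    arm_of = np.asarray(arm_of)
    arm_means = pd.DataFrame(vals.T, columns=arm_of).T.groupby(level=0).mean()
    vals = vals - np.median(arm_means.to_numpy(), axis=0)[None, :]
    vals = np.clip(vals, -clip, clip)

    windows = genes.loc[idx, ["chromosome", "arm", "start_bp"]].copy()
    windows.index.name = "gene"
    values = pd.DataFrame(vals.T, index=norm.cells, columns=idx)
    return CNVMatrix(values=values, windows=windows, clip=clip)


def arm_scores(cnvm: CNVMatrix, arms) -> pd.DataFrame:
    """Per-cell mean smoothed value over each requested arm."""
    out = {}
    for arm in arms:
        cols = cnvm.windows.index[cnvm.windows["arm"] == arm]
        if len(cols) == 0:
            raise KeyError(f"arm {arm!r} has no windows in the CNV matrix")
        out[arm] = cnvm.values[cols].mean(axis=1)
    return pd.DataFrame(out)


def call_aberrant(
    scores: pd.DataFrame, reference_cells, threshold_sd: float = 3.0
) -> pd.DataFrame:
    """Discretize arm scores into gain / neutral / loss calls.

    The null spread per arm is the standard deviation of the reference
    cells' scores; a cell is called gained (lost) on an arm when its
    score exceeds ``threshold_sd`` reference SDs above (below) the
    reference mean.
    """
    reference_cells = list(reference_cells)
    ref = scores.loc[reference_cells]
    sd = ref.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"reference SD is zero for arm(s) {bad}")
    center = ref.mean()
    calls = pd.DataFrame("neutral", index=scores.index, columns=scores.columns)
    calls = calls.mask(scores.gt(center + threshold_sd * sd, axis=1), "gain")
    calls = calls.mask(scores.lt(center - threshold_sd * sd, axis=1), "loss")
    return calls
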