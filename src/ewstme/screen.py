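"""Screen for interactions tracking CD8+ T-cell dysfunction.

Communication probabilities are computed within each sample
independently (myeloid source subsets -> CD8+ T cells), giving a
samples x pairs strength matrix; pairs whose per-sample strength
correlates positively (rank correlation above a threshold, 0.5 by
default) with the per-sample mean CD8 dysfunction score are selected.
No multiple-testing correction is applied to the screen correlations by
default; a Benjamini-Hochberg flag is available as an extension.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import NormMatrix
from .interactions import LRDatabase, _prob_tensor, group_mean_expression


def per_sample_strengths(
    norm: NormMatrix,
    cells: pd.DataFrame,
    lr_db: LRDatabase,
    source_types,
    target_type: str,
    type_col: str = "cell_type",
    min_cells: int = 5,
    trim: float = 0.1,
    kh: float = 0.5,
    hill_n: float = 1.0,
    aggregate: str = "max",
) -> pd.DataFrame:
    """Samples x pairs matrix of within-sample communication strengths.

    For each sample, trimmed-mean expression is computed per source type
    and for the target type, and the Hill communication probability is
    evaluated for every (source type, pair).  Source types with fewer
    than ``min_cells`` cells in a sample contribute nothing there; if
    the target group is under ``min_cells`` the whole sample row is
    missing (NaN), never zero.  With ``aggregate="max"`` (default) a
    pair's strength in a sample is the strongest signal over the source
    subsets; ``aggregate=None`` keeps (source, pair) columns.
    """
    source_types = list(source_types)
    meta = cells.loc[norm.cells]
    present = lr_db.subset_present(norm.genes)
    samples = sorted(meta["sample_id"].unique())
    usable = 0
    rows = {}
    for sample in samples:
        in_sample = meta["sample_id"] == sample
        tgt_cells = norm.cells[in_sample & (meta[type_col] == target_type)]
        row: dict = {}
        if len(tgt_cells) >= min_cells:
            usable += 1
            for src in source_types:
                src_cells = norm.cells[in_sample & (meta[type_col] == src)]
                if len(src_cells) < min_cells:
                    for p in present:
                        row[(src, p.pair_id)] = np.nan
                    continue
                idx = norm.cells.get_indexer(src_cells.append(tgt_cells))
                sub = NormMatrix(norm.X[:, idx], norm.genes, norm.cells[idx], norm.method)
                grp = pd.DataFrame(
                    {"g": ["source"] * len(src_cells) + ["target"] * len(tgt_cells)},
                    index=sub.cells,
                )
                means = group_mean_expression(sub, grp, "g", trim)
                tensor = _prob_tensor(means, present, kh, hill_n)
                si = means.index.get_loc("source")
                ti = means.index.get_loc("target")
                for k, p in enumerate(present):
                    row[(src, p.pair_id)] = float(tensor[k, si, ti])
        else:
            row = {(src, p.pair_id): np.nan for src in source_types for p in present}
        rows[sample] = row
    if usable < 3:
        raise ValueError(f"only {usable} sample(s) have >= {min_cells} {target_type} cells; need 3")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["source", "pair_id"])
    if aggregate is None:
        return out
    if aggregate == "max":
        return out.T.groupby(level="pair_id").max().T
    if aggregate == "mean":
        return out.T.groupby(level="pair_id").mean().T
    raise ValueError(f"unknown aggregate {aggregate!r}")


def sample_dysfunction(
    scores: pd.Series, cells: pd.DataFrame, cd8_type: str = "CD8_T",
    type_col: str = "cell_type", stat: str = "mean", min_cells: int = 5,
) -> pd.Series:
    """Per-sample summary (mean by default) of CD8 dysfunction scores."""
    meta = cells.loc[scores.index]
    cd8 = meta[type_col] == cd8_type
    grouped = scores[cd8].groupby(meta.loc[cd8, "sample_id"])
    n = grouped.size()
    agg = grouped.mean() if stat == "mean" else grouped.median()
    return agg.where(n >= min_cells).rename("dysfunction")


def screen(
    strengths: pd.DataFrame,
    dysfunction: pd.Series,
    rho_threshold: float = 0.5,
    method: str = "spearman",
    min_samples: int = 3,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Correlate per-sample strengths with per-sample dysfunction.

    One row per pair: correlation coefficient, number of
    pairwise-complete samples, and a ``selected`` flag (positive
    correlation above the threshold, one-sided).  Zero-variance columns
    are reported as not evaluable and never selected.
    """
    if dysfunction.dropna().empty:
        raise ValueError("dysfunction scores missing for all samples")
    dys = dysfunction.reindex(strengths.index)
    rows = []
    for pair in strengths.columns:
        joint = pd.concat([strengths[pair], dys], axis=1).dropna()
        n = len(joint)
        x, y = joint.iloc[:, 0].to_numpy(), joint.iloc[:, 1].to_numpy()
        evaluable = n >= min_samples and np.ptp(x) > 0 and np.ptp(y) > 0
        if not evaluable:
            rho, p = np.nan, np.nan
        elif method == "spearman":
            rho, p = st.spearmanr(x, y)
        elif method == "pearson":
            rho, p = st.pearsonr(x, y)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        rows.append(
            {
                "pair_id": pair,
                "rho": float(rho) if evaluable else np.nan,
                "p": float(p) if evaluable else np.nan,
                "n": n,
                "evaluable": bool(evaluable),
                "selected": bool(evaluable and rho > rho_threshold),
            }
        )
    out = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        ok = out["evaluable"] & out["p"].notna()
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["selected"] = out["selected"] & (out.get("p_bh", pd.Series(1.0, index=out.index)) <= 0.05)
    return out.sort_values("rho", ascending=False, na_position="last").reset_index(drop=True)
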