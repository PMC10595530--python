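"""Gene-signature scoring and group-comparison statistics.

Three per-cell scores are provided:

* :func:`module_score` -- mean expression of a gene set minus the mean of
  expression-matched control genes drawn from average-expression bins.
  This is the standard "module score" used for, e.g., HLA class I scores.
* :func:`zscore_signature` -- mean per-gene z-score over the set, used
  for the dendritic-cell maturation comparison.
* :func:`dysfunction_score` -- module score over an inhibitory-receptor
  panel (LAG3, HAVCR2/TIM-3, TIGIT, ...), marking exhausted/tolerized
  T and NK cells.

:func:`expressing_fraction` computes, per sample and cell group, the
fraction of cells with a raw count > 0 for selected costimulatory genes,
excluding sample/group combinations with too few cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st

from ._utils import substream
from .containers import CountMatrix, NormMatrix

#: Costimulatory genes whose expressing fractions are compared across
#: antigen-presenting cell subsets.
COSTIM_GENES = ("CD70", "CD80", "CD83", "CD86", "TNFSF9")

#: Default inhibitory-receptor panel for the dysfunction score.
DYSFUNCTION_PANEL = ("LAG3", "HAVCR2", "TIGIT", "PDCD1", "CTLA4", "BTLA", "KLRG1", "ENTPD1")

#: HLA class I genes (heavy chains + beta-2 microglobulin).
HLA_CLASS_I = ("HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "B2M")


@dataclass
class SignatureSet:
    """A named gene list; all packaged signatures are up-signatures."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path) -> dict[str, SignatureSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, SignatureSet] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets[name] = SignatureSet(name, tuple(genes), desc)
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets.values() if isinstance(sets, dict) else sets:
            fh.write("\t".join([s.name, s.description or s.name, *s.genes]) + "\n")


def default_signatures() -> dict[str, SignatureSet]:
    """Load the packaged signature collection (GMT-backed)."""
    with resources.as_file(resources.files("ewstme.data") / "signatures.gmt") as p:
        return read_gmt(p)


def _present_genes(norm: NormMatrix, sig: SignatureSet) -> list[str]:
    present = [g for g in sig.genes if g in norm.genes]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} is present in the matrix")
    missing = set(sig.genes) - set(present)
    if missing:
        warnings.warn(
            f"signature {sig.name!r}: {len(missing)} gene(s) absent from matrix and dropped "
            f"({sorted(missing)[:5]}...)"
        )
    return present


def module_score(
    norm: NormMatrix,
    sig: SignatureSet,
    n_bins: int = 25,
    n_ctrl: int | str = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control module score per cell.

    Genes are binned into ``n_bins`` bins of average expression; for each
    signature gene ``n_ctrl`` control genes are drawn (without
    replacement) from its bin, and the score is mean(signature
    expression) - mean(control expression) per cell.  The control pool
    may include signature genes, so with ``n_bins=1`` and
    ``n_ctrl="all"`` the score reduces exactly to mean(signature) minus
    the grand mean over all genes.

    Parameters
    ----------
    n_ctrl
        Number of control genes per signature gene, or ``"all"`` to use
        every gene in the bin.  Draws larger than the bin use the whole
        bin.
    seed
        Mandatory seed for the control draw; the same seed reproduces
        the same controls.
    """
    present = _present_genes(norm, sig)
    avg = norm.X.mean(axis=1)
    order = pd.Series(avg, index=norm.genes).rank(method="first")
    n_bins = min(int(n_bins), len(norm.genes))
    bins = pd.qcut(order, q=n_bins, labels=False, duplicates="drop")
    rng = substream(seed, f"module_score:{sig.name}")

    ctrl: set[str] = set()
    gene_bins = bins.loc[present]
    for b in sorted(gene_bins.unique()):
        pool = bins.index[bins.values == b].to_numpy()
        k_sig = int((gene_bins == b).sum())
        if n_ctrl == "all":
            take = len(pool)
        else:
            take = min(int(n_ctrl) * k_sig, len(pool))
        # one draw per bin covering all signature genes falling in it
        chosen = rng.choice(pool, size=take, replace=False)
        ctrl.update(chosen.tolist())

    sig_mean = norm.gene_values(present).mean(axis=0)
    ctrl_mean = norm.gene_values(sorted(ctrl)).mean(axis=0)
    return pd.Series(sig_mean - ctrl_mean, index=norm.cells, name=sig.name)


def zscore_signature(norm: NormMatrix, sig: SignatureSet) -> pd.Series:
    """Mean per-gene z-score (standardized across cells) over the set."""
    present = _present_genes(norm, sig)
    vals = norm.gene_values(present)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    zero_var = (sd == 0).ravel()
    if zero_var.any():
        warnings.warn(
            f"signature {sig.name!r}: {int(zero_var.sum())} zero-variance gene(s); z defined 0"
        )
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd
    z[zero_var, :] = 0.0
    return pd.Series(z.mean(axis=0), index=norm.cells, name=sig.name)


def dysfunction_score(
    norm: NormMatrix,
    panel: SignatureSet | None = None,
    method: str = "module",
    n_bins: int = 25,
    n_ctrl: int | str = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell dysfunction score over an inhibitory-receptor panel."""
    if panel is None:
        panel = SignatureSet("dysfunction", DYSFUNCTION_PANEL)
    if method == "module":
        s = module_score(norm, panel, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    elif method == "zscore":
        s = zscore_signature(norm, panel)
    else:
        raise ValueError(f"unknown dysfunction method {method!r}")
    return s.rename("dysfunction")


def summarize_dysfunction(
    scores: pd.Series,
    cells: pd.DataFrame,
    by: str = "cell_type",
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Per-group mean dysfunction with Kruskal-Wallis + Dunn contrasts.

    When ``reference_group`` is given, Dunn post hoc p-values are
    reported for each group versus the reference (e.g. naive T cells);
    otherwise all pairwise contrasts are returned alongside the
    group-mean table.
    """
    groups = cells.loc[scores.index, by]
    summary = scores.groupby(groups).agg(["mean", "median", "size"])
    summary.columns = ["mean_score", "median_score", "n_cells"]
    summary = summary.sort_values("mean_score", ascending=False)
    if groups.nunique() >= 3:
        dunn = dunn_test(scores, groups)
        if reference_group is not None:
            dunn = dunn[(dunn["group_a"] == reference_group) | (dunn["group_b"] == reference_group)]
        summary.attrs["dunn"] = dunn.reset_index(drop=True)
        summary.attrs["kruskal_p"] = float(
            st.kruskal(*[scores[groups == g].to_numpy() for g in groups.unique()]).pvalue
        )
    return summary


def expressing_fraction(
    counts: CountMatrix,
    cells: pd.DataFrame,
    genes=COSTIM_GENES,
    group_by: str = "cell_type",
    groups=None,
    min_cells: int = 5,
) -> pd.DataFrame:
    """Fraction of cells with raw count > 0 per (sample, group, gene).

    Operates on raw (optionally depth-downsampled) counts, never on
    normalized values.  Sample/group combinations with fewer than
    ``min_cells`` cells are omitted from the table.
    """
    if not len(genes):
        raise ValueError("no genes given")
    known = [g for g in genes if g in counts.genes]
    unknown = [g for g in genes if g not in counts.genes]
    if unknown:
        warnings.warn(f"unknown gene(s) skipped: {unknown}")
    if not known:
        return pd.DataFrame(columns=["sample_id", "group", "gene", "fraction", "n_cells"])

    meta = cells.loc[counts.cells]
    expressed = pd.DataFrame(
        counts.subset(genes=known).to_dense().T > 0, index=counts.cells, columns=known
    )
    rows = []
    for (sample, group), idx in meta.groupby(["sample_id", group_by], observed=True).groups.items():
        if groups is not None and group not in groups:
            continue
        n = len(idx)
        if n < min_cells:
            continue
        frac = expressed.loc[idx].mean(axis=0)
        for g in known:
            rows.append({"sample_id": sample, "group": group, "gene": g, "fraction": float(frac[g]), "n_cells": n})
    out = pd.DataFrame(rows, columns=["sample_id", "group", "gene", "fraction", "n_cells"])
    if out.empty:
        warnings.warn(f"all sample/group combinations have < {min_cells} cells")
    return out


# ---------------------------------------------------------------------------
# Group comparison statistics


def dunn_test(values: pd.Series, groups: pd.Series, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post hoc test on ranks after a Kruskal-Wallis comparison.

    Pairwise z statistics use the pooled rank variance with tie
    correction; two-sided p-values are adjusted across all pairwise
    contrasts (Bonferroni by default).
    """
    values = pd.Series(values)
    groups = pd.Series(groups).loc[values.index]
    labels = groups.unique().tolist()
    if len(labels) < 2:
        raise ValueError("Dunn test needs at least two groups")
    N = len(values)
    ranks = values.rank()
    mean_rank = ranks.groupby(groups).mean()
    n = ranks.groupby(groups).size()
    _, tie_counts = np.unique(values.to_numpy(), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2 * st.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p": float(p)})
    out = pd.DataFrame(rows)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    elif adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="holm")[1]
    elif adjust is None or adjust == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["significant"] = out["p_adj"] <= 0.05
    return out


def compare_groups(values, groups, test: str = "wilcoxon", alpha: float = 0.05) -> pd.DataFrame:
    """Nonparametric comparison of per-sample or per-cell values.

    ``wilcoxon`` and ``mannwhitney`` both perform the two-sided
    Wilcoxon rank-sum / Mann-Whitney U test (exact for small groups);
    ``kruskal_dunn`` performs a Kruskal-Wallis test followed by Dunn's
    post hoc contrasts.  Contrasts with p <= ``alpha`` are flagged
    significant (the <= rule, so p exactly at the threshold counts).
    """
    values = pd.Series(values)
    groups = pd.Series(groups)
    groups = groups.loc[values.index] if values.index.equals(groups.index) else groups
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups to compare")
    by = {g: values[groups == g].to_numpy() for g in labels}

    if test in ("wilcoxon", "mannwhitney"):
        rows = []
        for a, b in combinations(labels, 2):
            res = st.mannwhitneyu(by[a], by[b], alternative="two-sided")
            rows.append(
                {"group_a": a, "group_b": b, "statistic": float(res.statistic), "p": float(res.pvalue)}
            )
        out = pd.DataFrame(rows)
        out["significant"] = out["p"] <= alpha
        return out
    if test == "kruskal_dunn":
        if len(labels) < 3:
            raise ValueError("kruskal_dunn needs three or more groups")
        out = dunn_test(values, groups)
        out["significant"] = out["p_adj"] <= alpha
        out.attrs["kruskal_p"] = float(st.kruskal(*by.values()).pvalue)
        return out
    raise ValueError(f"unknown test {test!r}")
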