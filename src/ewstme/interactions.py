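"""Ligand-receptor communication scoring between annotated cell groups.

The communication model is a mass-action Hill form: with trimmed-mean
ligand expression L in the source group and receptor expression R in the
target group, the communication probability is::

    P = (L * R)^n / (Kh^n + (L * R)^n)

a saturating function of the ligand-receptor product (half-saturation
Kh, Hill coefficient n).  Multi-subunit complexes are aggregated by the
geometric mean of their subunit means, so a missing subunit zeroes the
complex (AND semantics).  Significance comes from a label-permutation
null.  Cofactor and agonist/antagonist terms of richer communication
frameworks are deliberately not modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import scipy.stats as st

from ._utils import substream
from .containers import NormMatrix


@dataclass
class LRPair:
    pair_id: str
    ligand: tuple[str, ...]
    receptor: tuple[str, ...]
    pathway: str = ""
    display: str = ""

    def __post_init__(self) -> None:
        self.ligand = tuple(self.ligand)
        self.receptor = tuple(self.receptor)
        if not self.ligand or not self.receptor:
            raise ValueError(f"pair {self.pair_id!r} has an empty subunit list")


class LRDatabase:
    """Curated ligand-receptor pairs, multi-subunit capable.

    Pairs are stored canonically ligand -> receptor; the ``display``
    field keeps a presentation order (some published pair names list the
    receptor first).
    """

    def __init__(self, pairs):
        self.pairs = list(pairs)
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pair ids in LR database")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.update(p.ligand)
            out.update(p.receptor)
        return out

    def subset_present(self, genes) -> "LRDatabase":
        """Pairs whose every subunit is present in the given gene index."""
        genes = set(genes)
        return LRDatabase(
            [p for p in self.pairs if set(p.ligand) <= genes and set(p.receptor) <= genes]
        )

    @classmethod
    def from_tsv(cls, path) -> "LRDatabase":
        df = pd.read_csv(path, sep="\t")
        pairs = [
            LRPair(
                row["pair_id"],
                tuple(row["ligand_subunits"].split("+")),
                tuple(row["receptor_subunits"].split("+")),
                row.get("pathway", ""),
                row.get("display", ""),
            )
            for _, row in df.iterrows()
        ]
        return cls(pairs)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "pair_id": [p.pair_id for p in self.pairs],
                "ligand_subunits": ["+".join(p.ligand) for p in self.pairs],
                "receptor_subunits": ["+".join(p.receptor) for p in self.pairs],
                "pathway": [p.pathway for p in self.pairs],
                "display": [p.display for p in self.pairs],
            }
        ).to_csv(path, sep="\t", index=False)


def default_lr_database() -> LRDatabase:
    """The packaged database of immunoregulatory ligand-receptor pairs."""
    with resources.as_file(resources.files("ewstme.data") / "lr_pairs.tsv") as p:
        return LRDatabase.from_tsv(p)


def group_mean_expression(
    norm: NormMatrix, cells: pd.DataFrame, group_by: str = "cell_type", trim: float = 0.1
) -> pd.DataFrame:
    """Trimmed mean of normalized expression per group (groups x genes)."""
    labels = cells.loc[norm.cells, group_by]
    out = {}
    for g, idx in labels.groupby(labels).groups.items():
        cols = norm.cells.get_indexer(idx)
        if len(cols) == 0:
            raise ValueError(f"group {g!r} is empty")
        vals = norm.X[:, cols]
        out[g] = st.trim_mean(vals, proportiontocut=trim, axis=1) if trim > 0 else vals.mean(axis=1)
    return pd.DataFrame(out, index=norm.genes).T


def _complex_mean(means: pd.DataFrame, subunits: tuple[str, ...]) -> pd.Series:
    """Geometric mean over subunits; zero if any subunit mean is zero."""
    sub = means[list(subunits)]
    if (sub < 0).to_numpy().any():
        raise ValueError("negative group means; communication needs a non-negative scale")
    return np.exp(np.log(sub.where(sub > 0)).mean(axis=1)).fillna(0.0) * (sub > 0).all(axis=1)


def _subunit_index(pairs: LRDatabase, genes: pd.Index) -> tuple[np.ndarray, np.ndarray]:
    """Padded (n_pairs, max_subunits) gene-index matrices for ligand/receptor."""

    def build(units_of):
        lists = [genes.get_indexer(units_of(p)) for p in pairs]
        width = max(len(v) for v in lists)
        idx = np.zeros((len(lists), width), dtype=int)
        mask = np.zeros((len(lists), width), dtype=bool)
        for i, v in enumerate(lists):
            if (v < 0).any():
                raise KeyError(f"pair {pairs.pairs[i].pair_id!r} has subunits absent from matrix")
            idx[i, : len(v)] = v
            mask[i, : len(v)] = True
        return idx, mask

    return build(lambda p: list(p.ligand)), build(lambda p: list(p.receptor))


def _complex_values(means_np: np.ndarray, idx_mask) -> np.ndarray:
    """(n_pairs, n_groups) geometric means over subunits; 0 if any subunit is 0."""
    idx, mask = idx_mask
    with np.errstate(divide="ignore"):
        logm = np.log(means_np)  # -inf where 0; propagates to geometric mean 0
    gathered = logm[:, idx]  # groups x pairs x width
    gathered = np.where(mask[None, :, :], gathered, 0.0)
    avg = gathered.sum(axis=2) / mask.sum(axis=1)[None, :]
    return np.exp(avg).T  # pairs x groups


def _prob_tensor_np(means_np: np.ndarray, idx, kh: float, hill_n: float) -> np.ndarray:
    """(n_pairs, n_source, n_target) Hill probabilities from a groups x genes array."""
    if (means_np < 0).any():
        raise ValueError("negative group means; communication needs a non-negative scale")
    lig_idx, rec_idx = idx
    lig = _complex_values(means_np, lig_idx)
    rec = _complex_values(means_np, rec_idx)
    x = (lig[:, :, None] * rec[:, None, :]) ** hill_n
    return x / (kh**hill_n + x)


def _prob_tensor(means: pd.DataFrame, pairs: LRDatabase, kh: float, hill_n: float) -> np.ndarray:
    """(n_pairs, n_source, n_target) Hill probabilities from group means."""
    idx = _subunit_index(pairs, pd.Index(means.columns))
    return _prob_tensor_np(means.to_numpy(dtype=float), idx, kh, hill_n)


def communication_probability(
    means: pd.DataFrame, lr_db: LRDatabase, kh: float = 0.5, hill_n: float = 1.0
) -> pd.DataFrame:
    """Hill-form communication probability for every (source, target, pair).

    ``means`` is the groups x genes table from
    :func:`group_mean_expression`.  Pairs with a subunit absent from the
    matrix are skipped with a warning.
    """
    if kh <= 0 or hill_n < 1:
        raise ValueError("need Kh > 0 and hill_n >= 1")
    present = lr_db.subset_present(means.columns)
    skipped = set(lr_db.pair_ids()) - set(present.pair_ids())
    if skipped:
        warnings.warn(f"{len(skipped)} pair(s) with absent subunits skipped")
    groups = means.index.tolist()
    tensor = _prob_tensor(means, present, kh, hill_n)
    rows = []
    for i, p in enumerate(present):
        for si, s in enumerate(groups):
            for ti, t in enumerate(groups):
                rows.append(
                    {"source": s, "target": t, "pair_id": p.pair_id, "probability": float(tensor[i, si, ti])}
                )
    return pd.DataFrame(rows)


def permutation_test(
    norm: NormMatrix,
    cells: pd.DataFrame,
    lr_db: LRDatabase,
    group_by: str = "cell_type",
    n_perm: int = 1000,
    seed: int = 0,
    trim: float = 0.1,
    kh: float = 0.5,
    hill_n: float = 1.0,
) -> pd.DataFrame:
    """Communication probabilities with label-permutation p-values.

    Group labels are shuffled across cells ``n_perm`` times;
    p = (1 + #{perm P >= observed P}) / (n_perm + 1).  An observed
    probability of exactly 0 is reported with p = 1 (there is nothing
    to exceed).  Deterministic given the seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = cells.loc[norm.cells, group_by]
    sizes = labels.value_counts()
    if (sizes < 3).any():
        warnings.warn(f"groups with < 3 cells permute poorly: {sizes[sizes < 3].index.tolist()}")

    lr_genes = sorted(lr_db.genes() & set(norm.genes))
    sub = NormMatrix(norm.gene_values(lr_genes), pd.Index(lr_genes), norm.cells, norm.method)
    present = lr_db.subset_present(lr_genes)
    skipped = set(lr_db.pair_ids()) - set(present.pair_ids())
    if skipped:
        warnings.warn(f"{len(skipped)} pair(s) with absent subunits skipped")

    groups = sorted(labels.unique())
    lab_arr = labels.to_numpy()
    idx = _subunit_index(present, sub.genes)

    def group_means(lab) -> np.ndarray:
        rows = []
        for g in groups:
            vals = sub.X[:, lab == g]
            if trim > 0:
                k = int(np.floor(trim * vals.shape[1]))
                vals = np.sort(vals, axis=1)
                vals = vals[:, k : vals.shape[1] - k] if k else vals
            rows.append(vals.mean(axis=1))
        return np.stack(rows)

    obs = _prob_tensor_np(group_means(lab_arr), idx, kh, hill_n)
    exceed = np.zeros_like(obs, dtype=int)
    rng = substream(seed, "lr_permutation")
    for _ in range(n_perm):
        perm = _prob_tensor_np(group_means(rng.permutation(lab_arr)), idx, kh, hill_n)
        exceed += perm >= obs

    pvals = (1 + exceed) / (n_perm + 1)
    rows = []
    for i, p in enumerate(present):
        for si, s in enumerate(groups):
            for ti, t in enumerate(groups):
                prob = float(obs[i, si, ti])
                rows.append(
                    {
                        "source": s,
                        "target": t,
                        "pair_id": p.pair_id,
                        "probability": prob,
                        "p": 1.0 if prob == 0 else float(pvals[i, si, ti]),
                    }
                )
    return pd.DataFrame(rows)


def count_unique_interactions(
    result: pd.DataFrame, source_set, target_set, p_thresh: float = 0.05
) -> tuple[int, list[str]]:
    """Distinct significant pairs between two collections of groups.

    A pair counts once if it is significant for any (source, target)
    combination in either direction between the two sets.
    """
    known = set(result["source"]) | set(result["target"])
    for g in list(source_set) + list(target_set):
        if g not in known:
            raise KeyError(f"unknown group {g!r}")
    a, b = set(source_set), set(target_set)
    mask = (
        (result["source"].isin(a) & result["target"].isin(b))
        | (result["source"].isin(b) & result["target"].isin(a))
    ) & (result["p"] <= p_thresh)
    pairs = sorted(result.loc[mask, "pair_id"].unique())
    return len(pairs), pairs
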