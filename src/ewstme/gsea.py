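"""Preranked gene set enrichment analysis.

The classic weighted Kolmogorov-Smirnov running sum: walking down a
ranked gene list, hits increment the walk by |stat|^weight (normalized
over the hit total) and misses decrement it by 1/(N - Nh); the
enrichment score (ES) is the extremum of the walk.  Normalized scores
(NES) and p-values come from gene-label permutations, appropriate for
preranked DE lists where no phenotype labels remain to permute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import substream
from .signatures import SignatureSet


def rank_genes(stats: pd.Series) -> pd.Series:
    """Sort a signed per-gene statistic into a ranked list.

    Descending by statistic; ties broken by symbol order so the walk is
    deterministic.
    """
    df = pd.DataFrame({"stat": stats})
    df["symbol"] = df.index
    df = df.sort_values(["stat", "symbol"], ascending=[False, True], kind="stable")
    if df["symbol"].duplicated().any():
        raise ValueError("ranked list has duplicate symbols")
    return df["stat"]


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    leading_edge: tuple[str, ...]


def _walk(stats: np.ndarray, is_hit: np.ndarray, weight: float) -> np.ndarray:
    n = len(stats)
    nh = int(is_hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("signature overlap must be a strict nonempty subset of the list")
    inc = np.abs(stats) ** weight
    hit_total = inc[is_hit].sum()
    steps = np.where(is_hit, inc / hit_total if hit_total > 0 else 1.0 / nh, -1.0 / (n - nh))
    if hit_total == 0:  # all hit stats are zero: fall back to unweighted hits
        steps[is_hit] = 1.0 / nh
    return np.cumsum(steps)


def enrichment_score(
    ranked: pd.Series, sig: SignatureSet, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES of a signature on a ranked list, plus the full running walk.

    The ES is the walk value of largest magnitude; its sign says whether
    the signature concentrates at the top (+) or bottom (-) of the
    ranking.
    """
    stats = ranked.to_numpy(dtype=float)
    is_hit = ranked.index.isin(sig.genes)
    if not is_hit.any():
        raise ValueError(f"no gene of {sig.name!r} appears in the ranked list")
    walk = _walk(stats, is_hit, weight)
    es = walk[np.argmax(np.abs(walk))]
    return float(es), walk


def nes_permutation(
    ranked: pd.Series,
    sig: SignatureSet,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """NES and permutation p-value by gene-label permutation.

    NES = ES / mean(|ES_perm| over same-sign permutations);
    p = (1 + #{same-sign |ES_perm| >= |ES|}) / (n_same_sign + 1).
    Deterministic given the seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es, walk = enrichment_score(ranked, sig, weight)
    stats = ranked.to_numpy(dtype=float)
    is_hit = ranked.index.isin(sig.genes)
    nh = int(is_hit.sum())
    n = len(ranked)
    rng = substream(seed, f"gsea:{sig.name}")
    perm_es = np.empty(n_perm)
    hit = np.zeros(n, dtype=bool)
    for k in range(n_perm):
        hit[:] = False
        hit[rng.choice(n, size=nh, replace=False)] = True
        w = _walk(stats, hit, weight)
        perm_es[k] = w[np.argmax(np.abs(w))]

    same_sign = perm_es * np.sign(es) > 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        warnings.warn("no same-sign permutation scores; p floored at 1/(n_perm+1)")
        nes = np.sign(es) * np.inf if es != 0 else 0.0
        p = 1.0 / (n_perm + 1)
    else:
        denom = np.abs(perm_es[same_sign]).mean()
        nes = es / denom if denom > 0 else 0.0
        p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (n_same + 1)

    # leading edge: hits at or before the walk extremum, on the ES side
    ext = int(np.argmax(np.abs(walk)))
    if es >= 0:
        le = ranked.index[: ext + 1][is_hit[: ext + 1]]
    else:
        le = ranked.index[ext:][is_hit[ext:]]
    return GseaResult(sig.name, float(es), float(nes), float(p), tuple(le))
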