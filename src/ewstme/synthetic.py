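"""Synthetic multi-sample scRNA-seq cohorts with planted ground truth.

The generator emulates every statistical structure the downstream
analysis assumes: a multi-patient cohort with tumor, stromal and immune
compartments; cell-type marker programs; tumor-restricted arm-level copy
number gains; HLA class I downregulation in tumor cells; zero-inflated
costimulatory-gene expression with plantable per-type expressing
probabilities; and per-sample ligand-receptor axes whose strength drives
a CD8+ T-cell dysfunction gradient.

Counts are drawn from a negative binomial (gamma-Poisson) model::

    count ~ NB(mean = depth_factor x type_mean x cnv_fold x hla_factor,
               dispersion)

with a shared dispersion (variance = mu + dispersion * mu^2) and
per-cell lognormal library-size factors.  All latent draws are recorded
in a :class:`SimTruth` object that serves as the oracle for tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._utils import substream
from .containers import CountMatrix
from .signatures import COSTIM_GENES, DYSFUNCTION_PANEL, SignatureSet, write_gmt

# ---------------------------------------------------------------------------
# Gene universe

COMPARTMENT_OF = {
    "tumor": "tumor",
    "endothelial": "endothelial",
    "CAF": "CAF",
}
# every other type is immune

DEFAULT_PROPORTIONS = {
    "tumor": 0.40,
    "endothelial": 0.05,
    "CAF": 0.05,
    "CD8_T": 0.12,
    "CD4_T": 0.10,
    "NK": 0.05,
    "Treg": 0.03,
    "Mo": 0.08,
    "Mphi": 0.07,
    "cDC": 0.05,
}

DEFAULT_MARKERS = {
    "tumor": ("CD99", "CAV1", "CCND1", "HES1", "KDSR", "PAPPA"),
    "endothelial": ("PECAM1", "VWF", "CDH5", "CLDN5"),
    "CAF": ("COL1A1", "COL1A2", "ACTA2", "FAP", "DCN", "LUM"),
    "CD8_T": ("CD8A", "CD8B", "GZMA", "GZMH", "GZMK", "CCL5"),
    "CD4_T": ("CD4", "IL7R", "CD3D", "CD3E"),
    "NK": ("GNLY", "PRF1", "GZMB", "NCAM1", "FCGR3A", "KLRD1"),
    "Treg": ("FOXP3", "IL2RA", "IKZF2", "TNFRSF4"),
    "Mo": ("VCAN", "S100A8", "S100A9", "FCN1", "LYZ"),
    "Mphi": ("CD68", "CD163", "MRC1", "APOE", "GPNMB", "MSR1"),
    "cDC": ("ITGAX", "CD1C", "CLEC10A", "FLT3", "FCER1A"),
}

# Genomic arm of every named gene in the universe (approximate, for the
# synthetic genome layout; positions within arms are synthetic).
_SPECIAL_ARMS = {
    # tumor / stroma / immune markers
    "CD99": "Xp", "CAV1": "7q", "CCND1": "11q", "HES1": "3q", "KDSR": "18q", "PAPPA": "9q",
    "PECAM1": "17q", "VWF": "12p", "CDH5": "16q", "CLDN5": "22q",
    "COL1A1": "17q", "COL1A2": "7q", "ACTA2": "10q", "FAP": "2q", "DCN": "12q", "LUM": "12q",
    "CD8A": "2p", "CD8B": "2p", "GZMA": "5q", "GZMH": "14q", "GZMK": "5q", "CCL5": "17q",
    "CD4": "12p", "IL7R": "5p", "CD3D": "11q", "CD3E": "11q",
    "GNLY": "2p", "PRF1": "10q", "GZMB": "14q", "NCAM1": "11q", "FCGR3A": "1q", "KLRD1": "12p",
    "FOXP3": "Xp", "IL2RA": "10p", "IKZF2": "2q", "TNFRSF4": "1p",
    "VCAN": "5q", "S100A8": "1q", "S100A9": "1q", "FCN1": "9q", "LYZ": "12q",
    "CD68": "17p", "CD163": "12p", "MRC1": "10p", "APOE": "19q", "GPNMB": "7p", "MSR1": "8p",
    "ITGAX": "16p", "CD1C": "1q", "CLEC10A": "17p", "FLT3": "13q", "FCER1A": "1q",
    # HLA and antigen presentation
    "HLA-A": "6p", "HLA-B": "6p", "HLA-C": "6p", "HLA-E": "6p", "HLA-F": "6p", "B2M": "15q",
    "HLA-DRA": "6p", "HLA-DRB1": "6p", "HLA-DPA1": "6p", "HLA-DPB1": "6p",
    "HLA-DQA1": "6p", "HLA-DQB1": "6p",
    # costimulation
    "CD40": "20q", "CD70": "19p", "CD80": "3q", "CD83": "6p", "CD86": "3q",
    "TNFSF9": "19p", "ICOSLG": "21q",
    # inhibitory receptors (dysfunction panel)
    "LAG3": "12p", "HAVCR2": "5q", "TIGIT": "3q", "PDCD1": "2q", "CTLA4": "2q",
    "BTLA": "3q", "KLRG1": "12p", "ENTPD1": "10q",
    # ligand-receptor genes
    "WNT5A": "3p", "FZD2": "17q", "TGFB1": "19q", "TGFBR3": "1p", "TGFBR1": "9q",
    "TGFBR2": "3p", "VEGFA": "6p", "NRP1": "10p", "NRP2": "2q", "SPP1": "4q",
    "CD44": "11p", "SEMA4D": "9q", "PLXNB2": "22q", "SEMA3A": "7q", "MDK": "11p",
    "LRP1": "12q", "IGF1": "12q", "IGF1R": "15q", "ANXA1": "9q", "FPR1": "19q",
    "FPR2": "19q", "FPR3": "19q", "TNFSF10": "3q", "TNFRSF10B": "8p", "CD47": "3q",
    "SIRPA": "20p", "RPS19": "19q", "C5AR1": "19q", "GAS6": "13q", "AXL": "19q",
    "NECTIN2": "19q", "SELPLG": "12q", "SELL": "1q", "SPN": "16p", "SIGLEC1": "20p",
    "LGALS9": "17p",
    # cytokine / polarization panels
    "CCR7": "17q", "RELB": "19q", "NFKB1": "4q", "STAT3": "17q", "IL12B": "5q",
    "TRAF1": "9q", "IL1B": "2q", "TNF": "6p", "IL6": "7p", "IL18": "11q",
    "CCL3": "17q", "CCL4": "17q", "CXCL8": "4q", "CXCL9": "4q", "CXCL10": "4q",
    "CXCL11": "4q", "NOS2": "17q", "FCGR1A": "1q", "SOCS1": "16p", "IL10": "1q",
    "IL1RN": "2q", "CCL22": "16q", "IL4R": "16p", "STAB1": "3p", "LYVE1": "11p",
}

ALL_ARMS = tuple(f"{c}{a}" for c in list(range(1, 23)) + ["X"] for a in ("p", "q"))


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class CNVEvent:
    arm: str
    fold: float
    cell_type: str = "tumor"


@dataclass
class LRAxis:
    """A planted ligand-receptor communication axis.

    The ligand gene's mean in source-type cells of sample *j* is scaled
    by a per-sample strength factor drawn lognormal(0, strength_sigma);
    both genes additionally receive a fixed boost in their source/target
    type so the pair is genuinely expressed where it should be.
    """

    ligand: str
    receptor: str
    source_type: str
    target_type: str
    strength_sigma: float = 0.5
    ligand_boost: float = 3.0
    receptor_boost: float = 3.0

    @property
    def axis_id(self) -> str:
        return f"{self.ligand}_{self.receptor}"


def _default_costim_probs(prob: float = 0.05) -> dict:
    return {(t, g): prob for t in ("Mo", "Mphi", "cDC") for g in COSTIM_GENES}


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults are sized for desk scale and mirror a small multi-sample
    pediatric sarcoma cohort: 12 samples from 8 patients, ~400 cells per
    sample, 2,000 genes with a median library size of ~5,000 UMIs, tumor
    cells carrying 1.5x gains on arms 1q/2q/8q with HLA class I reduced
    to 0.3x, sparse costimulatory-gene expression in myeloid cells
    (P(expressing) = 0.05), and one NECTIN2->TIGIT axis from macrophages
    to CD8+ T cells coupled to the CD8 dysfunction panel.
    """

    n_samples: int = 12
    n_patients: int = 8
    cells_per_sample: tuple[int, int] = (350, 450)
    n_genes: int = 2000
    cell_type_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    proportion_concentration: float = 50.0
    marker_programs: dict = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    marker_fold: float = 6.0
    cnv_events: list = field(
        default_factory=lambda: [CNVEvent("1q", 1.5), CNVEvent("2q", 1.5), CNVEvent("8q", 1.5)]
    )
    genes_per_cnv_arm: int = 150
    hla_downreg_factor: float = 0.3
    costim_expression_probs: dict = field(default_factory=_default_costim_probs)
    costim_on_mean: float = 2.5
    lr_axes: list = field(
        default_factory=lambda: [LRAxis("NECTIN2", "TIGIT", "Mphi", "CD8_T")]
    )
    dysfunction_coupling: float = 0.5
    dysfunction_noise_sd: float = 0.36
    dysfunction_panel: tuple = DYSFUNCTION_PANEL
    panel_cd8_boost: float = 3.0
    cd8_type: str = "CD8_T"
    nb_dispersion: float = 0.3
    depth_lognormal: tuple[float, float] = (0.0, 0.35)
    median_depth: float = 5000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if self.n_patients < 1 or self.n_patients > self.n_samples:
            raise ValueError("need 1 <= n_patients <= n_samples")
        lo, hi = self.cells_per_sample
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_sample must be a nonempty positive range")
        if not self.cell_type_proportions:
            raise ValueError("cell_type_proportions is empty")
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"cell type proportions sum to {total}, not 1")
        if any(p < 0 for p in self.cell_type_proportions.values()):
            raise ValueError("negative cell type proportion")
        for ev in self.cnv_events:
            if ev.fold <= 0:
                raise ValueError(f"CNV fold must be > 0, got {ev.fold}")
        if not (0 < self.hla_downreg_factor):
            raise ValueError("hla_downreg_factor must be > 0")
        for (t, g), p in self.costim_expression_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"costim probability for ({t}, {g}) outside [0, 1]: {p}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class SimTruth:
    """Planted simulation parameters and realized latent draws."""

    cells: pd.DataFrame
    cnv_state: pd.DataFrame  # cells x aberrant arms, planted fold (1.0 = neutral)
    axis_strengths: pd.DataFrame  # samples x axes
    expected_dysfunction: pd.Series  # per sample, arbitrary (log-fold) units
    config: SimConfig

    def to_json(self) -> str:
        payload = {
            "cell_types": self.cells["cell_type"].tolist(),
            "cell_ids": self.cells.index.tolist(),
            "sample_ids": self.cells["sample_id"].tolist(),
            "patient_ids": self.cells["patient_id"].tolist(),
            "treatment_status": self.cells["treatment_status"].tolist(),
            "axis_strengths": {
                c: self.axis_strengths[c].to_dict() for c in self.axis_strengths.columns
            },
            "expected_dysfunction": self.expected_dysfunction.to_dict(),
            "config": _config_to_dict(self.config),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        config = _config_from_dict(payload["config"])
        cells = pd.DataFrame(
            {
                "sample_id": payload["sample_ids"],
                "patient_id": payload["patient_ids"],
                "treatment_status": payload["treatment_status"],
                "cell_type": payload["cell_types"],
            },
            index=pd.Index(payload["cell_ids"], name="cell_id"),
        )
        cells["compartment"] = [COMPARTMENT_OF.get(t, "immune") for t in cells["cell_type"]]
        strengths = pd.DataFrame(payload["axis_strengths"])
        strengths.index.name = "sample_id"
        dysf = pd.Series(payload["expected_dysfunction"], name="expected_dysfunction")
        dysf.index.name = "sample_id"
        return cls(cells, _cnv_state(cells, config), strengths, dysf, config)


def _config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["costim_expression_probs"] = [
        [t, g, p] for (t, g), p in config.costim_expression_probs.items()
    ]
    return d


def _config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["cells_per_sample"] = tuple(d["cells_per_sample"])
    d["depth_lognormal"] = tuple(d["depth_lognormal"])
    d["dysfunction_panel"] = tuple(d["dysfunction_panel"])
    d["cnv_events"] = [CNVEvent(**ev) for ev in d["cnv_events"]]
    d["lr_axes"] = [LRAxis(**ax) for ax in d["lr_axes"]]
    d["costim_expression_probs"] = {(t, g): p for t, g, p in d["costim_expression_probs"]}
    d["marker_programs"] = {t: tuple(gs) for t, gs in d["marker_programs"].items()}
    return SimConfig(**d)


def _cnv_state(cells: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    arms = [ev.arm for ev in config.cnv_events]
    state = pd.DataFrame(1.0, index=cells.index, columns=arms)
    for ev in config.cnv_events:
        state.loc[cells["cell_type"] == ev.cell_type, ev.arm] = ev.fold
    return state


# ---------------------------------------------------------------------------
# Gene table


def build_gene_table(config: SimConfig) -> pd.DataFrame:
    """Synthetic genome layout: symbols with chromosome, arm, start_bp.

    Named genes (markers, HLA, costimulatory, inhibitory receptors,
    ligand-receptor genes, cytokine panels) sit on their approximate
    real arms; filler genes are laid out so that every aberrant arm
    carries at least ``genes_per_cnv_arm`` genes and the rest are
    distributed round-robin.
    """
    symbols: list[str] = []
    arms: list[str] = []
    for sym, arm in _SPECIAL_ARMS.items():
        symbols.append(sym)
        arms.append(arm)
    if len(symbols) > config.n_genes:
        symbols = symbols[: config.n_genes]
        arms = arms[: config.n_genes]

    n_fill = config.n_genes - len(symbols)
    fill_arms: list[str] = []
    arm_counts = pd.Series(arms).value_counts()
    for ev in config.cnv_events:
        have = int(arm_counts.get(ev.arm, 0)) + fill_arms.count(ev.arm)
        need = max(0, config.genes_per_cnv_arm - have)
        fill_arms.extend([ev.arm] * min(need, n_fill - len(fill_arms)))
    cnv_arms = {ev.arm for ev in config.cnv_events}
    other = [a for a in ALL_ARMS if a not in cnv_arms]
    i = 0
    while len(fill_arms) < n_fill:
        fill_arms.append(other[i % len(other)])
        i += 1
    for k, arm in enumerate(fill_arms):
        symbols.append(f"GENE{k + 1:04d}")
        arms.append(arm)

    table = pd.DataFrame({"symbol": symbols, "arm": arms})
    table["chromosome"] = table["arm"].str[:-1]
    # q-arm genes placed after all p-arm genes within a chromosome
    offset = np.where(table["arm"].str[-1] == "q", 150_000_000, 1_000_000)
    within = table.groupby("arm").cumcount()
    table["start_bp"] = offset + within * 100_000
    return table.set_index("symbol")[["chromosome", "arm", "start_bp"]]


# ---------------------------------------------------------------------------
# Simulation


def _baseline_means(config: SimConfig, gene_table: pd.DataFrame) -> pd.Series:
    rng = substream(config.seed, "baseline")
    w = pd.Series(rng.lognormal(0.0, 1.0, size=len(gene_table)), index=gene_table.index)
    for g in ("HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "B2M"):
        if g in w.index:
            w[g] *= 6.0
    for g in ("HLA-DRA", "HLA-DRB1", "HLA-DPA1", "HLA-DPB1", "HLA-DQA1", "HLA-DQB1"):
        if g in w.index:
            w[g] *= 3.0
    for g in config.dysfunction_panel:
        if g in w.index:
            w[g] = max(w[g], 1.0) * 2.0
    lr_genes = {ax.ligand for ax in config.lr_axes} | {ax.receptor for ax in config.lr_axes}
    for g in lr_genes:
        if g in w.index:
            w[g] = max(w[g], 1.0) * 2.5
    costim = {g for (_, g) in config.costim_expression_probs}
    w[w.index.isin(costim)] = 0.0  # zero-inflated layer handles these
    return w / w.sum() * config.median_depth


def plant_dysfunction_axis(
    truth: SimTruth,
    coupling: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SimTruth:
    """Couple per-sample dysfunction to the (standardized) axis strength.

    The expected per-sample CD8 dysfunction shift (in log-fold units on
    the panel genes) is ``coupling * z(mean log strength) + noise``.
    With ``coupling = 0`` and no noise the expected dysfunction is equal
    across samples; with nonzero coupling and no noise the sample
    ranking by strength equals the ranking by expected dysfunction.
    """
    if truth.axis_strengths.shape[1] == 0:
        raise ValueError("no ligand-receptor axes planted in this cohort")
    if not (truth.cells["cell_type"] == truth.config.cd8_type).any():
        raise ValueError(f"no {truth.config.cd8_type} cells simulated; cannot plant dysfunction")
    log_s = np.log(truth.axis_strengths).mean(axis=1)
    sd = log_s.std()
    z = (log_s - log_s.mean()) / sd if sd > 0 else log_s * 0.0
    alpha = coupling * z
    if noise_sd > 0:
        rng = substream(truth.config.seed if seed is None else seed, "dysfunction_noise")
        alpha = alpha + noise_sd * rng.standard_normal(len(alpha))
    alpha.name = "expected_dysfunction"
    return SimTruth(truth.cells, truth.cnv_state, truth.axis_strengths, alpha, truth.config)


def simulate_cohort(config: SimConfig):
    """Draw a full cohort: counts, cell table, gene table and truth.

    Returns ``(CountMatrix, CellTable, GeneTable, SimTruth)``.  The
    draw is deterministic given ``config.seed``; every stochastic layer
    consumes its own named substream.
    """
    config.validate()
    gene_table = build_gene_table(config)
    mu_gene = _baseline_means(config, gene_table)
    types = list(config.cell_type_proportions)
    base_props = np.array([config.cell_type_proportions[t] for t in types])

    # --- samples, patients, cells
    rng_cells = substream(config.seed, "cells")
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    patient_of = {s: f"P{(i % config.n_patients) + 1:02d}" for i, s in enumerate(sample_ids)}
    treatment_of = {s: ("naive" if i % 2 == 0 else "exposed") for i, s in enumerate(sample_ids)}
    lo, hi = config.cells_per_sample
    rows = []
    for s in sample_ids:
        n = int(rng_cells.integers(lo, hi + 1))
        props = base_props
        if config.proportion_concentration and len(types) > 1:
            props = rng_cells.dirichlet(base_props * config.proportion_concentration)
        labels = rng_cells.choice(types, size=n, p=props)
        for j, t in enumerate(labels):
            rows.append((f"{s}_C{j + 1:04d}", s, patient_of[s], treatment_of[s], t))
    cells = pd.DataFrame(
        rows, columns=["cell_id", "sample_id", "patient_id", "treatment_status", "cell_type"]
    ).set_index("cell_id")
    cells["compartment"] = [COMPARTMENT_OF.get(t, "immune") for t in cells["cell_type"]]

    # --- per-sample axis strengths and dysfunction coupling
    rng_strength = substream(config.seed, "strengths")
    strengths = pd.DataFrame(
        {
            ax.axis_id: rng_strength.lognormal(0.0, ax.strength_sigma, size=config.n_samples)
            for ax in config.lr_axes
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SimTruth(
        cells,
        _cnv_state(cells, config),
        strengths,
        pd.Series(0.0, index=strengths.index, name="expected_dysfunction"),
        config,
    )
    if config.lr_axes and (cells["cell_type"] == config.cd8_type).any():
        truth = plant_dysfunction_axis(
            truth, config.dysfunction_coupling, config.dysfunction_noise_sd
        )

    # --- expected means per cell
    n_genes, n_cells = len(gene_table), len(cells)
    rng_depth = substream(config.seed, "depth")
    depth = rng_depth.lognormal(*config.depth_lognormal, size=n_cells)
    M = np.outer(mu_gene.to_numpy(), depth)
    gidx = pd.Series(np.arange(n_genes), index=gene_table.index)
    type_of = cells["cell_type"].to_numpy()
    sample_of = cells["sample_id"].to_numpy()

    for t, markers in config.marker_programs.items():
        cols = type_of == t
        if not cols.any():
            continue
        present = [m for m in markers if m in gidx.index]
        M[np.ix_(gidx[present].to_numpy(), cols)] *= config.marker_fold

    tumor_like: dict[str, np.ndarray] = {}
    for ev in config.cnv_events:
        cols = tumor_like.setdefault(ev.cell_type, type_of == ev.cell_type)
        arm_genes = gidx[gene_table["arm"] == ev.arm].to_numpy()
        if cols.any() and len(arm_genes):
            M[np.ix_(arm_genes, cols)] *= ev.fold

    hla_genes = gidx[gidx.index.isin(["HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "B2M"])]
    tumor_cols = type_of == "tumor"
    if config.hla_downreg_factor != 1.0 and tumor_cols.any() and len(hla_genes):
        M[np.ix_(hla_genes.to_numpy(), tumor_cols)] *= config.hla_downreg_factor

    for ax in config.lr_axes:
        src = type_of == ax.source_type
        tgt = type_of == ax.target_type
        if ax.receptor in gidx.index and tgt.any():
            M[gidx[ax.receptor], tgt] *= ax.receptor_boost
        if ax.ligand in gidx.index and src.any():
            s_of_cell = strengths[ax.axis_id].reindex(sample_of[src]).to_numpy()
            M[gidx[ax.ligand], src] *= ax.ligand_boost * s_of_cell

    panel = [g for g in config.dysfunction_panel if g in gidx.index]
    cd8 = type_of == config.cd8_type
    if panel and cd8.any():
        shift = np.exp(truth.expected_dysfunction.reindex(sample_of[cd8]).to_numpy())
        M[np.ix_(gidx[panel].to_numpy(), cd8)] *= config.panel_cd8_boost * shift

    # --- zero-inflated costimulatory layer
    rng_costim = substream(config.seed, "costim")
    for (t, g), p in config.costim_expression_probs.items():
        cols = type_of == t
        if g not in gidx.index or not cols.any():
            continue
        on = rng_costim.random(int(cols.sum())) < p
        M[gidx[g], cols] = np.where(on, config.costim_on_mean * depth[cols], 0.0)

    # --- NB draw (gamma-Poisson)
    rng_counts = substream(config.seed, "counts")
    r = 1.0 / config.nb_dispersion
    lam = np.where(M > 0, rng_counts.gamma(r, M / r), 0.0)
    X = sp.csr_matrix(rng_counts.poisson(lam).astype(np.int32))

    counts = CountMatrix(X, gene_table.index, cells.index)
    cell_table = cells.copy()
    cell_table["cluster_id"] = -1
    return counts, cell_table, gene_table, truth


# ---------------------------------------------------------------------------
# On-disk cohort format


def write_cohort(counts: CountMatrix, cells: pd.DataFrame, genes: pd.DataFrame, truth: SimTruth | None, outdir) -> dict:
    """Write a cohort as Matrix Market counts plus TSV/JSON sidecars.

    Produces ``matrix.mtx`` (genes x cells), ``features.tsv`` and
    ``barcodes.tsv`` (axis labels), ``cells.tsv`` (cell metadata),
    ``genes.tsv`` (genomic coordinates), ``truth.json`` and
    ``markers.gmt`` (marker programs of the generating config).
    The round trip through :func:`read_cohort` is lossless.
    """
    if len(cells) != counts.shape[1]:
        raise ValueError(f"cells table has {len(cells)} rows for {counts.shape[1]} columns")
    if len(genes) != counts.shape[0]:
        raise ValueError(f"gene table has {len(genes)} rows for {counts.shape[0]} rows")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", counts.X.tocoo(), field="integer")
    (outdir / "features.tsv").write_text("\n".join(counts.genes) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(counts.cells) + "\n")
    cells.to_csv(outdir / "cells.tsv", sep="\t")
    genes.to_csv(outdir / "genes.tsv", sep="\t")
    written = {
        "matrix": outdir / "matrix.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "cells": outdir / "cells.tsv",
        "genes": outdir / "genes.tsv",
    }
    if truth is not None:
        (outdir / "truth.json").write_text(truth.to_json())
        written["truth"] = outdir / "truth.json"
        markers = {
            t: SignatureSet(t, tuple(gs), f"{t} marker program")
            for t, gs in truth.config.marker_programs.items()
            if gs
        }
        if markers:
            write_gmt(markers, outdir / "markers.gmt")
            written["markers"] = outdir / "markers.gmt"
    return written


def read_cohort(indir):
    """Read a cohort written by :func:`write_cohort`.

    Returns ``(CountMatrix, CellTable, GeneTable, SimTruth | None)``.
    """
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    features = (indir / "features.tsv").read_text().splitlines()
    barcodes = (indir / "barcodes.tsv").read_text().splitlines()
    counts = CountMatrix(X, features, barcodes)
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
    genes["chromosome"] = genes["chromosome"].astype(str)
    truth = None
    if (indir / "truth.json").exists():
        truth = SimTruth.from_json((indir / "truth.json").read_text())
    return counts, cells, genes, truth
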