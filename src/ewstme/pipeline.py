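"""Config-driven end-to-end pipeline and report generation.

Stages run in the order QC -> normalize -> cluster -> annotate -> CNV ->
signatures/fractions -> interactions -> dysfunction screen -> GSEA.
Every stage writes its outputs as UTF-8 TSV (floats at 6 significant
digits) plus a JSON-lines run log recording parameters, seeds and
warnings, so a run is auditable and restartable from serialized outputs
alone.  The master seed is split into named per-stage substreams:
changing one stage's parameters never perturbs another stage's draws.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnv_mod, gsea as gsea_mod
from ._utils import substream
from .interactions import LRDatabase, count_unique_interactions, default_lr_database, permutation_test
from .preprocess import annotate_clusters, cluster, de_wilcoxon, normalize, qc_filter
from .screen import per_sample_strengths, sample_dysfunction, screen
from .signatures import (
    SignatureSet,
    compare_groups,
    default_signatures,
    dysfunction_score,
    expressing_fraction,
    module_score,
    read_gmt,
)
from .synthetic import read_cohort

_VERSION = "0.1.0"
FLOAT_FMT = "%.6g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All paths and stage parameters of a pipeline run."""

    cohort_dir: str
    out_dir: str
    seed: int = 0
    signatures_gmt: str | None = None  # packaged defaults when None
    markers_gmt: str | None = None  # cohort markers.gmt when None
    lr_db: str | None = None  # packaged defaults when None
    min_genes_per_cell: int = 100
    min_cells_per_sample: int = 20
    norm_method: str = "log1p_cp10k"
    n_pcs: int = 30
    n_neighbors: int = 15
    resolution: float = 1.0
    cnv_window: int = 101
    cnv_clip: float = 3.0
    cnv_threshold_sd: float = 3.0
    reference_compartments: tuple = ("immune", "endothelial")
    fraction_min_cells: int = 5
    fraction_groups: tuple = ("Mo", "Mphi", "cDC")
    n_perm: int = 1000
    kh: float = 0.5
    hill_n: float = 1.0
    screen_source_types: tuple = ("Mo", "Mphi", "cDC")
    screen_target_type: str = "CD8_T"
    rho_threshold: float = 0.5
    screen_method: str = "spearman"
    gsea_weight: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.cohort_dir).is_dir():
            raise FileNotFoundError(f"cohort directory not found: {self.cohort_dir}")
        for key in ("signatures_gmt", "markers_gmt", "lr_db"):
            val = getattr(self, key)
            if val is not None and not Path(val).is_file():
                raise FileNotFoundError(f"{key} not found: {val}")
        if self.resolution <= 0 or self.n_perm < 100:
            raise ValueError("resolution must be > 0 and n_perm >= 100")


def _write(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a dict of output paths.

    A stage failure aborts the run with the stage name and cause;
    partial outputs are retained next to a FAILED marker file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **fields) -> None:
        rec = {"stage": stage, "time": round(time.time(), 2), "version": _VERSION, **fields}
        log_fh.write(json.dumps(rec, default=str) + "\n")
        log_fh.flush()

    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    outputs: dict[str, Path] = {"config": out / "config.yaml", "log": log_path}
    stage = "load"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            counts, cells, genes, truth = read_cohort(config.cohort_dir)
        log(stage, n_genes=counts.shape[0], n_cells=counts.shape[1])

        stage = "qc"
        counts, cells, qc_report = qc_filter(
            counts, cells, config.min_genes_per_cell, config.min_cells_per_sample
        )
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=1))
        outputs["qc_report"] = out / "qc_report.json"
        log(stage, kept_cells=counts.shape[1], removed_cells=len(qc_report["removed_cells"]),
            removed_samples=len(qc_report["removed_samples"]))

        stage = "normalize"
        norm = normalize(counts, method=config.norm_method)
        log(stage, method=config.norm_method)

        stage = "cluster"
        seed_cluster = int(substream(config.seed, "stage:cluster").integers(2**31))
        labels = cluster(
            norm, n_neighbors=config.n_neighbors, resolution=config.resolution,
            n_pcs=config.n_pcs, seed=seed_cluster,
        )
        cells = cells.copy()
        cells["cluster_id"] = labels
        log(stage, seed=seed_cluster, n_clusters=int(labels.nunique()))

        stage = "annotate"
        markers_path = config.markers_gmt or (Path(config.cohort_dir) / "markers.gmt")
        marker_sets = read_gmt(markers_path)
        seed_annot = int(substream(config.seed, "stage:annotate").integers(2**31))
        assignment, score_table = annotate_clusters(norm, labels, marker_sets, seed=seed_annot)
        cells["cell_type"] = labels.map(assignment)
        from .synthetic import COMPARTMENT_OF

        cells["compartment"] = [COMPARTMENT_OF.get(t, "immune") for t in cells["cell_type"]]
        _write(cells, out / "cells_annotated.tsv")
        _write(score_table, out / "cluster_annotation.tsv")
        outputs["cells"] = out / "cells_annotated.tsv"
        log(stage, seed=seed_annot, labels=sorted(cells["cell_type"].unique()))

        stage = "cnv"
        reference = cells.index[cells["compartment"].isin(config.reference_compartments)]
        cnvm = cnv_mod.infer_cnv(
            norm, genes, reference, window_size=config.cnv_window, clip=config.cnv_clip,
            reference_groups=cells.loc[reference, "cell_type"],
        )
        arms = sorted(cnvm.windows["arm"].unique())
        arm_table = cnv_mod.arm_scores(cnvm, arms)
        calls = cnv_mod.call_aberrant(arm_table, reference, config.cnv_threshold_sd)
        _write(arm_table, out / "cnv_arm_scores.tsv")
        _write(calls, out / "cnv_arm_calls.tsv")
        outputs["cnv_calls"] = out / "cnv_arm_calls.tsv"
        log(stage, n_reference=len(reference), arms=len(arms))

        stage = "signatures"
        sigs = read_gmt(config.signatures_gmt) if config.signatures_gmt else default_signatures()
        seed_score = int(substream(config.seed, "stage:signatures").integers(2**31))
        scores = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for name in ("hla_class_i", "antigen_presentation_costim"):
                if name in sigs:
                    scores[name] = module_score(norm, sigs[name], seed=seed_score)
            scores["dysfunction"] = dysfunction_score(
                norm, sigs.get("dysfunction"), seed=seed_score
            )
        score_df = pd.DataFrame(scores)
        _write(score_df, out / "signature_scores.tsv")
        outputs["scores"] = out / "signature_scores.tsv"
        tumor = cells["compartment"] == "tumor"
        hla_p = np.nan
        if "hla_class_i" in score_df and tumor.any() and (~tumor).any():
            comp = compare_groups(
                score_df["hla_class_i"],
                tumor.map({True: "tumor", False: "non-tumor"}),
                test="wilcoxon",
            )
            hla_p = float(comp["p"].iloc[0])
        log(stage, seed=seed_score, hla_tumor_vs_rest_p=hla_p)

        stage = "fractions"
        fractions = expressing_fraction(
            counts, cells, group_by="cell_type", groups=config.fraction_groups,
            min_cells=config.fraction_min_cells,
        )
        _write(fractions, out / "costim_fractions.tsv", index=False)
        outputs["fractions"] = out / "costim_fractions.tsv"
        log(stage, n_rows=len(fractions))

        stage = "interactions"
        lr_db = LRDatabase.from_tsv(config.lr_db) if config.lr_db else default_lr_database()
        seed_perm = int(substream(config.seed, "stage:interactions").integers(2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comm = permutation_test(
                norm, cells, lr_db, n_perm=config.n_perm, seed=seed_perm,
                kh=config.kh, hill_n=config.hill_n,
            )
        _write(comm, out / "communication.tsv", index=False)
        outputs["communication"] = out / "communication.tsv"
        log(stage, seed=seed_perm, n_pairs=len(lr_db))

        stage = "screen"
        strengths = per_sample_strengths(
            norm, cells, lr_db, config.screen_source_types, config.screen_target_type,
            min_cells=config.fraction_min_cells, kh=config.kh, hill_n=config.hill_n,
        )
        dys = sample_dysfunction(
            score_df["dysfunction"], cells, cd8_type=config.screen_target_type,
            min_cells=config.fraction_min_cells,
        )
        screen_result = screen(
            strengths, dys, rho_threshold=config.rho_threshold, method=config.screen_method
        )
        _write(strengths, out / "strengths.tsv")
        _write(screen_result, out / "screen_result.tsv", index=False)
        outputs["screen"] = out / "screen_result.tsv"
        log(stage, n_selected=int(screen_result["selected"].sum()))

        stage = "gsea"
        gsea_rows = []
        if tumor.any() and (~tumor).any():
            de = de_wilcoxon(norm, cells.index[tumor], cells.index[~tumor])
            signed = np.sign(de["mean_diff"]) * -np.log10(np.clip(de["p"], 1e-300, 1.0))
            ranked = gsea_mod.rank_genes(pd.Series(signed.to_numpy(), index=de["gene"]))
            seed_gsea = int(substream(config.seed, "stage:gsea").integers(2**31))
            for name, sig in marker_sets.items():
                try:
                    res = gsea_mod.nes_permutation(
                        ranked, sig, weight=config.gsea_weight, n_perm=config.n_perm,
                        seed=seed_gsea,
                    )
                except ValueError:
                    continue
                gsea_rows.append(
                    {"set": name, "es": res.es, "nes": res.nes, "p": res.p,
                     "leading_edge": ",".join(res.leading_edge)}
                )
        _write(pd.DataFrame(gsea_rows), out / "gsea.tsv", index=False)
        outputs["gsea"] = out / "gsea.tsv"
        log(stage, n_sets=len(gsea_rows))

        stage = "report"
        outputs["report"] = make_report(out)
        log(stage, report=str(outputs["report"]))
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        log_fh.close()
        raise StageError(stage, exc) from exc
    log_fh.close()
    return outputs


def make_report(out_dir) -> Path:
    """Assemble a human-readable summary from a run's serialized outputs."""
    out = Path(out_dir)
    required = {
        "cells": "cells_annotated.tsv",
        "screen": "screen_result.tsv",
        "cnv": "cnv_arm_calls.tsv",
        "fractions": "costim_fractions.tsv",
    }
    missing = [f for f in required.values() if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing stage outputs: {missing}")
    cells = pd.read_csv(out / "cells_annotated.tsv", sep="\t", index_col=0)
    screen_result = pd.read_csv(out / "screen_result.tsv", sep="\t")
    calls = pd.read_csv(out / "cnv_arm_calls.tsv", sep="\t", index_col=0)
    fractions = pd.read_csv(out / "costim_fractions.tsv", sep="\t")

    lines = ["# Cohort analysis report", ""]
    comp = cells.groupby(["sample_id", "cell_type"], observed=True).size().unstack(fill_value=0)
    lines += ["## Cohort composition (cells per sample and type)", "", comp.to_string(), ""]

    lines += ["## CNV arm calls (fraction of cells called gained, by compartment)", ""]
    gains = (calls == "gain").groupby(cells.loc[calls.index, "compartment"]).mean()
    lines += [gains.round(3).to_string(), ""]

    if not fractions.empty:
        frac_summary = fractions.groupby(["group", "gene"])["fraction"].mean().unstack()
        lines += ["## Costimulatory expressing fractions (mean over samples)", "",
                  frac_summary.round(3).to_string(), ""]

    n_sel = int(screen_result["selected"].sum())
    lines += [f"## Dysfunction-correlated interactions: {n_sel} selected", ""]
    if n_sel:
        sel = screen_result[screen_result["selected"]][["pair_id", "rho", "n"]]
        lines += [sel.round(3).to_string(index=False), ""]
    else:
        lines += ["0 selected interactions at the configured threshold.", ""]

    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
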