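"""End-to-end orchestration: inputs -> cascade -> interactome -> report.

The pipeline consumes either the bundled synthetic study (generated in
memory from a seed) or user-supplied files, and runs: differential
expression per disease -> upregulated-gene selection -> screen dropouts ->
surface/blacklist filter -> disease categorization -> per-population ligand
enrichment -> ligand-based exclusion -> interactome assembly -> temporal
classification -> survival prioritization. It emits the receptor ledger,
the edge list, a temporal class table, the prognosis table and a JSON
report whose counts satisfy the ledger conservation identity; identical
configurations produce byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .cascade import ReceptorLedger, run_cascade
from .destats import de_test
from .ligandmap import (
    build_interactome,
    call_enriched,
    edges_to_frame,
    normalize_cells,
    population_markers,
)
from .survival import prioritize
from .synth import SynthConfig, SynthData, default_atlas, default_config, simulate_all
from .temporal import classify_all, population_proportions, stage_tensor

log = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "PipelineConfig",
    "PipelineResult",
    "ligand_calls_from_niche",
    "run_synthetic_once",
    "run_all",
]


@dataclass(frozen=True)
class Thresholds:
    """All tunable decision thresholds of the pipeline."""

    alpha: float = 0.05  # significance level for DE, enrichment, survival
    fold: float = 2.0  # screen dropout fold threshold
    min_lfc: float = 0.0  # ligand enrichment log2FC gate
    min_pct: float = 0.1  # ligand detection fraction gate
    min_cells: int = 10  # smallest population tested per marker call
    theta_expr: float = 0.1  # detection fraction defining "expressed"
    theta_cv: float = 0.5  # CV bound for a steady trajectory
    per_stage_ligands: bool = False  # test ligand enrichment per stage

    def validate(self) -> None:
        for name in ("alpha", "min_pct", "theta_expr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a pipeline run.

    ``mode="synthetic"`` generates all inputs from ``seed``; ``mode="files"``
    reads the documented TSV/MatrixMarket schemas from ``paths`` (keys:
    bulk_bccml, groups_bccml, bulk_aml, groups_aml, screen, atlas,
    blacklist, lr, niche_counts, niche_meta, survival).
    """

    mode: str = "synthetic"
    seed: int = 1
    out_dir: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    paths: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.thresholds.validate()
        if self.mode == "files":
            required = (
                "bulk_bccml", "groups_bccml", "bulk_aml", "groups_aml",
                "screen", "atlas", "blacklist", "lr", "niche_counts",
                "niche_meta",
            )
            missing = [k for k in required if k not in self.paths]
            if missing:
                raise ValueError(f"missing input path(s): {', '.join(missing)}")
            for key, p in self.paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"input path for {key!r} not found: {p}")


@dataclass
class PipelineResult:
    """Everything one run produces."""

    ledger: ReceptorLedger
    edges: list
    calls: list
    temporal_classes: dict
    proportions: pd.DataFrame
    proportion_trends: dict
    prognosis: pd.DataFrame | None
    report: dict
    data: SynthData | None = None


def ligand_calls_from_niche(
    niche_counts: pd.DataFrame,
    niche_meta: pd.DataFrame,
    lr: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> list:
    """Enrichment calls for every interaction-table ligand in the niche panel.

    Stages are pooled by default; with ``per_stage_ligands`` each stage is
    tested separately and BH correction spans all (ligand, population,
    stage) tests of that mode.
    """
    expr = normalize_cells(niche_counts)
    pops = niche_meta["population"].to_numpy()
    ligands = sorted(set(lr["ligand"]) & set(niche_counts.columns))
    if thresholds.per_stage_ligands:
        calls = []
        markers_by_stage = {}
        for stage in pd.unique(niche_meta["stage"]):
            mask = (niche_meta["stage"] == stage).to_numpy()
            sub_expr, sub_pops = expr.loc[mask], pops[mask]
            for lig in ligands:
                for pop, res in population_markers(
                    sub_expr, sub_pops, lig, thresholds.min_cells
                ).items():
                    markers_by_stage[(lig, pop, stage)] = res
        # flatten to (ligand, population)-keyed batches per stage for BH
        for stage in sorted({k[2] for k in markers_by_stage}):
            batch = {
                (l, p): r
                for (l, p, s), r in markers_by_stage.items()
                if s == stage
            }
            calls.extend(
                call_enriched(
                    batch,
                    alpha=thresholds.alpha,
                    min_lfc=thresholds.min_lfc,
                    min_pct=thresholds.min_pct,
                    stage=str(stage),
                )
            )
        return calls
    markers = {}
    for lig in ligands:
        for pop, res in population_markers(
            expr, pops, lig, thresholds.min_cells
        ).items():
            markers[(lig, pop)] = res
    return call_enriched(
        markers,
        alpha=thresholds.alpha,
        min_lfc=thresholds.min_lfc,
        min_pct=thresholds.min_pct,
    )


def _build_report(
    config: PipelineConfig, ledger: ReceptorLedger, edges, classes, trends, prognosis
) -> dict:
    from . import __version__

    report = {
        "provenance": {
            "tool": "nichemapper",
            "version": __version__,
            "seed": config.seed,
            "mode": config.mode,
        },
        "ledger": ledger.counts(),
        "interactome": {
            "n_edges": len(edges),
            "receptors": sorted({e.receptor for e in edges}),
        },
        "temporal_classes": {g: c for g, c in sorted(classes.items())},
        "population_trends": dict(sorted(trends.items())),
    }
    if prognosis is not None:
        report["prognosis"] = {
            "poor_prognosis": sorted(
                prognosis.loc[prognosis["poor_prognosis"], "gene"]
            ),
            "n_tested": int(len(prognosis)),
        }
    return report


def run_synthetic_once(
    synth_config: SynthConfig,
    thresholds: Thresholds = Thresholds(),
    with_survival: bool = True,
    data: SynthData | None = None,
) -> PipelineResult:
    """Run the full analysis on one synthetic dataset.

    ``data`` may carry pre-generated inputs to avoid regeneration; otherwise
    they are simulated from ``synth_config``.
    """
    if data is None:
        data = simulate_all(synth_config)
    de_bc = de_test(*data.bulk["bcCML"])
    de_aml = de_test(*data.bulk["AML"])
    atlas = default_atlas(synth_config)
    calls = ligand_calls_from_niche(
        data.niche_counts, data.niche_meta, data.lr_table, thresholds
    )
    ledger = run_cascade(
        de_bc,
        de_aml,
        data.screen,
        atlas=atlas,
        blacklist=set(synth_config.blacklist_genes),
        lr=data.lr_table,
        calls=calls,
        alpha=thresholds.alpha,
        fold=thresholds.fold,
    )
    edges = build_interactome(ledger, data.lr_table, calls)
    tensor = stage_tensor(data.niche_counts, data.niche_meta, synth_config.stages)
    ligand_genes = [p.gene for p in synth_config.planted_ligands]
    classes = classify_all(
        tensor,
        genes=ligand_genes,
        theta_expr=thresholds.theta_expr,
        theta_cv=thresholds.theta_cv,
    )
    props, trends = population_proportions(data.niche_meta, synth_config.stages)
    prognosis = (
        prioritize(data.survival, alpha=thresholds.alpha) if with_survival else None
    )
    config = PipelineConfig(mode="synthetic", seed=synth_config.seed, thresholds=thresholds)
    report = _build_report(config, ledger, edges, classes, trends, prognosis)
    return PipelineResult(
        ledger=ledger,
        edges=edges,
        calls=calls,
        temporal_classes=classes,
        proportions=props,
        proportion_trends=trends,
        prognosis=prognosis,
        report=report,
        data=data,
    )


def _run_from_files(config: PipelineConfig) -> PipelineResult:
    paths = config.paths
    th = config.thresholds
    counts_bc = nio.read_counts(paths["bulk_bccml"])
    counts_aml = nio.read_counts(paths["bulk_aml"])
    groups_bc = pd.read_csv(paths["groups_bccml"], sep="\t")["group"].to_numpy()
    groups_aml = pd.read_csv(paths["groups_aml"], sep="\t")["group"].to_numpy()
    de_bc = de_test(counts_bc, groups_bc, disease_label="disease")
    de_aml = de_test(counts_aml, groups_aml, disease_label="disease")
    screen = nio.read_table(paths["screen"], "screen")
    atlas = set(nio.read_gene_list(paths["atlas"]))
    blacklist = set(nio.read_gene_list(paths["blacklist"]))
    lr = nio.read_table(paths["lr"], "lr")
    fmt = "mtx" if str(paths["niche_counts"]).endswith(".mtx") else "tsv"
    niche = nio.read_counts(paths["niche_counts"], fmt=fmt)
    meta = nio.read_table(paths["niche_meta"], "cell_meta").set_index(
        "cell_id", drop=False
    )
    niche = niche.T  # genes x cells on disk -> cells x genes in memory
    niche = niche.loc[meta.index]
    calls = ligand_calls_from_niche(niche, meta, lr, th)
    ledger = run_cascade(
        de_bc, de_aml, screen, atlas, blacklist, lr, calls,
        alpha=th.alpha, fold=th.fold,
    )
    edges = build_interactome(ledger, lr, calls)
    tensor = stage_tensor(niche, meta)
    ligand_genes = sorted(set(lr["ligand"]) & set(niche.columns))
    classes = classify_all(
        tensor, genes=ligand_genes, theta_expr=th.theta_expr, theta_cv=th.theta_cv
    )
    props, trends = population_proportions(meta)
    prognosis = None
    if "survival" in paths:
        surv = nio.read_table(paths["survival"], "survival")
        if "gene" not in surv.columns:
            raise ValueError("survival table needs a 'gene' column")
        prognosis = prioritize(surv, alpha=th.alpha)
    report = _build_report(config, ledger, edges, classes, trends, prognosis)
    return PipelineResult(
        ledger=ledger,
        edges=edges,
        calls=calls,
        temporal_classes=classes,
        proportions=props,
        proportion_trends=trends,
        prognosis=prognosis,
        report=report,
    )


def run_all(config: PipelineConfig) -> PipelineResult:
    """Validate the configuration, run the pipeline, write outputs.

    Output files (when ``out_dir`` is set): ledger.tsv, edges.tsv,
    temporal_classes.tsv, prognosis.tsv and report.json.
    """
    config.validate()
    if config.mode == "synthetic":
        result = run_synthetic_once(
            default_config(seed=config.seed), thresholds=config.thresholds
        )
    else:
        result = _run_from_files(config)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.ledger.to_tsv(out / "ledger.tsv")
        frame = edges_to_frame(result.edges)
        frame["weight"] = frame["weight"].map(nio.format_sig)
        frame.to_csv(out / "edges.tsv", sep="\t", index=False)
        pd.Series(result.temporal_classes, name="temporal_class").rename_axis(
            "gene"
        ).to_csv(out / "temporal_classes.tsv", sep="\t")
        if result.prognosis is not None:
            prog = result.prognosis.copy()
            for c in ("cutoff", "chi2", "p", "padj", "hr", "hr_lo", "hr_hi"):
                prog[c] = prog[c].map(nio.format_sig)
            prog.to_csv(out / "prognosis.tsv", sep="\t", index=False)
        nio.write_report_json(result.report, out / "report.json")
    return result
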