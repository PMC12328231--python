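"""Per-population ligand enrichment and receptor-ligand interactome assembly.

Candidate ligands are tested one-vs-rest per niche population with the
rank-sum test on library-size-normalized expression; significant calls
(BH-adjusted p below alpha, positive fold-change, minimum detection
fraction) become the ligand side of the interactome. Edges join cascade
survivor receptors to their enriched ligands, weighted by the capped log2
fold-change used for circos-style export.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .destats import RankSumResult, bh_adjust, rank_sum

log = logging.getLogger(__name__)

__all__ = [
    "LOG2FC_CAP",
    "LigandCall",
    "InteractomeEdge",
    "normalize_cells",
    "population_markers",
    "call_enriched",
    "build_interactome",
    "edges_to_frame",
]

# Export cap: ligand fold-changes of 5 or higher are limited to 5.
LOG2FC_CAP = 5.0


@dataclass(frozen=True)
class LigandCall:
    """One (ligand, population) enrichment decision.

    ``stage`` is "pooled" when stages were pooled for testing. ``passed``
    records whether the call clears all enrichment gates.
    """

    ligand: str
    population: str
    stage: str
    log2fc: float
    log2fc_capped: float
    p: float
    padj: float
    pct_in: float
    pct_out: float
    passed: bool


@dataclass(frozen=True)
class InteractomeEdge:
    """Receptor-ligand edge with the populations supplying the ligand."""

    receptor: str
    ligand: str
    populations: tuple
    weight: float  # max capped log2fc over supplying populations


def normalize_cells(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalization of a cell x gene matrix: per-cell counts
    scaled to ``scale`` then log1p-transformed. Cells with zero totals error.
    """
    totals = counts.sum(axis=1)
    bad = totals[totals <= 0]
    if len(bad) > 0:
        raise ValueError(
            f"zero-total cell(s), cannot normalize: {', '.join(map(str, bad.index[:5]))}"
        )
    return np.log1p(counts.div(totals, axis=0) * scale)


def population_markers(
    expr: pd.DataFrame,
    populations,
    gene: str,
    min_cells: int = 10,
) -> dict:
    """One-vs-rest rank-sum marker test of ``gene`` for every population.

    ``expr`` is a normalized cell x gene matrix; ``populations`` labels each
    cell (row). Populations with fewer than ``min_cells`` cells are skipped
    with a warning. Returns {population: RankSumResult}.
    """
    populations = np.asarray(populations)
    if populations.size != expr.shape[0]:
        raise ValueError("populations must label every cell (row)")
    levels = pd.unique(populations)
    if len(levels) < 2:
        raise ValueError("need at least two populations for one-vs-rest testing")
    if gene not in expr.columns:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    values = expr[gene].to_numpy()
    out = {}
    for pop in levels:
        mask = populations == pop
        if mask.sum() < min_cells:
            warnings.warn(
                f"population {pop} has {int(mask.sum())} cells (< {min_cells}); skipped"
            )
            continue
        out[pop] = rank_sum(values[mask], values[~mask])
    return out


def call_enriched(
    markers: dict,
    alpha: float = 0.05,
    min_lfc: float = 0.0,
    min_pct: float = 0.1,
    stage: str = "pooled",
) -> list:
    """Turn marker results into enrichment calls with BH correction.

    ``markers`` maps (ligand, population) -> RankSumResult. BH adjustment is
    applied across all tests jointly. A call passes iff padj < alpha and
    log2fc > min_lfc and pct_in >= min_pct. Fold-changes are capped at
    ``LOG2FC_CAP`` into ``log2fc_capped`` for export.
    """
    keys = sorted(markers)
    if not keys:
        return []
    pvals = np.array([markers[k].p for k in keys])
    padj = bh_adjust(pvals)
    calls = []
    for (ligand, population), p, q in zip(keys, pvals, padj):
        r: RankSumResult = markers[(ligand, population)]
        passed = bool(q < alpha and r.log2fc > min_lfc and r.pct_in >= min_pct)
        calls.append(
            LigandCall(
                ligand=ligand,
                population=population,
                stage=stage,
                log2fc=r.log2fc,
                log2fc_capped=min(r.log2fc, LOG2FC_CAP),
                p=float(p),
                padj=float(q),
                pct_in=r.pct_in,
                pct_out=r.pct_out,
                passed=passed,
            )
        )
    return calls


def build_interactome(ledger, lr: pd.DataFrame, calls) -> list:
    """Assemble receptor-ligand edges for cascade survivors.

    One edge per (surviving receptor, ligand) linked by the interaction
    table where the ligand has at least one passing call; ``populations``
    collects every population with a passing call for that ligand, and the
    edge weight is the maximum capped log2fc over those populations. Output
    is deterministically sorted by (receptor, ligand).
    """
    survivors = set(ledger.survivors)
    passing = {}
    for c in calls:
        if c.passed:
            passing.setdefault(c.ligand, []).append(c)
    edges = []
    seen = set()
    for row in lr.sort_values(["receptor", "ligand"]).itertuples(index=False):
        if row.receptor not in survivors:
            continue
        if (row.receptor, row.ligand) in seen:
            continue
        pops = passing.get(row.ligand)
        if not pops:
            continue
        seen.add((row.receptor, row.ligand))
        edges.append(
            InteractomeEdge(
                receptor=row.receptor,
                ligand=row.ligand,
                populations=tuple(sorted(c.population for c in pops)),
                weight=max(c.log2fc_capped for c in pops),
            )
        )
    edges.sort(key=lambda e: (e.receptor, e.ligand))
    log.info("interactome: %d edges for %d survivors", len(edges), len(survivors))
    return edges


def edges_to_frame(edges) -> pd.DataFrame:
    """Edge list as a TSV-ready DataFrame (populations ';'-joined)."""
    return pd.DataFrame(
        {
            "receptor": [e.receptor for e in edges],
            "ligand": [e.ligand for e in edges],
            "populations": [";".join(e.populations) for e in edges],
            "weight": [e.weight for e in edges],
        }
    )
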