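"""Stage-resolved expression summaries and temporal ligand classification.

The niche is sampled at four ordered disease stages (naive, initiation,
expansion, end). A :class:`StageTensor` holds mean normalized expression and
detection fractions per (gene, population, stage). Ligand trajectories are
classified into four temporal classes:

* ``steady`` - one population expresses the gene at every stage with a flat
  trajectory;
* ``lost`` - expressed at the naive stage but in no population at the end;
* ``transient`` - absent at naive, present at an interior stage, absent at
  the end (up-then-down);
* ``population_shift`` - expressed at every stage, but the dominant
  expressing population changes.

"Expressed" means detection fraction at or above a threshold; the class
rules are checked in the order lost, transient, population_shift, steady,
first match wins, with ``unclassified`` as fallback.

The module also provides correlation-based hierarchical clustering of
stage trajectories (degPatterns-style) and population-proportion dynamics
with monotone-trend tagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .ligandmap import normalize_cells

__all__ = [
    "StageTensor",
    "stage_tensor",
    "classify_trajectory",
    "classify_all",
    "TrajectoryClusters",
    "cluster_trajectories",
    "population_proportions",
]

TEMPORAL_LABELS = ("steady", "lost", "transient", "population_shift", "unclassified")


@dataclass
class StageTensor:
    """Mean expression and detection per (gene, population, stage)."""

    genes: list
    populations: list
    stages: tuple
    mean: np.ndarray  # gene x population x stage
    detection: np.ndarray  # same shape, fraction of cells with count > 0

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in tensor") from None

    def trajectory(self, gene: str, population: str) -> np.ndarray:
        gi = self.gene_index(gene)
        pi = self.populations.index(population)
        return self.mean[gi, pi, :]


def stage_tensor(
    counts: pd.DataFrame, meta: pd.DataFrame, stages=None, normalize: bool = True
) -> StageTensor:
    """Group-mean tensor from a cell x gene count matrix and cell metadata.

    ``meta`` must carry ``population`` and ``stage`` columns indexed like the
    rows of ``counts``. All four stages must be present; detection fractions
    are computed on raw counts (count > 0), means on normalized expression.
    """
    for col in ("population", "stage"):
        if col not in meta.columns:
            raise ValueError(f"metadata misses required column {col!r}")
    if not counts.index.equals(meta.index):
        meta = meta.loc[counts.index]
    if stages is None:
        stages = ("naive", "initiation", "expansion", "end")
    missing = [s for s in stages if s not in set(meta["stage"])]
    if missing:
        raise ValueError(f"missing stage(s) in metadata: {', '.join(missing)}")
    populations = sorted(meta["population"].unique())
    genes = list(counts.columns)
    expr = normalize_cells(counts) if normalize else counts
    mean = np.zeros((len(genes), len(populations), len(stages)))
    det = np.zeros_like(mean)
    for pi, pop in enumerate(populations):
        for si, st in enumerate(stages):
            mask = ((meta["population"] == pop) & (meta["stage"] == st)).to_numpy()
            if mask.sum() == 0:
                continue
            mean[:, pi, si] = expr.loc[mask].mean(axis=0).to_numpy()
            det[:, pi, si] = (counts.loc[mask] > 0).mean(axis=0).to_numpy()
    return StageTensor(
        genes=genes,
        populations=populations,
        stages=tuple(stages),
        mean=mean,
        detection=det,
    )


def classify_trajectory(
    tensor: StageTensor,
    gene: str,
    theta_expr: float = 0.1,
    theta_cv: float = 0.5,
) -> str:
    """Assign one temporal class to ``gene``.

    ``theta_expr`` is the detection fraction above which a (population,
    stage) group counts as expressing the gene; ``theta_cv`` bounds the
    coefficient of variation of a steady trajectory. Argmax ties between
    populations are broken lexicographically (populations are stored
    sorted), so permuting input population order cannot change the label.
    """
    gi = tensor.gene_index(gene)
    expressed = tensor.detection[gi] >= theta_expr  # population x stage
    any_stage = expressed.any(axis=0)  # per stage

    # lost: expressed at naive, nothing anywhere at the end
    if any_stage[0] and not any_stage[3]:
        return "lost"
    # transient: absent at naive, present at an interior stage, absent at end
    if not any_stage[0] and (any_stage[1] or any_stage[2]) and not any_stage[3]:
        return "transient"
    # population_shift: expressed at every stage but the dominant population moves
    if any_stage.all():
        argmax_pop = tensor.mean[gi].argmax(axis=0)  # lexicographic tie-break
        if len(set(argmax_pop.tolist())) > 1:
            return "population_shift"
        # steady: some population expressed at all stages with a flat trajectory
        for pi in range(len(tensor.populations)):
            if expressed[pi].all():
                traj = tensor.mean[gi, pi, :]
                m = traj.mean()
                if m > 0 and traj.std() / m < theta_cv:
                    return "steady"
    return "unclassified"


def classify_all(tensor: StageTensor, genes=None, **kwargs) -> dict:
    """Classify several genes; returns {gene: label}."""
    if genes is None:
        genes = tensor.genes
    return {g: classify_trajectory(tensor, g, **kwargs) for g in genes}


@dataclass
class TrajectoryClusters:
    """Result of degPatterns-style trajectory clustering in one population."""

    labels: dict  # gene -> cluster id (int) or "flat"
    consensus: dict = field(default_factory=dict)  # cluster id -> z-trajectory
    trend: dict = field(default_factory=dict)  # cluster id -> tag


def _monotone_tag(traj: np.ndarray, min_rho: float = 0.8) -> str:
    rho = stats.spearmanr(np.arange(traj.size), traj).statistic
    if np.isnan(rho):
        return "other"
    if rho >= min_rho:
        return "increasing"
    if rho <= -min_rho:
        return "decreasing"
    return "other"


def cluster_trajectories(
    tensor: StageTensor,
    population: str,
    k: int | None = None,
    height: float | None = None,
    genes=None,
) -> TrajectoryClusters:
    """Average-linkage hierarchical clustering of stage trajectories.

    Per-gene trajectories in ``population`` are z-scored across stages;
    distance is 1 - Pearson correlation; the dendrogram is cut at ``k``
    clusters or at correlation-distance ``height``. Zero-variance genes go
    to a dedicated "flat" cluster and are excluded from the correlation
    clustering. Each cluster gets a consensus (mean z) trajectory and a
    monotone-direction tag (increasing / decreasing / other).
    """
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    if population not in tensor.populations:
        raise ValueError(f"unknown population {population!r}")
    pi = tensor.populations.index(population)
    if genes is None:
        genes = tensor.genes
    trajs = {g: tensor.mean[tensor.gene_index(g), pi, :] for g in genes}
    flat = [g for g, t in trajs.items() if np.std(t) == 0]
    variable = [g for g in genes if g not in set(flat)]
    labels = {g: "flat" for g in flat}
    if len(variable) < 2:
        raise ValueError("need at least 2 genes with nonzero variance")
    z = np.vstack(
        [(trajs[g] - trajs[g].mean()) / trajs[g].std() for g in variable]
    )
    corr = np.corrcoef(z)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if k is not None:
        assign = hierarchy.fcluster(link, t=k, criterion="maxclust")
    else:
        assign = hierarchy.fcluster(link, t=height, criterion="distance")
    consensus, trend = {}, {}
    for g, c in zip(variable, assign):
        labels[g] = int(c)
    for c in sorted(set(assign.tolist())):
        members = [i for i, a in enumerate(assign) if a == c]
        cz = z[members].mean(axis=0)
        consensus[int(c)] = cz
        trend[int(c)] = _monotone_tag(cz)
    return TrajectoryClusters(labels=labels, consensus=consensus, trend=trend)


def population_proportions(meta: pd.DataFrame, stages=None, min_rho: float = 0.8):
    """Per-stage population fractions plus a monotone-trend tag.

    Returns (proportions DataFrame population x stage, {population: tag})
    where the tag is "increasing"/"decreasing" when the Spearman correlation
    between stage index and proportion reaches ``min_rho`` in magnitude
    (with four stages only near-perfect monotonicity qualifies), else
    "untagged".
    """
    if stages is None:
        stages = ("naive", "initiation", "expansion", "end")
    missing = [s for s in stages if s not in set(meta["stage"])]
    if missing:
        raise ValueError(f"missing stage(s): {', '.join(missing)}")
    tab = (
        meta.groupby(["stage", "population"]).size().unstack(fill_value=0)
    ).T  # population x stage
    tab = tab[list(stages)]
    props = tab / tab.sum(axis=0)
    tags = {}
    x = np.arange(len(stages))
    for pop in props.index:
        y = props.loc[pop].to_numpy()
        if np.std(y) == 0:
            tags[pop] = "untagged"
            continue
        rho = stats.spearmanr(x, y).statistic
        if rho >= min_rho:
            tags[pop] = "increasing"
        elif rho <= -min_rho:
            tags[pop] = "decreasing"
        else:
            tags[pop] = "untagged"
    return props, tags
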