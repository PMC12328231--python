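"""Replicate-based evaluation of the pipeline against planted ground truth.

Each function here reruns the relevant part of the pipeline on freshly
generated synthetic data and scores it against the truth ledger: planted
receptor/edge recovery and decoy leakage, temporal-class accuracy,
prognostic-flag exactness, type-I error calibration of the differential
expression and log-rank tests, and median-effect fit recovery. All
randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .destats import de_test
from .pipeline import Thresholds, run_synthetic_once
from .survival import logrank, median_split, prioritize
from .synergy import combination_index, median_effect_fit
from .synth import (
    SurvivalSpec,
    default_config,
    simulate_bulk,
    simulate_niche,
    simulate_survival,
)
from .temporal import classify_all, stage_tensor

__all__ = [
    "edge_recovery",
    "temporal_accuracy",
    "prognostic_exactness",
    "de_type1_rate",
    "logrank_type1_rate",
    "sham_combination_index",
    "median_effect_recovery",
]


def _child_seeds(seed: int, n: int) -> list:
    """n reproducible sub-seeds below 2**31 derived from one root seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(1, 2**31 - 1, size=n)]


def edge_recovery(n_reps: int = 200, seed: int = 1, thresholds=Thresholds()):
    """Planted-axis recovery and decoy leakage of the interactome.

    Runs the full cascade + interactome on ``n_reps`` synthetic replicates.
    Returns (mean fraction of planted ligand-receptor pairs recovered as
    edges, mean number of decoy edges per replicate).
    """
    recovered, decoys = [], []
    for s in _child_seeds(seed, n_reps):
        cfg = default_config(seed=s)
        res = run_synthetic_once(cfg, thresholds=thresholds, with_survival=False)
        planted = {(l, r) for l, r in res.data.truth["lr"]["planted_pairs"]}
        got = {(e.ligand, e.receptor) for e in res.edges}
        recovered.append(len(planted & got) / len(planted))
        decoys.append(len(got - planted))
    return float(np.mean(recovered)), float(np.mean(decoys))


def temporal_accuracy(n_reps: int = 50, seed: int = 1, thresholds=Thresholds()):
    """Mean fraction of planted ligands assigned their planted temporal class."""
    acc = []
    for s in _child_seeds(seed, n_reps):
        cfg = default_config(seed=s)
        counts, meta = simulate_niche(cfg)
        tensor = stage_tensor(counts, meta, cfg.stages)
        truth = {p.gene: p.temporal_class for p in cfg.planted_ligands}
        classes = classify_all(
            tensor,
            genes=list(truth),
            theta_expr=thresholds.theta_expr,
            theta_cv=thresholds.theta_cv,
        )
        hits = sum(classes[g] == c for g, c in truth.items())
        acc.append(hits / len(truth))
    return float(np.mean(acc))


def prognostic_exactness(n_reps: int = 100, seed: int = 1, alpha: float = 0.05):
    """Fraction of replicates flagging exactly the planted prognostic genes."""
    exact = []
    for s in _child_seeds(seed, n_reps):
        cfg = default_config(seed=s)
        surv = simulate_survival(cfg)
        truth = {g for g, b in cfg.survival.betas.items() if b != 0}
        prog = prioritize(surv, alpha=alpha)
        flagged = set(prog.loc[prog["poor_prognosis"], "gene"])
        exact.append(flagged == truth)
    return float(np.mean(exact))


def de_type1_rate(seed: int = 1, n_genes: int = 2000, alpha: float = 0.05):
    """Null DE rejection rate: no planted effects, raw p < alpha per gene."""
    cfg = default_config(seed=seed)
    cfg = replace_null(cfg, n_genes=n_genes)
    bulk = simulate_bulk(cfg)
    counts, groups = bulk["bcCML"]
    de = de_test(counts, groups)
    return float((de["p"] < alpha).mean())


def replace_null(cfg, n_genes: int | None = None):
    """Strip every planted effect from a config (null study conditions)."""
    kwargs = dict(
        planted_receptors=[],
        dropout_genes=[],
        planted_ligands=[],
        lr_pairs=[],
        ligandless_receptors=[],
        blacklist_genes=[],
    )
    if n_genes is not None:
        kwargs["n_genes"] = n_genes
    if cfg.survival is not None:
        kwargs["survival"] = SurvivalSpec(
            genes=cfg.survival.genes,
            betas={},
            n_patients=cfg.survival.n_patients,
        )
    return replace(cfg, **kwargs)


def logrank_type1_rate(
    n_reps: int = 2000, n: int = 200, seed: int = 1, alpha: float = 0.05
):
    """Null log-rank rejection rate over median-split exponential cohorts."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        expr = rng.normal(10.0, 2.0, size=n)
        t_event = rng.exponential(10.0, size=n)
        t_cens = rng.uniform(0.0, 30.0, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        _, low, high = median_split(expr)
        _, p = logrank(time[high], event[high], time[low], event[low])
        rejections += p < alpha
    return rejections / n_reps


def sham_combination_index(m: float = 2.0, dm: float = 1.0):
    """Loewe-additivity identity: a drug combined 50/50 with itself has CI = 1.

    The full dose D produces fa(D) from the drug's own median-effect curve;
    crediting each half dose against that same curve must sum to exactly 1.
    """
    doses = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    fa = (doses / dm) ** m / (1.0 + (doses / dm) ** m)
    fit = median_effect_fit(doses, fa)
    combos = [(d / 2, d / 2, f) for d, f in zip(doses, fa)]
    res = combination_index(fit, fit, combos)
    return float(np.mean([c.ci for c in res]))


def median_effect_recovery(
    noise_sd: float = 0.05, n_seeds: int = 100, seed: int = 1,
    m: float = 2.0, dm: float = 1.0,
):
    """Median relative error of (m, Dm) under gaussian noise on the line.

    Noise of ``noise_sd`` is added to the linearized response
    log10(fa/(1-fa)); returns (median |m_hat - m| / m, median
    |Dm_hat - Dm| / Dm) over ``n_seeds`` replicates.
    """
    doses = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    y_true = m * np.log10(doses / dm)
    m_err, dm_err = [], []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        y = y_true + rng.normal(0.0, noise_sd, size=doses.size)
        fa = 10.0**y / (1 + 10.0**y)
        fit = median_effect_fit(doses, fa)
        m_err.append(abs(fit.m - m) / m)
        dm_err.append(abs(fit.dm - dm) / dm)
    return float(np.median(m_err)), float(np.median(dm_err))
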