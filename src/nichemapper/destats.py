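"""Shared statistical kernel.

Two-group differential expression on bulk counts, Wilcoxon/Mann-Whitney
rank-sum testing (exact by enumeration for small samples), Benjamini-Hochberg
FDR adjustment, and hypergeometric over-representation analysis. These are the
primitives every downstream stage (receptor cascade, ligand enrichment,
trajectory annotation) is built on.

The differential-expression model is deliberately simple and transparent: a
Welch t-test on log2(CPM + 1) with a pseudocounted fold-change, adequate for
recovering planted effects in negative-binomial counts and fully checkable
against hand arithmetic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEResult",
    "RankSumResult",
    "cpm_normalize",
    "log_cpm",
    "de_test",
    "bh_adjust",
    "rank_sum",
    "hypergeom_ora",
]

# Exact rank-sum enumeration is used up to this combined sample size.
EXACT_RANKSUM_MAX_N = 10


@dataclass(frozen=True)
class DEResult:
    """Per-gene two-group differential expression result."""

    gene: str
    log2fc: float
    p: float
    padj: float


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney rank-sum comparison of one group against another.

    ``statistic`` is the U statistic of the first group (x); ``pct_in`` and
    ``pct_out`` are the fractions of nonzero observations in x and y, the
    common single-cell detection convention.
    """

    statistic: float
    p: float
    log2fc: float
    pct_in: float
    pct_out: float


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million column normalization of a gene x sample matrix.

    Raises
    ------
    ValueError
        If any sample (column) has a zero total count; the offending sample
        is named in the message.
    """
    totals = counts.sum(axis=0)
    bad = totals[totals <= 0]
    if len(bad) > 0:
        raise ValueError(
            f"zero-total sample(s), cannot normalize: {', '.join(map(str, bad.index))}"
        )
    return counts * 1e6 / totals


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) transform used by the DE test."""
    return np.log2(cpm_normalize(counts) + 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns adjusted p-values in the input order:
    padj_(i) = min_{j >= i}( p_(j) * m / j ), capped at 1. Ties are handled
    by a stable sort so equal p-values get equal adjusted values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_test(counts: pd.DataFrame, groups, disease_label=None) -> pd.DataFrame:
    """Two-group differential expression on a gene x sample count matrix.

    Welch t-test per gene on log2(CPM + 1), with
    log2fc = log2((mean_cpm_disease + 0.5) / (mean_cpm_control + 0.5)).
    The second factor level (or ``disease_label``) is treated as the disease
    group; positive log2fc means higher in disease.

    Returns a DataFrame with columns gene, log2fc, p, padj (BH-adjusted).
    """
    groups = np.asarray(groups)
    if groups.size != counts.shape[1]:
        raise ValueError("groups must label every sample column")
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"expected exactly two group levels, got {list(levels)}")
    if disease_label is None:
        disease_label = levels[1]
    control_label = [l for l in levels if l != disease_label][0]
    mask_d = groups == disease_label
    mask_c = groups == control_label
    if mask_d.sum() < 2 or mask_c.sum() < 2:
        raise ValueError("each group needs at least 2 samples (variance undefined)")

    cpm = cpm_normalize(counts)
    logc = np.log2(cpm + 1.0)
    xd = logc.loc[:, mask_d].to_numpy()
    xc = logc.loc[:, mask_c].to_numpy()
    t, p = stats.ttest_ind(xd, xc, axis=1, equal_var=False)
    # Degenerate rows (zero variance in both groups, equal means) give nan; the
    # comparison is uninformative there, report p = 1.
    p = np.where(np.isnan(p), 1.0, p)
    mean_d = cpm.loc[:, mask_d].mean(axis=1).to_numpy()
    mean_c = cpm.loc[:, mask_c].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_d + 0.5) / (mean_c + 0.5))
    return pd.DataFrame(
        {
            "gene": counts.index,
            "log2fc": log2fc,
            "p": p,
            "padj": bh_adjust(p),
        }
    ).set_index("gene", drop=False)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mid-rank U statistic of x against y."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[: x.size].sum()
    return r1 - x.size * (x.size + 1) / 2.0


def rank_sum(x, y, pseudocount: float = 0.5) -> RankSumResult:
    """Two-sided Mann-Whitney rank-sum test with mid-rank ties.

    Exact p by permutation enumeration when n1 + n2 <= 10 (two-sided defined
    as the probability of a U at least as far from its null mean n1*n2/2 as
    observed); otherwise the normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum requires both samples to be nonempty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    if n1 + n2 <= EXACT_RANKSUM_MAX_N:
        combined = np.concatenate([x, y])
        mu = n1 * n2 / 2.0
        d_obs = abs(u - mu)
        hits = 0
        total = 0
        idx = np.arange(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(comb)] = True
            u_perm = _u_statistic(combined[sel], combined[~sel])
            # tolerance guards float midranks
            if abs(u_perm - mu) >= d_obs - 1e-9:
                hits += 1
            total += 1
        p = hits / total
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
    mean_x, mean_y = x.mean(), y.mean()
    log2fc = float(np.log2((mean_x + pseudocount) / (mean_y + pseudocount)))
    return RankSumResult(
        statistic=float(u),
        p=float(min(p, 1.0)),
        log2fc=log2fc,
        pct_in=float(np.mean(x > 0)),
        pct_out=float(np.mean(y > 0)),
    )


def hypergeom_ora(query, geneset, universe):
    """Upper-tail hypergeometric over-representation of ``query`` in ``geneset``.

    Returns (overlap count, p, enrichment ratio) with
    p = P(X >= overlap) for X ~ Hypergeom(|universe|, |geneset|, |query|).
    The test is symmetric in (query, geneset).
    """
    query = set(query)
    geneset = set(geneset)
    universe = set(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(f"query genes not in universe: {', '.join(offenders)}")
    offenders = sorted(geneset - universe)
    if offenders:
        raise ValueError(f"gene-set genes not in universe: {', '.join(offenders)}")
    M, K, N = len(universe), len(geneset), len(query)
    k = len(query & geneset)
    p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K and N else 1.0
    expected = K * N / M if M else 0.0
    ratio = (k / expected) if expected > 0 else float("nan")
    return k, min(p, 1.0), ratio
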