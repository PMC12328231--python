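"""Expression-stratified survival analysis and receptor prioritization.

Patients are split at the sample median of a gene's expression (ties go to
the high group, matching a <cutoff / >=cutoff convention); the two strata
are compared with the Kaplan-Meier estimator and the log-rank test, and the
hazard ratio is estimated by the Pike O/E ratio with a log-scale Wald
confidence interval. Receptors are ranked by log-rank p and flagged as
poor-prognosis when significantly associated with shorter survival in the
high-expression group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .destats import bh_adjust

__all__ = [
    "KaplanMeier",
    "StratifiedResult",
    "median_split",
    "km_estimate",
    "logrank",
    "hazard_ratio",
    "stratify",
    "prioritize",
]


@dataclass(frozen=True)
class KaplanMeier:
    """Product-limit survival estimate: step function over event times."""

    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    survival: np.ndarray  # S(t) just after each event time

    def __call__(self, t) -> np.ndarray | float:
        """S(t); right-continuous, S = 1 before the first event."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StratifiedResult:
    """Median-split survival comparison for one gene."""

    gene: str
    cutoff: float
    n_low: int
    n_high: int
    chi2: float
    p: float
    hr: float
    hr_ci: tuple


def median_split(expression):
    """Split subjects at the sample median of expression.

    Returns (cutoff, low_mask, high_mask): low is strictly below the median,
    high is at or above it (ties at the cutoff fall in the high group).
    Raises on fewer than 2 subjects or an all-identical vector.
    """
    x = np.asarray(expression, dtype=float)
    if x.size < 2:
        raise ValueError("median_split needs at least 2 subjects")
    if np.all(x == x[0]):
        raise ValueError("all expression values identical: degenerate split")
    cutoff = float(np.median(x))
    low = x < cutoff
    high = ~low
    if low.sum() == 0 or high.sum() == 0:
        raise ValueError("degenerate split: one stratum is empty")
    return cutoff, low, high


def km_estimate(times, events) -> KaplanMeier:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i;
    censored subjects leave the risk set after their recorded time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    distinct = np.unique(t[e == 1])
    surv = []
    s = 1.0
    for ti in distinct:
        n_at_risk = np.sum(t >= ti)
        d = np.sum((t == ti) & (e == 1))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return KaplanMeier(event_times=distinct, survival=np.asarray(surv))


def _risk_counts(t1, e1, t2, e2):
    """Per-distinct-event-time (n1, n2, d1, d2) accumulation."""
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    times = np.unique(all_t[all_e == 1])
    for ti in times:
        n1 = np.sum(t1 >= ti)
        n2 = np.sum(t2 >= ti)
        d1 = np.sum((t1 == ti) & (e1 == 1))
        d2 = np.sum((t2 == ti) & (e2 == 1))
        yield ti, n1, n2, d1, d2


def _oe_terms(t1, e1, t2, e2):
    """Observed/expected events and hypergeometric variance for group 1."""
    o1 = e1_exp = o2 = e2_exp = v = 0.0
    for _, n1, n2, d1, d2 in _risk_counts(t1, e1, t2, e2):
        n = n1 + n2
        d = d1 + d2
        o1 += d1
        o2 += d2
        e1_exp += d * n1 / n
        e2_exp += d * n2 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o1, e1_exp, o2, e2_exp, v


def _as_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty group in survival comparison")
    return t, e


def logrank(times1, events1, times2, events2):
    """Two-group log-rank test; returns (chi2, p).

    chi2 = (O1 - E1)^2 / V with the standard hypergeometric variance,
    skipping times where only one subject remains at risk. V = 0 with
    O1 = E1 yields chi2 = 0 (p = 1); V = 0 with O1 != E1 is an error.
    """
    t1, e1 = _as_arrays(times1, events1)
    t2, e2 = _as_arrays(times2, events2)
    o1, e1_exp, _, _, v = _oe_terms(t1, e1, t2, e2)
    if v == 0:
        if abs(o1 - e1_exp) < 1e-12:
            return 0.0, 1.0
        raise ValueError("log-rank variance is zero but O1 != E1")
    chi2 = (o1 - e1_exp) ** 2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def hazard_ratio(times1, events1, times2, events2):
    """Pike O/E hazard ratio of group 1 vs group 2 with a 95% CI.

    hr = (O1/E1) / (O2/E2); CI = exp(log hr +/- 1.96 sqrt(1/E1 + 1/E2)).
    Requires at least one event in each group.
    """
    t1, e1 = _as_arrays(times1, events1)
    t2, e2 = _as_arrays(times2, events2)
    if e1.sum() == 0 or e2.sum() == 0:
        raise ValueError("hazard_ratio requires >= 1 event per group")
    o1, e1_exp, o2, e2_exp, _ = _oe_terms(t1, e1, t2, e2)
    if e1_exp == 0 or e2_exp == 0:
        raise ValueError("zero expected events in one group")
    hr = (o1 / e1_exp) / (o2 / e2_exp)
    se = np.sqrt(1.0 / e1_exp + 1.0 / e2_exp)
    ci = (float(hr * np.exp(-1.959963984540054 * se)),
          float(hr * np.exp(1.959963984540054 * se)))
    return float(hr), ci


def stratify(table: pd.DataFrame, gene: str = "") -> StratifiedResult:
    """Median-split one gene's survival table and compare the strata.

    ``table`` needs columns time, event, expression. The high-expression
    stratum is group 1, so hr > 1 means high expression carries excess
    hazard (poor prognosis).
    """
    cutoff, low, high = median_split(table["expression"].to_numpy())
    t = table["time"].to_numpy()
    e = table["event"].to_numpy()
    chi2, p = logrank(t[high], e[high], t[low], e[low])
    hr, ci = hazard_ratio(t[high], e[high], t[low], e[low])
    return StratifiedResult(
        gene=gene,
        cutoff=cutoff,
        n_low=int(low.sum()),
        n_high=int(high.sum()),
        chi2=chi2,
        p=p,
        hr=hr,
        hr_ci=ci,
    )


def prioritize(
    survival: pd.DataFrame,
    genes=None,
    alpha: float = 0.05,
    adjust: str | None = "bh",
) -> pd.DataFrame:
    """Rank receptors by prognostic association.

    ``survival`` is long-form (gene, time, event, expression). Each gene is
    median-split and tested; the poor-prognosis flag requires hr > 1 and a
    significant test - on the BH-adjusted p by default (``adjust="bh"``) or
    on the raw p (``adjust=None``). Returns a DataFrame ranked by p.
    """
    if genes is None:
        genes = sorted(survival["gene"].unique())
    rows = []
    for g in genes:
        sub = survival[survival["gene"] == g]
        if len(sub) == 0:
            raise ValueError(f"no survival rows for gene {g}")
        res = stratify(sub, gene=g)
        rows.append(res)
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "cutoff": [r.cutoff for r in rows],
            "n_low": [r.n_low for r in rows],
            "n_high": [r.n_high for r in rows],
            "chi2": [r.chi2 for r in rows],
            "p": [r.p for r in rows],
            "hr": [r.hr for r in rows],
            "hr_lo": [r.hr_ci[0] for r in rows],
            "hr_hi": [r.hr_ci[1] for r in rows],
        }
    )
    df["padj"] = bh_adjust(df["p"].to_numpy())
    crit = df["padj"] if adjust == "bh" else df["p"]
    df["poor_prognosis"] = (crit < alpha) & (df["hr"] > 1)
    return df.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)
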