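"""Chou-Talalay median-effect analysis and combination-index computation.

The median-effect equation fa/(1-fa) = (D/Dm)^m linearizes to
log10(fa/(1-fa)) = m log10(D) - m log10(Dm); an ordinary least-squares fit
of that line gives the slope m, the median-effect dose Dm and the fit
correlation r. Effective doses Dx(fa) = Dm (fa/(1-fa))^(1/m) feed the
combination index CI = d1/Dx1(fa) + d2/Dx2(fa), whose two addends are the
normalized-isobologram coordinates (CI < 1 synergy, = 1 additivity, > 1
antagonism).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MedianEffectFit",
    "ComboResult",
    "median_effect_fit",
    "effective_dose",
    "combination_index",
]


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect line fit: slope m, median-effect dose Dm, correlation r."""

    m: float
    dm: float
    r: float


@dataclass(frozen=True)
class ComboResult:
    """One dose combination: CI and its isobologram coordinates."""

    d1: float
    d2: float
    fa: float
    ci: float
    isobologram: tuple  # (d1/Dx1(fa), d2/Dx2(fa)); CI is their sum


def _check_fa(fa) -> np.ndarray:
    fa = np.asarray(fa, dtype=float)
    bad = np.where((fa <= 0) | (fa >= 1))[0]
    if bad.size:
        raise ValueError(
            f"fraction affected must lie strictly in (0, 1); offending point(s) "
            f"at index {bad.tolist()} with value(s) {fa[bad].tolist()}"
        )
    return fa


def median_effect_fit(doses, fa) -> MedianEffectFit:
    """Least-squares fit of the linearized median-effect equation.

    ``doses`` must be positive; ``fa`` strictly inside (0, 1) - exact 0 or 1
    (no effect / complete effect) carry no information about the line and
    are rejected rather than clipped.
    """
    d = np.asarray(doses, dtype=float)
    fa = _check_fa(fa)
    if d.size != fa.size:
        raise ValueError("doses and fa must have equal length")
    if d.size < 2:
        raise ValueError("median-effect fit needs at least 2 dose points")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    x = np.log10(d)
    y = np.log10(fa / (1.0 - fa))
    m, intercept = np.polyfit(x, y, 1)
    if m <= 0:
        raise ValueError(f"non-positive median-effect slope m = {m:.4g}")
    dm = 10.0 ** (-intercept / m)
    # degenerate correlation (e.g. two points) is exactly 1 by construction
    if np.std(x) == 0 or np.std(y) == 0:
        r = 1.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return MedianEffectFit(m=float(m), dm=float(dm), r=r)


def effective_dose(fit: MedianEffectFit, fa: float) -> float:
    """Dose of the single agent producing effect ``fa``:
    Dx = Dm (fa/(1-fa))^(1/m). Monotone increasing in fa for m > 0."""
    fa_arr = _check_fa(np.atleast_1d(fa))
    dx = fit.dm * (fa_arr / (1.0 - fa_arr)) ** (1.0 / fit.m)
    return float(dx[0]) if np.isscalar(fa) or np.ndim(fa) == 0 else dx


def combination_index(fit1: MedianEffectFit, fit2: MedianEffectFit, combos):
    """Combination index per measured combination.

    ``combos`` is an iterable of (d1, d2, fa) with fa the measured fraction
    affected of the combination. CI = d1/Dx1(fa) + d2/Dx2(fa); a dose of 0
    contributes 0 (single-agent limit). Returns a list of ComboResult.
    """
    out = []
    for d1, d2, fa in combos:
        if d1 < 0 or d2 < 0:
            raise ValueError("doses must be nonnegative")
        a = d1 / effective_dose(fit1, fa) if d1 > 0 else 0.0
        b = d2 / effective_dose(fit2, fa) if d2 > 0 else 0.0
        out.append(
            ComboResult(
                d1=float(d1), d2=float(d2), fa=float(fa),
                ci=float(a + b), isobologram=(float(a), float(b)),
            )
        )
    return out
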