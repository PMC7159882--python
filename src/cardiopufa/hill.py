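"""Hill fits of PUFA dose-response curves.

The observable is the 0 mV current ratio I/I0 against PUFA concentration x
(uM), fitted with

    I/I0 = 1 + A / (1 + (Km / x)^n)

A is the fold change at saturating concentration (negative for inhibition,
bounded below by -1), Km the apparent affinity and n the Hill coefficient.
The curve equals 1 exactly at x = 0 for any parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

CMAX_DEFAULT_UM = 20.0


def hill_ii0(x, a, km, n=1.0):
    """I/I0 at concentration x; exactly 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x > 0
    out[nz] = 1.0 + a / (1.0 + (km / x[nz]) ** n)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class HillFit:
    a: float
    km: float
    n: float
    adj_r2: float
    converged: bool
    km_above_range: bool = False    # fitted Km beyond the largest tested dose
    flat: bool = False              # no dose dependence: A ~ 0, Km undefined

    def __call__(self, x):
        return hill_ii0(x, self.a, self.km, self.n)

    @property
    def km_label(self) -> str:
        """Reporting convention: '>Cmax' beyond the tested range, 'NA' flat."""
        if self.flat:
            return "NA"
        if self.km_above_range:
            return f">{CMAX_DEFAULT_UM:g}"
        return f"{self.km:.3g}"


def _adj_r2(y, yhat, n_params):
    y = np.asarray(y, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    n = y.size
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    r2 = 1.0 - ss_res / ss_tot
    dof = n - n_params - 1
    if dof <= 0:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / dof


def fit_hill(concentrations, ratios, init=None, cmax: float | None = None,
             n_restarts: int = 5) -> HillFit:
    """Least-squares Hill fit of I/I0 vs concentration (uM).

    Needs >= 3 nonzero concentrations.  All-ones data is reported as flat
    (A pinned to 0, Km undefined) rather than fitted.  A fitted Km beyond
    the largest tested concentration is flagged ``km_above_range`` so it can
    be reported as ">Cmax" instead of a point estimate.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.size != y.size:
        raise ValueError("concentrations and ratios must have equal length")
    if np.any(y < 0):
        raise ValueError("I/I0 must be non-negative")
    nz = x > 0
    if np.count_nonzero(nz) < 3:
        raise ValueError("need at least 3 nonzero concentrations")
    if cmax is None:
        cmax = float(np.max(x))

    if np.allclose(y[nz], 1.0, atol=1e-12):
        return HillFit(0.0, float("nan"), 1.0, 1.0, True, flat=True)

    end = float(y[nz][np.argmax(x[nz])])
    p0 = list(init) if init is not None else [end - 1.0, float(np.median(x[nz])), 1.0]
    rng = np.random.default_rng(0)
    lo = [-1.0, 1e-6, 0.1]
    hi = [np.inf, 1e6, 10.0]

    best = None
    for trial in range(n_restarts):
        if trial == 0:
            start = p0
        else:
            start = [p0[0] * np.exp(rng.normal(0, 0.3)) if p0[0] != 0 else rng.normal(0, 0.5),
                     p0[1] * np.exp(rng.normal(0, 0.5)),
                     min(max(p0[2] * np.exp(rng.normal(0, 0.3)), 0.2), 5.0)]
        start = [min(max(s, l), h) for s, l, h in zip(start, lo, hi)]
        try:
            popt, _ = curve_fit(hill_ii0, x[nz], y[nz], p0=start,
                                bounds=(lo, hi), maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((hill_ii0(x[nz], *popt) - y[nz]) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return HillFit(p0[0], p0[1], p0[2], float("nan"), False)
    popt, _ = best
    a, km, n = (float(q) for q in popt)
    r2 = _adj_r2(y[nz], hill_ii0(x[nz], a, km, n), 3)
    return HillFit(a, km, n, r2, True, km_above_range=km > cmax)
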