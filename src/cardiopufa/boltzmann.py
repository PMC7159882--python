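"""Boltzmann fits of conductance-voltage and availability curves.

The working equation is

    G(V) = (Gmax - Gmin) / (1 + exp((V05 - V) / s)) + Gmin

with V05 the half-maximal voltage and s the slope factor in mV (s < 0
describes a decreasing availability curve; the sign is fitted freely).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


def boltzmann(v, v05, s, gmax, gmin=0.0):
    """Two-state Boltzmann curve."""
    v = np.asarray(v, dtype=float)
    z = np.clip((v05 - v) / s, -500.0, 500.0)  # avoid exp overflow far from V05
    return (gmax - gmin) / (1.0 + np.exp(z)) + gmin


@dataclass
class BoltzmannFit:
    v05: float
    s: float
    gmax: float
    gmin: float
    rss: float
    converged: bool

    @property
    def amplitude(self) -> float:
        """Gmax - Gmin: the conductance span used for Gmax ratios."""
        return self.gmax - self.gmin

    def __call__(self, v):
        return boltzmann(v, self.v05, self.s, self.gmax, self.gmin)


def _initial_guesses(v, g):
    """Heuristic starts: extrema for Gmax/Gmin, mid-crossing for V05."""
    gmax0, gmin0 = float(np.max(g)), float(np.min(g))
    mid = 0.5 * (gmax0 + gmin0)
    increasing = g[-1] >= g[0]
    # first crossing of the midpoint in the curve's own direction
    idx = np.argmin(np.abs(g - mid))
    v05_0 = float(v[idx])
    span = max(float(v[-1] - v[0]), 1.0)
    s0 = span / 8.0 if increasing else -span / 8.0
    return v05_0, s0, gmax0, gmin0


def fit_boltzmann(voltages, values, init=None, constrain_gmin: bool = False,
                  n_restarts: int = 5) -> BoltzmannFit:
    """Least-squares Boltzmann fit with jittered multi-start.

    Needs at least 5 points spanning the transition.  Availability curves
    are handled by the freely-signed slope.  With ``constrain_gmin`` the
    baseline is pinned to 0.  Non-convergence is reported via the
    ``converged`` flag, never silently.
    """
    v = np.asarray(voltages, dtype=float)
    g = np.asarray(values, dtype=float)
    if v.size != g.size:
        raise ValueError("voltages and values must have equal length")
    if v.size < 5:
        raise ValueError("need at least 5 points spanning the transition")
    if np.any(np.diff(v) <= 0):
        raise ValueError("voltages must be strictly increasing")

    p0 = list(init) if init is not None else list(_initial_guesses(v, g))
    rng = np.random.default_rng(0)

    def model4(vv, v05, s, gmax, gmin):
        return boltzmann(vv, v05, s, gmax, gmin)

    def model3(vv, v05, s, gmax):
        return boltzmann(vv, v05, s, gmax, 0.0)

    best = None
    for trial in range(n_restarts):
        if trial == 0:
            start = p0
        else:
            start = [p0[0] + rng.normal(0, 10.0),
                     p0[1] * np.exp(rng.normal(0, 0.3)),
                     p0[2] * np.exp(rng.normal(0, 0.2)),
                     p0[3] + rng.normal(0, 0.1 * max(abs(p0[2]), 1e-12))]
        try:
            if constrain_gmin:
                popt, _ = curve_fit(model3, v, g, p0=start[:3], maxfev=10000)
                popt = np.append(popt, 0.0)
            else:
                popt, _ = curve_fit(model4, v, g, p0=start, maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((boltzmann(v, *popt) - g) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        p = p0 if not constrain_gmin else p0[:3] + [0.0]
        return BoltzmannFit(p[0], p[1], p[2], p[3], float("inf"), False)
    popt, rss = best
    return BoltzmannFit(float(popt[0]), float(popt[1]), float(popt[2]),
                        float(popt[3]), rss, True)


def delta_v05(fit: BoltzmannFit, control_fit: BoltzmannFit) -> float:
    """PUFA-induced midpoint shift V05 - V05(control), in mV."""
    _require_converged(fit, control_fit)
    return fit.v05 - control_fit.v05


def gmax_ratio(fit: BoltzmannFit, control_fit: BoltzmannFit) -> float:
    """Conductance-span ratio (Gmax - Gmin) / (Gmax - Gmin)(control)."""
    _require_converged(fit, control_fit)
    return fit.amplitude / control_fit.amplitude


def _require_converged(*fits):
    for f in fits:
        if not f.converged:
            raise ValueError("cannot summarize an unconverged Boltzmann fit")
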