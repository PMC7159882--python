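"""Reduction of voltage-clamp families to dose-response effect summaries.

Tail currents -> G-V curves -> Boltzmann fits -> dV05 and Gmax ratios;
peak currents -> I-V / availability curves; 0 mV current ratios -> Hill
fits of I/I0 against concentration.  Control rows are exactly
(0 mV, ratio 1, I/I0 1) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boltzmann import BoltzmannFit, delta_v05, fit_boltzmann, gmax_ratio
from .hill import HillFit, fit_hill
from .synth import TraceFamily


@dataclass
class GVCurve:
    """Conductance (or normalized current) against swept voltage."""
    voltages: np.ndarray
    values: np.ndarray
    kind: str                 # "activation" | "availability"
    concentration_uM: float
    normalization: str = "raw"

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.voltages.size != self.values.size:
            raise ValueError("voltages and values must have equal length")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass
class DoseResponsePoint:
    concentration_uM: float
    ratio: float


@dataclass
class EffectSummary:
    """Per-concentration PUFA effect summary for one channel/family."""
    channel_id: str
    table: pd.DataFrame            # concentration_uM, dv05_mV, gmax_ratio, i_i0
    hill: HillFit | None
    fits: dict = field(default_factory=dict)   # conc -> BoltzmannFit
    def control_row(self) -> pd.Series:
        return self.table[self.table.concentration_uM == 0].iloc[0]


# ---------------------------------------------------------------------------
# curve extraction
# ---------------------------------------------------------------------------

def measure_tail_gv(family: TraceFamily, window_ms: tuple = (5.0, 25.0)) -> dict:
    """Tail-current G-V curves, one per concentration.

    G(V) is the mean tail current inside the window (measured on the tail
    clock) relative to the post-tail baseline (mean of the final 10% of the
    tail); the raw scale is preserved so Gmax ratios stay meaningful.
    """
    if family.protocol.kind != "tail":
        raise ValueError("measure_tail_gv requires a tail-protocol family")
    t0, t1 = family.segments["tail"]
    w0, w1 = (t0 + window_ms[0], t0 + window_ms[1])
    if not (t0 <= w0 < w1 <= t1):
        raise ValueError(f"window {window_ms} lies outside the tail step")
    t = family.time_ms
    in_win = (t >= w0) & (t < w1)
    base_sel = t >= t1 - 0.1 * (t1 - t0)
    out = {}
    for ci, c in enumerate(family.concentrations_uM):
        vals = (family.currents[ci, :, in_win].mean(axis=0)
                - family.currents[ci, :, base_sel].mean(axis=0))
        out[c] = GVCurve(family.swept_mV, vals, "activation", c,
                         normalization="raw tail minus post-tail baseline")
    return out


def _signed_peak(trace: np.ndarray) -> float:
    """Signed extremum; first sample in time wins exact ties."""
    i = int(np.argmax(np.abs(trace)))
    return float(trace[i])


def measure_peak_iv(family: TraceFamily) -> dict:
    """Signed peak current per test voltage, one curve per concentration."""
    if family.protocol.kind != "activation":
        raise ValueError("measure_peak_iv requires an activation-protocol family")
    out = {}
    for ci, c in enumerate(family.concentrations_uM):
        peaks = np.array([_signed_peak(tr) for tr in family.currents[ci]])
        out[c] = GVCurve(family.swept_mV, peaks, "activation", c,
                         normalization="signed peak, raw")
    return out


def measure_availability(family: TraceFamily) -> dict:
    """Availability curves: peak test current per prepulse voltage,
    normalized to the most-negative-prepulse control value."""
    if family.protocol.kind != "inactivation":
        raise ValueError("measure_availability requires an inactivation family")
    if 0.0 not in family.concentrations_uM:
        raise ValueError("family must include the 0 uM control for normalization")
    ci0 = family.concentrations_uM.index(0.0)
    peaks0 = np.array([_signed_peak(tr) for tr in family.currents[ci0]])
    anchor = peaks0[0]   # most negative prepulse: full availability
    if anchor == 0:
        raise ValueError("control anchor current is zero")
    out = {}
    for ci, c in enumerate(family.concentrations_uM):
        peaks = np.array([_signed_peak(tr) for tr in family.currents[ci]])
        out[c] = GVCurve(family.swept_mV, peaks / anchor, "availability", c,
                         normalization="peak / control peak at most negative prepulse")
    return out


def current_ratio_at_0mV(family: TraceFamily,
                         control_family: TraceFamily | None = None) -> list:
    """I/I0 at the 0 mV step per concentration (control = 1).

    For the IKs tail protocol the steady-state current at the end of the
    0 mV test step is used; for peak protocols, the 0 mV peak.
    """
    src = control_family if control_family is not None else family
    if 0.0 not in src.concentrations_uM:
        raise ValueError("control (0 uM) sweeps are required")
    volts = list(family.swept_mV)
    if 0.0 not in volts:
        raise ValueError("0 mV is not a step of this protocol")
    vi = volts.index(0.0)

    def level(fam, ci):
        if fam.protocol.kind == "tail":
            t0, t1 = fam.segments["test"]
            sel = (fam.time_ms >= t1 - 0.05 * (t1 - t0)) & (fam.time_ms < t1)
            return float(fam.currents[ci, vi, sel].mean())
        return _signed_peak(fam.currents[ci, vi])

    i0 = level(src, src.concentrations_uM.index(0.0))
    if i0 == 0:
        raise ValueError("control current at 0 mV is zero")
    pts = []
    for ci, c in enumerate(family.concentrations_uM):
        pts.append(DoseResponsePoint(c, level(family, ci) / i0))
    return pts


# ---------------------------------------------------------------------------
# family-level summaries
# ---------------------------------------------------------------------------

def analyze_activation_family(family: TraceFamily,
                              window_ms: tuple = (5.0, 25.0),
                              constrain_gmin: bool = False) -> EffectSummary:
    """IKs pipeline: tail G-V -> Boltzmann per concentration -> dV05, Gmax
    ratio, 0 mV I/I0 and the Hill fit of the dose-response."""
    curves = measure_tail_gv(family, window_ms)
    if 0.0 not in curves:
        raise ValueError("family must include the 0 uM control")
    fits = {c: fit_boltzmann(cu.voltages, cu.values,
                             constrain_gmin=constrain_gmin)
            for c, cu in curves.items()}
    return _summarize(family, fits)


def analyze_availability_family(family: TraceFamily,
                                constrain_gmin: bool = False) -> EffectSummary:
    """Nav/Cav pipeline on the inactivation protocol: availability
    Boltzmann fits (slope sign free) -> dV05(inact), amplitude ratios."""
    curves = measure_availability(family)
    fits = {c: fit_boltzmann(cu.voltages, cu.values,
                             constrain_gmin=constrain_gmin)
            for c, cu in curves.items()}
    return _summarize(family, fits, ratio_source=None)


def _summarize(family, fits, ratio_source="self") -> EffectSummary:
    ctrl = fits[0.0]
    try:
        points = current_ratio_at_0mV(family) if ratio_source == "self" else None
    except ValueError:
        points = None
    rows = []
    for c in family.concentrations_uM:
        f = fits[c]
        row = dict(concentration_uM=c,
                   dv05_mV=delta_v05(f, ctrl),
                   gmax_ratio=gmax_ratio(f, ctrl),
                   v05_mV=f.v05, slope_mV=f.s)
        if points is not None:
            row["i_i0"] = next(p.ratio for p in points
                               if p.concentration_uM == c)
        rows.append(row)
    table = pd.DataFrame(rows)
    hill = None
    if points is not None:
        nz = table[table.concentration_uM > 0]
        if len(nz) >= 3:
            hill = fit_hill(nz.concentration_uM.to_numpy(),
                            nz.i_i0.to_numpy())
    return EffectSummary(family.channel_id, table, hill, fits)


def summarize_replicates(summaries: list) -> pd.DataFrame:
    """Mean +/- SEM across replicate families ("oocytes") per concentration."""
    if not summaries:
        raise ValueError("need at least one replicate")
    frames = [s.table.assign(replicate=i) for i, s in enumerate(summaries)]
    df = pd.concat(frames, ignore_index=True)
    cols = [c for c in ("dv05_mV", "gmax_ratio", "i_i0") if c in df.columns]
    g = df.groupby("concentration_uM")[cols]
    n = df.groupby("concentration_uM").size()
    mean = g.mean().add_suffix("_mean")
    sem = (g.std(ddof=1) / np.sqrt(n.to_numpy()[:, None])).add_suffix("_sem")
    out = pd.concat([mean, sem], axis=1).reset_index()
    out["n"] = n.to_numpy()
    return out
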