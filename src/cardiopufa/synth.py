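"""Seeded synthetic two-electrode voltage-clamp data.

Generates current families with the statistical structure the analysis
pipeline assumes -- Boltzmann-shaped activation/availability, Hill-shaped
concentration dependence of the PUFA effects, single-exponential gating,
additive Gaussian recording noise -- plus fluorescence calcium-transient
records with spontaneous, jittered beating.  Everything is a pure function
of (parameters, seed).

The voltage protocols mirror the oocyte recordings: IKs tail protocol
(hold -80 mV, prepulse -140 mV, steps -100..+60 mV in 20 mV increments,
tail -20 mV), Nav activation -90..+40 mV and availability prepulses
-140..-30 mV with a -30 mV test, Cav activation -70..+40 mV and
availability prepulses -80..+20 mV with a +10 mV test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from . import effects as _effects


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoltageProtocol:
    """Step protocol; all potentials mV, durations ms, inter-sweep s.

    For ``kind="inactivation"`` the swept axis is the conditioning prepulse
    and ``test_mV`` holds the single fixed test potential.
    """
    kind: str                       # "tail" | "activation" | "inactivation"
    holding_mV: float
    test_mV: tuple
    test_ms: float
    prepulse_mV: tuple = ()
    prepulse_ms: float = 0.0
    tail_mV: float | None = None
    tail_ms: float = 0.0
    inter_sweep_s: float = 30.0

    def __post_init__(self):
        if self.kind not in ("tail", "activation", "inactivation"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if (self.tail_mV is not None) != (self.kind == "tail"):
            raise ValueError("tail_mV is present iff the protocol is a tail protocol")
        for name in ("test_ms",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        sw = self.swept_mV
        if len(sw) < 2 or np.any(np.diff(sw) <= 0):
            raise ValueError("swept voltages must be strictly increasing")

    @property
    def swept_mV(self) -> np.ndarray:
        if self.kind == "inactivation":
            return np.asarray(self.prepulse_mV, dtype=float)
        return np.asarray(self.test_mV, dtype=float)


IKS_ACTIVATION = VoltageProtocol(
    kind="tail", holding_mV=-80.0, prepulse_mV=(-140.0,), prepulse_ms=500.0,
    test_mV=tuple(np.arange(-100.0, 61.0, 20.0)), test_ms=2000.0,
    tail_mV=-20.0, tail_ms=500.0)

NAV_ACTIVATION = VoltageProtocol(
    kind="activation", holding_mV=-80.0,
    test_mV=tuple(np.arange(-90.0, 41.0, 10.0)), test_ms=50.0)

NAV_INACTIVATION = VoltageProtocol(
    kind="inactivation", holding_mV=-80.0,
    prepulse_mV=tuple(np.arange(-140.0, -29.0, 10.0)), prepulse_ms=500.0,
    test_mV=(-30.0,), test_ms=50.0)

CAV_ACTIVATION = VoltageProtocol(
    kind="activation", holding_mV=-80.0,
    test_mV=tuple(np.arange(-70.0, 41.0, 10.0)), test_ms=300.0)

CAV_INACTIVATION = VoltageProtocol(
    kind="inactivation", holding_mV=-80.0,
    prepulse_mV=tuple(np.arange(-80.0, 21.0, 10.0)), prepulse_ms=500.0,
    test_mV=(10.0,), test_ms=300.0)


# ---------------------------------------------------------------------------
# channel parameters and effect profiles
# ---------------------------------------------------------------------------

@dataclass
class ChannelSimParams:
    """Closed-form gating parameters of one heterologously expressed channel.

    Activation follows an increasing Boltzmann (V05_act, s_act); channels
    with voltage-dependent inactivation carry a decreasing availability
    Boltzmann (V05_inact, s_inact, both slopes positive by convention).
    Kinetics are single-exponential with fixed, concentration-independent
    time constants -- sufficient for steady-state/peak analysis.
    """
    channel_id: str
    V05_act: float
    s_act: float
    gmax: float = 1.0
    Erev: float = 0.0
    V05_inact: float | None = None
    s_inact: float | None = None
    tau_act_ms: float = 1.0
    tau_inact_ms: float = 5.0
    tau_deact_ms: float = 150.0

    def __post_init__(self):
        if self.s_act <= 0:
            raise ValueError("s_act must be positive")
        if self.gmax <= 0:
            raise ValueError("gmax must be positive")
        if (self.V05_inact is None) != (self.s_inact is None):
            raise ValueError("V05_inact and s_inact must be given together")
        if self.s_inact is not None and self.s_inact <= 0:
            raise ValueError("s_inact must be positive")

    def act_po(self, v, dv05=0.0):
        return 1.0 / (1.0 + np.exp((self.V05_act + dv05 - np.asarray(v, float))
                                   / self.s_act))

    def avail(self, v, dv05=0.0):
        if self.V05_inact is None:
            raise ValueError(f"{self.channel_id} has no inactivation curve")
        return 1.0 / (1.0 + np.exp((np.asarray(v, float)
                                    - (self.V05_inact + dv05)) / self.s_inact))


#: control gating parameters used throughout (oocyte-like values)
DEFAULT_PARAMS = {
    "IKs": ChannelSimParams("IKs", V05_act=25.0, s_act=17.5, gmax=1.0,
                            Erev=-85.0, tau_act_ms=750.0, tau_deact_ms=150.0),
    "INa": ChannelSimParams("INa", V05_act=-40.0, s_act=7.0, gmax=1.0,
                            Erev=45.0, V05_inact=-85.0, s_inact=6.0,
                            tau_act_ms=0.2, tau_inact_ms=1.0),
    "ICaL": ChannelSimParams("ICaL", V05_act=-10.0, s_act=6.0, gmax=1.0,
                             Erev=60.0, V05_inact=-30.0, s_inact=7.0,
                             tau_act_ms=2.0, tau_inact_ms=150.0),
}


def default_params(channel_id: str) -> ChannelSimParams:
    return replace(DEFAULT_PARAMS[channel_id])


@dataclass
class PufaEffectProfile:
    """Concentration dependence of one compound's effects on one channel.

    Either Hill-parameterized (saturating value, Km, n) or given as explicit
    per-concentration tables.  The identity holds at concentration 0.
    """
    channel_id: str
    km_uM: float = 1.0
    n: float = 1.0
    dv05_sat_mV: float = 0.0
    gmax_sat: float = 1.0
    ratio_A: float = 0.0
    n_dv05: float | None = None     # per-observable Hill coefficients;
    n_gmax: float | None = None     # None falls back to the shared n
    n_ratio: float | None = None
    dv05_table: dict = field(default_factory=dict)
    gmax_table: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.km_uM <= 0:
            raise ValueError("Km must be positive")

    def _frac(self, c, n=None):
        if c == 0:
            return 0.0
        return 1.0 / (1.0 + (self.km_uM / c) ** (self.n if n is None else n))

    def dv05(self, c: float) -> float:
        if self.dv05_table:
            return self._lookup(self.dv05_table, c, 0.0)
        return self.dv05_sat_mV * self._frac(c, self.n_dv05)

    def gmax_factor(self, c: float) -> float:
        if self.gmax_table:
            return self._lookup(self.gmax_table, c, 1.0)
        return 1.0 + (self.gmax_sat - 1.0) * self._frac(c, self.n_gmax)

    def current_ratio(self, c: float) -> float:
        return 1.0 + self.ratio_A * self._frac(c, self.n_ratio)

    @staticmethod
    def _lookup(table, c, identity):
        if c == 0:
            return identity
        if c not in table:
            raise KeyError(f"concentration {c} uM not in effect table and no "
                           "Hill parameters given")
        return table[c]

    @classmethod
    def identity(cls, channel_id: str) -> "PufaEffectProfile":
        return cls(channel_id, km_uM=1.0)

    @classmethod
    def from_compound(cls, compound: str, channel_id: str) -> "PufaEffectProfile":
        """Generating truth anchored at the printed 7 uM effect values."""
        tr = _effects.dose_truth(compound, channel_id)
        return cls(channel_id, km_uM=tr["km_uM"],
                   dv05_sat_mV=tr["dv05_sat_mV"], gmax_sat=tr["gmax_sat"],
                   ratio_A=tr["ratio_A"], n_dv05=tr["dv05_n"],
                   n_gmax=tr["gmax_n"], n_ratio=tr["ratio_n"])


# ---------------------------------------------------------------------------
# trace families
# ---------------------------------------------------------------------------

@dataclass
class TraceFamily:
    """Voltage-clamp sweeps keyed by (concentration, swept voltage).

    ``currents`` has shape (n_concentrations, n_swept_voltages, n_samples);
    ``segments`` maps segment name to (start_ms, end_ms) on the sweep clock.
    """
    channel_id: str
    protocol: VoltageProtocol
    concentrations_uM: tuple
    time_ms: np.ndarray
    currents: np.ndarray
    segments: dict
    noise_sd: float
    seed: int
    sampling_ms: float
    truth: dict = field(default_factory=dict)

    def sweep(self, conc: float, volt: float) -> np.ndarray:
        ci = self.concentrations_uM.index(conc)
        sw = list(self.protocol.swept_mV)
        vi = sw.index(volt)
        return self.currents[ci, vi]

    @property
    def swept_mV(self) -> np.ndarray:
        return self.protocol.swept_mV


def _validate_generate(params, channel_id, concentrations, noise_sd, effect):
    if params.channel_id != channel_id:
        raise ValueError(f"params are for {params.channel_id}, not {channel_id}")
    if effect.channel_id != channel_id:
        raise ValueError(f"effect profile is for {effect.channel_id}, not {channel_id}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    for c in concentrations:
        if c < 0:
            raise ValueError("concentrations must be non-negative")
        effect.dv05(c)       # raises for unknown table-only concentrations
        effect.gmax_factor(c)


def generate_iks_family(params: ChannelSimParams, effect: PufaEffectProfile,
                        concentrations, noise_sd: float = 0.0, seed: int = 0,
                        protocol: VoltageProtocol = IKS_ACTIVATION,
                        sampling_ms: float = 0.2,
                        oocyte_jitter_sd: float = 0.0) -> TraceFamily:
    """IKs tail-protocol family.

    Per sweep the current follows single-exponential activation toward
    gmax*Po(V)*(V - Erev) with Po the concentration-shifted activation
    Boltzmann; the tail at -20 mV deactivates exponentially from the
    end-of-step open probability.  Gaussian noise is added pointwise.
    """
    _validate_generate(params, "IKs", concentrations, noise_sd, effect)
    if protocol.kind != "tail":
        raise ValueError("IKs generation requires the tail protocol")
    concentrations = tuple(float(c) for c in concentrations)
    rng = np.random.default_rng(seed)
    # optional per-oocyte (per-family) expression variability
    oocyte_scale = rng.lognormal(0.0, oocyte_jitter_sd) if oocyte_jitter_sd else 1.0
    pre, test, tail = protocol.prepulse_ms, protocol.test_ms, protocol.tail_ms
    total = pre + test + tail
    t = np.arange(0.0, total + sampling_ms / 2, sampling_ms)
    volts = protocol.swept_mV
    out = np.zeros((len(concentrations), len(volts), t.size))
    seg = {"prepulse": (0.0, pre), "test": (pre, pre + test),
           "tail": (pre + test, total)}
    truth = {"params": params, "per_concentration": {}}
    in_test = (t >= pre) & (t < pre + test)
    in_tail = t >= pre + test
    vt = protocol.tail_mV
    for ci, c in enumerate(concentrations):
        dv = effect.dv05(c)
        g = params.gmax * oocyte_scale * effect.gmax_factor(c)
        po_tail_ss = float(params.act_po(vt, dv))
        truth["per_concentration"][c] = {
            "v05_mV": params.V05_act + dv, "gmax": g,
            "dv05_mV": dv, "gmax_factor": effect.gmax_factor(c)}
        for vi, v in enumerate(volts):
            po_inf = float(params.act_po(v, dv))
            po = np.zeros_like(t)
            po[in_test] = po_inf * (1.0 - np.exp(-(t[in_test] - pre)
                                                 / params.tau_act_ms))
            po_end = po_inf * (1.0 - math.exp(-test / params.tau_act_ms))
            po[in_tail] = (po_tail_ss + (po_end - po_tail_ss)
                           * np.exp(-(t[in_tail] - pre - test)
                                    / params.tau_deact_ms))
            drive = np.where(in_tail, vt - params.Erev,
                             np.where(in_test, v - params.Erev, 0.0))
            out[ci, vi] = g * po * drive
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, out.shape)
    return TraceFamily("IKs", protocol, concentrations, t, out, seg,
                       noise_sd, seed, sampling_ms, truth)


def _normalized_peak_shape(t, tau_rise, tau_decay):
    """Transient shape normalized so its sampled maximum is exactly 1."""
    s = (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)
    m = s.max()
    if m <= 0:
        raise ValueError("degenerate peak shape")
    return s / m


def _generate_peak_family(channel_id, params, effect, concentrations, noise_sd,
                          seed, kind, protocol, sampling_ms,
                          oocyte_jitter_sd=0.0):
    _validate_generate(params, channel_id, concentrations, noise_sd, effect)
    if kind not in ("activation", "inactivation"):
        raise ValueError("kind must be 'activation' or 'inactivation'")
    if protocol.kind != kind:
        raise ValueError(f"protocol kind {protocol.kind!r} does not match {kind!r}")
    concentrations = tuple(float(c) for c in concentrations)
    rng = np.random.default_rng(seed)
    oocyte_scale = rng.lognormal(0.0, oocyte_jitter_sd) if oocyte_jitter_sd else 1.0
    t = np.arange(0.0, protocol.test_ms + sampling_ms / 2, sampling_ms)
    shape = _normalized_peak_shape(t, params.tau_act_ms, params.tau_inact_ms)
    volts = protocol.swept_mV
    out = np.zeros((len(concentrations), len(volts), t.size))
    truth = {"params": params, "per_concentration": {}}
    for ci, c in enumerate(concentrations):
        dv = effect.dv05(c)
        g = params.gmax * oocyte_scale * effect.gmax_factor(c)
        truth["per_concentration"][c] = {
            "dv05_mV": dv, "gmax_factor": effect.gmax_factor(c)}
        for vi, v in enumerate(volts):
            if kind == "activation":
                # peak I-V; the inactivation shift does not move activation
                peak = g * float(params.act_po(v)) * (v - params.Erev)
            else:
                vtest = float(protocol.test_mV[0])
                peak = (g * float(params.avail(v, dv))
                        * float(params.act_po(vtest)) * (vtest - params.Erev))
            out[ci, vi] = peak * shape
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, out.shape)
    seg = {"test": (0.0, protocol.test_ms)}
    return TraceFamily(channel_id, protocol, concentrations, t, out, seg,
                       noise_sd, seed, sampling_ms, truth)


def generate_nav_family(params: ChannelSimParams, effect: PufaEffectProfile,
                        concentrations, noise_sd: float = 0.0, seed: int = 0,
                        kind: str = "inactivation",
                        protocol: VoltageProtocol | None = None,
                        sampling_ms: float = 0.05,
                        oocyte_jitter_sd: float = 0.0) -> TraceFamily:
    """Nav peak-current family (activation I-V or availability protocol).

    Peak model: activation I(V) = g*a(V)*(V - Erev); availability
    I = g*h(Vpre)*a(Vtest)*(Vtest - Erev) with h the concentration-shifted
    decreasing Boltzmann.  The sampled transient shape is identical across
    sweeps, so peak extraction recovers the closed form exactly at noise 0.
    """
    if protocol is None:
        protocol = NAV_ACTIVATION if kind == "activation" else NAV_INACTIVATION
    return _generate_peak_family("INa", params, effect, concentrations,
                                 noise_sd, seed, kind, protocol, sampling_ms,
                                 oocyte_jitter_sd)


def generate_cav_family(params: ChannelSimParams, effect: PufaEffectProfile,
                        concentrations, noise_sd: float = 0.0, seed: int = 0,
                        kind: str = "inactivation",
                        protocol: VoltageProtocol | None = None,
                        sampling_ms: float = 0.5,
                        oocyte_jitter_sd: float = 0.0) -> TraceFamily:
    """Cav peak-current family (Ba2+ charge carrier, no Ca-dependent
    inactivation); taurine-class effects are pure conductance reductions."""
    if protocol is None:
        protocol = CAV_ACTIVATION if kind == "activation" else CAV_INACTIVATION
    return _generate_peak_family("ICaL", params, effect, concentrations,
                                 noise_sd, seed, kind, protocol, sampling_ms,
                                 oocyte_jitter_sd)


# ---------------------------------------------------------------------------
# calcium transients
# ---------------------------------------------------------------------------

@dataclass
class CaTParams:
    """Spontaneously beating monolayer fluorescence model."""
    period_s: float = 1.25
    jitter_sd_s: float = 0.05
    amplitude: float = 1.0
    tau_rise_ms: float = 60.0
    tau_decay_ms: float = 170.0
    baseline: float = 0.1
    noise_sd: float = 0.01
    duration_s: float = 15.0
    fs_hz: float = 1000.0

    def __post_init__(self):
        if self.tau_decay_ms <= self.tau_rise_ms:
            raise ValueError("decay time constant must exceed rise time constant")
        if self.duration_s < 3.0 * self.period_s:
            raise ValueError("duration must cover at least 3 beat periods")


@dataclass
class CaTRecord:
    time_s: np.ndarray
    signal: np.ndarray
    fs_hz: float
    seed: int
    truth: dict = field(default_factory=dict)


def _transient_shape_value(t_ms, tau_r, tau_d):
    return (1.0 - math.exp(-t_ms / tau_r)) * math.exp(-t_ms / tau_d)


def analytic_cat_apd90(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Time (ms) from transient onset to 90% return toward baseline,
    computed by root-finding on the closed-form transient."""
    t_peak = tau_rise_ms * math.log(1.0 + tau_decay_ms / tau_rise_ms)
    s_peak = _transient_shape_value(t_peak, tau_rise_ms, tau_decay_ms)
    target = 0.1 * s_peak

    def f(t):
        return _transient_shape_value(t, tau_rise_ms, tau_decay_ms) - target

    hi = t_peak + 20.0 * tau_decay_ms
    return float(brentq(f, t_peak, hi))


def generate_cat_trace(params: CaTParams, seed: int = 0) -> CaTRecord:
    """Fluorescence record of jittered spontaneous calcium transients.

    True beat onsets and the analytic per-transient APD90 are returned in
    the truth metadata for pipeline validation.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, params.duration_s, 1.0 / params.fs_hz)
    beats = []
    tk = 0.3  # settle time before the first beat
    while tk < params.duration_s:
        beats.append(tk)
        step = params.period_s + rng.normal(0.0, params.jitter_sd_s)
        tk += max(step, 0.2 * params.period_s)
    sig = np.full_like(t, params.baseline)
    for bk in beats:
        dt_ms = (t - bk) * 1000.0
        mask = dt_ms >= 0
        sig[mask] += params.amplitude * (
            (1.0 - np.exp(-dt_ms[mask] / params.tau_rise_ms))
            * np.exp(-dt_ms[mask] / params.tau_decay_ms))
    if params.noise_sd > 0:
        sig = sig + rng.normal(0.0, params.noise_sd, sig.shape)
    truth = {
        "beat_times_s": np.asarray(beats),
        "apd90_ms": analytic_cat_apd90(params.tau_rise_ms, params.tau_decay_ms),
        "params": params,
    }
    return CaTRecord(t, sig, params.fs_hz, seed, truth)


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

def write_family(family: TraceFamily, directory, stem: str = "family") -> tuple:
    """Long-format CSV (channel, concentration_uM, step_mV, time_ms, current)
    plus a YAML sidecar holding the protocol and generating truth."""
    import pathlib

    import pandas as pd
    import yaml

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, c in enumerate(family.concentrations_uM):
        for vi, v in enumerate(family.swept_mV):
            rows.append(pd.DataFrame({
                "channel": family.channel_id,
                "concentration_uM": c,
                "step_mV": v,
                "time_ms": family.time_ms,
                "current": family.currents[ci, vi],
            }))
    csv_path = directory / f"{stem}.csv"
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False)
    proto = family.protocol
    sidecar = {
        "channel": family.channel_id,
        "protocol": {
            "kind": proto.kind, "holding_mV": float(proto.holding_mV),
            "prepulse_mV": [float(v) for v in proto.prepulse_mV],
            "prepulse_ms": float(proto.prepulse_ms),
            "test_mV": [float(v) for v in proto.test_mV],
            "test_ms": float(proto.test_ms),
            "tail_mV": None if proto.tail_mV is None else float(proto.tail_mV),
            "tail_ms": float(proto.tail_ms),
            "inter_sweep_s": float(proto.inter_sweep_s),
        },
        "segments": {k: [float(x) for x in v]
                     for k, v in family.segments.items()},
        "noise_sd": float(family.noise_sd),
        "seed": int(family.seed),
        "sampling_ms": float(family.sampling_ms),
        "truth_per_concentration": {
            str(c): {k: float(val) for k, val in d.items()}
            for c, d in family.truth.get("per_concentration", {}).items()
        },
    }
    yaml_path = directory / f"{stem}.yaml"
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return csv_path, yaml_path


def read_family(csv_path, yaml_path) -> TraceFamily:
    import pandas as pd
    import yaml

    with open(yaml_path) as fh:
        side = yaml.safe_load(fh)
    df = pd.read_csv(csv_path)
    pr = side["protocol"]
    proto = VoltageProtocol(
        kind=pr["kind"], holding_mV=pr["holding_mV"],
        prepulse_mV=tuple(pr["prepulse_mV"]), prepulse_ms=pr["prepulse_ms"],
        test_mV=tuple(pr["test_mV"]), test_ms=pr["test_ms"],
        tail_mV=pr["tail_mV"], tail_ms=pr["tail_ms"],
        inter_sweep_s=pr["inter_sweep_s"])
    concs = tuple(sorted(df["concentration_uM"].unique()))
    volts = proto.swept_mV
    t = np.sort(df["time_ms"].unique())
    arr = np.zeros((len(concs), len(volts), t.size))
    for ci, c in enumerate(concs):
        for vi, v in enumerate(volts):
            sel = df[(df.concentration_uM == c) & (df.step_mV == v)]
            arr[ci, vi] = sel.sort_values("time_ms")["current"].to_numpy()
    truth = {"per_concentration": {
        float(c): d for c, d in side.get("truth_per_concentration", {}).items()}}
    return TraceFamily(side["channel"], proto, concs, t, arr,
                       {k: tuple(v) for k, v in side["segments"].items()},
                       side["noise_sd"], side["seed"], side["sampling_ms"],
                       truth)


def write_cat(record: CaTRecord, path) -> None:
    """Two-column (time_s, F) text."""
    np.savetxt(path, np.column_stack([record.time_s, record.signal]),
               header="time_s\tF", comments="", delimiter="\t", fmt="%.6f")


def read_cat(path, fs_hz: float | None = None) -> CaTRecord:
    data = np.loadtxt(path, skiprows=1)
    t, sig = data[:, 0], data[:, 1]
    if fs_hz is None:
        fs_hz = 1.0 / float(np.median(np.diff(t)))
    return CaTRecord(t, sig, fs_hz, seed=-1)
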