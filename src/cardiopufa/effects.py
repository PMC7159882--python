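"""PUFA-analogue effect fixtures and model-level channel modifications.

The fixture library encodes the measured 7 uM effects of each PUFA analogue
on the three cloned channel complexes (Kv7.1/KCNE1 -> IKs, Cav1.2/b3/a2d ->
ICaL, Nav1.5/b1 -> INa), the Hill dose-response summaries (I/I0 at 7 uM,
apparent affinity Km, adjusted R2) and the fitted G-V slope factors, each
with its statistical-significance flag.  Effects reported as non-significant
map to the identity modification unless explicitly included, so simulations
do not inject noise-level parameter changes.

Sign conventions: dv05 < 0 is a leftward (hyperpolarizing) shift; g_factor
multiplies the maximal conductance (1 = no change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

CHANNELS = ("IKs", "ICaL", "INa")
TESTED_CONCENTRATIONS_UM = (0.2, 0.7, 2.0, 7.0, 20.0)

#: placeholder affinity used where the fitted Km lies beyond the tested range
KM_ABOVE_RANGE_UM = 40.0
CMAX_UM = 20.0


@dataclass
class ChannelModification:
    """Per-channel model modification: voltage shifts (mV) + conductance factor."""
    channel_id: str
    dv05_act: float = 0.0
    dv05_inact: float = 0.0
    g_factor: float = 1.0

    def __post_init__(self):
        if self.g_factor <= 0:
            raise ValueError("g_factor must be positive")

    @property
    def is_identity(self) -> bool:
        return (self.dv05_act == 0.0 and self.dv05_inact == 0.0
                and self.g_factor == 1.0)

    def compose(self, other: "ChannelModification") -> "ChannelModification":
        """Shifts compose additively, conductance factors multiplicatively."""
        if other.channel_id != self.channel_id:
            raise ValueError("cannot compose modifications of different channels")
        return ChannelModification(
            self.channel_id,
            self.dv05_act + other.dv05_act,
            self.dv05_inact + other.dv05_inact,
            self.g_factor * other.g_factor,
        )


@dataclass
class ModificationSet:
    """Named bundle of per-channel modifications at one concentration."""
    name: str
    concentration_uM: float
    channels: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.concentration_uM < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class Observed:
    """One measured observable: value, SEM, significance at p < 0.05."""
    value: float
    sem: float
    significant: bool


@dataclass
class HillTruth:
    """Dose-response summary of I/I0 at 0 mV for one compound/channel."""
    i_i0_7uM: Observed
    km_uM: float | None          # None = not defined (flat dose-response)
    km_above_range: bool = False
    adj_r2: float | None = None


@dataclass
class CompoundFixture:
    name: str
    # IKs (activation protocol): voltage-dependence of activation + Gmax
    iks_dv05: Observed
    iks_gmax: Observed
    # ICaL (inactivation protocol): voltage-dependence of inactivation + Gmax
    ical_dv05_inact: Observed
    ical_gmax: Observed
    # INa (inactivation protocol): voltage-dependence of inactivation + Gmax
    ina_dv05_inact: Observed
    ina_gmax: Observed
    hill: dict = field(default_factory=dict)   # channel -> HillTruth
    iks_slope_mV: dict = field(default_factory=dict)  # conc label -> (value, sem)


def _h(i_i0, sem, sig, km, r2, above=False):
    return HillTruth(Observed(i_i0, sem, sig), km, above, r2)


# Measured 7 uM effects (mean, SEM, significant) and Hill summaries.
FIXTURES: dict[str, CompoundFixture] = {
    "Lin-taurine": CompoundFixture(
        "Lin-taurine",
        iks_dv05=Observed(-39.9, 3.6, True), iks_gmax=Observed(1.9, 0.6, True),
        ical_dv05_inact=Observed(-1.9, 2.5, False), ical_gmax=Observed(0.6, 0.05, True),
        ina_dv05_inact=Observed(-23.5, 1.9, True), ina_gmax=Observed(0.5, 0.07, True),
        hill={"IKs": _h(7.7, 2.9, False, 11.4, 0.99),
              "ICaL": _h(0.6, 0.1, True, 1.4, 0.98),
              "INa": _h(0.1, 0.02, True, 2.4, 0.99)},
        iks_slope_mV={"control": (17.5, 0.75), "0.2": (17.7, 0.76),
                      "0.7": (17.7, 0.77), "2": (18.6, 1.0),
                      "7": (18.1, 1.0), "20": (12.2, 1.8)},
    ),
    "N-AT": CompoundFixture(
        "N-AT",
        iks_dv05=Observed(-1.8, 2.6, False), iks_gmax=Observed(0.9, 0.03, False),
        ical_dv05_inact=Observed(0.6, 2.0, False), ical_gmax=Observed(0.7, 0.1, True),
        ina_dv05_inact=Observed(-16.7, 3.5, True), ina_gmax=Observed(0.3, 0.04, True),
        hill={"IKs": _h(1.12, 0.1, False, None, None),
              "ICaL": _h(0.8, 0.1, False, 2.5, 0.70),
              "INa": _h(0.2, 0.01, True, 3.1, 0.99)},
        iks_slope_mV={"control": (16.7, 0.71), "0.2": (16.9, 0.65),
                      "0.7": (17.2, 0.62), "2": (17.4, 0.60),
                      "7": (18.2, 0.59), "20": (18.7, 0.73)},
    ),
    "Pin-taurine": CompoundFixture(
        "Pin-taurine",
        iks_dv05=Observed(-23.8, 2.7, True), iks_gmax=Observed(2.3, 0.4, True),
        ical_dv05_inact=Observed(4.1, 2.2, False), ical_gmax=Observed(0.8, 0.1, False),
        ina_dv05_inact=Observed(-16.0, 2.7, True), ina_gmax=Observed(0.4, 0.09, True),
        hill={"IKs": _h(6.8, 1.0, True, 4.5, 0.99),
              "ICaL": _h(0.7, 0.1, True, None, None),
              "INa": _h(0.5, 0.1, True, 5.8, 0.89)},
        iks_slope_mV={"control": (17.7, 0.67), "0.2": (17.9, 0.82),
                      "0.7": (17.7, 0.82), "2": (18.3, 0.96),
                      "7": (18.8, 1.0), "20": (16.8, 0.73)},
    ),
    "DHA-taurine": CompoundFixture(
        "DHA-taurine",
        iks_dv05=Observed(-45.3, 2.9, True), iks_gmax=Observed(1.7, 0.1, True),
        ical_dv05_inact=Observed(0.2, 0.8, False), ical_gmax=Observed(1.1, 0.1, False),
        ina_dv05_inact=Observed(-28.5, 0.6, True), ina_gmax=Observed(0.05, 0.01, True),
        hill={"IKs": _h(5.1, 0.7, True, 5.9, 0.99),
              "ICaL": _h(0.9, 0.1, False, KM_ABOVE_RANGE_UM, 0.75, above=True),
              "INa": _h(0.07, 0.01, True, 2.3, 0.99)},
        iks_slope_mV={"control": (18.7, 1.2), "0.2": (18.7, 1.1),
                      "0.7": (18.6, 1.2), "2": (18.6, 1.3),
                      "7": (18.1, 1.2)},
    ),
    "Lin-glycine": CompoundFixture(
        "Lin-glycine",
        iks_dv05=Observed(-23.8, 1.6, True), iks_gmax=Observed(2.3, 0.2, True),
        ical_dv05_inact=Observed(-3.0, 1.6, False), ical_gmax=Observed(1.0, 0.1, False),
        ina_dv05_inact=Observed(-15.2, 2.8, True), ina_gmax=Observed(0.5, 0.1, True),
        hill={"IKs": _h(5.1, 0.4, True, 5.4, 0.99),
              "ICaL": _h(1.1, 0.2, False, None, None),
              "INa": _h(0.5, 0.1, True, 5.6, 0.96)},
        iks_slope_mV={"control": (18.4, 1.2), "0.2": (18.2, 0.89),
                      "0.7": (19.0, 1.0), "2": (19.2, 1.2),
                      "7": (20.6, 1.5), "20": (22.1, 1.7)},
    ),
    "Pin-glycine": CompoundFixture(
        "Pin-glycine",
        iks_dv05=Observed(-8.7, 1.8, True), iks_gmax=Observed(1.7, 0.1, True),
        ical_dv05_inact=Observed(-3.1, 4.2, False), ical_gmax=Observed(0.8, 0.1, False),
        ina_dv05_inact=Observed(-4.7, 1.9, False), ina_gmax=Observed(0.7, 0.08, True),
        hill={"IKs": _h(2.5, 0.2, True, KM_ABOVE_RANGE_UM, 0.98, above=True),
              "ICaL": _h(0.8, 0.1, False, None, None),
              "INa": _h(0.7, 0.1, False, KM_ABOVE_RANGE_UM, 0.90, above=True)},
        iks_slope_mV={"control": (18.4, 0.70), "0.2": (17.9, 0.83),
                      "0.7": (17.8, 0.84), "2": (17.9, 0.91),
                      "7": (18.7, 1.1), "20": (20.9, 1.4)},
    ),
    "DHA-glycine": CompoundFixture(
        "DHA-glycine",
        iks_dv05=Observed(-10.5, 1.0, True), iks_gmax=Observed(1.9, 0.2, True),
        ical_dv05_inact=Observed(7.6, 3.1, False), ical_gmax=Observed(1.0, 0.1, False),
        ina_dv05_inact=Observed(-2.4, 0.6, True), ina_gmax=Observed(1.0, 0.04, False),
        hill={"IKs": _h(3.7, 1.0, False, KM_ABOVE_RANGE_UM, 0.99, above=True),
              "ICaL": _h(0.9, 0.1, False, None, None),
              "INa": _h(1.1, 0.05, False, KM_ABOVE_RANGE_UM, 1.0, above=True)},
        iks_slope_mV={"control": (16.7, 0.44), "0.2": (16.5, 0.49),
                      "0.7": (16.6, 0.45), "2": (16.6, 0.52),
                      "7": (17.0, 0.56), "20": (17.9, 0.68)},
    ),
}

COMPOUNDS = tuple(FIXTURES)


def _gated(obs: Observed, identity: float, include_ns: bool) -> tuple[float, str]:
    """Apply the significance gate; returns (value, provenance tag)."""
    if obs.significant or include_ns:
        tag = "measured 7uM value" if obs.significant else "ns value included"
        return obs.value, tag
    return identity, f"ns (measured {obs.value}) -> identity"


def modification_set(compound: str, conc_uM: float = 7.0, *,
                     include_ns: bool = False,
                     ina_scale: str = "i_i0") -> ModificationSet:
    """Build the simulation ModificationSet for a compound.

    Only the 7 uM working concentration has a complete printed effect set;
    other concentrations go through :func:`effect_at_concentration` in
    ``hill`` mode.  ``ina_scale`` selects whether the INa conductance factor
    comes from the 0 mV current ratio I/I0 ("i_i0", the net block actually
    entered in the AP simulations) or the fitted Gmax ratio ("gmax").
    """
    fx = fixture(compound)
    if conc_uM == 0:
        return ModificationSet(compound, 0.0,
                               {c: ChannelModification(c) for c in CHANNELS},
                               {c: "concentration 0 -> identity" for c in CHANNELS})
    if conc_uM != 7.0:
        channels = {c: effect_at_concentration(compound, c, conc_uM, mode="hill",
                                               include_ns=include_ns,
                                               ina_scale=ina_scale)
                    for c in CHANNELS}
        prov = {c: f"Hill interpolation at {conc_uM} uM" for c in CHANNELS}
        return ModificationSet(compound, conc_uM, channels, prov)

    channels = {}
    prov = {}
    dv, tag_dv = _gated(fx.iks_dv05, 0.0, include_ns)
    g, tag_g = _gated(fx.iks_gmax, 1.0, include_ns)
    channels["IKs"] = ChannelModification("IKs", dv05_act=dv, g_factor=g)
    prov["IKs"] = f"dV05: {tag_dv}; Gmax: {tag_g}"

    dv, tag_dv = _gated(fx.ical_dv05_inact, 0.0, include_ns)
    g, tag_g = _gated(fx.ical_gmax, 1.0, include_ns)
    channels["ICaL"] = ChannelModification("ICaL", dv05_inact=dv, g_factor=g)
    prov["ICaL"] = f"dV05_inact: {tag_dv}; Gmax: {tag_g}"

    dv, tag_dv = _gated(fx.ina_dv05_inact, 0.0, include_ns)
    if ina_scale == "i_i0":
        g, tag_g = _gated(fx.hill["INa"].i_i0_7uM, 1.0, include_ns)
        tag_g = "I/I0 at 0 mV: " + tag_g
    elif ina_scale == "gmax":
        g, tag_g = _gated(fx.ina_gmax, 1.0, include_ns)
    else:
        raise ValueError("ina_scale must be 'i_i0' or 'gmax'")
    channels["INa"] = ChannelModification("INa", dv05_inact=dv, g_factor=g)
    prov["INa"] = f"dV05_inact: {tag_dv}; g: {tag_g}"
    return ModificationSet(compound, conc_uM, channels, prov)


def fixture(compound: str) -> CompoundFixture:
    try:
        return FIXTURES[compound]
    except KeyError:
        raise KeyError(f"unknown compound {compound!r}; "
                       f"known: {', '.join(COMPOUNDS)}") from None


# ---------------------------------------------------------------------------
# concentration dependence
# ---------------------------------------------------------------------------

def _hill_frac(conc: float, km: float, n: float = 1.0) -> float:
    """Fractional saturation c^n / (Km^n + c^n); 0 at c = 0."""
    if conc == 0:
        return 0.0
    return 1.0 / (1.0 + (km / conc) ** n)


def _km_for(fx: CompoundFixture, channel: str) -> float:
    h = fx.hill[channel]
    if h.km_uM is None:
        return KM_ABOVE_RANGE_UM
    return h.km_uM


ANCHOR_UM = 7.0


def _solve_saturation(value_7uM: float, identity: float, km: float,
                      floor: float | None = None) -> tuple[float, float]:
    """(saturating value, Hill n) passing through the 7 uM anchor.

    Starts from n = 1; when that would extrapolate past a physical floor
    (e.g. current ratios below full block), the saturation is pinned to the
    floor and n is solved instead, keeping the anchor exact.
    """
    f7 = _hill_frac(ANCHOR_UM, km)
    sat = identity + (value_7uM - identity) / f7
    if floor is None or sat >= floor or value_7uM == identity:
        return sat, 1.0
    frac7 = (value_7uM - identity) / (floor - identity)
    if not 0.0 < frac7 < 1.0 or km == ANCHOR_UM:
        return floor, 1.0
    n = math.log(1.0 / frac7 - 1.0) / math.log(km / ANCHOR_UM)
    return floor, n


def _scaled_effect(value_7uM: float, identity: float, conc: float,
                   km: float, floor: float | None = None) -> float:
    """Hill concentration dependence anchored at the 7 uM value."""
    sat, n = _solve_saturation(value_7uM, identity, km, floor)
    return identity + (sat - identity) * _hill_frac(conc, km, n)


def effect_at_concentration(compound: str, channel: str, conc_uM: float,
                            mode: str = "nearest", *,
                            include_ns: bool = False,
                            ina_scale: str = "i_i0") -> ChannelModification:
    """ChannelModification for a compound/channel at a concentration.

    ``nearest`` returns printed values at a tested concentration (only 0 and
    7 uM carry complete printed sets; anything else is an error rather than a
    silent extrapolation).  ``hill`` evaluates the fitted concentration
    dependence anchored at the 7 uM values with the channel's Table-level Km.
    """
    if conc_uM < 0:
        raise ValueError("concentration must be non-negative")
    if channel not in CHANNELS:
        raise KeyError(f"unknown channel {channel!r}")
    if conc_uM == 0:
        return ChannelModification(channel)
    if mode == "nearest":
        if conc_uM != 7.0:
            raise ValueError(
                f"no complete printed effect set at {conc_uM} uM; tested "
                "working concentration is 7 uM (use mode='hill' to "
                "interpolate)")
        return modification_set(compound, 7.0, include_ns=include_ns,
                                ina_scale=ina_scale).channels[channel]
    if mode != "hill":
        raise ValueError("mode must be 'nearest' or 'hill'")

    ref = modification_set(compound, 7.0, include_ns=include_ns,
                           ina_scale=ina_scale).channels[channel]
    km = _km_for(fixture(compound), channel)
    return ChannelModification(
        channel,
        dv05_act=_scaled_effect(ref.dv05_act, 0.0, conc_uM, km),
        dv05_inact=_scaled_effect(ref.dv05_inact, 0.0, conc_uM, km),
        g_factor=_scaled_effect(ref.g_factor, 1.0, conc_uM, km, floor=0.0),
    )


def dose_truth(compound: str, channel: str) -> dict:
    """Generating-truth dose profiles for the synthetic TEVC module.

    Hill parameterizations of dV05(c), gmax_factor(c) and the 0 mV current
    ratio I/I0(c), anchored exactly at the printed 7 uM values (flat where
    the 7 uM effect was non-significant).  The conductance and current-ratio
    saturations are floored at full block, steepening n instead of letting
    the curve extrapolate to negative currents.
    """
    fx = fixture(compound)
    km = _km_for(fx, channel)
    if channel == "IKs":
        dv_obs, g_obs = fx.iks_dv05, fx.iks_gmax
    elif channel == "ICaL":
        dv_obs, g_obs = fx.ical_dv05_inact, fx.ical_gmax
    else:
        dv_obs, g_obs = fx.ina_dv05_inact, fx.ina_gmax
    dv7 = dv_obs.value if dv_obs.significant else 0.0
    g7 = g_obs.value if g_obs.significant else 1.0
    ratio7 = fx.hill[channel].i_i0_7uM.value
    dv_sat, dv_n = _solve_saturation(dv7, 0.0, km)
    g_sat, g_n = _solve_saturation(g7, 1.0, km, floor=0.0)
    r_sat, r_n = _solve_saturation(ratio7, 1.0, km, floor=0.0)
    return {
        "km_uM": km,
        "dv05_sat_mV": dv_sat, "dv05_n": dv_n,
        "gmax_sat": g_sat, "gmax_n": g_n,
        "ratio_A": r_sat - 1.0, "ratio_n": r_n,
    }


def hill_ratio_truth(compound: str, channel: str, conc_uM: float) -> float:
    """Generating-truth I/I0 at 0 mV from the Table-level Hill summary."""
    tr = dose_truth(compound, channel)
    return 1.0 + tr["ratio_A"] * _hill_frac(conc_uM, tr["km_uM"],
                                            tr["ratio_n"])


# ---------------------------------------------------------------------------
# closed-form single-channel recapitulation
# ---------------------------------------------------------------------------

def predict_clamp_response(params, mod: ChannelModification,
                           voltages=None) -> dict:
    """Closed-form G-V / availability / I-V curves under a modification.

    ``params`` is a ChannelSimParams (see cardiopufa.synth); the activation
    Boltzmann is shifted by dv05_act, the availability Boltzmann by
    dv05_inact, and amplitudes scaled by g_factor -- the single-channel
    voltage-clamp recapitulation used to validate AP-model parameter changes.
    """
    import numpy as np

    if params.channel_id != mod.channel_id:
        raise ValueError(
            f"channel mismatch: params {params.channel_id}, mod {mod.channel_id}")
    if voltages is None:
        voltages = np.arange(-120.0, 61.0, 5.0)
    v = np.asarray(voltages, dtype=float)
    g = params.gmax * mod.g_factor
    act = 1.0 / (1.0 + np.exp((params.V05_act + mod.dv05_act - v) / params.s_act))
    out = {"voltages": v, "gv": g * act,
           "iv": g * act * (v - params.Erev),
           "v05_act": params.V05_act + mod.dv05_act}
    if params.V05_inact is not None:
        avail = 1.0 / (1.0 + np.exp(
            (v - (params.V05_inact + mod.dv05_inact)) / params.s_inact))
        out["availability"] = mod.g_factor * avail
        out["v05_inact"] = params.V05_inact + mod.dv05_inact
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def modset_to_dict(mods: ModificationSet) -> dict:
    return {
        "compound": mods.name,
        "concentration_uM": mods.concentration_uM,
        "channels": {
            cid: {"dv05_act_mV": m.dv05_act, "dv05_inact_mV": m.dv05_inact,
                  "g_factor": m.g_factor}
            for cid, m in mods.channels.items()
        },
        "provenance": dict(mods.provenance),
    }


def modset_from_dict(d: dict) -> ModificationSet:
    channels = {cid: ChannelModification(cid,
                                         dv05_act=c.get("dv05_act_mV", 0.0),
                                         dv05_inact=c.get("dv05_inact_mV", 0.0),
                                         g_factor=c.get("g_factor", 1.0))
                for cid, c in d["channels"].items()}
    return ModificationSet(d["compound"], d["concentration_uM"], channels,
                           d.get("provenance", {}))


def save_modset(mods: ModificationSet, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(modset_to_dict(mods), fh, sort_keys=False)


def load_modset(path) -> ModificationSet:
    import yaml
    with open(path) as fh:
        return modset_from_dict(yaml.safe_load(fh))
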