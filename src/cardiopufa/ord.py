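"""O'Hara–Rudy dynamic (ORd) human ventricular myocyte model.

Full 41-state formulation (endo/epi/M variants) with hooks for the channel
modifications studied in this package: voltage shifts of the IKs activation
gates, the INa/INaL inactivation gates and the ICaL inactivation gates, and
multiplicative scaling of the IKs, INa(+INaL), ICaL and IKr maximal
conductances.  Shifts act on steady-state (in)activation curves only; time
constants are untouched.

Units: mV, ms, mM, uA/uF.  The right-hand side is evaluated by a single
numba-compiled core that exposes, per state, either a plain derivative or a
(steady-state, time-constant) pair so the integrator can use Rush–Larsen
updates for the Hodgkin–Huxley-type gates.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
)
N_STATES = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

# parameter vector layout (post cell-type scaling; drug factors folded in)
PARAM_NAMES = (
    "GNa", "GNaL", "Gto", "PCa", "GKr", "GKs", "GK1", "Gncx", "Pnak",
    "GKb", "PNab", "PCab", "GpCa",
    "shift_iks_act", "shift_ina_inact", "shift_ical_inact",
    "celltype",  # 0 endo, 1 epi, 2 M
)
N_PARAMS = len(PARAM_NAMES)
PIDX = {name: i for i, name in enumerate(PARAM_NAMES)}

CELLTYPES = {"endo": 0, "epi": 1, "M": 2}

#: order of entries returned by :func:`currents`
CURRENT_NAMES = (
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs", "IK1",
    "INaCa_i", "INaCa_ss", "INaK", "INab", "IKb", "IpCa", "ICab",
)

# physical constants / geometry (cm, uF); the model definition uses pi = 3.14
_R = 8314.0
_T = 310.0
_F = 96485.0
_L = 0.01
_RAD = 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL

_NAO = 140.0
_CAO = 1.8
_KO = 5.4


def initial_state() -> np.ndarray:
    """Published resting initial conditions (shared across cell types)."""
    y = np.zeros(N_STATES)
    y[IDX["v"]] = -87.0
    y[IDX["nai"]] = 7.0
    y[IDX["nass"]] = 7.0
    y[IDX["ki"]] = 145.0
    y[IDX["kss"]] = 145.0
    y[IDX["cai"]] = 1.0e-4
    y[IDX["cass"]] = 1.0e-4
    y[IDX["cansr"]] = 1.2
    y[IDX["cajsr"]] = 1.2
    for g in ("hf", "hs", "j", "hsp", "jp", "hL", "hLp",
              "iF", "iS", "iFp", "iSp", "ff", "fs", "fcaf", "fcas", "jca",
              "ffp", "fcafp", "xk1"):
        y[IDX[g]] = 1.0
    return y


def base_params(celltype: str = "epi") -> np.ndarray:
    """Parameter vector with cell-type conductance scalings applied."""
    if celltype not in CELLTYPES:
        raise ValueError(f"unknown cell type {celltype!r}; expected one of {sorted(CELLTYPES)}")
    ct = CELLTYPES[celltype]
    p = np.zeros(N_PARAMS)
    p[PIDX["GNa"]] = 75.0
    p[PIDX["GNaL"]] = 0.0075
    p[PIDX["Gto"]] = 0.02
    p[PIDX["PCa"]] = 0.0001
    p[PIDX["GKr"]] = 0.046
    p[PIDX["GKs"]] = 0.0034
    p[PIDX["GK1"]] = 0.1908
    p[PIDX["Gncx"]] = 0.0008
    p[PIDX["Pnak"]] = 30.0
    p[PIDX["GKb"]] = 0.003
    p[PIDX["PNab"]] = 3.75e-10
    p[PIDX["PCab"]] = 2.5e-8
    p[PIDX["GpCa"]] = 0.0005
    if ct == 1:  # epicardial
        p[PIDX["GNaL"]] *= 0.6
        p[PIDX["Gto"]] *= 4.0
        p[PIDX["PCa"]] *= 1.2
        p[PIDX["GKr"]] *= 1.3
        p[PIDX["GKs"]] *= 1.4
        p[PIDX["GK1"]] *= 1.2
        p[PIDX["Gncx"]] *= 1.1
        p[PIDX["Pnak"]] *= 0.9
        p[PIDX["GKb"]] *= 0.6
    elif ct == 2:  # mid-myocardial
        p[PIDX["Gto"]] *= 4.0
        p[PIDX["PCa"]] *= 2.5
        p[PIDX["GKr"]] *= 0.8
        p[PIDX["GK1"]] *= 1.3
        p[PIDX["Gncx"]] *= 1.4
        p[PIDX["Pnak"]] *= 0.7
    p[PIDX["celltype"]] = float(ct)
    return p


@njit(cache=True)
def _core(y, p, ist, dy, inf, tau):  # noqa: C901 - the model is simply large
    """Fill dy (plain derivatives) and inf/tau (Rush-Larsen states).

    For indices with tau > 0 the integrator must use (inf, tau); their dy
    entry is also filled so the same core serves a generic ODE solver.
    Returns the 16 membrane currents for diagnostics.
    """
    v = y[0]
    nai = y[1]; nass = y[2]; ki = y[3]; kss = y[4]
    cai = y[5]; cass = y[6]; cansr = y[7]; cajsr = y[8]
    m = y[9]; hf = y[10]; hs = y[11]; jj = y[12]; hsp = y[13]; jp = y[14]
    mL = y[15]; hL = y[16]; hLp = y[17]
    a = y[18]; iF = y[19]; iS = y[20]; ap = y[21]; iFp = y[22]; iSp = y[23]
    d = y[24]; ff = y[25]; fs = y[26]; fcaf = y[27]; fcas = y[28]; jca = y[29]
    nca = y[30]; ffp = y[31]; fcafp = y[32]
    xrf = y[33]; xrs = y[34]; xs1 = y[35]; xs2 = y[36]; xk1 = y[37]
    Jrelnp = y[38]; Jrelp = y[39]; CaMKt = y[40]

    GNa = p[0]; GNaL = p[1]; Gto = p[2]; PCa = p[3]; GKr = p[4]; GKs = p[5]
    GK1 = p[6]; Gncx = p[7]; Pnak = p[8]; GKb = p[9]; PNab = p[10]
    PCab = p[11]; GpCa = p[12]
    sh_ks = p[13]; sh_na = p[14]; sh_cal = p[15]
    celltype = int(p[16])

    # CaMK
    KmCaMK = 0.15
    aCaMK = 0.05; bCaMK = 0.00068; CaMKo = 0.05; KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    dy[40] = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt
    fp_frac = 1.0 / (1.0 + KmCaMK / CaMKa)  # CaMK-phosphorylated fraction

    # reversal potentials
    ENa = (_R * _T / _F) * math.log(_NAO / nai)
    EK = (_R * _T / _F) * math.log(_KO / ki)
    PKNa = 0.01833
    EKs = (_R * _T / _F) * math.log((_KO + PKNa * _NAO) / (ki + PKNa * nai))
    vfrt = v * _F / (_R * _T)
    vffrt = v * _F * _F / (_R * _T)

    # --- INa (fast) -------------------------------------------------------
    vna = v - sh_na  # inactivation-shifted voltage
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77)
                + 8.552 * math.exp(-(v + 77.42) / 5.955))
    inf[9] = mss; tau[9] = tm
    hss = 1.0 / (1.0 + math.exp((vna + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285)
                 + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * math.exp((v + 5.730) / 56.66))
    Ahf = 0.99; Ahs = 1.0 - Ahf
    inf[10] = hss; tau[10] = thf
    inf[11] = hss; tau[11] = ths
    h = Ahf * hf + Ahs * hs
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * math.exp((v + 0.9941) / 38.45))
    inf[12] = jss; tau[12] = tj
    hssp = 1.0 / (1.0 + math.exp((vna + 89.1) / 6.086))
    inf[13] = hssp; tau[13] = 3.0 * ths
    hp = Ahf * hf + Ahs * hsp
    inf[14] = jss; tau[14] = 1.46 * tj
    INa = GNa * (v - ENa) * m ** 3 * ((1.0 - fp_frac) * h * jj + fp_frac * hp * jp)

    # --- INaL -------------------------------------------------------------
    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    inf[15] = mLss; tau[15] = tm
    hLss = 1.0 / (1.0 + math.exp((vna + 87.61) / 7.488))
    inf[16] = hLss; tau[16] = 200.0
    hLssp = 1.0 / (1.0 + math.exp((vna + 93.81) / 7.488))
    inf[17] = hLssp; tau[17] = 600.0
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fp_frac) * hL + fp_frac * hLp)

    # --- Ito --------------------------------------------------------------
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
    inf[18] = ass; tau[18] = ta
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    if celltype == 1:
        delta_epi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    tiF *= delta_epi; tiS *= delta_epi
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    inf[19] = iss; tau[19] = tiF
    inf[20] = iss; tau[20] = tiS
    i_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    inf[21] = assp; tau[21] = ta
    dti_develop = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89)
                                    + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    inf[22] = iss; tau[22] = dti_develop * dti_recover * tiF
    inf[23] = iss; tau[23] = dti_develop * dti_recover * tiS
    ip = AiF * iFp + AiS * iSp
    Ito = Gto * (v - EK) * ((1.0 - fp_frac) * a * i_gate + fp_frac * ap * ip)

    # --- ICaL / ICaNa / ICaK ---------------------------------------------
    vca = v - sh_cal
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    inf[24] = dss; tau[24] = td
    fss = 1.0 / (1.0 + math.exp((vca + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * math.exp((v + 5.0) / 6.0))
    Aff = 0.6; Afs = 1.0 - Aff
    inf[25] = fss; tau[25] = tff
    inf[26] = fss; tau[26] = tfs
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0)
                         + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0)
                           + 0.00012 * math.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    inf[27] = fcass; tau[27] = tfcaf
    inf[28] = fcass; tau[28] = tfcas
    fca = Afcaf * fcaf + Afcas * fcas
    inf[29] = fcass; tau[29] = 75.0
    inf[31] = fss; tau[31] = 2.5 * tff
    fpg = Aff * ffp + Afs * fs
    inf[32] = fcass; tau[32] = 2.5 * tfcaf
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002; k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)
    # d(nca)/dt = anca*k2n - nca*km2n : linear, expose as RL pair
    inf[30] = anca * k2n / km2n; tau[30] = 1.0 / km2n
    u = 2.0 * vfrt
    eu = math.exp(u)
    den = eu - 1.0
    if abs(den) < 1.0e-10:
        den = u if u != 0.0 else 1.0e-10
    PhiCaL = 4.0 * vffrt * (cass * eu - 0.341 * _CAO) / den
    e1 = math.exp(vfrt)
    den1 = e1 - 1.0
    if abs(den1) < 1.0e-10:
        den1 = vfrt if vfrt != 0.0 else 1.0e-10
    PhiCaNa = vffrt * (0.75 * nass * e1 - 0.75 * _NAO) / den1
    PhiCaK = vffrt * (0.75 * kss * e1 - 0.75 * _KO) / den1
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa; PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap; PCaKp = 3.574e-4 * PCap
    gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = d * (fpg * (1.0 - nca) + jca * fcap * nca)
    ICaL = (1.0 - fp_frac) * PCa * PhiCaL * gate_np + fp_frac * PCap * PhiCaL * gate_p
    ICaNa = (1.0 - fp_frac) * PCaNa * PhiCaNa * gate_np + fp_frac * PCaNap * PhiCaNa * gate_p
    ICaK = (1.0 - fp_frac) * PCaK * PhiCaK * gate_np + fp_frac * PCaKp * PhiCaK * gate_p

    # --- IKr --------------------------------------------------------------
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    inf[33] = xrss; tau[33] = txrf
    inf[34] = xrss; tau[34] = txrs
    xr = Axrf * xrf + Axrs * xrs
    rkr = (1.0 / (1.0 + math.exp((v + 55.0) / 75.0))
           * 1.0 / (1.0 + math.exp((v - 10.0) / 30.0)))
    IKr = GKr * math.sqrt(_KO / 5.4) * xr * rkr * (v - EK)

    # --- IKs --------------------------------------------------------------
    vks = v - sh_ks  # activation-shifted voltage
    xs1ss = 1.0 / (1.0 + math.exp(-(vks + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                          + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    inf[35] = xs1ss; tau[35] = txs1
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                  + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    inf[36] = xs2ss; tau[36] = txs2
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

    # --- IK1 --------------------------------------------------------------
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * _KO + 144.59)
                                  / (1.5692 * _KO + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36) + math.exp((v + 236.8) / 69.33))
    inf[37] = xk1ss; tau[37] = txk1
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * _KO) / 9.493))
    IK1 = GK1 * math.sqrt(_KO) * rk1 * xk1 * (v - EK)

    # --- INaCa (myoplasmic and subspace) ---------------------------------
    kna1 = 15.0; kna2 = 5.0; kna3 = 88.12
    kasymm = 12.5; wna = 6.0e4; wca = 6.0e4; wnaca = 5.0e3
    kcaon = 1.5e6; kcaoff = 5.0e3
    qna = 0.5224; qca = 0.1670
    hca = math.exp(qca * vfrt)
    hna = math.exp(qna * vfrt)
    zca = 2.0; zna = 1.0

    # myoplasmic exchanger
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + _NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = _NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + _NAO / kna1 * (1.0 + _NAO / kna2)
    h11 = _NAO * _NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * _CAO * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    KmCaAct = 150.0e-6
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # subspace exchanger
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k1 = h12 * _CAO * kcaon
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # --- INaK -------------------------------------------------------------
    k1p = 949.5; k1m = 182.4; k2p = 687.2; k2m = 39.4
    k3p_ = 1899.0; k3m = 79300.0; k4p_ = 639.0; k4m = 40.0
    Knai0 = 9.073; Knao0 = 27.78; delta = -0.1550
    Knai = Knai0 * math.exp(delta * vfrt / 3.0)
    Knao = Knao0 * math.exp((1.0 - delta) * vfrt / 3.0)
    Kki = 0.5; Kko = 0.3582
    MgADP = 0.05; MgATP = 9.8; Kmgatp = 1.698e-7
    H = 1.0e-7; eP = 4.2; Khp = 1.698e-7; Knap = 224.0; Kxkur = 292.0
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3
          / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (_NAO / Knao) ** 3
          / ((1.0 + _NAO / Knao) ** 3 + (1.0 + _KO / Kko) ** 2 - 1.0))
    a3 = (k3p_ * (_KO / Kko) ** 2
          / ((1.0 + _NAO / Knao) ** 3 + (1.0 + _KO / Kko) ** 2 - 1.0))
    b3 = k3m * P * H / (1.0 + MgATP / Kmgatp)
    a4 = k4p_ * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2
          / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b1 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    INaK = Pnak * (zna * JnakNa + zk * JnakK)

    # --- background / minor currents -------------------------------------
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    IKb = GKb * xkb * (v - EK)
    INab = PNab * vffrt * (nai * e1 - _NAO) / den1
    ICab = PCab * 4.0 * vffrt * (cai * eu - 0.341 * _CAO) / den
    IpCa = GpCa * cai / (0.0005 + cai)

    # --- diffusion / SR fluxes -------------------------------------------
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    if celltype == 2:
        Jrel_inf *= 1.7
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    inf[38] = Jrel_inf; tau[38] = tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    if celltype == 2:
        Jrel_infp *= 1.7
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    inf[39] = Jrel_infp; tau[39] = tau_relp
    Jrel = (1.0 - fp_frac) * Jrelnp + fp_frac * Jrelp

    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    if celltype == 1:
        Jupnp *= 1.3
        Jupp *= 1.3
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fp_frac) * Jupnp + fp_frac * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # --- concentration and voltage derivatives ---------------------------
    dy[1] = (-(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * _ACAP
             / (_F * _VMYO) + JdiffNa * _VSS / _VMYO)
    dy[2] = -(ICaNa + 3.0 * INaCa_ss) * _ACAP / (_F * _VSS) - JdiffNa
    dy[3] = (-(Ito + IKr + IKs + IK1 + IKb + ist - 2.0 * INaK) * _ACAP
             / (_F * _VMYO) + JdiffK * _VSS / _VMYO)
    dy[4] = -ICaK * _ACAP / (_F * _VSS) - JdiffK

    cmdnmax = 0.05
    if celltype == 1:
        cmdnmax *= 1.3
    kmcmdn = 0.00238; trpnmax = 0.07; kmtrpn = 0.0005
    BSRmax = 0.047; KmBSR = 0.00087; BSLmax = 1.124; KmBSL = 0.0087
    csqnmax = 10.0; kmcsqn = 0.8
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
                  + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    dy[5] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * _ACAP / (2.0 * _F * _VMYO)
                    - Jup * _VNSR / _VMYO + Jdiff * _VSS / _VMYO)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    dy[6] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * _ACAP / (2.0 * _F * _VSS)
                     + Jrel * _VJSR / _VSS - Jdiff)
    dy[7] = Jup - Jtr * _VJSR / _VNSR
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dy[8] = Bcajsr * (Jtr - Jrel)

    dy[0] = -(INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
              + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + ist)

    return (INa, INaL, Ito, ICaL, ICaNa, ICaK, IKr, IKs, IK1,
            INaCa_i, INaCa_ss, INaK, INab, IKb, IpCa, ICab)


@njit(cache=True)
def derivs(y, p, ist):
    """Full derivative vector (for generic / reference ODE solvers)."""
    dy = np.zeros(N_STATES)
    inf = np.zeros(N_STATES)
    tau = np.zeros(N_STATES)
    _core(y, p, ist, dy, inf, tau)
    for i in range(N_STATES):
        if tau[i] > 0.0:
            dy[i] = (inf[i] - y[i]) / tau[i]
    return dy


@njit(cache=True)
def step_rl(y, p, ist, dt, dy, inf, tau):
    """Advance state in place by one hybrid Rush-Larsen / Euler step."""
    _core(y, p, ist, dy, inf, tau)
    for i in range(N_STATES):
        if tau[i] > 0.0:
            y[i] = inf[i] + (y[i] - inf[i]) * math.exp(-dt / tau[i])
        else:
            y[i] += dt * dy[i]


def currents(y: np.ndarray, p: np.ndarray) -> dict:
    """Instantaneous membrane currents (uA/uF) at a frozen state."""
    dy = np.zeros(N_STATES)
    inf = np.zeros(N_STATES)
    tau = np.zeros(N_STATES)
    vals = _core(np.asarray(y, dtype=float), np.asarray(p, dtype=float),
                 0.0, dy, inf, tau)
    return dict(zip(CURRENT_NAMES, vals))


def rhs_numpy(t: float, y: np.ndarray, p: np.ndarray, ist: float = 0.0) -> np.ndarray:
    """scipy-compatible right-hand side wrapper."""
    return derivs(np.asarray(y, dtype=float), p, ist)
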