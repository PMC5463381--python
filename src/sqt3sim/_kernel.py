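"""Numba-compiled numerical core.

Single-cell ionic right-hand side (ten Tusscher-Panfilov 2006 human
ventricular model + late sodium current, variant inward rectifier), and
explicit forward-Euler / Rush-Larsen integrators for a single cell, a 1D
cable and a 2D sheet.

State vector layout (length NSTATE):
    0  V      membrane voltage (mV)
    1  m      I_Na activation
    2  h      I_Na fast inactivation
    3  j      I_Na slow inactivation
    4  xr1    I_Kr activation
    5  xr2    I_Kr inactivation
    6  xs     I_Ks activation
    7  r      I_to activation
    8  s      I_to inactivation
    9  d      I_CaL activation
    10 f      I_CaL voltage inactivation
    11 f2     I_CaL voltage inactivation (slow)
    12 fcass  I_CaL calcium-dependent inactivation
    13 rr     ryanodine-receptor closed fraction
    14 ml     I_NaL activation
    15 hl     I_NaL inactivation
    16 cai    cytosolic Ca2+ (mM)
    17 casr   SR Ca2+ (mM)
    18 cass   subspace Ca2+ (mM)
    19 nai    intracellular Na+ (mM)
    20 ki     intracellular K+ (mM)

Parameter vector layout (length NPARAM):
    0  g_na (nS/pF)      1  g_cal (cm3 uF-1 s-1)   2  g_kr     3  g_ks
    4  g_to              5  g_k1                   6  g_nal    7  p_nak
    8  k_naca            9  g_bna                  10 g_bca    11 g_pk
    12 g_pca             13 k_o (mM)               14 na_o     15 ca_o
    16 ik1_scale (variant multiplicative scale on x_K1inf)
    17 ik1_shift (variant rightward voltage shift of the rectification
       cutoff, mV)
    18 endo_s  (1.0 -> endocardial I_to inactivation kinetics)
    19 ik1_slope (rectification cutoff steepness, mV-1; baseline 0.1)

Current vector layout (length NCURRENT), densities in pA/pF:
    0 I_Na  1 I_NaL  2 I_CaL  3 I_to  4 I_Kr  5 I_Ks  6 I_K1
    7 I_NaCa  8 I_NaK  9 I_pCa  10 I_pK  11 I_bNa  12 I_bCa  13 I_ion
"""

import math

import numpy as np
from numba import njit

NSTATE = 21
NPARAM = 20
NCURRENT = 14

# physical constants
RGAS = 8314.472      # mJ mol-1 K-1
TEMP = 310.0         # K
FARADAY = 96485.3415  # C mol-1
RTONF = RGAS * TEMP / FARADAY
FONRT = 1.0 / RTONF

# cell geometry / capacitance used in flux conversions
CAP = 0.185          # uF
VOL_C = 0.016404     # cytosolic volume scaling
VOL_SR = 0.001094
VOL_SS = 0.00005468

V_DIVERGED = 300.0   # |V| beyond this -> instability


@njit(cache=True)
def xk1_inf(u, shift, slope):
    """Inward-rectification factor at u = V - E_K.

    ``shift`` (mV) moves the outward-limb cutoff exponential rightward,
    displacing the peak of the outward current toward more positive
    voltages; ``slope`` (mV-1, baseline 0.1) sets the steepness of that
    cutoff, a shallower value widening the voltage range over which the
    channel passes outward current.  Neither alters the behaviour near the
    reversal potential, so the gain-of-function variant phenotype is
    reproduced without moving the reversal potential.
    """
    a = 0.1 / (1.0 + math.exp(0.06 * (u - 200.0)))
    b = (3.0 * math.exp(0.0002 * (u + 100.0)) + math.exp(slope * (u - 10.0 - shift))) / (
        1.0 + math.exp(-0.5 * u)
    )
    return a / (a + b)


@njit(cache=True)
def ik1_density(v, ki, ko, g_k1, scale, shift, slope):
    """Variant inward-rectifier current density (pA/pF)."""
    ek = RTONF * math.log(ko / ki)
    return (
        g_k1
        * scale
        * math.sqrt(ko / 5.4)
        * xk1_inf(v - ek, shift, slope)
        * (v - ek)
    )


@njit(cache=True)
def compute_currents(S, P, out):
    """All membrane current densities at state S; out has length NCURRENT."""
    v = S[0]
    m = S[1]
    h = S[2]
    j = S[3]
    xr1 = S[4]
    xr2 = S[5]
    xs = S[6]
    r = S[7]
    s = S[8]
    d = S[9]
    f = S[10]
    f2 = S[11]
    fcass = S[12]
    ml = S[14]
    hl = S[15]
    cai = S[16]
    cass = S[18]
    nai = S[19]
    ki = S[20]

    ko = P[13]
    nao = P[14]
    cao = P[15]

    ek = RTONF * math.log(ko / ki)
    ena = RTONF * math.log(nao / nai)
    eks = RTONF * math.log((ko + 0.03 * nao) / (ki + 0.03 * nai))
    eca = 0.5 * RTONF * math.log(cao / cai)

    ina = P[0] * m * m * m * h * j * (v - ena)
    inal = P[6] * ml * hl * (v - ena)

    z = 2.0 * (v - 15.0) * FONRT
    if abs(v - 15.0) < 1e-6:
        ical = P[1] * d * f * f2 * fcass * 2.0 * FARADAY * (0.25 * cass - cao)
    else:
        ez = math.exp(z)
        ical = (
            P[1]
            * d
            * f
            * f2
            * fcass
            * 4.0
            * (v - 15.0)
            * FARADAY
            * FONRT
            * (0.25 * cass * ez - cao)
            / (ez - 1.0)
        )

    ito = P[4] * r * s * (v - ek)
    ikr = P[2] * math.sqrt(ko / 5.4) * xr1 * xr2 * (v - ek)
    iks = P[3] * xs * xs * (v - eks)
    ik1 = P[5] * P[16] * math.sqrt(ko / 5.4) * xk1_inf(v - ek, P[17], P[19]) * (v - ek)

    evf = math.exp(0.35 * v * FONRT)
    evfm = math.exp(-0.65 * v * FONRT)
    inaca = (
        P[8]
        * (evf * nai * nai * nai * cao - evfm * nao * nao * nao * cai * 2.5)
        / (
            (87.5 ** 3 + nao ** 3)
            * (1.38 + cao)
            * (1.0 + 0.1 * evfm)
        )
    )

    inak = (
        P[7]
        * ko
        * nai
        / ((ko + 1.0) * (nai + 40.0))
        / (1.0 + 0.1245 * math.exp(-0.1 * v * FONRT) + 0.0353 * math.exp(-v * FONRT))
    )

    ipca = P[12] * cai / (0.0005 + cai)
    ipk = P[11] * (v - ek) / (1.0 + math.exp((25.0 - v) / 5.98))
    ibna = P[9] * (v - ena)
    ibca = P[10] * (v - eca)

    out[0] = ina
    out[1] = inal
    out[2] = ical
    out[3] = ito
    out[4] = ikr
    out[5] = iks
    out[6] = ik1
    out[7] = inaca
    out[8] = inak
    out[9] = ipca
    out[10] = ipk
    out[11] = ibna
    out[12] = ibca
    out[13] = (
        ina + inal + ical + ito + ikr + iks + ik1
        + inaca + inak + ipca + ipk + ibna + ibca
    )
    return out[13]


@njit(cache=True)
def step_node(S, P, istim, dt, rush_larsen):
    """Advance gates and concentrations of one node by dt; return reaction dV/dt.

    Gates use the Rush-Larsen exponential update (or forward Euler when
    rush_larsen is False); concentrations and the RyR gate use forward Euler.
    The caller advances V (adding any diffusion term).
    """
    v = S[0]
    cai = S[16]
    casr = S[17]
    cass = S[18]
    nai = S[19]
    ki = S[20]

    ko = P[13]
    nao = P[14]
    cao = P[15]

    ek = RTONF * math.log(ko / ki)
    ena = RTONF * math.log(nao / nai)
    eks = RTONF * math.log((ko + 0.03 * nao) / (ki + 0.03 * nai))
    eca = 0.5 * RTONF * math.log(cao / cai)

    # ---- currents (same expressions as compute_currents, inlined) ----
    ina = P[0] * S[1] * S[1] * S[1] * S[2] * S[3] * (v - ena)
    inal = P[6] * S[14] * S[15] * (v - ena)

    z = 2.0 * (v - 15.0) * FONRT
    if abs(v - 15.0) < 1e-6:
        ical = P[1] * S[9] * S[10] * S[11] * S[12] * 2.0 * FARADAY * (
            0.25 * cass - cao
        )
    else:
        ez = math.exp(z)
        ical = (
            P[1]
            * S[9]
            * S[10]
            * S[11]
            * S[12]
            * 4.0
            * (v - 15.0)
            * FARADAY
            * FONRT
            * (0.25 * cass * ez - cao)
            / (ez - 1.0)
        )

    ito = P[4] * S[7] * S[8] * (v - ek)
    ikr = P[2] * math.sqrt(ko / 5.4) * S[4] * S[5] * (v - ek)
    iks = P[3] * S[6] * S[6] * (v - eks)
    ik1 = P[5] * P[16] * math.sqrt(ko / 5.4) * xk1_inf(v - ek, P[17], P[19]) * (v - ek)

    evf = math.exp(0.35 * v * FONRT)
    evfm = math.exp(-0.65 * v * FONRT)
    inaca = (
        P[8]
        * (evf * nai * nai * nai * cao - evfm * nao * nao * nao * cai * 2.5)
        / ((87.5 ** 3 + nao ** 3) * (1.38 + cao) * (1.0 + 0.1 * evfm))
    )
    inak = (
        P[7]
        * ko
        * nai
        / ((ko + 1.0) * (nai + 40.0))
        / (1.0 + 0.1245 * math.exp(-0.1 * v * FONRT) + 0.0353 * math.exp(-v * FONRT))
    )
    ipca = P[12] * cai / (0.0005 + cai)
    ipk = P[11] * (v - ek) / (1.0 + math.exp((25.0 - v) / 5.98))
    ibna = P[9] * (v - ena)
    ibca = P[10] * (v - eca)

    iion = (
        ina + inal + ical + ito + ikr + iks + ik1
        + inaca + inak + ipca + ipk + ibna + ibca
    )

    # ---- gate kinetics ----
    # I_Na
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (
        1.0 + math.exp((v - 50.0) / 200.0)
    )
    tau_m = am * bm

    h_inf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    tau_h = 1.0 / (ah + bh)

    j_inf = h_inf
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        aj = (
            (-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        bj = 0.02424 * math.exp(-0.01052 * v) / (
            1.0 + math.exp(-0.1378 * (v + 40.14))
        )
    tau_j = 1.0 / (aj + bj)

    # I_Kr
    xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    tau_xr1 = axr1 * bxr1

    xr2_inf = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    tau_xr2 = axr2 * bxr2

    # I_Ks
    xs_inf = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
    tau_xs = axs * bxs + 80.0

    # I_to
    r_inf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    tau_r = 9.5 * math.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
    if P[18] > 0.5:  # endocardial s-gate
        s_inf = 1.0 / (1.0 + math.exp((v + 28.0) / 5.0))
        tau_s = 1000.0 * math.exp(-(v + 67.0) ** 2 / 1000.0) + 8.0
    else:
        s_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
        tau_s = (
            85.0 * math.exp(-(v + 45.0) ** 2 / 320.0)
            + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0))
            + 3.0
        )

    # I_CaL
    d_inf = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    tau_d = ad * bd + gd

    f_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tau_f = (
        1102.5 * math.exp(-(v + 27.0) ** 2 / 225.0)
        + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
        + 180.0 / (1.0 + math.exp((v + 30.0) / 10.0))
        + 20.0
    )

    f2_inf = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
    tau_f2 = (
        562.0 * math.exp(-(v + 27.0) ** 2 / 240.0)
        + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
        + 80.0 / (1.0 + math.exp((v + 30.0) / 10.0))
    )

    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

    # I_NaL
    ml_inf = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    tau_ml = 1.0 / (
        6.765 * math.exp((v + 11.64) / 34.77)
        + 8.552 * math.exp(-(v + 77.42) / 5.955)
    )
    hl_inf = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    tau_hl = 200.0

    if rush_larsen:
        S[1] = m_inf - (m_inf - S[1]) * math.exp(-dt / tau_m)
        S[2] = h_inf - (h_inf - S[2]) * math.exp(-dt / tau_h)
        S[3] = j_inf - (j_inf - S[3]) * math.exp(-dt / tau_j)
        S[4] = xr1_inf - (xr1_inf - S[4]) * math.exp(-dt / tau_xr1)
        S[5] = xr2_inf - (xr2_inf - S[5]) * math.exp(-dt / tau_xr2)
        S[6] = xs_inf - (xs_inf - S[6]) * math.exp(-dt / tau_xs)
        S[7] = r_inf - (r_inf - S[7]) * math.exp(-dt / tau_r)
        S[8] = s_inf - (s_inf - S[8]) * math.exp(-dt / tau_s)
        S[9] = d_inf - (d_inf - S[9]) * math.exp(-dt / tau_d)
        S[10] = f_inf - (f_inf - S[10]) * math.exp(-dt / tau_f)
        S[11] = f2_inf - (f2_inf - S[11]) * math.exp(-dt / tau_f2)
        S[12] = fcass_inf - (fcass_inf - S[12]) * math.exp(-dt / tau_fcass)
        S[14] = ml_inf - (ml_inf - S[14]) * math.exp(-dt / tau_ml)
        S[15] = hl_inf - (hl_inf - S[15]) * math.exp(-dt / tau_hl)
    else:
        S[1] += dt * (m_inf - S[1]) / tau_m
        S[2] += dt * (h_inf - S[2]) / tau_h
        S[3] += dt * (j_inf - S[3]) / tau_j
        S[4] += dt * (xr1_inf - S[4]) / tau_xr1
        S[5] += dt * (xr2_inf - S[5]) / tau_xr2
        S[6] += dt * (xs_inf - S[6]) / tau_xs
        S[7] += dt * (r_inf - S[7]) / tau_r
        S[8] += dt * (s_inf - S[8]) / tau_s
        S[9] += dt * (d_inf - S[9]) / tau_d
        S[10] += dt * (f_inf - S[10]) / tau_f
        S[11] += dt * (f2_inf - S[11]) / tau_f2
        S[12] += dt * (fcass_inf - S[12]) / tau_fcass
        S[14] += dt * (ml_inf - S[14]) / tau_ml
        S[15] += dt * (hl_inf - S[15]) / tau_hl

    # ---- calcium handling ----
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) ** 2)
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    S[13] += dt * (0.005 * (1.0 - S[13]) - k2 * cass * S[13])
    o_ryr = k1 * cass * cass * S[13] / (0.06 + k1 * cass * cass)
    irel = 0.102 * o_ryr * (casr - cass)
    ileak = 0.00036 * (casr - cai)
    iup = 0.006375 / (1.0 + (0.00025 / cai) ** 2)
    ixfer = 0.0038 * (cass - cai)

    bufc = 1.0 / (1.0 + 0.2 * 0.001 / (cai + 0.001) ** 2)
    S[16] += dt * bufc * (
        (ileak - iup) * VOL_SR / VOL_C
        + ixfer
        - (ibca + ipca - 2.0 * inaca) * CAP / (2.0 * VOL_C * FARADAY)
    )
    bufsr = 1.0 / (1.0 + 10.0 * 0.3 / (casr + 0.3) ** 2)
    S[17] += dt * bufsr * (iup - ileak - irel)
    bufss = 1.0 / (1.0 + 0.4 * 0.00025 / (cass + 0.00025) ** 2)
    S[18] += dt * bufss * (
        -ical * CAP / (2.0 * VOL_SS * FARADAY)
        + irel * VOL_SR / VOL_SS
        - ixfer * VOL_C / VOL_SS
    )

    S[19] += dt * (
        -(ina + inal + ibna + 3.0 * inak + 3.0 * inaca) * CAP / (VOL_C * FARADAY)
    )
    S[20] += dt * (
        -(istim + ik1 + ito + ikr + iks - 2.0 * inak + ipk) * CAP / (VOL_C * FARADAY)
    )

    return -(iion + istim)




# ---------------------------------------------------------------------------
# Tabulated voltage-dependent factors for the tissue integrators.
#
# Gate steady states, their Rush-Larsen factors exp(-dt/tau(V)) and the
# voltage-only current factors are sampled on a fine uniform grid and
# linearly interpolated inside the PDE loops; the grid is fine enough
# (0.02 mV) that the interpolation error is far below the spatial
# discretization error.  The inward-rectifier factor is NOT tabulated (it
# depends on V - E_K and the per-node variant constants) and neither are
# the Nernst potentials.
# ---------------------------------------------------------------------------

TAB_V_MIN = -110.0
TAB_V_MAX = 70.0
TAB_DV = 0.02
TAB_N = int(round((TAB_V_MAX - TAB_V_MIN) / TAB_DV)) + 1
TAB_NCOL = 34

_TABLE_CACHE = {}


def rate_table(dt):
    """(TAB_N, TAB_NCOL) lookup table for time step dt (cached)."""
    key = round(float(dt), 12)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = _build_rate_table(float(dt))
    return _TABLE_CACHE[key]


def _build_rate_table(dt):
    v = TAB_V_MIN + TAB_DV * np.arange(TAB_N)
    T = np.empty((TAB_N, TAB_NCOL))
    exp = np.exp

    m_inf = 1.0 / (1.0 + exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + exp((v - 50.0) / 200.0))
    tau_m = am * bm

    h_inf = 1.0 / (1.0 + exp((v + 71.55) / 7.43)) ** 2
    hi = v >= -40.0
    ah = np.where(hi, 0.0, 0.057 * exp(-(v + 80.0) / 6.8))
    bh = np.where(
        hi,
        0.77 / (0.13 * (1.0 + exp(-(v + 10.66) / 11.1))),
        2.7 * exp(0.079 * v) + 3.1e5 * exp(0.3485 * v),
    )
    tau_h = 1.0 / (ah + bh)

    aj = np.where(
        hi,
        0.0,
        (-2.5428e4 * exp(0.2444 * v) - 6.948e-6 * exp(-0.04391 * v))
        * (v + 37.78)
        / (1.0 + exp(0.311 * (v + 79.23))),
    )
    bj = np.where(
        hi,
        0.6 * exp(0.057 * v) / (1.0 + exp(-0.1 * (v + 32.0))),
        0.02424 * exp(-0.01052 * v) / (1.0 + exp(-0.1378 * (v + 40.14))),
    )
    tau_j = 1.0 / (aj + bj)

    xr1_inf = 1.0 / (1.0 + exp((-26.0 - v) / 7.0))
    tau_xr1 = (450.0 / (1.0 + exp((-45.0 - v) / 10.0))) * (
        6.0 / (1.0 + exp((v + 30.0) / 11.5))
    )
    xr2_inf = 1.0 / (1.0 + exp((v + 88.0) / 24.0))
    tau_xr2 = (3.0 / (1.0 + exp((-60.0 - v) / 20.0))) * (
        1.12 / (1.0 + exp((v - 60.0) / 20.0))
    )
    xs_inf = 1.0 / (1.0 + exp((-5.0 - v) / 14.0))
    tau_xs = (1400.0 / np.sqrt(1.0 + exp((5.0 - v) / 6.0))) * (
        1.0 / (1.0 + exp((v - 35.0) / 15.0))
    ) + 80.0

    r_inf = 1.0 / (1.0 + exp((20.0 - v) / 6.0))
    tau_r = 9.5 * exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    s_inf_epi = 1.0 / (1.0 + exp((v + 20.0) / 5.0))
    tau_s_epi = (
        85.0 * exp(-((v + 45.0) ** 2) / 320.0)
        + 5.0 / (1.0 + exp((v - 20.0) / 5.0))
        + 3.0
    )
    s_inf_endo = 1.0 / (1.0 + exp((v + 28.0) / 5.0))
    tau_s_endo = 1000.0 * exp(-((v + 67.0) ** 2) / 1000.0) + 8.0

    d_inf = 1.0 / (1.0 + exp((-8.0 - v) / 7.5))
    tau_d = (1.4 / (1.0 + exp((-35.0 - v) / 13.0)) + 0.25) * (
        1.4 / (1.0 + exp((v + 5.0) / 5.0))
    ) + 1.0 / (1.0 + exp((50.0 - v) / 20.0))
    f_inf = 1.0 / (1.0 + exp((v + 20.0) / 7.0))
    tau_f = (
        1102.5 * exp(-((v + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + exp((13.0 - v) / 10.0))
        + 180.0 / (1.0 + exp((v + 30.0) / 10.0))
        + 20.0
    )
    f2_inf = 0.67 / (1.0 + exp((v + 35.0) / 7.0)) + 0.33
    tau_f2 = (
        562.0 * exp(-((v + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + exp((25.0 - v) / 10.0))
        + 80.0 / (1.0 + exp((v + 30.0) / 10.0))
    )

    ml_inf = 1.0 / (1.0 + exp(-(v + 42.85) / 5.264))
    tau_ml = 1.0 / (
        6.765 * exp((v + 11.64) / 34.77) + 8.552 * exp(-(v + 77.42) / 5.955)
    )
    hl_inf = 1.0 / (1.0 + exp((v + 87.61) / 7.488))
    tau_hl = 200.0 * np.ones_like(v)

    z = 2.0 * (v - 15.0) * FONRT
    ez = exp(z)
    small = np.abs(v - 15.0) < 1e-6
    zsafe = np.where(small, 1.0, z)
    ezsafe = np.where(small, np.e, ez)
    c1 = np.where(
        small, 0.5 * FARADAY,
        0.5 * FARADAY * zsafe * ezsafe / (ezsafe - 1.0),
    )
    c2 = np.where(small, 2.0 * FARADAY, 2.0 * FARADAY * zsafe / (ezsafe - 1.0))

    cols = [
        (0, m_inf, tau_m), (2, h_inf, tau_h), (4, h_inf, tau_j),
        (6, xr1_inf, tau_xr1), (8, xr2_inf, tau_xr2), (10, xs_inf, tau_xs),
        (12, r_inf, tau_r), (14, s_inf_epi, tau_s_epi),
        (16, s_inf_endo, tau_s_endo), (18, d_inf, tau_d),
        (20, f_inf, tau_f), (22, f2_inf, tau_f2),
        (24, ml_inf, tau_ml), (26, hl_inf, tau_hl),
    ]
    for c0, inf, tau in cols:
        T[:, c0] = inf
        T[:, c0 + 1] = np.exp(-dt / tau)
    T[:, 28] = exp(0.35 * v * FONRT)
    T[:, 29] = exp(-0.65 * v * FONRT)
    T[:, 30] = 1.0 / (
        1.0 + 0.1245 * exp(-0.1 * v * FONRT) + 0.0353 * exp(-v * FONRT)
    )
    T[:, 31] = 1.0 / (1.0 + exp((25.0 - v) / 5.98))
    T[:, 32] = c1
    T[:, 33] = c2
    return T


@njit(cache=True)
def step_node_tab(S, P, T, istim, dt):
    """Tabulated analogue of step_node (Rush-Larsen gates, FE elsewhere).

    T is rate_table(dt).  Returns the reaction dV/dt; the caller advances V.
    """
    v = S[0]
    cai = S[16]
    casr = S[17]
    cass = S[18]
    nai = S[19]
    ki = S[20]

    ko = P[13]
    nao = P[14]
    cao = P[15]

    # table lookup with linear interpolation
    pos = (v - TAB_V_MIN) / TAB_DV
    if pos < 0.0:
        pos = 0.0
    elif pos > TAB_N - 1.000001:
        pos = TAB_N - 1.000001
    i0 = int(pos)
    fr = pos - i0

    ek = RTONF * math.log(ko / ki)
    ena = RTONF * math.log(nao / nai)
    eks = RTONF * math.log((ko + 0.03 * nao) / (ki + 0.03 * nai))
    eca = 0.5 * RTONF * math.log(cao / cai)

    ina = P[0] * S[1] * S[1] * S[1] * S[2] * S[3] * (v - ena)
    inal = P[6] * S[14] * S[15] * (v - ena)

    c1 = T[i0, 32] + fr * (T[i0 + 1, 32] - T[i0, 32])
    c2 = T[i0, 33] + fr * (T[i0 + 1, 33] - T[i0, 33])
    ical = P[1] * S[9] * S[10] * S[11] * S[12] * (c1 * cass - c2 * cao)

    ito = P[4] * S[7] * S[8] * (v - ek)
    sqko = math.sqrt(ko / 5.4)
    ikr = P[2] * sqko * S[4] * S[5] * (v - ek)
    iks = P[3] * S[6] * S[6] * (v - eks)
    ik1 = P[5] * P[16] * sqko * xk1_inf(v - ek, P[17], P[19]) * (v - ek)

    e1 = T[i0, 28] + fr * (T[i0 + 1, 28] - T[i0, 28])
    e2 = T[i0, 29] + fr * (T[i0 + 1, 29] - T[i0, 29])
    inaca = (
        P[8]
        * (e1 * nai * nai * nai * cao - e2 * nao * nao * nao * cai * 2.5)
        / ((87.5 ** 3 + nao ** 3) * (1.38 + cao) * (1.0 + 0.1 * e2))
    )
    fnak = T[i0, 30] + fr * (T[i0 + 1, 30] - T[i0, 30])
    inak = P[7] * ko * nai / ((ko + 1.0) * (nai + 40.0)) * fnak
    ipca = P[12] * cai / (0.0005 + cai)
    fpk = T[i0, 31] + fr * (T[i0 + 1, 31] - T[i0, 31])
    ipk = P[11] * (v - ek) * fpk
    ibna = P[9] * (v - ena)
    ibca = P[10] * (v - eca)

    iion = (
        ina + inal + ical + ito + ikr + iks + ik1
        + inaca + inak + ipca + ipk + ibna + ibca
    )

    # Rush-Larsen gate updates from the table
    for g in range(14):
        c0 = 2 * g
        if c0 == 14 and P[18] > 0.5:   # endocardial s-gate columns
            c0 = 16
        elif c0 == 16:                 # skip the endo slot for non-endo
            continue
        inf = T[i0, c0] + fr * (T[i0 + 1, c0] - T[i0, c0])
        rl = T[i0, c0 + 1] + fr * (T[i0 + 1, c0 + 1] - T[i0, c0 + 1])
        si = _GATE_SLOT[g]
        if si >= 0:
            S[si] = inf - (inf - S[si]) * rl

    # fcass (Ca-dependent) stays analytic
    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
    S[12] = fcass_inf - (fcass_inf - S[12]) * math.exp(-dt / tau_fcass)

    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) ** 2)
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    S[13] += dt * (0.005 * (1.0 - S[13]) - k2 * cass * S[13])
    o_ryr = k1 * cass * cass * S[13] / (0.06 + k1 * cass * cass)
    irel = 0.102 * o_ryr * (casr - cass)
    ileak = 0.00036 * (casr - cai)
    iup = 0.006375 / (1.0 + (0.00025 / cai) ** 2)
    ixfer = 0.0038 * (cass - cai)

    bufc = 1.0 / (1.0 + 0.2 * 0.001 / (cai + 0.001) ** 2)
    S[16] += dt * bufc * (
        (ileak - iup) * VOL_SR / VOL_C
        + ixfer
        - (ibca + ipca - 2.0 * inaca) * CAP / (2.0 * VOL_C * FARADAY)
    )
    bufsr = 1.0 / (1.0 + 10.0 * 0.3 / (casr + 0.3) ** 2)
    S[17] += dt * bufsr * (iup - ileak - irel)
    bufss = 1.0 / (1.0 + 0.4 * 0.00025 / (cass + 0.00025) ** 2)
    S[18] += dt * bufss * (
        -ical * CAP / (2.0 * VOL_SS * FARADAY)
        + irel * VOL_SR / VOL_SS
        - ixfer * VOL_C / VOL_SS
    )
    S[19] += dt * (
        -(ina + inal + ibna + 3.0 * inak + 3.0 * inaca) * CAP / (VOL_C * FARADAY)
    )
    S[20] += dt * (
        -(istim + ik1 + ito + ikr + iks - 2.0 * inak + ipk) * CAP / (VOL_C * FARADAY)
    )
    return -(iion + istim)


# state-vector slot for each tabulated gate group (index into the 14 groups)
_GATE_SLOT = np.array([1, 2, 3, 4, 5, 6, 7, 8, -1, 9, 10, 11, 14, 15], np.int64)


@njit(cache=True)
def integrate_cell(
    S,
    P,
    dt,
    n_steps,
    stim_start_steps,
    stim_dur_steps,
    stim_amp,
    rec_stride,
    v_rec,
    snap_steps,
    snaps,
    rush_larsen,
):
    """Integrate one cell for n_steps; record V every rec_stride steps.

    v_rec must have length n_steps // rec_stride + 1; snaps has shape
    (len(snap_steps), NSTATE) and receives full-state copies at the given
    step indices (taken before the step is applied, i.e. state at t =
    step * dt).  Returns -1 on success, else the step index at which |V|
    diverged.
    """
    n_stim = stim_start_steps.shape[0]
    sp = 0
    snp = 0
    n_snap = snap_steps.shape[0]
    ir = 0
    for step in range(n_steps):
        if snp < n_snap and step == snap_steps[snp]:
            for k in range(NSTATE):
                snaps[snp, k] = S[k]
            snp += 1
        if step % rec_stride == 0:
            v_rec[ir] = S[0]
            ir += 1
        istim = 0.0
        while sp < n_stim and step >= stim_start_steps[sp] + stim_dur_steps:
            sp += 1
        if sp < n_stim and stim_start_steps[sp] <= step < stim_start_steps[sp] + stim_dur_steps:
            istim = stim_amp
        dv = step_node(S, P, istim, dt, rush_larsen)
        S[0] += dt * dv
        if abs(S[0]) > V_DIVERGED:
            return step
    if ir < v_rec.shape[0]:
        v_rec[ir] = S[0]
    return -1


@njit(cache=True)
def integrate_fiber(
    S,
    P,
    T,
    w,
    dt,
    n_steps,
    s1_lo,
    s1_hi,
    s1_start_steps,
    s2_lo,
    s2_hi,
    s2_start_step,
    stim_dur_steps,
    stim_amp,
    rec_stride,
    v_rec,
    snap_steps,
    snaps,
):
    """Monodomain cable: explicit diffusion + per-node ionic step.

    S: (n, NSTATE) node states.  P: (n, NPARAM).  w: (n-1,) face coupling
    coefficients in ms^-1 (D_face / dx^2); no-flux ends.  S1 is applied to
    nodes [s1_lo, s1_hi) at each start step; S2 (same duration/amplitude) to
    [s2_lo, s2_hi) at s2_start_step (pass a negative step to disable).
    v_rec: (n_steps // rec_stride + 1, n).  snaps: (len(snap_steps), n,
    NSTATE), full states captured before the step at the listed step
    indices.  Returns -1 on success else diverging step index.
    """
    n = S.shape[0]
    dv = np.empty(n)
    ir = 0
    snp = 0
    n_snap = snap_steps.shape[0]
    n_s1 = s1_start_steps.shape[0]
    sp = 0
    for step in range(n_steps):
        if snp < n_snap and step == snap_steps[snp]:
            for i in range(n):
                for k in range(NSTATE):
                    snaps[snp, i, k] = S[i, k]
            snp += 1
        if step % rec_stride == 0:
            for i in range(n):
                v_rec[ir, i] = S[i, 0]
            ir += 1
        while sp < n_s1 and step >= s1_start_steps[sp] + stim_dur_steps:
            sp += 1
        s1_on = (
            sp < n_s1
            and s1_start_steps[sp] <= step < s1_start_steps[sp] + stim_dur_steps
        )
        s2_on = (
            s2_start_step >= 0
            and s2_start_step <= step < s2_start_step + stim_dur_steps
        )
        for i in range(n):
            istim = 0.0
            if s1_on and s1_lo <= i < s1_hi:
                istim = stim_amp
            if s2_on and s2_lo <= i < s2_hi:
                istim = stim_amp
            dv[i] = step_node_tab(S[i], P[i], T, istim, dt)
        for i in range(n):
            lap = 0.0
            if i > 0:
                lap += w[i - 1] * (S[i - 1, 0] - S[i, 0])
            if i < n - 1:
                lap += w[i] * (S[i + 1, 0] - S[i, 0])
            dv[i] += lap
        # V is updated only after all face fluxes were evaluated, so the
        # diffusion operator sees the time-level-n field throughout
        for i in range(n):
            S[i, 0] += dt * dv[i]
            if abs(S[i, 0]) > V_DIVERGED:
                return step
    if ir < v_rec.shape[0]:
        for i in range(n):
            v_rec[ir, i] = S[i, 0]
    return -1


@njit(cache=True)
def integrate_sheet(
    S,
    P,
    T,
    wx,
    wy,
    dt,
    n_steps,
    s1_x_hi,
    s1_start_step,
    s2_x_lo,
    s2_x_hi,
    s2_ny,
    s2_start_step,
    stim_dur_steps,
    stim_amp,
    sample_x,
    sample_y,
    rec_stride,
    v_sample,
    activity_stride,
    activity,
    upstrokes,
    snap_steps,
    snaps,
    early_stop_margin_steps,
):
    """Monodomain 2D sheet (x transmural with heterogeneous coupling, y lateral).

    S: (nx, ny, NSTATE); P: (nx, NPARAM) (cell type varies along x only);
    wx: (nx-1,) x-face couplings (ms^-1), wy: scalar y-face coupling.
    S1: planar stimulus to x < s1_x_hi, all y, at s1_start_step.
    S2: x in [s2_x_lo, s2_x_hi), y < s2_ny, at s2_start_step (negative
    disables).  v_sample records V at (sample_x, sample_y) every rec_stride.
    activity[k] = 1 if any node V > -40 mV at step k*activity_stride.
    upstrokes: (nx, ny) int32, incremented at each upward crossing of
    -20 mV that follows recovery below -60 mV (counted only after S2).
    snaps: (len(snap_steps), nx, ny) stores V fields.  When
    early_stop_margin_steps >= 0, integration ends once the whole sheet is
    quiescent (V < -40 everywhere), no node was ever re-excited after S2,
    and at least that margin has elapsed since S2 (the outcome can no
    longer change).  Returns -1 on success (or early stop) or the
    diverging step index.
    """
    nx = S.shape[0]
    ny = S.shape[1]
    dv = np.empty((nx, ny))
    refr = np.zeros((nx, ny), np.uint8)  # 1 once below -60, armed for upstroke
    for i in range(nx):
        for jj in range(ny):
            if S[i, jj, 0] < -60.0:
                refr[i, jj] = 1
    ir = 0
    ia = 0
    snp = 0
    n_snap = snap_steps.shape[0]
    for step in range(n_steps):
        if snp < n_snap and step == snap_steps[snp]:
            for i in range(nx):
                for jj in range(ny):
                    snaps[snp, i, jj] = S[i, jj, 0]
            snp += 1
        if step % rec_stride == 0 and ir < v_sample.shape[0]:
            v_sample[ir] = S[sample_x, sample_y, 0]
            ir += 1
        if step % activity_stride == 0 and ia < activity.shape[0]:
            act = 0
            for i in range(nx):
                for jj in range(ny):
                    if S[i, jj, 0] > -40.0:
                        act = 1
                        break
                if act == 1:
                    break
            activity[ia] = act
            ia += 1
            if (
                early_stop_margin_steps >= 0
                and act == 0
                and s2_start_step >= 0
                and step > s2_start_step + early_stop_margin_steps
            ):
                done = True
                for i in range(nx):
                    for jj in range(ny):
                        if upstrokes[i, jj] >= 2:
                            done = False
                            break
                    if not done:
                        break
                if done:
                    return -1
        s1_on = s1_start_step <= step < s1_start_step + stim_dur_steps
        s2_on = (
            s2_start_step >= 0
            and s2_start_step <= step < s2_start_step + stim_dur_steps
        )
        count_upstrokes = s2_start_step >= 0 and step >= s2_start_step
        for i in range(nx):
            for jj in range(ny):
                istim = 0.0
                if s1_on and i < s1_x_hi:
                    istim = stim_amp
                if s2_on and s2_x_lo <= i < s2_x_hi and jj < s2_ny:
                    istim = stim_amp
                dv[i, jj] = step_node_tab(S[i, jj], P[i], T, istim, dt)
        for i in range(nx):
            for jj in range(ny):
                lap = 0.0
                if i > 0:
                    lap += wx[i - 1] * (S[i - 1, jj, 0] - S[i, jj, 0])
                if i < nx - 1:
                    lap += wx[i] * (S[i + 1, jj, 0] - S[i, jj, 0])
                if jj > 0:
                    lap += wy * (S[i, jj - 1, 0] - S[i, jj, 0])
                if jj < ny - 1:
                    lap += wy * (S[i, jj + 1, 0] - S[i, jj, 0])
                dv[i, jj] += lap
        for i in range(nx):
            for jj in range(ny):
                vnew = S[i, jj, 0] + dt * dv[i, jj]
                S[i, jj, 0] = vnew
                if abs(vnew) > V_DIVERGED:
                    return step
                if vnew < -60.0:
                    refr[i, jj] = 1
                elif vnew > -20.0 and refr[i, jj] == 1:
                    refr[i, jj] = 0
                    if count_upstrokes:
                        upstrokes[i, jj] += 1
    return -1
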