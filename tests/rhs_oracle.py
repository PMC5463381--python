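"""Independent re-implementation of the ionic current equations.

Used only as a cross-check oracle: written separately from the package
kernel (dict-based, numpy scalar math, np.where instead of branches) so
that algebraic or transcription errors in either implementation surface as
disagreements.
"""

import numpy as np

R = 8314.472
T = 310.0
F = 96485.3415
RTF = R * T / F

CONSTS = dict(
    k_mna=40.0, k_mk=1.0, k_mca=1.38, k_mnai=87.5, k_sat=0.1, gamma=0.35,
    alpha_ncx=2.5, k_pca=0.0005, p_kna=0.03,
)


def nernst(z, outside, inside):
    return RTF / z * np.log(outside / inside)


def currents(state: dict, p: dict) -> dict:
    """All membrane current densities (pA/pF) at a state.

    ``state`` holds V, gates, concentrations by name; ``p`` holds
    conductances, external concentrations and the inward-rectifier variant
    constants (scale, shift, slope).
    """
    v = state["V"]
    e_na = nernst(1, p["na_o"], state["nai"])
    e_k = nernst(1, p["k_o"], state["ki"])
    e_ks = RTF * np.log(
        (p["k_o"] + CONSTS["p_kna"] * p["na_o"])
        / (state["ki"] + CONSTS["p_kna"] * state["nai"])
    )
    e_ca = nernst(2, p["ca_o"], state["cai"])

    out = {}
    out["I_Na"] = (
        p["g_na"] * state["m"] ** 3 * state["h"] * state["j"] * (v - e_na)
    )
    out["I_NaL"] = p["g_nal"] * state["ml"] * state["hl"] * (v - e_na)

    zz = 2.0 * (v - 15.0) / RTF
    expz = np.exp(zz)
    ghk = np.where(
        np.abs(v - 15.0) < 1e-6,
        2.0 * F * (0.25 * state["cass"] - p["ca_o"]),
        2.0 * F * zz * (0.25 * state["cass"] * expz - p["ca_o"]) / (expz - 1.0),
    )
    out["I_CaL"] = (
        p["g_cal"] * state["d"] * state["f"] * state["f2"] * state["fcass"] * ghk
    )

    out["I_to"] = p["g_to"] * state["r"] * state["s"] * (v - e_k)
    out["I_Kr"] = (
        p["g_kr"] * np.sqrt(p["k_o"] / 5.4) * state["xr1"] * state["xr2"] * (v - e_k)
    )
    out["I_Ks"] = p["g_ks"] * state["xs"] ** 2 * (v - e_ks)

    u = v - e_k
    alpha = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
    beta = (
        3.0 * np.exp(0.0002 * (u + 100.0))
        + np.exp(p["ik1_slope"] * (u - 10.0 - p["ik1_shift"]))
    ) / (1.0 + np.exp(-0.5 * u))
    out["I_K1"] = (
        p["g_k1"] * p["ik1_scale"] * np.sqrt(p["k_o"] / 5.4)
        * alpha / (alpha + beta) * u
    )

    g = CONSTS["gamma"]
    ef = np.exp(g * v / RTF)
    eb = np.exp((g - 1.0) * v / RTF)
    num = ef * state["nai"] ** 3 * p["ca_o"] - eb * p["na_o"] ** 3 * state[
        "cai"
    ] * CONSTS["alpha_ncx"]
    den = (
        (CONSTS["k_mnai"] ** 3 + p["na_o"] ** 3)
        * (CONSTS["k_mca"] + p["ca_o"])
        * (1.0 + CONSTS["k_sat"] * eb)
    )
    out["I_NaCa"] = p["k_naca"] * num / den

    out["I_NaK"] = (
        p["p_nak"]
        * p["k_o"] * state["nai"]
        / ((p["k_o"] + CONSTS["k_mk"]) * (state["nai"] + CONSTS["k_mna"]))
        / (
            1.0
            + 0.1245 * np.exp(-0.1 * v / RTF)
            + 0.0353 * np.exp(-v / RTF)
        )
    )
    out["I_pCa"] = p["g_pca"] * state["cai"] / (CONSTS["k_pca"] + state["cai"])
    out["I_pK"] = p["g_pk"] * (v - e_k) / (1.0 + np.exp((25.0 - v) / 5.98))
    out["I_bNa"] = p["g_bna"] * (v - e_na)
    out["I_bCa"] = p["g_bca"] * (v - e_ca)
    out["I_ion"] = float(sum(out.values()))
    return out


def cell_params_to_dict(params) -> dict:
    """Bridge a package CellParams object to the oracle's flat dict."""
    return dict(
        g_na=params.g_na, g_cal=params.g_cal, g_kr=params.g_kr,
        g_ks=params.g_ks, g_to=params.g_to, g_k1=params.ik1.g_k1,
        g_nal=params.g_nal, p_nak=params.p_nak, k_naca=params.k_naca,
        g_bna=params.g_bna, g_bca=params.g_bca, g_pk=params.g_pk,
        g_pca=params.g_pca, k_o=params.ik1.k_o, na_o=params.na_o,
        ca_o=params.ca_o, ik1_scale=params.ik1.scale,
        ik1_shift=params.ik1.shift_mV, ik1_slope=params.ik1.slope,
    )


def state_to_dict(state) -> dict:
    from sqt3sim.ionic_cell import STATE_NAMES

    return {name: float(v) for name, v in zip(STATE_NAMES, state.values)}


def pseudo_ecg_oracle(t, v_field, x_cm, electrode_cm, alpha_cm):
    """Independent evaluation of the far-field integral.

    Same central-difference / Riemann-sum convention as the package
    (np.gradient at the nodes), written as an explicit per-electrode loop.
    """
    phie = np.empty(v_field.shape[0])
    dx = x_cm[1] - x_cm[0]
    inv_r = 1.0 / np.abs(x_cm - electrode_cm)
    dinv = np.gradient(inv_r, x_cm)
    for k in range(v_field.shape[0]):
        dvdx = np.gradient(v_field[k], x_cm)
        phie[k] = (alpha_cm**2 / 4.0) * np.sum(-dvdx * dinv) * dx
    return phie
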