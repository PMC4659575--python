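"""Fast fixed-step integrator for the coupled electromechanical cell.

Scheme: exact-exponential (Rush-Larsen) updates for every gate-like state
(the 12 voltage gates, fca/u/v, and the cross-bridge mean distortions, all of
which are linear in themselves at frozen inputs), forward Euler for the
remaining slow states, at a fixed dt (default 0.01 ms).  Voltage-dependent
gate targets and Rush-Larsen factors, and the V-dependent current prefactors,
are tabulated on a 0.05 mV grid and linearly interpolated, which keeps the
per-step cost to a handful of transcendentals.

The same compiled step serves the single-cell pacing drivers here and the
tissue reaction sweep in ``atriomech.tissue``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ..ionic import crn
from ..ionic.crn import CellParameters, gate_inf_tau
from ..myofilament.rice import RiceParameters
from .state import N_STATES

__all__ = ["build_lut", "pack_params", "pace_beats", "integrate_record", "LUT_V0", "LUT_DV"]

LUT_V0 = -100.0
LUT_DV = 0.05
LUT_N = int(round((70.0 - LUT_V0) / LUT_DV)) + 1

_RTF = crn.RTF
_NA_O = crn.NA_O
_K_O = crn.K_O
_CA_O = crn.CA_O
_GAMMA = crn.GAMMA_NCX
_KSAT = crn.K_SAT
_KMNA3 = crn.K_M_NA**3
_KMCA = crn.K_M_CA
_KMNAI = crn.K_M_NA_I
_KMKO = crn.K_M_K_O
_CSQN = crn.CSQN_MAX
_KMCSQN = crn.KM_CSQN
_TAU_TR = crn.TAU_TR

_lut_cache: dict[float, tuple] = {}


def build_lut(dt: float):
    """Tabulate gate targets/RL factors and current prefactors for one dt."""
    key = round(float(dt), 9)
    if key in _lut_cache:
        return _lut_cache[key]
    V = LUT_V0 + LUT_DV * np.arange(LUT_N)
    inf, tau = gate_inf_tau(V)
    lut = np.empty((LUT_N, 30))
    lut[:, 0:12] = inf
    lut[:, 12:24] = np.exp(-dt / tau)
    lut[:, 24] = 1.0 / (1.0 + np.exp(0.07 * (V + 80.0)))                     # IK1
    lut[:, 25] = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))           # gKur(V)
    lut[:, 26] = 1.0 / (1.0 + np.exp((V + 15.0) / 22.4))                     # IKr rectification
    sigma = (np.exp(_NA_O / 67.3) - 1.0) / 7.0
    lut[:, 27] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / _RTF)
                        + 0.0365 * sigma * np.exp(-V / _RTF))                # fNaK
    lut[:, 28] = np.exp(_GAMMA * V / _RTF)                                   # NCX fwd
    lut[:, 29] = np.exp((_GAMMA - 1.0) * V / _RTF)                           # NCX rev
    aux = np.array([np.exp(-dt / crn.TAU_F_CA), np.exp(-dt / crn.TAU_U)])
    _lut_cache[key] = (lut, aux)
    return lut, aux


N_PARAMS = 64

def pack_params(
    p: CellParameters,
    rice: RiceParameters,
    mode: str = "cell",
    coupled: bool = True,
    rel_cyto: float = 1.0,
    rel_sr: float = 1.0,
) -> np.ndarray:
    """Flatten cell + myofilament parameters into the kernel's vector.

    ``coupled=False`` selects the original electrophysiology-only Ca balance
    (instantaneous troponin buffer, no myofilament feedback); the myofilament
    still integrates passively as an observer.
    """
    ssprer, sspostr = rice.ss_fractions
    preload = np.sign(rice.SLset - rice.SLrest) * rice.PCon_t * (
        np.exp(rice.PExp_t * abs(rice.SLset - rice.SLrest)) - 1.0
    )
    pv = np.array([
        p.g_Na, p.g_to, p.g_CaL, p.g_Kr, p.g_Ks, p.g_K1, p.g_Kur_scale,
        p.g_bNa, p.g_bCa, p.i_NaK_max, p.i_pCa_max, p.i_NaCa_max,
        p.i_up_max, p.k_rel, p.k_leak, p.Cm, p.V_myo, p.V_nsr, p.V_jsr,
        p.cmdn_max, p.km_cmdn, p.F_const,
        # myofilament, temperature/species-modified, per second
        rice.konT, rice.koffLT, rice.koffHT,
        rice.kn_p * rice._q(rice.Qkn_p), rice.kp_n * rice._q(rice.Qkp_n),
        rice.fappT, rice.gappT_base, rice.hfT_base, rice.hbT_base, rice.gxbT_base,
        rice.gslmod, rice.hfmdc, rice.hbmdc, rice.sigmap, rice.sigman,
        rice.x_0, rice.xPsi, rice.perm50, rice.nperm, rice.Trop_conc,
        ssprer, sspostr,
        rice.SLrest, rice.SLset, rice.PCon_t, rice.PExp_t,
        rice.SL_c, rice.PCon_c, rice.PExp_c,
        rice.KSE, 1.0 if rice.SEon else 0.0, rice.mass, rice.visc,
        rice.SLmin, rice.SLmax, rice.len_thick, rice.len_hbare, rice.len_thin,
        0.0 if mode == "cell" else 1.0,
        1.0 if coupled else 0.0,
        rel_cyto,
        rel_sr,
    ])
    assert pv.size == N_PARAMS
    return pv


@njit(cache=True, fastmath=True, inline="always")
def _lerp(lut, col, x):
    # x is the fractional row index, clamped to the table
    i = int(x)
    w = x - i
    return lut[i, col] * (1.0 - w) + lut[i + 1, col] * w


@njit(cache=True, fastmath=True)
def cell_step(y, pv, lut, aux, dt, i_stim):
    """Advance one cell state in place by dt.  Returns the normalised active
    force at the start of the step.  ``i_stim`` is the depolarising stimulus
    amplitude in pA (positive depolarises)."""
    V = y[0]
    Nai = y[16]
    Ki = y[17]
    Cai = y[18]
    Caup = y[19]
    Carel = y[20]

    x = (V - LUT_V0) / LUT_DV
    if x < 0.0:
        x = 0.0
    elif x > LUT_N - 2:
        x = float(LUT_N - 2)

    E_Na = _RTF * np.log(_NA_O / Nai)
    E_K = _RTF * np.log(_K_O / Ki)
    E_Ca = 0.5 * _RTF * np.log(_CA_O / Cai)
    Cm = pv[15]

    m = y[1]; h = y[2]; jg = y[3]; oa = y[4]; oi = y[5]; ua = y[6]; ui = y[7]
    xr = y[8]; xs = y[9]; d = y[10]; f = y[11]; w = y[12]
    fca = y[13]; u = y[14]; v = y[15]

    i_Na = Cm * pv[0] * m * m * m * h * jg * (V - E_Na)
    i_K1 = Cm * pv[5] * (V - E_K) * _lerp(lut, 24, x)
    i_to = Cm * pv[1] * oa * oa * oa * oi * (V - E_K)
    i_Kur = Cm * pv[6] * _lerp(lut, 25, x) * ua * ua * ua * ui * (V - E_K)
    i_Kr = Cm * pv[3] * xr * (V - E_K) * _lerp(lut, 26, x)
    i_Ks = Cm * pv[4] * xs * xs * (V - E_K)
    i_CaL = Cm * pv[2] * d * f * fca * (V - 65.0)
    i_NaK = Cm * pv[9] * _lerp(lut, 27, x) * (1.0 / (1.0 + (_KMNAI / Nai) ** 1.5)) \
        * (_K_O / (_K_O + _KMKO))
    e1 = _lerp(lut, 28, x)
    e2 = _lerp(lut, 29, x)
    i_NaCa = Cm * pv[11] * (e1 * Nai * Nai * Nai * _CA_O - e2 * _NA_O**3 * Cai) / (
        (_KMNA3 + _NA_O**3) * (_KMCA + _CA_O) * (1.0 + _KSAT * e2)
    )
    i_bNa = Cm * pv[7] * (V - E_Na)
    i_bCa = Cm * pv[8] * (V - E_Ca)
    i_pCa = Cm * pv[10] * Cai / (0.0005 + Cai)

    j_rel = pv[13] * u * u * v * w * (Carel - Cai)
    j_up = pv[12] / (1.0 + 0.00092 / Cai)
    j_leak = pv[14] * Caup
    j_tr = (Caup - Carel) / _TAU_TR

    i_ion = (i_Na + i_K1 + i_to + i_Kur + i_Kr + i_Ks + i_CaL
             + i_pCa + i_NaK + i_NaCa + i_bNa + i_bCa)

    # --- myofilament rates (per second; converted at the updates) ---------
    N = y[21]; XBprer = y[22]; XBpostr = y[23]
    xXBprer = y[24]; xXBpostr = y[25]
    trpnL = y[26]; trpnH = y[27]; SL = y[28]; intf = y[29]
    P = 1.0 - N - XBprer - XBpostr

    len_thick = pv[57]; len_hbare = pv[58]; len_thin = pv[59]
    sovr_ze = min(len_thick * 0.5, SL * 0.5)
    hb_half = len_hbare * 0.5
    cle = SL * 0.5 - (SL - len_thin)
    sovr_cle = cle if cle > hb_half else hb_half
    len_sovr = sovr_ze - sovr_cle
    SOVFThick = 2.0 * len_sovr / (len_thick - len_hbare)
    SOVFThin = len_sovr / len_thin

    konT = pv[22]; koffLT = pv[23]; koffHT = pv[24]
    Ca_uM = Cai * 1000.0
    dtrpnL = konT * Ca_uM * (1.0 - trpnL) - koffLT * trpnL
    dtrpnH = konT * Ca_uM * (1.0 - trpnH) - koffHT * trpnH

    trop_reg = (1.0 - SOVFThin) * trpnL + SOVFThin * trpnH
    perm50 = pv[39]; nperm = pv[40]
    if trop_reg > 1e-12:
        permtot = (1.0 / (1.0 + (perm50 / trop_reg) ** nperm)) ** 0.5
    else:
        permtot = 1e-12
    inprmt = 1.0 / permtot
    if inprmt > 100.0:
        inprmt = 100.0
    kn_pT = pv[25] * permtot
    kp_nT = pv[26] * inprmt

    x_0 = pv[37]
    fappT = pv[27]
    gappT = pv[28] * (1.0 + (1.0 - SOVFThick) * pv[32])
    # exponent arguments clamped to +-30 so extreme (non-physiological)
    # distortions cannot under/overflow the rates into 0 or inf
    s = 1.0 if xXBprer >= 0.0 else -1.0
    a = -s * pv[33] * (xXBprer / x_0) ** 2
    hfT = pv[29] * np.exp(min(max(a, -30.0), 30.0))
    s = 1.0 if xXBpostr >= x_0 else -1.0
    a = s * pv[34] * ((xXBpostr - x_0) / x_0) ** 2
    hbT = pv[30] * np.exp(min(max(a, -30.0), 30.0))
    if xXBpostr < x_0:
        a = pv[35] * ((x_0 - xXBpostr) / x_0) ** 2
    else:
        a = pv[36] * ((xXBpostr - x_0) / x_0) ** 2
    gxbT = pv[31] * np.exp(min(max(a, -30.0), 30.0))

    dN = -kn_pT * N + kp_nT * P
    dXBprer = fappT * P - gappT * XBprer - hfT * XBprer + hbT * XBpostr
    dXBpostr = hfT * XBprer - hbT * XBpostr - gxbT * XBpostr

    denom = (gappT * hbT + gappT * gxbT + hfT * gxbT
             + fappT * hbT + fappT * gxbT + fappT * hfT)
    dutyprer = (hbT * fappT + gxbT * fappT) / denom
    dutypostr = fappT * hfT / denom

    ssprer = pv[42]; sspostr = pv[43]
    force = SOVFThick * (xXBpostr * XBpostr + xXBprer * XBprer) / (x_0 * sspostr)

    # SL dynamics (normalised force units, per second)
    mode = pv[60]
    if mode == 0.0:
        dSL = (intf + (pv[45] - SL) * pv[54]) / pv[53]
        if SL < pv[55] or SL > pv[56]:
            dSL = 0.0
        sgn = 1.0 if SL >= pv[44] else -1.0
        ppt = sgn * pv[46] * (np.exp(pv[47] * abs(SL - pv[44])) - 1.0)
        if SL > pv[48]:
            ppt += pv[49] * (np.exp(pv[50] * (SL - pv[48])) - 1.0)
        preload = pv[46] * (np.exp(pv[47] * abs(pv[45] - pv[44])) - 1.0)
        afterload = pv[51] * (pv[45] - SL) if pv[52] != 0.0 else 0.0
        dintf = -ppt + preload - force + afterload
    else:
        dSL = 0.0
        dintf = 0.0

    # troponin-bound Ca feedback
    frac = (XBprer + XBpostr) / (ssprer + sspostr)
    dfrac = (dXBprer + dXBpostr) / (ssprer + sspostr)
    dze = 0.5 if SL < len_thick else 0.0
    dcle = -0.5 if cle > hb_half else 0.0
    dSOVFThin = (dze - dcle) * dSL / len_thin
    dTropTot = pv[41] * (
        -dSOVFThin * trpnL + (1.0 - SOVFThin) * dtrpnL
        + dSOVFThin * (frac * trpnH + (1.0 - frac) * trpnL)
        + SOVFThin * (dfrac * trpnH + frac * dtrpnH
                      - dfrac * trpnL + (1.0 - frac) * dtrpnL)
    )  # uM/s

    # --- updates ----------------------------------------------------------
    # membrane potential (stimulus positive-depolarising)
    y[0] = V + dt * (-(i_ion - i_stim) / Cm)

    # voltage gates: Rush-Larsen from the tables
    for g in range(12):
        inf = _lerp(lut, g, x)
        y[1 + g] = inf + (y[1 + g] - inf) * _lerp(lut, 12 + g, x)

    fca_inf = 1.0 / (1.0 + Cai / 0.00035)
    y[13] = fca_inf + (fca - fca_inf) * aux[0]
    Fn = 1e3 * (1e-15 * pv[18] * j_rel - (1e-15 / (2.0 * pv[21])) * (0.5 * i_CaL - 0.2 * i_NaCa))
    ef = np.exp(-(Fn - 3.4175e-13) / 13.67e-16)
    u_inf = 1.0 / (1.0 + ef)
    tau_v = 1.91 + 2.09 / (1.0 + ef)
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 13.67e-16))
    y[14] = u_inf + (u - u_inf) * aux[1]
    y[15] = v_inf + (v - v_inf) * np.exp(-dt / tau_v)

    FVi = pv[21] * pv[16]
    y[16] = max(Nai + dt * ((-3.0 * i_NaK - 3.0 * i_NaCa - i_bNa - i_Na) / FVi), 1e-9)
    y[17] = max(Ki + dt * ((2.0 * i_NaK - i_K1 - i_to - i_Kur - i_Kr - i_Ks) / FVi), 1e-9)

    # currents are whole-cell pA (Cm already included in their definitions)
    sarco = (2.0 * i_NaCa - i_CaL - i_bCa - i_pCa) / (2.0 * pv[16] * pv[21])
    sr = (pv[17] * (j_leak - j_up) + pv[62] * j_rel * pv[18]) / pv[16]
    if pv[61] != 0.0:
        # coupled Ca balance: calmodulin instantaneous + dynamic troponin
        b = 1.0 / (1.0 + pv[19] * pv[20] / (Cai + pv[20]) ** 2)
        dCai = b * (sarco + sr - dTropTot * 1e-6)
    else:
        # original EP-only balance with instantaneous troponin buffering
        b2 = (1.0 + 0.070 * 0.0005 / (Cai + 0.0005) ** 2
              + pv[19] * pv[20] / (Cai + pv[20]) ** 2)
        dCai = (sarco + sr) / b2
    # concentration floors guard against absurd (far supra-threshold) inputs;
    # physiological trajectories never approach them
    y[18] = max(Cai + dt * dCai, 1e-12)

    y[19] = max(Caup + dt * (j_up - j_leak - j_tr * pv[18] / pv[17]), 1e-12)
    y[20] = max(
        Carel
        + dt * ((j_tr - pv[63] * j_rel) / (1.0 + _CSQN * _KMCSQN / (Carel + _KMCSQN) ** 2)),
        1e-12,
    )

    ms = 1e-3  # myofilament rates are per second
    y[21] = N + dt * ms * dN
    y[22] = XBprer + dt * ms * dXBprer
    y[23] = XBpostr + dt * ms * dXBpostr

    # mean distortions: exponential update (linear in themselves)
    r1 = pv[38] / dutyprer * (fappT + hbT) * ms
    c1 = dSL * 0.5 * ms + pv[38] / dutyprer * hbT * (xXBpostr - x_0) * ms
    xinf = c1 / r1
    y[24] = xinf + (xXBprer - xinf) * np.exp(-r1 * dt)
    r2 = pv[38] / dutypostr * hfT * ms
    c2 = dSL * 0.5 * ms + r2 * (x_0 + xXBprer)
    xinf = c2 / r2
    y[25] = xinf + (xXBpostr - xinf) * np.exp(-r2 * dt)

    y[26] = trpnL + dt * ms * dtrpnL
    y[27] = trpnH + dt * ms * dtrpnH
    y[28] = SL + dt * ms * dSL
    y[29] = intf + dt * ms * dintf

    return force


@njit(cache=True, fastmath=True)
def pace_beats(y, pv, lut, aux, dt, n_beats, period, stim_dur, stim_amp):
    """Pace n_beats at the given period, returning per-beat biomarkers.

    Columns: 0 V_rest (pre-stimulus), 1 V_max, 2 APD90 (ms, nan if the AP did
    not repolarise within the cycle), 3 Ca_min, 4 Ca_max (mM), 5 SL_min,
    6 SL_max (um), 7 peak normalised force, 8 volume-weighted SR Ca content
    at end of beat (mM, myoplasm-referred), 9 max dV/dt (mV/ms).
    """
    steps_per_beat = int(round(period / dt))
    stim_steps = int(round(stim_dur / dt))
    out = np.full((n_beats, 10), np.nan)
    for beat in range(n_beats):
        vrest = y[0]
        vmax = -1e9
        camin = 1e9; camax = -1e9
        slmin = 1e9; slmax = -1e9
        fmax = -1e9
        dvmax = -1e9
        t_up = 0.0
        apd = np.nan
        vprev = y[0]
        crossed = False
        for k in range(steps_per_beat):
            amp = stim_amp if k < stim_steps else 0.0
            force = cell_step(y, pv, lut, aux, dt, amp)
            V = y[0]
            dv = (V - vprev) / dt
            t = (k + 1) * dt
            if dv > dvmax:
                dvmax = dv
                t_up = t
            if V > vmax:
                vmax = V
            if not crossed and t > t_up and dv < 0.0:
                v90 = vmax - 0.9 * (vmax - vrest)
                if V < v90:
                    apd = t - t_up
                    crossed = True
            ca = y[18]
            if ca < camin:
                camin = ca
            if ca > camax:
                camax = ca
            sl = y[28]
            if sl < slmin:
                slmin = sl
            if sl > slmax:
                slmax = sl
            if force > fmax:
                fmax = force
            vprev = V
        casr = (y[19] * pv[17] + y[20] * pv[18]) / pv[16]
        out[beat, 0] = vrest
        out[beat, 1] = vmax
        out[beat, 2] = apd
        out[beat, 3] = camin
        out[beat, 4] = camax
        out[beat, 5] = slmin
        out[beat, 6] = slmax
        out[beat, 7] = fmax
        out[beat, 8] = casr
        out[beat, 9] = dvmax
    return out


@njit(cache=True, fastmath=True)
def integrate_record(y, pv, lut, aux, dt, t_end, onsets, stim_dur, stim_amp, record_dt):
    """Integrate to t_end with rectangular stimuli at the given onset times,
    recording (t, V, Cai, Caup, Carel, SL, force, TropTot-free slot) every
    record_dt.  Returns the record array [n_rec, 8]."""
    n_steps = int(round(t_end / dt))
    every = max(1, int(round(record_dt / dt)))
    n_rec = n_steps // every + 1
    rec = np.zeros((n_rec, 8))
    row = 0
    force = 0.0
    for k in range(n_steps):
        t = k * dt
        amp = 0.0
        for s in range(onsets.size):
            if onsets[s] <= t < onsets[s] + stim_dur:
                amp = stim_amp
        if k % every == 0:
            rec[row, 0] = t
            rec[row, 1] = y[0]
            rec[row, 2] = y[18]
            rec[row, 3] = y[19]
            rec[row, 4] = y[20]
            rec[row, 5] = y[28]
            rec[row, 6] = force
            row += 1
        force = cell_step(y, pv, lut, aux, dt, amp)
    # final sample
    rec[row if row < n_rec else n_rec - 1, 0] = n_steps * dt
    rec[row if row < n_rec else n_rec - 1, 1] = y[0]
    rec[row if row < n_rec else n_rec - 1, 2] = y[18]
    rec[row if row < n_rec else n_rec - 1, 3] = y[19]
    rec[row if row < n_rec else n_rec - 1, 4] = y[20]
    rec[row if row < n_rec else n_rec - 1, 5] = y[28]
    rec[row if row < n_rec else n_rec - 1, 6] = force
    return rec[: row + 1]
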