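"""Approximate cross-bridge / cooperative-activation myofilament model.

This is the Rice-type mean-field contraction model: thin-filament regulatory
units switch between non-permissive (N) and permissive (P) states under
cooperative control of Ca2+ bound to low/high-affinity troponin sites, and
permissive units cycle through strongly-bound pre- and post-powerstroke
cross-bridge states (XBprer, XBpostr) whose mean distortions (xXBprer,
xXBpostr) carry the force.  Sarcomere overlap enters through single-overlap
fractions of the thick (SOVFThick) and thin (SOVFThin) filaments.

Rate constants are the published 37 degC base values, scaled by Q10 factors for
other temperatures and by a species factor ``xbmodsp`` for the cross-bridge
cycling rates.  Internal units are seconds and micromolar; the cell-coupling
layer converts to ms and mM.

States (in the order of ``MF_STATE_NAMES``):
  N, XBprer, XBpostr      regulatory/cross-bridge fractions (P = 1 - sum)
  xXBprer, xXBpostr       mean distortions (um)
  TRPNCaL, TRPNCaH        fractional Ca occupancy of troponin sites
  SL                      sarcomere length (um)
  intf                    integral of net normalised force (internal-load mode)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RiceParameters",
    "MF_STATE_NAMES",
    "initial_myofilament_state",
    "sarcomere_overlap",
    "myofilament_derivatives",
    "trop_total",
    "steady_state_force_calcium",
]

MF_STATE_NAMES = (
    "N", "XBprer", "XBpostr", "xXBprer", "xXBpostr",
    "TRPNCaL", "TRPNCaH", "SL", "intf",
)


@dataclass(frozen=True)
class RiceParameters:
    # sarcomere geometry (um)
    SLmin: float = 1.4
    SLmax: float = 2.4
    len_thick: float = 1.65
    len_hbare: float = 0.1
    len_thin: float = 1.2
    # temperature and species scaling
    TmpC: float = 37.0
    xbmodsp: float = 1.0
    # Ca binding to troponin (uM^-1 s^-1, s^-1)
    kon: float = 50.0
    koffL: float = 250.0
    koffH: float = 25.0
    koffmod: float = 1.0
    Qkon: float = 1.5
    Qkoff: float = 1.3
    Trop_conc: float = 70.0  # uM
    # thin-filament regulation
    perm50: float = 0.5
    nperm: float = 15.0
    kn_p: float = 500.0
    kp_n: float = 50.0
    Qkn_p: float = 1.6
    Qkp_n: float = 1.6
    # cross-bridge cycling (s^-1)
    fapp: float = 500.0
    gapp: float = 70.0
    hf: float = 2000.0
    hb: float = 400.0
    gxb: float = 70.0
    gslmod: float = 6.0
    hfmdc: float = 5.0
    hbmdc: float = 0.0
    sigmap: float = 8.0
    sigman: float = 1.0
    Qfapp: float = 6.25
    Qgapp: float = 2.5
    Qhf: float = 6.25
    Qhb: float = 6.25
    Qgxb: float = 6.25
    x_0: float = 0.007  # um, powerstroke distortion
    xPsi: float = 2.0
    kxb: float = 120.0  # mN/mm^2, absolute force scale
    # passive elements and internal load (normalised force units)
    SLrest: float = 1.85
    SLset: float = 1.9
    PCon_t: float = 0.002
    PExp_t: float = 10.0
    SL_c: float = 2.25
    PCon_c: float = 0.02
    PExp_c: float = 70.0
    KSE: float = 1.0
    SEon: bool = True
    mass: float = 5e-5
    visc: float = 0.003

    def with_(self, **kw) -> "RiceParameters":
        return replace(self, **kw)

    # temperature/species-modified rates -----------------------------------
    def _q(self, Q):
        return Q ** ((self.TmpC - 37.0) / 10.0)

    @property
    def konT(self):
        return self.kon * self._q(self.Qkon)

    @property
    def koffLT(self):
        return self.koffL * self.koffmod * self._q(self.Qkoff)

    @property
    def koffHT(self):
        return self.koffH * self.koffmod * self._q(self.Qkoff)

    @property
    def fappT(self):
        return self.fapp * self.xbmodsp * self._q(self.Qfapp)

    @property
    def gappT_base(self):
        return self.gapp * self.xbmodsp * self._q(self.Qgapp)

    @property
    def hfT_base(self):
        return self.hf * self.xbmodsp * self._q(self.Qhf)

    @property
    def hbT_base(self):
        return self.hb * self.xbmodsp * self._q(self.Qhb)

    @property
    def gxbT_base(self):
        return self.gxb * self.xbmodsp * self._q(self.Qgxb)

    @property
    def ss_fractions(self):
        """(SSXBprer, SSXBpostr) of the fully-permissive cycle at base rates
        (force-normalisation constants)."""
        f, g, hfw, hbw, gx = self.fapp, self.gapp, self.hf, self.hb, self.gxb
        denom = gx * hfw + f * hfw + gx * g + hbw * f + hbw * g + gx * f
        return (f * (hbw + gx)) / denom, (f * hfw) / denom


def sarcomere_overlap(SL: float, p: RiceParameters):
    """Single-overlap fractions (SOVFThick, SOVFThin) at sarcomere length SL."""
    sovr_ze = min(p.len_thick / 2.0, SL / 2.0)
    sovr_cle = max(SL / 2.0 - (SL - p.len_thin), p.len_hbare / 2.0)
    len_sovr = sovr_ze - sovr_cle
    return (
        2.0 * len_sovr / (p.len_thick - p.len_hbare),
        len_sovr / p.len_thin,
    )


def _overlap_slope(SL: float, p: RiceParameters) -> float:
    """d(len_sovr)/dSL with the piecewise branches of the overlap geometry."""
    dze = 0.5 if SL < p.len_thick else 0.0
    dcle = -0.5 if (SL / 2.0 - (SL - p.len_thin)) > p.len_hbare / 2.0 else 0.0
    return dze - dcle


def _passive_force(SL: float, p: RiceParameters) -> float:
    titin = np.sign(SL - p.SLrest) * p.PCon_t * (
        np.exp(p.PExp_t * abs(SL - p.SLrest)) - 1.0
    )
    collagen = (
        p.PCon_c * (np.exp(p.PExp_c * (SL - p.SL_c)) - 1.0) if SL > p.SL_c else 0.0
    )
    return titin + collagen


def initial_myofilament_state(p: RiceParameters | None = None, Ca_uM: float = 0.1):
    """Rest state near diastolic Ca (settles fully during pre-pacing)."""
    p = p or RiceParameters()
    trpnL = Ca_uM / (Ca_uM + p.koffLT / p.konT)
    trpnH = Ca_uM / (Ca_uM + p.koffHT / p.konT)
    return np.array(
        [0.99, 1e-6, 1e-6, 0.0, p.x_0, trpnL, trpnH, p.SLset, 0.0]
    )


def myofilament_derivatives(
    mf: np.ndarray,
    Ca_uM: float,
    p: RiceParameters | None = None,
    mode: str = "cell",
):
    """Time derivatives (per second) of the myofilament state.

    ``mode`` is "cell" (sarcomere shortens against the internal viscoelastic
    load) or "isosarcometric" (SL fixed).  Returns ``(dmf, force, dTropTot)``
    where ``force`` is the active force normalised to the fully-permissive
    isometric maximum and ``dTropTot`` the rate of change of troponin-bound
    Ca2+ (uM/s) fed back to the Ca balance.
    """
    p = p or RiceParameters()
    if Ca_uM < 0:
        raise ValueError(f"negative intracellular Ca {Ca_uM} uM")
    if mode not in ("cell", "isosarcometric"):
        raise ValueError(f"unknown contraction mode {mode!r}")
    if not np.all(np.isfinite(mf)):
        raise ValueError("non-finite myofilament state")

    N, XBprer, XBpostr, xXBprer, xXBpostr, trpnL, trpnH, SL, intf = mf
    P = 1.0 - N - XBprer - XBpostr

    SOVFThick, SOVFThin = sarcomere_overlap(SL, p)

    # troponin Ca binding
    dtrpnL = p.konT * Ca_uM * (1.0 - trpnL) - p.koffLT * trpnL
    dtrpnH = p.konT * Ca_uM * (1.0 - trpnH) - p.koffHT * trpnH

    # cooperative permissivity
    trop_reg = (1.0 - SOVFThin) * trpnL + SOVFThin * trpnH
    if trop_reg <= 0.0:
        permtot = 0.0
    else:
        permtot = np.sqrt(1.0 / (1.0 + (p.perm50 / trop_reg) ** p.nperm))
    inprmt = min(1.0 / permtot, 100.0) if permtot > 0 else 100.0
    kn_pT = p.kn_p * permtot * p._q(p.Qkn_p)
    kp_nT = p.kp_n * inprmt * p._q(p.Qkp_n)

    # distortion-dependent cross-bridge rates
    fappT = p.fappT
    gappT = p.gappT_base * (1.0 + (1.0 - SOVFThick) * p.gslmod)
    hfmd = np.exp(-np.sign(xXBprer) * p.hfmdc * (xXBprer / p.x_0) ** 2)
    hbmd = np.exp(np.sign(xXBpostr - p.x_0) * p.hbmdc * ((xXBpostr - p.x_0) / p.x_0) ** 2)
    hfT = p.hfT_base * hfmd
    hbT = p.hbT_base * hbmd
    if xXBpostr < p.x_0:
        gxbmd = np.exp(p.sigmap * ((p.x_0 - xXBpostr) / p.x_0) ** 2)
    else:
        gxbmd = np.exp(p.sigman * ((xXBpostr - p.x_0) / p.x_0) ** 2)
    gxbT = p.gxbT_base * gxbmd

    dN = -kn_pT * N + kp_nT * P
    dXBprer = fappT * P - gappT * XBprer - hfT * XBprer + hbT * XBpostr
    dXBpostr = hfT * XBprer - hbT * XBpostr - gxbT * XBpostr

    # mean distortions
    denom = (
        gappT * hbT + gappT * gxbT + hfT * gxbT
        + fappT * hbT + fappT * gxbT + fappT * hfT
    )
    dutyprer = (hbT * fappT + gxbT * fappT) / denom
    dutypostr = fappT * hfT / denom

    ssprer, sspostr = p.ss_fractions
    force = SOVFThick * (xXBpostr * XBpostr + xXBprer * XBprer)
    active = force / (p.x_0 * sspostr)

    # sarcomere length dynamics
    if mode == "cell":
        dSL = (intf + (p.SLset - SL) * p.visc) / p.mass
        if not (p.SLmin <= SL <= p.SLmax):
            dSL = 0.0
        afterload = p.KSE * (p.SLset - SL) if p.SEon else 0.0
        preload = np.sign(p.SLset - p.SLrest) * p.PCon_t * (
            np.exp(p.PExp_t * abs(p.SLset - p.SLrest)) - 1.0
        )
        dintf = -_passive_force(SL, p) + preload - active + afterload
    else:
        dSL = 0.0
        dintf = 0.0

    dxXBprer = dSL / 2.0 + (p.xPsi / dutyprer) * (
        -xXBprer * fappT + hbT * (xXBpostr - p.x_0 - xXBprer)
    )
    dxXBpostr = dSL / 2.0 + (p.xPsi / dutypostr) * hfT * (p.x_0 + xXBprer - xXBpostr)

    # troponin-bound Ca feedback (chain rule of trop_total)
    frac = (XBprer + XBpostr) / (ssprer + sspostr)
    dfrac = (dXBprer + dXBpostr) / (ssprer + sspostr)
    dSOVFThin = _overlap_slope(SL, p) * dSL / p.len_thin
    dTropTot = p.Trop_conc * (
        -dSOVFThin * trpnL
        + (1.0 - SOVFThin) * dtrpnL
        + dSOVFThin * (frac * trpnH + (1.0 - frac) * trpnL)
        + SOVFThin * (
            dfrac * trpnH + frac * dtrpnH - dfrac * trpnL + (1.0 - frac) * dtrpnL
        )
    )

    dmf = np.array(
        [dN, dXBprer, dXBpostr, dxXBprer, dxXBpostr, dtrpnL, dtrpnH, dSL, dintf]
    )
    return dmf, active, dTropTot


def trop_total(mf: np.ndarray, p: RiceParameters | None = None) -> float:
    """Troponin-bound Ca2+ (uM) as a function of the myofilament state."""
    p = p or RiceParameters()
    N, XBprer, XBpostr, _, _, trpnL, trpnH, SL, _ = mf
    _, SOVFThin = sarcomere_overlap(SL, p)
    ssprer, sspostr = p.ss_fractions
    frac = (XBprer + XBpostr) / (ssprer + sspostr)
    return p.Trop_conc * (
        (1.0 - SOVFThin) * trpnL
        + SOVFThin * (frac * trpnH + (1.0 - frac) * trpnL)
    )


def steady_state_force_calcium(
    p: RiceParameters | None = None,
    Ca_grid=None,
    SL: float = 2.2,
):
    """Normalised steady-state force at clamped Ca and fixed SL.

    At isometric steady state the mean distortions settle at xXBprer = 0 and
    xXBpostr = x_0, so the 4-state chain N <-> P <-> XBprer <-> XBpostr -> P is
    linear and solved in closed form per Ca level.  Returns an array matching
    ``Ca_grid`` (uM), normalised to the fully-permissive maximum; the curve is
    monotone non-decreasing in Ca.
    """
    p = p or RiceParameters()
    Ca_grid = np.asarray(Ca_grid if Ca_grid is not None else np.logspace(-2, 2, 50), dtype=float)
    if np.any(Ca_grid <= 0) or np.any(np.diff(Ca_grid) <= 0):
        raise ValueError("Ca grid must be positive and strictly ascending")
    SOVFThick, SOVFThin = sarcomere_overlap(SL, p)
    ssprer, sspostr = p.ss_fractions

    out = np.empty_like(Ca_grid)
    for i, ca in enumerate(Ca_grid):
        trpnL = ca / (ca + p.koffLT / p.konT)
        trpnH = ca / (ca + p.koffHT / p.konT)
        trop_reg = (1.0 - SOVFThin) * trpnL + SOVFThin * trpnH
        permtot = np.sqrt(1.0 / (1.0 + (p.perm50 / trop_reg) ** p.nperm)) if trop_reg > 0 else 0.0
        inprmt = min(1.0 / permtot, 100.0) if permtot > 0 else 100.0
        kn = p.kn_p * permtot * p._q(p.Qkn_p)
        kp = p.kp_n * inprmt * p._q(p.Qkp_n)
        fapp = p.fappT
        gapp = p.gappT_base * (1.0 + (1.0 - SOVFThick) * p.gslmod)
        hf = p.hfT_base
        hb = p.hbT_base
        gxb = p.gxbT_base  # at xXBpostr = x_0, gxbmd = 1
        # steady state of the cycle, with N/P partition kp/kn
        cyc = gapp * hb + gapp * gxb + hf * gxb + fapp * (hb + gxb) + fapp * hf
        p_frac = (gapp * hb + gapp * gxb + hf * gxb) / cyc
        prer = fapp * (hb + gxb) / cyc
        postr = fapp * hf / cyc
        # N = (kp/kn) * P; normalise total occupancy to 1
        if kn == 0.0:
            out[i] = 0.0
            continue
        scale = 1.0 / (1.0 + (kp / kn) * p_frac)
        out[i] = SOVFThick * (p.x_0 * postr * scale) / (p.x_0 * sspostr)
    return out
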