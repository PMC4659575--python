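"""Electrical remodeling of the atrial myocyte by persistent AF (AFER).

Chronic atrial fibrillation remodels the maximal activities of the main
sarcolemmal channels and the SR Ca2+ handling machinery.  The AF profile
reduces I_CaL by 70%, I_Kur by 50%, I_to by 65%, doubles I_K1 and I_Ks,
increases I_NaCa by 55%, SERCA uptake by 50%, RyR release by 300% and the SR
leak by 25%; I_Kr is unchanged.  The base electrophysiology model carries no
I_KACh, so its "no change" entry is a recorded no-op.

Factors apply to the *maximal* scaling constants (conductances, i_NaCa_max,
i_up_max, k_rel, k_leak), not to instantaneous currents.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = ["RemodelingProfile", "CONTROL", "AF", "get_remodeling"]


@dataclass(frozen=True)
class RemodelingProfile:
    """Multiplicative AF-remodeling factors on maximal channel/pump activities."""

    name: str
    i_CaL: float = 1.0
    i_Kur: float = 1.0
    i_to: float = 1.0
    i_K1: float = 1.0
    i_Ks: float = 1.0
    i_NaCa: float = 1.0
    i_Kr: float = 1.0
    i_KAch: float = 1.0  # no-op: the base model has no I_KACh
    serca: float = 1.0
    ryr: float = 1.0
    sr_leak: float = 1.0

    def __post_init__(self):
        for fld in fields(self):
            if fld.type == "float" and getattr(self, fld.name) <= 0.0:
                raise ValueError(f"{self.name}: factor {fld.name} must be strictly positive")

    def factors(self) -> dict:
        # the SR leak rate is defined as I_up_max/Ca_up_max in the base model,
        # so it inherits the SERCA factor and the leak factor applies on top
        return {
            "g_CaL": self.i_CaL,
            "g_Kur_scale": self.i_Kur,
            "g_to": self.i_to,
            "g_K1": self.i_K1,
            "g_Ks": self.i_Ks,
            "i_NaCa_max": self.i_NaCa,
            "g_Kr": self.i_Kr,
            "i_up_max": self.serca,
            "k_rel": self.ryr,
            "k_leak": self.serca * self.sr_leak,
        }


CONTROL = RemodelingProfile("control")
AF = RemodelingProfile(
    "af",
    i_CaL=0.30,
    i_Kur=0.50,
    i_to=0.35,
    i_K1=2.0,
    i_Ks=2.0,
    i_NaCa=1.55,
    i_Kr=1.0,
    i_KAch=1.0,
    serca=1.5,
    ryr=4.0,
    sr_leak=1.25,
)

_PROFILES = {"control": CONTROL, "af": AF, "afer": AF}


def get_remodeling(remodeling) -> RemodelingProfile:
    if isinstance(remodeling, RemodelingProfile):
        return remodeling
    try:
        return _PROFILES[str(remodeling).lower()]
    except KeyError:
        raise KeyError(
            f"unknown remodeling profile {remodeling!r}; valid: control, af"
        ) from None
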