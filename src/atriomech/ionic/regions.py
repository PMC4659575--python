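"""Regional heterogeneity of the atrial action potential.

Scale factors on the maximal conductances G_Na, G_to, G_CaL, G_Kr, G_Kur of
the base right-atrial model reproduce the AP morphologies of the distinct
atrial regions (crista terminalis, Bachmann's bundle, valve rings, appendages,
septum, ...).  The right atrium / pectinate muscle profile is the base model
(all factors one).

The pulmonary-vein sleeve is electrophysiologically distinct (shortest atrial
APD) but its factor set is not part of the main regional table; the profile
shipped here (reduced I_CaL, enhanced I_Kr, reduced I_to) is calibrated once so
the control PV APD90 matches the reported 181 ms, and can be overridden via
``register_region``.  The left-atrial part of Bachmann's bundle is mapped to
the CT-upper-endo profile (the two are reported jointly as CT/BBLA).
"""

from __future__ import annotations

from dataclasses import dataclass

from .crn import CellParameters, BASE_PARAMETERS
from .remodeling import RemodelingProfile, CONTROL

__all__ = [
    "RegionProfile",
    "REGION_PROFILES",
    "TABLE3_REGIONS",
    "get_region",
    "register_region",
    "build_cell_parameters",
]


@dataclass(frozen=True)
class RegionProfile:
    """Multiplicative conductance scale factors for one atrial region."""

    name: str
    f_Na: float = 1.0
    f_to: float = 1.0
    f_CaL: float = 1.0
    f_Kr: float = 1.0
    f_Kur: float = 1.0

    def __post_init__(self):
        for field in ("f_Na", "f_to", "f_CaL", "f_Kr", "f_Kur"):
            if getattr(self, field) <= 0.0:
                raise ValueError(f"{self.name}: factor {field} must be strictly positive")

    def factors(self) -> dict:
        return {
            "g_Na": self.f_Na,
            "g_to": self.f_to,
            "g_CaL": self.f_CaL,
            "g_Kr": self.f_Kr,
            "g_Kur_scale": self.f_Kur,
        }


REGION_PROFILES: dict[str, RegionProfile] = {}


def register_region(profile: RegionProfile, aliases: tuple[str, ...] = ()) -> None:
    REGION_PROFILES[profile.name] = profile
    for alias in aliases:
        REGION_PROFILES[alias] = profile


register_region(RegionProfile("RA/PM"), aliases=("RA", "PM", "RA-PM"))
register_region(RegionProfile("CT-upper-endo", f_CaL=1.67))
register_region(RegionProfile("CT-upper-epi", f_to=0.50, f_CaL=1.67))
register_region(RegionProfile("CT-lower-endo", f_to=0.68, f_CaL=1.67))
register_region(RegionProfile("CT-lower-epi", f_to=0.34, f_CaL=1.67))
register_region(RegionProfile("BB-RA", f_CaL=1.67), aliases=("BBRA",))
# BB (LA part) is reported jointly with the crista terminalis (CT/BBLA row)
register_region(RegionProfile("BB-LA", f_CaL=1.67), aliases=("BBLA", "CT/BBLA"))
register_region(RegionProfile("TVR", f_CaL=0.67, f_Kr=1.53))
register_region(RegionProfile("MVR", f_CaL=0.67, f_Kr=2.44))
register_region(RegionProfile("RAA", f_to=0.68, f_CaL=1.06))
register_region(RegionProfile("LAA", f_to=0.68, f_CaL=1.06, f_Kr=1.60))
register_region(RegionProfile("LA", f_Kr=1.60))
register_region(RegionProfile("SEP", f_Na=1.50, f_CaL=0.25, f_Kur=0.67))
# PV: calibrated to the reported control APD90 of 181 ms (see module docstring)
register_region(RegionProfile("PV", f_to=0.75, f_CaL=0.42, f_Kr=3.00))

# the ten rows of the regional biomarker table, in reported order
TABLE3_REGIONS = (
    "RA/PM", "LA", "CT/BBLA", "BB-RA", "TVR", "MVR", "RAA", "LAA", "PV", "SEP",
)


def get_region(region) -> RegionProfile:
    if isinstance(region, RegionProfile):
        return region
    try:
        return REGION_PROFILES[str(region)]
    except KeyError:
        valid = sorted({p.name for p in REGION_PROFILES.values()})
        raise KeyError(
            f"unknown atrial region {region!r}; valid regions: {', '.join(valid)}"
        ) from None


def build_cell_parameters(
    region="RA/PM",
    remodeling: RemodelingProfile | str = CONTROL,
    base: CellParameters = BASE_PARAMETERS,
) -> CellParameters:
    """Base parameters with regional factors, then remodeling factors, applied
    multiplicatively (each factor exactly once)."""
    from .remodeling import get_remodeling

    profile = get_region(region)
    remodeling = get_remodeling(remodeling)
    params = base.scaled(**profile.factors())
    params = params.scaled(**remodeling.factors())
    return params.validate()
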