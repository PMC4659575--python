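"""Action-potential, Ca-transient and contraction biomarkers.

APD90 is measured from the time of maximum upstroke velocity (max dV/dt) to
90% repolarisation of the amplitude V_max - V_diastolic, with the diastolic
reference sampled immediately before the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BiomarkerSet", "apd90", "compute_biomarkers", "percent_change"]


class NoActionPotential(ValueError):
    """Raised when a trace contains no action potential to measure."""


class Unrepolarized(ValueError):
    """Raised when the AP does not repolarise within the analysed window."""


@dataclass(frozen=True)
class BiomarkerSet:
    """Per-beat electromechanical biomarkers of one cell variant."""

    apd90: float          # ms
    v_rest: float         # mV, pre-stimulus diastolic potential
    v_max: float          # mV
    ca_dias: float        # mM
    ca_sys: float         # mM
    sl_shortening: float  # % of resting sarcomere length
    force_peak: float     # normalised active force
    ca_sr: float = float("nan")  # myoplasm-referred SR Ca content (mM)

    def __post_init__(self):
        if not self.apd90 > 0:
            raise ValueError(f"APD90 must be positive, got {self.apd90}")
        if self.ca_sys < self.ca_dias:
            raise ValueError("systolic Ca below diastolic Ca")

    @property
    def ca_amplitude(self) -> float:
        return self.ca_sys - self.ca_dias


def apd90(t: np.ndarray, V: np.ndarray, v_dias: float | None = None) -> float:
    """APD at 90% repolarisation from a sampled (t, V) trace of >= 1 beat.

    ``v_dias`` is the pre-stimulus diastolic potential; if omitted the trace
    minimum is used (appropriate for idealised test waveforms).  The
    repolarisation crossing is linearly interpolated between samples.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if t.size < 3 or t.size != V.size:
        raise ValueError("need matching t/V arrays with at least 3 samples")
    v_max = float(V.max())
    if v_dias is None:
        v_dias = float(V.min())
    amplitude = v_max - v_dias
    if amplitude < 30.0:
        raise NoActionPotential(
            f"amplitude {amplitude:.1f} mV is too small for an action potential"
        )
    dv = np.diff(V) / np.diff(t)
    # first index attaining the maximal slope (tolerance absorbs float noise
    # on idealised constant-slope waveforms)
    dv_max = dv.max()
    tol = 1e-9 * max(1.0, abs(dv_max))
    i_up = int(np.argmax(dv >= dv_max - tol))
    t_up = t[i_up + 1]
    v90 = v_max - 0.9 * amplitude
    i_peak = int(np.argmax(V[i_up:])) + i_up
    below = np.where(V[i_peak:] < v90)[0]
    if below.size == 0:
        raise Unrepolarized("AP did not reach 90% repolarisation in the window")
    k = below[0] + i_peak
    # interpolate the crossing between samples k-1 and k
    t_cross = t[k - 1] + (v90 - V[k - 1]) * (t[k] - t[k - 1]) / (V[k] - V[k - 1])
    return float(t_cross - t_up)


def compute_biomarkers(
    t: np.ndarray,
    V: np.ndarray,
    Cai: np.ndarray | None = None,
    SL: np.ndarray | None = None,
    force: np.ndarray | None = None,
    SL0: float = 1.9,
    ca_sr: float = float("nan"),
) -> BiomarkerSet:
    """Biomarkers of one beat whose trace starts immediately pre-stimulus."""
    v_dias = float(V[0])
    apd = apd90(t, V, v_dias=v_dias)
    nan = float("nan")
    ca_dias = float(np.min(Cai)) if Cai is not None else nan
    ca_sys = float(np.max(Cai)) if Cai is not None else nan
    shortening = 100.0 * (SL0 - float(np.min(SL))) / SL0 if SL is not None else nan
    fpeak = float(np.max(force)) if force is not None else nan
    return BiomarkerSet(
        apd90=apd,
        v_rest=v_dias,
        v_max=float(np.max(V)),
        ca_dias=ca_dias,
        ca_sys=ca_sys,
        sl_shortening=shortening,
        force_peak=fpeak,
        ca_sr=ca_sr,
    )


def percent_change(control_value: float, test_value: float) -> float:
    """Signed percentage reduction from control to test:
    100*(control - test)/control (positive = reduction)."""
    if control_value == 0:
        raise ValueError("control value is zero; percent change undefined")
    return 100.0 * (control_value - test_value) / control_value
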