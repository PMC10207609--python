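"""Population arterial input function (AIF).

The plasma concentration time-course Cp(t) that drives the tissue model is
represented as the minimal standard bolus shape: zero before arrival, a
linear rise to peak over a short upslope, then a biexponential washout

    Cp(t0 + rise + tau) = A * (a1 * exp(-m1 * tau) + a2 * exp(-m2 * tau)).

Parameters may be specified in whole-blood or plasma units; blood values
are converted to plasma exactly once, at evaluation, via
Cp = Cb / (1 - Hct).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AIFParams", "AIFCurve", "evaluate_aif", "default_aif_params"]


@dataclass(frozen=True)
class AIFParams:
    """Parametric bolus AIF.

    t0 : bolus arrival time (s); rise_duration : linear upslope (s);
    A : peak concentration (mM) in the units named by ``specified_in``;
    a1, a2 : biexponential fractions (a1 + a2 = 1); m1, m2 : decay rates
    (s^-1) with m1 > m2 >= 0 (fast mixing phase, slow clearance phase).
    """

    t0: float = 60.0
    rise_duration: float = 5.0
    A: float = 3.0
    a1: float = 0.7
    a2: float = 0.3
    m1: float = 0.05
    m2: float = 0.002
    specified_in: str = "blood"

    def __post_init__(self):
        if self.t0 < 0 or self.rise_duration < 0:
            raise ValueError("t0 and rise_duration must be nonnegative")
        if self.A <= 0:
            raise ValueError("peak concentration A must be positive")
        if self.a1 < 0 or self.a2 < 0 or not np.isclose(self.a1 + self.a2, 1.0):
            raise ValueError("fractions must be nonnegative with a1 + a2 = 1")
        if not self.m1 > self.m2 >= 0:
            raise ValueError("decay rates must satisfy m1 > m2 >= 0")
        if self.specified_in not in ("blood", "plasma"):
            raise ValueError("specified_in must be 'blood' or 'plasma'")

    @classmethod
    def from_config(cls, cfg: dict) -> "AIFParams":
        return cls(**cfg)


@dataclass
class AIFCurve:
    """Plasma concentration sampled on a time grid (always plasma units)."""

    times: np.ndarray
    cp: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.shape != self.cp.shape or self.times.ndim != 1:
            raise ValueError("times and cp must be 1D arrays of equal length")
        if np.any(self.cp < -1e-12):
            raise ValueError("plasma concentration must be nonnegative")

    def scaled(self, factor: float) -> "AIFCurve":
        return AIFCurve(times=self.times, cp=self.cp * factor)


def default_aif_params() -> AIFParams:
    return AIFParams()


def evaluate_aif(params: AIFParams, times, hematocrit: float) -> AIFCurve:
    """Sample the AIF on ``times`` (s) and return it in plasma units.

    The curve is 0 for t < t0, rises linearly to the peak over
    ``rise_duration``, then decays biexponentially.  If the parameters are
    specified in whole blood, the plasma curve is Cb / (1 - Hct).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1D array")
    if not 0.0 < hematocrit < 1.0:
        raise ValueError("hematocrit must be in (0, 1)")

    t_peak = params.t0 + params.rise_duration
    c = np.zeros_like(times)
    rising = (times >= params.t0) & (times < t_peak)
    if params.rise_duration > 0:
        c[rising] = params.A * (times[rising] - params.t0) / params.rise_duration
    decay = times >= t_peak
    tau = times[decay] - t_peak
    c[decay] = params.A * (
        params.a1 * np.exp(-params.m1 * tau) + params.a2 * np.exp(-params.m2 * tau)
    )
    if params.specified_in == "blood":
        c = c / (1.0 - hematocrit)
    return AIFCurve(times=times, cp=c)
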