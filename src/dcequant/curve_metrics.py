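"""Semi-quantitative perfusion metrics: area under the curve, maximum slope.

These model-free descriptors of the enhancement curve complement the
pharmacokinetic fit: the area under the curve (AUC) and the maximum
upslope of the enhancement time-course characterise tumor perfusion
without committing to a compartment model.  The default curve basis is
relative signal enhancement (S - S_base) / S_base; a concentration basis
is available for cross-study comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core_io import AcquisitionParams, DynamicSeries, LabelMask, ScalarMap

__all__ = ["EnhancementCurve", "auc", "max_slope", "metric_maps"]


@dataclass
class EnhancementCurve:
    """One pixel's (or ROI's) enhancement time-course."""

    times: np.ndarray
    values: np.ndarray
    basis: str = "signal_enhancement"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.basis not in ("signal_enhancement", "concentration"):
            raise ValueError(f"unknown basis {self.basis!r}")


def auc(curve: EnhancementCurve, window) -> float:
    """Trapezoidal integral of the curve over ``window = (t_start, t_end)``.

    Window endpoints need not coincide with samples; the curve is linearly
    interpolated at the endpoints, so the trapezoid rule stays exact for
    piecewise-linear data.  Units: s (enhancement basis) or mM s
    (concentration basis).
    """
    t0, t1 = float(window[0]), float(window[1])
    if not t0 < t1:
        raise ValueError("window must satisfy t_start < t_end")
    if t0 < curve.times[0] - 1e-9 or t1 > curve.times[-1] + 1e-9:
        raise ValueError("window lies outside the sampled time span")
    inside = (curve.times > t0) & (curve.times < t1)
    ts = np.concatenate(([t0], curve.times[inside], [t1]))
    vs = np.interp(ts, curve.times, curve.values)
    return float(np.trapezoid(vs, ts))


def max_slope(
    curve: EnhancementCurve, smooth_window: int = 5, t_min: float | None = None
) -> float:
    """Maximum upslope (per s) after box smoothing.

    The curve is smoothed with a centred moving average of odd width
    ``smooth_window`` (a line passes through unchanged), then the maximum
    of centred finite differences is taken over samples with
    t >= ``t_min`` (default: the whole curve).
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    n = curve.times.size
    if n < smooth_window + 2:
        raise ValueError("curve too short for the requested smoothing window")
    smoothed = uniform_filter1d(curve.values, size=smooth_window, mode="nearest")
    slopes = np.empty(n)
    slopes[1:-1] = (smoothed[2:] - smoothed[:-2]) / (curve.times[2:] - curve.times[:-2])
    slopes[0] = (smoothed[1] - smoothed[0]) / (curve.times[1] - curve.times[0])
    slopes[-1] = (smoothed[-1] - smoothed[-2]) / (curve.times[-1] - curve.times[-2])
    if t_min is not None:
        sel = curve.times >= t_min
        slopes = slopes[sel]
    return float(np.max(slopes))


def metric_maps(
    series: DynamicSeries,
    mask: LabelMask,
    params: AcquisitionParams,
    basis: str = "signal_enhancement",
    window=None,
    smooth_window: int = 5,
) -> dict:
    """Pixel-wise AUC and maximum-slope maps over the masked region.

    For the signal-enhancement basis each pixel's curve is
    (S - S_base) / S_base with S_base the pre-injection baseline mean;
    concentration series are used as-is.  AUC integrates from
    ``injection_start`` to the end of the scan unless ``window`` overrides
    it; the slope search is restricted to post-injection samples.
    """
    if mask.grid_shape != series.grid_shape:
        raise ValueError("mask grid must match the series grid")
    sel = mask.labels != 0
    if not sel.any():
        raise ValueError("empty mask: no pixels to analyse")
    times = series.times
    n_base = int(np.searchsorted(times, params.injection_start))
    if n_base < 2:
        raise ValueError("need at least 2 baseline frames before injection")
    if window is None:
        window = (params.injection_start, float(times[-1]))

    shape = series.grid_shape
    auc_map = np.full(shape, np.nan)
    slope_map = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for r, c in zip(*np.nonzero(sel)):
        y = series.data[r, c, :]
        if not np.all(np.isfinite(y)):
            continue
        if basis == "signal_enhancement":
            base = y[:n_base].mean()
            if base <= 0:
                continue
            y = (y - base) / base
        curve = EnhancementCurve(times, y, basis=basis)
        auc_map[r, c] = auc(curve, window)
        slope_map[r, c] = max_slope(curve, smooth_window, t_min=params.injection_start)
        valid[r, c] = True
    return {
        "AUC": ScalarMap(auc_map, "AUC", valid, series.pixel_spacing),
        "slope_max": ScalarMap(slope_map, "slope_max", valid, series.pixel_spacing),
    }
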