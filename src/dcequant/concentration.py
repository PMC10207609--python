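"""Signal <-> gadolinium concentration conversion for spoiled gradient echo.

The dynamic acquisition is a spoiled gradient echo (FLASH), whose
steady-state magnitude signal is

    S = M0 sin(alpha) (1 - E1) / (1 - cos(alpha) E1),   E1 = exp(-TR * R1),

with R1(t) = 1/T10 + r1 * C(t).  T2*/TE weighting is absorbed into M0.
The inversion used here is the closed-form solution of the SPGR law for R1
(not the linearised low-concentration approximation): albumin-binding
agents at preclinical doses can leave the linear regime near vessels.
Per-pixel M0 is calibrated from the pre-injection baseline signal and the
pre-contrast T1 map, which makes the recovered concentration invariant to
any global receiver gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import MS_PER_SECOND, AcquisitionParams, DynamicSeries, ScalarMap

__all__ = ["ConversionContext", "spgr_signal", "signal_to_concentration"]


@dataclass
class ConversionContext:
    """Inputs needed to convert a dynamic signal series to concentration.

    ``t10`` is the pre-contrast T1 map (ms) already resampled to the
    dynamic grid; ``baseline_frames`` the index range (start, stop) of
    pre-injection frames used for M0 calibration.
    """

    t10: ScalarMap
    baseline_frames: tuple
    params: AcquisitionParams

    def __post_init__(self):
        if self.t10.semantic != "T1_ms":
            raise ValueError("t10 must be a T1_ms map")
        b0, b1 = self.baseline_frames
        if b1 <= b0:
            raise ValueError("baseline window must be nonempty")

    @classmethod
    def from_params(
        cls, t10: ScalarMap, params: AcquisitionParams, guard_frames: int = 2
    ) -> "ConversionContext":
        """Baseline = all frames before injection_start minus a guard."""
        n_base = int(np.floor(params.injection_start / params.frame_interval))
        n_base -= guard_frames
        if n_base < 1:
            raise ValueError("no usable pre-injection baseline frames")
        return cls(t10=t10, baseline_frames=(0, n_base), params=params)


def spgr_signal(c, t10_ms, m0, params: AcquisitionParams):
    """SPGR magnitude signal for concentration ``c`` (mM).

    ``t10_ms`` is the pre-contrast T1 (ms), ``m0`` the equilibrium signal
    (a.u., absorbing proton density, T2* and gain).  Broadcasts over
    arrays.  Strictly increasing in ``c`` for flip angles in (0, 90].
    """
    c = np.asarray(c, dtype=float)
    t10_s = np.asarray(t10_ms, dtype=float) / MS_PER_SECOND
    if np.any(t10_s <= 0):
        raise ValueError("T1 must be positive")
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    alpha = np.deg2rad(params.flip_angle)
    tr_s = params.tr_dce / MS_PER_SECOND
    r1_total = 1.0 / t10_s + params.r1 * c
    e1 = np.exp(-tr_s * r1_total)
    return m0 * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)


def _invert_spgr_to_r1(signal, m0, params: AcquisitionParams):
    """Solve the SPGR law for R1 (s^-1); returns (r1_total, physical mask).

    The physical branch requires E1 in (0, 1); signals at or above the
    saturation plateau m0 sin(alpha) have no finite solution and are
    flagged unphysical rather than extrapolated.
    """
    alpha = np.deg2rad(params.flip_angle)
    tr_s = params.tr_dce / MS_PER_SECOND
    sa, ca = np.sin(alpha), np.cos(alpha)
    num = m0 * sa - signal
    den = m0 * sa - signal * ca
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = num / den
        physical = (e1 > 0) & (e1 < 1) & np.isfinite(e1)
        r1 = np.where(physical, -np.log(np.where(physical, e1, 0.5)) / tr_s, np.nan)
    return r1, physical


def signal_to_concentration(
    series: DynamicSeries, ctx: ConversionContext
) -> tuple:
    """Convert a signal-unit dynamic series to concentration (mM).

    Per pixel, M0 is calibrated by inverting the SPGR law at c = 0 against
    the baseline-frame mean signal; every frame is then inverted in closed
    form and c = (R1 - 1/T10) / r1.  Noise-driven negative concentrations
    are retained (not clipped) so downstream least squares stays unbiased.

    Returns ``(conc_series, valid)`` where ``valid`` marks pixels whose
    baseline was positive, whose T10 was valid, and whose every frame
    admitted a physical inversion; other pixels are NaN throughout.
    """
    if series.unit != "signal_au":
        raise ValueError("expected a signal_au series")
    if series.grid_shape != ctx.t10.values.shape:
        raise ValueError("series grid must match the T10 map grid")
    params = ctx.params
    b0, b1 = ctx.baseline_frames
    if b1 > series.n_frames:
        raise ValueError("baseline window exceeds the series")

    t10_ms = ctx.t10.values
    t10_s = t10_ms / MS_PER_SECOND
    baseline = series.data[:, :, b0:b1].mean(axis=2)

    valid = ctx.t10.valid & (baseline > 0) & (t10_ms > 0)

    alpha = np.deg2rad(params.flip_angle)
    tr_s = params.tr_dce / MS_PER_SECOND
    with np.errstate(divide="ignore", invalid="ignore"):
        e10 = np.exp(-tr_s / t10_s)
        m0 = baseline * (1.0 - np.cos(alpha) * e10) / (np.sin(alpha) * (1.0 - e10))

    conc = np.full(series.data.shape, np.nan)
    m0_3d = m0[:, :, None]
    r1_total, physical = _invert_spgr_to_r1(series.data, m0_3d, params)
    with np.errstate(invalid="ignore"):
        conc = (r1_total - 1.0 / t10_s[:, :, None]) / params.r1
    valid = valid & np.all(physical, axis=2)
    conc[~valid, :] = np.nan

    out = DynamicSeries(
        data=conc,
        times=series.times,
        unit="concentration_mM",
        pixel_spacing=series.pixel_spacing,
        slice_thickness=series.slice_thickness,
    )
    return out, valid
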