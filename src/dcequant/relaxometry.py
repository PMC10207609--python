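"""T1 mapping from variable-TR data, delta-T1, and grid resampling.

T1 is estimated per pixel from a saturation-recovery ladder
S(TR) = M0 (1 - exp(-TR / T1)) acquired at several repetition times; the
RARE echo-train weighting is absorbed into M0, the standard simplification
for variable-TR fitting.  Delta-T1 (pre-contrast minus post-contrast T1,
per ROI) measures contrast-agent retention: residual gadolinium shortens
T1, so retaining tissue has delta-T1 > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit

from .core_io import LabelMask, ScalarMap

__all__ = ["T1FitResult", "fit_t1", "delta_t1", "resample_linear"]

T1_BOUNDS_MS = (50.0, 10000.0)


@dataclass
class T1FitResult:
    """Pixel-wise T1/M0 maps with residuals and a convergence mask."""

    t1: ScalarMap
    m0: ScalarMap
    rss: np.ndarray
    converged: np.ndarray


def _recovery(tr, m0, t1):
    return m0 * (1.0 - np.exp(-tr / t1))


def _t1_init(trs_sorted, sig_sorted):
    """Initial guess: M0 from the longest-TR signal, T1 from the TR at
    half-maximal recovery via linear interpolation of the ladder."""
    m0 = float(sig_sorted[-1])
    half = 0.5 * m0
    idx = np.searchsorted(sig_sorted, half)
    if idx == 0:
        tr_half = trs_sorted[0]
    elif idx >= trs_sorted.size:
        tr_half = trs_sorted[-1]
    else:
        s0, s1 = sig_sorted[idx - 1], sig_sorted[idx]
        f = 0.0 if s1 == s0 else (half - s0) / (s1 - s0)
        tr_half = trs_sorted[idx - 1] + f * (trs_sorted[idx] - trs_sorted[idx - 1])
    # S(TR)=M0/2 at TR = T1 ln 2
    t1 = float(np.clip(tr_half / np.log(2.0), *T1_BOUNDS_MS))
    return max(m0, 1e-6), t1


def fit_pixel_t1(trs: np.ndarray, signal: np.ndarray):
    """Fit one saturation-recovery curve; returns (t1, m0, rss, converged)."""
    order = np.argsort(trs)
    trs_s, sig_s = trs[order], signal[order]
    smax = float(np.max(sig_s))
    if smax <= 0 or (smax - float(np.min(sig_s))) < 1e-9 * max(smax, 1.0):
        return np.nan, np.nan, np.nan, False  # no recovery curvature
    p0 = _t1_init(trs_s, sig_s)
    try:
        popt, _ = curve_fit(
            _recovery,
            trs_s,
            sig_s,
            p0=p0,
            bounds=([0.0, T1_BOUNDS_MS[0]], [np.inf, T1_BOUNDS_MS[1]]),
            xtol=1e-12,
            ftol=1e-12,
            maxfev=2000,
        )
    except RuntimeError:
        return np.nan, np.nan, np.nan, False
    m0, t1 = float(popt[0]), float(popt[1])
    rss = float(np.sum((_recovery(trs_s, m0, t1) - sig_s) ** 2))
    # a T1 pinned to either bound is not a trustworthy estimate
    pinned = t1 <= T1_BOUNDS_MS[0] * (1 + 1e-9) or t1 >= T1_BOUNDS_MS[1] * (1 - 1e-9)
    return t1, m0, rss, not pinned


def fit_t1(vtr, mask: LabelMask | None = None) -> T1FitResult:
    """Per-pixel nonlinear least-squares T1/M0 fit of a variable-TR series.

    Pixels outside ``mask`` (if given) are skipped and left invalid;
    non-converged pixels (flat signal, bound-pinned T1, solver failure) are
    flagged, never silently filled.
    """
    trs = np.asarray(vtr.tr_values, dtype=float)
    if trs.size < 3:
        raise ValueError("T1 fitting needs at least 3 TR points")
    if np.any(vtr.data < 0):
        raise ValueError("VTR signals must be nonnegative")
    shape = vtr.grid_shape
    if mask is not None:
        if mask.grid_shape != shape:
            raise ValueError("mask grid must match the VTR grid")
        sel = mask.labels != 0
    else:
        sel = np.ones(shape, dtype=bool)

    t1 = np.full(shape, np.nan)
    m0 = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    for r, c in zip(*np.nonzero(sel)):
        t1_i, m0_i, rss_i, ok = fit_pixel_t1(trs, vtr.data[r, c, :])
        if ok:
            t1[r, c], m0[r, c], rss[r, c], conv[r, c] = t1_i, m0_i, rss_i, True
    return T1FitResult(
        t1=ScalarMap(t1, "T1_ms", conv, vtr.pixel_spacing),
        m0=ScalarMap(m0, "M0_au", conv, vtr.pixel_spacing),
        rss=rss,
        converged=conv,
    )


def delta_t1(pre: T1FitResult, post: T1FitResult, rois: LabelMask) -> dict:
    """Per-ROI delta-T1 (ms): mean pre-contrast T1 minus mean post-contrast T1.

    Means are taken over pixels converged in the respective map; the value
    is reported unclamped (a noisy contrast-free ROI may give a small
    negative number).  Raises if any ROI has no converged pixels.
    """
    if pre.t1.values.shape != post.t1.values.shape:
        raise ValueError("pre and post maps must share a grid")
    if rois.grid_shape != pre.t1.values.shape:
        raise ValueError("ROI mask grid must match the maps")
    out = {}
    for label in sorted(set(np.unique(rois.labels)) - {0}):
        region = rois.labels == label
        name = rois.names.get(int(label), str(label))
        pre_sel = region & pre.converged
        post_sel = region & post.converged
        if not pre_sel.any() or not post_sel.any():
            raise ValueError(f"ROI {name!r} has no converged pixels")
        out[name] = float(pre.t1.values[pre_sel].mean() - post.t1.values[post_sel].mean())
    return out


def resample_linear(src: ScalarMap, target_shape, target_spacing=None) -> ScalarMap:
    """Bilinear resampling of a map onto a new grid covering the same FOV.

    Pixel centres of both grids are placed at (i + 1/2) * spacing across a
    shared field of view, matching how a scanner reconstructs two matrices
    of the same FOV.  Values cannot overshoot (bilinear weights are convex);
    the validity mask resamples conservatively — a target pixel is valid
    only if every source pixel with nonzero weight is valid.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if len(target_shape) != 2 or min(target_shape) < 1:
        raise ValueError("target grid must be 2D and nonempty")
    src_shape = src.values.shape
    fov = (src_shape[0] * src.pixel_spacing, src_shape[1] * src.pixel_spacing)
    if target_spacing is None:
        target_spacing = fov[0] / target_shape[0]

    # target pixel-centre coordinates in source index space
    rows = (np.arange(target_shape[0]) + 0.5) * (fov[0] / target_shape[0])
    cols = (np.arange(target_shape[1]) + 0.5) * (fov[1] / target_shape[1])
    ri = rows / src.pixel_spacing - 0.5
    ci = cols / src.pixel_spacing - 0.5
    rr, cc = np.meshgrid(ri, ci, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])

    filled = np.where(src.valid, src.values, 0.0)
    vals = map_coordinates(filled, coords, order=1, mode="nearest").reshape(target_shape)
    wsum = map_coordinates(
        src.valid.astype(float), coords, order=1, mode="nearest"
    ).reshape(target_shape)
    valid = wsum > 1.0 - 1e-9  # all contributing source pixels valid
    out = np.where(valid, vals, np.nan)
    return ScalarMap(out, src.semantic, valid, float(target_spacing))
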