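"""Digital tumor phantoms with known tissue and pharmacokinetic ground truth.

The phantom emulates the single-slice preclinical acquisition the pipeline
targets: a tumor with a perfused viable rim and a poorly perfused necrotic
core embedded next to a muscle band, imaged with (a) a variable-TR
saturation-recovery ladder before and after contrast, and (b) a dynamic
spoiled-gradient-echo series during bolus passage of a macromolecular
agent.  Every region has known T1, M0, Ktrans, ve, vp, so recovery error
of the full pipeline can be measured exactly.  Magnitude images receive
Rician noise (the physically correct model for magnitude MRI); the
high-SNR VTR ladder may use Gaussian noise.

Multi-animal cohort scenarios apply group-level multiplicative effects to
rim Ktrans/vp on top of between-animal lognormal biological variability,
emulating treated-versus-control contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import i0e, i1e

from .aif import AIFCurve
from .concentration import spgr_signal
from .core_io import AcquisitionParams, DynamicSeries, LabelMask, ScalarMap, VTRSeries
from .tofts import tofts_forward

__all__ = [
    "RegionParams",
    "PhantomTruth",
    "ScenarioSpec",
    "make_truth",
    "simulate_vtr",
    "simulate_dce",
    "simulate_cohort",
    "place_rim_rois",
    "rician_mean",
    "add_rician_noise",
    "DEFAULT_REGION_PARAMS",
]

REGION_LABELS = {"background": 0, "muscle": 1, "tumor_rim": 2, "tumor_core": 3}


@dataclass(frozen=True)
class RegionParams:
    """Ground-truth tissue parameters of one phantom region.

    T1_pre in ms, M0 in a.u., Ktrans in min^-1, ve/vp fractions with
    ve + vp <= 1.
    """

    t1_pre: float
    m0: float
    ktrans: float
    ve: float
    vp: float

    def __post_init__(self):
        if self.t1_pre <= 0:
            raise ValueError("T1_pre must be positive")
        if self.ktrans < 0 or self.ve < 0 or self.vp < 0:
            raise ValueError("PK parameters must be nonnegative")
        if self.ve + self.vp > 1.0:
            raise ValueError(f"ve + vp = {self.ve + self.vp:.3f} exceeds 1")


# Field-typical magnitudes for a 9.4 T mammary tumor phantom; synthetic
# stand-ins, not estimates of any particular tumor line's biology.
DEFAULT_REGION_PARAMS = {
    "background": RegionParams(t1_pre=1000.0, m0=0.0, ktrans=0.0, ve=0.0, vp=0.0),
    "muscle": RegionParams(t1_pre=1200.0, m0=900.0, ktrans=0.08, ve=0.15, vp=0.02),
    "tumor_rim": RegionParams(t1_pre=1800.0, m0=1000.0, ktrans=0.25, ve=0.35, vp=0.04),
    "tumor_core": RegionParams(t1_pre=1800.0, m0=1000.0, ktrans=0.02, ve=0.10, vp=0.01),
}


@dataclass
class PhantomTruth:
    """Region masks plus per-region ground truth on a square grid."""

    masks: LabelMask
    regions: dict  # name -> RegionParams
    pixel_spacing: float
    seed: int

    def __post_init__(self):
        present = set(np.unique(self.masks.labels))
        for name, label in REGION_LABELS.items():
            if label in present and name not in self.regions:
                raise ValueError(f"region {name!r} present in mask but has no params")

    def param_map(self, attr: str) -> np.ndarray:
        """Broadcast one ground-truth parameter over the grid."""
        out = np.zeros(self.masks.grid_shape)
        for name, label in REGION_LABELS.items():
            if name in self.regions:
                out[self.masks.labels == label] = getattr(self.regions[name], attr)
        return out

    def t1_map(self) -> ScalarMap:
        vals = self.param_map("t1_pre")
        return ScalarMap(vals, "T1_ms", vals > 0, self.pixel_spacing)


@dataclass(frozen=True)
class ScenarioSpec:
    """Two-group cohort scenario.

    ``group_effects`` maps group name -> dict of multiplicative factors on
    rim ``ktrans``/``vp`` (1.0 = no effect) and an optional additive
    ``retention_shift_mM`` on residual contrast for post-contrast T1
    mapping.  ``biological_cv`` is the between-animal lognormal coefficient
    of variation applied to rim PK parameters.
    """

    name: str
    n_per_group: int
    group_effects: dict
    noise_snr: float
    seed: int
    biological_cv: float = 0.15

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need at least 2 animals per group")
        if self.noise_snr <= 0:
            raise ValueError("noise_snr must be positive")
        if len(self.group_effects) != 2:
            raise ValueError("exactly two groups are compared")
        for g, eff in self.group_effects.items():
            for key in ("ktrans", "vp"):
                if eff.get(key, 1.0) <= 0:
                    raise ValueError(f"group {g}: multiplier {key} must be positive")


def make_truth(
    grid_shape=(96, 96),
    region_params: dict | None = None,
    pixel_spacing: float = 0.1875,
    seed: int = 0,
    tumor_radius_frac: float = 0.30,
    core_radius_frac: float = 0.55,
) -> PhantomTruth:
    """Build a deterministic phantom: core disk, rim annulus, muscle band.

    The tumor sits at the grid centre; the viable rim is the annulus
    between ``core_radius_frac`` x tumor radius and the tumor radius; a
    muscle band runs along the bottom edge.  Geometry is a pure function of
    the arguments, so equal seeds (and equal everything else) give
    identical phantoms.
    """
    params = dict(DEFAULT_REGION_PARAMS)
    if region_params:
        params.update(region_params)
    for name, rp in params.items():
        if not isinstance(rp, RegionParams):
            params[name] = RegionParams(**rp)  # validates ve + vp <= 1

    h, w = grid_shape
    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    r_tumor = tumor_radius_frac * min(h, w)
    r_core = core_radius_frac * r_tumor
    labels[r <= r_tumor] = REGION_LABELS["tumor_rim"]
    labels[r <= r_core] = REGION_LABELS["tumor_core"]
    band = max(2, h // 12)
    muscle_rows = slice(h - band, h)
    muscle = np.zeros_like(labels, dtype=bool)
    muscle[muscle_rows, :] = True
    muscle &= labels == 0
    labels[muscle] = REGION_LABELS["muscle"]

    names = {v: k for k, v in REGION_LABELS.items() if v != 0}
    return PhantomTruth(
        masks=LabelMask(labels, names),
        regions=params,
        pixel_spacing=pixel_spacing,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Noise


def add_rician_noise(signal: np.ndarray, sd: float, rng: np.random.Generator):
    """Rician-distributed magnitude: |signal + n1 + i n2| with n ~ N(0, sd)."""
    if sd == 0:
        return np.asarray(signal, dtype=float).copy()
    n1 = rng.normal(0.0, sd, size=np.shape(signal))
    n2 = rng.normal(0.0, sd, size=np.shape(signal))
    return np.hypot(np.asarray(signal) + n1, n2)


def rician_mean(nu, sd):
    """Analytic mean of a Rician(nu, sd) variable.

    E[R] = sd sqrt(pi/2) L_{1/2}(-nu^2 / (2 sd^2)), evaluated with
    exponentially scaled Bessel functions for numerical stability at high
    SNR.  Used to check that simulated noise carries the correct
    magnitude-MRI bias.
    """
    nu = np.asarray(nu, dtype=float)
    if sd == 0:
        return nu.copy()
    x = nu**2 / (4.0 * sd**2)  # argument of the scaled Bessels
    # L_{1/2}(-z) = e^{z/2} [(1+z) I0(z/2) + z I1(z/2)] with z = nu^2/(2 sd^2)
    z = 2.0 * x
    lag = (1.0 + z) * i0e(x) + z * i1e(x)  # e^{-x} factored into i*e
    return sd * np.sqrt(np.pi / 2.0) * lag


# ---------------------------------------------------------------------------
# Forward simulation


def simulate_vtr(
    truth: PhantomTruth,
    params: AcquisitionParams,
    phase: str = "pre",
    concentration: ScalarMap | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_model: str = "gaussian",
) -> VTRSeries:
    """Forward-simulate the variable-TR T1-mapping ladder.

    Noiseless pixel signal follows saturation recovery
    S(TR) = M0 (1 - exp(-TR / T1)).  For ``phase='post'`` a residual
    concentration map shortens T1 via R1 = 1/T1_pre + r1 C (the long
    post-contrast mapping scan sees a quasi-static residual, so a frozen
    map is used).  Noise is Gaussian by default (the ladder is high-SNR);
    ``noise_model='rician'`` applies magnitude noise instead.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if phase not in ("pre", "post"):
        raise ValueError("phase must be 'pre' or 'post'")
    if phase == "post" and concentration is None:
        raise ValueError("phase='post' requires a residual concentration map")

    t1 = truth.param_map("t1_pre")
    m0 = truth.param_map("m0")
    if phase == "post":
        if concentration.values.shape != t1.shape:
            raise ValueError("concentration map grid must match the phantom")
        c = np.where(concentration.valid, concentration.values, 0.0)
        with np.errstate(divide="ignore"):
            r1_map = np.where(t1 > 0, 1.0 / (t1 / 1000.0), np.inf) + params.r1 * c
        t1 = np.where(t1 > 0, 1000.0 / r1_map, 0.0)

    trs = np.asarray(params.vtr_ladder, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rec = 1.0 - np.exp(-trs[None, None, :] / np.where(t1 > 0, t1, np.inf)[:, :, None])
    data = m0[:, :, None] * rec
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        if noise_model == "rician":
            data = add_rician_noise(data, noise_sd, rng)
        else:
            data = data + rng.normal(0.0, noise_sd, size=data.shape)
        data = np.maximum(data, 0.0)  # magnitude images are nonnegative
    return VTRSeries(data=data, tr_values=trs, pixel_spacing=truth.pixel_spacing)


def simulate_dce(
    truth: PhantomTruth,
    aif: AIFCurve,
    params: AcquisitionParams,
    snr: float = np.inf,
    seed: int = 0,
) -> tuple:
    """Forward-simulate the dynamic series; returns (signal, truth_conc).

    Per region, the tissue concentration follows the extended Tofts model
    with that region's ground truth; the signal follows the SPGR law with
    the region's T1_pre and M0.  Rician noise is added at the stated SNR,
    defined as (noiseless baseline mean signal in the tumor rim) / sd.
    Frames before the bolus have zero concentration by construction of the
    AIF.
    """
    if not snr > 0:
        raise ValueError("snr must be positive (np.inf disables noise)")
    times = params.frame_times
    if aif.times.shape != times.shape or not np.allclose(aif.times, times):
        raise ValueError("AIF must be sampled on the dynamic time grid")

    shape = truth.masks.grid_shape
    conc = np.zeros(shape + (times.size,))
    signal = np.zeros_like(conc)
    for name, label in REGION_LABELS.items():
        region = truth.masks.labels == label
        if not region.any() or name not in truth.regions:
            continue
        rp = truth.regions[name]
        ct = tofts_forward(rp.ktrans, rp.ve, rp.vp, aif, times)
        conc[region, :] = ct
        if rp.m0 > 0:
            signal[region, :] = spgr_signal(ct, rp.t1_pre, rp.m0, params)

    if np.isfinite(snr):
        rim = truth.masks.labels == REGION_LABELS["tumor_rim"]
        n_base = max(1, int(params.injection_start / params.frame_interval))
        baseline = float(signal[rim, :n_base].mean())
        sd = baseline / snr
        rng = np.random.default_rng(seed)
        signal = add_rician_noise(signal, sd, rng)

    common = dict(
        times=times,
        pixel_spacing=truth.pixel_spacing,
        slice_thickness=1.0,
    )
    return (
        DynamicSeries(data=signal, unit="signal_au", **common),
        DynamicSeries(data=conc, unit="concentration_mM", **common),
    )


# ---------------------------------------------------------------------------
# ROIs and cohorts


def place_rim_rois(truth: PhantomTruth, n_rois: int = 3, half_size: int = 1) -> LabelMask:
    """Place ``n_rois`` square, non-overlapping ROIs in the viable rim.

    ROIs are centred at equally spaced angles on the mid-rim circle,
    mirroring the protocol of sampling the viable tumor periphery while
    excluding the necrotic core.
    """
    h, w = truth.masks.grid_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rim = truth.masks.labels == REGION_LABELS["tumor_rim"]
    ys, xs = np.nonzero(rim)
    rr = np.hypot(ys - cy, xs - cx)
    r_mid = 0.5 * (rr.min() + rr.max())
    labels = np.zeros((h, w), dtype=np.int32)
    names = {}
    for k in range(n_rois):
        ang = 2.0 * np.pi * k / n_rois
        y = int(round(cy + r_mid * np.sin(ang)))
        x = int(round(cx + r_mid * np.cos(ang)))
        block = np.zeros_like(labels, dtype=bool)
        block[
            max(0, y - half_size) : y + half_size + 1,
            max(0, x - half_size) : x + half_size + 1,
        ] = True
        block &= rim & (labels == 0)
        labels[block] = k + 1
        names[k + 1] = f"roi_{k + 1}"
        if not block.any():
            raise ValueError(f"could not place ROI {k + 1} inside the rim")
    return LabelMask(labels, names)


def _animal_truth(
    base: PhantomTruth, effects: dict, rng: np.random.Generator, cv: float
) -> PhantomTruth:
    """Per-animal truth: group effects on rim Ktrans/vp, lognormal biology."""
    regions = dict(base.regions)
    rim = regions["tumor_rim"]
    sigma = np.sqrt(np.log(1.0 + cv**2)) if cv > 0 else 0.0

    def draw(mean):
        if sigma == 0:
            return mean
        return float(mean * rng.lognormal(-0.5 * sigma**2, sigma))

    ktrans = draw(rim.ktrans * effects.get("ktrans", 1.0))
    vp = draw(rim.vp * effects.get("vp", 1.0))
    ve = min(draw(rim.ve), 1.0 - vp)
    regions["tumor_rim"] = replace(rim, ktrans=ktrans, ve=ve, vp=vp)
    return replace(base, regions=regions)


def simulate_cohort(
    spec: ScenarioSpec,
    base_truth: PhantomTruth,
    params: AcquisitionParams,
    aif: AIFCurve,
) -> tuple:
    """Simulate all animals of a two-group scenario.

    Returns ``(datasets, truth_table)``: per animal a dict with the
    animal's id, group, per-animal :class:`PhantomTruth`, noisy signal
    series and noiseless truth concentration; and a tidy DataFrame of every
    animal's true rim parameters.  Noise and biology seeds derive from
    ``spec.seed`` through independent spawned streams, so cohorts are
    reproducible end to end.
    """
    datasets = []
    rows = []
    root = np.random.SeedSequence(spec.seed)
    idx = 0
    for group, effects in spec.group_effects.items():
        for j in range(spec.n_per_group):
            # one spawned stream per animal, split for biology vs noise
            animal_ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(idx,))
            bio_child, noise_child = animal_ss.spawn(2)
            bio_rng = np.random.default_rng(bio_child)
            noise_seed = int(noise_child.generate_state(1)[0] % (2**31))
            truth = _animal_truth(base_truth, effects, bio_rng, spec.biological_cv)
            signal, conc = simulate_dce(truth, aif, params, snr=spec.noise_snr, seed=noise_seed)
            animal_id = f"{spec.name}_{group}_{j:02d}"
            datasets.append(
                {
                    "animal_id": animal_id,
                    "group": group,
                    "truth": truth,
                    "signal": signal,
                    "conc_truth": conc,
                }
            )
            rim = truth.regions["tumor_rim"]
            rows.append(
                {
                    "animal_id": animal_id,
                    "group": group,
                    "ktrans_true": rim.ktrans,
                    "ve_true": rim.ve,
                    "vp_true": rim.vp,
                    "t1_pre_true": rim.t1_pre,
                }
            )
            idx += 1
    return datasets, pd.DataFrame(rows)
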