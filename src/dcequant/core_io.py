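"""Core data model, NIfTI + JSON-sidecar I/O, and unit conventions.

All raster data (dynamic series, variable-TR series, parameter maps, label
masks) live on row-major 2D grids with 0-based indices.  NIfTI-1 carries the
voxel data; per-series metadata that NIfTI cannot hold natively (frame
timestamps, the TR ladder, semantic tags, label names) goes into a JSON
sidecar next to the image file.

Unit conventions (normalised here, at the boundary, and nowhere else):

* time axes are seconds internally; repetition/echo times are carried in
  milliseconds as acquired;
* relaxivity may be given in ms^-1 mM^-1 (common on preclinical systems) or
  s^-1 mM^-1 and is stored in s^-1 mM^-1;
* rate constants (Ktrans, kep) are reported in min^-1, the field convention.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "AcquisitionParams",
    "DynamicSeries",
    "VTRSeries",
    "ScalarMap",
    "LabelMask",
    "ConfigError",
    "FormatError",
    "read_series",
    "write_series",
    "volume_from_mask",
    "load_config",
    "write_stage_log",
    "SECONDS_PER_MINUTE",
    "MS_PER_SECOND",
]

SECONDS_PER_MINUTE = 60.0
MS_PER_SECOND = 1000.0

#: semantic tags a ScalarMap may carry
MAP_SEMANTICS = (
    "T1_ms",
    "M0_au",
    "Ktrans_per_min",
    "ve",
    "vp",
    "kep_per_min",
    "AUC",
    "slope_max",
    "deltaT1_ms",
    "rss",
    "concentration_mM",
)


class ConfigError(ValueError):
    """Missing or inconsistent configuration / sidecar metadata."""


class FormatError(ValueError):
    """On-disk data does not match its declared kind or shape."""


def _as_float_array(x, ndim: int, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != ndim:
        raise FormatError(f"{name} must be {ndim}-dimensional, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition and contrast-agent parameters for one imaging session.

    Parameters
    ----------
    tr_dce : float
        Repetition time of the dynamic spoiled-gradient-echo sequence (ms).
    te_dce : float
        Echo time of the dynamic sequence (ms); carried as metadata, the
        signal model absorbs T2* weighting into M0.
    flip_angle : float
        Excitation flip angle of the dynamic sequence (degrees), in (0, 90].
    n_frames : int
        Number of dynamic repetitions.
    frame_interval : float
        Time between successive dynamic frames (s).
    injection_start : float
        Bolus start relative to the start of the dynamic scan (s).
    vtr_ladder : tuple of float
        Repetition times of the variable-TR T1-mapping acquisition (ms),
        pairwise distinct, at least three values.
    r1 : float
        Longitudinal relaxivity of the contrast agent (s^-1 mM^-1).  Use
        :meth:`from_config` to accept ms^-1 mM^-1 input.
    hematocrit : float
        Blood hematocrit fraction in (0, 1); converts blood to plasma
        concentration via Cp = Cb / (1 - Hct).
    dose : float
        Contrast dose (mmol/kg); metadata only.
    """

    tr_dce: float = 24.6
    te_dce: float = 1.5
    flip_angle: float = 15.0
    n_frames: int = 610
    frame_interval: float = 1200.0 / 610.0
    injection_start: float = 60.0
    vtr_ladder: tuple = (7500.0, 5000.0, 3000.0, 1500.0, 800.0, 400.0, 311.0, 123.0)
    r1: float = 4.5
    hematocrit: float = 0.45
    dose: float = 0.6

    def __post_init__(self):
        if not 0.0 < self.flip_angle <= 90.0:
            raise ConfigError(f"flip_angle must be in (0, 90], got {self.flip_angle}")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be at least 2")
        ladder = tuple(float(v) for v in self.vtr_ladder)
        object.__setattr__(self, "vtr_ladder", ladder)
        if len(ladder) < 3:
            raise ConfigError("vtr_ladder needs at least 3 repetition times")
        if any(v <= 0 for v in ladder):
            raise ConfigError("vtr_ladder values must be strictly positive")
        if len(set(ladder)) != len(ladder):
            raise ConfigError("vtr_ladder values must be pairwise distinct")
        if not 0.0 < self.hematocrit < 1.0:
            raise ConfigError("hematocrit must be in (0, 1)")
        if self.r1 <= 0:
            raise ConfigError("r1 must be positive")
        if not 0.0 <= self.injection_start < self.n_frames * self.frame_interval:
            raise ConfigError("injection_start must fall within the dynamic scan")

    @property
    def frame_times(self) -> np.ndarray:
        """Nominal frame timestamps (s), uniform at ``frame_interval``."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def scan_duration(self) -> float:
        return self.n_frames * self.frame_interval

    @classmethod
    def from_config(cls, cfg: dict) -> "AcquisitionParams":
        """Build from a config mapping, normalising relaxivity units.

        ``r1`` may be given under ``r1`` (s^-1 mM^-1) or ``r1_per_ms_mM``
        (ms^-1 mM^-1, as vendor consoles print it); the latter is converted
        here, the single place unit normalisation happens.
        """
        cfg = dict(cfg)
        if "r1_per_ms_mM" in cfg:
            if "r1" in cfg:
                raise ConfigError("give relaxivity as 'r1' or 'r1_per_ms_mM', not both")
            cfg["r1"] = float(cfg.pop("r1_per_ms_mM")) * MS_PER_SECOND
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"unknown acquisition keys: {sorted(unknown)}")
        return cls(**cfg)


@dataclass
class DynamicSeries:
    """A single-slice image stack over time.

    ``data`` has shape (rows, cols, n_frames); ``times`` are frame
    timestamps in seconds, strictly increasing; ``unit`` tags whether the
    values are raw scanner signal (``signal_au``) or gadolinium
    concentration (``concentration_mM``).
    """

    data: np.ndarray
    times: np.ndarray
    unit: str = "signal_au"
    pixel_spacing: float = 0.1875
    slice_thickness: float = 1.0

    def __post_init__(self):
        self.data = _as_float_array(self.data, 3, "dynamic data")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.data.shape[2] != self.times.size:
            raise FormatError(
                f"frame count {self.data.shape[2]} does not match "
                f"{self.times.size} timestamps"
            )
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("frame timestamps must be strictly increasing")
        if self.unit not in ("signal_au", "concentration_mM"):
            raise FormatError(f"unknown unit tag {self.unit!r}")
        if self.pixel_spacing <= 0:
            raise FormatError("pixel_spacing must be positive")

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


@dataclass
class VTRSeries:
    """Image stack indexed by repetition time, the substrate for T1 fitting."""

    data: np.ndarray
    tr_values: np.ndarray
    pixel_spacing: float = 0.1875
    slice_thickness: float = 1.0

    def __post_init__(self):
        self.data = _as_float_array(self.data, 3, "VTR data")
        self.tr_values = np.asarray(self.tr_values, dtype=float)
        if self.tr_values.ndim != 1 or self.data.shape[2] != self.tr_values.size:
            raise FormatError(
                f"TR count {self.data.shape[2]} does not match "
                f"{self.tr_values.size} declared TR values"
            )

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:2]


@dataclass
class ScalarMap:
    """A 2D parameter map with a validity mask.

    Invalid pixels (fit did not converge, outside the analysis region) carry
    NaN in ``values`` and False in ``valid``; values are finite wherever
    ``valid`` is True.
    """

    values: np.ndarray
    semantic: str
    valid: np.ndarray = None
    pixel_spacing: float = 0.1875

    def __post_init__(self):
        self.values = _as_float_array(self.values, 2, "map values")
        if self.semantic not in MAP_SEMANTICS:
            raise FormatError(f"unknown map semantic {self.semantic!r}")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise FormatError("validity mask shape must match values")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise FormatError("values must be finite wherever valid")
        if self.semantic in ("ve", "vp"):
            v = self.values[self.valid]
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise FormatError(f"{self.semantic} map must lie in [0, 1] where valid")

    def masked(self) -> np.ndarray:
        """Values with invalid pixels as NaN (storage convention)."""
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out


@dataclass
class LabelMask:
    """Integer region labels plus a label -> name mapping (0 = background)."""

    labels: np.ndarray
    names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("label mask must be 2-dimensional")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("label mask must be integer-valued")
        self.names = {int(k): str(v) for k, v in self.names.items()}
        present = set(np.unique(self.labels)) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise FormatError(f"labels without names: {sorted(unnamed)}")

    def region(self, label) -> np.ndarray:
        """Boolean mask for one label (int) or named region (str)."""
        if isinstance(label, str):
            matches = [k for k, v in self.names.items() if v == label]
            if not matches:
                raise KeyError(f"no region named {label!r}")
            label = matches[0]
        return self.labels == int(label)

    @property
    def grid_shape(self) -> tuple:
        return self.labels.shape


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_series(obj, path) -> Path:
    """Write a series/map/mask as NIfTI with a JSON sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, DynamicSeries):
        data, meta = obj.data, {
            "kind": "dynamic",
            "times": obj.times.tolist(),
            "unit": obj.unit,
            "pixel_spacing": obj.pixel_spacing,
            "slice_thickness": obj.slice_thickness,
        }
    elif isinstance(obj, VTRSeries):
        data, meta = obj.data, {
            "kind": "vtr",
            "tr_values": obj.tr_values.tolist(),
            "pixel_spacing": obj.pixel_spacing,
            "slice_thickness": obj.slice_thickness,
        }
    elif isinstance(obj, ScalarMap):
        data, meta = obj.masked(), {
            "kind": "map",
            "semantic": obj.semantic,
            "pixel_spacing": obj.pixel_spacing,
        }
    elif isinstance(obj, LabelMask):
        data, meta = obj.labels.astype(np.int32), {
            "kind": "mask",
            "names": {str(k): v for k, v in obj.names.items()},
        }
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    img = nib.Nifti1Image(np.asarray(data), affine=np.eye(4))
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_series(path, kind: str):
    """Read a NIfTI volume plus JSON sidecar back into its domain object.

    ``kind`` must be one of ``dynamic``, ``vtr``, ``map``, ``mask`` and must
    agree with the sidecar's record of what was written.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise ConfigError(f"missing JSON sidecar for {path} (expected {side})")
    meta = json.loads(side.read_text())
    if meta.get("kind") != kind:
        raise FormatError(
            f"{path} was written as kind {meta.get('kind')!r}, requested {kind!r}"
        )
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if kind == "dynamic":
        times = np.asarray(meta["times"], dtype=float)
        if data.ndim != 3 or data.shape[2] != times.size:
            raise FormatError(
                f"dynamic volume {data.shape} does not match {times.size} timestamps"
            )
        return DynamicSeries(
            data=data,
            times=times,
            unit=meta["unit"],
            pixel_spacing=meta["pixel_spacing"],
            slice_thickness=meta["slice_thickness"],
        )
    if kind == "vtr":
        trs = np.asarray(meta["tr_values"], dtype=float)
        if data.ndim != 3 or data.shape[2] != trs.size:
            raise FormatError(
                f"VTR volume {data.shape} does not match {trs.size} TR values"
            )
        return VTRSeries(
            data=data,
            tr_values=trs,
            pixel_spacing=meta["pixel_spacing"],
            slice_thickness=meta["slice_thickness"],
        )
    if kind == "map":
        if data.ndim != 2:
            raise FormatError(f"map volume must be 2D, got {data.shape}")
        return ScalarMap(
            values=data,
            semantic=meta["semantic"],
            valid=np.isfinite(np.asarray(data, dtype=float)),
            pixel_spacing=meta["pixel_spacing"],
        )
    if kind == "mask":
        if data.ndim != 2:
            raise FormatError(f"mask volume must be 2D, got {data.shape}")
        return LabelMask(
            labels=np.asarray(data).astype(np.int32),
            names={int(k): v for k, v in meta["names"].items()},
        )
    raise ValueError(f"unknown kind {kind!r}")


def volume_from_mask(mask: LabelMask, voxel_dims, label: int) -> float:
    """Volume (mm^3) of one label: voxel count times voxel volume.

    ``voxel_dims`` is the (dx, dy, dz) voxel size in mm.  An absent label
    yields zero volume with a warning rather than an error, since an empty
    region (e.g. no necrotic core) is a legitimate finding.
    """
    dims = np.asarray(voxel_dims, dtype=float)
    if dims.shape != (3,) or np.any(dims <= 0):
        raise ConfigError("voxel_dims must be three positive lengths (mm)")
    count = int(np.count_nonzero(mask.labels == int(label)))
    if count == 0:
        warnings.warn(f"label {label} not present in mask; volume is 0", stacklevel=2)
    return count * float(np.prod(dims))


# ---------------------------------------------------------------------------
# Configuration and stage logging


def load_config(path) -> dict:
    """Load a YAML pipeline config; returns the raw mapping.

    The ``acquisition`` block maps onto :class:`AcquisitionParams` via
    :meth:`AcquisitionParams.from_config`; other blocks are stage-specific.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_stage_log(log_path, stage: str, inputs, config: dict, seed) -> None:
    """Append a machine-readable provenance record for one pipeline stage.

    Records the stage name, sha256 of every input file, the effective
    config, and the seed — enough to re-run the stage bit-identically (or,
    for seeded stochastic stages, statistically identically).
    """
    if log_path is None:
        return
    record = {
        "stage": stage,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
        "config": config,
        "seed": seed,
    }
    log_path = Path(log_path)
    log_path.parent.mkdir(parents=True, exist_ok=True)
    with open(log_path, "a") as fh:
        fh.write(json.dumps(record, default=str) + "\n")
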