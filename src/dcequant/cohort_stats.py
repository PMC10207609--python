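"""ROI aggregation to per-animal values and normality-gated group tests.

Per animal, three representative non-overlapping ROIs are sampled in the
viable tumor rim; the unweighted mean of the three ROI means yields one
value per parameter per animal.  Two groups are then compared parameter by
parameter: a Shapiro-Wilk test (alpha = 0.05) gates the choice between a
two-tailed unpaired t-test (both groups normal) and a two-sided
Mann-Whitney U test.  The t-test defaults to the Welch flavour (unequal
variances); no multiple-testing correction is applied by default,
mirroring per-parameter reporting, with Holm available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import LabelMask, ScalarMap

__all__ = ["AnimalRecord", "GroupComparison", "aggregate_animal", "compare_groups"]


@dataclass
class AnimalRecord:
    """One animal's per-parameter values (mean over the three ROI means)."""

    animal_id: str
    group: str
    values: dict  # parameter name -> float

    def __post_init__(self):
        if not self.group:
            raise ValueError("group must be nonempty")


@dataclass
class GroupComparison:
    """Result of one two-group, one-parameter comparison."""

    parameter: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    shapiro_p_a: float
    shapiro_p_b: float
    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    direction: int  # sign of mean(b) - mean(a)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.test_used not in ("t_test", "mann_whitney"):
            raise ValueError(f"unknown test {self.test_used!r}")


def roi_means(map_: ScalarMap, rois: LabelMask) -> dict:
    """Mean over valid pixels of each ROI; raises on an all-invalid ROI."""
    if rois.grid_shape != map_.values.shape:
        raise ValueError("ROI mask grid must match the map grid")
    out = {}
    for label in sorted(set(np.unique(rois.labels)) - {0}):
        name = rois.names.get(int(label), str(label))
        sel = (rois.labels == label) & map_.valid
        if not sel.any():
            raise ValueError(f"ROI {name!r} contains no valid pixels")
        out[name] = float(map_.values[sel].mean())
    return out


def aggregate_animal(
    maps: dict,
    rois: LabelMask,
    animal_id: str = "animal",
    group: str = "group",
    pooled: bool = False,
) -> AnimalRecord:
    """Aggregate parameter maps to one value per parameter for one animal.

    ``maps`` maps parameter name -> ScalarMap.  Default is the unweighted
    mean of the per-ROI means (each ROI counts equally regardless of its
    pixel count); ``pooled=True`` instead pools all ROI pixels, which
    differs whenever ROI sizes differ.
    """
    labels = sorted(set(np.unique(rois.labels)) - {0})
    if len(labels) < 3:
        raise ValueError("need the three rim ROIs present in the mask")
    values = {}
    for name, map_ in maps.items():
        if pooled:
            sel = (rois.labels != 0) & map_.valid
            if not sel.any():
                raise ValueError(f"no valid pixels for parameter {name!r}")
            values[name] = float(map_.values[sel].mean())
        else:
            means = roi_means(map_, rois)
            values[name] = float(np.mean(list(means.values())))
    return AnimalRecord(animal_id=animal_id, group=group, values=values)


def records_to_frame(records) -> pd.DataFrame:
    """Tidy per-animal table: one row per animal, one column per parameter."""
    rows = []
    for rec in records:
        row = {"animal_id": rec.animal_id, "group": rec.group}
        row.update(rec.values)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    records,
    parameter: str,
    alpha: float = 0.05,
    welch: bool = True,
) -> GroupComparison:
    """Compare one parameter between the two groups present in ``records``.

    ``records`` is a list of :class:`AnimalRecord` or a tidy DataFrame with
    ``group`` and parameter columns.  Shapiro-Wilk is run per group at
    ``alpha``; only if both groups look normal is a two-tailed unpaired
    t-test used (Welch by default), otherwise a two-sided Mann-Whitney U
    (exact null distribution for small tie-free samples).  A zero-variance
    group makes the normality test undefined; the comparison then falls
    through to Mann-Whitney with a warning.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(records)
    if parameter not in df.columns:
        raise KeyError(f"parameter {parameter!r} not found")
    if df[parameter].isna().any():
        raise ValueError(f"parameter {parameter!r} has missing values")
    groups = list(dict.fromkeys(df["group"]))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    ga, gb = groups
    a = df.loc[df["group"] == ga, parameter].to_numpy(dtype=float)
    b = df.loc[df["group"] == gb, parameter].to_numpy(dtype=float)
    if min(a.size, b.size) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations per group")

    def _shapiro(x):
        if np.ptp(x) == 0:
            warnings.warn(
                "zero variance in a group: normality undefined, using Mann-Whitney",
                stacklevel=3,
            )
            return np.nan
        return float(stats.shapiro(x).pvalue)

    p_a, p_b = _shapiro(a), _shapiro(b)
    normal = (p_a > alpha if np.isfinite(p_a) else False) and (
        p_b > alpha if np.isfinite(p_b) else False
    )
    if normal:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        test_used = "t_test"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        test_used = "mann_whitney"
    return GroupComparison(
        parameter=parameter,
        group_a=ga,
        group_b=gb,
        n_a=int(a.size),
        n_b=int(b.size),
        shapiro_p_a=p_a,
        shapiro_p_b=p_b,
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=int(np.sign(b.mean() - a.mean())),
    )


def holm_adjust(pvalues: dict) -> dict:
    """Holm step-down adjustment over a family of parameter p-values."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted = {}
    running = 0.0
    for rank, (name, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[name] = running
    return adjusted
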