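"""Neuronal densities, log-density z-scores and severity grades.

A count record (subject x region x subtype) yields a density
``nd = count / area`` in cells/mm². Severity of neuronal loss is graded
by standardising the natural-log density against the control subjects
of the same region x subtype stratum,

    z = (ln nd - mean control ln nd) / SD control ln nd,

and binning with the same +/-2 / -3 / -4 SD limits as the expression
classifier, relabelled for density:

    severe_loss    z <= -4
    moderate_loss  -4 < z <= -3
    mild_loss      -3 < z <= -2
    normal         -2 < z < 2
    increased      z >= 2

Tissues with a complete loss of a neuronal subtype (nd = 0) receive the
sentinel category ``complete_loss``; no z-score is defined for them.
Group-level loss is summarised as percent remaining,
``100 x mean patient density / mean control density``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    ClassificationError,
    ControlReferenceError,
    InputError,
)
from .oxphos import Z_EDGES, build_reference, zscore

DENSITY_CATEGORIES: tuple[str, ...] = (
    "severe_loss", "moderate_loss", "mild_loss", "normal", "increased")

#: sentinel for nd = 0, where no z-score exists
COMPLETE_LOSS = "complete_loss"


def compute_density(counts: pd.DataFrame) -> pd.DataFrame:
    """Append ``nd`` (cells/mm²) to a count table.

    Requires columns ``count`` and ``area_mm2``; any nonpositive area
    is an input error.
    """
    for col in ("count", "area_mm2"):
        if col not in counts.columns:
            raise InputError(f"count table lacks column {col!r}")
    if (counts["area_mm2"] <= 0).any():
        raise InputError("sampled area must be > 0 mm² for every record")
    if (counts["count"] < 0).any():
        raise InputError("counts must be >= 0")
    out = counts.copy()
    out["nd"] = out["count"] / out["area_mm2"]
    return out


def density_zscore(nd: float, control_nds) -> float:
    """z-score of one density against control densities (log scale).

    ``nd`` must be positive; controls with nd = 0 are excluded from the
    reference (at least two positive control densities are required).
    """
    if not nd > 0:
        raise InputError(
            "nd = 0 has no z-score; handle as complete_loss upstream")
    ctrl = np.asarray(control_nds, dtype=float)
    ctrl = ctrl[ctrl > 0]
    ref = build_reference(np.log(ctrl), metric="log_nd")
    return float(zscore(np.log(nd), ref))


def classify_density(z):
    """Map density z-score(s) to severity categories.

    Same half-open bins as the expression classifier (boundaries to the
    extreme side); non-finite input raises ClassificationError.
    """
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ClassificationError("z-scores must be finite for classification")
    severe, moderate, mild, normal, increased = DENSITY_CATEGORIES
    out = np.full(arr.shape, normal, dtype=object)
    out[arr >= Z_EDGES[3]] = increased
    out[arr <= Z_EDGES[2]] = mild
    out[arr <= Z_EDGES[1]] = moderate
    out[arr <= Z_EDGES[0]] = severe
    return out if arr.ndim else out[()]


def grade_densities(
    counts: pd.DataFrame,
    control_group: str = "control",
    reference: str = "pooled",
) -> pd.DataFrame:
    """Density, log-density z and severity grade for every record.

    Control references pool the control subjects of each region x
    subtype stratum. ``reference="loo"`` scores each control subject
    against the *other* controls (leave-one-out), removing the
    self-inclusion shrinkage when judging control calibration; patient
    and SUDEP records always use the full control pool.

    Records with nd = 0 get ``category = complete_loss`` and a missing
    z, mirroring how complete subtype loss is reported.
    """
    if reference not in ("pooled", "loo"):
        raise InputError(f"unknown reference mode {reference!r}")
    dens = compute_density(counts)
    # nd = 0 stays NaN on the log scale (complete_loss sentinel below)
    dens["log_nd"] = np.log(dens["nd"].where(dens["nd"] > 0))
    dens["z"] = np.nan
    dens["category"] = pd.array([None] * len(dens), dtype="object")
    for (region, subtype), grp in dens.groupby(["region", "subtype"]):
        ctrl = grp[(grp["group"] == control_group) & (grp["nd"] > 0)]
        if len(ctrl) < 2:
            raise ControlReferenceError(
                f"density reference for {region}/{subtype} needs >= 2 "
                f"positive control densities, got {len(ctrl)}")
        for idx, row in grp.iterrows():
            if row["nd"] == 0:
                dens.loc[idx, "category"] = COMPLETE_LOSS
                continue
            pool = ctrl["log_nd"]
            if (reference == "loo" and row["group"] == control_group
                    and idx in ctrl.index):
                pool = ctrl.loc[ctrl.index != idx, "log_nd"]
            ref = build_reference(pool, region=region, subtype=subtype,
                                  metric="log_nd")
            z = float(zscore(row["log_nd"], ref))
            dens.loc[idx, "z"] = z
            dens.loc[idx, "category"] = classify_density(z)
    return dens


def percent_remaining(
    patient_mean_nd: float,
    control_mean_nd: float,
) -> float:
    """Percent of a neuronal population remaining at the group level."""
    if not control_mean_nd > 0:
        raise InputError(
            f"control mean density must be > 0, got {control_mean_nd}")
    return 100.0 * patient_mean_nd / control_mean_nd


def percent_remaining_table(
    counts: pd.DataFrame,
    patient_group: str = "alpers",
    control_group: str = "control",
) -> pd.DataFrame:
    """Percent remaining per region x subtype from a count table.

    Group means are arithmetic means of subject densities.
    """
    dens = compute_density(counts)
    rows = []
    for (region, subtype), grp in dens.groupby(["region", "subtype"]):
        means = grp.groupby("group")["nd"].mean()
        if patient_group not in means.index or control_group not in means.index:
            continue
        rows.append({
            "region": region,
            "subtype": subtype,
            "control_mean_nd": means[control_group],
            "patient_mean_nd": means[patient_group],
            "percent_remaining": percent_remaining(
                means[patient_group], means[control_group]),
        })
    return pd.DataFrame(rows)
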