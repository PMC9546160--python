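"""Per-cell OXPHOS metrics, z-scores and deficiency classification.

For every segmented interneuron the abundance of the complex I subunit
NDUFB8 and the complex IV subunit COXI is normalised to mitochondrial
mass by taking the ratio of log-transformed intensities relative to
log-transformed porin intensity:

    r_ndufb8 = ln(I_ndufb8) / ln(I_porin)
    r_coxi   = ln(I_coxi)   / ln(I_porin)

Porin and calcium-binding-protein intensities are analysed on the
natural-log scale (``log_porin``, ``log_cbp``). Each metric is then
standardised against the pooled control cells of the same region x
subtype stratum,

    z = (value - control mean) / control SD   (sample SD, n-1),

and binned into five expression categories:

    severe_deficiency  z <= -4
    deficiency         -4 < z <= -3
    low                -3 < z <= -2
    normal             -2 < z < 2
    increased          z >= 2

The bins form a total partition of the real line; boundary values are
assigned to the more extreme bin, honouring the direction of every
inequality that defines the scheme (z < -4 severe, z < -3 deficiency,
z < -2 low, z > 2 increased).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ClassificationError,
    ControlReferenceError,
    InputError,
)

#: expression categories from most depleted to most elevated
EXPRESSION_CATEGORIES: tuple[str, ...] = (
    "severe_deficiency", "deficiency", "low", "normal", "increased")

#: per-cell metrics the classification layer operates on
METRICS: tuple[str, ...] = ("r_ndufb8", "r_coxi", "log_porin", "log_cbp")

#: z bin edges shared by the expression and density classifiers
Z_EDGES: tuple[float, ...] = (-4.0, -3.0, -2.0, 2.0)


@dataclass(frozen=True)
class ControlReference:
    """Pooled-control mean/SD of one metric in one stratum."""

    region: str
    subtype: str
    metric: str
    mean: float
    sd: float
    n: int


def compute_ratios(
    cells: pd.DataFrame,
    guard: float = 0.0,
    ratio_mode: str = "log_over_log",
) -> pd.DataFrame:
    """Derive per-cell OXPHOS metrics from a measurement table.

    Parameters
    ----------
    cells
        Table with intensity columns ``i_ndufb8, i_coxi, i_porin,
        i_cbp`` (one row per cell).
    guard
        Positivity guard: any required intensity <= guard flags the
        cell as excluded (columns ``excluded``/``exclusion_reason``)
        rather than silently dropping it.
    ratio_mode
        ``"log_over_log"`` (default): ratio of log-transformed
        intensities, ln(I)/ln(I_porin). ``"log_of_ratio"``: log of the
        intensity ratio, ln(I/I_porin).

    Returns
    -------
    pandas.DataFrame
        Copy of the input with ``r_ndufb8, r_coxi, log_porin, log_cbp,
        excluded, exclusion_reason`` appended; metric columns are NaN
        for excluded cells.
    """
    if ratio_mode not in ("log_over_log", "log_of_ratio"):
        raise InputError(f"unknown ratio_mode {ratio_mode!r}")
    required = ["i_ndufb8", "i_coxi", "i_porin", "i_cbp"]
    missing = [c for c in required if c not in cells.columns]
    if missing:
        raise InputError(f"measurement table lacks columns {missing}")
    out = cells.copy()
    bad = {c: out[c].to_numpy(dtype=float) <= guard for c in required}
    excluded = np.logical_or.reduce(list(bad.values()))
    reasons = [
        "; ".join(f"{c} <= guard ({guard})" for c in required if bad[c][i])
        if excluded[i] else ""
        for i in range(len(out))
    ]
    with np.errstate(divide="ignore", invalid="ignore"):
        log = {c: np.log(np.where(bad[c], np.nan, out[c].astype(float)))
               for c in required}
        if ratio_mode == "log_over_log":
            r_n = log["i_ndufb8"] / log["i_porin"]
            r_c = log["i_coxi"] / log["i_porin"]
        else:
            r_n = log["i_ndufb8"] - log["i_porin"]
            r_c = log["i_coxi"] - log["i_porin"]
    out["r_ndufb8"] = r_n
    out["r_coxi"] = r_c
    out["log_porin"] = log["i_porin"]
    out["log_cbp"] = log["i_cbp"]
    out["excluded"] = excluded
    out["exclusion_reason"] = reasons
    return out


def build_reference(
    values,
    region: str = "",
    subtype: str = "",
    metric: str = "",
) -> ControlReference:
    """Pooled-control mean and sample SD for one stratum.

    Raises :class:`ControlReferenceError` when fewer than two control
    cells carry the metric or their spread is zero.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    stratum = f"{region}/{subtype}/{metric}"
    if v.size < 2:
        raise ControlReferenceError(
            f"control reference for {stratum} needs >= 2 cells, got {v.size}")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        raise ControlReferenceError(
            f"control reference for {stratum} has zero spread "
            f"(all {v.size} values identical)")
    return ControlReference(region=region, subtype=subtype, metric=metric,
                            mean=float(np.mean(v)), sd=sd, n=int(v.size))


def zscore(value, ref: ControlReference):
    """Standardise value(s) against a control reference."""
    return (np.asarray(value, dtype=float) - ref.mean) / ref.sd


def classify_expression(z):
    """Map z-score(s) to the five-level expression category.

    Scalar in, scalar out; array in, object array out. Non-finite
    values raise :class:`ClassificationError`.
    """
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ClassificationError("z-scores must be finite for classification")
    cats = _bin_z(arr, EXPRESSION_CATEGORIES)
    return cats if arr.ndim else cats[()]


def _bin_z(arr: np.ndarray, categories: tuple[str, ...]) -> np.ndarray:
    """Half-open z bins with boundaries assigned to the extreme side."""
    severe, deficient, low, normal, increased = categories
    out = np.full(arr.shape, normal, dtype=object)
    out[arr >= Z_EDGES[3]] = increased
    out[arr <= Z_EDGES[2]] = low
    out[arr <= Z_EDGES[1]] = deficient
    out[arr <= Z_EDGES[0]] = severe
    return out


def build_references(
    ratio_table: pd.DataFrame,
    control_group: str = "control",
    metrics: tuple[str, ...] = METRICS,
    pool: str = "pooled",
) -> dict[tuple[str, str, str], ControlReference]:
    """Control references for every region x subtype x metric stratum.

    ``pool="pooled"`` (default) pools control *cells* within each
    stratum; ``pool="per-subject"`` first averages cells within each
    control subject and standardises against subject means, a
    sensitivity mode for within-subject correlation.
    """
    if pool not in ("pooled", "per-subject"):
        raise InputError(f"unknown pooling mode {pool!r}")
    controls = ratio_table[(ratio_table["group"] == control_group)
                           & ~ratio_table["excluded"]]
    refs: dict[tuple[str, str, str], ControlReference] = {}
    for (region, subtype), grp in controls.groupby(["region", "subtype"]):
        for metric in metrics:
            values = (grp.groupby("subject")[metric].mean()
                      if pool == "per-subject" else grp[metric])
            refs[(region, subtype, metric)] = build_reference(
                values, region=region, subtype=subtype, metric=metric)
    return refs


def classify_cells(
    ratio_table: pd.DataFrame,
    references: dict[tuple[str, str, str], ControlReference] | None = None,
    metrics: tuple[str, ...] = METRICS,
    **ref_kwargs,
) -> pd.DataFrame:
    """z-score and classify every non-excluded cell against controls.

    Appends ``z_<metric>`` and ``cat_<metric>`` columns for each metric
    (NaN / missing for excluded cells). References are built from the
    table's own control group when not supplied.
    """
    if references is None:
        references = build_references(ratio_table, metrics=metrics,
                                      **ref_kwargs)
    out = ratio_table.copy()
    for metric in metrics:
        zcol, ccol = f"z_{metric.removeprefix('r_')}", f"cat_{metric.removeprefix('r_')}"
        out[zcol] = np.nan
        out[ccol] = pd.array([None] * len(out), dtype="object")
        for (region, subtype), idx in out.groupby(["region", "subtype"]).groups.items():
            ref = references.get((region, subtype, metric))
            if ref is None:
                raise ControlReferenceError(
                    f"no control reference for {region}/{subtype}/{metric}")
            rows = out.loc[idx]
            ok = ~rows["excluded"] & np.isfinite(rows[metric])
            z = zscore(rows.loc[ok, metric], ref)
            out.loc[rows.index[ok], zcol] = z
            out.loc[rows.index[ok], ccol] = classify_expression(z)
    return out


def summarize_subject(
    classified: pd.DataFrame,
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Per-subject category proportions per metric.

    One row per subject x region x subtype x metric with the five
    category proportions (summing to 1 over classified cells), the
    number of classified cells and the number of excluded cells.
    An empty input yields an empty summary.
    """
    rows = []
    if len(classified) == 0:
        return pd.DataFrame(
            columns=["subject", "group", "region", "subtype", "metric",
                     "n_cells", "n_excluded", *EXPRESSION_CATEGORIES])
    for (subject, group, region, subtype), grp in classified.groupby(
            ["subject", "group", "region", "subtype"]):
        n_excl = int(grp["excluded"].sum())
        for metric in metrics:
            ccol = f"cat_{metric.removeprefix('r_')}"
            cats = grp.loc[~grp["excluded"], ccol].dropna()
            row = {"subject": subject, "group": group, "region": region,
                   "subtype": subtype, "metric": metric,
                   "n_cells": int(len(cats)), "n_excluded": n_excl}
            if len(cats) == 0:
                row.update({c: np.nan for c in EXPRESSION_CATEGORIES})
                row["empty_summary"] = True
            else:
                frac = cats.value_counts(normalize=True)
                row.update({c: float(frac.get(c, 0.0))
                            for c in EXPRESSION_CATEGORIES})
                row["empty_summary"] = False
            rows.append(row)
    return pd.DataFrame(rows)
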