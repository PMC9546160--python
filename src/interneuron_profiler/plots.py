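"""Figure mirrors: stacked deficiency proportions and density bars.

These are working plots of the pipeline's tables (per-patient stacked
category proportions; group mean +/- SEM density bars), not replicas of
any publication figure layout.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .oxphos import EXPRESSION_CATEGORIES  # noqa: E402

_CATEGORY_COLOURS = {
    "severe_deficiency": "#7f0000",
    "deficiency": "#d7301f",
    "low": "#fc8d59",
    "normal": "#74add1",
    "increased": "#2166ac",
}


def stacked_proportions(
    summary: pd.DataFrame,
    metric: str,
    region: str,
    subtype: str,
    path=None,
):
    """Stacked per-subject category proportions for one metric/stratum."""
    sub = summary[(summary["metric"] == metric)
                  & (summary["region"] == region)
                  & (summary["subtype"] == subtype)].copy()
    sub = sub.sort_values(["group", "subject"])
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(sub)), 3.5))
    bottom = np.zeros(len(sub))
    for cat in EXPRESSION_CATEGORIES:
        vals = sub[cat].fillna(0).to_numpy()
        ax.bar(np.arange(len(sub)), vals, bottom=bottom, label=cat,
               color=_CATEGORY_COLOURS[cat], width=0.8)
        bottom += vals
    ax.set_xticks(np.arange(len(sub)))
    ax.set_xticklabels(sub["subject"], rotation=90, fontsize=6)
    ax.set_ylabel("proportion of cells")
    ax.set_title(f"{metric} — {subtype} / {region}")
    ax.legend(fontsize=6, loc="center left", bbox_to_anchor=(1, 0.5))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def density_bars(densities: pd.DataFrame, region: str, path=None):
    """Group mean +/- SEM density bars per subtype for one region."""
    sub = densities[densities["region"] == region]
    stats = sub.groupby(["subtype", "group"])["nd"].agg(["mean", "sem"])
    subtypes = sorted(sub["subtype"].unique())
    groups = list(dict.fromkeys(sub["group"]))
    fig, ax = plt.subplots(figsize=(1.2 * len(subtypes) + 2, 3.5))
    width = 0.8 / len(groups)
    for gi, g in enumerate(groups):
        xs = np.arange(len(subtypes)) + gi * width
        means = [stats.loc[(s, g), "mean"] if (s, g) in stats.index else 0
                 for s in subtypes]
        sems = [stats.loc[(s, g), "sem"] if (s, g) in stats.index else 0
                for s in subtypes]
        ax.bar(xs, means, width=width, yerr=sems, capsize=2, label=g)
    ax.set_xticks(np.arange(len(subtypes)) + 0.4 - width / 2)
    ax.set_xticklabels(subtypes)
    ax.set_ylabel("neuronal density (cells/mm²)")
    ax.set_title(f"neuronal densities — {region}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
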