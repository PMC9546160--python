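"""Clinical-feature table summarisation.

The package ships the reference clinical table of the fourteen-patient
Alpers' syndrome cohort it models (one row per patient: sex, onset and
death ages, binary feature flags, POLG variants). Feature flags follow
the ``+`` convention: ``+`` marks a feature present, a blank cell counts
as absent/unknown, i.e. negative — so table-derived counts can differ
from narrative counts when a feature was described but not flagged.

Ages are given as ``"2 m"`` (months) or ``"4.0y"`` (years) and are
normalised to years on ingest. Disease onset is bimodal (infancy/
childhood vs adolescence/adulthood); the summariser splits onset ages
at a configurable cut, 16 years by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import InputError

#: binary feature columns of the clinical table
FEATURES: tuple[str, ...] = (
    "seizures",
    "developmental_delay",
    "cortical_visual_impairment",
    "liver_dysfunction",
    "ataxia_hypotonia",
)

#: adolescent-onset cut in years for the bimodality summary
DEFAULT_ONSET_CUT_YEARS = 16.0

_AGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(m|y)\s*$")


def parse_age_years(text: str) -> float:
    """Parse ``"2 m"`` / ``"4.0y"`` style ages into years."""
    m = _AGE_RE.match(str(text))
    if not m:
        raise InputError(f"unparseable age {text!r}; expected e.g. '2 m', '4.0y'")
    value, unit = float(m.group(1)), m.group(2)
    return value / 12.0 if unit == "m" else value


def load_clinical_table(path=None) -> pd.DataFrame:
    """Load a clinical table (the packaged cohort table by default).

    Adds ``onset_years``/``death_years`` columns and validates that
    case identifiers are unique.
    """
    if path is None:
        source = resources.files("interneuron_profiler.data").joinpath(
            "alpers_clinical.csv")
        with resources.as_file(source) as p:
            table = pd.read_csv(p, dtype=str, keep_default_na=False)
    else:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "case" not in table.columns:
        raise InputError("clinical table lacks a 'case' column")
    if table["case"].duplicated().any():
        raise InputError("clinical table case identifiers must be unique")
    table["onset_years"] = table["onset_age"].map(parse_age_years)
    table["death_years"] = table["death_age"].map(parse_age_years)
    return table


def summarize_clinical_table(table: pd.DataFrame, feature: str) -> int:
    """Count patients flagged positive (``+``) for one feature."""
    if feature not in table.columns:
        raise InputError(
            f"unknown feature {feature!r}; known features: {list(FEATURES)}")
    return int((table[feature].astype(str).str.strip() == "+").sum())


@dataclass(frozen=True)
class OnsetSummary:
    """Bimodal onset split at a configurable adolescent cut."""

    cut_years: float
    n_childhood: int  # onset strictly before the cut
    n_adolescent_adult: int  # onset at or after the cut


def summarize_onset(
    table: pd.DataFrame,
    cut_years: float = DEFAULT_ONSET_CUT_YEARS,
) -> OnsetSummary:
    """Split onset ages below vs at-or-above the adolescent cut."""
    onset = table["onset_years"]
    return OnsetSummary(
        cut_years=cut_years,
        n_childhood=int((onset < cut_years).sum()),
        n_adolescent_adult=int((onset >= cut_years).sum()),
    )


def clinical_summary(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Feature-positive counts for every known feature (tidy table)."""
    if table is None:
        table = load_clinical_table()
    rows = [{"feature": f,
             "n_positive": summarize_clinical_table(table, f),
             "n_patients": len(table)}
            for f in FEATURES]
    return pd.DataFrame(rows)
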