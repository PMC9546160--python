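"""Ground-truthed synthetic cohorts, cell tables, counts and scenes.

The generator emulates the data structure of a three-group postmortem
neuropathology study — controls, SUDEP (epilepsy disease controls) and
Alpers' syndrome patients — across three cortical regions (occipital,
frontal, temporal) and the interneuron subtypes analysed by
immunofluorescence (parvalbumin+ ``pv`` and calretinin+ ``cr``) or by
density counting (additionally calbindin+ ``cb``, somatostatin+ ``sst``
and SMI-32+ pyramidal neurons ``pyr``).

Generative model
----------------
Per-cell channel intensities are log-normal: the natural-log intensity
of each channel has a group/subtype-dependent location and scale.
Patient OXPHOS deficiency is a four-stratum mixture over
``{normal, low, deficient, severe}``: each cell's NDUFB8 (and, with a
configurable coupling probability, its COXI) stratum is drawn from the
mixture, and the cell's log-ratio metric is placed at a stratum-specific
position expressed in *control-referenced z units* (defaults 0 / -2.5 /
-3.5 / -5), converted to the ratio scale through the analytic control
ratio moments. Deficient strata are narrow (default 0.25 z units) so a
planted class maps essentially deterministically onto the downstream
z-score bins; the ``normal`` stratum keeps the full control spread.

Neuronal counts are Poisson with mean ``density x area``. Rendered
scenes place disk somata by rejection sampling and carry a full ground
truth (label image, per-cell true intensities and classes).

Every public function is deterministic for a fixed seed; one global
integer seed feeds a splittable :class:`numpy.random.SeedSequence`, with
independent sub-streams per operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .channels import CHANNELS, INTENSITY_COLUMNS
from .errors import PlacementError, SpecificationError
from .image import MultiChannelImage

GROUPS: tuple[str, ...] = ("control", "sudep", "alpers")
REGIONS: tuple[str, ...] = ("occipital", "frontal", "temporal")
#: subtypes carried through the immunofluorescence arm
IF_SUBTYPES: tuple[str, ...] = ("pv", "cr")
#: subtypes carried through the density arm
DENSITY_SUBTYPES: tuple[str, ...] = ("pv", "cr", "cb", "sst", "pyr")
STRATA: tuple[str, ...] = ("normal", "low", "deficient", "severe")


def _rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Demographic structure of the three-group cohort.

    Group sizes default to the study design this package targets: nine
    controls, five SUDEP patients and fourteen Alpers' syndrome
    patients. Demographic parameters are (location, scale) of normal
    distributions; ages are in years, postmortem interval in hours,
    fixation duration in months. Groups are matched by construction
    except for age, where patients skew younger, reflecting the
    childhood-predominant onset of the disease.
    """

    n_control: int = 9
    n_sudep: int = 5
    n_patient: int = 14
    age_params: dict = field(default_factory=lambda: {
        "control": (18.0, 10.0), "sudep": (25.0, 8.0), "alpers": (10.0, 8.0),
    })
    sex_ratio: dict = field(default_factory=lambda: {
        "control": 0.5, "sudep": 0.4, "alpers": 8 / 14,
    })
    pmi_params: dict = field(default_factory=lambda: {
        g: (48.0, 24.0) for g in GROUPS
    })
    fixation_params: dict = field(default_factory=lambda: {
        g: (7.0, 3.0) for g in GROUPS
    })
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, n in (("n_control", self.n_control),
                        ("n_sudep", self.n_sudep),
                        ("n_patient", self.n_patient)):
            if not (isinstance(n, (int, np.integer)) and n >= 0):
                raise SpecificationError(f"{name} must be a count >= 0, got {n!r}")
        for g in GROUPS:
            if not 0.0 <= self.sex_ratio[g] <= 1.0:
                raise SpecificationError(
                    f"sex_ratio[{g!r}] must lie in [0, 1]")
            for params in (self.age_params, self.pmi_params,
                           self.fixation_params):
                if params[g][1] < 0:
                    raise SpecificationError(
                        f"scale for group {g!r} must be >= 0")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"control": self.n_control, "sudep": self.n_sudep,
                "alpers": self.n_patient}


def generate_cohort(spec: CohortSpec, rng=None) -> pd.DataFrame:
    """Sample a subject table.

    Returns a DataFrame with columns ``subject, group, age, sex,
    pmi_hours, fixation_months``; exactly ``n_control + n_sudep +
    n_patient`` rows, deterministic for a fixed seed.
    """
    rng = _rng(spec.seed if rng is None else rng)
    prefix = {"control": "C", "sudep": "S", "alpers": "P"}
    rows = []
    for g in GROUPS:
        n = spec.group_sizes[g]
        age = rng.normal(*spec.age_params[g], size=n)
        age = np.clip(age, 0.2, None)  # postmortem ages are positive
        sex = np.where(rng.random(n) < spec.sex_ratio[g], "F", "M")
        pmi = np.clip(rng.normal(*spec.pmi_params[g], size=n), 1.0, None)
        fix = np.clip(rng.normal(*spec.fixation_params[g], size=n), 0.5, None)
        for i in range(n):
            rows.append({
                "subject": f"{prefix[g]}{i + 1:02d}",
                "group": g,
                "age": round(float(age[i]), 2),
                "sex": sex[i],
                "pmi_hours": round(float(pmi[i]), 1),
                "fixation_months": round(float(fix[i]), 1),
            })
    return pd.DataFrame(
        rows, columns=["subject", "group", "age", "sex",
                       "pmi_hours", "fixation_months"])


# ---------------------------------------------------------------------------
# per-cell intensities
# ---------------------------------------------------------------------------

def _default_mixtures() -> dict:
    """Deficiency mixtures per group x subtype.

    Patients' parvalbumin+ cells are dominated by severe deficiency,
    calretinin+ cells show a milder low-to-severe spread, SUDEP cells
    are largely normal with a minor low tail, controls are all normal.
    """
    return {
        "control": {
            "pv": {"normal": 1.0, "low": 0.0, "deficient": 0.0, "severe": 0.0},
            "cr": {"normal": 1.0, "low": 0.0, "deficient": 0.0, "severe": 0.0},
        },
        "sudep": {
            "pv": {"normal": 0.85, "low": 0.10, "deficient": 0.05, "severe": 0.0},
            "cr": {"normal": 0.85, "low": 0.10, "deficient": 0.05, "severe": 0.0},
        },
        "alpers": {
            "pv": {"normal": 0.15, "low": 0.10, "deficient": 0.15, "severe": 0.60},
            "cr": {"normal": 0.30, "low": 0.25, "deficient": 0.25, "severe": 0.20},
        },
    }


@dataclass
class IntensityModel:
    """Generative model for per-cell channel intensities.

    ``channel_loc``/``channel_scale`` give the natural-log intensity
    location and scale of each channel for control cells (arbitrary
    units). ``porin_shift`` and ``cbp_shift`` are additive log shifts
    per group x subtype (patients show increased porin — raised
    mitochondrial mass — and reduced parvalbumin). ``mixtures`` gives
    the deficiency-stratum fractions per group x subtype; strata are
    placed at ``stratum_z`` control-referenced z positions with
    ``stratum_z_scale`` within-stratum spread (z units). ``coupling``
    is the probability that a cell's COXI stratum copies its NDUFB8
    stratum (combined complex I + IV deficiency).
    """

    channel_loc: dict = field(default_factory=lambda: {
        "cbp": 5.0, "coxi": 5.0, "ndufb8": 5.0, "porin": 5.0})
    channel_scale: dict = field(default_factory=lambda: {
        "cbp": 0.20, "coxi": 0.15, "ndufb8": 0.15, "porin": 0.15})
    porin_shift: dict = field(default_factory=lambda: {
        "control": {"pv": 0.0, "cr": 0.0},
        "sudep": {"pv": 0.0, "cr": 0.0},
        "alpers": {"pv": 0.4, "cr": 0.15},
    })
    cbp_shift: dict = field(default_factory=lambda: {
        "control": {"pv": 0.0, "cr": 0.0},
        "sudep": {"pv": 0.0, "cr": 0.0},
        "alpers": {"pv": -0.5, "cr": 0.0},
    })
    mixtures: dict = field(default_factory=_default_mixtures)
    stratum_z: dict = field(default_factory=lambda: {
        "normal": 0.0, "low": -2.5, "deficient": -3.5, "severe": -5.0})
    stratum_z_scale: dict = field(default_factory=lambda: {
        "normal": 1.0, "low": 0.25, "deficient": 0.25, "severe": 0.25})
    coupling: float = 0.7
    cells_per_case: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.cells_per_case, (int, np.integer))
                and self.cells_per_case >= 0):
            raise SpecificationError(
                f"cells_per_case must be a count >= 0, got {self.cells_per_case!r}")
        for c in CHANNELS:
            if not self.channel_scale[c] > 0:
                raise SpecificationError(f"channel_scale[{c!r}] must be > 0")
        for g, per_subtype in self.mixtures.items():
            for st, mix in per_subtype.items():
                total = sum(mix.get(s, 0.0) for s in STRATA)
                if not np.isclose(total, 1.0, atol=1e-9):
                    raise SpecificationError(
                        f"mixture fractions for {g}/{st} sum to {total}, not 1")
                if any(mix.get(s, 0.0) < 0 for s in STRATA):
                    raise SpecificationError(
                        f"mixture fractions for {g}/{st} must be >= 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise SpecificationError("coupling must lie in [0, 1]")
        for s in STRATA:
            if not self.stratum_z_scale[s] > 0:
                raise SpecificationError(f"stratum_z_scale[{s!r}] must be > 0")

    def ratio_moments(self, marker: str) -> tuple[float, float]:
        """Control-population mean and SD of ``log(marker)/log(porin)``.

        First-order (delta-method) moments of the ratio of two
        independent normals; exact here because the generator samples
        the ratio from this normal directly.
        """
        mu_m, sd_m = self.channel_loc[marker], self.channel_scale[marker]
        mu_p, sd_p = self.channel_loc["porin"], self.channel_scale["porin"]
        mean = mu_m / mu_p
        sd = np.sqrt(sd_m**2 / mu_p**2 + mu_m**2 * sd_p**2 / mu_p**4)
        return float(mean), float(sd)


def _sample_cells(model: IntensityModel, group: str, subtype: str,
                  n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Sample ``n`` cells' channel intensities and true classes."""
    mix = model.mixtures[group][subtype]
    probs = np.array([mix.get(s, 0.0) for s in STRATA])
    strat_n = rng.choice(len(STRATA), size=n, p=probs)
    # COXI stratum copies the NDUFB8 stratum with probability `coupling`
    strat_c = np.where(rng.random(n) < model.coupling,
                       strat_n, rng.choice(len(STRATA), size=n, p=probs))

    log_porin = rng.normal(
        model.channel_loc["porin"] + model.porin_shift[group][subtype],
        model.channel_scale["porin"], size=n)
    log_cbp = rng.normal(
        model.channel_loc["cbp"] + model.cbp_shift[group][subtype],
        model.channel_scale["cbp"], size=n)

    out = {}
    for marker, strat in (("ndufb8", strat_n), ("coxi", strat_c)):
        mu_r, sd_r = model.ratio_moments(marker)
        centre = np.array([model.stratum_z[s] for s in STRATA])[strat]
        spread = np.array([model.stratum_z_scale[s] for s in STRATA])[strat]
        # ratio sampled on the analysis scale: exact z placement
        r = rng.normal(mu_r + centre * sd_r, spread * sd_r)
        out[INTENSITY_COLUMNS[marker]] = np.exp(r * log_porin)
        out[f"true_class_{marker}"] = np.array(STRATA)[strat]
    out[INTENSITY_COLUMNS["porin"]] = np.exp(log_porin)
    out[INTENSITY_COLUMNS["cbp"]] = np.exp(log_cbp)
    cols = ["cell_id"] + [INTENSITY_COLUMNS[c] for c in CHANNELS] + \
        ["true_class_ndufb8", "true_class_coxi"]
    out["cell_id"] = np.arange(1, n + 1)
    return pd.DataFrame(out)[cols]


def generate_cell_intensity_table(
    model: IntensityModel,
    cohort: pd.DataFrame,
    regions: tuple[str, ...] = REGIONS,
    subtypes: tuple[str, ...] = IF_SUBTYPES,
    rng=None,
) -> pd.DataFrame:
    """Per-cell intensity table for every subject x region x subtype.

    One row per cell with the four channel intensities (strictly
    positive, arbitrary units) and the planted NDUFB8/COXI deficiency
    classes. Each subject contributes ``model.cells_per_case`` cells per
    region x subtype.
    """
    rng = _rng(model.seed if rng is None else rng)
    frames = []
    for _, subj in cohort.iterrows():
        for region in regions:
            for subtype in subtypes:
                cells = _sample_cells(
                    model, subj["group"], subtype, model.cells_per_case, rng)
                cells.insert(0, "subject", subj["subject"])
                cells.insert(1, "group", subj["group"])
                cells.insert(2, "region", region)
                cells.insert(3, "subtype", subtype)
                frames.append(cells)
    if not frames:
        return pd.DataFrame(
            columns=["subject", "group", "region", "subtype", "cell_id"]
            + [INTENSITY_COLUMNS[c] for c in CHANNELS]
            + ["true_class_ndufb8", "true_class_coxi"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# neuronal counts
# ---------------------------------------------------------------------------

def default_density_rates() -> dict:
    """Planted neuronal densities (cells/mm²) per group x region x subtype.

    Control densities encode the occipital enrichment of parvalbumin+
    interneurons; group multipliers encode the planted survival
    fractions (15% of parvalbumin+, 57% of calretinin+, ~30% of the
    remaining subtypes in patients; SUDEP preserved).
    """
    control = {
        "occipital": {"pv": 40.0, "cr": 30.0, "cb": 10.0, "sst": 8.0,
                      "pyr": 120.0},
        "frontal": {"pv": 22.0, "cr": 30.0, "cb": 10.0, "sst": 8.0,
                    "pyr": 110.0},
        "temporal": {"pv": 22.0, "cr": 28.0, "cb": 9.0, "sst": 8.0,
                     "pyr": 110.0},
    }
    multipliers = {
        "control": {s: 1.0 for s in DENSITY_SUBTYPES},
        "sudep": {s: 1.0 for s in DENSITY_SUBTYPES},
        "alpers": {"pv": 0.15, "cr": 0.57, "cb": 0.30, "sst": 0.30,
                   "pyr": 0.30},
    }
    return {
        g: {r: {s: control[r][s] * multipliers[g][s]
                for s in DENSITY_SUBTYPES}
            for r in REGIONS}
        for g in GROUPS
    }


def generate_counts(
    rates: dict,
    area_mm2: float,
    cohort: pd.DataFrame,
    rng=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Poisson neuronal-count records per subject x region x subtype.

    ``rates`` maps group -> region -> subtype -> density (cells/mm²);
    counts are Poisson with mean ``rate x area_mm2``.
    """
    if not area_mm2 > 0:
        raise SpecificationError(f"area must be > 0 mm², got {area_mm2}")
    for g, per_region in rates.items():
        for r, per_subtype in per_region.items():
            for s, rate in per_subtype.items():
                if rate < 0:
                    raise SpecificationError(
                        f"negative density rate for {g}/{r}/{s}: {rate}")
    rng = _rng(seed if rng is None else rng)
    rows = []
    for _, subj in cohort.iterrows():
        g = subj["group"]
        for region, per_subtype in rates[g].items():
            for subtype, rate in per_subtype.items():
                rows.append({
                    "subject": subj["subject"],
                    "group": g,
                    "region": region,
                    "subtype": subtype,
                    "count": int(rng.poisson(rate * area_mm2)),
                    "area_mm2": float(area_mm2),
                })
    return pd.DataFrame(
        rows, columns=["subject", "group", "region", "subtype",
                       "count", "area_mm2"])


# ---------------------------------------------------------------------------
# rendered scenes
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Layout of one rendered multi-channel field of view.

    Somata are disks with radii drawn uniformly from ``soma_radius_um``;
    centres are rejection-sampled so that disk edges are at least
    ``min_separation_um`` apart and every disk lies inside the image.
    Per-channel cell intensities come from ``intensity_model`` for the
    configured group/subtype.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.5
    n_cells: int = 12
    soma_radius_um: tuple[float, float] = (4.0, 7.0)
    min_separation_um: float = 2.0
    background: dict = field(default_factory=lambda: {
        c: 5.0 for c in CHANNELS})
    noise_sd: dict = field(default_factory=lambda: {
        c: 2.0 for c in CHANNELS})
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    group: str = "control"
    subtype: str = "pv"
    region: str = "occipital"
    max_attempts: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.soma_radius_um
        if not (0 < lo <= hi):
            raise SpecificationError(
                f"soma radius range must satisfy 0 < lo <= hi, got {lo, hi}")
        if self.min_separation_um < 0:
            raise SpecificationError("min_separation must be >= 0")
        if not self.pixel_size > 0:
            raise SpecificationError("pixel_size must be > 0")
        if self.n_cells < 0:
            raise SpecificationError("n_cells must be >= 0")
        for c in CHANNELS:
            if self.background[c] < 0 or self.noise_sd[c] < 0:
                raise SpecificationError(
                    "background and noise_sd must be >= 0")
        h, w = self.image_shape
        if hi / self.pixel_size * 2 > min(h, w):
            raise SpecificationError(
                "largest soma does not fit within the image bounds")


@dataclass
class GroundTruth:
    """Planted truth for one rendered scene.

    ``label_image`` assigns every pixel to one cell (0 = background);
    ``cells`` carries centre, radius, the noise-free per-channel
    intensity of each disk and the planted deficiency classes;
    ``density_per_mm2`` is the realised cell density of the field.
    """

    label_image: np.ndarray
    cells: pd.DataFrame
    density_per_mm2: float


def _place_disks(spec: SceneSpec, radii_px: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample disk centres; raises PlacementError on failure."""
    h, w = spec.image_shape
    sep_px = spec.min_separation_um / spec.pixel_size
    centres: list[tuple[float, float]] = []
    for i, r in enumerate(radii_px):
        for _ in range(spec.max_attempts):
            cy = rng.uniform(r, h - r)
            cx = rng.uniform(r, w - r)
            ok = all(
                np.hypot(cy - oy, cx - ox) >= r + radii_px[j] + sep_px
                for j, (oy, ox) in enumerate(centres))
            if ok:
                centres.append((cy, cx))
                break
        else:
            raise PlacementError(
                f"could not place soma {i + 1}/{spec.n_cells} after "
                f"{spec.max_attempts} attempts under min_separation="
                f"{spec.min_separation_um} µm in a {h}x{w} px field")
    return np.array(centres).reshape(-1, 2)


def render_scene(spec: SceneSpec, rng=None) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one field of view and its ground truth.

    Each soma is a filled disk whose noise-free pixel value per channel
    equals the cell's true intensity; i.i.d. Gaussian noise with the
    configured per-channel SD is added on top (clipped at zero).
    """
    rng = _rng(spec.seed if rng is None else rng)
    h, w = spec.image_shape
    radii_um = rng.uniform(*spec.soma_radius_um, size=spec.n_cells)
    radii_px = radii_um / spec.pixel_size
    centres = _place_disks(spec, radii_px, rng)
    cells = _sample_cells(spec.intensity_model, spec.group, spec.subtype,
                          spec.n_cells, rng)
    cells.insert(1, "centroid_row", centres[:, 0] if spec.n_cells else [])
    cells.insert(2, "centroid_col", centres[:, 1] if spec.n_cells else [])
    cells.insert(3, "radius_um", radii_um)

    labels = np.zeros((h, w), dtype=np.int32)
    data = np.stack([np.full((h, w), spec.background[c]) for c in CHANNELS])
    yy, xx = np.mgrid[0:h, 0:w]
    for i in range(spec.n_cells):
        cy, cx = centres[i]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radii_px[i] ** 2
        labels[mask] = i + 1
        for k, c in enumerate(CHANNELS):
            data[k][mask] = cells.loc[i, INTENSITY_COLUMNS[c]]
    for k, c in enumerate(CHANNELS):
        if spec.noise_sd[c] > 0:
            data[k] = data[k] + rng.normal(0, spec.noise_sd[c], size=(h, w))
    data = np.clip(data, 0, None)

    area_mm2 = h * w * (spec.pixel_size * 1e-3) ** 2
    truth = GroundTruth(
        label_image=labels,
        cells=cells,
        density_per_mm2=spec.n_cells / area_mm2,
    )
    return MultiChannelImage(data=data, pixel_size=spec.pixel_size), truth


# ---------------------------------------------------------------------------
# seed plumbing
# ---------------------------------------------------------------------------

def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one integer seed into ``n`` independent generators.

    Sub-streams are order-stable: stream ``i`` is unaffected by how many
    further streams are spawned, so adding a pipeline stage never
    perturbs earlier stages.
    """
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def with_seed(obj, seed: int):
    """Return a copy of a spec/model dataclass with its seed replaced."""
    return replace(obj, seed=seed)
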