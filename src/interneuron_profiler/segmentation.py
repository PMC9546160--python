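"""Soma outlining and per-cell intensity measurement.

Somata are outlined by thresholding the 405 nm calcium-binding-protein
channel: pixels at or above the threshold form a mask whose 8-connected
components, filtered by a plausible soma-area gate, become the cell
labels. Within each label the arithmetic mean pixel value of every
channel is the cell's mean optical intensity.

The threshold is Otsu's method on the 405 nm channel by default, with a
fixed absolute override available; the choice is recorded on the result
so a run log can echo it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.segmentation import clear_border

from .channels import CHANNELS, INTENSITY_COLUMNS, SEGMENTATION_CHANNEL
from .errors import InputError, SpecificationError
from .image import MultiChannelImage

#: plausible 2-D soma area bounds, µm² (config-overridable)
DEFAULT_MIN_AREA_UM2 = 30.0
DEFAULT_MAX_AREA_UM2 = 2000.0


def segment_somata(
    image: MultiChannelImage,
    threshold: float | str = "otsu",
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    max_area_um2: float = DEFAULT_MAX_AREA_UM2,
    exclude_border: bool = False,
) -> np.ndarray:
    """Label somata on the 405 nm channel.

    Parameters
    ----------
    threshold
        ``"otsu"`` (default) or an absolute intensity value; pixels with
        value >= threshold are foreground.
    min_area_um2, max_area_um2
        Area gate in µm²; components outside the gate are discarded.
    exclude_border
        Drop cells touching the image border (kept by default).

    Returns
    -------
    numpy.ndarray
        Integer label image, labels numbered ``1..K`` in raster-scan
        order of each component's first pixel; 0 is background.
    """
    if not min_area_um2 < max_area_um2:
        raise SpecificationError(
            f"area gate requires min < max, got [{min_area_um2}, {max_area_um2}]")
    plane = image.channel(SEGMENTATION_CHANNEL)
    if threshold == "otsu":
        if np.ptp(plane) == 0:
            # featureless field: nothing to outline
            return np.zeros(plane.shape, dtype=np.int32)
        thr = threshold_otsu(plane)
    else:
        thr = float(threshold)
    mask = plane >= thr
    labels = measure.label(mask, connectivity=2)
    if exclude_border:
        labels = clear_border(labels)
    px_area = image.pixel_size ** 2
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for p in measure.regionprops(labels):
        keep[p.label] = min_area_um2 <= p.area * px_area <= max_area_um2
    labels[~keep[labels]] = 0
    return _relabel_scan_order(labels)


def _relabel_scan_order(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K by raster-scan order of first occurrence."""
    flat = labels.ravel()
    nonzero = flat[flat > 0]
    if nonzero.size == 0:
        return labels.astype(np.int32)
    # order of first appearance in the flattened (row-major) image
    _, first_idx = np.unique(nonzero, return_index=True)
    order = nonzero[np.sort(first_idx)]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[order] = np.arange(1, order.size + 1)
    return lut[labels]


def measure_cells(
    labels: np.ndarray,
    image: MultiChannelImage,
    subject: str | None = None,
    region: str | None = None,
    subtype: str | None = None,
) -> pd.DataFrame:
    """Measure every labelled soma.

    Returns one row per label with columns ``cell_id, centroid_row,
    centroid_col, area_um2`` and the per-channel mean optical intensity
    (``i_cbp, i_coxi, i_ndufb8, i_porin``). Area is pixel count times
    the squared pixel size. Context columns (subject/region/subtype)
    are prepended when provided.
    """
    labels = np.asarray(labels)
    if labels.shape != image.shape:
        raise InputError(
            f"label image shape {labels.shape} does not match "
            f"image shape {image.shape}")
    cols = ["cell_id", "centroid_row", "centroid_col", "area_um2"] + [
        INTENSITY_COLUMNS[c] for c in CHANNELS]
    if labels.max() == 0:
        df = pd.DataFrame(columns=cols)
    else:
        props = measure.regionprops_table(
            labels,
            intensity_image=np.moveaxis(image.data, 0, -1),
            properties=("label", "centroid", "area", "intensity_mean"),
        )
        df = pd.DataFrame({
            "cell_id": props["label"],
            "centroid_row": props["centroid-0"],
            "centroid_col": props["centroid-1"],
            "area_um2": props["area"] * image.pixel_size ** 2,
            **{INTENSITY_COLUMNS[c]: props[f"intensity_mean-{k}"]
               for k, c in enumerate(CHANNELS)},
        })[cols]
    for name, value in (("subtype", subtype), ("region", region),
                        ("subject", subject)):
        if value is not None:
            df.insert(0, name, value)
    return df
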