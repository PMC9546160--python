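"""Fluorescence channel conventions.

The quadruple immunofluorescence assay uses four channels:

====== ============== =================================================
Laser  Column key     Marker
====== ============== =================================================
405 nm ``cbp``        calcium-binding protein (parvalbumin/calretinin),
                      the soma-outlining channel
488 nm ``coxi``       COXI, mtDNA-encoded complex IV subunit I
546 nm ``ndufb8``     NDUFB8, nuclear-encoded complex I subunit
647 nm ``porin``      porin (VDAC1), mitochondrial mass marker
====== ============== =================================================

Multi-channel TIFFs are written and read in wavelength order
(405, 488, 546, 647); ``CHANNELS`` fixes that order everywhere.
"""

# wavelength order; index in a stacked (4, H, W) image
CHANNELS: tuple[str, ...] = ("cbp", "coxi", "ndufb8", "porin")

CHANNEL_WAVELENGTHS: dict[str, int] = {
    "cbp": 405,
    "coxi": 488,
    "ndufb8": 546,
    "porin": 647,
}

#: column names used in per-cell measurement tables
INTENSITY_COLUMNS: dict[str, str] = {c: f"i_{c}" for c in CHANNELS}

#: the channel used to outline somata
SEGMENTATION_CHANNEL: str = "cbp"
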