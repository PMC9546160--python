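"""Multi-channel image container and TIFF I/O.

A field of view is a stack of four co-registered fluorescence channels
(see :mod:`.channels`) with a known isotropic pixel size. TIFFs are
written one page per channel in wavelength order with the channel names
recorded in the image description, so files round-trip without external
metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .channels import CHANNELS
from .errors import InputError


@dataclass
class MultiChannelImage:
    """Four-channel fluorescence image with physical pixel size.

    Parameters
    ----------
    data
        Array of shape ``(4, H, W)`` in the channel order of
        :data:`~interneuron_profiler.channels.CHANNELS`; nonnegative,
        arbitrary units.
    pixel_size
        Isotropic pixel size in µm/pixel; must be positive.
    """

    data: np.ndarray
    pixel_size: float
    channel_names: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.channel_names):
            raise InputError(
                f"expected ({len(self.channel_names)}, H, W) channel stack, "
                f"got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise InputError("pixel values must be finite and nonnegative")
        if not self.pixel_size > 0:
            raise InputError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(H, W)``."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel plane by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise InputError(
                f"unknown channel {name!r}; have {self.channel_names}"
            ) from None
        return self.data[idx]

    # -- I/O ---------------------------------------------------------------

    def to_tiff(self, path) -> None:
        """Write the stack as a multi-page TIFF (one page per channel)."""
        meta = {
            "channel_names": list(self.channel_names),
            "pixel_size_um": self.pixel_size,
        }
        tifffile.imwrite(
            path,
            self.data.astype(np.float32),
            photometric="minisblack",
            description=json.dumps(meta),
            metadata=None,
        )

    @classmethod
    def from_tiff(
        cls,
        path,
        pixel_size: float | None = None,
        channel_map: dict[str, int] | None = None,
    ) -> "MultiChannelImage":
        """Read a multi-page/multi-channel TIFF.

        Parameters
        ----------
        pixel_size
            Overrides the pixel size recorded in the file; required when
            the file carries none.
        channel_map
            Optional mapping of channel name to page index, for files
            not written in the package's wavelength order.
        """
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray().astype(float)
            desc = tif.pages[0].description
        meta = {}
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        if pixel_size is None:
            pixel_size = meta.get("pixel_size_um")
        if pixel_size is None:
            raise InputError(
                "pixel_size not recorded in the TIFF and not supplied"
            )
        if data.ndim == 2:
            data = data[None]
        if channel_map is not None:
            order = [channel_map[c] for c in CHANNELS]
            data = data[order]
        return cls(data=data, pixel_size=float(pixel_size))


def write_label_tiff(path, labels: np.ndarray) -> None:
    """Write an integer label image (0 = background) as TIFF."""
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))


def read_label_tiff(path) -> np.ndarray:
    """Read an integer label image written by :func:`write_label_tiff`."""
    return np.asarray(tifffile.imread(path), dtype=np.int64)
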