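"""Two-channel ratiometric image sets and their TIFF layout.

An :class:`ImageSet` is one confocal field of root-meristem cells expressing
roGFP2, acquired at the two excitation wavelengths (405 nm excites the
oxidised form, 488 nm the reduced form), together with an integer label mask:

* ``0`` — background pixels,
* odd IDs (1, 3, 5, …) — nuclei,
* even IDs (2, 4, 6, …) — the cytosolic ring of the same cell, paired so
  that nucleus ``2i-1`` belongs with cytosol ``2i``.

On disk an image set is a two-page 16-bit unsigned TIFF (page 1 = 405 nm,
page 2 = 488 nm) plus a single-page 16-bit TIFF label mask with the same
shape, read and written with :mod:`tifffile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import InputError

__all__ = ["ImageSet", "NUCLEUS", "CYTOSOL", "BACKGROUND", "compartment_mask"]

NUCLEUS = "nucleus"
CYTOSOL = "cytosol"
BACKGROUND = "background"


def compartment_mask(label_mask: np.ndarray, compartment: str) -> np.ndarray:
    """Boolean mask of the pixels belonging to a compartment class."""
    if compartment == BACKGROUND:
        return label_mask == 0
    if compartment == NUCLEUS:
        return (label_mask > 0) & (label_mask % 2 == 1)
    if compartment == CYTOSOL:
        return (label_mask > 0) & (label_mask % 2 == 0)
    raise InputError(f"unknown compartment {compartment!r}")


@dataclass
class ImageSet:
    """One field: 405 nm channel, 488 nm channel and the label mask."""

    channel_405: np.ndarray
    channel_488: np.ndarray
    label_mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.channel_405.shape == self.channel_488.shape == self.label_mask.shape):
            raise InputError(
                f"channel/mask shapes differ: {self.channel_405.shape}, "
                f"{self.channel_488.shape}, {self.label_mask.shape}")

    @property
    def saturation_cap(self) -> int:
        return int(self.metadata.get("saturation_cap", 65535))

    def cell_ids(self) -> list[int]:
        """Nucleus IDs present in the mask (each pairs with nucleus_id + 1)."""
        ids = np.unique(self.label_mask)
        return [int(i) for i in ids if i > 0 and i % 2 == 1]

    # -- disk layout ------------------------------------------------------
    def save(self, stem: str | Path) -> tuple[Path, Path]:
        """Write ``<stem>.tif`` (two pages: 405 then 488) and ``<stem>_mask.tif``."""
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        img_path = stem.with_suffix(".tif")
        mask_path = stem.parent / f"{stem.name}_mask.tif"
        stack = np.stack([
            np.clip(np.rint(self.channel_405), 0, 65535).astype(np.uint16),
            np.clip(np.rint(self.channel_488), 0, 65535).astype(np.uint16),
        ])
        tifffile.imwrite(img_path, stack, metadata=None)
        tifffile.imwrite(mask_path, self.label_mask.astype(np.uint16), metadata=None)
        return img_path, mask_path

    @classmethod
    def load(cls, stem: str | Path, metadata: dict | None = None) -> "ImageSet":
        stem = Path(stem)
        stack = tifffile.imread(stem.with_suffix(".tif"))
        if stack.ndim != 3 or stack.shape[0] != 2:
            raise InputError(f"{stem}.tif is not a two-page 405/488 stack")
        mask = tifffile.imread(stem.parent / f"{stem.name}_mask.tif")
        return cls(stack[0].astype(np.float64), stack[1].astype(np.float64),
                   mask.astype(np.int64), metadata or {})
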