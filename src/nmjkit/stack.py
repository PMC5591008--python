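"""3D image stack container with physical voxel spacing.

Confocal stacks are stored as (z, y, x) arrays of unsigned integer gray
levels together with the voxel spacing in micrometres.  Typical
acquisition for this preparation is 1024x1024 in-plane with a 0.25 um
z-step for Bruchpilot (active-zone) channels and 0.5 um for the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack"]


@dataclass(frozen=True)
class ImageStack:
    """A 3D voxel grid of gray levels with physical spacing.

    Parameters
    ----------
    voxels
        Array of shape ``(z, y, x)``, unsigned integer dtype.
    spacing
        ``(dz, dy, dx)`` in micrometres; all strictly positive.
    channel
        Free-form channel label (e.g. ``"Brp"``, ``"HRP"``).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim == 2:  # single slice is promoted to a 1-slice stack
            v = v[None]
        if v.ndim != 3:
            raise ValueError(f"expected a (z, y, x) array, got ndim={v.ndim}")
        if not np.issubdtype(v.dtype, np.unsignedinteger):
            raise ValueError(f"gray levels must be unsigned integers, got {v.dtype}")
        if v.shape[0] < 1:
            raise ValueError("stack needs at least one slice")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def bit_depth(self) -> int:
        return self.voxels.dtype.itemsize * 8

    @property
    def n_levels(self) -> int:
        return 1 << self.bit_depth

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in um^3."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return replace(self, voxels=voxels)


def read_stack(
    path: str | Path,
    spacing: tuple[float, float, float],
    channel: str = "",
) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`."""
    voxels = tifffile.imread(str(path))
    voxels = np.asarray(voxels)
    if voxels.ndim == 2:
        voxels = voxels[None]
    return ImageStack(voxels=voxels, spacing=spacing, channel=channel)


def write_stack(path: str | Path, stack: ImageStack | np.ndarray) -> None:
    """Write a stack (or bare 3D array / boolean mask) as multi-page TIFF."""
    arr = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    tifffile.imwrite(str(path), arr)
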