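"""Core volumetric containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Volume:
    """A 3D scalar grid with isotropic-or-not voxel spacing in mm.

    Axis 0 is the axial (slice) axis, 0-based; axes 1 and 2 are the in-plane
    rows and columns.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")
        if any(s <= 0 for s in self.data.shape):
            raise ValueError("Volume dimensions must be positive")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A {0,1} labeling on the same lattice as its paired :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"BinaryMask must be 3D, got shape {data.shape}")
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("BinaryMask values must be exactly 0 or 1")
        self.data = data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def volume_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class ROISample:
    """Fixed-size multi-channel crop around the sinus centroid.

    ``image_channel`` holds intensities, ``mask_channel`` the stage-1
    segmentation (binary by default, probabilities if configured), both of
    shape ``crop_size`` = (D, H, W).  ``label`` is 0 = female, 1 = male, or
    None when unknown.
    """

    image_channel: np.ndarray
    mask_channel: np.ndarray
    centroid: tuple[int, int, int]
    label: int | None = None
    pad_fraction: float = 0.0
    centroid_fallback: bool = False

    def __post_init__(self) -> None:
        if self.image_channel.shape != self.mask_channel.shape:
            raise ValueError("image and mask channels must share crop_size")
        if self.mask_channel.min() < 0 or self.mask_channel.max() > 1:
            raise ValueError("mask channel must lie in [0, 1]")
        if not (0.0 <= self.pad_fraction < 1.0):
            raise ValueError("pad_fraction must be in [0, 1)")

    @property
    def crop_size(self) -> tuple[int, int, int]:
        return self.image_channel.shape
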