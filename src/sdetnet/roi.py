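"""ROI assembly between the two stages.

Stacks the per-slice segmentation into a 3D mask, finds the sinus centroid,
crops a fixed-size region centered on it (constant-padded where the window
leaves the volume) and stacks the image and mask channels into the
classifier's multi-channel input.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ROISample, Volume

DEFAULT_CROP = (122, 128, 128)


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest connected component (26-connectivity)."""
    labels, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3), dtype=int))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return BinaryMask((labels == keep).astype(np.uint8), mask.spacing)


def centroid_of(mask: BinaryMask) -> tuple[tuple[int, int, int], bool]:
    """Integer centroid of the foreground and an empty-mask fallback flag.

    The centroid is the arithmetic mean of foreground voxel indices rounded
    to the nearest voxel.  An empty mask falls back to the volume center
    (flag True) rather than erroring: downstream cropping still proceeds.
    """
    fg = np.argwhere(mask.data > 0)
    if fg.shape[0] == 0:
        center = tuple(int(s // 2) for s in mask.shape)
        return center, True
    c = tuple(int(v) for v in np.round(fg.mean(axis=0)).astype(int))
    return c, False


def crop_roi(volume: Volume, mask: np.ndarray | BinaryMask,
             center: tuple[int, int, int],
             crop_size: tuple[int, int, int] = DEFAULT_CROP,
             binarize_mask: bool = True,
             label: int | None = None,
             centroid_fallback: bool = False) -> ROISample:
    """Extract a fixed-size crop centered at ``center``.

    Voxels outside the volume are constant-padded: the image channel with
    the volume's minimum intensity (background), the mask channel with 0.
    The window is never shifted to fit — "centered at the centroid" is
    preserved exactly and ``pad_fraction`` records the padded share.
    """
    mdata = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    if mdata.shape != volume.data.shape:
        raise ValueError("mask and volume shapes differ")
    for cs, vs in zip(crop_size, volume.data.shape):
        if cs > 2 * vs:
            raise ValueError(f"crop size {crop_size} exceeds twice the volume "
                             f"shape {volume.data.shape}")
    if any(int(c) != c for c in center):
        raise ValueError("center must be an integer voxel coordinate")
    if binarize_mask:
        mdata = (mdata >= 0.5).astype(np.float32)
    else:
        mdata = mdata.astype(np.float32)

    bg = float(volume.data.min())
    img = np.full(crop_size, bg, dtype=np.float32)
    msk = np.zeros(crop_size, dtype=np.float32)

    src_lo, src_hi, dst_lo, dst_hi = [], [], [], []
    for ax in range(3):
        start = int(center[ax]) - crop_size[ax] // 2
        s_lo = max(start, 0)
        s_hi = min(start + crop_size[ax], volume.data.shape[ax])
        src_lo.append(s_lo)
        src_hi.append(s_hi)
        dst_lo.append(s_lo - start)
        dst_hi.append(s_lo - start + max(s_hi - s_lo, 0))
    if all(h > l for l, h in zip(src_lo, src_hi)):
        src = tuple(slice(l, h) for l, h in zip(src_lo, src_hi))
        dst = tuple(slice(l, h) for l, h in zip(dst_lo, dst_hi))
        img[dst] = volume.data[src]
        msk[dst] = mdata[src]
        inside = int(np.prod([h - l for l, h in zip(src_lo, src_hi)]))
    else:
        inside = 0
    pad_fraction = 1.0 - inside / float(np.prod(crop_size))
    return ROISample(img, msk, tuple(int(c) for c in center), label=label,
                     pad_fraction=pad_fraction, centroid_fallback=centroid_fallback)


def extract_roi(volume: Volume, mask: np.ndarray | BinaryMask,
                crop_size: tuple[int, int, int] = DEFAULT_CROP,
                binarize_mask: bool = True, label: int | None = None,
                keep_largest_component: bool = False) -> ROISample:
    """Centroid + crop in one step (the usual inter-stage path)."""
    m = mask if isinstance(mask, BinaryMask) else BinaryMask(
        (np.asarray(mask) >= 0.5).astype(np.uint8))
    if keep_largest_component:
        m = largest_component(m)
    center, fallback = centroid_of(m)
    return crop_roi(volume, mask, center, crop_size, binarize_mask,
                    label=label, centroid_fallback=fallback)


def assemble_mci(roi: ROISample, channels: tuple[str, ...] = ("image", "mask")
                 ) -> np.ndarray:
    """Stack the requested channels (image first) into a (C, D, H, W) input.

    The three ablation configurations are channel subsets: ("image",),
    ("mask",), and ("image", "mask").
    """
    if not channels:
        raise ValueError("channel subset must be nonempty")
    bad = set(channels) - {"image", "mask"}
    if bad:
        raise ValueError(f"unknown channels {sorted(bad)}")
    planes = []
    if "image" in channels:
        planes.append(roi.image_channel)
    if "mask" in channels:
        planes.append(roi.mask_channel)
    return np.stack(planes).astype(np.float32)
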