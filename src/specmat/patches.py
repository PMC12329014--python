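"""Model input construction and the overlapping-patch machinery.

The networks consume 4-channel slices: low-bin HU, high-bin HU, a
distance-from-center map and a distance-from-edge map (both in cm).  The two
distance channels encode where a voxel sits relative to the object outline,
letting one model adapt across phantom sizes.  Slices are cut into 64x64
patches overlapping by 16 px (stride 48); predictions are stitched back by
averaging the overlaps, with probability channels renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .simulate import SpectralAcquisition

__all__ = [
    "PATCH_SIZE",
    "PATCH_OVERLAP",
    "ModelInputStack",
    "PatchGrid",
    "build_input_stack",
    "extract_patches",
    "stitch_patches",
]

PATCH_SIZE = 64
PATCH_OVERLAP = 16

#: fixed affine HU normalization: [-1000, 2000] HU -> [-1, 2]
HU_SCALE = 1000.0
NORMALIZATION_VERSION = "hu/1000-dist-cm-v1"


class EmptyMaskError(ValueError):
    """No object found in the acquisition."""


@dataclass
class ModelInputStack:
    """Per-slice 4-channel network input, (nz, 4, n, n) float32."""

    channels: np.ndarray
    object_mask: np.ndarray  # (nz, n, n) bool
    normalization: str = NORMALIZATION_VERSION
    meta: dict | None = None

    @property
    def shape(self):
        return self.channels.shape


def build_input_stack(
    acquisition: SpectralAcquisition, hu_threshold: float = -300.0
) -> ModelInputStack:
    """Assemble the 4 input channels from a two-bin acquisition.

    The object mask is the filled largest connected component above
    ``hu_threshold`` in the low-bin image; distance-from-center is Euclidean
    distance (cm) to the mask centroid, distance-from-edge the Euclidean
    distance transform (cm) inside the mask (zero outside).
    """
    low, high = acquisition.hu["low"], acquisition.hu["high"]
    nz, n, _ = low.shape
    px = acquisition.pixel_cm
    chans = np.empty((nz, 4, n, n), dtype=np.float32)
    masks = np.empty((nz, n, n), dtype=bool)
    for k in range(nz):
        raw = low[k] > hu_threshold
        lab, nlab = ndimage.label(raw)
        if nlab == 0:
            raise EmptyMaskError(f"no object above {hu_threshold} HU in slice {k}")
        largest = np.argmax(ndimage.sum_labels(raw, lab, np.arange(1, nlab + 1))) + 1
        mask = ndimage.binary_fill_holes(lab == largest)
        masks[k] = mask
        cy, cx = ndimage.center_of_mass(mask)
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        chans[k, 0] = low[k] / HU_SCALE
        chans[k, 1] = high[k] / HU_SCALE
        chans[k, 2] = np.hypot(yy - cy, xx - cx) * px
        chans[k, 3] = ndimage.distance_transform_edt(mask) * px
    return ModelInputStack(
        channels=chans,
        object_mask=masks,
        meta={"phantom_id": acquisition.meta.get("phantom_id")},
    )


@dataclass(frozen=True)
class PatchGrid:
    """Anchors of overlapping patches fully covering an image."""

    image_shape: tuple[int, int]
    patch: int = PATCH_SIZE
    overlap: int = PATCH_OVERLAP

    @property
    def stride(self) -> int:
        return self.patch - self.overlap

    def axis_anchors(self, size: int) -> list[int]:
        if size < self.patch:
            raise ValueError(f"image side {size} smaller than patch {self.patch}")
        starts = list(range(0, size - self.patch + 1, self.stride))
        if starts[-1] != size - self.patch:
            starts.append(size - self.patch)  # clamped terminal anchor
        return starts

    @property
    def anchors(self) -> list[tuple[int, int]]:
        ny, nx = self.image_shape
        return [(r, c) for r in self.axis_anchors(ny) for c in self.axis_anchors(nx)]


def extract_patches(image: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Ordered (n_patches, C, patch, patch) tensor from a (C, H, W) image."""
    p = grid.patch
    return np.stack([image[..., r : r + p, c : c + p] for r, c in grid.anchors])


def stitch_patches(
    patches: np.ndarray,
    grid: PatchGrid,
    prob_channels: slice | None = None,
) -> np.ndarray:
    """Average overlapping patch outputs back into a full image.

    ``prob_channels`` marks a channel range holding a probability simplex;
    those channels are renormalized to sum to one after averaging.
    """
    anchors = grid.anchors
    if len(patches) != len(anchors):
        raise ValueError("patch count does not match grid anchors")
    p = grid.patch
    c = patches.shape[1]
    out = np.zeros((c, *grid.image_shape), dtype=np.float64)
    weight = np.zeros(grid.image_shape, dtype=np.float64)
    for patch, (r, cc) in zip(patches, anchors):
        out[:, r : r + p, cc : cc + p] += patch
        weight[r : r + p, cc : cc + p] += 1.0
    out /= weight[None]
    if prob_channels is not None:
        s = out[prob_channels].sum(axis=0, keepdims=True)
        out[prob_channels] = np.divide(
            out[prob_channels], s, out=np.zeros_like(out[prob_channels]), where=s > 0
        )
    return out.astype(patches.dtype)
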