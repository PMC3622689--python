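"""Mask filtering, region labeling, and the frame/stack segmentation pipeline.

The pipeline applied to each frame is fixed:

    gamma adjust -> threshold -> speckle (opening) filter -> label -> size filter

The speckle filter runs before the size filter on purpose: the opening
removes the noisiest thresholding artifacts first, which makes choosing the
minimum object size much simpler.

Labeling uses 8-connectivity; a region's border is the set of its pixels
4-adjacent to at least one pixel outside the region (this pairing keeps
borders closed curves).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as _sk_label

from .errors import ConfigError, DegenerateInputError, StructuralError
from .image_io import ChannelStack
from .thresholding import RayParams, gamma_adjust, threshold

__all__ = [
    "SegmentationParams",
    "Region",
    "LabeledRegions",
    "disk_element",
    "speckle_filter",
    "label_regions",
    "size_filter",
    "segment_frame",
    "segment_stack",
]


def disk_element(radius: int) -> np.ndarray:
    """Discrete disk structuring element: (i, j) included iff i^2 + j^2 <= r^2."""
    if radius < 0:
        raise ConfigError("disk radius must be >= 0")
    r = int(radius)
    ii, jj = np.mgrid[-r : r + 1, -r : r + 1]
    return (ii**2 + jj**2) <= r**2


@dataclass
class SegmentationParams:
    """User-tunable knobs of the per-frame segmentation pipeline.

    These are the handful of values a user dials in on a preview frame
    before batch-processing a whole movie: the preview frame index, the
    gamma adjustment, the minimum object area (px) below which a region is
    not a cell, the disk radius of the speckle-removal opening, the
    thresholding method, and the adaptive thresholder's own parameters.
    """

    frame_index: int = 0
    gamma: float = 1.0
    min_object_area: int = 30
    speckle_disk_radius: int = 1
    method: str = "ray"
    ray: RayParams = field(default_factory=RayParams)
    invert: bool = False

    def __post_init__(self) -> None:
        if self.min_object_area < 0:
            raise ConfigError("min_object_area must be >= 0")
        if self.speckle_disk_radius < 0:
            raise ConfigError("speckle_disk_radius must be >= 0")
        if not self.gamma > 0:
            raise ConfigError("gamma must be > 0")


@dataclass
class Region:
    """One labeled connected component."""

    id: int
    area_px: int
    centroid: tuple[float, float]  # (row, col), sub-pixel
    border_pixels: np.ndarray  # (n, 2) int array of (row, col)
    mean_intensity: dict[str, float] = field(default_factory=dict)


@dataclass
class LabeledRegions:
    """Integer label map (0 = background) plus per-region records.

    Labels are consecutive positive integers 1..n in record order.
    """

    label_map: np.ndarray
    regions: list[Region]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.label_map == region_id

    def centroids(self) -> np.ndarray:
        """(n, 2) array of region centroids in (row, col) order."""
        if not self.regions:
            return np.empty((0, 2))
        return np.array([r.centroid for r in self.regions])


def speckle_filter(mask: np.ndarray, disk_radius: int) -> np.ndarray:
    """Rough-pass filter: morphological opening with a discrete disk.

    Erosion followed by dilation removes any foreground feature that cannot
    contain the disk — in practice the single-pixel speckling a noisy
    threshold leaves behind.  ``disk_radius == 0`` is the identity.
    """
    mask = np.asarray(mask, dtype=bool)
    if disk_radius == 0:
        return mask.copy()
    selem = disk_element(disk_radius)
    return ndi.binary_opening(mask, structure=selem)


def _borders(label_map: np.ndarray) -> np.ndarray:
    """Boolean map of pixels 4-adjacent to a pixel with a different label."""
    border = np.zeros(label_map.shape, dtype=bool)
    padded = np.pad(label_map, 1, constant_values=-1)
    core = padded[1:-1, 1:-1]
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        border |= nb != core
    border &= label_map > 0
    return border


def label_regions(
    mask: np.ndarray,
    channels: ChannelStack | None = None,
    frame_index: int = 0,
) -> LabeledRegions:
    """Label 8-connected components and log per-region measurements.

    For every component the area, unweighted centroid, border pixels, and —
    when a stack is supplied — the mean intensity of each channel over the
    member pixels are recorded.  An empty mask yields an empty region list.
    """
    mask = np.asarray(mask, dtype=bool)
    if channels is not None and mask.shape != channels.frame_shape:
        raise StructuralError(
            f"mask shape {mask.shape} != frame shape {channels.frame_shape}"
        )
    label_map = _sk_label(mask, connectivity=2)
    n = int(label_map.max())
    border_map = _borders(label_map)
    regions: list[Region] = []
    if n:
        idx = np.arange(1, n + 1)
        areas = ndi.sum_labels(np.ones_like(label_map), label_map, idx).astype(int)
        centroids = ndi.center_of_mass(np.ones(mask.shape), label_map, idx)
        frame_means: dict[str, np.ndarray] = {}
        if channels is not None:
            for name in channels.channel_names:
                frame = channels.frame(name, frame_index)
                frame_means[name] = ndi.mean(frame, label_map, idx)
        br, bc = np.nonzero(border_map)
        blabels = label_map[br, bc]
        order = np.argsort(blabels, kind="stable")
        br, bc, blabels = br[order], bc[order], blabels[order]
        starts = np.searchsorted(blabels, idx)
        stops = np.searchsorted(blabels, idx, side="right")
        for i in range(n):
            regions.append(
                Region(
                    id=i + 1,
                    area_px=int(areas[i]),
                    centroid=(float(centroids[i][0]), float(centroids[i][1])),
                    border_pixels=np.column_stack(
                        [br[starts[i] : stops[i]], bc[starts[i] : stops[i]]]
                    ),
                    mean_intensity={k: float(v[i]) for k, v in frame_means.items()},
                )
            )
    return LabeledRegions(label_map=label_map, regions=regions)


def size_filter(labeled: LabeledRegions, min_area: int) -> LabeledRegions:
    """High-pass area filter: drop regions smaller than ``min_area`` pixels.

    Surviving labels are renumbered consecutively, preserving their original
    order.
    """
    if min_area < 0:
        raise ConfigError("min_area must be >= 0")
    keep = [r for r in labeled.regions if r.area_px >= min_area]
    remap = np.zeros(labeled.n_regions + 1, dtype=labeled.label_map.dtype)
    new_regions = []
    for new_id, r in enumerate(keep, start=1):
        remap[r.id] = new_id
        new_regions.append(replace(r, id=new_id))
    return LabeledRegions(label_map=remap[labeled.label_map], regions=new_regions)


def segment_frame(
    stack: ChannelStack, params: SegmentationParams, channel: str, frame_index: int | None = None
) -> LabeledRegions:
    """Run the full per-frame pipeline on one frame of ``channel``.

    Deterministic for fixed parameters.  Errors from individual stages (for
    example a constant frame handed to the thresholder) propagate unchanged.
    """
    idx = params.frame_index if frame_index is None else frame_index
    frame = stack.frame(channel, idx)
    if params.invert:
        frame = 1.0 - frame
    adjusted = gamma_adjust(frame, params.gamma)
    result = threshold(adjusted, params.method, params.ray)
    mask = speckle_filter(result.mask, params.speckle_disk_radius)
    labeled = label_regions(mask, stack, idx)
    return size_filter(labeled, params.min_object_area)


def segment_stack(
    stack: ChannelStack, params: SegmentationParams, channel: str
) -> tuple[list[LabeledRegions], np.ndarray]:
    """Segment every frame (or Z-slice) independently.

    Returns the per-frame labelings plus a 2-D outline projection counting,
    for each pixel, in how many slices it lies on a region border — the
    standard way to visualize per-slice segmentations of a Z-stack at a
    glance.  Slices with no detectable cells yield empty region lists and do
    not affect their neighbours.
    """
    labelings: list[LabeledRegions] = []
    projection = np.zeros(stack.frame_shape, dtype=int)
    for i in range(stack.n_frames):
        try:
            labeled = segment_frame(stack, params, channel, frame_index=i)
        except DegenerateInputError:
            # a content-free slice has no cells; it must not abort the stack
            labeled = LabeledRegions(
                label_map=np.zeros(stack.frame_shape, dtype=int), regions=[]
            )
        labelings.append(labeled)
        border = np.zeros(stack.frame_shape, dtype=bool)
        for r in labeled.regions:
            if len(r.border_pixels):
                border[r.border_pixels[:, 0], r.border_pixels[:, 1]] = True
        projection += border
    return labelings, projection
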