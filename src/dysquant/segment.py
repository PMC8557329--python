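"""Myofiber instance segmentation from the laminin-α2 mask channel.

The laminin network is binarized, inverted, and connected components of the
complement become fiber interiors; the interstitial network (which reaches
the frame border) and any region near the border are discarded.  Interiors
can optionally be expanded back into the laminin band so each fiber's
footprint includes its sarcolemma, from which a ring band is extracted and
parameterized into equal-angle arc segments around the centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk, erosion
from skimage.segmentation import expand_labels


class SegmentationError(ValueError):
    """Raised when no fibers can be segmented from the laminin channel."""


@dataclass
class FiberLabelMap:
    """Integer label image (0 = background/interstitium) with bookkeeping."""

    labels: np.ndarray  # int32, labels contiguous 1..n_labels
    n_labels: int
    threshold: float  # laminin binarization threshold actually used
    laminin_mask: np.ndarray  # boolean supra-threshold laminin network
    n_border_excluded: int = 0
    n_small_excluded: int = 0

    def areas(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel(), minlength=self.n_labels + 1)
        return {i: int(counts[i]) for i in range(1, self.n_labels + 1)}


@dataclass
class SarcolemmalRing:
    """Ring band of one fiber with equal-angle arc parameterization.

    ``arc_index`` maps each ring pixel to one of ``n_arcs`` equal-angle
    segments around the fiber centroid.  ``whole_fiber`` flags fibers too
    small to support the requested ring width (the ring is then the entire
    region).
    """

    fiber_id: int
    rows: np.ndarray
    cols: np.ndarray
    arc_index: np.ndarray
    n_arcs: int
    centroid: tuple[float, float]  # (row, col)
    area_px: int
    whole_fiber: bool = False

    def __len__(self) -> int:
        return self.rows.size


def segment_fibers(
    laminin_channel: np.ndarray,
    min_area: int = 100,
    laminin_threshold: float | str = "auto",
    border_margin: int = 5,
    expand_px: int = 0,
) -> FiberLabelMap:
    """Segment fiber interiors from the laminin channel.

    The channel is binarized (Otsu when ``laminin_threshold="auto"``),
    inverted, and 4-connected components of the complement are labeled.
    Components with any pixel within ``border_margin`` of the frame border
    (partial fiber profiles and the interstitial network) and components
    smaller than ``min_area`` are discarded; survivors are relabeled 1..N.
    With ``expand_px > 0`` each label is grown by up to that distance into
    the supra-threshold laminin band (never into other labels), so the
    fiber footprint includes its sarcolemma.

    Raises :class:`SegmentationError` when the image is flat or no laminin
    network is found.
    """
    lam = np.asarray(laminin_channel)
    if lam.ndim != 2:
        raise SegmentationError("laminin channel must be a 2-D image")
    if lam.max() == lam.min():
        raise SegmentationError("no fibers segmented: flat laminin channel")
    if laminin_threshold == "auto":
        threshold = float(threshold_otsu(lam))
    else:
        threshold = float(laminin_threshold)
    fg = lam > threshold  # strictly above: matches Otsu's binarization convention
    if not fg.any() or fg.all():
        raise SegmentationError("no fibers segmented: no laminin network found")

    labels, _ = ndi.label(~fg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    # drop anything near the border: partial profiles + interstitial network
    m = max(int(border_margin), 1)
    border = np.zeros_like(labels, dtype=bool)
    border[:m, :] = border[-m:, :] = True
    border[:, :m] = border[:, -m:] = True
    border_ids = np.setdiff1d(np.unique(labels[border]), [0])
    counts = np.bincount(labels.ravel())
    keep = np.ones(counts.size, dtype=bool)
    keep[0] = False
    keep[border_ids] = False
    n_border = len(border_ids)
    small_ids = np.nonzero(counts < min_area)[0]
    n_small = int(np.sum(keep[small_ids]))
    keep[small_ids] = False

    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    labels = remap[labels]
    n_labels = int(keep.sum())

    if expand_px > 0 and n_labels > 0:
        grown = expand_labels(labels, distance=expand_px)
        labels = np.where((labels > 0) | (fg & (grown > 0)), grown, 0).astype(np.int32)

    return FiberLabelMap(
        labels=labels.astype(np.int32),
        n_labels=n_labels,
        threshold=threshold,
        laminin_mask=fg,
        n_border_excluded=n_border,
        n_small_excluded=n_small,
    )


def extract_ring(
    label_map: FiberLabelMap | np.ndarray,
    ring_width: int = 3,
    n_arcs: int = 360,
) -> list[SarcolemmalRing]:
    """Extract the sarcolemmal ring band of each fiber and its arc segments.

    When a :class:`FiberLabelMap` is given and its labels were expanded into
    the laminin band, the ring is the fiber's share of the supra-threshold
    laminin network (``region ∩ laminin_mask``) — the sarcolemma exactly as
    the mask stain identifies it.  Otherwise (plain label array, or no
    laminin overlap) the ring falls back to the morphological inner band:
    fiber pixels within ``ring_width`` of the fiber boundary (region minus
    its erosion by a disk of radius ``ring_width``).  Fibers whose erosion is
    empty are flagged ``whole_fiber`` and the full region is used.  The ring
    is parameterized into ``n_arcs`` equal-angle segments around the region
    centroid.
    """
    if ring_width < 1:
        raise SegmentationError("ring_width must be >= 1")
    if isinstance(label_map, FiberLabelMap):
        labels = label_map.labels
        laminin_mask = label_map.laminin_mask
    else:
        labels = label_map
        laminin_mask = None
    selem = disk(ring_width)
    rings: list[SarcolemmalRing] = []
    for prop in regionprops(labels):
        mask = prop.image  # cropped to bbox
        whole = False
        band = None
        if laminin_mask is not None:
            r0_, c0_, r1_, c1_ = prop.bbox
            band = mask & laminin_mask[r0_:r1_, c0_:c1_]
            if not band.any():
                band = None
        if band is None:
            # pad so erosion sees background beyond the tight bbox crop
            padded = np.pad(mask, ring_width + 1)
            eroded = erosion(padded, selem)[
                ring_width + 1 : -(ring_width + 1), ring_width + 1 : -(ring_width + 1)
            ]
            whole = not eroded.any()
            band = mask if whole else (mask & ~eroded)
        rr, cc = np.nonzero(band)
        r0, c0, _, _ = prop.bbox
        rows = rr + r0
        cols = cc + c0
        cy, cx = prop.centroid  # (row, col), full-image coords
        theta = np.mod(np.arctan2(rows - cy, cols - cx), 2 * np.pi)
        arc_index = np.minimum(
            (theta / (2 * np.pi) * n_arcs).astype(np.int64), n_arcs - 1
        )
        rings.append(
            SarcolemmalRing(
                fiber_id=int(prop.label),
                rows=rows,
                cols=cols,
                arc_index=arc_index,
                n_arcs=n_arcs,
                centroid=(cy, cx),
                area_px=int(prop.area),
                whole_fiber=whole,
            )
        )
    return rings
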