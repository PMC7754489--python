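"""Automated ghost-artifact censoring.

Bright, pulsatile large vessels cast periodic ghost replicas along the
phase-encoding axis of a multishot phase-contrast acquisition. Spurious
velocity fluctuations inside those replica bands masquerade as perforators.
The censoring procedure:

1. detrend the temporal-mean magnitude image (subtract a large median-filtered
   copy) to flatten coil/receive inhomogeneity;
2. identify large vessels as the top fraction (default 0.3%) of brain-voxel
   intensities, keeping only connected clusters of at least 3 voxels so
   isolated perforators are not mistaken for vessels;
3. grow each cluster into a stripe: dilate along the readout axis and extend
   along the phase-encoding axis — clusters of >= 80 voxels by (2 px, 200 px),
   smaller ones by (1 px, 110 px);
4. exclude every detected perforator located on a stripe.

The fraction of the WM mask covered by stripes (the "ghost fraction") bounds
how much analyzable area the artifacts cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from ._fastmedian import median_filter_reflect
from .detection import PerforatorRecord, connectivity_structure
from .exceptions import DegenerateInputError, FormatError, ParameterError
from .io import MaskRaster, PEAxis, RunConfig
from .masking import CentralWMMask


@dataclass(frozen=True)
class VesselCluster:
    """A connected cluster of bright large-vessel voxels with its stripe rule."""

    voxels: frozenset[tuple[int, int]]
    dilate_px: int
    extend_px: int

    @property
    def size(self) -> int:
        return len(self.voxels)

    def voxel_array(self) -> np.ndarray:
        """(k, 2) array of (row, col), sorted row-major."""
        return np.array(sorted(self.voxels), dtype=int).reshape(-1, 2)


@dataclass(frozen=True)
class StripeMask:
    """Union of ghost stripes cast by the detected large-vessel clusters."""

    data: np.ndarray
    clusters: tuple[VesselCluster, ...]
    pe_axis: PEAxis

    def as_mask(self) -> MaskRaster:
        return MaskRaster(data=self.data.astype(np.uint8), kind="stripe")


def _nearest_odd(window: int) -> int:
    return window if window % 2 == 1 else window + 1


def detrend_magnitude(mean_magnitude: np.ndarray, window_px: int = 70) -> np.ndarray:
    """Subtract a median-filtered copy (``window_px`` square, reflect padding)
    from the temporal-mean magnitude image, flattening smooth intensity
    inhomogeneity while leaving compact bright vessels as positive residuals.

    Even windows are realized as the next odd size (70 -> 71); the difference
    is sub-pixel.
    """
    img = np.asarray(mean_magnitude, dtype=float)
    if img.ndim != 2:
        raise FormatError("mean magnitude must be 2-D")
    if window_px < 3:
        raise ParameterError(f"window_px must be >= 3, got {window_px}")
    window = _nearest_odd(window_px)
    if window > min(img.shape):
        raise ParameterError(
            f"median window {window} exceeds image extent {img.shape}"
        )
    return img - median_filter_reflect(img, window)


def identify_large_vessels(
    detrended: np.ndarray,
    brain: MaskRaster,
    top_fraction: float = 0.003,
    min_cluster: int = 3,
    connectivity: int = 8,
    *,
    config: RunConfig | None = None,
    percentile_scope: Literal["brain", "image"] = "brain",
) -> list[VesselCluster]:
    """Threshold the detrended magnitude at its top ``top_fraction`` quantile
    and keep connected clusters of at least ``min_cluster`` voxels.

    The threshold is the intensity of the ``ceil(top_fraction * N)``-th
    brightest voxel over the percentile scope (the brain mask by default; air
    background would dilute a whole-image percentile). Ties at the threshold
    are all included, so the result is order-independent. Each surviving
    cluster is annotated with its stripe rule from ``config``: raw (pre-
    dilation) size >= ``big_cluster_threshold`` gets (big_dilate, big_extend),
    smaller clusters (small_dilate, small_extend). Clusters are returned
    sorted by descending size.
    """
    cfg = config or RunConfig()
    img = np.asarray(detrended, dtype=float)
    if img.shape != brain.data.shape:
        raise FormatError("detrended image and brain mask shapes differ")
    if not 0 < top_fraction < 1:
        raise ParameterError(f"top_fraction must be in (0, 1), got {top_fraction}")
    scope = brain.data if percentile_scope == "brain" else np.ones_like(brain.data, bool)
    values = img[scope]
    if values.size == 0:
        raise DegenerateInputError("empty percentile scope")
    m = int(np.ceil(top_fraction * values.size))
    threshold = np.partition(values, values.size - m)[values.size - m]
    candidates = scope & (img >= threshold)
    labels, n_labels = ndimage.label(
        candidates, structure=connectivity_structure(connectivity)
    )
    clusters: list[VesselCluster] = []
    for lab in range(1, n_labels + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size < min_cluster:
            continue
        big = rows.size >= cfg.big_cluster_threshold
        clusters.append(
            VesselCluster(
                voxels=frozenset(zip(rows.tolist(), cols.tolist())),
                dilate_px=cfg.big_dilate if big else cfg.small_dilate,
                extend_px=cfg.big_extend if big else cfg.small_extend,
            )
        )
    clusters.sort(key=lambda c: (-c.size, min(c.voxels)))
    return clusters


def _line_structure(length_each_side: int, axis: int) -> np.ndarray:
    """1-D structuring element of half-length ``length_each_side`` along ``axis``."""
    size = 2 * length_each_side + 1
    struct = np.ones((size, 1) if axis == 0 else (1, size), dtype=bool)
    return struct


def build_stripe_mask(
    clusters: Sequence[VesselCluster],
    shape: tuple[int, int],
    pe_axis: PEAxis,
    extend_mode: Literal["per_side", "total"] = "per_side",
) -> StripeMask:
    """Grow each vessel cluster into its ghost stripe and take the union.

    Per cluster: dilate the voxel set by ``dilate_px`` along the readout axis
    (orthogonal to ``pe_axis``), then extend by ``extend_px`` on each side
    along ``pe_axis`` (``extend_mode="total"`` splits ``extend_px`` across the
    two sides instead). Growth clips at the image border — no wrap-around.
    """
    pe = 0 if pe_axis == "rows" else 1
    readout = 1 - pe
    data = np.zeros(shape, dtype=bool)
    for cluster in clusters:
        vox = cluster.voxel_array()
        if np.any(vox < 0) or np.any(vox >= np.array(shape)):
            raise FormatError("cluster voxel outside image shape")
        footprint = np.zeros(shape, dtype=bool)
        footprint[vox[:, 0], vox[:, 1]] = True
        if cluster.dilate_px > 0:
            footprint = ndimage.binary_dilation(
                footprint, structure=_line_structure(cluster.dilate_px, readout)
            )
        per_side = (
            cluster.extend_px if extend_mode == "per_side" else cluster.extend_px // 2
        )
        if per_side > 0:
            footprint = ndimage.binary_dilation(
                footprint, structure=_line_structure(per_side, pe)
            )
        data |= footprint
    return StripeMask(data=data, clusters=tuple(clusters), pe_axis=pe_axis)


def censor(
    records: Sequence[PerforatorRecord], stripes: StripeMask
) -> tuple[list[PerforatorRecord], list[PerforatorRecord]]:
    """Partition perforators into (included, excluded) by stripe membership.

    A perforator located on a stripe pixel is excluded with reason
    ``"ghost_stripe"``; everything else is included. Input order is preserved
    within each list, and the two lists always partition the input.
    """
    rows, cols = stripes.data.shape
    included: list[PerforatorRecord] = []
    excluded: list[PerforatorRecord] = []
    for rec in records:
        if not (0 <= rec.row < rows and 0 <= rec.col < cols):
            raise FormatError(f"record at ({rec.row}, {rec.col}) outside mask shape")
        if stripes.data[rec.row, rec.col]:
            excluded.append(
                replace(rec, included=False, exclusion_reason="ghost_stripe")
            )
        else:
            included.append(replace(rec, included=True, exclusion_reason="none"))
    return included, excluded


def ghost_fraction(wm: CentralWMMask | MaskRaster, stripes: StripeMask) -> float:
    """Percentage of the WM mask covered by ghost stripes, in [0, 100]."""
    wm_data = wm.data
    if wm_data.shape != stripes.data.shape:
        raise FormatError("WM mask and stripe mask shapes differ")
    n_wm = int(wm_data.sum())
    if n_wm == 0:
        raise DegenerateInputError("WM mask is empty; ghost fraction undefined")
    return 100.0 * int((wm_data & stripes.data).sum()) / n_wm
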