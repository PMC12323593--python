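"""Object detection: segmentation, signal-to-background, exposure merging.

Each channel raster is thresholded against a robust background estimate
(image median + ``k_mad`` robust standard deviations, where the robust sd is
1.4826x the median absolute deviation), labeled into connected components and
size-filtered.  Every object carries a signal-to-background ratio (SBR = mean
object intensity / median non-object intensity) and a saturation flag.

The FLAPS substrate channel is acquired at several exposure times so that
both dim and bright staining fall inside the camera's dynamic range.  The
per-exposure detections are consolidated by :func:`merge_exposures`: objects
within 0.5 um (or with intersecting masks) are treated as one physical
object, represented by its longest *unsaturated* exposure — or the shortest
exposure when every detection is clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateBackgroundError, InputError
from .io_formats import ChannelImage, FieldOfView

__all__ = [
    "SegmentationParams",
    "DetectedObject",
    "segment_channel",
    "signal_background_ratio",
    "estimate_background",
    "merge_exposures",
    "detect_field",
]

#: Fraction of the camera maximum above which a pixel counts as clipped.
SATURATION_LEVEL = 0.98
#: Fraction of an object's pixels that must be clipped to flag saturation.
SATURATION_PIXEL_FRAC = 0.01
#: Centroid distance (um) under which detections at different exposures merge.
MERGE_DISTANCE_UM = 0.5
_MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholding and size-filter settings for one channel.

    ``robust_background`` thresholds at median + k_mad * (1.4826 * MAD);
    ``otsu`` uses Otsu's method on the full raster.
    """

    threshold_method: str = "robust_background"
    k_mad: float = 5.0
    min_area_um2: float = 0.05
    max_area_um2: float = 20.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.threshold_method not in ("robust_background", "otsu"):
            raise InputError("threshold_method must be 'robust_background' or 'otsu'")
        if self.k_mad < 0:
            raise InputError("k_mad must be non-negative")
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise InputError("require 0 < min_area_um2 < max_area_um2")
        if self.connectivity not in (4, 8):
            raise InputError("connectivity must be 4 or 8")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(2, 2 if self.connectivity == 8 else 1)


@dataclass(frozen=True)
class DetectedObject:
    """One connected component detected in one channel raster.

    ``pixels`` are sorted flat (row-major) indices into the FOV raster; the
    boolean ``mask`` raster is materialized on demand.
    """

    object_id: int
    channel_role: str
    exposure_ms: float
    pixels: np.ndarray
    shape: tuple[int, int]
    area_um2: float
    centroid: tuple[float, float]
    mean_intensity: float
    sbr: float
    saturated: bool

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, bool)
        m.flat[self.pixels] = True
        return m

    @property
    def area_px(self) -> int:
        return int(self.pixels.size)


def estimate_background(
    img: ChannelImage, object_masks: Sequence[np.ndarray] | np.ndarray | None
) -> float:
    """Median intensity outside the union of object masks.

    Requires at least 100 background pixels; raises
    :class:`~flaps_phenotyper.errors.DegenerateBackgroundError` otherwise.
    """
    union = np.zeros(img.shape, bool)
    if object_masks is not None:
        if isinstance(object_masks, np.ndarray) and object_masks.dtype == bool:
            union = object_masks
        else:
            for m in object_masks:
                union |= m
    outside = img.raster[~union]
    if outside.size < 100:
        raise DegenerateBackgroundError(
            f"only {outside.size} background pixels remain; need >=100"
        )
    return float(np.median(outside))


def signal_background_ratio(
    obj_mask: np.ndarray, img: ChannelImage, background_estimate: float
) -> float:
    """Mean intensity inside the mask divided by the background estimate."""
    if background_estimate <= 0:
        raise DegenerateBackgroundError("background estimate must be positive")
    vals = img.raster[obj_mask]
    if vals.size == 0:
        raise DegenerateBackgroundError("empty object mask")
    return float(vals.mean() / background_estimate)


def _threshold(raster: np.ndarray, params: SegmentationParams) -> float:
    if params.threshold_method == "otsu":
        from skimage.filters import threshold_otsu

        return float(threshold_otsu(raster))
    # a strided subsample is ample for robust location/scale on ~1e5 pixels
    sample = raster.ravel()[:: 3 if raster.size > 30_000 else 1]
    med = float(np.median(sample))
    mad = float(np.median(np.abs(sample - med)))
    return med + params.k_mad * _MAD_TO_SD * mad


def segment_channel(
    img: ChannelImage, params: SegmentationParams, pixel_size_um: float
) -> list[DetectedObject]:
    """Detect objects in one channel as size-filtered connected components.

    Deterministic and idempotent for a fixed raster and parameters.  SBR is
    computed against the median intensity outside all above-threshold pixels
    (pre size-filter).
    """
    raster = np.asarray(img.raster, dtype=float)
    if raster.size == 0:
        raise InputError("cannot segment a zero-size raster")
    thr = _threshold(raster, params)
    binary = raster > thr
    if not binary.any():
        return []
    labels, n_labels = ndimage.label(binary, structure=params.structure)
    flat_labels = labels.ravel()
    px_area = pixel_size_um**2
    areas_px = np.bincount(flat_labels, minlength=n_labels + 1)

    try:
        background = estimate_background(img, binary)
    except DegenerateBackgroundError:
        # nearly everything is signal; fall back to the global median
        background = float(np.median(raster))
        if background <= 0:
            raise

    idx = np.flatnonzero(flat_labels)
    labs = flat_labels[idx]
    order = np.argsort(labs, kind="stable")
    idx = idx[order]
    splits = np.cumsum(areas_px[1:])[:-1]
    pixel_groups = np.split(idx, splits)

    sums = np.bincount(flat_labels, weights=raster.ravel(), minlength=n_labels + 1)[1:]
    clipped_labels = flat_labels[raster.ravel() >= SATURATION_LEVEL * img.bit_max]
    n_clipped = np.bincount(clipped_labels, minlength=n_labels + 1)[1:]

    width = raster.shape[1]
    objects: list[DetectedObject] = []
    oid = 0
    for lab in range(1, n_labels + 1):
        npx = int(areas_px[lab])
        area_um2 = npx * px_area
        if not params.min_area_um2 <= area_um2 <= params.max_area_um2:
            continue
        pix = np.sort(pixel_groups[lab - 1])
        rows, cols = pix // width, pix % width
        mean = float(sums[lab - 1] / npx)
        objects.append(
            DetectedObject(
                object_id=oid,
                channel_role=img.channel_role,
                exposure_ms=img.exposure_ms,
                pixels=pix,
                shape=raster.shape,
                area_um2=float(area_um2),
                centroid=(float(rows.mean()), float(cols.mean())),
                mean_intensity=mean,
                sbr=mean / background if background > 0 else np.inf,
                saturated=bool(n_clipped[lab - 1] >= SATURATION_PIXEL_FRAC * npx),
            )
        )
        oid += 1
    return objects


def _masks_intersect(a: DetectedObject, b: DetectedObject) -> bool:
    return np.intersect1d(a.pixels, b.pixels, assume_unique=True).size > 0


def merge_exposures(
    per_exposure_objects: Mapping[float, Sequence[DetectedObject]] | Sequence[Sequence[DetectedObject]],
    pixel_size_um: float,
) -> list[DetectedObject]:
    """Consolidate FLAPS detections across exposure times.

    Detections whose centroids fall within 0.5 um of each other, or whose
    masks intersect, are considered one physical object.  The retained
    representative comes from the longest unsaturated exposure; when every
    member is saturated, the shortest exposure is used (its statistics are
    least clipped).  Each physical object appears exactly once in the output.
    """
    if isinstance(per_exposure_objects, Mapping):
        groups: Iterable[Sequence[DetectedObject]] = per_exposure_objects.values()
    else:
        groups = per_exposure_objects
    all_objs = [o for grp in groups for o in grp]
    if not all_objs:
        return []
    n = len(all_objs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    cents = np.array([o.centroid for o in all_objs]) * pixel_size_um
    width = all_objs[0].shape[1]
    rows = [o.pixels // width for o in all_objs]
    cols = [o.pixels % width for o in all_objs]
    bbox = np.array(
        [(r.min(), r.max(), c.min(), c.max()) for r, c in zip(rows, cols)], dtype=float
    )
    exposures = np.array([o.exposure_ms for o in all_objs])
    diff = cents[:, None, :] - cents[None, :, :]
    close = np.hypot(diff[..., 0], diff[..., 1]) < MERGE_DISTANCE_UM
    touch = (
        (bbox[:, None, 0] <= bbox[None, :, 1])
        & (bbox[None, :, 0] <= bbox[:, None, 1])
        & (bbox[:, None, 2] <= bbox[None, :, 3])
        & (bbox[None, :, 2] <= bbox[:, None, 3])
    )
    cross_exposure = exposures[:, None] != exposures[None, :]
    candidates = np.argwhere(np.triu(cross_exposure & (close | touch), k=1))
    for i, j in candidates:
        if close[i, j] or _masks_intersect(all_objs[i], all_objs[j]):
            union(int(i), int(j))

    clusters: dict[int, list[DetectedObject]] = {}
    for i, obj in enumerate(all_objs):
        clusters.setdefault(find(i), []).append(obj)

    merged: list[DetectedObject] = []
    for members in clusters.values():
        unsat = [o for o in members if not o.saturated]
        if unsat:
            rep = max(unsat, key=lambda o: o.exposure_ms)
        else:
            rep = min(members, key=lambda o: o.exposure_ms)
        merged.append(rep)
    merged.sort(key=lambda o: (o.centroid[0], o.centroid[1]))
    return [replace(o, object_id=i) for i, o in enumerate(merged)]


def detect_field(
    fov: FieldOfView,
    params: SegmentationParams | Mapping[str, SegmentationParams],
    crosstalk_coeff: float = 0.0,
) -> dict[str, list[DetectedObject]]:
    """Segment every channel of a field of view.

    Returns a dict with keys ``DAPI``, ``FLAPS`` (merged over exposures) and,
    when present, ``FISH`` and ``AUTO``.  ``params`` may be a single
    :class:`SegmentationParams` applied everywhere or a per-role mapping.
    ``crosstalk_coeff`` > 0 subtracts that multiple of the FISH raster
    (exposure-scaled) from each FLAPS raster before segmentation, countering
    red-to-green bleed-through that otherwise yields false FLAPS positives.
    """

    def p(role: str) -> SegmentationParams:
        if isinstance(params, SegmentationParams):
            return params
        return params[role]

    px = fov.meta.pixel_size_um
    out: dict[str, list[DetectedObject]] = {
        "DAPI": segment_channel(fov.dapi, p("DAPI"), px)
    }
    fish = fov.fish
    per_exposure: dict[float, list[DetectedObject]] = {}
    for ch in fov.flaps:
        if crosstalk_coeff > 0 and fish is not None:
            bleed = crosstalk_coeff * fish.raster.astype(float) * (
                ch.exposure_ms / fish.exposure_ms
            )
            corrected = np.clip(ch.raster.astype(float) - bleed, 0, ch.bit_max)
            ch = ChannelImage(corrected, "FLAPS", ch.exposure_ms, ch.bit_max)
        per_exposure[ch.exposure_ms] = segment_channel(ch, p("FLAPS"), px)
    out["FLAPS"] = merge_exposures(per_exposure, px)
    if fish is not None:
        out["FISH"] = segment_channel(fish, p("FISH"), px)
    if fov.auto is not None:
        out["AUTO"] = segment_channel(fov.auto, p("AUTO"), px)
    return out
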