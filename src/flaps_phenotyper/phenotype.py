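"""Cell classification by multi-channel co-localization, and quantification.

A cell is a DAPI-defined object.  It is called FLAPS-positive when some
detected FLAPS object covers at least ``min_overlap`` (default 30%) of the
DAPI mask *and* that FLAPS object's signal-to-background ratio is at least
``min_sbr`` (default 1); both thresholds are inclusive.  FISH and Auto
positivity use the same overlap rule.  The phenotype truth table is:

===================  ==========================================
phenotype            evidence
===================  ==========================================
cyanobacterium       FLAPS-positive AND Auto-positive
flaps_fish_cell      FLAPS-positive AND FISH-positive (not Auto)
flaps_cell           FLAPS-positive only
unstained_cell       not FLAPS-positive (any FISH/Auto state)
background_particle  FLAPS object with no DAPI co-localization
===================  ==========================================

Autofluorescent cells positive in DAPI, FLAPS and Auto are counted as
cyanobacteria and excluded from both numerator and denominator of the
selfish-uptake fraction; FLAPS objects lacking a nucleic-acid counterstain
are background noise and excluded from all cell counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .detect import DetectedObject
from .errors import DegenerateObjectError, InputError
from .io_formats import AcquisitionMeta

__all__ = [
    "Thresholds",
    "CellRecord",
    "SampleQuant",
    "overlap_fraction",
    "classify_cell",
    "reject_background",
    "classify_field",
    "quantify_sample",
    "timecourse_summary",
    "records_to_frame",
    "summary_to_frame",
    "CELL_TABLE_COLUMNS",
]

PHENOTYPES = (
    "unstained_cell",
    "flaps_cell",
    "flaps_fish_cell",
    "cyanobacterium",
    "background_particle",
)

CELL_TABLE_COLUMNS = [
    "cell_id",
    "sample_id",
    "fov_id",
    "phenotype",
    "flaps_overlap",
    "flaps_sbr",
    "fish_overlap",
    "auto_positive",
    "probe",
    "area_um2",
    "centroid_row",
    "centroid_col",
]


@dataclass(frozen=True)
class Thresholds:
    """Inclusive co-localization thresholds for positive identification."""

    min_overlap: float = 0.30
    min_sbr: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_overlap <= 1.0:
            raise InputError("min_overlap must lie in (0, 1]")
        if self.min_sbr <= 0:
            raise InputError("min_sbr must be positive")


@dataclass(frozen=True)
class CellRecord:
    """Classification evidence and phenotype for one DAPI-defined cell.

    ``flaps_overlap`` is the largest fraction of the DAPI mask covered by any
    single FLAPS object and ``flaps_sbr`` the signal-to-background ratio of
    that same object (NaN when no FLAPS object touches the cell).
    """

    cell_id: str
    sample_id: str
    fov_id: str
    phenotype: str
    flaps_overlap: float
    flaps_sbr: float
    fish_overlap: float
    auto_positive: bool
    probe: str | None = None
    area_um2: float = float("nan")
    centroid_row: float = float("nan")
    centroid_col: float = float("nan")
    dapi_object: DetectedObject | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise InputError(f"unknown phenotype {self.phenotype!r}")
        for name in ("flaps_overlap", "fish_overlap"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise InputError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SampleQuant:
    """Sample-level quantification pooled over fields of view."""

    sample_id: str
    timepoint_h: float
    n_fov: int
    total_cells: int
    cells_per_L: float
    n_flaps_pos: int
    frac_flaps_pos: float
    n_fish_flaps_pos: dict[str, int]
    n_cyanobacteria: int
    n_background_particles: int
    ci95_frac: tuple[float, float]


def overlap_fraction(reference_mask: np.ndarray, query_mask: np.ndarray) -> float:
    """|reference AND query| / |reference| for two boolean masks.

    The reference is the DAPI object (cell-centric denominator).
    """
    ref = np.asarray(reference_mask, bool)
    qry = np.asarray(query_mask, bool)
    if ref.shape != qry.shape:
        raise InputError("masks must share one shape")
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise DegenerateObjectError("reference mask is empty")
    return float((ref & qry).sum() / n_ref)


def _overlap_pixels(ref_pixels: np.ndarray, qry_pixels: np.ndarray) -> float:
    if ref_pixels.size == 0:
        raise DegenerateObjectError("reference object has no pixels")
    inter = np.intersect1d(ref_pixels, qry_pixels, assume_unique=True).size
    return inter / ref_pixels.size


def _decide(
    flaps_overlap: float,
    flaps_sbr: float,
    fish_overlap: float,
    auto_overlap: float,
    th: Thresholds,
) -> tuple[str, bool]:
    """One shared truth table for both classification code paths."""
    flaps_pos = flaps_overlap >= th.min_overlap and (
        not np.isnan(flaps_sbr) and flaps_sbr >= th.min_sbr
    )
    fish_pos = fish_overlap >= th.min_overlap
    auto_pos = auto_overlap >= th.min_overlap
    if flaps_pos and auto_pos:
        return "cyanobacterium", auto_pos
    if flaps_pos and fish_pos:
        return "flaps_fish_cell", auto_pos
    if flaps_pos:
        return "flaps_cell", auto_pos
    return "unstained_cell", auto_pos


def classify_cell(
    dapi_obj: DetectedObject,
    flaps_objs: Sequence[DetectedObject],
    fish_objs: Sequence[DetectedObject] = (),
    auto_objs: Sequence[DetectedObject] = (),
    th: Thresholds = Thresholds(),
    cell_id: str = "cell_0",
    sample_id: str = "sample",
    fov_id: str = "fov_0",
    probe: str | None = None,
) -> CellRecord:
    """Classify one DAPI-defined cell against detected channel objects.

    The FLAPS call uses the single best-overlapping FLAPS object: overlap must
    reach ``th.min_overlap`` and that object's SBR must reach ``th.min_sbr``
    (both inclusive).
    """
    if dapi_obj.pixels.size == 0:
        raise DegenerateObjectError("DAPI object has no pixels")

    def best(objs: Sequence[DetectedObject]) -> tuple[float, DetectedObject | None]:
        best_ov, best_obj = 0.0, None
        for o in objs:
            ov = _overlap_pixels(dapi_obj.pixels, o.pixels)
            if ov > best_ov:
                best_ov, best_obj = ov, o
        return best_ov, best_obj

    flaps_ov, flaps_obj = best(flaps_objs)
    fish_ov, _ = best(fish_objs)
    auto_ov, _ = best(auto_objs)
    flaps_sbr = flaps_obj.sbr if flaps_obj is not None else float("nan")
    phenotype, auto_pos = _decide(flaps_ov, flaps_sbr, fish_ov, auto_ov, th)
    return CellRecord(
        cell_id=cell_id,
        sample_id=sample_id,
        fov_id=fov_id,
        phenotype=phenotype,
        flaps_overlap=flaps_ov,
        flaps_sbr=flaps_sbr,
        fish_overlap=fish_ov,
        auto_positive=auto_pos,
        probe=probe,
        area_um2=dapi_obj.area_um2,
        centroid_row=dapi_obj.centroid[0],
        centroid_col=dapi_obj.centroid[1],
        dapi_object=dapi_obj,
    )


def reject_background(
    flaps_objs: Sequence[DetectedObject],
    dapi_objs: Sequence[DetectedObject],
    th: Thresholds = Thresholds(),
) -> list[DetectedObject]:
    """FLAPS objects lacking DAPI co-localization (substrate background).

    A FLAPS object is background when its overlap with *every* DAPI object
    (DAPI-mask denominator) stays below ``th.min_overlap``; such objects are
    excluded from all cell counts.
    """
    out = []
    for fo in flaps_objs:
        if all(
            _overlap_pixels(d.pixels, fo.pixels) < th.min_overlap for d in dapi_objs
        ):
            out.append(fo)
    return out


def _paint_labels(objs: Sequence[DetectedObject], shape: tuple[int, int]) -> np.ndarray:
    lab = np.zeros(shape, np.int32)
    for k, o in enumerate(objs, start=1):
        lab.flat[o.pixels] = k
    return lab


def classify_field(
    detections: Mapping[str, Sequence[DetectedObject]],
    th: Thresholds = Thresholds(),
    sample_id: str = "sample",
    fov_id: str = "fov_0",
    probe: str | None = None,
) -> tuple[list[CellRecord], list[DetectedObject]]:
    """Classify every DAPI object of one field of view.

    Equivalent to calling :func:`classify_cell` per cell (overlaps are
    computed through label rasters for speed) plus :func:`reject_background`
    for the FLAPS-only particles.  Returns ``(cell_records, particles)``.
    """
    dapi_objs = list(detections.get("DAPI", ()))
    flaps_objs = list(detections.get("FLAPS", ()))
    fish_objs = list(detections.get("FISH", ()))
    auto_objs = list(detections.get("AUTO", ()))
    if not dapi_objs:
        return [], reject_background(flaps_objs, [], th)
    shape = dapi_objs[0].shape
    flaps_lab = _paint_labels(flaps_objs, shape)
    fish_lab = _paint_labels(fish_objs, shape)
    auto_lab = _paint_labels(auto_objs, shape)
    flaps_sbrs = np.array([o.sbr for o in flaps_objs])

    def best_overlap(lab: np.ndarray, pixels: np.ndarray, n: int) -> tuple[float, int]:
        if n == 0:
            return 0.0, -1
        hits = lab.flat[pixels]
        counts = np.bincount(hits, minlength=n + 1)[1:]
        k = int(counts.argmax())
        return float(counts[k] / pixels.size), k

    records = []
    for i, dobj in enumerate(dapi_objs):
        f_ov, f_k = best_overlap(flaps_lab, dobj.pixels, len(flaps_objs))
        fish_ov, _ = best_overlap(fish_lab, dobj.pixels, len(fish_objs))
        auto_ov, _ = best_overlap(auto_lab, dobj.pixels, len(auto_objs))
        f_sbr = float(flaps_sbrs[f_k]) if f_ov > 0 else float("nan")
        phenotype, auto_pos = _decide(f_ov, f_sbr, fish_ov, auto_ov, th)
        records.append(
            CellRecord(
                cell_id=f"{fov_id}_cell_{i}",
                sample_id=sample_id,
                fov_id=fov_id,
                phenotype=phenotype,
                flaps_overlap=f_ov,
                flaps_sbr=f_sbr,
                fish_overlap=fish_ov,
                auto_positive=auto_pos,
                probe=probe,
                area_um2=dobj.area_um2,
                centroid_row=dobj.centroid[0],
                centroid_col=dobj.centroid[1],
                dapi_object=dobj,
            )
        )

    # background rejection through the DAPI label raster (same rule as
    # reject_background, vectorized)
    dapi_lab = _paint_labels(dapi_objs, shape)
    dapi_areas = np.array([o.pixels.size for o in dapi_objs], dtype=float)
    particles = []
    for fo in flaps_objs:
        hits = dapi_lab.flat[fo.pixels]
        counts = np.bincount(hits, minlength=len(dapi_objs) + 1)[1:]
        if not np.any(counts / dapi_areas >= th.min_overlap):
            particles.append(fo)
    return records, particles


def quantify_sample(
    records: Sequence[CellRecord],
    meta: AcquisitionMeta,
    n_fov: int | None = None,
    n_background_particles: int = 0,
) -> SampleQuant:
    """Pool per-cell records of one sample into abundances and fractions.

    ``total_cells`` counts every DAPI object (cyanobacteria included,
    background particles excluded).  The selfish fraction is
    ``n_flaps_pos / (total_cells - n_cyanobacteria)`` with a Wilson 95%
    interval; cyanobacteria are excluded from numerator and denominator.
    ``cells_per_L`` scales mean cells per FOV by the filter-to-FOV area ratio
    over the filtered volume.
    """
    records = list(records)
    fovs = {r.fov_id for r in records}
    if n_fov is None:
        n_fov = len(fovs)
    if n_fov < 1:
        raise InputError("quantification requires at least one field of view")
    cells = [r for r in records if r.phenotype != "background_particle"]
    total = len(cells)
    n_cyano = sum(1 for r in cells if r.phenotype == "cyanobacterium")
    n_flaps = sum(1 for r in cells if r.phenotype in ("flaps_cell", "flaps_fish_cell"))
    per_probe: dict[str, int] = {}
    for r in cells:
        if r.phenotype == "flaps_fish_cell":
            key = r.probe if r.probe else "unlabeled"
            per_probe[key] = per_probe.get(key, 0) + 1
    denom = total - n_cyano
    if denom > 0:
        frac = n_flaps / denom
        lo, hi = proportion_confint(n_flaps, denom, alpha=0.05, method="wilson")
        ci = (float(lo), float(hi))
    else:
        frac, ci = float("nan"), (float("nan"), float("nan"))
    cells_per_L = (
        (total / n_fov)
        * (meta.filter_area_um2 / meta.fov_area_um2)
        / meta.volume_filtered_L
    )
    return SampleQuant(
        sample_id=meta.sample_id,
        timepoint_h=meta.timepoint_h,
        n_fov=n_fov,
        total_cells=total,
        cells_per_L=float(cells_per_L),
        n_flaps_pos=n_flaps,
        frac_flaps_pos=float(frac),
        n_fish_flaps_pos=per_probe,
        n_cyanobacteria=n_cyano,
        n_background_particles=n_background_particles,
        ci95_frac=ci,
    )


def timecourse_summary(
    quants: Sequence[SampleQuant],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-interval changes along a timecourse, with dilution flags.

    A drop in the FLAPS-positive fraction coinciding with an increase in cell
    numbers over the same interval flags possible fluorescence dilution by
    cell division (substrate split between daughter cells) rather than a true
    loss of selfish activity.
    """
    quants = list(quants)
    if len(quants) < 2:
        raise InputError("a timecourse needs at least two timepoints")
    times = np.array([q.timepoint_h for q in quants])
    if not np.all(np.diff(times) > 0):
        raise InputError("timepoints must be strictly increasing")
    fracs = np.array([q.frac_flaps_pos for q in quants])
    counts = np.array([q.cells_per_L for q in quants])
    d_frac = np.diff(fracs)
    d_counts = np.diff(counts)
    flags = (d_frac < 0) & (d_counts > 0)
    df = pd.DataFrame(
        {
            "t_start_h": times[:-1],
            "t_end_h": times[1:],
            "frac_flaps_pos_start": fracs[:-1],
            "frac_flaps_pos_end": fracs[1:],
            "delta_frac_flaps_pos": d_frac,
            "delta_cells_per_L": d_counts,
            "dilution_flag": flags,
        }
    )
    return df, flags


# ---------------------------------------------------------------------------
# tabular serialization helpers (used by io_formats)


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": r.cell_id,
            "sample_id": r.sample_id,
            "fov_id": r.fov_id,
            "phenotype": r.phenotype,
            "flaps_overlap": r.flaps_overlap,
            "flaps_sbr": r.flaps_sbr,
            "fish_overlap": r.fish_overlap,
            "auto_positive": r.auto_positive,
            "probe": r.probe if r.probe is not None else "",
            "area_um2": r.area_um2,
            "centroid_row": r.centroid_row,
            "centroid_col": r.centroid_col,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def summary_to_frame(quant: SampleQuant) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": quant.sample_id,
                "timepoint_h": quant.timepoint_h,
                "n_fov": quant.n_fov,
                "total_cells": quant.total_cells,
                "cells_per_L": quant.cells_per_L,
                "n_flaps_pos": quant.n_flaps_pos,
                "frac_flaps_pos": quant.frac_flaps_pos,
                "n_fish_flaps_pos": json.dumps(quant.n_fish_flaps_pos, sort_keys=True),
                "n_cyanobacteria": quant.n_cyanobacteria,
                "n_background_particles": quant.n_background_particles,
                "ci95_low": quant.ci95_frac[0],
                "ci95_high": quant.ci95_frac[1],
            }
        ]
    )
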