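"""Readers and writers for all external data formats.

One microscope stage position ("field of view", FOV) is represented as a set
of pre-registered channel rasters — a DAPI nucleic-acid counterstain, the
FLAPS substrate channel acquired at several exposure times (10/35/140 ms by
default, to span the dynamic range of staining intensities), and optional
FISH and autofluorescence (Auto) channels — plus acquisition metadata needed
to express counts per litre of filtered sample.

Chromatograms, cytometry event tables and the tabular outputs of the
phenotyping pipeline are plain delimited text; cytometry additionally accepts
binary FCS 3.0/3.1 via :mod:`flaps_phenotyper._fcs`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import _fcs
from .cytometry import EventTable
from .errors import ConfigurationError, FormatError, RegistrationError
from .hydrolysis import Chromatogram

__all__ = [
    "ChannelImage",
    "AcquisitionMeta",
    "FieldOfView",
    "load_field_of_view",
    "read_chromatogram",
    "read_event_table",
    "write_cell_table",
    "read_cell_table",
    "write_summary",
    "read_summary",
]

CHANNEL_ROLES = ("DAPI", "FLAPS", "FISH", "AUTO")


@dataclass(frozen=True)
class ChannelImage:
    """One channel raster of a field of view.

    ``raster`` is a 2-D non-negative intensity grid (0-based, row-major pixel
    coordinates); ``bit_max`` is the camera's maximum representable intensity
    and bounds every pixel.
    """

    raster: np.ndarray
    channel_role: str
    exposure_ms: float
    bit_max: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.raster)
        object.__setattr__(self, "raster", arr)
        if arr.ndim != 2 or arr.size == 0:
            raise FormatError("channel raster must be a non-empty 2-D array")
        if self.channel_role not in CHANNEL_ROLES:
            raise ConfigurationError(
                f"channel_role must be one of {CHANNEL_ROLES}, got {self.channel_role!r}"
            )
        if self.exposure_ms <= 0:
            raise ConfigurationError("exposure_ms must be positive")
        if self.bit_max <= 0:
            raise ConfigurationError("bit_max must be positive")
        if arr.min() < 0 or arr.max() > self.bit_max:
            raise FormatError("intensities must lie in [0, bit_max]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata linking pixel counts to environmental abundances.

    ``filter_area_um2`` is the effective filtration area of the polycarbonate
    filter; together with the FOV area and filtered volume it converts mean
    cells per FOV into cells per litre.
    """

    pixel_size_um: float
    fov_area_um2: float
    filter_area_um2: float
    volume_filtered_L: float
    sample_id: str = "sample"
    timepoint_h: float = 0.0

    def __post_init__(self) -> None:
        if min(self.pixel_size_um, self.fov_area_um2, self.filter_area_um2) <= 0:
            raise ConfigurationError("pixel size and areas must be positive")
        if self.volume_filtered_L <= 0:
            raise ConfigurationError("volume_filtered_L must be positive")
        if self.fov_area_um2 > self.filter_area_um2:
            raise ConfigurationError("fov_area_um2 cannot exceed filter_area_um2")
        if self.timepoint_h < 0:
            raise ConfigurationError("timepoint_h must be non-negative")


@dataclass(frozen=True)
class FieldOfView:
    """All channel rasters of one stage position plus acquisition metadata.

    Exactly one DAPI channel, at least one FLAPS exposure (strictly
    increasing, unique exposure times), optional FISH and AUTO channels; all
    rasters share one shape and that shape is consistent with the metadata's
    FOV area to within 1%.
    """

    channels: tuple[ChannelImage, ...]
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        channels = tuple(self.channels)
        object.__setattr__(self, "channels", channels)
        roles = [c.channel_role for c in channels]
        if roles.count("DAPI") != 1:
            raise ConfigurationError("a field of view requires exactly one DAPI channel")
        if roles.count("FLAPS") < 1:
            raise ConfigurationError("a field of view requires >=1 FLAPS exposure")
        if roles.count("FISH") > 1 or roles.count("AUTO") > 1:
            raise ConfigurationError("at most one FISH and one AUTO channel allowed")
        shapes = {c.shape for c in channels}
        if len(shapes) != 1:
            raise RegistrationError(f"channel rasters differ in shape: {sorted(shapes)}")
        exps = [c.exposure_ms for c in channels if c.channel_role == "FLAPS"]
        if sorted(set(exps)) != exps:
            raise ConfigurationError("FLAPS exposures must be strictly increasing and unique")
        shape = channels[0].shape
        area = shape[0] * shape[1] * self.meta.pixel_size_um**2
        if abs(area - self.meta.fov_area_um2) > 0.01 * self.meta.fov_area_um2:
            raise ConfigurationError(
                f"fov_area_um2 ({self.meta.fov_area_um2:.1f}) inconsistent with "
                f"raster {shape} at {self.meta.pixel_size_um} um/px ({area:.1f})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def dapi(self) -> ChannelImage:
        return next(c for c in self.channels if c.channel_role == "DAPI")

    @property
    def flaps(self) -> tuple[ChannelImage, ...]:
        return tuple(
            sorted(
                (c for c in self.channels if c.channel_role == "FLAPS"),
                key=lambda c: c.exposure_ms,
            )
        )

    def _optional(self, role: str) -> ChannelImage | None:
        return next((c for c in self.channels if c.channel_role == role), None)

    @property
    def fish(self) -> ChannelImage | None:
        return self._optional("FISH")

    @property
    def auto(self) -> ChannelImage | None:
        return self._optional("AUTO")


def load_field_of_view(
    image_paths: Sequence[str | Path],
    meta: AcquisitionMeta,
    channel_map: Sequence[Mapping],
) -> FieldOfView:
    """Load TIFF channel images into a validated :class:`FieldOfView`.

    ``channel_map`` is a sequence parallel to ``image_paths``; each entry is a
    mapping with keys ``role`` (DAPI/FLAPS/FISH/AUTO), ``exposure_ms``,
    ``bit_max`` and optionally ``page`` for multi-page TIFFs.  Intensities are
    loaded without rescaling.
    """
    if len(channel_map) != len(image_paths):
        raise ConfigurationError("channel_map must assign every image file a role")
    if sum(1 for m in channel_map if m.get("role") == "DAPI") != 1:
        raise ConfigurationError("channel_map must assign exactly one DAPI channel")
    channels = []
    for path, cmap in zip(image_paths, channel_map):
        try:
            arr = tifffile.imread(path)
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot read image {path}: {exc}") from exc
        if arr.ndim == 3:
            page = int(cmap.get("page", 0))
            arr = arr[page]
        channels.append(
            ChannelImage(
                raster=arr,
                channel_role=str(cmap["role"]),
                exposure_ms=float(cmap["exposure_ms"]),
                bit_max=int(cmap["bit_max"]),
            )
        )
    return FieldOfView(channels=tuple(channels), meta=meta)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse delimited table: {exc}") from exc


def read_chromatogram(path: str | Path, timepoint_h: float = 0.0) -> Chromatogram:
    """Read a 2-column (elution volume mL, fluorescence) delimited table.

    The first column must be strictly increasing and the second non-negative;
    a header row is required.  Violations raise
    :class:`~flaps_phenotyper.errors.FormatError` (via the Chromatogram
    invariants).
    """
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: chromatogram needs >=2 columns")
    return Chromatogram(
        elution_vol=df.iloc[:, 0].to_numpy(dtype=float),
        signal=df.iloc[:, 1].to_numpy(dtype=float),
        timepoint_h=timepoint_h,
    )


def read_event_table(
    path: str | Path,
    required_columns: Sequence[str] = ("FSC-H", "FL1-H"),
) -> EventTable:
    """Read cytometry events from FCS 3.x or a delimited table with header.

    Required columns are matched case-insensitively and renamed to their
    canonical spelling; a missing required column raises
    :class:`~flaps_phenotyper.errors.FormatError`.
    """
    if _fcs.is_fcs(path):
        df = _fcs.read_fcs(path)
    else:
        df = _read_delimited(path)
    lower = {str(c).strip().lower(): c for c in df.columns}
    rename = {}
    for want in required_columns:
        got = lower.get(want.lower())
        if got is None:
            raise FormatError(f"{path}: missing required column {want!r}")
        rename[got] = want
    # keep canonical SSC-H when present even if not required
    if "ssc-h" in lower and "SSC-H" not in required_columns:
        rename.setdefault(lower["ssc-h"], "SSC-H")
    return EventTable(data=df.rename(columns=rename))


# ---------------------------------------------------------------------------
# tabular pipeline outputs


def write_cell_table(records: Sequence, path: str | Path) -> None:
    """Write per-cell classification records as a delimited table.

    All records must share one ``sample_id``; the column order is stable so
    re-reading reproduces values exactly.
    """
    from .phenotype import records_to_frame  # local import: avoids a cycle

    records = list(records)
    if records and len({r.sample_id for r in records}) > 1:
        raise ConfigurationError("records in one cell table must share a sample_id")
    records_to_frame(records).to_csv(path, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read back a cell table written by :func:`write_cell_table`."""
    from .phenotype import CELL_TABLE_COLUMNS

    df = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: cell table lacks columns {missing}")
    return df


def write_summary(quant, path: str | Path) -> None:
    """Write one sample-level quantification as a one-row delimited table."""
    from .phenotype import summary_to_frame

    summary_to_frame(quant).to_csv(path, index=False)


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# field-of-view directory layout (one directory per stage position)


def write_field_of_view(fov: FieldOfView, dirpath: str | Path) -> None:
    """Write one FOV as single-page TIFFs plus a ``channel_map.yaml``."""
    import yaml

    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, ch in enumerate(fov.channels):
        name = f"{i:02d}_{ch.channel_role.lower()}_{int(round(ch.exposure_ms))}ms.tif"
        tifffile.imwrite(dirpath / name, np.asarray(ch.raster))
        entries.append(
            {
                "file": name,
                "role": ch.channel_role,
                "exposure_ms": float(ch.exposure_ms),
                "bit_max": int(ch.bit_max),
            }
        )
    meta = fov.meta
    doc = {
        "channels": entries,
        "meta": {
            "pixel_size_um": meta.pixel_size_um,
            "fov_area_um2": meta.fov_area_um2,
            "filter_area_um2": meta.filter_area_um2,
            "volume_filtered_L": meta.volume_filtered_L,
            "sample_id": meta.sample_id,
            "timepoint_h": meta.timepoint_h,
        },
    }
    with open(dirpath / "channel_map.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_field_of_view_dir(dirpath: str | Path) -> FieldOfView:
    """Load a FOV directory written by :func:`write_field_of_view`."""
    import yaml

    dirpath = Path(dirpath)
    map_path = dirpath / "channel_map.yaml"
    if not map_path.exists():
        raise ConfigurationError(f"{dirpath}: no channel_map.yaml found")
    with open(map_path) as fh:
        doc = yaml.safe_load(fh)
    meta = AcquisitionMeta(**doc["meta"])
    entries = doc["channels"]
    paths = [dirpath / e["file"] for e in entries]
    return load_field_of_view(paths, meta, entries)
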