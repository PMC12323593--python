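"""Ground-truthed synthetic data for the FLAPS phenotyping workflow.

Three generators, each deterministic under a fixed seed:

``simulate_field``
    Renders one multi-channel epifluorescence field of view.  Cells are
    random-orientation filled ellipses in the DAPI channel.  "Selfish" cells
    additionally carry a FLAPS deposit that is either a periplasmic *halo*
    band straddling the cell outline or *polar* caps at one or both cell
    ends — the two staining patterns seen by super-resolution imaging.
    Autofluorescent (cyanobacteria-like) cells light up in DAPI, FLAPS and
    AUTO; FISH-probe-positive cells light up in the FISH channel.  Non-cell
    background particles appear in FLAPS only (no DAPI), mimicking substrate
    adhering to particulate organic matter.  FLAPS deposits scale linearly
    with exposure time and clip ("saturate") at the camera maximum, and an
    optional FISH-to-FLAPS crosstalk term emulates red-channel bleed-through.

``simulate_chromatogram_series``
    A gel-permeation timecourse in which a stated fraction of the parent
    polysaccharide's mass moves into lower-molecular-weight product classes;
    total integrated signal is conserved exactly.

``simulate_event_table``
    A two-component log-normal FL1-H mixture (FLAPS-negative and
    FLAPS-positive events) with independent log-normal forward/side scatter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cytometry import EventTable
from .errors import ConfigurationError, PlacementError
from .hydrolysis import Chromatogram, MWCalibration
from .io_formats import AcquisitionMeta, ChannelImage, FieldOfView

__all__ = [
    "SimFieldConfig",
    "TruthObject",
    "GroundTruth",
    "simulate_field",
    "simulate_chromatogram_series",
    "simulate_event_table",
    "LogNormalLaw",
    "DEFAULT_CALIBRATION",
    "DEFAULT_CLASS_BOUNDS",
]

_STRUCT8 = np.ones((3, 3), bool)


def round_half_away(x: float) -> int:
    """Round half away from zero; used once per fraction so counts are exact."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class SimFieldConfig:
    """Parameters of one synthetic field of view.

    Intensity levels for DAPI/FISH/AUTO are deposit amplitudes in camera
    counts at that channel's (fixed) exposure; the FLAPS level is a rate in
    counts per ms so the three exposures scale linearly.  ``brightness_sigma``
    is the log-sd of a per-object brightness factor applied to all of an
    object's deposits.
    """

    n_cells: int = 100
    frac_selfish: float = 0.16
    frac_autofluorescent: float = 0.02
    frac_fish_positive: float = 0.5
    pattern_mix: tuple[float, float] = (0.5, 0.5)  # (halo, polar) among selfish
    cell_length_um: float = 1.6
    cell_width_um: float = 0.8
    shape: tuple[int, int] = (320, 320)
    pixel_size_um: float = 0.1
    bit_max: int = 4095
    dapi_level: float = 1500.0
    flaps_rate: float = 40.0  # counts per ms
    fish_level: float = 1200.0
    auto_level: float = 1000.0
    particle_rate: float = 10.0  # counts per ms
    background_mean: float = 100.0
    noise_sd: float = 0.0
    n_background_particles: int = 10
    crosstalk_coeff: float = 0.0
    brightness_sigma: float = 0.3
    flaps_exposures: tuple[float, ...] = (10.0, 35.0, 140.0)
    dapi_exposure_ms: float = 50.0
    fish_exposure_ms: float = 100.0
    auto_exposure_ms: float = 300.0
    include_fish_channel: bool = True
    include_auto_channel: bool = True
    filter_area_um2: float = 2.0e8
    volume_filtered_L: float = 0.01
    sample_id: str = "sim"
    timepoint_h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_selfish, self.frac_autofluorescent, self.frac_fish_positive)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigurationError("all proportions must lie in [0, 1]")
        if abs(sum(self.pattern_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.pattern_mix):
            raise ConfigurationError("pattern_mix must be non-negative and sum to 1")
        if self.n_cells < 0 or self.n_background_particles < 0:
            raise ConfigurationError("counts must be non-negative")
        if not 0.0 <= self.crosstalk_coeff < 1.0:
            raise ConfigurationError("crosstalk_coeff must lie in [0, 1)")
        if self.background_mean < 0 or self.noise_sd < 0:
            raise ConfigurationError("background_mean and noise_sd must be >= 0")
        if min(self.cell_length_um, self.cell_width_um, self.pixel_size_um) <= 0:
            raise ConfigurationError("lengths must be positive")
        if list(self.flaps_exposures) != sorted(set(self.flaps_exposures)):
            raise ConfigurationError("flaps_exposures must be strictly increasing")

    def meta(self) -> AcquisitionMeta:
        h, w = self.shape
        return AcquisitionMeta(
            pixel_size_um=self.pixel_size_um,
            fov_area_um2=h * w * self.pixel_size_um**2,
            filter_area_um2=self.filter_area_um2,
            volume_filtered_L=self.volume_filtered_L,
            sample_id=self.sample_id,
            timepoint_h=self.timepoint_h,
        )


@dataclass(frozen=True)
class TruthObject:
    """Per-object ground-truth record backing validation of the pipeline."""

    object_id: int
    kind: str  # "cell" | "particle"
    centroid: tuple[float, float]
    pixels: np.ndarray  # flat indices of the DAPI ellipse (cells) / disk (particles)
    is_selfish: bool
    is_autofluorescent: bool
    is_fish_positive: bool
    pattern: str  # "halo" | "polar" | "none"


@dataclass(frozen=True)
class GroundTruth:
    """All truth objects of one simulated field of view."""

    objects: tuple[TruthObject, ...]
    shape: tuple[int, int]

    def _count(self, pred) -> int:
        return sum(1 for o in self.objects if pred(o))

    @property
    def n_cells(self) -> int:
        return self._count(lambda o: o.kind == "cell")

    @property
    def n_selfish(self) -> int:
        return self._count(lambda o: o.is_selfish)

    @property
    def n_autofluorescent(self) -> int:
        return self._count(lambda o: o.is_autofluorescent)

    @property
    def n_fish_positive(self) -> int:
        return self._count(lambda o: o.is_fish_positive)

    @property
    def n_particles(self) -> int:
        return self._count(lambda o: o.kind == "particle")

    def to_frame(self) -> pd.DataFrame:
        """Tabular truth (one row per object; pixel masks are not serialized)."""
        return pd.DataFrame(
            [
                {
                    "object_id": o.object_id,
                    "kind": o.kind,
                    "centroid_row": o.centroid[0],
                    "centroid_col": o.centroid[1],
                    "n_pixels": int(o.pixels.size),
                    "is_selfish": o.is_selfish,
                    "is_autofluorescent": o.is_autofluorescent,
                    "is_fish_positive": o.is_fish_positive,
                    "pattern": o.pattern,
                }
                for o in self.objects
            ]
        )


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipse_patch(a_px: float, b_px: float, angle: float) -> tuple[np.ndarray, int]:
    """Boolean patch of a rotated filled ellipse; returns (patch, half-extent)."""
    e = int(math.ceil(max(a_px, b_px))) + 3
    yy, xx = np.mgrid[-e : e + 1, -e : e + 1]
    xr = xx * math.cos(angle) + yy * math.sin(angle)
    yr = -xx * math.sin(angle) + yy * math.cos(angle)
    return (xr / a_px) ** 2 + (yr / b_px) ** 2 <= 1.0, e


def _disk_patch(r_px: int) -> tuple[np.ndarray, int]:
    e = r_px + 3
    yy, xx = np.mgrid[-e : e + 1, -e : e + 1]
    return xx**2 + yy**2 <= r_px**2, e


#: Caps start this fraction of the semi-major axis from the cell centre; a
#: single-end cap then still covers ~40% of the DAPI ellipse, comfortably
#: above the 30% co-localization threshold.
POLAR_CAP_FRAC = 0.15


def _polar_caps(
    footprint: np.ndarray, a_px: float, angle: float, ends: int, sign: int
) -> np.ndarray:
    """Cap deposit at one or both ellipse ends, on the dilated outline."""
    e = footprint.shape[0] // 2
    yy, xx = np.mgrid[-e : e + 1, -e : e + 1]
    xr = xx * math.cos(angle) + yy * math.sin(angle)
    if ends == 2:
        return footprint & (np.abs(xr) >= POLAR_CAP_FRAC * a_px)
    return footprint & (sign * xr >= POLAR_CAP_FRAC * a_px)


def _halo_band(patches: "_PatchSet") -> np.ndarray:
    """Periplasmic band: 1 px outside to 2 px inside the cell outline.

    The band overlaps the DAPI ellipse by well over the 30% co-localization
    threshold, as a diffraction-limited periplasmic ring does in real images.
    """
    core = ndimage.binary_erosion(patches.patch, _STRUCT8, iterations=2)
    return patches.footprint & ~core


@dataclass(frozen=True)
class _PatchSet:
    """A deposit geometry with its dilations, precomputed once per shape."""

    patch: np.ndarray  # the object proper (DAPI ellipse / particle disk)
    footprint: np.ndarray  # rendered extent incl. 1-px halo: dilate(patch, 1)
    probe: np.ndarray  # footprint + 1-px separation gap: dilate(patch, 2)
    half: int
    angle: float = 0.0


@dataclass
class _Placed:
    row: int
    col: int
    patches: _PatchSet

    @property
    def angle(self) -> float:
        return self.patches.angle

    @property
    def patch(self) -> np.ndarray:
        return self.patches.patch

    def flat_pixels(self, mask: np.ndarray, width: int) -> np.ndarray:
        pr, pc = np.nonzero(mask)
        half = self.patches.half
        return (pr + self.row - half) * width + (pc + self.col - half) * 1


def _place_objects(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    make_patches,
    occupied: np.ndarray,
    max_tries: int = 300,
) -> list[_Placed]:
    """Rejection-sample non-overlapping, non-adjacent object footprints.

    Footprints (the rendered extent plus a one-pixel gap) never touch, so
    every rendered object stays its own 8-connected component.
    """
    h, w = shape
    placed: list[_Placed] = []
    for _ in range(n):
        ps = make_patches()
        half = ps.half
        for _try in range(max_tries):
            row = int(rng.integers(half + 1, h - half - 1))
            col = int(rng.integers(half + 1, w - half - 1))
            sl = (slice(row - half, row + half + 1), slice(col - half, col + half + 1))
            if not (occupied[sl] & ps.probe).any():
                occupied[sl] |= ps.footprint
                placed.append(_Placed(row, col, ps))
                break
        else:
            raise PlacementError(
                f"could not place object {len(placed) + 1}/{n} after {max_tries} tries; "
                "reduce density or enlarge the field"
            )
    return placed


# ---------------------------------------------------------------------------
# field-of-view generator


def simulate_field(config: SimFieldConfig) -> tuple[FieldOfView, GroundTruth]:
    """Render one synthetic multi-channel field of view with ground truth.

    Deterministic: identical config (including seed) gives bit-identical
    rasters.  Counts derived from fractions use round-half-away-from-zero
    applied once, so truth counts are exact
    (``n_selfish = round(frac_selfish * n_cells)`` etc.).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    a_px = config.cell_length_um / 2 / config.pixel_size_um
    b_px = config.cell_width_um / 2 / config.pixel_size_um

    occupied = np.zeros(config.shape, bool)

    # geometry is cached per quantized orientation / radius; dilations are by
    # far the costliest part of placement
    n_bins = 24
    cell_cache: dict[int, _PatchSet] = {}
    halo_cache: dict[int, np.ndarray] = {}
    disk_cache: dict[int, _PatchSet] = {}

    def _build(patch: np.ndarray, half: int, angle: float = 0.0) -> _PatchSet:
        foot = ndimage.binary_dilation(patch, _STRUCT8)
        return _PatchSet(patch, foot, ndimage.binary_dilation(foot, _STRUCT8), half, angle)

    def make_cell() -> _PatchSet:
        angle = float(rng.uniform(0.0, math.pi))
        b = min(int(angle / math.pi * n_bins), n_bins - 1)
        if b not in cell_cache:
            aq = (b + 0.5) * math.pi / n_bins
            cell_cache[b] = _build(*_ellipse_patch(a_px, b_px, aq), angle=aq)
        return cell_cache[b]

    cells = _place_objects(rng, config.shape, config.n_cells, make_cell, occupied)

    def make_particle() -> _PatchSet:
        r = int(rng.integers(3, 6))
        if r not in disk_cache:
            disk_cache[r] = _build(*_disk_patch(r))
        return disk_cache[r]

    particles = _place_objects(
        rng, config.shape, config.n_background_particles, make_particle, occupied
    )

    # deterministic truth assignment: counts fixed by rounding, identities by
    # placement order (positions are i.i.d., so there is no spatial bias)
    n_auto = round_half_away(config.frac_autofluorescent * config.n_cells)
    n_selfish = round_half_away(config.frac_selfish * config.n_cells)
    if n_auto + n_selfish > config.n_cells:
        raise ConfigurationError("frac_selfish + frac_autofluorescent exceed the cell pool")
    n_fish = round_half_away(config.frac_fish_positive * n_selfish)
    n_halo = round_half_away(config.pattern_mix[0] * n_selfish)

    is_auto = [i < n_auto for i in range(config.n_cells)]
    is_selfish = [n_auto <= i < n_auto + n_selfish for i in range(config.n_cells)]
    is_fish = [n_auto <= i < n_auto + n_fish for i in range(config.n_cells)]
    patterns = [
        ("halo" if (i - n_auto) < n_halo else "polar") if is_selfish[i] else "none"
        for i in range(config.n_cells)
    ]

    bf = np.exp(config.brightness_sigma * rng.standard_normal(len(cells) + len(particles)))

    dapi = np.zeros(config.shape)
    flaps_rate_img = np.zeros(config.shape)
    fish_img = np.zeros(config.shape)
    auto_img = np.zeros(config.shape)

    truth: list[TruthObject] = []
    for i, cell in enumerate(cells):
        pix = cell.flat_pixels(cell.patch, w)
        dapi.flat[pix] += config.dapi_level * bf[i]
        if is_auto[i]:
            # pigment autofluorescence bleeds into the substrate channel too
            flaps_rate_img.flat[pix] += config.flaps_rate * bf[i]
            auto_img.flat[pix] += config.auto_level * bf[i]
        if is_selfish[i]:
            if patterns[i] == "halo":
                key = id(cell.patches)
                if key not in halo_cache:
                    halo_cache[key] = _halo_band(cell.patches)
                deposit = halo_cache[key]
            else:
                ends = int(rng.integers(1, 3))
                sign = 1 if rng.random() < 0.5 else -1
                deposit = _polar_caps(cell.patches.footprint, a_px, cell.angle, ends, sign)
            flaps_rate_img.flat[cell.flat_pixels(deposit, w)] += config.flaps_rate * bf[i]
        if is_fish[i]:
            fish_img.flat[pix] += config.fish_level * bf[i]
        truth.append(
            TruthObject(
                object_id=i,
                kind="cell",
                centroid=(cell.row, cell.col),
                pixels=np.sort(pix),
                is_selfish=is_selfish[i],
                is_autofluorescent=is_auto[i],
                is_fish_positive=is_fish[i],
                pattern=patterns[i],
            )
        )
    for j, part in enumerate(particles):
        pix = part.flat_pixels(part.patch, w)
        flaps_rate_img.flat[pix] += config.particle_rate * bf[len(cells) + j]
        truth.append(
            TruthObject(
                object_id=config.n_cells + j,
                kind="particle",
                centroid=(part.row, part.col),
                pixels=np.sort(pix),
                is_selfish=False,
                is_autofluorescent=False,
                is_fish_positive=False,
                pattern="none",
            )
        )

    def finalize(img: np.ndarray) -> np.ndarray:
        out = img + config.background_mean
        if config.noise_sd > 0:
            out = out + config.noise_sd * rng.standard_normal(img.shape, dtype=np.float32)
        return np.clip(np.round(out), 0, config.bit_max).astype(np.uint16)

    channels = [
        ChannelImage(finalize(dapi), "DAPI", config.dapi_exposure_ms, config.bit_max)
    ]
    fish_rate_img = fish_img / config.fish_exposure_ms
    for exp_ms in config.flaps_exposures:
        raw = (flaps_rate_img + config.crosstalk_coeff * fish_rate_img) * exp_ms
        channels.append(ChannelImage(finalize(raw), "FLAPS", exp_ms, config.bit_max))
    if config.include_fish_channel:
        channels.append(
            ChannelImage(finalize(fish_img), "FISH", config.fish_exposure_ms, config.bit_max)
        )
    if config.include_auto_channel:
        channels.append(
            ChannelImage(finalize(auto_img), "AUTO", config.auto_exposure_ms, config.bit_max)
        )

    fov = FieldOfView(channels=tuple(channels), meta=config.meta())
    return fov, GroundTruth(objects=tuple(truth), shape=config.shape)


# ---------------------------------------------------------------------------
# chromatogram timecourse generator

#: Default GPC calibration: log10(MW) = 7 - 0.2 * elution_vol(mL), so a
#: 100 kDa parent elutes at 10 mL and 1 kDa products around 20 mL.
DEFAULT_CALIBRATION = MWCalibration(slope=-0.2, intercept=7.0, standards=())

#: Default descending MW class bounds (Da); class 0 holds the parent.
DEFAULT_CLASS_BOUNDS = (1.0e6, 3.0e4, 3.0e3, 3.0e2, 3.0e1)


def simulate_chromatogram_series(
    parent_mw: float = 1.0e5,
    product_profile: Sequence[float] = (0.5, 0.3, 0.2),
    transfer_fracs: Sequence[float] = (0.0, 0.1, 0.3, 0.5),
    timepoints_h: Sequence[float] = (0.0, 24.0, 48.0, 72.0),
    peak_width: float = 0.3,
    seed: int = 0,
    noise_sd: float = 0.0,
    calibration: MWCalibration = DEFAULT_CALIBRATION,
    class_bounds: Sequence[float] = DEFAULT_CLASS_BOUNDS,
    elution_grid: np.ndarray | None = None,
    total_signal: float = 1000.0,
) -> list[Chromatogram]:
    """Gel-permeation timecourse with a known parent-to-product mass transfer.

    At timepoint *t* a fraction ``transfer_fracs[t]`` of the parent peak's
    mass is redistributed to Gaussian product peaks located at the geometric
    mean MW of each product class, split according to ``product_profile``.
    Every peak is normalized to unit trapezoidal integral on the grid, so
    total integrated signal is conserved exactly (noise-free).
    """
    fracs = np.asarray(transfer_fracs, dtype=float)
    times = np.asarray(timepoints_h, dtype=float)
    if fracs.size != times.size:
        raise ConfigurationError("transfer_fracs and timepoints_h must align")
    if np.any(fracs < 0) or np.any(fracs > 1):
        raise ConfigurationError("transfer fractions must lie in [0, 1]")
    if np.any(np.diff(fracs) < 0):
        raise ConfigurationError("transfer_fracs must be non-decreasing over time")
    profile = np.asarray(product_profile, dtype=float)
    if np.any(profile < 0) or abs(profile.sum() - 1.0) > 1e-9:
        raise ConfigurationError("product_profile must be non-negative and sum to 1")
    bounds = np.asarray(class_bounds, dtype=float)
    n_product = bounds.size - 2  # classes below the parent class
    if profile.size != n_product:
        raise ConfigurationError(
            f"product_profile needs one entry per product class ({n_product})"
        )
    if not (bounds[0] >= parent_mw > bounds[1]):
        raise ConfigurationError("parent_mw must lie inside the first class")

    if elution_grid is None:
        elution_grid = np.linspace(4.0, 30.0, 600)
    product_mws = np.sqrt(bounds[1:-1] * bounds[2:])
    centers = [calibration.elution_of_mw(parent_mw)] + [
        calibration.elution_of_mw(m) for m in product_mws
    ]

    def unit_peak(center: float) -> np.ndarray:
        shape = np.exp(-0.5 * ((elution_grid - center) / peak_width) ** 2)
        return shape / np.trapezoid(shape, elution_grid)

    peaks = np.array([unit_peak(c) for c in centers])
    rng = np.random.default_rng(seed)
    out = []
    for t, f in zip(times, fracs):
        masses = np.concatenate(([1.0 - f], f * profile))
        signal = total_signal * masses @ peaks
        if noise_sd > 0:
            signal = np.clip(signal + rng.normal(0.0, noise_sd, signal.shape), 0.0, None)
        out.append(Chromatogram(elution_vol=elution_grid, signal=signal, timepoint_h=float(t)))
    return out


# ---------------------------------------------------------------------------
# cytometry event generator


@dataclass(frozen=True)
class LogNormalLaw:
    """Log-normal component: ``median * exp(sigma * Z)``."""

    median: float
    sigma: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median * np.exp(self.sigma * rng.standard_normal(n))


def simulate_event_table(
    n_events: int = 10_000,
    frac_positive: float = 0.3,
    neg_fl1_law: LogNormalLaw = LogNormalLaw(100.0, 0.5),
    pos_fl1_law: LogNormalLaw = LogNormalLaw(5000.0, 0.5),
    fsc_law: LogNormalLaw = LogNormalLaw(50_000.0, 0.4),
    ssc_law: LogNormalLaw = LogNormalLaw(30_000.0, 0.5),
    seed: int = 0,
) -> tuple[EventTable, np.ndarray]:
    """Simulate one cytometry acquisition with planted positive events.

    Exactly ``round(frac_positive * n_events)`` events are drawn from the
    positive FL1-H component (deterministic rounding); scatter is independent
    of the positive flag.  Returns the event table and the boolean truth flag
    per event (in table order).
    """
    if n_events <= 0:
        raise ConfigurationError("n_events must be positive")
    if not 0.0 <= frac_positive <= 1.0:
        raise ConfigurationError("frac_positive must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = round_half_away(frac_positive * n_events)
    flags = np.zeros(n_events, bool)
    flags[:n_pos] = True
    flags = flags[rng.permutation(n_events)]
    fl1 = np.where(
        flags, pos_fl1_law.sample(rng, n_events), neg_fl1_law.sample(rng, n_events)
    )
    table = EventTable(
        data=pd.DataFrame(
            {
                "FSC-H": fsc_law.sample(rng, n_events),
                "SSC-H": ssc_law.sample(rng, n_events),
                "FL1-H": fl1,
            }
        )
    )
    return table, flags
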