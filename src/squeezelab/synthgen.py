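"""Synthetic-microscopy generator with known ground truth.

Emulates the five data kinds the analysis pipeline consumes:

1. cells transiting a four-stage constriction device (per-region snapshots,
   ellipse cells deformed by projected-area conservation);
2. fixed-cell immunofluorescence plates (DAPI + actin + marker channels,
   two-compartment intensities, multiplicative flatfield / additive darkfield
   illumination bias);
3. calcium time-lapse traces with region-dependent influx amplitude;
4. dextran exchange across an endothelial barrier with known permeability;
5. brightfield tumorsphere series with linearly growing area.

Every generator takes an explicit integer seed and is bit-reproducible.
The defaults encode the study conditions: a 30/20/10/5 µm channel cascade,
15 µm melanoma-like cells, partial post-channel shape retention, calcium
influx concentrated in the two narrowest channels, 2-minute frames over
90 minutes for the permeability assay, and 7-day sphere growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .core import (
    BASELINE,
    DeviceGeometry,
    ImageStack,
    InvalidGeometryError,
)

__all__ = [
    "DeviceGeometry",
    "SqueezeModelParams",
    "MarkerSpec",
    "PlateSpec",
    "generate_transit_sequence",
    "generate_if_plate",
    "sample_feature_table",
    "generate_calcium_series",
    "generate_permeability_series",
    "generate_tumorsphere_series",
    "make_flatfield",
    "permeability_solution",
    "DEFAULT_REGION_AMPLITUDES",
]


class InvalidSpecError(ValueError):
    """Raised when generator parameters are physically meaningless."""


# --------------------------------------------------------------------------
# transit / squeeze model
# --------------------------------------------------------------------------

#: Post-channel retention fractions rho per channel width.  With the default
#: 15 µm baseline diameter these reproduce the retained median deformation
#: levels the device produces downstream of the 10 µm and 5 µm channels
#: (about +29% and +52%); channels wider than the cells leave no deformation
#: to retain.
DEFAULT_RETENTION = {30.0: 0.0, 20.0: 0.0, 10.0: 0.58, 5.0: 0.26}


@dataclass
class SqueezeModelParams:
    """Parameters of the synthetic squeeze model (houses the true D0)."""

    baseline_diameter_mean: float = 15.0  # µm
    baseline_diameter_sd: float = 1.0  # µm
    retention_fraction: float | Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_RETENTION)
    )
    cell_intensity: float = 1000.0
    background_level: float = 100.0
    photon_noise_scale: float = 1.0  # Gaussian sd = scale * sqrt(signal)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_diameter_mean <= 0:
            raise InvalidSpecError("baseline diameter must be positive")
        rhos = (
            [self.retention_fraction]
            if np.isscalar(self.retention_fraction)
            else list(self.retention_fraction.values())
        )
        for rho in rhos:
            if not 0.0 <= rho <= 1.0:
                raise InvalidSpecError("retention_fraction must lie in [0, 1]")

    def rho(self, width: float) -> float:
        if np.isscalar(self.retention_fraction):
            return float(self.retention_fraction)
        return float(self.retention_fraction[float(width)])


def squeeze_axes(d0: float, width: float) -> tuple[float, float]:
    """(major, minor) axes of a cell inside a channel of the given width.

    Projected-area conservation of the ellipse: when the channel is narrower
    than the cell, the minor axis clamps to the channel width and the major
    axis grows to D0^2 / w; otherwise the cell is an undeformed circle.
    """
    if width >= d0:
        return d0, d0
    return d0 * d0 / width, width


def relaxed_axes(d0: float, width: float, rho: float) -> tuple[float, float]:
    """(major, minor) axes after exiting a channel, with retention rho.

    rho = 0 recovers the circle; rho = 1 retains the full in-channel
    elongation.  The minor axis keeps the projected area equal to the
    baseline circle.
    """
    if width >= d0:
        return d0, d0
    major = d0 * (1.0 + rho * (d0 / width - 1.0))
    return major, d0 * d0 / major


def _render_ellipse(
    frame: np.ndarray,
    cy: float,
    cx: float,
    major_px: float,
    minor_px: float,
    intensity: float,
) -> None:
    rr, cc = draw_ellipse(
        cy, cx, minor_px / 2.0, major_px / 2.0, shape=frame.shape
    )
    frame[rr, cc] += intensity


def generate_transit_sequence(
    geometry: DeviceGeometry,
    params: SqueezeModelParams,
    n_cells: int,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render per-region snapshots of cells transiting the device.

    One frame per region (baseline field first), mimicking flow-interrupted
    imaging at each device location: every cell appears once per frame, in
    its own flow lane, at a random position inside the region's flow-axis
    interval.  Frame f covers only its region; the stack metadata records
    each frame's region label and x offset so global coordinates recover as
    ``x_global = x_local + offset``.

    Returns the stack and a tidy ground-truth table with one row per
    cell x region carrying the true axes, DI and centroid.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(params.seed)
    px = geometry.pixel_size

    intervals = geometry.region_intervals
    regions = list(intervals)  # BASELINE first

    if n_cells == 0:
        empty = ImageStack(
            np.zeros((0, 1, 1, 1), dtype=np.float32),
            pixel_size=px,
            channel_names=("fluor",),
            metadata={"frame_regions": [], "frame_x_offset_um": []},
        )
        return empty, pd.DataFrame(
            columns=[
                "cell_id", "region", "d0_um", "major_um", "minor_um",
                "di", "x_um", "y_um",
            ]
        )

    d0 = rng.normal(params.baseline_diameter_mean, params.baseline_diameter_sd, n_cells)
    d0 = np.clip(d0, 0.2 * params.baseline_diameter_mean, None)

    # one lane per cell; lane tall enough for the fattest undeformed cell
    lane_um = float(np.max(d0)) + 12.0
    height_px = int(math.ceil(n_cells * lane_um / px))
    rows = []
    frames = []
    offsets = []
    for region in regions:
        x0, x1 = intervals[region]
        width_px = int(math.ceil((x1 - x0) / px))
        frame = np.full((height_px, width_px), params.background_level, dtype=np.float64)
        w = geometry.width_of(region)
        for i in range(n_cells):
            if region == BASELINE or w == float("inf"):
                major, minor = d0[i], d0[i]
            elif region.startswith("CC"):
                major, minor = squeeze_axes(d0[i], w)
            else:
                major, minor = relaxed_axes(d0[i], w, params.rho(w))
            margin = major / 2.0 + px
            lo, hi = x0 + margin, x1 - margin
            cx_um = rng.uniform(lo, hi) if hi > lo else (x0 + x1) / 2.0
            cy_um = (i + 0.5) * lane_um
            _render_ellipse(
                frame,
                cy_um / px,
                (cx_um - x0) / px,
                major / px,
                minor / px,
                params.cell_intensity,
            )
            rows.append(
                dict(
                    cell_id=i,
                    region=region,
                    d0_um=d0[i],
                    major_um=major,
                    minor_um=minor,
                    di=major / d0[i],
                    x_um=cx_um,
                    y_um=cy_um,
                )
            )
        if params.photon_noise_scale > 0:
            frame += rng.normal(0.0, params.photon_noise_scale * np.sqrt(frame))
        frames.append(np.clip(frame, 0, None).astype(np.float32))
        offsets.append(x0)

    stack = ImageStack(
        np.stack(frames)[:, np.newaxis],
        pixel_size=px,
        channel_names=("fluor",),
        metadata={
            "frame_regions": regions,
            "frame_x_offset_um": offsets,
            "seed": params.seed,
        },
    )
    return stack, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# immunofluorescence plates
# --------------------------------------------------------------------------


@dataclass
class MarkerSpec:
    """Ground-truth intensity model of one IF marker.

    ``effect_size`` multiplies the treated-condition means (both
    compartments unless a per-compartment override is given).
    """

    name: str
    nuclear_mean: float = 400.0
    cyto_mean: float = 200.0
    effect_size: float = 1.0
    nuclear_effect: float | None = None
    cyto_effect: float | None = None

    def __post_init__(self) -> None:
        if self.nuclear_mean < 0 or self.cyto_mean < 0:
            raise InvalidSpecError("marker intensities must be >= 0")
        for e in (self.effect_size, self.nuclear_effect, self.cyto_effect):
            if e is not None and e < 0:
                raise InvalidSpecError("effect size must be >= 0")

    def means(self, condition: str) -> tuple[float, float]:
        if condition == "control":
            return self.nuclear_mean, self.cyto_mean
        en = self.nuclear_effect if self.nuclear_effect is not None else self.effect_size
        ec = self.cyto_effect if self.cyto_effect is not None else self.effect_size
        return self.nuclear_mean * en, self.cyto_mean * ec


@dataclass
class PlateSpec:
    """Layout and statistical model of a synthetic IF plate.

    Half the wells are labelled ``control``, half ``squeeze``; cells are
    non-overlapping disks (nucleus inside cell body).  The observed image is
    ``truth * flatfield + darkfield + noise``.  ``cell_cv`` is the
    cell-to-cell lognormal coefficient of variation of marker intensities,
    the dominant biological variability the group statistics see.
    """

    n_wells: int = 8
    cells_per_well: int = 25
    markers: tuple[MarkerSpec, ...] = field(
        default_factory=lambda: (MarkerSpec("marker",),)
    )
    timepoints: tuple[float, ...] = (4.0,)
    image_size: int = 512
    pixel_size: float = 0.65  # µm/px, 20x air objective
    cell_radius_mean: float = 11.0  # µm
    cell_radius_sd: float = 1.0
    nucleus_radius_mean: float = 5.5  # µm
    nucleus_radius_sd: float = 0.5
    dapi_nuclear_mean: float = 800.0
    actin_cyto_mean: float = 600.0
    actin_nuclear_mean: float = 250.0
    cell_cv: float = 0.2
    read_noise_sd: float = 8.0
    photon_noise_scale: float = 0.5
    flatfield_corner_factor: float = 0.75  # corner/centre vignetting ratio
    darkfield_level: float = 5.0
    seed: int = 0
    noise_seed: int | None = None  # separate noise stream (default: tied to seed)

    def __post_init__(self) -> None:
        if self.n_wells < 1 or self.cells_per_well < 0:
            raise InvalidSpecError("need >= 1 well and >= 0 cells per well")
        for m in self.markers:
            if m.effect_size < 0:
                raise InvalidSpecError("effect size must be >= 0")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return ("DAPI", "actin") + tuple(m.name for m in self.markers)

    def well_condition(self, well: int) -> str:
        return "control" if well < self.n_wells // 2 or self.n_wells == 1 else "squeeze"


def make_flatfield(shape: tuple[int, int], corner_factor: float) -> np.ndarray:
    """Smooth radial vignette, normalized to mean 1.

    ``corner_factor`` is the ratio of the corner to the centre of the
    un-normalized field (0 < factor <= 1).
    """
    if not 0 < corner_factor <= 1:
        raise InvalidSpecError("corner_factor must be in (0, 1]")
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r2 = ((yy - cy) / cy) ** 2 + ((xx - cx) / cx) ** 2
    field = 1.0 - (1.0 - corner_factor) * r2 / 2.0  # r2 = 2 at corners
    return field / field.mean()


def _place_disks(
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    size: int,
    max_tries: int = 2000,
) -> np.ndarray:
    """Non-overlapping disk centres via rejection sampling; (n, 2) in px."""
    centres: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for i in range(n):
        r = radii[i]
        for _ in range(max_tries):
            cy = rng.uniform(r + 1, size - r - 1)
            cx = rng.uniform(r + 1, size - r - 1)
            if all(
                (cy - py) ** 2 + (cx - px_) ** 2 > (r + pr + 1) ** 2
                for (py, px_), pr in zip(centres, placed_r)
            ):
                centres.append((cy, cx))
                placed_r.append(r)
                break
        else:
            raise InvalidSpecError(
                "could not place non-overlapping cells; reduce cells_per_well"
            )
    return np.array(centres).reshape(n, 2)


def sample_feature_table(
    spec: PlateSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the ground-truth single-cell table without rendering images.

    One row per cell x timepoint with the per-marker compartment means the
    imaging pipeline would ideally measure (true condition means times a
    lognormal per-cell factor).  ``generate_if_plate`` uses these same draws
    as rendering truth.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.cell_cv**2))
    rows = []
    for tp in spec.timepoints:
        for well in range(spec.n_wells):
            condition = spec.well_condition(well)
            for i in range(spec.cells_per_well):
                row = dict(
                    cell_id=f"t{tp:g}_w{well}_c{i}",
                    well=well,
                    condition=condition,
                    timepoint=tp,
                )
                for m in spec.markers:
                    nuc, cyt = m.means(condition)
                    f = rng.lognormal(-0.5 * sigma**2, sigma)
                    row[f"nucleus_mean_{m.name}"] = nuc * f
                    row[f"cytoplasm_mean_{m.name}"] = cyt * f
                rows.append(row)
    return pd.DataFrame(rows)


def generate_if_plate(
    spec: PlateSpec,
) -> tuple[dict[int, ImageStack], pd.DataFrame]:
    """Render one multi-channel image per well plus the ground-truth table.

    Only the first timepoint in ``spec.timepoints`` is rendered (rendering
    scales linearly and the statistics stack consumes tables, not pixels);
    the returned table covers the rendered timepoint only.
    """
    rng = np.random.default_rng(spec.seed)
    noise_rng = (
        rng if spec.noise_seed is None else np.random.default_rng(spec.noise_seed)
    )
    tp_spec = replace(spec, timepoints=(spec.timepoints[0],))
    truth = sample_feature_table(tp_spec, rng)
    flat = make_flatfield((spec.image_size, spec.image_size), spec.flatfield_corner_factor)
    dark = np.full((spec.image_size, spec.image_size), spec.darkfield_level)

    wells: dict[int, ImageStack] = {}
    extra_rows = []
    for well in range(spec.n_wells):
        sub = truth[truth.well == well].reset_index(drop=True)
        n = len(sub)
        cell_r = np.clip(
            rng.normal(spec.cell_radius_mean, spec.cell_radius_sd, n), 3.0, None
        )
        nuc_r = np.clip(
            rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_sd, n),
            1.5,
            cell_r - 1.0,
        )
        centres = _place_disks(rng, n, cell_r / spec.pixel_size, spec.image_size)
        chans = []
        for ch in spec.channel_names:
            chans.append(np.zeros((spec.image_size, spec.image_size)))
        for i in range(n):
            cy, cx = centres[i]
            rr_c, cc_c = draw_disk(
                (cy, cx), cell_r[i] / spec.pixel_size, shape=(spec.image_size,) * 2
            )
            rr_n, cc_n = draw_disk(
                (cy, cx), nuc_r[i] / spec.pixel_size, shape=(spec.image_size,) * 2
            )
            # DAPI: nuclear only; actin: whole body with dimmer nucleus
            chans[0][rr_n, cc_n] = spec.dapi_nuclear_mean
            chans[1][rr_c, cc_c] = spec.actin_cyto_mean
            chans[1][rr_n, cc_n] = spec.actin_nuclear_mean
            for j, m in enumerate(spec.markers):
                chans[2 + j][rr_c, cc_c] = sub.loc[i, f"cytoplasm_mean_{m.name}"]
                chans[2 + j][rr_n, cc_n] = sub.loc[i, f"nucleus_mean_{m.name}"]
            extra_rows.append(
                dict(
                    cell_id=sub.loc[i, "cell_id"],
                    y_um=cy * spec.pixel_size,
                    x_um=cx * spec.pixel_size,
                    cell_radius_um=cell_r[i],
                    nucleus_radius_um=nuc_r[i],
                )
            )
        observed = []
        for truth_img in chans:
            img = truth_img * flat + dark
            noise = noise_rng.normal(0.0, spec.read_noise_sd, img.shape)
            if spec.photon_noise_scale > 0:
                noise += noise_rng.normal(0.0, 1.0, img.shape) * (
                    spec.photon_noise_scale * np.sqrt(np.clip(truth_img, 0, None))
                )
            observed.append(np.clip(img + noise, 0, None).astype(np.float32))
        wells[well] = ImageStack(
            np.stack(observed)[np.newaxis],
            pixel_size=spec.pixel_size,
            channel_names=spec.channel_names,
            metadata={"well": well, "condition": spec.well_condition(well),
                      "seed": spec.seed},
        )
    geom = pd.DataFrame(extra_rows)
    truth = truth.merge(geom, on="cell_id")
    return wells, truth


# --------------------------------------------------------------------------
# calcium traces
# --------------------------------------------------------------------------

#: Influx gains per device region: calcium entry concentrated in the two
#: narrowest constrictions, partially decayed in the chambers downstream.
DEFAULT_REGION_AMPLITUDES = {
    "CC_30": 1.0, "RC_30": 1.0, "CC_20": 1.05, "RC_20": 1.0,
    "CC_10": 1.4, "RC_10": 1.2, "CC_5": 1.8, "RC_5": 1.4,
}


def generate_calcium_series(
    baseline: float = 100.0,
    region_amplitudes: Mapping[str, float] | None = None,
    noise_sd: float = 1.0,
    n_cells: int = 20,
    frames_per_region: int = 5,
    baseline_frames: int = 10,
    frame_interval_s: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-cell calcium traces: flat baseline, then ``baseline * amplitude``
    inside each successive region.

    Returns a tidy trace table (cell_id, frame, time_s, region, intensity)
    and the true fold change per region (= the amplitude).
    """
    if baseline <= 0:
        raise InvalidSpecError("baseline must be positive")
    if region_amplitudes is None:
        region_amplitudes = dict(DEFAULT_REGION_AMPLITUDES)
    for region, amp in region_amplitudes.items():
        if amp < 0:
            raise InvalidSpecError(f"negative amplitude for {region}")
    rng = np.random.default_rng(seed)

    segments = [(BASELINE, 1.0)] * baseline_frames
    for region, amp in region_amplitudes.items():
        segments += [(region, amp)] * frames_per_region

    rows = []
    for cell in range(n_cells):
        for frame, (region, amp) in enumerate(segments):
            val = baseline * amp
            if noise_sd > 0:
                val += rng.normal(0.0, noise_sd)
            rows.append(
                dict(
                    cell_id=cell,
                    frame=frame,
                    time_s=frame * frame_interval_s,
                    region=region,
                    intensity=val,
                )
            )
    truth = {region: float(amp) for region, amp in region_amplitudes.items()}
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------
# permeability time-lapse
# --------------------------------------------------------------------------


def permeability_solution(
    t_s: np.ndarray, p_cm_s: float, s_over_v: float, i_vessel: float
) -> np.ndarray:
    """Closed-form tissue intensity of the two-compartment exchange ODE
    dI/dt = P (S/V) (I_vessel - I), I(0) = 0."""
    k = p_cm_s * s_over_v  # 1/s
    return i_vessel * (1.0 - np.exp(-k * np.asarray(t_s, dtype=float)))


def generate_permeability_series(
    p_true: float = 1e-5,  # cm/s
    s_over_v: float = 2.0,  # 1/cm
    i_vessel: float = 1000.0,
    duration_min: float = 90.0,
    frame_interval_min: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tissue-compartment dye trace sampled every ``frame_interval_min``
    over ``duration_min`` (defaults: 2-minute frames over 90 minutes)."""
    if p_true < 0:
        raise InvalidSpecError("permeability must be >= 0")
    if frame_interval_min <= 0:
        raise InvalidSpecError("frame interval must be positive")
    if duration_min < 0:
        raise InvalidSpecError("duration must be >= 0")
    rng = np.random.default_rng(seed)
    t_min = np.arange(0.0, duration_min + 1e-9, frame_interval_min)
    intensity = permeability_solution(t_min * 60.0, p_true, s_over_v, i_vessel)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)
    return pd.DataFrame(
        dict(time_min=t_min, time_s=t_min * 60.0, intensity=intensity, roi_id="tissue")
    )


# --------------------------------------------------------------------------
# tumorsphere series
# --------------------------------------------------------------------------


def generate_tumorsphere_series(
    initial_area: float = 1000.0,  # µm²
    growth_rate: float = 500.0,  # µm²/day
    days: int = 7,
    noise_sd: float = 50.0,  # µm², area jitter of the rendered sphere
    pixel_size: float = 1.0,
    image_size: int | None = None,
    seed: int = 0,
) -> tuple[ImageStack, np.ndarray]:
    """Brightfield series of one sphere whose area grows linearly.

    Spheres render dark on a bright background.  Returns the stack (one
    frame per day, day 0 first) and the true (noise-free) areas in µm².
    """
    if initial_area <= 0:
        raise InvalidSpecError("initial_area must be positive")
    if days < 1:
        raise InvalidSpecError("need >= 1 day")
    day_idx = np.arange(days + 1)
    true_areas = initial_area + growth_rate * day_idx
    if np.any(true_areas <= 0):
        raise InvalidSpecError("growth_rate drives area non-positive")
    rng = np.random.default_rng(seed)
    max_r_px = math.sqrt(true_areas.max() / math.pi) / pixel_size
    if image_size is None:
        image_size = int(2 * max_r_px + 40)
    frames = []
    for a in true_areas:
        a_noisy = max(a + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0), 1.0)
        r_px = math.sqrt(a_noisy / math.pi) / pixel_size
        frame = np.full((image_size, image_size), 200.0)
        rr, cc = draw_disk((image_size / 2, image_size / 2), r_px, shape=frame.shape)
        frame[rr, cc] = 60.0
        frame += rng.normal(0.0, 2.0, frame.shape)
        frames.append(frame.astype(np.float32))
    stack = ImageStack(
        np.stack(frames)[:, np.newaxis],
        pixel_size=pixel_size,
        channel_names=("brightfield",),
        metadata={"days": list(map(int, day_idx)), "seed": seed},
    )
    return stack, true_areas
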