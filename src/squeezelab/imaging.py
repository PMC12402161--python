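"""Illumination correction, segmentation and per-cell feature extraction.

The segmentation chain mirrors a standard high-content workflow: nuclei from
minimum cross-entropy thresholding (MCET) of the DAPI channel, cell bodies by
marker-controlled propagation (watershed) seeded from the nuclear masks on
the actin channel, cytoplasm as the per-label set difference, and
second-moment ellipse morphometrics per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

from .core import ImageStack, LabelMask, as_float

__all__ = [
    "IlluminationModel",
    "estimate_illumination",
    "correct_illumination",
    "mce_threshold",
    "segment_nuclei",
    "segment_cells",
    "derive_cytoplasm",
    "segment_spheres",
    "extract_features",
    "ConstantImageError",
]


class ConstantImageError(ValueError):
    """Raised when a threshold is requested for a constant image."""


# --------------------------------------------------------------------------
# illumination
# --------------------------------------------------------------------------


@dataclass
class IlluminationModel:
    """Multiplicative flatfield (mean 1) plus additive darkfield.

    ``corrected = (observed - darkfield) / flatfield``.
    """

    flatfield: np.ndarray
    darkfield: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flatfield = as_float(self.flatfield)
        self.darkfield = as_float(self.darkfield)
        if self.flatfield.shape != self.darkfield.shape:
            raise ValueError("flatfield/darkfield shape mismatch")
        if np.any(self.flatfield <= 0):
            raise ValueError("flatfield must be strictly positive")

    @classmethod
    def identity(cls, shape: tuple[int, int], **meta) -> "IlluminationModel":
        return cls(np.ones(shape), np.zeros(shape), meta=dict(meta))


def _fit_quadratic_surface(
    img: np.ndarray, mask: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted least-squares 2D quadratic fit of ``img`` over ``mask``,
    evaluated on the full grid.  Captures the smooth radial vignettes
    typical of wide-field illumination while extrapolating cleanly to
    corners."""
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    y = (yy - h / 2) / h
    x = (xx - w / 2) / w
    design = np.stack([np.ones_like(y), y, x, y * y, x * x, y * x], axis=-1)
    a = design[mask].reshape(-1, 6)
    b = img[mask].ravel()
    if weights is not None:
        sw = np.sqrt(weights[mask].ravel())
        a = a * sw[:, None]
        b = b * sw
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    return design @ coef


def estimate_illumination(
    stack: ImageStack,
    smooth_sigma: float | None = None,
) -> dict[str, IlluminationModel]:
    """Estimate a per-channel illumination model from a frame ensemble.

    Darkfield: smoothed per-pixel median across frames (with sparse content
    the per-pixel median is the additive offset).  Flatfield: each frame is
    foreground-thresholded (MCET) and the per-pixel mean of foreground
    values is accumulated across frames; this conditional mean is
    proportional to the multiplicative field regardless of how unevenly
    objects cover the frame.  A quadratic surface is fitted to it (weighted
    by visit counts), clipped positive and normalized to mean 1.

    Fewer than 8 frames triggers a warning; an all-zero channel returns the
    identity model with a warning.
    """
    models: dict[str, IlluminationModel] = {}
    h, w = stack.frame_shape
    if smooth_sigma is None:
        smooth_sigma = max(min(h, w) / 24.0, 3.0)
    for name in stack.channel_names:
        frames = as_float(stack.channel(name))
        n = frames.shape[0]
        if n < 8:
            warnings.warn(
                f"channel {name!r}: only {n} frame(s); illumination estimate "
                "will be noisy (>= 8 recommended)",
                stacklevel=2,
            )
        if not np.any(frames):
            warnings.warn(f"channel {name!r} is all zero; identity model", stacklevel=2)
            models[name] = IlluminationModel.identity((h, w), channel=name, n_frames=n)
            continue
        if n == 1:
            dark = np.zeros((h, w))
        else:
            dark = ndi.gaussian_filter(np.median(frames, axis=0), smooth_sigma)
            dark = np.clip(dark, 0, None)
        # two passes: the second re-thresholds on vignette-corrected frames so
        # dim objects in dark corners are not dropped from the foreground
        flat = None
        for _ in range(2):
            fg_sum = np.zeros((h, w))
            fg_cnt = np.zeros((h, w))
            for frame in frames:
                ref = frame if flat is None else (frame - dark) / flat
                try:
                    thr = mce_threshold(ref)
                except ConstantImageError:
                    continue
                fg = ref > thr
                fg_sum[fg] += frame[fg]
                fg_cnt[fg] += 1
            valid = fg_cnt > 0
            content = np.zeros((h, w))
            content[valid] = fg_sum[valid] / fg_cnt[valid] - dark[valid]
            if not valid.any() or np.median(content[valid]) <= 0:
                flat = np.ones((h, w))
                break
            flat = _fit_quadratic_surface(content, valid, weights=fg_cnt)
            flat = np.clip(flat, 0.05 * flat.max(), None)
            flat = flat / flat.mean()
        models[name] = IlluminationModel(
            flatfield=flat, darkfield=dark, meta=dict(channel=name, n_frames=n)
        )
    return models


def correct_illumination(
    stack: ImageStack, models: dict[str, IlluminationModel]
) -> ImageStack:
    """Apply ``(observed - darkfield) / flatfield`` per channel, clamping
    negative residuals at zero (the clamp count is recorded in metadata)."""
    out = np.empty_like(stack.data, dtype=np.float64)
    clamped = {}
    for ci, name in enumerate(stack.channel_names):
        model = models[name]
        if model.flatfield.shape != stack.frame_shape:
            raise ValueError(
                f"channel {name!r}: model shape {model.flatfield.shape} does not "
                f"match frames {stack.frame_shape}"
            )
        corr = (as_float(stack.data[:, ci]) - model.darkfield) / model.flatfield
        clamped[name] = int(np.count_nonzero(corr < 0))
        out[:, ci] = np.clip(corr, 0, None)
    meta = dict(stack.metadata)
    meta["illumination_corrected"] = True
    meta["clamped_pixels"] = clamped
    return ImageStack(
        out, pixel_size=stack.pixel_size, channel_names=stack.channel_names,
        metadata=meta,
    )


# --------------------------------------------------------------------------
# minimum cross-entropy threshold
# --------------------------------------------------------------------------


def mce_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Minimum cross-entropy threshold of an image histogram.

    The objective for a cut between histogram bins is

        eta(t) = -m1_below(t) * log(mu_below(t)) - m1_above(t) * log(mu_above(t))

    where ``m1`` is the first moment (sum of gray * count) and ``mu`` the
    class mean of each side; the returned threshold is the bin edge that
    minimizes ``eta`` over all candidate cuts (exhaustive over the
    histogram).  Float images are histogrammed on ``n_bins`` bins over
    [min, max]; integer 8-bit images use their native 256 gray levels, so
    the result is exactly comparable with a per-gray-level search.
    """
    img = np.asarray(image)
    vmin, vmax = float(img.min()), float(img.max())
    if vmin == vmax:
        raise ConstantImageError("cannot threshold a constant image")
    if img.dtype == np.uint8:
        edges = np.arange(257, dtype=float)
    else:
        edges = np.linspace(vmin, vmax, n_bins + 1)
    counts, _ = np.histogram(img.ravel(), bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0

    m0 = counts.astype(float)
    m1 = m0 * centers
    c0_below = np.cumsum(m0)
    c1_below = np.cumsum(m1)
    c0_above = c0_below[-1] - c0_below
    c1_above = c1_below[-1] - c1_below

    # candidate cut k separates bins [0, k) from [k, n); need mass on both sides
    c0b = c0_below[:-1]
    c1b = c1_below[:-1]
    c0a = c0_above[:-1]
    c1a = c1_above[:-1]
    valid = (c0b > 0) & (c0a > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_b = np.where(c0b > 0, c1b / c0b, 1.0)
        mu_a = np.where(c0a > 0, c1a / c0a, 1.0)
        term_b = np.where((c1b > 0) & (mu_b > 0), -c1b * np.log(mu_b), 0.0)
        term_a = np.where((c1a > 0) & (mu_a > 0), -c1a * np.log(mu_a), 0.0)
    eta = term_b + term_a
    eta[~valid] = np.inf
    k = int(np.argmin(eta)) + 1  # cut index -> edge index
    return float(edges[k])


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------


def _drop_small(fg: np.ndarray, min_px: int) -> np.ndarray:
    """Remove connected components with fewer than ``min_px`` pixels."""
    labels = cc_label(fg)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_px
    keep[0] = False
    return keep[labels]


def _finalize_mask(
    labels: np.ndarray, pixel_size: float, provenance: str, flags: dict | None = None
) -> LabelMask:
    relabelled, _, _ = relabel_sequential(labels)
    return LabelMask(
        relabelled.astype(np.int32), pixel_size=pixel_size,
        provenance=provenance, flags=flags or {},
    )


def segment_nuclei(
    dapi: np.ndarray,
    pixel_size: float,
    min_area_um2: float = 20.0,
    split_touching: bool = False,
    min_seed_distance_um: float = 4.0,
) -> LabelMask:
    """Nuclei = connected components above the MCE threshold of the DAPI
    channel, small objects removed.

    With ``split_touching``, maxima of the foreground distance transform
    (at least ``min_seed_distance_um`` apart) seed a watershed that splits
    merged nuclei.
    """
    img = as_float(dapi)
    try:
        thr = mce_threshold(img)
    except ConstantImageError:
        return _finalize_mask(
            np.zeros(img.shape, dtype=np.int32), pixel_size, "nuclei:mcet"
        )
    fg = img > thr
    min_px = max(int(round(min_area_um2 / pixel_size**2)), 1)
    fg = _drop_small(fg, min_px)
    if not fg.any():
        return _finalize_mask(
            np.zeros(img.shape, dtype=np.int32), pixel_size, "nuclei:mcet"
        )
    if split_touching:
        dist = ndi.distance_transform_edt(fg)
        min_dist_px = max(int(round(min_seed_distance_um / pixel_size)), 1)
        peaks = peak_local_max(
            dist, min_distance=min_dist_px, labels=fg, exclude_border=False
        )
        seeds = np.zeros(img.shape, dtype=np.int32)
        seeds[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist, markers=seeds, mask=fg)
    else:
        labels = cc_label(fg)
    return _finalize_mask(labels, pixel_size, "nuclei:mcet")


def segment_cells(body: np.ndarray, nuclei: LabelMask) -> LabelMask:
    """Cell bodies by nucleus-seeded propagation over the MCE foreground of
    the body channel.

    Each foreground pixel joins the nucleus it reaches by watershed on the
    inverted body intensity; labels match their seeding nucleus.  Foreground
    components containing no nucleus are discarded; a nucleus falling
    outside the foreground keeps its own pixels as its cell and is flagged.
    """
    img = as_float(body)
    if img.shape != nuclei.data.shape:
        raise ValueError("body image and nucleus mask shapes differ")
    if nuclei.n_labels == 0:
        return _finalize_mask(
            np.zeros(img.shape, dtype=np.int32), nuclei.pixel_size, "cells:propagation"
        )
    try:
        thr = mce_threshold(img)
        fg = img > thr
    except ConstantImageError:
        fg = np.zeros(img.shape, dtype=bool)
    fg = fg | (nuclei.data > 0)
    labels = watershed(-img, markers=nuclei.data, mask=fg)
    flags = {}
    for lab in nuclei.labels:
        nuc_px = int(np.count_nonzero(nuclei.data == lab))
        cell_px = int(np.count_nonzero(labels == lab))
        if cell_px <= nuc_px:
            flags[int(lab)] = "nucleus outside body foreground"
    return LabelMask(
        labels.astype(np.int32), pixel_size=nuclei.pixel_size,
        provenance="cells:propagation", flags=flags,
    )


def derive_cytoplasm(cells: LabelMask, nuclei: LabelMask) -> LabelMask:
    """Cytoplasm label i = cell i minus nucleus i (exact set difference).

    Labels with empty cytoplasm (nucleus fills the cell) are flagged.
    """
    if cells.data.shape != nuclei.data.shape:
        raise ValueError("cell and nucleus masks have different shapes")
    cyto = np.where(nuclei.data > 0, 0, cells.data).astype(np.int32)
    flags = {}
    for lab in cells.labels:
        if not np.any(cyto == lab):
            flags[int(lab)] = "empty cytoplasm"
    return LabelMask(
        cyto, pixel_size=cells.pixel_size, provenance="cytoplasm:subtraction",
        flags=flags,
    )


def segment_spheres(
    image: np.ndarray, pixel_size: float, min_area_um2: float = 100.0
) -> tuple[LabelMask, pd.DataFrame]:
    """Detect tumorspheres in a brightfield frame.

    Thresholds with MCET and takes the minority intensity class as the blob
    (spheres image dark on a bright background or vice versa), fills holes
    and removes specks.  Returns the mask and a per-label area table (µm²).
    """
    img = as_float(image)
    try:
        thr = mce_threshold(img)
    except ConstantImageError:
        empty = _finalize_mask(np.zeros(img.shape, np.int32), pixel_size, "spheres")
        return empty, pd.DataFrame(columns=["label", "area_um2"])
    below = img < thr
    blob = below if below.mean() <= 0.5 else ~below
    blob = ndi.binary_fill_holes(blob)
    min_px = max(int(round(min_area_um2 / pixel_size**2)), 1)
    blob = _drop_small(blob, min_px)
    mask = _finalize_mask(cc_label(blob), pixel_size, "spheres:mcet")
    areas = pd.DataFrame(
        dict(
            label=mask.labels.astype(int),
            area_um2=[mask.area(l) * pixel_size**2 for l in mask.labels],
        )
    )
    return mask, areas


# --------------------------------------------------------------------------
# features
# --------------------------------------------------------------------------

_COMPARTMENTS = ("cell", "nucleus", "cytoplasm")


def extract_features(
    cells: LabelMask,
    nuclei: LabelMask,
    cytoplasm: LabelMask,
    channels: dict[str, np.ndarray],
    exclude_border: bool = True,
) -> pd.DataFrame:
    """One row per cell: morphology plus per-channel, per-compartment
    intensities.

    Morphology (area, centroid, second-moment ellipse axes, eccentricity) is
    measured on the cell mask and converted to µm via the mask pixel size.
    Compartment means of empty compartments are missing values with a QC
    flag.  Cells touching the image border are flagged and, by default,
    dropped.
    """
    px = cells.pixel_size
    masks = {"cell": cells, "nucleus": nuclei, "cytoplasm": cytoplasm}
    rows: dict[int, dict] = {}
    h, w = cells.data.shape
    for prop in regionprops(cells.data):
        lab = int(prop.label)
        minr, minc, maxr, maxc = prop.bbox
        rows[lab] = dict(
            label=lab,
            area_um2=prop.area * px**2,
            centroid_y_um=prop.centroid[0] * px,
            centroid_x_um=prop.centroid[1] * px,
            major_axis_um=prop.axis_major_length * px,
            minor_axis_um=prop.axis_minor_length * px,
            eccentricity=prop.eccentricity,
            qc_border=bool(minr == 0 or minc == 0 or maxr == h or maxc == w),
            qc_empty_cytoplasm=False,
        )
    labels = sorted(rows)
    for comp in _COMPARTMENTS:
        mask = masks[comp]
        comp_areas = ndi.sum_labels(
            np.ones_like(mask.data, dtype=float), labels=mask.data, index=labels
        )
        for lab, a in zip(labels, comp_areas):
            rows[lab][f"{comp}_area_um2"] = a * px**2
            if comp == "cytoplasm" and a == 0:
                rows[lab]["qc_empty_cytoplasm"] = True
        for ch_name, img in channels.items():
            img = as_float(img)
            sums = ndi.sum_labels(img, labels=mask.data, index=labels)
            for lab, s, a in zip(labels, sums, comp_areas):
                rows[lab][f"{comp}_int_{ch_name}"] = s
                rows[lab][f"{comp}_mean_{ch_name}"] = s / a if a > 0 else np.nan
    table = pd.DataFrame([rows[lab] for lab in labels])
    if exclude_border and len(table):
        table = table[~table.qc_border].reset_index(drop=True)
    return table
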