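"""Deformation-index morphometrics, nuclear morphometrics and tumorsphere
growth quantification.

The deformation index of a cell at device location x is

    DI = D_x / D_0

with ``D_x`` the major axis at that location and ``D_0`` the undeformed
major axis.  The headline statistic is the % median deformation: the median
DI of at least 20 cells at a location divided by the median DI of 20 cells
before deformation, times 100; "% increase" is that value minus 100.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BASELINE, UNASSIGNED, DeviceGeometry, ImageStack
from .imaging import segment_nuclei, extract_features, derive_cytoplasm

__all__ = [
    "compute_di",
    "assign_region",
    "percent_median_deformation",
    "deformation_summary",
    "nuclear_morphometrics",
    "fit_growth",
    "measure_transit_stack",
]

MIN_CELLS_HEADLINE = 20


def compute_di(dx: float, d0: float) -> float:
    """Deformation index DI = Dx / D0."""
    if d0 <= 0:
        raise ValueError("D0 must be positive")
    return float(dx) / float(d0)


def assign_region(centroid_x_um: float, geometry: DeviceGeometry) -> str:
    """Region label whose flow-axis interval contains the centroid.

    Boundary points belong to the upstream region; positions beyond the
    device are UNASSIGNED.
    """
    for region, (x0, x1) in geometry.region_intervals.items():
        if x0 <= centroid_x_um <= x1:
            return region
    return UNASSIGNED


def percent_median_deformation(
    region_dis: Sequence[float], baseline_dis: Sequence[float]
) -> tuple[float, float]:
    """(% median deformation, % increase).

    % value = 100 * median(region DIs) / median(baseline DIs); % increase is
    that value minus 100.  Warns when either group has fewer than 20 cells.
    Medians of even-length lists are the mean of the central order
    statistics.
    """
    region_dis = np.asarray(region_dis, dtype=float)
    baseline_dis = np.asarray(baseline_dis, dtype=float)
    if region_dis.size == 0 or baseline_dis.size == 0:
        raise ValueError("both DI lists must be non-empty")
    for name, arr in (("region", region_dis), ("baseline", baseline_dis)):
        if arr.size < MIN_CELLS_HEADLINE:
            warnings.warn(
                f"{name} group has {arr.size} cells (< {MIN_CELLS_HEADLINE}); "
                "headline summary will be unstable",
                stacklevel=2,
            )
    base = float(np.median(baseline_dis))
    if base == 0:
        raise ValueError("baseline median DI is zero")
    pct = 100.0 * float(np.median(region_dis)) / base
    return pct, pct - 100.0


def deformation_summary(
    shapes: pd.DataFrame, geometry: DeviceGeometry
) -> pd.DataFrame:
    """Per-region deformation summary from a tidy shape table.

    ``shapes`` needs columns ``region`` and ``di`` (one row per cell per
    region).  Returns one row per device region with n, median DI, % median
    deformation relative to the BASELINE rows, and % increase.
    """
    if not {"region", "di"} <= set(shapes.columns):
        raise ValueError("shape table needs 'region' and 'di' columns")
    base = shapes.loc[shapes.region == BASELINE, "di"].to_numpy()
    if base.size == 0:
        raise ValueError("no BASELINE rows to normalize against")
    rows = []
    for region in geometry.region_labels:
        dis = shapes.loc[shapes.region == region, "di"].to_numpy()
        if dis.size == 0:
            continue
        pct, inc = percent_median_deformation(dis, base)
        rows.append(
            dict(
                region=region,
                n=int(dis.size),
                median_di=float(np.median(dis)),
                pct_median_deformation=pct,
                pct_increase=inc,
                channel_width_um=geometry.width_of(region),
            )
        )
    return pd.DataFrame(rows)


def measure_transit_stack(
    stack: ImageStack,
    geometry: DeviceGeometry,
    min_area_um2: float = 20.0,
    d0_strategy: str = "lane",
) -> pd.DataFrame:
    """Segment each region snapshot and ellipse-fit every cell into a tidy
    shape table (cell lane, region, measured axes, DI).

    ``d0_strategy``: ``"lane"`` pairs each cell with its own baseline-frame
    major axis via its flow lane (cells keep their lane across snapshots);
    ``"cohort"`` divides by the median baseline major axis instead, the
    fallback when frames cannot be linked.
    """
    if d0_strategy not in ("lane", "cohort"):
        raise ValueError("d0_strategy must be 'lane' or 'cohort'")
    regions = stack.metadata.get("frame_regions")
    offsets = stack.metadata.get("frame_x_offset_um")
    if regions is None or offsets is None:
        raise ValueError("stack lacks frame_regions / frame_x_offset_um metadata")
    px = stack.pixel_size
    frames = stack.channel(stack.channel_names[0])
    measured = []
    for f, (region, x0) in enumerate(zip(regions, offsets)):
        mask = segment_nuclei(frames[f], px, min_area_um2=min_area_um2)
        cyto = derive_cytoplasm(mask, mask)
        feats = extract_features(
            mask, mask, cyto, channels={}, exclude_border=False
        )
        for _, row in feats.iterrows():
            measured.append(
                dict(
                    region=region,
                    major_um=row.major_axis_um,
                    minor_um=row.minor_axis_um,
                    x_um=row.centroid_x_um + x0,
                    y_um=row.centroid_y_um,
                )
            )
    table = pd.DataFrame(measured)
    if table.empty:
        return table.assign(di=pd.Series(dtype=float))

    base = table[table.region == BASELINE]
    if base.empty:
        raise ValueError("no baseline frame found in stack")
    if d0_strategy == "lane":
        base_sorted = base.sort_values("y_um").reset_index(drop=True)
        lane_y = base_sorted.y_um.to_numpy()
        lane_d0 = base_sorted.major_um.to_numpy()
        idx = np.abs(table.y_um.to_numpy()[:, None] - lane_y[None, :]).argmin(axis=1)
        table["d0_um"] = lane_d0[idx]
    else:
        table["d0_um"] = float(np.median(base.major_um))
    table["di"] = table.major_um / table.d0_um
    return table


def nuclear_morphometrics(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    area_col: str = "area_um2",
    intensity_col: str | None = None,
) -> pd.DataFrame:
    """Group means and % change of nuclear area (and optionally intensity).

    % change = 100 * (mean_treated - mean_control) / mean_control, so a 33%
    area reduction reports as -33 and a 66% intensity gain as +66.
    """
    if len(control) == 0 or len(treated) == 0:
        raise ValueError("both groups must be non-empty")
    feats = [area_col] + ([intensity_col] if intensity_col else [])
    rows = []
    for col in feats:
        mc = float(control[col].mean())
        mt = float(treated[col].mean())
        if mc == 0:
            raise ValueError(f"control mean of {col} is zero")
        rows.append(
            dict(
                feature=col,
                mean_control=mc,
                mean_treated=mt,
                percent_change=100.0 * (mt - mc) / mc,
            )
        )
    return pd.DataFrame(rows)


def fit_growth(
    days: Sequence[float],
    areas: Sequence[float],
    other: tuple[Sequence[float], Sequence[float]] | None = None,
) -> dict:
    """OLS growth rate (slope of mean area vs day, µm²/day).

    With a second (days, areas) series in ``other``, also reports the rate
    ratio first/second; a zero denominator leaves the ratio missing with a
    flag.  Requires >= 3 timepoints.
    """
    days = np.asarray(days, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if days.size < 3:
        raise ValueError("need >= 3 timepoints to fit a growth rate")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    fit = stats.linregress(days, areas)
    out = dict(
        rate=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
    )
    if other is not None:
        o = fit_growth(other[0], other[1])
        out["rate_other"] = o["rate"]
        if o["rate"] == 0:
            out["rate_ratio"] = np.nan
            out["ratio_flag"] = "zero denominator rate"
        else:
            out["rate_ratio"] = out["rate"] / o["rate"]
    return out
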