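"""Time-series quantification: calcium fold change and endothelial
permeability from dye time-lapse.

Calcium responses are summarized as the maximum in-region intensity
normalized to the mean pre-entry baseline.  Permeability uses the
two-compartment initial-slope estimator: with tissue intensity rising as
dI/dt = P (S/V) (I_vessel - I), the early-time slope gives

    P = (V/S) * slope / (I_vessel - I(0))      [cm/s]

for S/V in 1/cm and time in seconds; the fit window should stay inside the
linear regime (P * S/V * t_window well below 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FluorescenceTrace",
    "PermeabilityRecord",
    "calcium_fold_change",
    "calcium_fold_changes_by_region",
    "estimate_permeability",
]


@dataclass
class FluorescenceTrace:
    """One ROI's intensity over time (seconds)."""

    time_s: np.ndarray
    intensity: np.ndarray
    roi_id: str = "roi"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time and intensity must have the same length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.time_s))) if self.time_s.size > 1 else 0.0


@dataclass
class PermeabilityRecord:
    p_cm_s: float
    slope: float  # intensity / s
    i_vessel: float
    fit_window: tuple[int, int]
    r_value: float
    flags: list[str] = field(default_factory=list)


def calcium_fold_change(
    intensity: np.ndarray,
    baseline_mask: np.ndarray,
    region_mask: np.ndarray | None = None,
) -> float:
    """max(in-region intensity) / mean(baseline intensity).

    ``baseline_mask`` selects the pre-entry frames; ``region_mask`` selects
    the in-region frames (default: everything outside the baseline).
    """
    intensity = np.asarray(intensity, dtype=float)
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    if not baseline_mask.any():
        raise ValueError("baseline window is empty")
    if region_mask is None:
        region_mask = ~baseline_mask
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region window is empty")
    base = float(intensity[baseline_mask].mean())
    if base <= 0:
        raise ValueError("baseline mean must be positive")
    return float(intensity[region_mask].max()) / base


def calcium_fold_changes_by_region(traces: pd.DataFrame) -> pd.DataFrame:
    """Per-cell, per-region fold changes from a tidy trace table.

    Expects columns ``cell_id``, ``region``, ``intensity`` with the
    pre-entry frames labelled ``BASELINE``.  Returns one row per
    (cell, region) plus the per-region mean across cells.
    """
    from .core import BASELINE

    rows = []
    for cell, sub in traces.groupby("cell_id"):
        base = sub.region.to_numpy() == BASELINE
        for region in pd.unique(sub.region[~base]):
            fc = calcium_fold_change(
                sub.intensity.to_numpy(), base, (sub.region == region).to_numpy()
            )
            rows.append(dict(cell_id=cell, region=region, fold_change=fc))
    return pd.DataFrame(rows)


def estimate_permeability(
    trace: FluorescenceTrace,
    i_vessel: float,
    s_over_v: float,
    fit_frames: int | str = 10,
) -> PermeabilityRecord:
    """Initial-slope permeability estimate from a tissue-compartment trace.

    OLS over the first ``fit_frames`` frames yields the influx slope; a
    negative slope is clamped to P = 0 with a flag.  Raises if the vessel
    intensity does not exceed the starting tissue intensity.

    ``fit_frames="auto"`` keeps only frames where the tissue signal has
    risen less than 15% of the way to the vessel intensity (minimum 3
    frames), so leaky barriers do not drag the fit out of the linear
    regime.
    """
    if s_over_v <= 0:
        raise ValueError("S/V must be positive")
    if fit_frames == "auto":
        rise = (trace.intensity - trace.intensity[0]) / max(
            i_vessel - trace.intensity[0], 1e-12
        )
        inside = np.nonzero(rise >= 0.15)[0]
        fit_frames = int(inside[0]) + 1 if inside.size else trace.time_s.size
        fit_frames = max(fit_frames, 3)
    n = min(int(fit_frames), trace.time_s.size)
    if n < 3:
        raise ValueError("need >= 3 frames in the fit window")
    t = trace.time_s[:n]
    y = trace.intensity[:n]
    i0 = float(y[0])
    if i_vessel <= i0:
        raise ValueError("vessel intensity must exceed initial tissue intensity")
    fit = stats.linregress(t, y)
    flags = []
    slope = float(fit.slope)
    if slope < 0:
        flags.append("negative slope clamped to zero")
        p = 0.0
    else:
        p = slope / (s_over_v * (i_vessel - i0))
    return PermeabilityRecord(
        p_cm_s=p,
        slope=slope,
        i_vessel=i_vessel,
        fit_window=(0, n),
        r_value=float(fit.rvalue),
        flags=flags,
    )
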