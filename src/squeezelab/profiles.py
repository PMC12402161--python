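"""Single-cell immunofluorescence statistics.

The parsing pipeline runs in a fixed, logged order: QC -> IQR outlier
removal (per condition x timepoint stratum, a cell drops if any feature
leaves its Tukey fence) -> robust-Z standardization -> PCA retaining 97% of
variance -> 2-D manifold embedding (visualization only).  Group effects are
tested per feature and timepoint with Mann-Whitney U and Benjamini-Hochberg
correction across timepoints; plotted values are centred on the control
median per marker and timepoint.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PIPELINE_ORDER",
    "nc_ratio",
    "iqr_outlier_filter",
    "robust_z",
    "robust_z_table",
    "pca_reduce",
    "embed_2d",
    "normalize_to_control",
    "mannwhitney_u",
    "bh_adjust",
    "marker_fold_change",
    "compare_groups",
    "heatmap_matrix",
]

PIPELINE_ORDER = ("qc", "iqr_outlier_filter", "robust_z", "pca", "embedding")

MAD_SCALE = 1.4826  # consistency constant for a normal distribution
EXACT_MW_MAX_N = 12  # combined group size for exact enumeration (no ties)


def nc_ratio(nuclear_mean: float, cyto_mean: float) -> float:
    """log10(nuclear mean / cytoplasmic mean); NaN with non-positive
    cytoplasm (caller flags and excludes the cell for that feature)."""
    if nuclear_mean <= 0 or cyto_mean <= 0:
        return float("nan")
    return math.log10(nuclear_mean / cyto_mean)


def iqr_outlier_filter(
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    k: float = 1.5,
    strata: Sequence[str] = ("condition", "timepoint"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove cells outside the Tukey fence of any feature.

    The fence is R = [Q1 - k IQR, Q3 + k IQR] per feature, computed within
    each condition x timepoint stratum with linear-interpolation quantiles.
    Returns the filtered table and a per-(stratum, feature) removal report.
    Raises if a stratum has < 4 cells or if every cell would be removed.
    """
    strata = [s for s in strata if s in table.columns]
    groups = table.groupby(list(strata), sort=False) if strata else [((), table)]
    keep = pd.Series(True, index=table.index)
    report_rows = []
    for key, sub in groups:
        if len(sub) < 4:
            raise ValueError(f"stratum {key}: need >= 4 cells for the IQR fence")
        for col in feature_cols:
            vals = sub[col].to_numpy(dtype=float)
            q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear interpolation
            iqr = q3 - q1
            if np.isfinite(k):
                lo, hi = q1 - k * iqr, q3 + k * iqr
            else:
                lo, hi = -np.inf, np.inf
            out = (vals < lo) | (vals > hi)
            keep.loc[sub.index[out]] = False
            report_rows.append(
                dict(
                    stratum=str(key),
                    feature=col,
                    n_outside=int(out.sum()),
                    lower=lo,
                    upper=hi,
                )
            )
    if not keep.any():
        raise ValueError("IQR filter removed every cell; degenerate input")
    return table[keep].reset_index(drop=True), pd.DataFrame(report_rows)


def robust_z(values: Sequence[float]) -> np.ndarray:
    """(x - median) / (1.4826 * MAD); raises when the MAD is zero."""
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError("MAD is zero; feature carries no robust spread")
    return (x - med) / (MAD_SCALE * mad)


def robust_z_table(table: pd.DataFrame, feature_cols: Sequence[str]) -> pd.DataFrame:
    """Robust-Z standardize the given columns, dropping (with a warning)
    any feature whose MAD is zero."""
    out = {}
    for col in feature_cols:
        try:
            out[col] = robust_z(table[col].to_numpy())
        except ValueError:
            warnings.warn(f"feature {col!r} has zero MAD; dropped", stacklevel=2)
    return pd.DataFrame(out, index=table.index)


def pca_reduce(
    matrix: np.ndarray, variance_retained: float = 0.97
) -> tuple[np.ndarray, dict]:
    """Scores on the fewest leading principal components whose cumulative
    explained variance reaches ``variance_retained``.

    Component signs follow the convention that each component's
    largest-magnitude loading is positive, so results are fully
    deterministic.  Rank-deficient input truncates at the rank.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 1:
        raise ValueError("need a 2-D matrix with >= 2 rows and >= 1 column")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(x)
    ratios = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratios), variance_retained) + 1)
    k = min(k, scores.shape[1])
    flip = np.sign(
        pca.components_[np.arange(len(ratios)), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip
    return scores[:, :k], dict(
        n_components=k,
        explained_variance_ratio=ratios[:k].tolist(),
        total_explained=float(np.cumsum(ratios)[k - 1]),
    )


def embed_2d(
    scores: np.ndarray, seed: int, n_neighbors: int = 15
) -> np.ndarray:
    """2-D neighbor-graph manifold embedding (UMAP), seeded.

    Visualization aid only: no downstream statistic may consume these
    coordinates.  The neighborhood shrinks with a warning when there are
    fewer rows than ``n_neighbors``.
    """
    import umap  # deferred: heavy numba compilation on first import

    x = np.asarray(scores, dtype=float)
    if x.shape[0] < 10:
        raise ValueError("need >= 10 rows to embed")
    if x.shape[0] <= n_neighbors:
        warnings.warn(
            f"{x.shape[0]} rows < n_neighbors={n_neighbors}; shrinking neighborhood",
            stacklevel=2,
        )
        n_neighbors = x.shape[0] - 1
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, random_state=seed)
    return reducer.fit_transform(x)


def normalize_to_control(
    table: pd.DataFrame,
    value_cols: Sequence[str],
    condition_col: str = "condition",
    control_label: str = "control",
    stratum_cols: Sequence[str] = ("timepoint",),
) -> pd.DataFrame:
    """Centre values on the control median per stratum (marker x timepoint):
    norm value = raw value - control median."""
    stratum_cols = [c for c in stratum_cols if c in table.columns]
    out = table.copy()
    groups = (
        table.groupby(list(stratum_cols), sort=False)
        if stratum_cols
        else [((), table)]
    )
    for key, sub in groups:
        ctrl = sub[sub[condition_col] == control_label]
        if ctrl.empty:
            raise ValueError(f"no control cells in stratum {key}")
        for col in value_cols:
            out.loc[sub.index, col] = sub[col] - float(ctrl[col].median())
    return out


# --------------------------------------------------------------------------
# group testing
# --------------------------------------------------------------------------


def _exact_mw_p(ranks_a_sum: float, n_a: int, n_b: int) -> float:
    """Two-sided exact p by full enumeration of rank assignments (no ties)."""
    n = n_a + n_b
    u_obs = ranks_a_sum - n_a * (n_a + 1) / 2.0
    mean = n_a * n_b / 2.0
    dev = abs(u_obs - mean)
    count = 0
    total = 0
    for comb in combinations(range(1, n + 1), n_a):
        u = sum(comb) - n_a * (n_a + 1) / 2.0
        total += 1
        if abs(u - mean) >= dev - 1e-12:
            count += 1
    return count / total


def mannwhitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (midrank ties) with a two-sided p value.

    Exact p by enumeration when n_a + n_b <= 12 and there are no ties;
    otherwise the normal approximation with tie correction and continuity
    correction.  Returns (U of group A, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    u = r_a - n_a * (n_a + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    if n_a + n_b <= EXACT_MW_MAX_N and not has_ties:
        return u, _exact_mw_p(r_a, n_a, n_b)
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    mean = n_a * n_b / 2.0
    dev = abs(u - mean)
    z = max(dev - 0.5, 0.0) / math.sqrt(sigma2)  # continuity correction
    p = min(2.0 * sps.norm.sf(z), 1.0)
    return u, p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def marker_fold_change(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    marker: str,
    compartment: str = "cell",
    column: str | None = None,
) -> float:
    """mean(per-cell mean intensity, treated) / mean(control) for a marker.

    ``column`` overrides the default ``{compartment}_mean_{marker}`` column
    name when tables use another schema.
    """
    if len(control) == 0 or len(treated) == 0:
        raise ValueError("both groups must be non-empty")
    col = column or f"{compartment}_mean_{marker}"
    mc = float(control[col].mean())
    if mc <= 0:
        raise ValueError("control mean must be positive")
    return float(treated[col].mean()) / mc


def compare_groups(
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    condition_col: str = "condition",
    control_label: str = "control",
    treated_label: str = "squeeze",
    timepoint_col: str = "timepoint",
    bh_family: str = "per_feature",
) -> pd.DataFrame:
    """Mann-Whitney comparisons of every feature at every timepoint.

    BH correction runs across timepoints within each feature (default) or
    over all tests at once (``bh_family="global"``).  Also reports the
    median fold change (treated median / control median) and its log10.
    """
    if bh_family not in ("per_feature", "global"):
        raise ValueError("bh_family must be 'per_feature' or 'global'")
    timepoints = (
        sorted(table[timepoint_col].unique())
        if timepoint_col in table.columns
        else [None]
    )
    rows = []
    for feature in feature_cols:
        for tp in timepoints:
            sub = table if tp is None else table[table[timepoint_col] == tp]
            a = sub.loc[sub[condition_col] == treated_label, feature].dropna().to_numpy()
            b = sub.loc[sub[condition_col] == control_label, feature].dropna().to_numpy()
            if a.size == 0 or b.size == 0:
                continue
            u, p = mannwhitney_u(a, b)
            med_b = float(np.median(b))
            fc = float(np.median(a)) / med_b if med_b != 0 else np.nan
            rows.append(
                dict(
                    feature=feature,
                    timepoint=tp,
                    n_treated=int(a.size),
                    n_control=int(b.size),
                    u_statistic=u,
                    p_value=p,
                    median_fold_change=fc,
                    median_log10_fc=np.log10(fc) if fc and fc > 0 else np.nan,
                )
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    if bh_family == "global":
        result["p_adjusted"] = bh_adjust(result.p_value.to_numpy())
    else:
        result["p_adjusted"] = np.nan
        for feature, idx in result.groupby("feature").groups.items():
            result.loc[idx, "p_adjusted"] = bh_adjust(
                result.loc[idx, "p_value"].to_numpy()
            )
    return result


def heatmap_matrix(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Median log10 fold changes as features x timepoints (heatmap export)."""
    return comparisons.pivot(
        index="feature", columns="timepoint", values="median_log10_fc"
    )
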