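"""Voxel-wise MRI–microscopy correlation.

Brings registered microscopy stacks onto the MRI grid (z-grouping and in-
plane density downsampling), normalizes MRI to normal-appearing gray matter
(NAGM) z-units, fits mono-exponential T2* maps from multi-echo data, extracts
paired voxel tables, bins them by density, quantifies longitudinal growth
rates and runs the group statistics used for bin comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinaryMask, GeometryError, LabelMask, Volume, same_grid

__all__ = [
    "NormalizationStats",
    "GrowthRecord",
    "group_z_by_average",
    "downsample_xy_density",
    "znormalize_nagm",
    "fit_t2star_map",
    "extract_voxel_table",
    "DENSITY_BIN_LABELS",
    "bin_by_density",
    "compute_growth_rate",
    "growth_records_to_frame",
    "group_stats",
]


@dataclass
class NormalizationStats:
    """Reference statistics of the normal-appearing gray matter mask."""

    mean: float
    sd: float
    n_voxels: int

    MIN_VOXELS = 30

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("NAGM standard deviation must be positive")
        if self.n_voxels < self.MIN_VOXELS:
            warnings.warn(
                f"NAGM mask has only {self.n_voxels} voxels "
                f"(< {self.MIN_VOXELS}); normalization may be unstable"
            )


def group_z_by_average(stack: Volume, mri_z_spacing: float) -> Volume:
    """Group microscopy z-slices by averaging to match the MRI voxel depth.

    ``mri_z_spacing`` must be an integer multiple of the stack z spacing
    (±1 %).  A trailing partial group is dropped with a warning.  For a
    binary input the output values are per-voxel volume fractions in [0, 1].
    """
    ratio = mri_z_spacing / stack.spacing[0]
    group = int(round(ratio))
    if group < 1 or abs(ratio - group) > 0.01 * ratio:
        raise GeometryError(
            f"MRI z spacing {mri_z_spacing} is not an integer multiple of the "
            f"stack z spacing {stack.spacing[0]} (ratio {ratio:.4f}); resample "
            "the stack in z first"
        )
    n_groups = stack.shape[0] // group
    if n_groups == 0:
        raise GeometryError("stack thinner than one MRI voxel depth")
    remainder = stack.shape[0] - n_groups * group
    if remainder:
        warnings.warn(
            f"dropping trailing partial group of {remainder} slice(s) "
            f"(stack depth {stack.shape[0]}, group size {group})"
        )
    data = np.asarray(stack.data[: n_groups * group], dtype=float)
    grouped = data.reshape(n_groups, group, *stack.shape[1:]).mean(axis=1)
    # first output slice center sits at the mean of its input slice centers
    new_origin = (
        stack.origin[0] + (group - 1) / 2.0 * stack.spacing[0],
        stack.origin[1],
        stack.origin[2],
    )
    role = "density" if stack.dtype_role in ("density", "probability") else stack.dtype_role
    return Volume(
        grouped,
        (group * stack.spacing[0], stack.spacing[1], stack.spacing[2]),
        new_origin,
        dtype_role=role,
    )


def downsample_xy_density(micro: Volume, mri_grid) -> Volume:
    """Downscale a z-grouped microscopy volume in (y, x) to the MRI grid.

    Output values lie in [0, 1] and represent the structure density within
    each MRI voxel.  When the scale factor is an integer ≥ 2 the operation is
    an area-weighted block average (which preserves the volume-fraction
    interpretation exactly); otherwise plain bilinear sampling is used.
    Constant fields and linear ramps are preserved exactly.
    """
    if abs(micro.spacing[0] - mri_grid.spacing[0]) > 0.01 * mri_grid.spacing[0]:
        raise GeometryError(
            f"z spacing mismatch: microscopy {micro.spacing[0]} vs MRI "
            f"{mri_grid.spacing[0]}; group z first"
        )
    if micro.shape[0] != mri_grid.shape[0]:
        raise GeometryError(
            f"z slice count mismatch: {micro.shape[0]} vs {mri_grid.shape[0]}"
        )
    factors = [mri_grid.spacing[a] / micro.spacing[a] for a in (1, 2)]
    data = np.asarray(micro.data, dtype=float)
    if all(
        abs(f - round(f)) <= 0.01 and round(f) >= 1 for f in factors
    ):
        fy, fx = (int(round(f)) for f in factors)
        ny = min(data.shape[1] // fy, mri_grid.shape[1])
        nx = min(data.shape[2] // fx, mri_grid.shape[2])
        block = data[:, : ny * fy, : nx * fx].reshape(
            data.shape[0], ny, fy, nx, fx
        ).mean(axis=(2, 4))
        out = np.zeros(mri_grid.shape, dtype=float)
        out[:, :ny, :nx] = block
    else:
        from scipy.interpolate import RegularGridInterpolator

        y_old = micro.origin[1] + np.arange(micro.shape[1]) * micro.spacing[1]
        x_old = micro.origin[2] + np.arange(micro.shape[2]) * micro.spacing[2]
        y_new = mri_grid.origin[1] + np.arange(mri_grid.shape[1]) * mri_grid.spacing[1]
        x_new = mri_grid.origin[2] + np.arange(mri_grid.shape[2]) * mri_grid.spacing[2]
        yy, xx = np.meshgrid(y_new, x_new, indexing="ij")
        query = np.stack([yy.ravel(), xx.ravel()], axis=-1)
        out = np.empty(mri_grid.shape, dtype=float)
        for z in range(data.shape[0]):
            interp = RegularGridInterpolator(
                (y_old, x_old), data[z], method="linear",
                bounds_error=False, fill_value=None,
            )
            out[z] = interp(query).reshape(mri_grid.shape[1:])
    return Volume(
        np.clip(out, 0.0, 1.0), mri_grid.spacing, mri_grid.origin, dtype_role="density"
    )


def znormalize_nagm(
    mri: Volume, nagm_mask: BinaryMask
) -> tuple[Volume, NormalizationStats]:
    """Z-normalize an MRI volume by the mean/SD of its normal-appearing gray
    matter mask: out = (in − mean_NAGM) / sd_NAGM."""
    if not same_grid(mri, nagm_mask):
        raise GeometryError("NAGM mask geometry does not match the MRI volume")
    values = np.asarray(mri.data, dtype=float)[nagm_mask.data]
    if values.size == 0:
        raise ValueError("NAGM mask is empty")
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    if sd <= 0:
        raise ValueError("NAGM voxels have zero variance; cannot normalize")
    stats_ = NormalizationStats(mean, sd, int(values.size))
    out = (np.asarray(mri.data, dtype=float) - mean) / sd
    return Volume(out, mri.spacing, mri.origin, dtype_role="intensity"), stats_


def fit_t2star_map(
    multi_echo, echo_times_ms, t2star_cap_ms: float = 500.0, floor: float = 1e-6
) -> tuple[Volume, Volume]:
    """Per-voxel mono-exponential T2* fit from multi-echo magnitude images.

    Fits S(TE) = S0 · exp(−TE / T2*) by weighted log-linear regression
    (weights S², the standard variance correction for log-transformed
    exponentials).  Non-physical fits (T2* ≤ 0 or above ``t2star_cap_ms``)
    are masked as NaN.  Returns (T2* map in ms, S0 map).
    """
    volumes = list(multi_echo)
    te = np.asarray(echo_times_ms, dtype=float)
    if len(volumes) < 3 or te.size != len(volumes):
        raise ValueError("need ≥ 3 echoes with matching echo times")
    first = volumes[0]
    for v in volumes[1:]:
        if not same_grid(first, v):
            raise GeometryError("echo volumes must share one grid")
    signal = np.stack([np.maximum(np.asarray(v.data, float), floor) for v in volumes])
    logs = np.log(signal)
    w = signal**2
    sw = w.sum(axis=0)
    swt = (w * te[:, None, None, None]).sum(axis=0)
    swt2 = (w * (te**2)[:, None, None, None]).sum(axis=0)
    swy = (w * logs).sum(axis=0)
    swty = (w * logs * te[:, None, None, None]).sum(axis=0)
    denom = sw * swt2 - swt**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sw * swty - swt * swy) / denom
        intercept = (swy - slope * swt) / sw
        t2star = -1.0 / slope
    s0 = np.exp(intercept)
    invalid = ~np.isfinite(t2star) | (t2star <= 0) | (t2star > t2star_cap_ms)
    t2star = np.where(invalid, np.nan, t2star)
    s0 = np.where(invalid, np.nan, s0)
    return (
        Volume(t2star, first.spacing, first.origin),
        Volume(s0, first.spacing, first.origin),
    )


def extract_voxel_table(
    layers: dict, category_mask: LabelMask, category_names=None, metadata=None
) -> pd.DataFrame:
    """One row per voxel with category > 0, carrying every layer's value.

    ``layers`` maps column names to Volumes sharing the category mask's grid
    exactly; ``category_names`` optionally maps label integers to names;
    ``metadata`` adds constant columns (timepoint_days, dataset_id, ...).
    """
    for name, vol in layers.items():
        if not same_grid(vol, category_mask):
            raise GeometryError(f"layer {name!r} geometry differs from the mask")
    idx = np.argwhere(category_mask.data > 0)
    world = category_mask.index_to_world(idx) if len(idx) else np.zeros((0, 3))
    table = {
        "i": idx[:, 0] if len(idx) else np.array([], dtype=int),
        "j": idx[:, 1] if len(idx) else np.array([], dtype=int),
        "k": idx[:, 2] if len(idx) else np.array([], dtype=int),
        "world_z": world[:, 0] if len(idx) else np.array([]),
        "world_y": world[:, 1] if len(idx) else np.array([]),
        "world_x": world[:, 2] if len(idx) else np.array([]),
    }
    labels = (
        category_mask.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        if len(idx)
        else np.array([], dtype=int)
    )
    if category_names:
        table["category"] = [category_names.get(int(l), str(int(l))) for l in labels]
    else:
        table["category"] = [str(int(l)) for l in labels]
    for name, vol in layers.items():
        table[name] = (
            np.asarray(vol.data)[idx[:, 0], idx[:, 1], idx[:, 2]]
            if len(idx)
            else np.array([])
        )
    df = pd.DataFrame(table)
    for key, value in (metadata or {}).items():
        df[key] = value
    return df


DENSITY_BIN_LABELS = ["w/o glioma", "0-5%", "5-25%", "25-50%", "50-75%", "75-100%"]
_DENSITY_EDGES = np.array([0.0, 0.05, 0.25, 0.50, 0.75, 1.0])


def bin_by_density(
    table: pd.DataFrame,
    density_column: str = "glioma_density",
    category_column: str = "category",
    normal_category: str = "normal",
) -> pd.DataFrame:
    """Assign every voxel row to a density bin.

    Bins follow the convention half-open [lo, hi) with the top bin closed at
    100 %; rows whose category marks normal tissue go to 'w/o glioma' with
    density forced to 0 regardless of the recorded value.  Adds a
    ``density_bin`` categorical column; bin sizes always partition the table.
    """
    density = table[density_column].to_numpy(dtype=float)
    if np.any(density < 0) or np.any(density > 1):
        raise ValueError("densities must lie within [0, 1]")
    idx = np.searchsorted(_DENSITY_EDGES[1:-1], density, side="right")
    labels = np.asarray(DENSITY_BIN_LABELS[1:], dtype=object)[idx]
    if category_column in table.columns:
        normal = table[category_column].astype(str).to_numpy() == normal_category
        labels = np.where(normal, DENSITY_BIN_LABELS[0], labels)
        density = np.where(normal, 0.0, density)
    out = table.copy()
    out[density_column] = density
    out["density_bin"] = pd.Categorical(
        labels, categories=DENSITY_BIN_LABELS, ordered=True
    )
    return out


@dataclass
class GrowthRecord:
    """Per-voxel longitudinal density change."""

    index: tuple[int, int, int]
    densities: np.ndarray  # one per timepoint
    growth_rate: float  # %/day; NaN when overlap is False
    overlap: bool


def compute_growth_rate(
    density_volumes, days, overlap_masks=None
) -> list[GrowthRecord]:
    """Per-voxel growth rate across co-registered timepoints.

    rate = 100 · (density(t_last) − density(t_first)) / (t_last − t_first)
    in %/day, computed only inside the intersection of all timepoint masks
    (every mask must claim the voxel; others get ``overlap=False`` and a NaN
    rate).
    """
    volumes = list(density_volumes)
    days = np.asarray(days, dtype=float)
    if len(volumes) < 2 or days.size != len(volumes):
        raise ValueError("need ≥ 2 co-registered timepoints with matching days")
    span = days[-1] - days[0]
    if span == 0:
        raise ValueError("zero day span between first and last timepoint")
    first = volumes[0]
    for v in volumes[1:]:
        if not same_grid(first, v):
            raise GeometryError("timepoint volumes must share one grid")
    if overlap_masks is None:
        overlap = np.ones(first.shape, dtype=bool)
        candidates = overlap
    else:
        overlap = np.ones(first.shape, dtype=bool)
        union = np.zeros(first.shape, dtype=bool)
        for m in overlap_masks:
            if not same_grid(first, m):
                raise GeometryError("overlap mask geometry mismatch")
            overlap &= m.data
            union |= m.data
        candidates = union
    stacked = np.stack([np.asarray(v.data, float) for v in volumes])
    rate = 100.0 * (stacked[-1] - stacked[0]) / span
    records = []
    for i, j, k in np.argwhere(candidates):
        records.append(
            GrowthRecord(
                (int(i), int(j), int(k)),
                stacked[:, i, j, k].copy(),
                float(rate[i, j, k]) if overlap[i, j, k] else float("nan"),
                bool(overlap[i, j, k]),
            )
        )
    return records


def growth_records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "i": [r.index[0] for r in records],
            "j": [r.index[1] for r in records],
            "k": [r.index[2] for r in records],
            "growth_rate_pct_per_day": [r.growth_rate for r in records],
            "overlap": [r.overlap for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Group statistics

def _dunn_bonferroni(groups: dict) -> pd.DataFrame:
    """Dunn's post-hoc z-tests on pooled ranks with tie correction,
    Bonferroni-adjusted."""
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], float) for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    offsets = np.cumsum([0] + [len(groups[g]) for g in names])
    mean_ranks = {
        g: ranks[offsets[i] : offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ga, gb = names[a], names[b]
            na, nb = len(groups[ga]), len(groups[gb])
            var = (
                n_total * (n_total + 1) / 12.0
                - tie_term / (12.0 * (n_total - 1))
            ) * (1.0 / na + 1.0 / nb)
            z = (mean_ranks[ga] - mean_ranks[gb]) / np.sqrt(var)
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "group1": ga,
                    "group2": gb,
                    "statistic": z,
                    "p_raw": p_raw,
                    "p_adjusted": min(1.0, m * p_raw),
                    "direction": np.sign(mean_ranks[ga] - mean_ranks[gb]),
                }
            )
    return pd.DataFrame(rows)


def group_stats(
    grouped: pd.DataFrame,
    value_column: str,
    group_column: str = "density_bin",
    test: str = "anova_tukey",
) -> dict:
    """Omnibus + post-hoc comparison of a value across groups.

    test : {'anova_tukey', 'kruskal_dunn_bonf', 'mannwhitney', 'welch'}
        One-way ANOVA with Tukey HSD, Kruskal-Wallis with Dunn-Bonferroni,
        or the two-sample tests (exactly two groups required).
    Returns a dict with the omnibus statistic/p-value and a pairwise
    DataFrame ready for CSV serialization.
    """
    observed = grouped.dropna(subset=[value_column, group_column])
    groups = {
        str(name): sub[value_column].to_numpy(dtype=float)
        for name, sub in observed.groupby(group_column, observed=True)
        if len(sub) >= 2
    }
    if len(groups) < 2:
        raise ValueError("need ≥ 2 groups with ≥ 2 observations each")
    names = list(groups)
    if test == "anova_tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        stat, p = stats.f_oneway(*groups.values())
        tukey = pairwise_tukeyhsd(
            observed[value_column].to_numpy(dtype=float),
            observed[group_column].astype(str).to_numpy(),
        )
        frame = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        ).rename(columns={"p-adj": "p_adjusted"})
        return {"test": test, "statistic": float(stat), "pvalue": float(p),
                "pairwise": frame}
    if test == "kruskal_dunn_bonf":
        stat, p = stats.kruskal(*groups.values())
        return {"test": test, "statistic": float(stat), "pvalue": float(p),
                "pairwise": _dunn_bonferroni(groups)}
    if test in ("mannwhitney", "welch"):
        if len(names) != 2:
            raise ValueError(f"{test} requires exactly 2 groups, got {len(names)}")
        a, b = groups[names[0]], groups[names[1]]
        if test == "mannwhitney":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
        frame = pd.DataFrame(
            [{
                "group1": names[0],
                "group2": names[1],
                "statistic": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_adjusted": float(res.pvalue),
                "direction": float(np.sign(np.median(a) - np.median(b))),
            }]
        )
        return {"test": test, "statistic": float(res.statistic),
                "pvalue": float(res.pvalue), "pairwise": frame}
    raise ValueError(f"unknown test {test!r}")
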