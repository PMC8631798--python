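"""Counting and spatial-mapping stages for labelled-cell tables.

Implements the measurement conventions of a dual-colour tracing experiment:
normalisation of raw section coordinates to the central-canal origin,
quadrant assignment (dorso-ventral x ipsi-contralateral), 1-in-k section
subsampling to avoid double-counting cells split across consecutive
sections, divergence-rate summaries (pooled and per-animal), rank-based
soma-area statistics, and binned spatial density profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

#: default 1-in-k section sampling per region: lumbar premotor cells are
#: dense enough that only every third section is counted; elsewhere every
#: section is counted (k=1).  Motoneuron counts use every other section.
DEFAULT_SAMPLING: dict[str, tuple[int, int]] = {"lumbar": (3, 0)}
MOTONEURON_SAMPLING: tuple[int, int] = (2, 0)

DEFAULT_COLOURS = ("eGFP", "mCherry")


def format_percent(rate: float, decimals: int = 1) -> str:
    """Render a fraction as a percentage, rounding half away from zero."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(100.0 * float(rate))).quantize(
        q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# coordinates and quadrants

def normalize_coordinates(raw_points, grey_matter_bounds: Mapping[str, float],
                          central_canal: tuple[float, float],
                          injection_side: str) -> pd.DataFrame:
    """Map raw section coordinates (µm) to the normalized [-1, 1]² frame.

    The central canal maps to (0, 0); the lateral grey-matter border
    ipsilateral to the hindlimb injection maps to x = +1 and the
    contralateral border to x = -1; the dorsal-most border maps to
    y = +1, the ventral-most to y = -1.  Each side of the canal is scaled
    by its own extent, so the canal need not sit mid-way.

    Parameters
    ----------
    raw_points : array-like of shape (n, 2) or DataFrame with columns x, y
        Coordinates in µm, x increasing to the animal's right, y
        increasing dorsally.
    grey_matter_bounds : mapping with keys x_min, x_max, y_min, y_max
        Grey-matter extents (µm) of the section(s); scalars or per-point
        arrays.
    central_canal : (x, y) in µm
    injection_side : "left" or "right"

    Returns
    -------
    DataFrame with columns ``x_norm``, ``y_norm`` and a boolean
    ``out_of_bounds`` flag; flagged rows fall outside the stated bounds
    and must be excluded from summaries.
    """
    if injection_side not in ("left", "right"):
        raise ConfigError(
            f"injection_side must be 'left' or 'right', got {injection_side!r}")
    if isinstance(raw_points, pd.DataFrame):
        x = raw_points["x"].to_numpy(float)
        y = raw_points["y"].to_numpy(float)
    else:
        pts = np.asarray(raw_points, float).reshape(-1, 2)
        x, y = pts[:, 0], pts[:, 1]
    cx, cy = central_canal
    b = {k: np.asarray(grey_matter_bounds[k], float)
         for k in ("x_min", "x_max", "y_min", "y_max")}
    if np.any(b["x_min"] >= cx) or np.any(b["x_max"] <= cx) \
            or np.any(b["y_min"] >= cy) or np.any(b["y_max"] <= cy):
        raise ConfigError("grey_matter_bounds must strictly enclose the "
                          "central canal")

    # each half-axis scaled by its own canal-to-border distance
    with np.errstate(invalid="ignore"):
        x_n = np.where(x >= cx, (x - cx) / (b["x_max"] - cx),
                       (x - cx) / (cx - b["x_min"]))
        if injection_side == "left":
            x_n = -x_n
        y_n = np.where(y >= cy, (y - cy) / (b["y_max"] - cy),
                       (y - cy) / (cy - b["y_min"]))
    oob = (np.abs(x_n) > 1) | (np.abs(y_n) > 1) | ~np.isfinite(x_n) \
        | ~np.isfinite(y_n)
    return pd.DataFrame({"x_norm": x_n, "y_norm": y_n, "out_of_bounds": oob})


def assign_quadrant(x_norm, y_norm):
    """Quadrant of normalized coordinates: DI/DC/VI/VC.

    x >= 0 is ipsilateral, y >= 0 is dorsal (ties go to
    ipsilateral/dorsal).  Scalars return a string; arrays return an object
    array with ``pd.NA`` for non-finite (flagged) coordinates.
    """
    scalar = np.isscalar(x_norm) and np.isscalar(y_norm)
    x = np.atleast_1d(np.asarray(x_norm, float))
    y = np.atleast_1d(np.asarray(y_norm, float))
    if x.shape != y.shape:
        raise ValueError("x_norm and y_norm must have the same shape")
    dorsal = y >= 0
    ipsi = x >= 0
    out = np.where(dorsal, np.where(ipsi, "DI", "DC"),
                   np.where(ipsi, "VI", "VC")).astype(object)
    bad = ~(np.isfinite(x) & np.isfinite(y))
    if scalar:
        if bad[0]:
            raise ValueError("non-finite coordinates")
        return str(out[0])
    out[bad] = pd.NA
    return out


# ---------------------------------------------------------------------------
# section subsampling

def subsample_sections(cells: pd.DataFrame, region: str, k: int,
                       offset: int = 0) -> pd.DataFrame:
    """Keep one of every ``k`` sections (those with index ≡ offset mod k)
    within ``region``; rows from other regions pass through unchanged."""
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if not (0 <= offset < k):
        raise ConfigError(f"offset must satisfy 0 <= offset < k, got {offset}")
    if k == 1:
        return cells
    in_region = cells["region"] == region
    keep = ~in_region | (cells["section_index"] % k == offset)
    return cells[keep]


def apply_sampling(cells: pd.DataFrame,
                   sampling: Optional[Mapping[str, tuple[int, int]]] = None
                   ) -> pd.DataFrame:
    """Apply per-region (k, offset) subsampling; default ``DEFAULT_SAMPLING``."""
    if sampling is None:
        sampling = DEFAULT_SAMPLING
    for region, (k, offset) in sampling.items():
        cells = subsample_sections(cells, region, k, offset)
    return cells


# ---------------------------------------------------------------------------
# divergence summaries

def classify_labels(labels: pd.Series,
                    colours: Sequence[str] = DEFAULT_COLOURS) -> pd.Series:
    """Map a label string to 'A', 'B' or 'double'."""
    ca, cb = colours
    parts = labels.astype(str).str.split("+")
    has_a = parts.map(lambda p: ca in p)
    has_b = parts.map(lambda p: cb in p)
    if not (has_a | has_b).all():
        bad = labels[~(has_a | has_b)].unique()[:5]
        raise ValueError(f"label values {list(bad)} contain neither colour "
                         f"{ca!r} nor {cb!r}")
    return pd.Series(np.where(has_a & has_b, "double",
                              np.where(has_a, "A", "B")),
                     index=labels.index)


def divergence_summary(cells: pd.DataFrame,
                       group_by: Sequence[str] = ("region",),
                       sampling: Optional[Mapping[str, tuple[int, int]]] = None,
                       colours: Sequence[str] = DEFAULT_COLOURS
                       ) -> pd.DataFrame:
    """Count single/double-labelled premotor cells per group.

    Motoneuron rows are excluded from all denominators.  For each group the
    summary reports the pooled rate (summed double / summed total) and the
    unweighted per-animal mean ± SD of animal-level rates — the two
    estimators deliberately both appear because they answer different
    questions and diverge for heterogeneous animals (see
    :func:`mean_pooled_discrepancy`).

    Returns
    -------
    DataFrame with the grouping keys plus columns
    ``n_single_A, n_single_B, n_double, n_total, rate_pooled,
    rate_mean, rate_sd, n_animals``.  Groups with no labelled cells are
    simply absent.
    """
    group_by = list(group_by)
    cells = apply_sampling(cells, sampling)
    if "is_motoneuron" in cells.columns:
        cells = cells[~cells["is_motoneuron"].astype(bool)]
    if cells.empty:
        return pd.DataFrame(columns=group_by + [
            "n_single_A", "n_single_B", "n_double", "n_total",
            "rate_pooled", "rate_mean", "rate_sd", "n_animals"])
    cls = classify_labels(cells["labels"], colours)
    work = cells[group_by + (["animal_id"] if "animal_id" in cells else [])]
    work = work.assign(_cls=cls.to_numpy())

    counts = (work.groupby(group_by, observed=True)["_cls"]
              .value_counts().unstack(fill_value=0)
              .reindex(columns=["A", "B", "double"], fill_value=0))
    out = pd.DataFrame({
        "n_single_A": counts["A"],
        "n_single_B": counts["B"],
        "n_double": counts["double"],
    })
    out["n_total"] = out.sum(axis=1)
    out["rate_pooled"] = out["n_double"] / out["n_total"]

    if "animal_id" in work.columns:
        per_animal = (work.groupby(group_by + ["animal_id"], observed=True)
                      ["_cls"].agg(total="size",
                                   double=lambda s: (s == "double").sum()))
        per_animal = per_animal[per_animal["total"] > 0]
        rates = per_animal["double"] / per_animal["total"]
        agg = rates.groupby(level=group_by, observed=True).agg(
            rate_mean="mean", rate_sd="std", n_animals="size")
        out = out.join(agg)
    else:
        out["rate_mean"] = np.nan
        out["rate_sd"] = np.nan
        out["n_animals"] = 0
    return out.reset_index()


def per_animal_rates(cells: pd.DataFrame,
                     group_by: Sequence[str] = ("region",),
                     sampling: Optional[Mapping[str, tuple[int, int]]] = None,
                     colours: Sequence[str] = DEFAULT_COLOURS) -> pd.DataFrame:
    """Animal-level double/total counts and rates per group."""
    cells = apply_sampling(cells, sampling)
    if "is_motoneuron" in cells.columns:
        cells = cells[~cells["is_motoneuron"].astype(bool)]
    cls = classify_labels(cells["labels"], colours)
    work = cells[list(group_by) + ["animal_id"]].assign(_cls=cls.to_numpy())
    g = work.groupby(list(group_by) + ["animal_id"], observed=True)["_cls"]
    out = g.agg(n_total="size", n_double=lambda s: (s == "double").sum())
    out["rate"] = out["n_double"] / out["n_total"]
    return out.reset_index()


def mean_pooled_discrepancy(summary: pd.DataFrame,
                            rel_tol: float = 0.10,
                            abs_tol: float = 0.01) -> pd.DataFrame:
    """Diagnostic for per-animal-mean vs pooled-rate disagreement.

    The unweighted animal mean equals the pooled (count-weighted) rate only
    when animals are homogeneous; a cohort in which animal size correlates
    with animal-level divergence pulls the two apart.  A group is flagged
    when |mean - pooled| exceeds ``max(abs_tol, rel_tol * pooled)``.
    """
    out = summary.copy()
    out["discrepancy"] = out["rate_mean"] - out["rate_pooled"]
    threshold = np.maximum(abs_tol, rel_tol * out["rate_pooled"])
    out["flagged"] = out["discrepancy"].abs() > threshold
    return out


# ---------------------------------------------------------------------------
# soma-area statistics

@dataclass
class SomaAreaStats:
    """Rank-based group comparison of soma cross-sectional areas."""

    group_stats: pd.DataFrame
    kruskal_h: float = np.nan
    kruskal_p: float = np.nan
    dunn: pd.DataFrame = field(default_factory=pd.DataFrame)
    mannwhitney_u: float = np.nan
    mannwhitney_p: float = np.nan
    adjustment: str = "bonferroni"

    def summary(self) -> str:
        lines = ["Soma area comparison (rank-based, two-sided)", ""]
        for _, r in self.group_stats.iterrows():
            lines.append(f"  {r['group']}: {r['mean']:.0f} ± {r['sd']:.0f} µm² "
                         f"(n = {int(r['n'])})")
        if np.isfinite(self.kruskal_p):
            lines.append(f"  Kruskal–Wallis H = {self.kruskal_h:.2f}, "
                         f"p = {self.kruskal_p:.3g}")
        if len(self.dunn):
            lines.append(f"  Dunn's pairwise ({self.adjustment}-adjusted):")
            for _, r in self.dunn.iterrows():
                lines.append(f"    {r['group1']} vs {r['group2']}: "
                             f"z = {r['z']:.2f}, p = {r['p_adj']:.3g}")
        if np.isfinite(self.mannwhitney_p):
            lines.append(f"  Mann–Whitney U = {self.mannwhitney_u:.1f}, "
                         f"p = {self.mannwhitney_p:.3g}")
        return "\n".join(lines)


def dunn_test(groups: Mapping[str, Sequence[float]],
              adjustment: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post-hoc pairwise z tests on pooled ranks with tie correction.

    The pairwise statistic compares mean ranks of groups i, j:
    ``z = (Rbar_i - Rbar_j) / sqrt(A (1/n_i + 1/n_j))`` where
    ``A = N(N+1)/12 - sum(t³ - t)/(12 (N - 1))`` corrects for ties.
    Two-sided p-values, Bonferroni-multiplied over the pair count.
    """
    if adjustment != "bonferroni":
        raise ConfigError(f"unsupported adjustment {adjustment!r}")
    names = list(groups)
    values = [np.asarray(groups[g], float) for g in names]
    pooled = np.concatenate(values)
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank, sizes = {}, {}
    start = 0
    for g, v in zip(names, values):
        mean_rank[g] = ranks[start:start + len(v)].mean()
        sizes[g] = len(v)
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    a = n_tot * (n_tot + 1) / 12.0
    if n_tot > 1:
        a -= tie_term / (12.0 * (n_tot - 1))
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for g1, g2 in combinations(names, 2):
        se = np.sqrt(a * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = 0.0 if se == 0 else (mean_rank[g1] - mean_rank[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z,
                     "p_unadj": p, "p_adj": min(1.0, p * n_pairs)})
    return pd.DataFrame(rows)


def soma_area_stats(groups: Mapping[str, Sequence[float]]) -> SomaAreaStats:
    """Descriptive and rank-based statistics for named soma-area groups.

    Two groups get a Mann–Whitney test; three or more get Kruskal–Wallis
    plus Dunn's Bonferroni-adjusted pairwise comparisons (Kruskal–Wallis is
    also reported for two groups).  Groups with fewer than two values are
    excluded with a warning.
    """
    clean = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 2:
            warnings.warn(f"group {name!r} has fewer than 2 values; excluded")
            continue
        clean[name] = arr
    if len(clean) < 2:
        raise ValueError("need at least two groups with >= 2 values each")

    gs = pd.DataFrame([{"group": g, "n": len(v), "mean": v.mean(),
                        "sd": v.std(ddof=1), "median": np.median(v)}
                       for g, v in clean.items()])
    result = SomaAreaStats(group_stats=gs)
    try:
        result.kruskal_h, result.kruskal_p = stats.kruskal(*clean.values())
    except ValueError:  # all values identical in every group
        result.kruskal_h, result.kruskal_p = 0.0, 1.0
    if len(clean) >= 3:
        result.dunn = dunn_test(clean)
    if len(clean) == 2:
        v1, v2 = clean.values()
        result.mannwhitney_u, result.mannwhitney_p = stats.mannwhitneyu(
            v1, v2, alternative="two-sided")
    return result


# ---------------------------------------------------------------------------
# spatial density profiles

def spatial_density(cells: pd.DataFrame, axis: str = "x",
                    by: Optional[str] = None, bins: int = 40,
                    normalization: str = "unit") -> pd.DataFrame:
    """Binned density profile of normalized positions over [-1, 1].

    ``normalization="unit"`` makes every profile integrate to 1 (the
    violin-area-normalised convention); ``"count"`` weights each group's
    profile by its share of cells so areas compare group sizes.
    """
    if axis not in ("x", "y"):
        raise ConfigError(f"axis must be 'x' or 'y', got {axis!r}")
    if normalization not in ("unit", "count"):
        raise ConfigError(
            f"normalization must be 'unit' or 'count', got {normalization!r}")
    col = f"{axis}_norm"
    edges = np.linspace(-1.0, 1.0, bins + 1)
    width = edges[1] - edges[0]
    if cells.empty:
        cols = ([by] if by else []) + ["bin_left", "bin_right", "density"]
        return pd.DataFrame(columns=cols)
    total = len(cells)
    frames = []
    groups = cells.groupby(by, observed=True) if by else [(None, cells)]
    for key, grp in groups:
        vals = np.clip(grp[col].to_numpy(float), -1.0, 1.0)
        counts, _ = np.histogram(vals, bins=edges)
        denom = len(vals) if normalization == "unit" else total
        prof = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                             "density": counts / (denom * width)})
        if by:
            prof.insert(0, by, key)
        frames.append(prof)
    return pd.concat(frames, ignore_index=True)
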