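"""Comparative statistics: simple regression, one-way ANOVA, Tukey-Kramer,
collecting effort, and the diversity-vs-area contrasts.

Sums of squares, F ratios and studentized-range q statistics are computed
explicitly (transparent, auditable arithmetic); tail probabilities come
from ``scipy.stats`` distributions.  All log transforms are base 10 and
the significance threshold is α = 0.05 throughout, with no multiple-
testing correction beyond the Tukey adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

logger = logging.getLogger(__name__)

TRANSFORMS = ("none", "log10_x", "log10_y", "log10_both")


def _log10_checked(values: np.ndarray, label: str) -> np.ndarray:
    if np.any(values <= 0):
        bad = np.flatnonzero(values <= 0)[0]
        raise InputError(
            f"log10 transform of {label} requires positive values; "
            f"element {bad} is {values[bad]}"
        )
    return np.log10(values)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    n: int
    transform: str = "none"

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "f_stat": self.f_stat,
            "df": list(self.df),
            "p_value": self.p_value,
            "n": self.n,
            "transform": self.transform,
        }


def linear_regression(x, y, transform: str = "none") -> RegressionResult:
    """Least-squares simple regression with an F test of the slope.

    ``transform`` applies base-10 logs to x, y, or both before fitting
    (raising :class:`InputError` on non-positive values).  F is computed
    as (n-2) R² / (1-R²) with p from the F(1, n-2) distribution.
    """
    if transform not in TRANSFORMS:
        raise InputError(f"unknown transform {transform!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise InputError(f"need at least 3 points, got {n}")
    if transform in ("log10_x", "log10_both"):
        x = _log10_checked(x, "x")
    if transform in ("log10_y", "log10_both"):
        y = _log10_checked(y, "y")

    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise InputError("zero variance in x")
    sxy = float(((x - xm) * (y - ym)).sum())
    syy = float(((y - ym) ** 2).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = 0.0 if syy == 0.0 else (sxy * sxy) / (sxx * syy)
    r2 = min(max(r2, 0.0), 1.0)
    df = (1, n - 2)
    if r2 >= 1.0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = df[1] * r2 / (1.0 - r2)
        p = float(sps.f.sf(f_stat, *df))
    return RegressionResult(
        slope=slope, intercept=intercept, r_squared=r2,
        f_stat=f_stat, df=df, p_value=p, n=n, transform=transform,
    )


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_sizes: list[int]
    group_means: list[float]
    ss_between: float
    ss_within: float
    note: str | None = None  # flags degenerate layouts (singleton groups etc.)

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat,
            "df": [self.df_between, self.df_within],
            "p_value": self.p_value,
            "group_sizes": self.group_sizes,
            "group_means": self.group_means,
            "note": self.note,
        }


def one_way_anova(groups: list) -> AnovaResult:
    """Fixed-effects one-way ANOVA (between/within decomposition).

    Requires ≥ 2 groups, every group non-empty, and at least one group
    with ≥ 2 values.  Identical data in all groups yields F = 0, p = 1
    rather than NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InputError("need at least 2 groups")
    if any(len(a) == 0 for a in arrays):
        raise InputError("every group must hold at least one value")
    if all(len(a) < 2 for a in arrays):
        raise InputError("at least one group needs 2 or more values")

    sizes = [len(a) for a in arrays]
    means = [float(a.mean()) for a in arrays]
    n_total = sum(sizes)
    grand = float(np.concatenate(arrays).mean())
    ssb = float(sum(n * (m - grand) ** 2 for n, m in zip(sizes, means)))
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)

    note = None
    if any(n == 1 for n in sizes):
        note = f"{sum(1 for n in sizes if n == 1)} singleton group(s); df=({df_b},{df_w})"
    if ssw == 0.0:
        if ssb == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = math.inf, 0.0
    else:
        f_stat = (ssb / df_b) / (ssw / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))
    return AnovaResult(
        f_stat=f_stat, df_between=df_b, df_within=df_w, p_value=p,
        group_sizes=sizes, group_means=means,
        ss_between=ssb, ss_within=ssw, note=note,
    )


@dataclass
class PairComparison:
    group_i: str
    group_j: str
    mean_diff: float  # mean_i - mean_j
    q_stat: float
    p_adjusted: float
    significant: bool


@dataclass
class TukeyResult:
    comparisons: list[PairComparison]
    alpha: float
    df_within: int
    excluded_groups: list[str] = field(default_factory=list)

    def pair(self, a: str, b: str) -> PairComparison:
        for c in self.comparisons:
            if {c.group_i, c.group_j} == {a, b}:
                return c
        raise KeyError((a, b))


def tukey_hsd(groups: list, labels: list[str] | None = None, alpha: float = 0.05) -> TukeyResult:
    """Tukey-Kramer pairwise comparisons after a one-way ANOVA.

    Handles unequal group sizes via the Kramer adjustment
    ``q = |m_i - m_j| / sqrt(MSW/2 (1/n_i + 1/n_j))`` with the adjusted p
    from the studentized range distribution on (k, N-k).  Groups of size 1
    are excluded with a logged warning.
    """
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise InputError("labels/groups length mismatch")
    keep, excluded = [], []
    for lab, g in zip(labels, groups):
        arr = np.asarray(g, dtype=float)
        if len(arr) < 2:
            logger.warning("excluding singleton group %s from Tukey test", lab)
            excluded.append(lab)
        else:
            keep.append((lab, arr))
    if len(keep) < 2:
        raise InputError("need at least 2 groups of size >= 2")

    arrays = [a for _, a in keep]
    names = [lab for lab, _ in keep]
    sizes = [len(a) for a in arrays]
    means = [float(a.mean()) for a in arrays]
    k = len(arrays)
    df_w = sum(sizes) - k
    msw = sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)) / df_w

    comparisons = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        if msw == 0.0:
            q = 0.0 if diff == 0.0 else math.inf
            p = 1.0 if diff == 0.0 else 0.0
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_w))
        p = min(max(p, 0.0), 1.0)
        comparisons.append(
            PairComparison(
                group_i=names[i], group_j=names[j], mean_diff=diff,
                q_stat=q, p_adjusted=p, significant=bool(p < alpha),
            )
        )
    return TukeyResult(
        comparisons=comparisons, alpha=alpha, df_within=df_w, excluded_groups=excluded
    )


# ---------------------------------------------------------------------------
# collecting effort
# ---------------------------------------------------------------------------

def collecting_effort(frame: pd.DataFrame, level: str = "genus") -> pd.DataFrame:
    """Per-taxon sampling intensity: log10(records per species).

    ``level`` groups the cleaned records by genus or family; the returned
    table has columns taxon, n_species, n_records, effort.
    """
    column = {"genus": "genus", "family": "family"}.get(level)
    if column is None:
        raise InputError(f"grouping level must be genus or family, got {level!r}")
    agg = frame.groupby(column).agg(
        n_species=("scientificName", "nunique"), n_records=("record_id", "size")
    )
    agg["effort"] = np.log10(agg["n_records"] / agg["n_species"])
    return agg.reset_index(names="taxon").sort_values(
        "n_species", ascending=False, ignore_index=True
    )


def effort_family_contrast(
    effort_table: pd.DataFrame, focal_family: str, k: int = 10
) -> AnovaResult:
    """Focal family's effort vs the top-k most species-rich other families.

    Implemented literally as a two-group ANOVA in which the focal family
    contributes a single value (its one effort score); the singleton
    layout is flagged in the result's ``note``.  Fewer than ``k``
    comparison families is tolerated with a logged message.
    """
    focal = effort_table[effort_table["taxon"] == focal_family]
    if len(focal) != 1:
        raise InputError(f"focal family {focal_family!r} not found exactly once")
    others = effort_table[effort_table["taxon"] != focal_family]
    others = others.sort_values(
        ["n_species", "taxon"], ascending=[False, True]
    ).head(k)
    if len(others) < 2:
        raise InputError("need at least 2 comparison families")
    if len(others) < k:
        logger.info("only %d comparison families available (asked for %d)", len(others), k)
    return one_way_anova(
        [focal["effort"].to_numpy(), others["effort"].to_numpy()]
    )


# ---------------------------------------------------------------------------
# diversity vs land area
# ---------------------------------------------------------------------------

@dataclass
class DiversityAreaResult:
    regression: RegressionResult       # log10(species) ~ area
    density_anova: AnovaResult         # focal density vs other regions
    densities: dict[str, float]        # species per km² per region
    excluded_region: str | None = None


def diversity_vs_area(
    table: pd.DataFrame,
    focal_region: str,
    excluded_region: str | None = None,
) -> dict[str, DiversityAreaResult]:
    """Regress log10 richness on land area and contrast per-km² density.

    ``table`` needs columns region, n_species, area_km2.  Returns results
    under ``"all"`` and, when ``excluded_region`` is given, under
    ``"excluded"`` with that region dropped (excluding a region reduces
    the contrast's df by one).  The focal region forms a singleton ANOVA
    group against all other regions, flagged in the result note.
    """
    required = {"region", "n_species", "area_km2"}
    if not required.issubset(table.columns):
        raise InputError(f"table must have columns {sorted(required)}")
    if (table["area_km2"] <= 0).any():
        raise InputError("all areas must be positive")
    if (table["n_species"] <= 0).any():
        raise InputError("all species counts must be positive")
    if focal_region not in set(table["region"]):
        raise InputError(f"focal region {focal_region!r} not in table")

    def analyse(sub: pd.DataFrame, excluded: str | None) -> DiversityAreaResult:
        if len(sub) < 3:
            raise InputError("need at least 3 regions")
        reg = linear_regression(
            sub["area_km2"].to_numpy(), sub["n_species"].to_numpy(), "log10_y"
        )
        density = sub["n_species"] / sub["area_km2"]
        densities = dict(zip(sub["region"], density))
        focal = density[sub["region"] == focal_region].to_numpy()
        rest = density[sub["region"] != focal_region].to_numpy()
        anova = one_way_anova([focal, rest])
        return DiversityAreaResult(
            regression=reg, density_anova=anova,
            densities=densities, excluded_region=excluded,
        )

    out = {"all": analyse(table, None)}
    if excluded_region is not None:
        sub = table[table["region"] != excluded_region]
        if len(sub) == len(table):
            raise InputError(f"excluded region {excluded_region!r} not in table")
        out["excluded"] = analyse(sub.reset_index(drop=True), excluded_region)
    return out
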