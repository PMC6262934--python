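"""Per-species climate niche breadths and genus-level summaries.

Niche breadth is the realized range (max - min) of a climate variable
across a species' valid climate samples: zero for a single record, never
negative.  Genus summaries mirror the diversity contrast of the analysis:
the k most speciose genera individually, plus a single "remaining genera"
group whose statistics pool the species-level values (not genus means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .stats import RegressionResult, linear_regression

logger = logging.getLogger(__name__)

REMAINING_LABEL = "Remaining genera"


@dataclass
class NicheBreadth:
    species: str
    genus: str
    n_samples: int
    mat_min: float
    mat_max: float
    ap_min: float
    ap_max: float

    @property
    def mat_breadth(self) -> float:
        return self.mat_max - self.mat_min

    @property
    def ap_breadth(self) -> float:
        return self.ap_max - self.ap_min


def niche_breadth(samples: pd.DataFrame) -> NicheBreadth:
    """Breadth of one species from its climate samples.

    ``samples`` is the climate-extraction output restricted to one
    species; rows with ``valid=False`` are ignored.  Zero valid samples
    is an error — distinct from a legitimate breadth of zero.
    """
    valid = samples[samples["valid"]] if "valid" in samples else samples
    names = valid["scientificName"].unique() if "scientificName" in valid else ["?"]
    if len(names) > 1:
        raise InputError("samples of several species passed to niche_breadth")
    if len(valid) == 0:
        raise InputError("no valid climate samples; breadth undefined")
    return NicheBreadth(
        species=str(names[0]),
        genus=str(valid["genus"].iloc[0]) if "genus" in valid else "",
        n_samples=len(valid),
        mat_min=float(valid["mat"].min()),
        mat_max=float(valid["mat"].max()),
        ap_min=float(valid["ap"].min()),
        ap_max=float(valid["ap"].max()),
    )


def niche_breadth_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Breadth table over all species with ≥ 1 valid climate sample.

    Species whose every record failed climate extraction are dropped with
    a logged count.
    """
    valid = samples[samples["valid"]]
    dropped = set(samples["scientificName"]) - set(valid["scientificName"])
    if dropped:
        logger.info("%d species have no valid climate sample and are dropped", len(dropped))
    agg = valid.groupby("scientificName").agg(
        genus=("genus", "first"),
        n_samples=("mat", "size"),
        mat_min=("mat", "min"),
        mat_max=("mat", "max"),
        ap_min=("ap", "min"),
        ap_max=("ap", "max"),
    )
    agg["mat_breadth"] = agg["mat_max"] - agg["mat_min"]
    agg["ap_breadth"] = agg["ap_max"] - agg["ap_min"]
    return agg.reset_index(names="species")


# ---------------------------------------------------------------------------
# genus-level summaries
# ---------------------------------------------------------------------------

def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    se = 0.0 if len(values) < 2 else float(values.std(ddof=1) / np.sqrt(len(values)))
    return mean, se


def rank_genera(breadths: pd.DataFrame) -> list[tuple[str, int]]:
    """Genera ordered by species count (desc), ties alphabetical."""
    counts = breadths.groupby("genus")["species"].nunique()
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def genus_summaries(
    breadths: pd.DataFrame, ranges: pd.DataFrame, k: int = 5
) -> pd.DataFrame:
    """Mean ± SE of range size and niche breadths for the top-k genera.

    ``breadths`` comes from :func:`niche_breadth_table`; ``ranges`` from
    ``spatial.range_summaries`` (columns species, aoo).  The last row
    pools every remaining genus at the species level.  SE is the sample
    SD over species-level values divided by √n.
    """
    ranked = rank_genera(breadths)
    if not 1 <= k < len(ranked):
        raise ConfigError(f"k must be in [1, {len(ranked) - 1}], got {k}")
    merged = breadths.merge(ranges[["species", "aoo"]], on="species", how="left")
    top = [g for g, _ in ranked[:k]]

    rows = []
    def summarize(label: str, sub: pd.DataFrame, n_genera: int) -> dict:
        aoo_m, aoo_se = _mean_se(sub["aoo"].dropna())
        mat_m, mat_se = _mean_se(sub["mat_breadth"])
        ap_m, ap_se = _mean_se(sub["ap_breadth"])
        return {
            "group": label,
            "n_genera": n_genera,
            "n_species": sub["species"].nunique(),
            "range_mean": aoo_m, "range_se": aoo_se,
            "mat_breadth_mean": mat_m, "mat_breadth_se": mat_se,
            "ap_breadth_mean": ap_m, "ap_breadth_se": ap_se,
        }

    for genus in top:
        rows.append(summarize(genus, merged[merged["genus"] == genus], 1))
    rest = merged[~merged["genus"].isin(top)]
    rows.append(summarize(REMAINING_LABEL, rest, len(ranked) - k))
    return pd.DataFrame(rows)


def top_rest_breadth_groups(
    breadths: pd.DataFrame, k: int = 5, variable: str = "ap_breadth", log10: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Species-level breadth values split into top-k genera vs the rest.

    With ``log10=True`` (the analysis default) species with zero breadth
    are excluded — log10(0) is undefined — with a logged count.
    """
    if variable not in {"ap_breadth", "mat_breadth"}:
        raise InputError(f"unknown breadth variable {variable!r}")
    ranked = rank_genera(breadths)
    if not 1 <= k < len(ranked):
        raise ConfigError(f"k must be in [1, {len(ranked) - 1}], got {k}")
    top = {g for g, _ in ranked[:k]}
    values = breadths[["genus", variable]].copy()
    if log10:
        n_zero = int((values[variable] <= 0).sum())
        if n_zero:
            logger.info("excluding %d zero-breadth species from log10 analysis", n_zero)
        values = values[values[variable] > 0]
        values[variable] = np.log10(values[variable])
    in_top = values["genus"].isin(top)
    return (
        values.loc[in_top, variable].to_numpy(),
        values.loc[~in_top, variable].to_numpy(),
    )


# ---------------------------------------------------------------------------
# collecting effort vs range and breadth
# ---------------------------------------------------------------------------

def effort_vs_breadth(
    breadths: pd.DataFrame,
    ranges: pd.DataFrame,
    transform: str = "log10_both",
) -> dict[str, RegressionResult]:
    """Do well-collected species have large ranges / wide niches?

    Regresses per-species record count on range size (AOO), MAT breadth
    and AP breadth.  Under a log transform, species with non-positive
    predictor values (zero breadth singletons) are excluded per
    regression with a logged count.
    """
    merged = breadths.merge(
        ranges[["species", "n_records", "aoo"]], on="species", how="inner"
    )
    if len(merged) < 3:
        raise InputError("need at least 3 species with both breadth and range data")

    out: dict[str, RegressionResult] = {}
    for key, column in [
        ("records_vs_range", "aoo"),
        ("records_vs_mat_breadth", "mat_breadth"),
        ("records_vs_ap_breadth", "ap_breadth"),
    ]:
        sub = merged[["n_records", column]].dropna()
        if transform in ("log10_x", "log10_both"):
            n_bad = int((sub[column] <= 0).sum())
            if n_bad:
                logger.info(
                    "excluding %d species with non-positive %s from log10 regression",
                    n_bad, column,
                )
            sub = sub[sub[column] > 0]
        if len(sub) < 3 or sub[column].nunique() < 2:
            logger.warning("degenerate predictor %s; regression skipped", column)
            continue
        out[key] = linear_regression(
            sub[column].to_numpy(), sub["n_records"].to_numpy(), transform
        )
    return out
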