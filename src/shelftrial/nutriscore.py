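"""FSAm-NPS (Nutri-Score) nutrient-profile scoring.

The FSAm-NPS score sums "negative" points for energy, total sugars,
saturated fat and sodium (0-10 each) and subtracts "positive" points
for fruit/vegetable content, fibre and protein (0-5 each; fruit/veg
reaches 10 for beverages).  Protein points are only subtracted when
the negative total is below 11 or the fruit/veg component is maximal,
except for cheese where protein always counts.  The raw score lives
on [-15, 40]; letter grades A (best) to E (worst) partition that
range via published category cut points.

Component point thresholds and letter cut points are shipped as CSV
data files (``data/fsa_nps_points.csv``,
``data/health_letter_cutpoints.csv``) rather than hard-coded, so the
tables are inspectable and versionable.

Scores here are additionally mapped to a 0-100 "scaled" score via the
affine map of the theoretical range, ``scaled = (raw + 15) * 100/55``;
higher scaled scores mean less healthy.  A catalog min-max variant is
available for sensitivity checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HealthScore",
    "nps_points",
    "scale_health",
    "scale_health_minmax",
    "health_letter",
    "score_catalog_health",
    "KJ_PER_KCAL",
    "RAW_MIN",
    "RAW_MAX",
]

KJ_PER_KCAL = 4.184
RAW_MIN, RAW_MAX = -15, 40

_CATEGORIES = ("general", "beverage", "added_fat", "cheese")

# fruit/veg points that unlock protein counting despite negative >= 11
_FV_UNLOCK = {"general": 5, "cheese": 5, "added_fat": 5, "beverage": 10}


def _load_points_table() -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray, str]]:
    with resources.files("shelftrial.data").joinpath("fsa_nps_points.csv").open() as fh:
        table = pd.read_csv(fh)
    out = {}
    for (component, category), grp in table.groupby(["component", "category"]):
        grp = grp.sort_values("threshold")
        cmps = grp["cmp"].unique()
        if len(cmps) != 1:
            raise ValueError(f"mixed comparison conventions for {component}/{category}")
        out[(component, category)] = (
            grp["threshold"].to_numpy(float),
            grp["points"].to_numpy(int),
            cmps[0],
        )
    return out


def _load_cutpoints() -> dict[str, list[tuple[str, int, int]]]:
    with resources.files("shelftrial.data").joinpath(
        "health_letter_cutpoints.csv"
    ).open() as fh:
        table = pd.read_csv(fh)
    out: dict[str, list[tuple[str, int, int]]] = {}
    for row in table.itertuples():
        out.setdefault(row.category, []).append(
            (row.letter, int(row.min_raw), int(row.max_raw))
        )
    return out


_POINTS = _load_points_table()
_CUTPOINTS = _load_cutpoints()


def _component_points(value: float, component: str, category: str) -> int:
    """Table lookup: points for one component value."""
    key = (component, category)
    if key not in _POINTS:
        key = (component, "general")
    thresholds, points, cmp = _POINTS[key]
    if cmp == "gt":
        hits = value > thresholds
    else:  # "ge"
        hits = value >= thresholds
    if not hits.any():
        return 0
    return int(points[hits][-1])


@dataclass(frozen=True)
class HealthScore:
    """Raw FSAm-NPS decomposition plus scaled score and letter."""

    negative_points: int
    positive_points: int  # all positive components (fv + fibre + protein)
    positive_counted: int  # the part actually subtracted
    raw: int
    component_points: dict = field(default_factory=dict, repr=False)

    @property
    def scaled(self) -> float:
        return scale_health(self.raw)


def nps_points(
    *,
    energy_kcal: float,
    sugar_g: float,
    satfat_g: float,
    salt_g: float,
    fat_g: float | None = None,
    fruitveg_pct: float | None = None,
    fibre_g: float | None = None,
    protein_g: float | None = None,
    category: str = "general",
) -> HealthScore:
    """Compute the raw FSAm-NPS score for one product.

    ``energy_kcal`` is converted to kJ (x 4.184) before the energy
    lookup; ``salt_g`` is converted to sodium mg (x 400).  Missing
    optional components (fruit/veg, fibre, saturated fat for the
    added-fat ratio, protein) contribute 0 points with a logged
    warning, mirroring a catalog where only energy/salt/sugar/fat
    completeness is guaranteed.
    """
    if category not in _CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    for name, v in (
        ("energy_kcal", energy_kcal),
        ("sugar_g", sugar_g),
        ("salt_g", salt_g),
    ):
        if v is None or math.isnan(v):
            raise ValueError(f"required component {name} is missing")

    def opt(name: str, v: float | None) -> float:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            logger.warning("missing %s treated as 0 points", name)
            return 0.0
        return v

    satfat = opt("satfat_g", satfat_g)
    fruitveg = opt("fruitveg_pct", fruitveg_pct)
    fibre = opt("fibre_g", fibre_g)
    protein = opt("protein_g", protein_g)

    pts: dict[str, int] = {}
    pts["energy"] = _component_points(energy_kcal * KJ_PER_KCAL, "energy_kj", category)
    pts["sugars"] = _component_points(sugar_g, "sugars_g", category)
    if category == "added_fat":
        fat = opt("fat_g", fat_g)
        ratio = 0.0 if fat <= 0 else satfat / fat * 100.0
        pts["satfat"] = _component_points(ratio, "satfat_ratio_pct", category)
    else:
        pts["satfat"] = _component_points(satfat, "satfat_g", category)
    pts["sodium"] = _component_points(salt_g * 400.0, "sodium_mg", category)

    pts["fruitveg"] = _component_points(fruitveg, "fruitveg_pct", category)
    pts["fibre"] = _component_points(fibre, "fibre_g", category)
    pts["protein"] = _component_points(protein, "protein_g", category)

    negative = pts["energy"] + pts["sugars"] + pts["satfat"] + pts["sodium"]
    positive_all = pts["fruitveg"] + pts["fibre"] + pts["protein"]
    count_protein = (
        category == "cheese"
        or negative < 11
        or pts["fruitveg"] >= _FV_UNLOCK[category]
    )
    counted = positive_all if count_protein else pts["fruitveg"] + pts["fibre"]
    raw = negative - counted
    return HealthScore(
        negative_points=negative,
        positive_points=positive_all,
        positive_counted=counted,
        raw=raw,
        component_points=pts,
    )


def scale_health(raw: float) -> float:
    """Affine map of the theoretical raw range [-15, 40] onto [0, 100]."""
    if raw < RAW_MIN or raw > RAW_MAX:
        raise ValueError(f"raw score {raw} outside [{RAW_MIN}, {RAW_MAX}]")
    return (raw - RAW_MIN) * 100.0 / (RAW_MAX - RAW_MIN)


def scale_health_minmax(raw, raws) -> np.ndarray:
    """Catalog min-max variant of the 0-100 scaling (config alternative)."""
    raws = np.asarray(raws, dtype=float)
    lo, hi = raws.min(), raws.max()
    if hi == lo:
        return np.full_like(np.asarray(raw, dtype=float), 50.0)
    return (np.asarray(raw, dtype=float) - lo) * 100.0 / (hi - lo)


def health_letter(raw: int, category: str = "general", *, is_water: bool = False) -> str:
    """Letter grade for a raw score via the published cut-point table."""
    if category == "beverage" and is_water:
        return "A"
    table_cat = "beverage" if category == "beverage" else "general"
    for letter, lo, hi in _CUTPOINTS[table_cat]:
        if lo <= raw <= hi:
            return letter
    raise ValueError(f"raw score {raw} outside the cut-point table for {table_cat}")


def score_catalog_health(
    catalog: pd.DataFrame,
    category: str = "general",
    scaling: str = "theoretical",
) -> pd.DataFrame:
    """Score a cleaned catalog; adds raw/scaled scores and letters.

    Expects the numeric columns produced by
    :func:`shelftrial.cleaning.clean_nutrients`.
    """
    raws = np.empty(len(catalog), dtype=int)
    for i, row in enumerate(catalog.itertuples()):
        score = nps_points(
            energy_kcal=row.energy_kcal,
            sugar_g=row.sugar_g,
            satfat_g=getattr(row, "satfat_g", math.nan),
            salt_g=row.salt_g,
            fat_g=getattr(row, "fat_g", math.nan),
            fruitveg_pct=getattr(row, "fruitveg_pct", math.nan),
            fibre_g=getattr(row, "fibre_g", math.nan),
            protein_g=getattr(row, "protein_g", math.nan),
            category=category,
        )
        raws[i] = score.raw
    out = catalog.copy()
    out["nutriscore_raw"] = raws
    if scaling == "theoretical":
        out["nutriscore_scaled"] = [scale_health(r) for r in raws]
    elif scaling == "minmax":
        out["nutriscore_scaled"] = scale_health_minmax(raws, raws)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    out["health_letter"] = [health_letter(r, category) for r in raws]
    return out
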