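"""Seedable synthetic product catalogs with retailer-export quirks.

Emulates a foodDB-style catalog of UK online-supermarket products:
one row per product with shelf assignment, per-100 g nutrients as raw
text fields, four environmental indicators, and a price.  The ten
shopping-list shelves of the trial are always present; optional
filler shelves stand in for the rest of the store.  Nutrients are
drawn from truncated normals per shelf with energy/fat/saturated-fat
coupled through a shared latent factor; environmental indicators and
price are log-normal (right-skewed), with filler shelves given
heavier environmental tails than the target shelves.

Raw-data quirks are injected at configurable rates:

* decimal commas ("1,2") on a per-product basis (flagged in
  ``comma_corrupted`` so the decimal-error sensitivity analysis can
  trace them);
* "trace"/"nil"/"negligible" words on fat/sugar/salt fields;
* "<" detection-limit prefixes on fat/sugar/salt fields;
* empty (missing) required fields, and an ``alcohol`` flag, both of
  which the completeness filter removes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cleaning import parse_nutrient

__all__ = [
    "SHOPPING_LIST",
    "CatalogConfig",
    "generate_catalog",
    "alcohol_and_missing_filter",
    "write_catalog",
    "read_catalog",
]

#: the ten shopping-list categories participants must cover
SHOPPING_LIST = (
    "savoury_pie",
    "cheese",
    "frozen_pizza",
    "sandwich",
    "yogurt",
    "ready_meal",
    "meat_or_alternative",
    "soup",
    "chilled_dessert",
    "crackers",
)

# per-shelf nutrient means/sds: (energy kcal, fat g, satfat ratio of fat,
# sugar g, salt g, fibre g, protein g, fruit+veg %)
_SHELF_NUTRIENTS = {
    "savoury_pie": dict(energy=(280, 50), fat=(17, 5), satfat_ratio=0.45,
                        sugar=(3, 2), salt=(0.9, 0.3), fibre=(1.5, 0.8),
                        protein=(9, 3), fruitveg=(5, 5)),
    "cheese": dict(energy=(350, 60), fat=(28, 6), satfat_ratio=0.65,
                   sugar=(1, 1), salt=(1.7, 0.4), fibre=(0.2, 0.2),
                   protein=(22, 4), fruitveg=(0, 1)),
    "frozen_pizza": dict(energy=(240, 40), fat=(9, 3), satfat_ratio=0.45,
                         sugar=(3.5, 1.5), salt=(1.1, 0.3), fibre=(2.2, 0.8),
                         protein=(10, 2), fruitveg=(8, 6)),
    "sandwich": dict(energy=(230, 40), fat=(10, 4), satfat_ratio=0.35,
                     sugar=(3, 1.5), salt=(1.0, 0.3), fibre=(2.0, 0.8),
                     protein=(10, 3), fruitveg=(10, 8)),
    "yogurt": dict(energy=(90, 30), fat=(3.5, 2), satfat_ratio=0.6,
                   sugar=(10, 4), salt=(0.15, 0.05), fibre=(0.3, 0.3),
                   protein=(5, 2), fruitveg=(5, 6)),
    "ready_meal": dict(energy=(140, 40), fat=(6, 3), satfat_ratio=0.4,
                       sugar=(3, 1.5), salt=(0.7, 0.25), fibre=(1.5, 0.8),
                       protein=(7, 2.5), fruitveg=(12, 9)),
    "meat_or_alternative": dict(energy=(220, 60), fat=(14, 6), satfat_ratio=0.4,
                                sugar=(1, 1), salt=(0.8, 0.35), fibre=(1.0, 1.0),
                                protein=(18, 5), fruitveg=(3, 4)),
    "soup": dict(energy=(45, 15), fat=(1.5, 1), satfat_ratio=0.35,
                 sugar=(2.5, 1.2), salt=(0.55, 0.2), fibre=(0.9, 0.6),
                 protein=(2, 1), fruitveg=(25, 15)),
    "chilled_dessert": dict(energy=(250, 60), fat=(12, 5), satfat_ratio=0.6,
                            sugar=(22, 6), salt=(0.2, 0.1), fibre=(0.8, 0.6),
                            protein=(4, 1.5), fruitveg=(3, 4)),
    "crackers": dict(energy=(430, 50), fat=(14, 5), satfat_ratio=0.35,
                     sugar=(3, 2), salt=(1.4, 0.4), fibre=(4, 1.5),
                     protein=(9, 2), fruitveg=(0, 1)),
    "_filler": dict(energy=(200, 90), fat=(9, 6), satfat_ratio=0.45,
                    sugar=(8, 7), salt=(0.7, 0.5), fibre=(1.8, 1.4),
                    protein=(7, 4), fruitveg=(10, 12)),
}

# per-shelf environmental log-normal parameters: (mu, sigma) of log per
# 100 g: ghg kg CO2e, water L, biodiversity species x 1e-14, eutrophication
# g PO4e.  Target shelves sit low so their composites concentrate in the
# sustainable tail of the full catalog; filler shelves are heavy-tailed.
_SHELF_ENV = {
    "meat_or_alternative": dict(ghg=(-0.4, 0.9), water=(3.2, 0.9),
                                biodiversity=(0.3, 1.0), eutrophication=(0.8, 0.9)),
    "cheese": dict(ghg=(-0.6, 0.7), water=(3.0, 0.8),
                   biodiversity=(0.0, 0.9), eutrophication=(0.5, 0.8)),
    "_target_default": dict(ghg=(-1.6, 0.7), water=(2.2, 0.8),
                            biodiversity=(-1.2, 0.9), eutrophication=(-0.6, 0.8)),
    "_filler": dict(ghg=(-0.2, 1.3), water=(3.6, 1.2),
                    biodiversity=(0.6, 1.3), eutrophication=(1.0, 1.2)),
}

_QUIRK_FIELDS = ("fat_str", "sugar_str", "salt_str")
_REQUIRED_FIELDS = ("energy_str", "fat_str", "sugar_str", "salt_str")
_ALL_NUTRIENT_FIELDS = (
    "energy_str", "fat_str", "satfat_str", "sugar_str",
    "salt_str", "fibre_str", "protein_str", "fruitveg_pct_str",
)


@dataclass
class CatalogConfig:
    """Generator settings; defaults emulate the study catalog (~8400)."""

    shelf_sizes: dict = field(default_factory=dict)
    comma_decimal_rate: float = 326 / 8400
    trace_word_rate: float = 0.01
    lt_prefix_rate: float = 0.01
    missing_rate: float = 0.01
    alcohol_rate: float = 0.02
    rng_seed: int = 0

    @classmethod
    def default(cls, n_products: int = 8400, n_filler_shelves: int = 90,
                seed: int = 0, **overrides) -> "CatalogConfig":
        """Study-scale catalog: 10 target shelves plus filler shelves."""
        target_sizes = [96, 120, 56, 88, 104, 112, 80, 64, 96, 84]
        sizes = dict(zip(SHOPPING_LIST, target_sizes))
        remaining = n_products - sum(target_sizes)
        if remaining < 0:
            raise ValueError("n_products too small for the default target shelves")
        if n_filler_shelves > 0 and remaining > 0:
            base = remaining // n_filler_shelves
            extra = remaining % n_filler_shelves
            for i in range(n_filler_shelves):
                sizes[f"filler_{i:02d}"] = base + (1 if i < extra else 0)
        elif remaining > 0:
            raise ValueError("leftover products but no filler shelves")
        return cls(shelf_sizes=sizes, rng_seed=seed, **overrides)

    @classmethod
    def compact(cls, shelf_size: int = 40, seed: int = 0, **overrides) -> "CatalogConfig":
        """Small target-shelves-only catalog for fast simulation runs."""
        return cls(
            shelf_sizes={shelf: shelf_size for shelf in SHOPPING_LIST},
            rng_seed=seed,
            **overrides,
        )

    @property
    def n_products(self) -> int:
        return sum(self.shelf_sizes.values())

    def validate(self) -> None:
        for rate_name in ("comma_decimal_rate", "trace_word_rate",
                          "lt_prefix_rate", "missing_rate", "alcohol_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{rate_name}={rate} outside [0, 1]")
        for shelf in SHOPPING_LIST:
            if self.shelf_sizes.get(shelf, 0) <= 0:
                raise ValueError(f"shopping-list shelf {shelf!r} has zero size")


def _truncpos(rng, mean, sd, size, floor=0.0):
    """Normal draw truncated below at `floor` by resampling."""
    x = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = x < floor
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(x, floor, None)


def _fmt(x: float, decimals: int) -> str:
    return f"{x:.{decimals}f}"


def generate_catalog(config: CatalogConfig) -> pd.DataFrame:
    """Generate the raw catalog table (one row per product).

    Deterministic for a given config: the same seed yields a
    byte-identical table.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    rows = []
    pid = 0
    for shelf in sorted(config.shelf_sizes):
        n = config.shelf_sizes[shelf]
        is_filler = shelf not in SHOPPING_LIST
        npar = _SHELF_NUTRIENTS["_filler" if is_filler else shelf]
        if is_filler:
            epar = _SHELF_ENV["_filler"]
        else:
            epar = _SHELF_ENV.get(shelf, _SHELF_ENV["_target_default"])

        # shared latent factor couples energy, fat and saturated fat
        z = rng.normal(size=n)
        def corr(mean, sd, w=0.6):
            e = rng.normal(size=n)
            return np.clip(mean + sd * (w * z + np.sqrt(1 - w**2) * e), 0.0, None)

        energy = corr(*npar["energy"])
        fat = corr(*npar["fat"])
        satfat = fat * np.clip(rng.normal(npar["satfat_ratio"], 0.08, n), 0.05, 0.95)
        sugar = _truncpos(rng, *npar["sugar"], n)
        salt = _truncpos(rng, *npar["salt"], n)
        fibre = _truncpos(rng, *npar["fibre"], n)
        protein = _truncpos(rng, *npar["protein"], n)
        fruitveg = np.clip(rng.normal(*npar["fruitveg"], n), 0.0, 100.0)

        env = {k: rng.lognormal(*epar[k], n) for k in
               ("ghg", "water", "biodiversity", "eutrophication")}
        price = rng.lognormal(np.log(2.6), 0.45, n)
        alcohol = rng.random(n) < config.alcohol_rate

        for i in range(n):
            pid += 1
            rows.append({
                "product_id": f"P{pid:06d}",
                "shelf": shelf,
                "alcohol": bool(alcohol[i]),
                "energy_str": _fmt(energy[i], 1),
                "fat_str": _fmt(fat[i], 1),
                "satfat_str": _fmt(satfat[i], 1),
                "sugar_str": _fmt(sugar[i], 1),
                "salt_str": _fmt(salt[i], 2),
                "fibre_str": _fmt(fibre[i], 1),
                "protein_str": _fmt(protein[i], 1),
                "fruitveg_pct_str": _fmt(fruitveg[i], 0),
                "ghg": env["ghg"][i],
                "water": env["water"][i],
                "biodiversity": env["biodiversity"][i],
                "eutrophication": env["eutrophication"][i],
                "price": float(price[i]),
                "comma_corrupted": False,
            })
    catalog = pd.DataFrame(rows)
    _inject_quirks(catalog, config, rng)
    return catalog


def _inject_quirks(catalog: pd.DataFrame, config: CatalogConfig,
                   rng: np.random.Generator) -> None:
    """Apply field-level quirks, then product-level comma corruption."""
    n = len(catalog)
    trace_words = ("trace", "nil", "negligible")
    for col in _QUIRK_FIELDS:
        u = rng.random(n)
        words = rng.choice(trace_words, size=n)
        for i in range(n):
            if u[i] < config.trace_word_rate:
                catalog.iat[i, catalog.columns.get_loc(col)] = words[i]
            elif u[i] < config.trace_word_rate + config.lt_prefix_rate:
                catalog.iat[i, catalog.columns.get_loc(col)] = (
                    "<" + catalog.iat[i, catalog.columns.get_loc(col)]
                )
    # missing required fields
    miss_field = rng.integers(0, len(_REQUIRED_FIELDS), size=n)
    miss = rng.random(n) < config.missing_rate
    for i in np.flatnonzero(miss):
        catalog.iat[i, catalog.columns.get_loc(_REQUIRED_FIELDS[miss_field[i]])] = ""
    # product-level comma corruption of every dotted nutrient string
    comma = rng.random(n) < config.comma_decimal_rate
    col_idx = [catalog.columns.get_loc(c) for c in _ALL_NUTRIENT_FIELDS]
    flag_idx = catalog.columns.get_loc("comma_corrupted")
    for i in np.flatnonzero(comma):
        for j in col_idx:
            catalog.iat[i, j] = str(catalog.iat[i, j]).replace(".", ",")
        catalog.iat[i, flag_idx] = True


def alcohol_and_missing_filter(catalog: pd.DataFrame) -> pd.DataFrame:
    """Drop alcohol-flagged products and rows with unparseable
    energy/fat/sugar/salt (the nutrients of interest)."""
    keep = ~catalog["alcohol"].astype(bool)
    kinds = {"energy_str": "energy", "fat_str": "fat",
             "sugar_str": "sugar", "salt_str": "salt"}
    for col, kind in kinds.items():
        parsed = np.array(
            [parse_nutrient(v, kind) for v in catalog[col]], dtype=float
        )
        keep &= ~np.isnan(parsed)
    return catalog.loc[keep].reset_index(drop=True)


def write_catalog(catalog: pd.DataFrame, path, config: CatalogConfig | None = None):
    """Write catalog CSV plus a JSON sidecar with the generating config."""
    path = Path(path)
    catalog.to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(".config.json")
        sidecar.write_text(json.dumps(asdict(config), indent=2, sort_keys=True))


def read_catalog(path) -> pd.DataFrame:
    """Read a catalog CSV, keeping raw nutrient columns as strings."""
    return pd.read_csv(
        path, dtype={c: str for c in _ALL_NUTRIENT_FIELDS}, keep_default_na=False,
        na_values=[],
    )
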