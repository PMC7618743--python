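#!/usr/bin/env python
"""Generate the synthetic study catalog.

Builds a study-scale catalog (~8400 products: the ten shopping-list
shelves plus filler shelves) with the raw-data quirks of a retailer
export, applies the alcohol/completeness filter, and reports what was
generated and removed.  The full catalog goes to scratch/ (it is an
intermediate, regenerable artifact); the summary table to results/.
"""

import argparse
import json
from pathlib import Path

from shelftrial.catalog import (
    CatalogConfig,
    alcohol_and_missing_filter,
    generate_catalog,
    write_catalog,
)

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    cfg = CatalogConfig.default(n_products=8400, seed=seed)
    raw = generate_catalog(cfg)
    kept = alcohol_and_missing_filter(raw)
    summary = {
        "seed": seed,
        "n_generated": len(raw),
        "n_after_filter": len(kept),
        "n_alcohol": int(raw["alcohol"].sum()),
        "n_comma_corrupted": int(raw["comma_corrupted"].sum()),
        "n_shelves": raw["shelf"].nunique(),
        "shopping_list_shelf_sizes": {
            s: int((kept["shelf"] == s).sum())
            for s in sorted(set(kept["shelf"])) if not s.startswith("filler")
        },
    }
    (ROOT / "scratch").mkdir(exist_ok=True)
    (ROOT / "results").mkdir(exist_ok=True)
    write_catalog(raw, ROOT / "scratch" / "catalog_raw.csv", cfg)
    write_catalog(kept, ROOT / "scratch" / "catalog_filtered.csv")
    (ROOT / "results" / "catalog_summary.json").write_text(
        json.dumps(summary, indent=2)
    )
    print(f"generated {summary['n_generated']} products on "
          f"{summary['n_shelves']} shelves; {summary['n_after_filter']} kept "
          f"after removing {summary['n_alcohol']} alcohol and "
          f"{summary['n_generated'] - summary['n_after_filter'] - summary['n_alcohol']}"
          f" incomplete rows; {summary['n_comma_corrupted']} products carry "
          f"comma decimals")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=42)
    main(p.parse_args().seed)
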