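#!/usr/bin/env python
"""Secondary, interaction, price and spill-over analyses.

Nutrient models (energy density, salt, fat, sugar; identity scale)
for the health arms and environmental-indicator models (GHG, water,
biodiversity, eutrophication; logged + exponentiated) for the eco
arms at p < 0.005; arm x covariate interaction models for gender,
age group, education, income and meat-consumption level; the basket
price ANOVA with its Levene-dependent branch; and the exploratory
cross-dimension spill-over models.
"""

import argparse
from pathlib import Path

import pandas as pd

from shelftrial.analysis import (
    fit_interactions,
    fit_secondary,
    fit_spillover,
    price_test,
    results_frame,
)

ROOT = Path(__file__).resolve().parents[1]

COVARIATES = ("gender", "age_group", "education", "income", "meat_level")


def main(seed: int) -> None:
    outcomes = pd.read_csv(ROOT / "scratch" / "outcomes.csv")
    frames = []
    for dim in ("health", "eco"):
        frames.append(results_frame(fit_secondary(outcomes, dim)).assign(
            dimension=dim, analysis="secondary"))
        frames.append(results_frame(price_test(outcomes, dim)).assign(
            dimension=dim, analysis="price"))
        frames.append(results_frame(fit_spillover(outcomes, dim)).assign(
            dimension=dim, analysis="spillover"))
        for cov in COVARIATES:
            frames.append(results_frame(
                fit_interactions(outcomes, cov, dim)
            ).assign(dimension=dim, analysis=f"interaction_{cov}"))
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(ROOT / "results" / "secondary_results.csv", index=False)

    sec = table[table["analysis"] == "secondary"]
    print(f"{int(sec['significant'].sum())} of {len(sec)} secondary contrasts "
          f"significant at p < 0.005")
    inter = table[table["analysis"].str.startswith("interaction")]
    print(f"{int(inter['significant'].sum())} of {len(inter)} interaction terms "
          f"significant at p < 0.005")
    price = table[(table["analysis"] == "price")
                  & (table["comparison"] == "omnibus")]
    for row in price.itertuples():
        print(f"price omnibus ({row.dimension}): {row.outcome} p={row.p:.3f}")
    spill = table[table["analysis"] == "spillover"]
    with pd.option_context("display.width", 140):
        print(spill[["dimension", "outcome", "comparison", "estimate", "p"]]
              .round(3).to_string(index=False))


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=42)
    main(p.parse_args().seed)
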