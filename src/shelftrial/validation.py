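"""Calibration experiments for the simulation-and-analysis pipeline.

Two study-design checks that are re-run routinely:

* **Null calibration** — with a uniform (position-, label- and
  price-insensitive) shopper, every arm's basket outcomes are
  identical in law, so the primary position-vs-control contrast
  should reject at its nominal rate.  :func:`null_rejection_rate`
  pushes many small replicate trials through the *full* pipeline
  (simulate -> exclusions -> primary regression) and reports the
  observed rejection fraction at p < 0.025.

* **Effect recovery** — a multiplicative shift planted on the
  log-normal eco outcome at the data-generation level must be
  recovered, after log-transform fitting and exponentiation, without
  material bias.  :func:`eco_effect_recovery` reports the mean
  recovered multiplier over replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import ECO_ARMS, PRIMARY_ALPHA, compute_basket_outcomes, fit_primary
from .catalog import CatalogConfig, alcohol_and_missing_filter, generate_catalog
from .cleaning import clean_nutrients
from .ecoscore import score_catalog_eco
from .nutriscore import score_catalog_health
from .trial import BehaviourConfig, apply_exclusions, generate_participants, simulate_trial

__all__ = [
    "build_scored_catalog",
    "null_rejection_rate",
    "eco_effect_recovery",
]


def build_scored_catalog(config: CatalogConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate, filter, clean and fully score a catalog in one call."""
    config = config or CatalogConfig.compact(seed=seed)
    raw = generate_catalog(config)
    clean = clean_nutrients(alcohol_and_missing_filter(raw))
    return score_catalog_eco(score_catalog_health(clean))


def null_rejection_rate(
    n_replicates: int = 1000,
    n_participants: int = 210,
    seed: int = 0,
    scored_catalog: pd.DataFrame | None = None,
    dimension: str = "health",
) -> dict:
    """Type-I error of the full pipeline under the uniform shopper.

    Each replicate randomises ``n_participants``, simulates sessions
    with the null shopper, applies the study exclusions, fits the
    primary model and records whether the position-vs-control
    contrast falls below the pre-registered 0.025 threshold.
    """
    if scored_catalog is None:
        scored_catalog = build_scored_catalog(seed=seed)
    null = BehaviourConfig.null()
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    rejections = 0
    for child in seeds:
        rng = np.random.default_rng(child)
        participants = generate_participants(n_participants, rng, null)
        sessions, items = simulate_trial(participants, scored_catalog, rng)
        included, _ = apply_exclusions(sessions)
        outcomes = compute_basket_outcomes(included, items, scored_catalog)
        results = fit_primary(outcomes, dimension)
        position_vs_control = results[0]  # first contrast: position vs control
        rejections += position_vs_control.p < PRIMARY_ALPHA
    return {
        "rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "n_participants": n_participants,
        "alpha": PRIMARY_ALPHA,
    }


def eco_effect_recovery(
    effect: float = 0.76,
    n_per_arm: int = 500,
    n_replicates: int = 200,
    seed: int = 0,
    log_sd: float = 0.45,
) -> dict:
    """Recovery of a multiplicative eco-outcome shift planted at the
    data-generation level.

    Baskets' mean eco scores are drawn log-normally around the
    control level, with the position arm's level multiplied by
    ``effect`` (the labels arm gets a slightly larger shift so all
    three contrasts are exercised).  Returns the mean recovered
    position-vs-control multiplier and its bias.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    base_log = np.log(4.5)
    arm_mult = {"control": 1.0, "eco_position": effect, "eco_position_labels": effect * 0.92}
    estimates = np.empty(n_replicates)
    for rep in range(n_replicates):
        rows = []
        for arm in ECO_ARMS:
            y = np.exp(
                base_log + np.log(arm_mult[arm]) + rng.normal(0, log_sd, n_per_arm)
            )
            rows.append(pd.DataFrame({
                "participant_id": [f"{arm}{i}" for i in range(n_per_arm)],
                "arm": arm,
                "mean_eco": y,
            }))
        results = fit_primary(pd.concat(rows, ignore_index=True), "eco")
        estimates[rep] = results[0].estimate  # eco_position vs control
    mean_estimate = float(estimates.mean())
    return {
        "planted": effect,
        "mean_estimate": mean_estimate,
        "bias": mean_estimate - effect,
        "n_per_arm": n_per_arm,
        "n_replicates": n_replicates,
    }
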