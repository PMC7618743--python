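"""Pre-registered statistical pipeline over simulated (or deposited)
shopping sessions.

Primary outcomes are the basket mean scaled Nutri-Score (identity
scale) and the basket mean eco score (natural-log transformed, with
estimates and 95% CIs exponentiated to multiplicative effects).
Contrasts are OLS arm effects with control as reference, plus a
separate position-vs-position&labels model, at a pre-registered
threshold of p < 0.025.  Secondary nutrient and environmental models
use p < 0.005 (Bonferroni); spill-over models are exploratory with no
threshold.  Basket price is compared by ANOVA: Levene's test first,
then Welch ANOVA + Games-Howell if variances differ (p < 0.05), else
classic ANOVA + Tukey HSD, pairwise at p < 0.025.

Thresholds are applied as fixed comparison cutoffs, exactly as
pre-registered, not as p-value adjustments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.power import TTestIndPower

from .catalog import SHOPPING_LIST
from .cleaning import clean_nutrients
from .ecoscore import INDICATORS
from .nutriscore import score_catalog_health
from .trial import compliance_full

__all__ = [
    "ModelResult",
    "basket_outcomes",
    "compute_basket_outcomes",
    "fit_primary",
    "iqr_outlier_filter",
    "iqr_outlier_mask",
    "fit_secondary",
    "fit_interactions",
    "price_test",
    "fit_spillover",
    "required_sample_size",
    "PowerResult",
    "planned_allocation",
    "decimal_error_sensitivity",
    "label_change_audit",
    "HEALTH_ARMS",
    "ECO_ARMS",
]

HEALTH_ARMS = ("control", "health_position", "health_position_labels")
ECO_ARMS = ("control", "eco_position", "eco_position_labels")

PRIMARY_ALPHA = 0.025
SECONDARY_ALPHA = 0.005


@dataclass(frozen=True)
class ModelResult:
    """One regression/ANOVA contrast on the reporting scale."""

    outcome: str
    reference: str
    comparison: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    transform: str  # "identity" | "exp"
    threshold: float | None  # None marks exploratory analyses
    n: int

    @property
    def significant(self) -> bool | None:
        if self.threshold is None:
            return None
        return self.p < self.threshold

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["significant"] = self.significant
        return d


def results_frame(results: list[ModelResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


# ---------------------------------------------------------------- outcomes

_MEAN_COLUMNS = {
    "mean_nutriscore": "nutriscore_scaled",
    "mean_eco": "eco_composite",
    "mean_energy": "energy_kcal",
    "mean_salt": "salt_g",
    "mean_fat": "fat_g",
    "mean_sugar": "sugar_g",
    "mean_ghg": "ghg",
    "mean_water": "water",
    "mean_biodiversity": "biodiversity",
    "mean_eutrophication": "eutrophication",
}


def basket_outcomes(basket_items: pd.DataFrame, scored_catalog: pd.DataFrame) -> dict:
    """Basket-level outcome summary: per-item means plus total price."""
    if basket_items.empty:
        raise ValueError("empty basket")
    merged = basket_items.merge(
        scored_catalog, on="product_id", how="left", suffixes=("", "_cat")
    )
    needed = set(_MEAN_COLUMNS.values()) | {"price"}
    missing_cols = needed - set(merged.columns)
    if missing_cols:
        raise ValueError(f"catalog not fully scored; missing {sorted(missing_cols)}")
    if merged[list(needed)].isna().any().any():
        bad = merged.loc[merged[list(needed)].isna().any(axis=1), "product_id"]
        raise ValueError(f"unscored catalog items in basket: {bad.tolist()}")
    out = {name: float(merged[col].mean()) for name, col in _MEAN_COLUMNS.items()}
    out["total_price"] = float(merged["price"].sum())
    return out


def compute_basket_outcomes(
    sessions: pd.DataFrame,
    items: pd.DataFrame,
    scored_catalog: pd.DataFrame,
    participants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One outcome row per (included) session, carrying arm and,
    optionally, participant covariates for interaction models.

    Vectorised equivalent of calling :func:`basket_outcomes` per
    basket (one merge + groupby over all included items).
    """
    value_cols = list(_MEAN_COLUMNS.values()) + ["price"]
    missing_cols = set(value_cols) - set(scored_catalog.columns)
    if missing_cols:
        raise ValueError(f"catalog not fully scored; missing {sorted(missing_cols)}")
    keep = items["participant_id"].isin(set(sessions["participant_id"]))
    merged = items.loc[keep].merge(
        scored_catalog[["product_id"] + value_cols], on="product_id", how="left"
    )
    if merged[value_cols].isna().any().any():
        bad = merged.loc[merged[value_cols].isna().any(axis=1), "product_id"]
        raise ValueError(f"unscored catalog items in baskets: {bad.tolist()}")
    g = merged.groupby("participant_id", sort=False)
    outcomes = g[list(_MEAN_COLUMNS.values())].mean()
    outcomes.columns = list(_MEAN_COLUMNS)
    outcomes["total_price"] = g["price"].sum()
    # full compliance: exactly 10 items, all on distinct list shelves
    n_items = g.size()
    is_target = merged["shelf"].isin(SHOPPING_LIST)
    n_target_shelves = (
        merged.loc[is_target].groupby("participant_id", sort=False)["shelf"].nunique()
    )
    outcomes["full_compliance"] = (
        (n_items == 10) & (n_target_shelves.reindex(n_items.index).fillna(0) == 10)
    )
    outcomes = outcomes.reset_index()
    outcomes = outcomes.merge(
        sessions[["participant_id", "arm"]], on="participant_id", how="left"
    )
    if participants is not None:
        covars = ["participant_id", "gender", "age_group", "education",
                  "income", "meat_level"]
        keep = [c for c in covars if c in participants.columns]
        outcomes = outcomes.merge(participants[keep], on="participant_id", how="left")
    return outcomes


# ---------------------------------------------------------------- OLS core

def _ols_contrasts(
    df: pd.DataFrame,
    outcome_col: str,
    outcome_name: str,
    reference: str,
    comparisons: tuple,
    log_transform: bool,
    threshold: float | None,
) -> list[ModelResult]:
    """OLS of outcome on arm indicators; one ModelResult per contrast."""
    arms = (reference,) + tuple(comparisons)
    data = df[df["arm"].isin(arms)].copy()
    y = data[outcome_col].to_numpy(float)
    if log_transform:
        if np.any(y <= 0):
            bad = data.loc[y <= 0, "participant_id"].tolist()
            raise ValueError(f"non-positive {outcome_name} for baskets {bad}")
        data["_y"] = np.log(y)
    else:
        data["_y"] = y
    model = smf.ols(f"_y ~ C(arm, Treatment('{reference}'))", data=data).fit()
    ci = model.conf_int(alpha=0.05)
    results = []
    for comparison in comparisons:
        term = f"C(arm, Treatment('{reference}'))[T.{comparison}]"
        est, lo, hi = model.params[term], ci.loc[term, 0], ci.loc[term, 1]
        if log_transform:
            est, lo, hi = math.exp(est), math.exp(lo), math.exp(hi)
        results.append(ModelResult(
            outcome=outcome_name,
            reference=reference,
            comparison=comparison,
            estimate=float(est),
            ci_low=float(lo),
            ci_high=float(hi),
            p=float(model.pvalues[term]),
            transform="exp" if log_transform else "identity",
            threshold=threshold,
            n=int(model.nobs),
        ))
    return results


def _dimension(dimension: str):
    if dimension == "health":
        return HEALTH_ARMS, "mean_nutriscore", False
    if dimension == "eco":
        return ECO_ARMS, "mean_eco", True
    raise ValueError(f"unknown dimension {dimension!r}")


def fit_primary(outcomes: pd.DataFrame, dimension: str) -> list[ModelResult]:
    """Primary contrasts at p < 0.025.

    Health: untransformed basket mean scaled Nutri-Score; eco: logged
    basket mean eco score with exponentiated estimates/CIs.  Three
    contrasts: position vs control, position&labels vs control (one
    control-referenced model), and position&labels vs position (a
    separate model with the position arm as reference).
    """
    arms, col, logt = _dimension(dimension)
    control, position, position_labels = arms
    results = _ols_contrasts(
        outcomes, col, col, control, (position, position_labels),
        logt, PRIMARY_ALPHA,
    )
    results += _ols_contrasts(
        outcomes, col, col, position, (position_labels,), logt, PRIMARY_ALPHA,
    )
    return results


def iqr_outlier_mask(values) -> np.ndarray:
    """True for values inside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (inclusive).

    Quartiles use linear interpolation (type 7), fixed for
    reproducibility.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 observations for the IQR rule")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    return (values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)


def iqr_outlier_filter(values) -> np.ndarray:
    """Values retained by the 1.5-IQR outlier rule."""
    values = np.asarray(values, dtype=float)
    return values[iqr_outlier_mask(values)]


_SECONDARY = {
    "health": [("mean_energy", False), ("mean_salt", False),
               ("mean_fat", False), ("mean_sugar", False)],
    "eco": [(f"mean_{ind}", True) for ind in INDICATORS],
}


def fit_secondary(outcomes: pd.DataFrame, dimension: str) -> list[ModelResult]:
    """Secondary nutrient (identity) or environmental (log+exp) models,
    intervention arms vs control, at p < 0.005."""
    arms, _, _ = _dimension(dimension)
    control, position, position_labels = arms
    results = []
    for col, logt in _SECONDARY[dimension]:
        results += _ols_contrasts(
            outcomes, col, col, control, (position, position_labels),
            logt, SECONDARY_ALPHA,
        )
    return results


_DROPPED_LEVELS = {
    "gender": ("Other gender identity",),
    "income": ("Prefer not to say",),
}
# Table-2 style merge: "No qualifications" folded into "Up to 4 GCSE's"
_MERGED_LEVELS = {"education": {"No qualifications": "Up to 4 GCSE's"}}


def fit_interactions(
    outcomes: pd.DataFrame, covariate: str, dimension: str
) -> list[ModelResult]:
    """Arm x covariate interaction models at p < 0.005.

    Small categories are handled as in the study: "other gender
    identity" and income "prefer not to say" rows are dropped, the
    lowest education band is merged upward, and rows missing the
    covariate (e.g. no meat score) are excluded.
    """
    allowed = ("gender", "age_group", "education", "income", "meat_level")
    if covariate not in allowed:
        raise ValueError(f"covariate must be one of {allowed}")
    arms, col, logt = _dimension(dimension)
    data = outcomes[outcomes["arm"].isin(arms)].copy()
    data = data.dropna(subset=[covariate])
    for level in _DROPPED_LEVELS.get(covariate, ()):
        data = data[data[covariate] != level]
    merges = _MERGED_LEVELS.get(covariate, {})
    if merges:
        data[covariate] = data[covariate].replace(merges)
    if data[covariate].nunique() < 2:
        raise ValueError(f"covariate {covariate!r} has fewer than two levels")
    y = data[col].to_numpy(float)
    data["_y"] = np.log(y) if logt else y
    model = smf.ols(
        f"_y ~ C(arm, Treatment('control')) * C(Q('{covariate}'))", data=data
    ).fit()
    ci = model.conf_int(alpha=0.05)
    results = []
    for term in model.params.index:
        if ":" not in term:
            continue
        est, lo, hi = model.params[term], ci.loc[term, 0], ci.loc[term, 1]
        if logt:
            est, lo, hi = math.exp(est), math.exp(lo), math.exp(hi)
        results.append(ModelResult(
            outcome=f"{col}:{covariate}",
            reference="control",
            comparison=term,
            estimate=float(est),
            ci_low=float(lo),
            ci_high=float(hi),
            p=float(model.pvalues[term]),
            transform="exp" if logt else "identity",
            threshold=SECONDARY_ALPHA,
            n=int(model.nobs),
        ))
    return results


def price_test(outcomes: pd.DataFrame, dimension: str) -> list[ModelResult]:
    """Basket-price ANOVA with variance-dependent branching.

    Levene's test first; if p < 0.05 a Welch ANOVA with Games-Howell
    post-hoc is used, otherwise classic ANOVA with Tukey HSD.
    Pairwise contrasts carry the p < 0.025 threshold; the omnibus row
    is reported with the same threshold.
    """
    arms, _, _ = _dimension(dimension)
    data = outcomes[outcomes["arm"].isin(arms)]
    groups = [data.loc[data["arm"] == arm, "total_price"].to_numpy(float)
              for arm in arms]
    _, p_levene = scipy.stats.levene(*groups, center="median")
    results = []
    if p_levene < 0.05:
        aov = pg.welch_anova(data=data, dv="total_price", between="arm")
        results.append(ModelResult(
            outcome="total_price[welch_anova]", reference="all", comparison="omnibus",
            estimate=float(aov["F"].iloc[0]), ci_low=math.nan, ci_high=math.nan,
            p=float(aov["p_unc"].iloc[0]), transform="identity",
            threshold=PRIMARY_ALPHA, n=len(data),
        ))
        gh = pg.pairwise_gameshowell(data=data, dv="total_price", between="arm")
        for row in gh.itertuples():
            results.append(ModelResult(
                outcome="total_price[games_howell]", reference=row.A, comparison=row.B,
                estimate=float(-row.diff),  # B - A, matching B-vs-reference-A
                ci_low=math.nan, ci_high=math.nan,
                p=float(row.pval), transform="identity",
                threshold=PRIMARY_ALPHA, n=len(data),
            ))
    else:
        f_stat, p_f = scipy.stats.f_oneway(*groups)
        results.append(ModelResult(
            outcome="total_price[anova]", reference="all", comparison="omnibus",
            estimate=float(f_stat), ci_low=math.nan, ci_high=math.nan,
            p=float(p_f), transform="identity", threshold=PRIMARY_ALPHA, n=len(data),
        ))
        tukey = pairwise_tukeyhsd(
            data["total_price"].to_numpy(float), data["arm"].to_numpy(object),
            alpha=0.05,
        )
        summary = tukey.summary().data[1:]
        for g1, g2, meandiff, p_adj, lower, upper, _reject in summary:
            results.append(ModelResult(
                outcome="total_price[tukey]", reference=str(g1), comparison=str(g2),
                estimate=float(meandiff), ci_low=float(lower), ci_high=float(upper),
                p=float(p_adj), transform="identity",
                threshold=PRIMARY_ALPHA, n=len(data),
            ))
    return results


def fit_spillover(outcomes: pd.DataFrame, dimension: str) -> list[ModelResult]:
    """Exploratory cross-dimension models: health arms on the eco
    outcome (log + exp) and eco arms on the Nutri-Score outcome
    (identity).  No pre-specified significance threshold."""
    if dimension == "health":
        arms, col, logt = HEALTH_ARMS, "mean_eco", True
    elif dimension == "eco":
        arms, col, logt = ECO_ARMS, "mean_nutriscore", False
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    control, position, position_labels = arms
    return _ols_contrasts(
        outcomes, col, f"{col}[spillover]", control, (position, position_labels),
        logt, None,
    )


# ---------------------------------------------------------------- power

@dataclass(frozen=True)
class PowerResult:
    n_pairwise: int          # per group, before non-compliance inflation
    n_per_group: dict        # arm-position -> planned n
    total: int
    f: float
    power: float
    alpha: float
    noncompliance_rate: float


def required_sample_size(
    f: float,
    power: float = 0.9,
    alpha: float = 0.05,
    noncompliance_rate: float = 0.0,
    allocation: tuple = (1, 5, 5, 5, 5),
    inflation: str = "multiply",
) -> PowerResult:
    """Planned sample size from a Cohen's f via the noncentral t.

    The pairwise two-group size uses d = 2f (two equal groups).
    Non-compliance inflates the per-group n either multiplicatively
    (x (1+rate), default, which reproduces the published allocation)
    or by division (/ (1-rate)).  Groups with the largest allocation
    weight receive the inflated pairwise n; others are scaled by their
    weight ratio.  All roundings are upward.
    """
    if not (f > 0 and 0 < power < 1 and 0 < alpha < 1 and
            0 <= noncompliance_rate < 1):
        raise ValueError("infeasible power-analysis parameters")
    d = 2.0 * f
    n_exact = TTestIndPower().solve_power(
        effect_size=d, power=power, alpha=alpha, alternative="two-sided"
    )
    if not np.isfinite(n_exact):
        raise ValueError("power computation did not converge")
    n_pairwise = math.ceil(n_exact)
    if inflation == "multiply":
        n_inflated = math.ceil(n_pairwise * (1.0 + noncompliance_rate))
    elif inflation == "divide":
        n_inflated = math.ceil(n_pairwise / (1.0 - noncompliance_rate))
    else:
        raise ValueError(f"unknown inflation convention {inflation!r}")
    w_max = max(allocation)
    n_per_group = {
        i: math.ceil(n_inflated * w / w_max) for i, w in enumerate(allocation)
    }
    return PowerResult(
        n_pairwise=n_pairwise,
        n_per_group=n_per_group,
        total=sum(n_per_group.values()),
        f=f, power=power, alpha=alpha, noncompliance_rate=noncompliance_rate,
    )


def planned_allocation() -> dict:
    """The trial's planned allocation: the add-on comparison (f = 0.1,
    power 0.9, alpha 0.05, 20% non-compliance) sizes the intervention
    groups; control is 1/5 of an intervention group."""
    res = required_sample_size(
        f=0.1, power=0.9, alpha=0.05, noncompliance_rate=0.2,
        allocation=(1, 5, 5, 5, 5), inflation="multiply",
    )
    return {
        "n_pairwise": res.n_pairwise,
        "control": res.n_per_group[0],
        "per_intervention": res.n_per_group[1],
        "total": res.total,
    }


# ------------------------------------------------- decimal-error sensitivity

def decimal_error_sensitivity(
    catalog_scored: pd.DataFrame,
    sessions: pd.DataFrame,
    items: pd.DataFrame,
    dimension: str = "health",
) -> dict:
    """Re-run the primary models after removing comma-corrupted data.

    (i) drops every corrupted product that was selected at least once
    from all baskets; (ii) drops, from the original data, every
    participant in the position & labels arm who selected a corrupted
    product.  Returns both result lists plus the affected counts.
    """
    if "comma_corrupted" not in catalog_scored.columns:
        raise ValueError("catalog lacks comma-corruption provenance flags")
    corrupted = set(
        catalog_scored.loc[catalog_scored["comma_corrupted"].astype(bool),
                           "product_id"]
    )
    affected_selected = corrupted & set(items["product_id"])
    items_wo = items[~items["product_id"].isin(affected_selected)]
    outcomes_wo = compute_basket_outcomes(sessions, items_wo, catalog_scored)
    without_products = fit_primary(outcomes_wo, dimension)

    labels_arm = ("health_position_labels" if dimension == "health"
                  else "eco_position_labels")
    arm_ids = set(sessions.loc[sessions["arm"] == labels_arm, "participant_id"])
    purchaser_ids = set(
        items.loc[items["product_id"].isin(affected_selected), "participant_id"]
    ) & arm_ids
    sessions_wo = sessions[~sessions["participant_id"].isin(purchaser_ids)]
    outcomes_wp = compute_basket_outcomes(
        sessions_wo, items[~items["participant_id"].isin(purchaser_ids)],
        catalog_scored,
    )
    without_purchasers = fit_primary(outcomes_wp, dimension)
    return {
        "without_affected_products": without_products,
        "without_affected_purchasers": without_purchasers,
        "n_affected_products": len(affected_selected),
        "n_affected_purchasers": len(purchaser_ids),
    }


def label_change_audit(raw_catalog: pd.DataFrame) -> pd.DataFrame:
    """Letter shifts of comma-corrupted products after correction.

    Scores each corrupted product under the legacy (comma-dropping)
    parse and the corrected parse and tabulates the absolute letter
    shift (0 = unchanged), mirroring the study's audit of wrong
    labels.
    """
    corrupted = raw_catalog[raw_catalog["comma_corrupted"].astype(bool)]
    if corrupted.empty:
        return pd.DataFrame({"letter_shift": [], "n": [], "fraction": []})
    legacy_clean = clean_nutrients(corrupted, mode="legacy")
    correct_clean = clean_nutrients(corrupted, mode="corrected")
    required = ["energy_kcal", "sugar_g", "salt_g"]
    ok = (legacy_clean[required].notna().all(axis=1)
          & correct_clean[required].notna().all(axis=1))
    legacy = score_catalog_health(legacy_clean[ok])
    correct = score_catalog_health(correct_clean[ok])
    order = {ltr: i for i, ltr in enumerate("ABCDE")}
    shift = np.abs(
        legacy["health_letter"].map(order).to_numpy()
        - correct["health_letter"].map(order).to_numpy()
    )
    counts = pd.Series(shift).value_counts().sort_index()
    return pd.DataFrame({
        "letter_shift": counts.index,
        "n": counts.to_numpy(),
        "fraction": counts.to_numpy() / len(legacy),
    })
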