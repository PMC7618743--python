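"""Basket outcomes and the pre-registered statistical pipeline."""

import math

import numpy as np
import pandas as pd
import pytest

from shelftrial.analysis import (
    ECO_ARMS,
    HEALTH_ARMS,
    ModelResult,
    basket_outcomes,
    compute_basket_outcomes,
    decimal_error_sensitivity,
    fit_interactions,
    fit_primary,
    fit_secondary,
    fit_spillover,
    iqr_outlier_filter,
    iqr_outlier_mask,
    label_change_audit,
    planned_allocation,
    price_test,
    required_sample_size,
)
from shelftrial.catalog import CatalogConfig, generate_catalog
from shelftrial.cleaning import clean_nutrients
from shelftrial.ecoscore import score_catalog_eco
from shelftrial.nutriscore import score_catalog_health
from shelftrial.trial import generate_participants, simulate_trial, apply_exclusions


# ----------------------------------------------------------- basket means

def _toy_catalog(n=12, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "product_id": [f"P{i}" for i in range(n)],
        "nutriscore_scaled": np.linspace(10, 80, n),
        "eco_composite": np.linspace(2, 60, n),
        "energy_kcal": rng.uniform(50, 400, n),
        "salt_g": rng.uniform(0, 2, n),
        "fat_g": rng.uniform(0, 30, n),
        "sugar_g": rng.uniform(0, 40, n),
        "ghg": rng.lognormal(0, 1, n),
        "water": rng.lognormal(2, 1, n),
        "biodiversity": rng.lognormal(0, 1, n),
        "eutrophication": rng.lognormal(0, 1, n),
        "price": rng.uniform(1, 6, n),
    })


def test_single_item_basket_equals_item():
    cat = _toy_catalog()
    basket = pd.DataFrame({"product_id": ["P3"], "shelf": ["cheese"]})
    out = basket_outcomes(basket, cat)
    row = cat.set_index("product_id").loc["P3"]
    assert out["mean_nutriscore"] == pytest.approx(row["nutriscore_scaled"])
    assert out["total_price"] == pytest.approx(row["price"])


def test_two_item_mean_and_hand_computed_basket():
    cat = _toy_catalog()
    two = pd.DataFrame({"product_id": ["P0", "P1"], "shelf": ["cheese"] * 2})
    out = basket_outcomes(two, cat)
    expected = cat.set_index("product_id").loc[["P0", "P1"], "nutriscore_scaled"].mean()
    assert out["mean_nutriscore"] == pytest.approx(expected)
    ten = pd.DataFrame({"product_id": [f"P{i}" for i in range(10)],
                        "shelf": ["cheese"] * 10})
    out10 = basket_outcomes(ten, cat)
    sub = cat.set_index("product_id").loc[[f"P{i}" for i in range(10)]]
    assert out10["mean_eco"] == pytest.approx(sub["eco_composite"].mean())
    assert out10["total_price"] == pytest.approx(sub["price"].sum())


def test_unscored_item_raises():
    cat = _toy_catalog().drop(columns=["eco_composite"])
    basket = pd.DataFrame({"product_id": ["P1"], "shelf": ["cheese"]})
    with pytest.raises(ValueError, match="not fully scored"):
        basket_outcomes(basket, cat)


def test_empty_basket_raises():
    with pytest.raises(ValueError, match="empty"):
        basket_outcomes(pd.DataFrame(columns=["product_id"]), _toy_catalog())


# ------------------------------------------------------------ primary fits

def _null_outcomes(n_per_arm=40, arms=HEALTH_ARMS, seed=0, col="mean_nutriscore"):
    rng = np.random.default_rng(seed)
    rows = []
    for arm in arms:
        for i in range(n_per_arm):
            rows.append({
                "participant_id": f"{arm}{i}",
                "arm": arm,
                col: rng.normal(35, 3) if col == "mean_nutriscore"
                else rng.lognormal(1.2, 0.4),
            })
    return pd.DataFrame(rows)


def test_primary_null_data_estimates_near_zero():
    out = _null_outcomes(n_per_arm=2000, seed=4)
    results = fit_primary(out, "health")
    assert len(results) == 3
    for r in results:
        assert r.transform == "identity"
        assert r.threshold == 0.025
        assert abs(r.estimate) < 0.5
        assert r.ci_low < 0 < r.ci_high


def test_primary_identical_outcomes_give_exact_null():
    out = _null_outcomes(n_per_arm=30)
    out["mean_nutriscore"] = 35.0
    for r in fit_primary(out, "health"):
        assert r.estimate == pytest.approx(0.0, abs=1e-10)
    eco = _null_outcomes(n_per_arm=30, arms=ECO_ARMS, col="mean_eco")
    eco["mean_eco"] = 4.0
    for r in fit_primary(eco, "eco"):
        assert r.estimate == pytest.approx(1.0, abs=1e-10)  # exp(0)


def test_eco_multiplicative_plant_recovered_exactly():
    """A noise-free 0.76x shift on the eco outcome is recovered as
    exactly 0.76 after exponentiation."""
    base = np.repeat([3.0, 4.0, 5.0, 6.0], 10)
    rows = []
    for arm, mult in zip(ECO_ARMS, (1.0, 0.76, 0.70)):
        for i, b in enumerate(base):
            rows.append({"participant_id": f"{arm}{i}", "arm": arm,
                         "mean_eco": b * mult})
    results = fit_primary(pd.DataFrame(rows), "eco")
    by_cmp = {(r.reference, r.comparison): r for r in results}
    assert by_cmp[("control", "eco_position")].estimate == pytest.approx(0.76)
    assert by_cmp[("control", "eco_position_labels")].estimate == pytest.approx(0.70)
    assert by_cmp[("eco_position", "eco_position_labels")].estimate == pytest.approx(
        0.70 / 0.76
    )
    assert all(r.transform == "exp" for r in results)


def test_eco_nonpositive_outcome_rejected():
    out = _null_outcomes(n_per_arm=10, arms=ECO_ARMS, col="mean_eco")
    out.loc[3, "mean_eco"] = 0.0
    with pytest.raises(ValueError, match="non-positive"):
        fit_primary(out, "eco")


# ------------------------------------------------------------- IQR filter

def test_iqr_constant_vector_kept():
    vals = np.full(10, 7.0)
    assert len(iqr_outlier_filter(vals)) == 10  # bounds inclusive


def test_iqr_hand_example():
    """[1..9, 100]: Q1=3.25, Q3=7.75 (type-7), so the fence is 14.5."""
    vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], dtype=float)
    kept = iqr_outlier_filter(vals)
    assert kept.tolist() == list(range(1, 10))


def test_iqr_symmetric_bounds():
    vals = np.concatenate([np.arange(-10, 11, dtype=float), [100, -100]])
    mask = iqr_outlier_mask(vals)
    assert mask[:-2].all() and not mask[-2:].any()


def test_iqr_needs_four_observations():
    with pytest.raises(ValueError):
        iqr_outlier_filter([1.0, 2.0, 3.0])


# -------------------------------------------------------------- secondary

def test_secondary_planted_ghg_shift():
    rng = np.random.default_rng(8)
    rows = []
    for arm, mult in zip(ECO_ARMS, (1.0, 0.76, 0.76)):
        for i in range(30):
            base = {f"mean_{k}": 1.0 for k in
                    ("ghg", "water", "biodiversity", "eutrophication")}
            base["mean_ghg"] = float(np.exp(rng.normal(0, 0.0))) * mult
            rows.append({"participant_id": f"{arm}{i}", "arm": arm, **base})
    results = fit_secondary(pd.DataFrame(rows), "eco")
    ghg = [r for r in results if r.outcome == "mean_ghg"]
    assert all(r.estimate == pytest.approx(0.76) for r in ghg)
    assert all(r.threshold == 0.005 for r in results)
    assert len(results) == 8  # 4 indicators x 2 contrasts


def test_secondary_health_identity_models():
    out = _null_outcomes(n_per_arm=25)
    for col in ("mean_energy", "mean_salt", "mean_fat", "mean_sugar"):
        out[col] = np.random.default_rng(1).normal(10, 1, len(out))
    results = fit_secondary(out, "health")
    assert len(results) == 8
    assert all(r.transform == "identity" for r in results)


# ------------------------------------------------------------ interactions

def _outcomes_with_covariates(n_per_arm=60, seed=0):
    rng = np.random.default_rng(seed)
    out = _null_outcomes(n_per_arm=n_per_arm, seed=seed)
    out["gender"] = rng.choice(
        ["Female", "Male", "Other gender identity"], size=len(out),
        p=[0.5, 0.47, 0.03],
    )
    out["income"] = rng.choice(
        ["Below £15.5K", "£40K or above", "Prefer not to say"], size=len(out),
        p=[0.45, 0.45, 0.1],
    )
    out["education"] = rng.choice(
        ["No qualifications", "Up to 4 GCSE's", "Bachelor's degree or above"],
        size=len(out),
    )
    out["meat_level"] = rng.choice(["low", "medium", "high"], size=len(out))
    return out


def test_interaction_dropped_categories_absent():
    out = _outcomes_with_covariates()
    res_gender = fit_interactions(out, "gender", "health")
    assert res_gender and all(
        "Other gender identity" not in r.comparison for r in res_gender
    )
    res_income = fit_interactions(out, "income", "health")
    assert res_income and all(
        "Prefer not to say" not in r.comparison for r in res_income
    )
    # lowest education band merged upward
    res_edu = fit_interactions(out, "education", "health")
    assert all("No qualifications" not in r.comparison for r in res_edu)
    assert all(r.threshold == 0.005 for r in res_gender)


def test_interaction_single_level_covariate_rejected():
    out = _outcomes_with_covariates()
    out["meat_level"] = "medium"
    with pytest.raises(ValueError, match="fewer than two"):
        fit_interactions(out, "meat_level", "health")


def test_interaction_detects_planted_subgroup_effect():
    """An effect present only in one subgroup shows up as a small
    interaction p at large n."""
    out = _outcomes_with_covariates(n_per_arm=800, seed=5)
    boost = (out["arm"] == "health_position") & (out["meat_level"] == "medium")
    out.loc[boost, "mean_nutriscore"] += 5.0
    results = fit_interactions(out, "meat_level", "health")
    relevant = [r for r in results
                if "health_position]" in r.comparison and "medium" in r.comparison]
    assert relevant and min(r.p for r in relevant) < 0.005


# -------------------------------------------------------------- price test

def _price_outcomes(sds=(3.0, 3.0, 3.0), means=(24.0, 24.0, 24.0),
                    n=80, seed=0, arms=HEALTH_ARMS):
    rng = np.random.default_rng(seed)
    rows = []
    for arm, m, s in zip(arms, means, sds):
        for i in range(n):
            rows.append({"participant_id": f"{arm}{i}", "arm": arm,
                         "total_price": rng.normal(m, s)})
    return pd.DataFrame(rows)


def test_price_equal_variances_takes_tukey_branch():
    results = price_test(_price_outcomes(seed=2), "health")
    assert results[0].outcome == "total_price[anova]"
    assert any(r.outcome == "total_price[tukey]" for r in results)
    assert all(r.threshold == 0.025 for r in results)


def test_price_heteroscedastic_takes_welch_branch():
    results = price_test(
        _price_outcomes(sds=(1.0, 8.0, 1.0), seed=3, n=150), "health"
    )
    assert results[0].outcome == "total_price[welch_anova]"
    assert any(r.outcome == "total_price[games_howell]" for r in results)


def test_price_identical_groups_nonsignificant():
    results = price_test(_price_outcomes(seed=4, arms=ECO_ARMS), "eco")
    pairwise = [r for r in results if r.comparison != "omnibus"]
    assert all(r.p > 0.025 for r in pairwise)


def test_price_levene_branch_rate_under_null():
    """Under equal variances the classic-ANOVA branch is taken ~95% of
    the time (Levene type-I at 0.05)."""
    classic = 0
    reps = 100
    for seed in range(reps):
        results = price_test(_price_outcomes(seed=seed, n=60), "health")
        classic += results[0].outcome == "total_price[anova]"
    assert 0.85 <= classic / reps <= 1.0


# --------------------------------------------------------------- spillover

def test_spillover_swaps_outcomes_and_is_exploratory():
    out = _null_outcomes(n_per_arm=50, seed=9)
    out["mean_eco"] = np.random.default_rng(9).lognormal(1.2, 0.3, len(out))
    results = fit_spillover(out, "health")
    assert all(r.outcome.startswith("mean_eco") for r in results)
    assert all(r.threshold is None and r.significant is None for r in results)
    assert all(r.transform == "exp" for r in results)
    eco_out = _null_outcomes(n_per_arm=50, arms=ECO_ARMS, seed=10)
    eco_out["mean_nutriscore"] = 35.0
    results = fit_spillover(eco_out, "eco")
    assert all(r.outcome.startswith("mean_nutriscore") for r in results)
    assert all(r.transform == "identity" for r in results)


# ------------------------------------------------------------------ power

def test_power_f01_pairwise_group_size():
    res = required_sample_size(f=0.1, power=0.9, alpha=0.05)
    assert res.n_pairwise == 527


def test_planned_allocation_identity():
    alloc = planned_allocation()
    assert alloc["control"] == 127
    assert alloc["per_intervention"] == 633
    assert alloc["control"] + 4 * alloc["per_intervention"] == alloc["total"] == 2659


def test_noncompliance_inflation_conventions():
    base = required_sample_size(f=0.1, noncompliance_rate=0.0)
    div = required_sample_size(f=0.1, noncompliance_rate=0.2, inflation="divide")
    mult = required_sample_size(f=0.1, noncompliance_rate=0.2, inflation="multiply")
    assert div.n_per_group[1] == math.ceil(base.n_pairwise / 0.8)
    assert mult.n_per_group[1] == math.ceil(base.n_pairwise * 1.2)


def test_power_monotone_in_effect_size():
    sizes = [required_sample_size(f=f).n_pairwise for f in (0.1, 0.25, 0.4)]
    assert sizes == sorted(sizes, reverse=True)


def test_power_rejects_infeasible():
    with pytest.raises(ValueError):
        required_sample_size(f=-0.1)
    with pytest.raises(ValueError):
        required_sample_size(f=0.1, power=1.5)


# ----------------------------------------------- decimal-error sensitivity

def _scored_quirky_catalog(seed=31):
    cfg = CatalogConfig.compact(
        seed=seed, comma_decimal_rate=0.08, trace_word_rate=0.0,
        lt_prefix_rate=0.0, missing_rate=0.0, alcohol_rate=0.0,
    )
    raw = generate_catalog(cfg)
    scored = score_catalog_health(clean_nutrients(raw))
    return raw, score_catalog_eco(scored)


def test_decimal_sensitivity_no_corruption_identical():
    cfg = CatalogConfig.compact(
        seed=32, comma_decimal_rate=0.0, trace_word_rate=0.0,
        lt_prefix_rate=0.0, missing_rate=0.0, alcohol_rate=0.0,
    )
    scored = score_catalog_eco(score_catalog_health(
        clean_nutrients(generate_catalog(cfg))
    ))
    rng = np.random.default_rng(33)
    parts = generate_participants(300, rng)
    sessions, items = simulate_trial(parts, scored, rng)
    included, _ = apply_exclusions(sessions)
    res = decimal_error_sensitivity(scored, included, items)
    assert res["n_affected_products"] == 0
    assert res["n_affected_purchasers"] == 0
    primary = fit_primary(
        compute_basket_outcomes(included, items, scored), "health"
    )
    for a, b in zip(primary, res["without_affected_products"]):
        assert a.estimate == pytest.approx(b.estimate)
        assert a.n == b.n


def test_decimal_sensitivity_hand_counted_exclusions():
    _, scored = _scored_quirky_catalog()
    rng = np.random.default_rng(34)
    parts = generate_participants(400, rng)
    sessions, items = simulate_trial(parts, scored, rng)
    included, _ = apply_exclusions(sessions)
    res = decimal_error_sensitivity(scored, included, items)
    corrupted = set(scored.loc[scored["comma_corrupted"], "product_id"])
    selected_corrupted = corrupted & set(items["product_id"])
    assert res["n_affected_products"] == len(selected_corrupted)
    labels_arm_ids = set(
        included.loc[included["arm"] == "health_position_labels",
                     "participant_id"]
    )
    purchasers = set(
        items.loc[items["product_id"].isin(selected_corrupted),
                  "participant_id"]
    ) & labels_arm_ids
    assert res["n_affected_purchasers"] == len(purchasers)


def test_label_change_audit_reports_shift_distribution():
    raw, _ = _scored_quirky_catalog(seed=35)
    audit = label_change_audit(raw)
    assert audit["fraction"].sum() == pytest.approx(1.0)
    assert set(audit["letter_shift"]).issubset({0, 1, 2, 3, 4})
    # corrupted labels really do shift for some products
    assert (audit.loc[audit["letter_shift"] > 0, "n"].sum()) > 0


def test_label_audit_empty_without_corruption():
    raw = generate_catalog(CatalogConfig.compact(
        seed=36, comma_decimal_rate=0.0, trace_word_rate=0.0,
        lt_prefix_rate=0.0, missing_rate=0.0, alcohol_rate=0.0,
    ))
    assert label_change_audit(raw).empty


# ------------------------------------------------------- pipeline wiring

def test_compute_outcomes_carries_covariates(compact_scored_catalog):
    rng = np.random.default_rng(40)
    parts = generate_participants(150, rng)
    sessions, items = simulate_trial(parts, compact_scored_catalog, rng)
    included, _ = apply_exclusions(sessions)
    out = compute_basket_outcomes(included, items, compact_scored_catalog, parts)
    assert {"gender", "age_group", "education", "income", "meat_level"} <= set(
        out.columns
    )
    assert out["full_compliance"].dtype == bool


def test_model_result_significance_flag():
    r = ModelResult("o", "a", "b", 1.0, 0.5, 1.5, 0.01, "identity", 0.025, 10)
    assert r.significant is True
    r2 = ModelResult("o", "a", "b", 1.0, 0.5, 1.5, 0.03, "identity", 0.025, 10)
    assert r2.significant is False
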