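"""End-to-end RCT simulation: participants, randomisation, shopping.

Participants are randomised 1:5:5:5:5 (control : four interventions)
and complete a shopping task over the ten shopping-list categories,
selecting one product per category from a shelf ordered by the arm's
positioning rule.  Checkout requires 10-15 distinct products.

The shopper is a synthetic stand-in for human choice (the study
measured people): a multinomial logit over the displayed shelf with

    utility = -rank / tau  +  beta_label * grade_value  -  beta_price * price

plus standard Gumbel noise, where ``rank`` is the product's 1-based
display position, ``tau`` is the position-sensitivity scale (larger
tau = flatter position effect; tau = inf with zero betas gives a
uniform chooser), and ``grade_value`` maps the *visible* label letter
A..E to +2..-2 (labels enter only in the two label arms).  With a
finite tau, items on page 1 dominate selection, consistent with
online-supermarket behaviour the positioning intervention exploits.

Study exclusion rules are applied after simulation: incomplete
sessions, more than 20 products, "speeders" (under 30% of the median
completion time), and fewer than 7 covered categories, attributed to
the first failing rule in that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .catalog import SHOPPING_LIST
from .positioning import ARMS, ArmSpec, PAGE_SIZE

__all__ = [
    "ARM_WEIGHTS",
    "BehaviourConfig",
    "randomise_arm",
    "generate_participants",
    "choose_item",
    "run_session",
    "simulate_trial",
    "apply_exclusions",
    "compliance_full",
    "meat_score",
    "MEAT_FREQUENCIES",
]

#: randomisation weights: control 1, each intervention 5
ARM_WEIGHTS = (1, 5, 5, 5, 5)

_GRADE_VALUE = {"A": 2.0, "B": 1.0, "C": 0.0, "D": -1.0, "E": -2.0}

MEAT_FREQUENCIES = (
    "Never",
    "less than once a week",
    "1-2 days a week",
    "3-4 days a week",
    "5-6 days a week",
    "Every day",
)


@dataclass(frozen=True)
class BehaviourConfig:
    """Synthetic-shopper parameters (all exposed; defaults give a
    position- and label-sensitive shopper with realistic adherence)."""

    tau: float = 10.0              # position-sensitivity scale (ranks)
    beta_label: float = 0.3        # utility per visible grade step
    beta_price: float = 0.05       # utility per GBP
    p_skip_adherent: float = 0.02  # per-category skip probability
    p_skip_nonadherent: float = 0.45
    nonadherent_fraction: float = 0.2   # matches the assumed 20% non-compliance
    extra_item_rate: float = 0.15  # Poisson mean of off-list additions
    dropout_rate: float = 0.03     # sessions never completed
    speeder_fraction: float = 0.04
    speeder_time_factor: float = 0.2
    time_mu: float = math.log(480.0)  # log-seconds of completion time
    time_sigma: float = 0.5

    @classmethod
    def null(cls) -> "BehaviourConfig":
        """Uniform chooser: no position, label or price sensitivity."""
        return cls(tau=math.inf, beta_label=0.0, beta_price=0.0)


def randomise_arm(rng: np.random.Generator, n: int | None = None):
    """Assign arm(s) with probabilities 1/21, 5/21, 5/21, 5/21, 5/21."""
    p = np.asarray(ARM_WEIGHTS, dtype=float)
    p /= p.sum()
    draws = rng.choice(len(ARMS), size=n if n is not None else 1, p=p)
    arms = np.asarray(ARMS, dtype=object)[draws]
    return arms if n is not None else str(arms[0])


# Table-2-like marginal distributions for the synthetic population
_DEMOGRAPHICS = {
    "gender": (("Female", "Male", "Other gender identity"),
               (0.514, 0.483, 0.003)),
    "age_group": (("18-24", "25-34", "35-44", "45-54", "55-64", "65+"),
                  (0.105, 0.164, 0.164, 0.167, 0.164, 0.236)),
    "education": (("No qualifications", "Up to 4 GCSE's",
                   "5 or more GCSE's/1 A-level", "2 or more A-levels",
                   "Bachelor's degree or above"),
                  (0.059, 0.163, 0.210, 0.200, 0.368)),
    "income": (("Below £15.5K", "£15.5K-£25K", "£25K-£39K", "£40K or above",
                "Prefer not to say"),
               (0.142, 0.179, 0.244, 0.393, 0.042)),
}
_MEAT_ANSWER_P = (0.12, 0.18, 0.22, 0.18, 0.15, 0.15)
_MEAT_MISSING_RATE = 0.002


def _sample_categorical(rng, levels, probs, n):
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return np.asarray(levels, dtype=object)[rng.choice(len(levels), size=n, p=p)]


def generate_participants(
    n: int,
    rng: np.random.Generator,
    behaviour: BehaviourConfig | None = None,
) -> pd.DataFrame:
    """Randomised participants with demographics and behaviour traits."""
    behaviour = behaviour or BehaviourConfig()
    df = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    df["arm"] = randomise_arm(rng, n)
    for col, (levels, probs) in _DEMOGRAPHICS.items():
        df[col] = _sample_categorical(rng, levels, probs, n)
    for meal in ("breakfast", "lunch", "dinner"):
        answers = rng.choice(6, size=n, p=np.asarray(_MEAT_ANSWER_P))
        answers = answers.astype(float)
        answers[rng.random(n) < _MEAT_MISSING_RATE] = np.nan
        df[f"meat_{meal}"] = answers
    scored = [
        meat_score([b, l, d])
        for b, l, d in zip(df["meat_breakfast"], df["meat_lunch"], df["meat_dinner"])
    ]
    df["meat_points"] = [s[0] for s in scored]
    df["meat_level"] = [s[1] for s in scored]

    nonadherent = rng.random(n) < behaviour.nonadherent_fraction
    df["p_skip"] = np.where(
        nonadherent, behaviour.p_skip_nonadherent, behaviour.p_skip_adherent
    )
    df["tau"] = behaviour.tau
    df["beta_label"] = behaviour.beta_label
    df["beta_price"] = behaviour.beta_price
    df["extra_item_rate"] = behaviour.extra_item_rate
    df["dropout"] = rng.random(n) < behaviour.dropout_rate
    base_time = rng.lognormal(behaviour.time_mu, behaviour.time_sigma, n)
    speeder = rng.random(n) < behaviour.speeder_fraction
    df["completion_time"] = np.where(
        speeder, base_time * behaviour.speeder_time_factor, base_time
    )
    return df


class _ShelfCache:
    """Per-shelf numpy arrays for fast repeated ordering/choice."""

    def __init__(self, scored_catalog: pd.DataFrame):
        required = {"product_id", "shelf", "price", "health_letter", "eco_letter"}
        missing = required - set(scored_catalog.columns)
        if missing:
            raise ValueError(f"catalog not fully scored; missing {sorted(missing)}")
        self.shelves = {}
        for shelf, grp in scored_catalog.groupby("shelf", sort=True):
            grp = grp.sort_values("product_id")
            self.shelves[shelf] = {
                "ids": grp["product_id"].to_numpy(object),
                "price": grp["price"].to_numpy(float),
                "health_letter": grp["health_letter"].to_numpy(object),
                "eco_letter": grp["eco_letter"].to_numpy(object),
                "health_grade": np.array(
                    [_GRADE_VALUE[g] for g in grp["health_letter"]]
                ),
                "eco_grade": np.array([_GRADE_VALUE[g] for g in grp["eco_letter"]]),
            }
        self.all_shelves = list(self.shelves)
        self._bounds: dict = {}

    def letters(self, shelf: str, dimension: str | None) -> np.ndarray:
        data = self.shelves[shelf]
        if dimension == "eco":
            return data["eco_letter"]
        return data["health_letter"]  # control draws ignore the letter anyway

    def key_bounds(self, shelf: str, arm_spec: ArmSpec) -> tuple:
        """Cached per-product (low, high) sort-key bounds for one arm."""
        cache_key = (shelf, arm_spec.arm)
        if cache_key not in self._bounds:
            letters = self.letters(shelf, arm_spec.position_dimension)
            lows = np.array([arm_spec.key_ranges[l][0] for l in letters])
            highs = np.array([arm_spec.key_ranges[l][1] for l in letters])
            self._bounds[cache_key] = (lows, highs)
        return self._bounds[cache_key]


def choose_item(
    ranked_prices: np.ndarray,
    ranked_grades: np.ndarray | None,
    tau: float,
    beta_label: float,
    beta_price: float,
    rng: np.random.Generator,
) -> int:
    """Gumbel-max multinomial choice over a displayed (ranked) shelf.

    Returns the 0-based display rank of the chosen product.  With
    tau = inf and zero betas this is a uniform draw.
    """
    n = len(ranked_prices)
    utility = np.zeros(n)
    if np.isfinite(tau):
        utility -= np.arange(1, n + 1) / tau
    if beta_label != 0.0 and ranked_grades is not None:
        utility += beta_label * ranked_grades
    if beta_price != 0.0:
        utility -= beta_price * ranked_prices
    return int(np.argmax(utility + rng.gumbel(size=n)))


def _select_from_shelf(cache, shelf, arm_spec, participant, rng, chosen_ids):
    """Order one shelf for this session and pick one unchosen item."""
    data = cache.shelves[shelf]
    lows, highs = cache.key_bounds(shelf, arm_spec)
    keys = rng.uniform(lows, highs)
    order = np.lexsort((data["ids"], keys))
    ranked_ids = data["ids"][order]
    ranked_prices = data["price"][order]
    if arm_spec.labels_visible == "health":
        ranked_grades = data["health_grade"][order]
    elif arm_spec.labels_visible == "eco":
        ranked_grades = data["eco_grade"][order]
    else:
        ranked_grades = None
    for _ in range(10):
        rank = choose_item(
            ranked_prices, ranked_grades,
            participant["tau"], participant["beta_label"],
            participant["beta_price"], rng,
        )
        if ranked_ids[rank] not in chosen_ids:
            break
    else:
        return None
    return {
        "product_id": ranked_ids[rank],
        "shelf": shelf,
        "rank": rank + 1,
        "page": rank // PAGE_SIZE + 1,
    }


def run_session(
    participant,
    cache: "_ShelfCache | pd.DataFrame",
    arm_spec: ArmSpec,
    rng: np.random.Generator,
) -> list[dict]:
    """Simulate one participant's shopping session; returns item rows.

    Iterates the ten list categories (each independently skipped with
    ``p_skip``), adds off-list extras at ``extra_item_rate``, and fills
    up to the 10-item checkout minimum from random shelves if needed.
    The 15-item checkout maximum is enforced.
    """
    if isinstance(cache, pd.DataFrame):
        cache = _ShelfCache(cache)
    items: list[dict] = []
    chosen: set = set()
    for shelf in SHOPPING_LIST:
        if rng.random() < participant["p_skip"]:
            continue
        item = _select_from_shelf(cache, shelf, arm_spec, participant, rng, chosen)
        if item is not None:
            items.append(item)
            chosen.add(item["product_id"])
    n_extra = rng.poisson(participant["extra_item_rate"])
    shortfall = max(0, 10 - (len(items) + n_extra))
    n_extra += shortfall  # fill to the checkout minimum
    n_extra = min(n_extra, 15 - len(items))
    for _ in range(n_extra):
        shelf = cache.all_shelves[rng.integers(len(cache.all_shelves))]
        item = _select_from_shelf(cache, shelf, arm_spec, participant, rng, chosen)
        if item is not None:
            items.append(item)
            chosen.add(item["product_id"])
    return items


def simulate_trial(
    participants: pd.DataFrame,
    scored_catalog: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every participant's session.

    Returns ``(sessions, items)``: one row per participant with
    completion status, item/category counts and completion time; and
    the long table of selected items (participant, product, shelf,
    rank and page at selection).
    """
    cache = _ShelfCache(scored_catalog)
    arm_specs = {arm: ArmSpec.for_arm(arm) for arm in ARMS}
    item_rows = []
    session_rows = []
    for participant in participants.to_dict("records"):
        completed = not participant["dropout"]
        items = []
        if completed:
            items = run_session(participant, cache, arm_specs[participant["arm"]], rng)
        covered = {it["shelf"] for it in items if it["shelf"] in SHOPPING_LIST}
        session_rows.append({
            "participant_id": participant["participant_id"],
            "arm": participant["arm"],
            "completed": completed,
            "n_items": len(items),
            "n_categories": len(covered),
            "completion_time": participant["completion_time"],
        })
        for it in items:
            item_rows.append({"participant_id": participant["participant_id"], **it})
    sessions = pd.DataFrame(session_rows)
    items = pd.DataFrame(
        item_rows, columns=["participant_id", "product_id", "shelf", "rank", "page"]
    )
    return sessions, items


#: exclusion rules in the order they are attributed
EXCLUSION_REASONS = ("incomplete", "too_many_items", "speeder", "too_few_categories")


def apply_exclusions(sessions: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the study's exclusion rules; first failing rule wins.

    Rules: did not complete; selected more than 20 products; finished
    in under 30% of the median completion time of completed sessions;
    covered fewer than 7 of the 10 list categories.  Returns the
    included sessions and CONSORT-style per-reason counts.
    """
    completed = sessions["completed"].astype(bool)
    median_time = sessions.loc[completed, "completion_time"].median()
    reasons = pd.Series("", index=sessions.index, dtype=object)
    rule_masks = {
        "incomplete": ~completed,
        "too_many_items": sessions["n_items"] > 20,
        "speeder": sessions["completion_time"] < 0.30 * median_time,
        "too_few_categories": sessions["n_categories"] < 7,
    }
    for reason in EXCLUSION_REASONS:
        mask = rule_masks[reason] & (reasons == "")
        reasons[mask] = reason
    included = sessions.loc[reasons == ""].reset_index(drop=True)
    counts = {reason: int((reasons == reason).sum()) for reason in EXCLUSION_REASONS}
    counts["included"] = len(included)
    counts["total"] = len(sessions)
    return included, counts


def compliance_full(basket_items: pd.DataFrame) -> bool:
    """Full compliance: one product per list category, nothing else."""
    if len(basket_items) != 10:
        return False
    counts = basket_items["shelf"].value_counts()
    return set(counts.index) == set(SHOPPING_LIST) and (counts == 1).all()


def meat_score(answers, scheme: str = "frequency6"):
    """Aggregate three meat/dairy frequency answers into points + level.

    ``frequency6`` (default): answers 0 ("Never") to 5 ("Every day"),
    summed to 0-15, banded low 0-5 / medium 6-10 / high 11-15.
    ``table2``: alternative 0-4 point scheme banded 0-4 / 5-8 / 9-12.
    Missing answers give a missing level (dropped from interaction
    models).
    """
    if scheme == "frequency6":
        max_pts, bands = 5, ((0, 5, "low"), (6, 10, "medium"), (11, 15, "high"))
    elif scheme == "table2":
        max_pts, bands = 4, ((0, 4, "low"), (5, 8, "medium"), (9, 12, "high"))
    else:
        raise ValueError(f"unknown meat-score scheme {scheme!r}")
    pts = []
    for a in answers:
        if isinstance(a, str):
            if a not in MEAT_FREQUENCIES:
                raise ValueError(f"unknown answer {a!r}")
            a = MEAT_FREQUENCIES.index(a)
            if scheme == "table2":
                a = max(0, a - 1)
        if a is None or (isinstance(a, float) and math.isnan(a)):
            return math.nan, None
        a = int(a)
        if not 0 <= a <= max_pts:
            raise ValueError(f"answer {a} outside 0-{max_pts}")
        pts.append(a)
    if len(pts) != 3:
        raise ValueError("expected three answers")
    total = sum(pts)
    for lo, hi, level in bands:
        if lo <= total <= hi:
            return total, level
    raise AssertionError("unreachable")
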