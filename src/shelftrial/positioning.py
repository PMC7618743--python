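"""Label-biased shelf ordering, price-match flagging, and pagination.

The five trial arms order each shelf by a uniform random sort key
drawn per product and sorted ascending.  In the control arm every
product draws from U[1, 6); in the four intervention arms the range
depends on the product's letter on the targeted dimension:

    A: [1, 2)    B: [1.1, 3)    C: [1.2, 4)    D: [1.3, 5)    E: [1.4, 6)

so better-lettered products stochastically precede worse ones (e.g.
P(key_A < key_E) = 0.9609).  Shelves paginate into pages of at most
28 products.  A fixed random 10% of products carry a decoy
"price match" label, identical across arms for a given seed.

Sort keys are drawn fresh per shopping session by default (a config
switch freezes one ordering per arm instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ARMS",
    "LETTERS",
    "PAGE_SIZE",
    "ArmSpec",
    "ShelfLayout",
    "draw_sort_key",
    "draw_sort_keys",
    "order_shelf",
    "flag_price_match",
    "key_dominance",
    "dominance_matrix",
]

ARMS = (
    "control",
    "health_position",
    "health_position_labels",
    "eco_position",
    "eco_position_labels",
)
LETTERS = ("A", "B", "C", "D", "E")
PAGE_SIZE = 28

_CONTROL_RANGE = (1.0, 6.0)
_INTERVENTION_RANGES = {
    "A": (1.0, 2.0),
    "B": (1.1, 3.0),
    "C": (1.2, 4.0),
    "D": (1.3, 5.0),
    "E": (1.4, 6.0),
}


@dataclass(frozen=True)
class ArmSpec:
    """Ordering and labelling rules for one trial arm."""

    arm: str
    key_ranges: dict = field(repr=False)
    labels_visible: str  # "none" | "health" | "eco"
    position_dimension: str | None  # None | "health" | "eco"
    price_match_rate: float = 0.10

    @classmethod
    def for_arm(cls, arm: str) -> "ArmSpec":
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}")
        if arm == "control":
            return cls(
                arm=arm,
                key_ranges={letter: _CONTROL_RANGE for letter in LETTERS},
                labels_visible="none",
                position_dimension=None,
            )
        dimension = "health" if arm.startswith("health") else "eco"
        labels = dimension if arm.endswith("labels") else "none"
        return cls(
            arm=arm,
            key_ranges=dict(_INTERVENTION_RANGES),
            labels_visible=labels,
            position_dimension=dimension,
        )


@dataclass
class ShelfLayout:
    """One arm's per-session ordering of a shelf, split into pages."""

    shelf: str
    product_ids: np.ndarray  # ordered ascending by sort key
    sort_keys: np.ndarray
    session_id: int | None = None

    @property
    def pages(self) -> list[np.ndarray]:
        return [
            self.product_ids[i : i + PAGE_SIZE]
            for i in range(0, len(self.product_ids), PAGE_SIZE)
        ]

    @property
    def page_of_rank(self) -> np.ndarray:
        """0-based page index for each rank position."""
        return np.arange(len(self.product_ids)) // PAGE_SIZE


def draw_sort_key(letter: str, arm_spec: ArmSpec, rng: np.random.Generator) -> float:
    """One uniform sort key in the arm's range for this letter."""
    low, high = arm_spec.key_ranges[letter]
    return float(rng.uniform(low, high))


def draw_sort_keys(letters, arm_spec: ArmSpec, rng: np.random.Generator) -> np.ndarray:
    """Vectorised sort keys for an array of letters."""
    letters = np.asarray(letters)
    lows = np.empty(len(letters))
    highs = np.empty(len(letters))
    for letter, (lo, hi) in arm_spec.key_ranges.items():
        mask = letters == letter
        lows[mask] = lo
        highs[mask] = hi
    return rng.uniform(lows, highs)


def order_shelf(
    shelf: str,
    product_ids,
    letters,
    arm_spec: ArmSpec,
    rng: np.random.Generator,
    session_id: int | None = None,
) -> ShelfLayout:
    """Order one shelf's products by fresh sort keys, ties by id."""
    product_ids = np.asarray(product_ids)
    if len(product_ids) == 0:
        raise ValueError(f"shelf {shelf!r} is empty")
    keys = draw_sort_keys(letters, arm_spec, rng)
    order = np.lexsort((product_ids, keys))  # stable: key, then id
    return ShelfLayout(
        shelf=shelf,
        product_ids=product_ids[order],
        sort_keys=keys[order],
        session_id=session_id,
    )


def flag_price_match(
    product_ids, rng: np.random.Generator, rate: float = 0.10
) -> set:
    """Pick the fixed decoy price-match subset (round(n*rate) products).

    The subset is a function of the seed only, so one study instance
    reuses the same flagged products in every arm.
    """
    product_ids = np.asarray(product_ids)
    k = int(round(len(product_ids) * rate))
    if k == 0:
        return set()
    return set(rng.choice(product_ids, size=k, replace=False).tolist())


def key_dominance(range_x: tuple, range_y: tuple) -> float:
    """Closed-form P(X < Y) for X~U(range_x), Y~U(range_y).

    Integrates P(Y > x) over the density of X piecewise-exactly.
    """
    a, b = map(float, range_x)
    c, d = map(float, range_y)
    if not (b > a and d > c):
        raise ValueError("degenerate uniform range")
    total = 0.0
    # segment of [a,b] entirely below c: P(Y > x) = 1
    lo, hi = a, min(b, c)
    if hi > lo:
        total += hi - lo
    # overlap with [c,d]: P(Y > x) = (d - x)/(d - c)
    lo, hi = max(a, c), min(b, d)
    if hi > lo:
        total += (d * (hi - lo) - (hi**2 - lo**2) / 2.0) / (d - c)
    return total / (b - a)


def dominance_matrix(arm_spec: ArmSpec) -> pd.DataFrame:
    """P(key_i < key_j) for all letter pairs under one arm's ranges."""
    out = pd.DataFrame(index=list(LETTERS), columns=list(LETTERS), dtype=float)
    for li in LETTERS:
        for lj in LETTERS:
            out.loc[li, lj] = key_dominance(
                arm_spec.key_ranges[li], arm_spec.key_ranges[lj]
            )
    return out
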