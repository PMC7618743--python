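"""Parsing and recoding of raw per-100 g nutrient strings.

Retailer nutrient exports arrive as text with a handful of recurring
quirks: decimal commas ("1,2"), verbal near-zero amounts ("trace",
"nil", "negligible"), and detection-limit prefixes ("<0.02").  The
recoding rules implemented here turn those into numeric g/100 g (or
kcal/100 g) values:

* decimal commas between digits become dots;
* "trace"/"nil"/"negligible" become 0 for fat, saturated fat, sugar
  and salt;
* fat/sugar (and saturated fat) values below 0.5 g are recoded to 0;
* salt values below 0.01 g are recoded to 0; a "<"-prefixed salt value
  whose numeric part is at least 0.01 keeps that numeric part
  (e.g. "<0.02" -> 0.02);
* anything unparseable becomes NaN (a missing-value marker picked up
  by the catalog completeness filter), never a silent zero.

A ``legacy`` parse mode reproduces a buggy upstream reader that
treated the decimal comma as a delimiter and kept only the integer
part ("1,2" read as 1); it exists so that the decimal-error
sensitivity analysis has a faithful wrong-label pathway to audit and
remove.
"""

from __future__ import annotations

import math
import re

import numpy as np
import pandas as pd

__all__ = [
    "fix_decimal_commas",
    "parse_nutrient",
    "clean_nutrients",
    "NUTRIENT_KINDS",
    "SODIUM_PER_SALT_MG",
]

#: kinds accepted by :func:`parse_nutrient`
NUTRIENT_KINDS = (
    "energy",
    "fat",
    "satfat",
    "sugar",
    "salt",
    "fibre",
    "protein",
    "fruitveg",
)

#: mg of sodium per g of salt (NaCl is ~40% sodium by mass)
SODIUM_PER_SALT_MG = 400.0

_TRACE_WORDS = frozenset({"trace", "nil", "negligible"})
_TRACE_KINDS = frozenset({"fat", "satfat", "sugar", "salt"})
_COMMA_BETWEEN_DIGITS = re.compile(r"(?<=\d),(?=\d)")

# small-value recode thresholds: numeric entries strictly below the
# threshold are recoded to zero
_ZERO_THRESHOLDS = {"fat": 0.5, "satfat": 0.5, "sugar": 0.5, "salt": 0.01}


def fix_decimal_commas(raw: str) -> str:
    """Replace commas used as decimal separators by dots.

    Only commas flanked by digits are touched; non-numeric strings
    pass through unchanged.
    """
    return _COMMA_BETWEEN_DIGITS.sub(".", raw)


def _to_float(text: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        return math.nan


def parse_nutrient(raw, kind: str, mode: str = "corrected") -> float:
    """Parse one raw nutrient string into a numeric per-100 g value.

    Parameters
    ----------
    raw
        The raw text field (may be None/NaN/empty -> NaN).
    kind
        One of :data:`NUTRIENT_KINDS`.
    mode
        ``"corrected"`` applies the decimal-comma fix; ``"legacy"``
        truncates at the comma instead (the misparse that produced
        wrong labels for comma-formatted products).

    Returns NaN for unparseable input; callers treat NaN as missing.
    """
    if kind not in NUTRIENT_KINDS:
        raise ValueError(f"unknown nutrient kind {kind!r}")
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    text = str(raw).strip()
    if not text:
        return math.nan

    # rule order: comma handling -> trace words -> "<" strip -> thresholds
    if mode == "corrected":
        text = fix_decimal_commas(text)
    elif mode == "legacy":
        text = text.split(",")[0]
    else:
        raise ValueError(f"unknown parse mode {mode!r}")

    if text.lower() in _TRACE_WORDS:
        return 0.0 if kind in _TRACE_KINDS else math.nan

    if text.startswith("<"):
        value = _to_float(text[1:].strip())
    else:
        value = _to_float(text)
    if math.isnan(value):
        return math.nan

    threshold = _ZERO_THRESHOLDS.get(kind)
    if threshold is not None and value < threshold:
        return 0.0
    return value


_COLUMN_KINDS = {
    "energy_str": ("energy_kcal", "energy"),
    "fat_str": ("fat_g", "fat"),
    "satfat_str": ("satfat_g", "satfat"),
    "sugar_str": ("sugar_g", "sugar"),
    "salt_str": ("salt_g", "salt"),
    "fibre_str": ("fibre_g", "fibre"),
    "protein_str": ("protein_g", "protein"),
    "fruitveg_pct_str": ("fruitveg_pct", "fruitveg"),
}


def clean_nutrients(catalog: pd.DataFrame, mode: str = "corrected") -> pd.DataFrame:
    """Add numeric nutrient columns to a raw catalog table.

    Adds ``energy_kcal, fat_g, satfat_g, sugar_g, salt_g, fibre_g,
    protein_g, fruitveg_pct`` plus the derived ``sodium_mg``
    (salt x 400).  The raw string columns are preserved verbatim.
    """
    out = catalog.copy()
    for col, (new, kind) in _COLUMN_KINDS.items():
        if col in out.columns:
            out[new] = np.array(
                [parse_nutrient(v, kind, mode=mode) for v in out[col]], dtype=float
            )
    if "salt_g" in out.columns:
        out["sodium_mg"] = out["salt_g"] * SODIUM_PER_SALT_MG
    return out
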