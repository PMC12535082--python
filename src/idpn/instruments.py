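"""Questionnaire scoring: item-level responses to canonical scale scores.

Supports the instruments used in adolescent NSSI screening batteries:

* Zung Self-rating Anxiety Scale (SAS) and Self-rating Depression Scale
  (SDS): 20 four-point items each, some reverse scored; the *standard
  score* is the raw item sum multiplied by 1.25 and rounded (half up).
* NEO Five-Factor Inventory: 60 five-point items, 27 reverse scored,
  summed into five personality dimensions.
* Family Environment Scale (Chinese version): 90 binary items summed into
  ten family dimensions.
* A 16-type self-harm inventory: per type a frequency code (0, 1, 2-4,
  >=5 times coded 0-3) and a severity code (none..extremely severe coded
  0-4); total NSSI severity is the sum over types of frequency x severity.

Item-to-dimension maps and reverse-item lists are configuration, not code:
the full NEO-FFI and FES-CV keys are copyrighted, so the package ships a
schema plus synthetic default maps for testing (see
:func:`neo_ffi_synthetic_spec` and :func:`fes_cv_synthetic_spec`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NSSI_N_TYPES = 16
NSSI_FREQ_MAX = 3  # codes 0..3 for {0, 1, 2-4, >=5} episodes
NSSI_SEV_MAX = 4  # codes 0..4 for {none .. extremely severe}
NSSI_SEVERITY_MAX = NSSI_N_TYPES * NSSI_FREQ_MAX * NSSI_SEV_MAX  # 192


@dataclass(frozen=True)
class InstrumentSpec:
    """Static description of one questionnaire.

    Items are 1-based. ``standardization`` is ``"none"`` (dimension sums)
    or ``"times-1.25-rounded"`` (Zung standard score).
    """

    instrument_id: str
    n_items: int
    item_range: tuple[int, int]
    reverse_items: frozenset[int] = field(default_factory=frozenset)
    dimension_map: dict[int, str] = field(default_factory=dict)
    standardization: str = "none"

    def __post_init__(self) -> None:
        lo, hi = self.item_range
        if not lo < hi:
            raise ValueError(f"{self.instrument_id}: item_range min must be < max")
        bad = [i for i in self.reverse_items if not 1 <= i <= self.n_items]
        if bad:
            raise ValueError(f"{self.instrument_id}: reverse items out of range: {bad}")
        if self.dimension_map:
            bad = [i for i in self.dimension_map if not 1 <= i <= self.n_items]
            if bad:
                raise ValueError(
                    f"{self.instrument_id}: mapped items out of range: {bad}"
                )
        if self.standardization not in ("none", "times-1.25-rounded"):
            raise ValueError(f"unknown standardization {self.standardization!r}")

    @property
    def dimensions(self) -> list[str]:
        seen: list[str] = []
        for d in self.dimension_map.values():
            if d not in seen:
                seen.append(d)
        return seen


def reverse_score(code: int, item_range: tuple[int, int]) -> int:
    """Reflect an item code about the midpoint of its range.

    The reflection (min + max) - code is an involution: applying it twice
    returns the original code.
    """
    lo, hi = item_range
    if not lo <= code <= hi:
        raise ValueError(f"code {code} outside item range [{lo}, {hi}]")
    return lo + hi - code


def _round_half_up(x: float) -> int:
    # Python's round() is banker's rounding; the scale convention is half-up.
    return int(math.floor(x + 0.5))


def _apply_reversals(items: np.ndarray, spec: InstrumentSpec) -> np.ndarray:
    lo, hi = spec.item_range
    items = np.asarray(items, dtype=float)
    with np.errstate(invalid="ignore"):
        in_range = np.isnan(items) | ((items >= lo) & (items <= hi))
    if not in_range.all():
        bad = np.argwhere(~in_range)
        raise ValueError(
            f"{spec.instrument_id}: out-of-range codes at (respondent, item) "
            f"{[tuple(int(v) for v in b) for b in bad[:5]]}"
        )
    out = items.copy()
    for item in spec.reverse_items:
        out[..., item - 1] = lo + hi - out[..., item - 1]
    return out


def score_standardized(items: np.ndarray, spec: InstrumentSpec) -> int:
    """Zung standard score of one respondent: round(sum x 1.25), half up.

    ``items`` are the raw codes for all ``spec.n_items`` items; reversals
    from ``spec.reverse_items`` are applied first.
    """
    items = np.asarray(items, dtype=float)
    if items.shape != (spec.n_items,):
        raise ValueError(
            f"{spec.instrument_id}: expected {spec.n_items} items, got {items.shape}"
        )
    if np.isnan(items).any():
        missing = np.flatnonzero(np.isnan(items)) + 1
        raise ValueError(f"{spec.instrument_id}: missing items {missing.tolist()}")
    adjusted = _apply_reversals(items, spec)
    return _round_half_up(float(adjusted.sum()) * 1.25)


def score_dimensions(items: np.ndarray, spec: InstrumentSpec) -> dict[str, float]:
    """Per-dimension sums of (reverse-adjusted) item codes for one respondent."""
    if not spec.dimension_map:
        raise ValueError(f"{spec.instrument_id}: empty dimension map")
    unmapped = set(range(1, spec.n_items + 1)) - set(spec.dimension_map)
    if unmapped:
        raise ValueError(
            f"{spec.instrument_id}: items not mapped to a dimension: {sorted(unmapped)}"
        )
    items = np.asarray(items, dtype=float)
    if items.shape != (spec.n_items,):
        raise ValueError(
            f"{spec.instrument_id}: expected {spec.n_items} items, got {items.shape}"
        )
    adjusted = _apply_reversals(items, spec)
    scores: dict[str, float] = {d: 0.0 for d in spec.dimensions}
    for item, dim in spec.dimension_map.items():
        scores[dim] += float(adjusted[item - 1])
    return scores


def score_instrument(responses: pd.DataFrame, spec: InstrumentSpec) -> pd.DataFrame:
    """Score a respondents x items table (columns item_1..item_N plus
    respondent_id) into one row of scores per respondent."""
    item_cols = [f"item_{i}" for i in range(1, spec.n_items + 1)]
    missing = [c for c in item_cols if c not in responses.columns]
    if missing:
        raise ValueError(f"{spec.instrument_id}: missing item columns {missing}")
    rows = []
    for _, row in responses.iterrows():
        items = row[item_cols].to_numpy(dtype=float)
        rec: dict[str, object] = {"respondent_id": row["respondent_id"]}
        if spec.standardization == "times-1.25-rounded":
            rec[spec.instrument_id] = score_standardized(items, spec)
        else:
            rec.update(score_dimensions(items, spec))
        rows.append(rec)
    return pd.DataFrame(rows)


def score_nssi(frequency: np.ndarray, severity: np.ndarray) -> tuple[int, bool]:
    """Total NSSI severity and presence flag for one respondent.

    severity_total = sum over the 16 types of frequency code x severity
    code; a type with frequency 0 contributes 0 regardless of its severity
    code.  The respondent has NSSI iff any frequency code is positive.
    """
    frequency = np.asarray(frequency, dtype=int)
    severity = np.asarray(severity, dtype=int)
    if frequency.shape != (NSSI_N_TYPES,) or severity.shape != (NSSI_N_TYPES,):
        raise ValueError(
            f"expected {NSSI_N_TYPES} (frequency, severity) pairs, got "
            f"{frequency.shape} and {severity.shape}"
        )
    if ((frequency < 0) | (frequency > NSSI_FREQ_MAX)).any():
        raise ValueError(f"frequency codes must lie in 0..{NSSI_FREQ_MAX}")
    if ((severity < 0) | (severity > NSSI_SEV_MAX)).any():
        raise ValueError(f"severity codes must lie in 0..{NSSI_SEV_MAX}")
    total = int((frequency * severity).sum())
    return total, bool((frequency > 0).any())


def score_nssi_table(records: pd.DataFrame) -> pd.DataFrame:
    """Score a table with respondent_id, freq_1..freq_16, sev_1..sev_16."""
    fcols = [f"freq_{i}" for i in range(1, NSSI_N_TYPES + 1)]
    scols = [f"sev_{i}" for i in range(1, NSSI_N_TYPES + 1)]
    missing = [c for c in fcols + scols if c not in records.columns]
    if missing:
        raise ValueError(f"NSSI record table missing columns {missing}")
    rows = []
    for _, row in records.iterrows():
        total, flag = score_nssi(
            row[fcols].to_numpy(dtype=int), row[scols].to_numpy(dtype=int)
        )
        rows.append(
            {
                "respondent_id": row["respondent_id"],
                "nssi_flag": flag,
                "nssi_severity": total,
            }
        )
    return pd.DataFrame(rows)


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of a respondents x items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of totals),
    with sample (ddof=1) variances.  Returns NaN with a warning when the
    total-score variance is zero (alpha is undefined).
    """
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[0] < 2 or items.shape[1] < 2:
        raise ValueError("need at least 2 respondents and 2 items")
    k = items.shape[1]
    item_var = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        import warnings

        warnings.warn("total-score variance is zero; alpha undefined", stacklevel=2)
        return float("nan")
    return (k / (k - 1)) * (1.0 - item_var.sum() / total_var)


# ---------------------------------------------------------------------------
# Built-in instrument specs


def sas_spec() -> InstrumentSpec:
    """Zung Self-rating Anxiety Scale: 20 four-point items, 5 reverse scored."""
    return InstrumentSpec(
        instrument_id="SAS",
        n_items=20,
        item_range=(1, 4),
        reverse_items=frozenset({5, 9, 13, 17, 19}),
        standardization="times-1.25-rounded",
    )


def sds_spec() -> InstrumentSpec:
    """Zung Self-rating Depression Scale: 20 four-point items, 10 reverse scored."""
    return InstrumentSpec(
        instrument_id="SDS",
        n_items=20,
        item_range=(1, 4),
        reverse_items=frozenset({2, 5, 6, 11, 12, 14, 16, 17, 18, 20}),
        standardization="times-1.25-rounded",
    )


NEO_DIMENSIONS = (
    "Neuroticism",
    "Extraversion",
    "Openness",
    "Agreeableness",
    "Conscientiousness",
)

FES_DIMENSIONS = (
    "Cohesion",
    "Expressiveness",
    "Conflict",
    "Independence",
    "Achievement Orientation",
    "Intellectual-Cultural Orientation",
    "Active-Recreational Orientation",
    "Moral-Religious Emphasis",
    "Organization",
    "Control",
)


def neo_ffi_synthetic_spec() -> InstrumentSpec:
    """Synthetic NEO-FFI layout for testing: 60 five-point items in five
    12-item dimension blocks with 27 reverse-scored items spread across
    blocks.  The published item key is copyrighted and is supplied by the
    user as configuration in real analyses."""
    dimension_map = {
        i: NEO_DIMENSIONS[(i - 1) // 12] for i in range(1, 61)
    }
    reverse = frozenset(range(1, 61, 2))  # 30 odd items; trim to 27
    reverse = frozenset(sorted(reverse)[:27])
    return InstrumentSpec(
        instrument_id="NEO-FFI",
        n_items=60,
        item_range=(1, 5),
        reverse_items=reverse,
        dimension_map=dimension_map,
    )


def fes_cv_synthetic_spec() -> InstrumentSpec:
    """Synthetic FES-CV layout for testing: 90 binary items in ten 9-item
    dimension blocks; every third item reverse scored.  The published key
    is copyrighted and is supplied by the user as configuration."""
    dimension_map = {i: FES_DIMENSIONS[(i - 1) // 9] for i in range(1, 91)}
    return InstrumentSpec(
        instrument_id="FES-CV",
        n_items=90,
        item_range=(0, 1),
        reverse_items=frozenset(range(3, 91, 3)),
        dimension_map=dimension_map,
    )
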