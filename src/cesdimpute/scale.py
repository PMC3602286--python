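"""CES-D scale data model: reverse coding, scoring, hDS classification, bounds.

The CES-D is a 20-item self-report depression screen. Each item records the
frequency of a feeling during the previous week on a four-point scale scored
0/1/2/3. Sixteen items are negatively worded and four positively worded; the
positive items are reverse-scored (x -> 3 - x) before summation so that higher
always means more depressive. The total ranges 0-60 and a total >= 16 flags
high depressive symptoms (hDS).

Items live in a pandas DataFrame under columns ``item_01`` .. ``item_20``;
missing responses are NaN. All functions here are vectorised over subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_ITEMS = 20
MAX_ITEM_SCORE = 3
DEFAULT_CUTOFF = 16.0

#: Positions of the positively worded (reverse-scored) items. The instrument's
#: canonical form places them at 4, 8, 12 and 16; configurable everywhere.
DEFAULT_POSITIVE_ITEMS = (4, 8, 12, 16)

ITEM_COLUMNS = tuple(f"item_{i:02d}" for i in range(1, N_ITEMS + 1))

HDS = "hDS"
NHDS = "NhDS"
UNDETERMINED = "undetermined"


def item_column(item_id: int) -> str:
    """Column name for a 1-based item id."""
    if not 1 <= item_id <= N_ITEMS:
        raise ValueError(f"item id must be in 1..{N_ITEMS}, got {item_id}")
    return f"item_{item_id:02d}"


def validate_items(items: pd.DataFrame) -> pd.DataFrame:
    """Check the ItemMatrix invariants and return the item sub-frame as float.

    Raises ``ValueError`` if any of the 20 item columns is absent or if a
    non-missing cell is not an integer in {0, 1, 2, 3}.
    """
    missing_cols = [c for c in ITEM_COLUMNS if c not in items.columns]
    if missing_cols:
        raise ValueError(f"missing item columns: {missing_cols}")
    block = items.loc[:, list(ITEM_COLUMNS)].astype(float)
    vals = block.to_numpy()
    observed = ~np.isnan(vals)
    ok = (vals[observed] >= 0) & (vals[observed] <= MAX_ITEM_SCORE)
    ok &= np.equal(np.mod(vals[observed], 1), 0)
    if not ok.all():
        raise ValueError("item responses must be integers in [0, 3] or missing")
    return block


def reverse_code(
    items: pd.DataFrame,
    positive_items: tuple[int, ...] = DEFAULT_POSITIVE_ITEMS,
) -> pd.DataFrame:
    """Map raw responses to the scored scale: positive items become ``3 - x``.

    Negative items and missing cells are untouched. Applying the function
    twice restores the original matrix (the map is an involution).
    """
    for i in positive_items:
        if not 1 <= int(i) <= N_ITEMS:
            raise ValueError(f"unknown item id in positive_items: {i}")
    out = items.copy()
    block = validate_items(items)
    for i in positive_items:
        col = item_column(int(i))
        out[col] = MAX_ITEM_SCORE - block[col]
    return out


def item_totals(items: pd.DataFrame) -> pd.Series:
    """Row sums over the item columns of a completed frame.

    Unlike :func:`score_total` this accepts fractional values (person-mean
    completions) but still requires every cell to be present and in [0, 3].
    """
    missing_cols = [c for c in ITEM_COLUMNS if c not in items.columns]
    if missing_cols:
        raise ValueError(f"missing item columns: {missing_cols}")
    block = items.loc[:, list(ITEM_COLUMNS)].astype(float)
    if block.isna().any().any():
        raise ValueError("item_totals requires complete rows")
    vals = block.to_numpy()
    if (vals < 0).any() or (vals > MAX_ITEM_SCORE).any():
        raise ValueError("item values must lie in [0, 3]")
    return block.sum(axis=1).rename("cesd_score")


def score_total(items: pd.DataFrame) -> pd.Series:
    """Sum the 20 scored items per subject. Every row must be complete.

    Use :func:`classify_partial` for rows with missing responses.
    """
    block = validate_items(items)
    if block.isna().any().any():
        raise ValueError(
            "score_total requires complete rows; use classify_partial "
            "or an imputation method for rows with missing items"
        )
    return block.sum(axis=1).rename("cesd_score")


def classify_hds(score, cutoff: float = DEFAULT_CUTOFF):
    """hDS iff total score >= cutoff (default 16). Vectorised over arrays."""
    arr = np.asarray(score, dtype=float)
    out = np.where(arr >= cutoff, HDS, NHDS)
    if np.ndim(score) == 0:
        return out.item()
    if isinstance(score, pd.Series):
        return pd.Series(out, index=score.index, name="status")
    return out


def mv_count(items: pd.DataFrame) -> pd.Series:
    """Number of missing items per subject (0..20)."""
    return validate_items(items).isna().sum(axis=1).rename("n_missing")


def classify_partial(
    items: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF
) -> pd.Series:
    """Bound-based status for partially observed rows.

    A subject is ``hDS`` when even the minimum completion (all missing items
    at 0) reaches the cut-off, ``NhDS`` when even the maximum completion (all
    missing at 3) stays below it, and ``undetermined`` otherwise. On complete
    rows this agrees with ``classify_hds(score_total(...))``.
    """
    block = validate_items(items)
    observed_sum = block.sum(axis=1, skipna=True)
    n_missing = block.isna().sum(axis=1)
    lo = observed_sum
    hi = observed_sum + MAX_ITEM_SCORE * n_missing
    status = np.where(
        lo >= cutoff, HDS, np.where(hi < cutoff, NHDS, UNDETERMINED)
    )
    return pd.Series(status, index=items.index, name="status")


@dataclass(frozen=True)
class PrevalenceBound:
    """hDS prevalence range over all completions of the missing items."""

    low_pct: float
    high_pct: float
    denominator: int

    def __post_init__(self):
        if not 0 <= self.low_pct <= self.high_pct <= 100:
            raise ValueError("require 0 <= low_pct <= high_pct <= 100")


def prevalence_bounds(
    n_hds: int, n_nhds: int, n_undetermined: int
) -> PrevalenceBound:
    """Prevalence bounds from determined/undetermined classification counts.

    The lower bound counts only determined hDS subjects (every missing item
    imputed to 0); the upper bound additionally counts every undetermined
    subject as hDS (every missing item imputed to 3).
    """
    if min(n_hds, n_nhds, n_undetermined) < 0:
        raise ValueError("counts must be non-negative")
    denom = n_hds + n_nhds + n_undetermined
    if denom == 0:
        raise ValueError("empty denominator")
    return PrevalenceBound(
        low_pct=100.0 * n_hds / denom,
        high_pct=100.0 * (n_hds + n_undetermined) / denom,
        denominator=denom,
    )


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, the convention used for reported %."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def attach_score_columns(
    cohort: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Add derived ``cesd_score`` and ``hds`` columns (NaN when any item is
    missing). Returns a copy; existing derived columns are refreshed."""
    out = cohort.copy()
    block = validate_items(cohort)
    complete = ~block.isna().any(axis=1)
    total = block.sum(axis=1)
    out["cesd_score"] = np.where(complete, total, np.nan)
    out["hds"] = np.where(complete, (total >= cutoff).astype(float), np.nan)
    return out


def load_items_csv(
    path,
    raw: bool = False,
    positive_items: tuple[int, ...] = DEFAULT_POSITIVE_ITEMS,
    na_values=("", "NA"),
) -> pd.DataFrame:
    """Read a wide cohort CSV (items + covariates); optionally reverse-code.

    ``raw=True`` flags that item columns are on the raw response scale and
    applies :func:`reverse_code` on ingestion, so everything downstream works
    on the scored scale.
    """
    df = pd.read_csv(path, na_values=list(na_values), comment="#")
    validate_items(df)
    if raw:
        df = reverse_code(df, positive_items=positive_items)
    return df
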