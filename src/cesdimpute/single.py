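"""Deterministic single-imputation comparators: minimum, maximum, person-mean.

These are the naive strategies multiple imputation is benchmarked against:
set every missing item to 0 (minimum), to 3 (maximum), or to the mean of the
subject's own observed items (person-mean, fractional values allowed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .scale import (
    DEFAULT_CUTOFF,
    ITEM_COLUMNS,
    MAX_ITEM_SCORE,
    item_totals,
    mv_count,
    validate_items,
)

STRATEGIES = ("min", "max", "person_mean")


class SingleImputer(BaseEstimator, TransformerMixin):
    """Fill missing CES-D items with a deterministic rule.

    Parameters
    ----------
    strategy : {"min", "max", "person_mean"}
        ``min`` imputes 0, ``max`` imputes 3, ``person_mean`` imputes the
        subject's observed-item mean (requires at least one observed item
        per row; fully missing rows raise).

    The transformer is stateless: ``fit`` only validates input. Observed
    cells and non-item columns pass through unchanged.
    """

    def __init__(self, strategy: str = "person_mean"):
        self.strategy = strategy

    def fit(self, X: pd.DataFrame, y=None):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        validate_items(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        block = validate_items(X)
        out = X.copy()
        if self.strategy == "min":
            filled = block.fillna(0.0)
        elif self.strategy == "max":
            filled = block.fillna(float(MAX_ITEM_SCORE))
        else:
            n_obs = block.notna().sum(axis=1)
            if (n_obs == 0).any():
                raise ValueError(
                    "person-mean imputation is undefined for subjects with "
                    "all 20 items missing; drop those rows first"
                )
            person_mean = block.mean(axis=1, skipna=True)
            filled = block.apply(lambda col: col.fillna(person_mean))
        out[list(ITEM_COLUMNS)] = filled
        return out


def impute_min(items: pd.DataFrame) -> pd.DataFrame:
    """Every missing item set to 0."""
    return SingleImputer("min").fit(items).transform(items)


def impute_max(items: pd.DataFrame) -> pd.DataFrame:
    """Every missing item set to 3."""
    return SingleImputer("max").fit(items).transform(items)


def impute_person_mean(items: pd.DataFrame) -> pd.DataFrame:
    """Every missing item set to the subject's observed-item mean.

    The completed total equals ``observed_sum * 20 / n_observed``; values are
    kept fractional (not rounded back to the 0-3 grid) so totals are exact.
    """
    return SingleImputer("person_mean").fit(items).transform(items)


def single_imputation_summary(
    cohort: pd.DataFrame,
    strategy: str,
    cutoff: float = DEFAULT_CUTOFF,
    strata: tuple[int, ...] = (20, 10, 4),
) -> pd.DataFrame:
    """Score summary after single imputation, per missing-count stratum.

    Rows follow the comparative-table layout: one row per inclusive ceiling
    ``0 - k MV`` with N, mean, SD, SEM of the mean, and % >= cutoff. For the
    person-mean strategy, subjects with all items missing are excluded (the
    ceiling is effectively 19).
    """
    n_mv = mv_count(cohort)
    rows = []
    for k in strata:
        kk = min(k, 19) if strategy == "person_mean" else k
        sub = cohort.loc[n_mv <= kk]
        completed = SingleImputer(strategy).fit(sub).transform(sub)
        total = item_totals(completed)
        n = len(total)
        sd = float(total.std(ddof=1))
        rows.append(
            {
                "method": strategy,
                "stratum": f"0-{kk}",
                "n": n,
                "mean": float(total.mean()),
                "sd": sd,
                "sem": sd / np.sqrt(n),
                "prev_pct": 100.0 * float((total >= cutoff).mean()),
            }
        )
    return pd.DataFrame(rows)
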