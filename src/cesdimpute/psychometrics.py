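"""Scale-validation statistics: Cronbach's alpha and PCA eigenvalues."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scale import ITEM_COLUMNS, validate_items


def _item_block(items: pd.DataFrame) -> pd.DataFrame:
    """Full 20-item cohorts go through ItemMatrix validation; smaller toy
    matrices are accepted as-is (any complete numeric frame)."""
    if all(c in items.columns for c in ITEM_COLUMNS):
        return validate_items(items)
    return items.astype(float)


def cronbach_alpha(items: pd.DataFrame, ddof: int = 1) -> float:
    """Internal-consistency coefficient for a complete item matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total),
    with the same variance denominator convention (ddof) throughout.
    """
    block = _item_block(items)
    if block.isna().any().any():
        raise ValueError("cronbach_alpha requires complete rows")
    arr = block.to_numpy()
    n, k = arr.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 items and 2 subjects")
    total_var = arr.sum(axis=1).var(ddof=ddof)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = arr.var(axis=0, ddof=ddof).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def pca_spectrum(items: pd.DataFrame) -> np.ndarray:
    """Eigenvalues of the item correlation matrix, non-increasing.

    Correlation (not covariance) scale: items share a response format but
    differ in spread, and first-eigenvalue dominance is conventionally judged
    on correlations. The eigenvalues are non-negative and sum to the number
    of items.
    """
    block = _item_block(items)
    if block.isna().any().any():
        raise ValueError("pca_spectrum requires complete rows")
    arr = block.to_numpy()
    if (arr.std(axis=0) == 0).any():
        raise ValueError("constant item column: correlation undefined")
    corr = np.corrcoef(arr, rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    return np.clip(eig, 0.0, None)


def psychometric_report(items: pd.DataFrame, n_eigen: int = 5) -> dict:
    """Summary block: alpha plus the leading eigenvalues and their ratio."""
    eig = pca_spectrum(items)
    return {
        "cronbach_alpha": cronbach_alpha(items),
        "eigenvalues": [float(v) for v in eig[:n_eigen]],
        "lambda1_over_lambda2": float(eig[0] / eig[1]),
    }
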