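"""MCAR amputation and the imputation-accuracy benchmark.

The benchmark deletes item values completely at random from a complete
cohort — a fixed fraction of subjects each lose exactly k items — then
re-imputes them and compares four indicators (mean score, score variance,
SEM of the mean, hDS prevalence) against the pre-amputation truth, across
k = 1..19 and across imputation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .mice import MICEImputer, pooled_score_summary
from .scale import DEFAULT_CUTOFF, ITEM_COLUMNS, N_ITEMS, item_totals, validate_items
from .single import SingleImputer
from .synthetic import observed_incomplete_fraction


@dataclass
class AmputationDesign:
    """MCAR deletion plan: ``subject_fraction`` of subjects each lose exactly
    ``k`` uniformly chosen items. The default fraction is the incomplete-
    responder rate derived from the printed cohort totals (44.8%)."""

    subject_fraction: float = field(
        default_factory=observed_incomplete_fraction
    )
    k: int = 5
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 <= self.subject_fraction <= 1.0:
            raise ValueError("subject_fraction must be in [0, 1]")
        if not 1 <= self.k <= N_ITEMS - 1:
            raise ValueError(f"k must be in [1, {N_ITEMS - 1}]")


class MCARAmputer(BaseEstimator, TransformerMixin):
    """Transformer deleting exactly k items for a random subject subset.

    Deletions are independent of all values (MCAR by construction) and fully
    reproducible under ``random_state``.
    """

    def __init__(
        self,
        subject_fraction: float | None = None,
        k: int = 5,
        random_state: int | None = None,
    ):
        self.subject_fraction = subject_fraction
        self.k = k
        self.random_state = random_state

    def _design(self) -> AmputationDesign:
        frac = (
            observed_incomplete_fraction()
            if self.subject_fraction is None
            else self.subject_fraction
        )
        design = AmputationDesign(
            subject_fraction=frac, k=self.k, seed=self.random_state
        )
        design.validate()
        return design

    def fit(self, X: pd.DataFrame, y=None):
        self._design()
        if validate_items(X).isna().any().any():
            raise ValueError("amputation requires a complete cohort")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        design = self._design()
        items = validate_items(X)
        if items.isna().any().any():
            raise ValueError("amputation requires a complete cohort")
        rng = np.random.default_rng(design.seed)
        n = len(X)
        n_amp = int(round(design.subject_fraction * n))
        subjects = rng.choice(n, size=n_amp, replace=False)
        block = items.to_numpy(copy=True)
        for i in subjects:
            cols = rng.choice(N_ITEMS, size=design.k, replace=False)
            block[i, cols] = np.nan
        out = X.copy()
        out[list(ITEM_COLUMNS)] = block
        return out


def ampute_mcar(cohort: pd.DataFrame, design: AmputationDesign) -> pd.DataFrame:
    """Functional form of :class:`MCARAmputer`."""
    design.validate()
    return MCARAmputer(
        subject_fraction=design.subject_fraction,
        k=design.k,
        random_state=design.seed,
    ).fit(cohort).transform(cohort)


def _indicators(total: np.ndarray, cutoff: float) -> dict:
    n = len(total)
    sd = float(np.std(total, ddof=1))
    return {
        "mean": float(np.mean(total)),
        "variance": sd**2,
        "sem": sd / np.sqrt(n),
        "prev_pct": 100.0 * float(np.mean(total >= cutoff)),
    }


def run_accuracy_study(
    complete_cohort: pd.DataFrame,
    k_range=range(1, 20),
    methods: tuple = ("person_mean", "mi_pmm", "mi_polyreg"),
    reps: int = 10,
    subject_fraction: float | None = None,
    m: int = 5,
    n_iter: int = 5,
    seed: int | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Accuracy indicators per (k, method), averaged over replicates.

    Multiple-imputation methods use the parsimonious item-level model and
    Rubin pooling; person-mean is the deterministic comparator. The returned
    table carries one ``truth`` row (pre-amputation indicators, identical for
    every method) plus ``len(k_range) * len(methods)`` method rows.
    """
    if not methods:
        raise ValueError("methods must be non-empty")
    truth_total = item_totals(complete_cohort).to_numpy()
    rows = [{"k": 0, "method": "truth", "reps": 1,
             **_indicators(truth_total, cutoff)}]
    ss = np.random.SeedSequence(seed)

    def _child_seed(*key) -> int:
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=key)
        return int(child.generate_state(1)[0] % (2**31))

    acc: dict[tuple, list] = {(int(k), meth): [] for k in k_range for meth in methods}
    for k in k_range:
        for rep in range(reps):
            # one amputation shared by every method, so method-to-method
            # differences are not confounded with deletion noise
            amputed = MCARAmputer(
                subject_fraction=subject_fraction,
                k=int(k),
                random_state=_child_seed(int(k), 0, rep),
            ).fit(complete_cohort).transform(complete_cohort)
            for mi, method in enumerate(methods):
                if method == "person_mean":
                    done = SingleImputer("person_mean").fit(amputed).transform(amputed)
                    total = item_totals(done).to_numpy()
                    acc[(int(k), method)].append(_indicators(total, cutoff))
                elif method in ("mi_pmm", "mi_polyreg"):
                    imputer = MICEImputer(
                        structure="items_parsimonious",
                        method=method.removeprefix("mi_"),
                        m=m,
                        n_iter=n_iter,
                        random_state=_child_seed(int(k), mi + 1, rep),
                        cutoff=cutoff,
                    )
                    sets = imputer.fit_impute(amputed)
                    summ = pooled_score_summary(sets, cutoff=cutoff)
                    acc[(int(k), method)].append(
                        {
                            "mean": summ["mean"],
                            "variance": summ["sd"] ** 2,
                            "sem": summ["sem"],
                            "prev_pct": summ["prev_pct"],
                        }
                    )
                else:
                    raise ValueError(f"unknown method {method!r}")
    rep_rows = []
    for (k, method), recs in acc.items():
        df = pd.DataFrame(recs)
        mc_sd = df.std(ddof=1) if reps > 1 else df.iloc[0] * 0.0
        rows.append(
            {
                "k": k, "method": method, "reps": reps,
                **df.mean().to_dict(),
                **{f"{c}_mc_sd": float(mc_sd[c]) for c in df.columns},
            }
        )
        for rep, rec in enumerate(recs):
            rep_rows.append({"k": k, "method": method, "rep": rep, **rec})
    table = pd.DataFrame(rows)
    # per-replicate indicator values (paired across methods by shared
    # amputation) for Monte-Carlo-error comparisons
    table.attrs["reps"] = pd.DataFrame(rep_rows)
    return table


def plot_accuracy_study(table: pd.DataFrame, path) -> None:
    """Indicator-vs-k curves, one per method, dotted truth reference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    indicators = ["mean", "variance", "sem", "prev_pct"]
    truth = table.loc[table["method"] == "truth"].iloc[0]
    body = table.loc[table["method"] != "truth"]
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for ax, ind in zip(axes.ravel(), indicators):
        for method, grp in body.groupby("method"):
            ax.plot(grp["k"], grp[ind], marker="o", ms=3, label=method)
        ax.axhline(truth[ind], ls=":", color="k", label="truth")
        ax.set_title(ind)
        ax.set_xlabel("missing items per amputated subject (k)")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
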