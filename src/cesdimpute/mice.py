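"""Multiple imputation by chained equations (MICE) with Rubin's-rules pooling.

The engine iterates variable by variable: each variable with missing cells is
modelled conditionally on the current completions of its predictors and
re-imputed, for a fixed number of cycles, independently ``m`` times. Three
elementary imputation methods are provided:

``pmm``
    Predictive mean matching on a Bayesian linear regression. Regression
    coefficients are drawn from their posterior (scaled-inverse-chi-square
    variance, conditional normal coefficients); each missing case copies the
    observed value of one of the ``donor_k`` observed cases whose (unperturbed)
    predictions are closest to the case's perturbed prediction. Imputations
    are therefore always members of the observed support.
``polyreg``
    Polytomous (multinomial) logistic regression with a small ridge penalty.
    Parameter uncertainty enters by refitting on a bootstrap resample of the
    observed rows; imputations are sampled from the predicted category
    probabilities.
``logreg``
    The two-category special case of ``polyreg``.

Four model structures mirror the analysis designs: impute the total score
(``score_pmm``), the binary hDS status (``status_logreg``), or the individual
items from the other items alone (``items_parsimonious``) or from the items
plus the covariate block (``items_full``).

Nonignorable (MNAR) scenarios hook into the two sampling steps: category
probabilities are tilted by odds ratios before sampling, and pmm predictions
are shifted by a constant before donor matching (see
:mod:`cesdimpute.mnar`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from . import mnar as _mnar
from .scale import (
    DEFAULT_CUTOFF,
    DEFAULT_POSITIVE_ITEMS,
    ITEM_COLUMNS,
    attach_score_columns,
    validate_items,
)

logger = logging.getLogger(__name__)

ITEM_LEVELS = (0.0, 1.0, 2.0, 3.0)
STRUCTURES = ("score_pmm", "status_logreg", "items_parsimonious", "items_full")
METHODS = ("pmm", "logreg", "polyreg", "none")

_PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Specifications and result containers
# ---------------------------------------------------------------------------


@dataclass
class ImputationSpec:
    """Complete description of one chained-equations run.

    Attributes
    ----------
    methods : mapping of target variable -> elementary method name.
    predictors : boolean DataFrame, rows = target variables, columns =
        predictor variables; ``predictors.loc[v, u]`` says u predicts v.
    m : number of imputations (>= 2).
    n_iter : chained-equation cycles per imputation.
    donor_k : pmm donor-pool size.
    ridge : L2 penalty for categorical fits and the linear normal equations.
    seed : master seed; child streams are spawned per imputation.
    levels : category support per categorical target.
    """

    methods: dict
    predictors: pd.DataFrame
    m: int = 5
    n_iter: int = 10
    donor_k: int = 5
    ridge: float = 1e-4
    seed: int | None = None
    levels: dict = field(default_factory=dict)

    def targets(self) -> list:
        return [v for v, meth in self.methods.items() if meth != "none"]

    def validate(self, data: pd.DataFrame) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.donor_k < 1:
            raise ValueError("donor_k must be >= 1")
        for v, meth in self.methods.items():
            if meth not in METHODS:
                raise ValueError(f"unknown method {meth!r} for {v!r}")
            if v not in data.columns:
                raise ValueError(f"target variable {v!r} not in data")
            if meth != "none" and data[v].notna().sum() == 0:
                raise ValueError(
                    f"variable {v!r} is 100% missing; imputation unsupported"
                )
            if v in self.predictors.columns and v in self.predictors.index:
                if bool(self.predictors.loc[v, v]):
                    raise ValueError(f"variable {v!r} predicts itself")
        targets = set(self.targets())
        for v in self.predictors.index:
            for u in self.predictors.columns[self.predictors.loc[v]]:
                if u not in data.columns:
                    raise ValueError(f"predictor {u!r} not in data")
                if data[u].isna().any() and u not in targets:
                    raise ValueError(
                        f"predictor {u!r} has missing cells but no "
                        "imputation method"
                    )


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin combination of m completed-data estimates.

    total_var = W + (1 + 1/m) B where W is the mean within-imputation
    variance and B the between-imputation (sample) variance of the point
    estimates.
    """

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


@dataclass
class CompletedSets:
    """The m completed datasets plus the spec and convergence trace."""

    datasets: list
    spec: ImputationSpec
    trace: pd.DataFrame

    def __len__(self) -> int:
        return len(self.datasets)


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Combine m point estimates and their complete-data variances."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = est.size
    if m < 2 or var.size != m:
        raise ValueError("pooling requires m >= 2 estimates with variances")
    within = float(var.mean())
    between = float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    return PooledEstimate(
        estimate=float(est.mean()),
        within_var=within,
        between_var=between,
        total_var=total,
        m=m,
    )


# ---------------------------------------------------------------------------
# Model structures
# ---------------------------------------------------------------------------


def covariate_columns(cohort: pd.DataFrame) -> list:
    """Every column that is neither an item nor a derived score column."""
    skip = set(ITEM_COLUMNS) | {"cesd_score", "hds"}
    return [c for c in cohort.columns if c not in skip]


def build_model(
    structure: str,
    cohort: pd.DataFrame,
    method: str = "pmm",
    covariates: list | None = None,
    m: int = 5,
    n_iter: int = 10,
    donor_k: int = 5,
    ridge: float = 1e-4,
    seed: int | None = None,
) -> ImputationSpec:
    """Construct the ImputationSpec for one of the four model structures.

    ``method`` selects pmm vs polyreg for the item-level structures and is
    ignored for ``score_pmm`` / ``status_logreg`` whose methods are fixed.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; choose from {STRUCTURES}")
    if covariates is None:
        covariates = covariate_columns(cohort)
    items = list(ITEM_COLUMNS)
    levels: dict = {}
    if structure == "score_pmm":
        targets = {"cesd_score": "pmm"}
        pred_cols = covariates
        preds = {"cesd_score": covariates}
    elif structure == "status_logreg":
        targets = {"hds": "logreg"}
        pred_cols = covariates
        preds = {"hds": covariates}
        levels["hds"] = (0.0, 1.0)
    else:
        if method not in ("pmm", "polyreg"):
            raise ValueError("item-level structures use method 'pmm' or 'polyreg'")
        targets = {c: method for c in items}
        extra = covariates if structure == "items_full" else []
        pred_cols = items + extra
        preds = {c: [o for o in items if o != c] + extra for c in items}
        if method == "polyreg":
            for c in items:
                levels[c] = ITEM_LEVELS
    matrix = pd.DataFrame(
        False, index=list(targets), columns=pred_cols, dtype=bool
    )
    for v, cols in preds.items():
        matrix.loc[v, cols] = True
    return ImputationSpec(
        methods=targets,
        predictors=matrix,
        m=m,
        n_iter=n_iter,
        donor_k=donor_k,
        ridge=ridge,
        seed=seed,
        levels=levels,
    )


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def _design(df: pd.DataFrame, cols) -> np.ndarray:
    """Numeric design matrix (no intercept column): numeric columns as float,
    categorical columns one-hot encoded with the first level dropped."""
    parts = []
    for c in cols:
        s = df[c]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            d = pd.get_dummies(s, drop_first=True, dtype=float)
            if d.shape[1]:
                parts.append(d.to_numpy())
        else:
            parts.append(s.to_numpy(dtype=float)[:, None])
    if not parts:
        return np.empty((len(df), 0))
    return np.column_stack(parts)


# ---------------------------------------------------------------------------
# Elementary imputation methods
# ---------------------------------------------------------------------------


def pmm_impute_variable(
    y: np.ndarray,
    miss: np.ndarray,
    X: np.ndarray,
    donor_k: int,
    ridge: float,
    rng: np.random.Generator,
    delta: float = 0.0,
) -> np.ndarray:
    """Predictive-mean-matching draws for the missing entries of ``y``.

    Returns the full vector with missing entries replaced by donor copies.
    ``delta`` shifts the missing cases' predictions before matching (the MNAR
    continuous-path adjustment); donors keep their unshifted predictions.
    """
    if not miss.any():
        return y.copy()
    X1 = np.column_stack([np.ones(len(X)), X])
    Xo, yo = X1[~miss], y[~miss]
    Xm = X1[miss]
    n, p = Xo.shape
    lam = ridge if n > p else max(ridge, 1e-2)
    if n <= p:
        logger.warning(
            "pmm: %d observed rows for %d parameters; ridge raised to %.3g",
            n, p, lam,
        )
    XtX = Xo.T @ Xo
    scale = np.maximum(np.sqrt(np.diag(XtX)), 1.0)
    A = XtX + lam * np.diag(scale**2)
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        logger.warning("pmm: singular penalised design; ridge escalated")
        A = XtX + np.eye(p) * (np.trace(XtX) / p * 1e-3 + 1e-8)
        L = np.linalg.cholesky(A)
    beta = np.linalg.solve(A, Xo.T @ yo)
    resid = yo - Xo @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    # beta* ~ N(beta, sigma2 * A^-1): solve L^T z = eps
    eps = rng.standard_normal(p)
    beta_star = beta + np.sqrt(sigma2) * np.linalg.solve(L.T, eps)
    pred_obs = Xo @ beta
    pred_mis = _mnar.shift_mean(Xm @ beta_star, delta)
    k = min(donor_k, n)
    dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
    dist += rng.random(dist.shape) * 1e-9  # uniform tie-breaking
    part = np.argpartition(dist, k - 1, axis=1)[:, :k]
    choice = part[np.arange(part.shape[0]), rng.integers(0, k, part.shape[0])]
    out = y.copy()
    out[miss] = yo[choice]
    return out


def _categorical_draw(
    y: np.ndarray,
    miss: np.ndarray,
    X: np.ndarray,
    levels: tuple,
    ridge: float,
    rng: np.random.Generator,
    theta: np.ndarray | None = None,
) -> np.ndarray:
    """Bootstrap-refit multinomial draw for the missing entries of ``y``.

    Every level in ``levels`` receives at least a floor probability, so a
    category absent from the observed rows is never impossible. ``theta``
    (length ``len(levels)``, first entry 1) tilts the probabilities by odds
    ratios before sampling — the MNAR categorical-path adjustment.
    """
    if not miss.any():
        return y.copy()
    levels_arr = np.asarray(levels, dtype=float)
    yo = y[~miss]
    Xo, Xm = X[~miss], X[miss]
    n = len(yo)
    n_mis = int(miss.sum())
    probs = np.full((n_mis, len(levels_arr)), _PROB_FLOOR)
    observed_levels = np.unique(yo)
    if observed_levels.size < 2:
        j = int(np.argmin(np.abs(levels_arr - observed_levels[0])))
        probs[:, j] += 1.0
    else:
        boot = rng.integers(0, n, n)
        if np.unique(yo[boot]).size < 2:
            boot = np.arange(n)  # degenerate resample: fall back to full fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LogisticRegression(
                C=1.0 / max(ridge * n, 1e-10), max_iter=200, tol=1e-3
            )
            clf.fit(Xo[boot], yo[boot])
            fitted = clf.predict_proba(Xm)
        for j, cls in enumerate(clf.classes_):
            col = int(np.argmin(np.abs(levels_arr - cls)))
            probs[:, col] += fitted[:, j]
    if theta is None:
        theta = np.ones(len(levels_arr))
    probs = _mnar.shift_category_probs(probs, theta[1:])
    cum = np.cumsum(probs, axis=1)
    u = rng.random(n_mis)
    idx = (u[:, None] > cum).sum(axis=1)
    out = y.copy()
    out[miss] = levels_arr[np.minimum(idx, len(levels_arr) - 1)]
    return out


def polyreg_impute_variable(y, miss, X, levels, ridge, rng, theta=None):
    """Polytomous-regression imputation (see :func:`_categorical_draw`)."""
    return _categorical_draw(y, miss, X, levels, ridge, rng, theta)


def logreg_impute_variable(y, miss, X, ridge, rng, theta=None):
    """Binary logistic imputation: polyreg with two levels."""
    return _categorical_draw(y, miss, X, (0.0, 1.0), ridge, rng, theta)


# ---------------------------------------------------------------------------
# The chained-equations loop
# ---------------------------------------------------------------------------


def _impute_once(
    data: pd.DataFrame,
    spec: ImputationSpec,
    scenario,
    positive_items,
    rng: np.random.Generator,
    trace_rows: list,
    imp_index: int,
) -> pd.DataFrame:
    work = data.copy()
    masks = {}
    order = sorted(
        spec.targets(), key=lambda v: (int(data[v].isna().sum()), str(v))
    )
    order = [v for v in order if data[v].isna().any()]
    for v in order:
        masks[v] = data[v].isna().to_numpy()
        observed = data[v].dropna().to_numpy(dtype=float)
        work.loc[masks[v], v] = rng.choice(observed, size=masks[v].sum())
    for it in range(spec.n_iter):
        for v in order:
            miss = masks[v]
            X = _design(work, spec.predictors.columns[spec.predictors.loc[v]])
            y = work[v].to_numpy(dtype=float)
            meth = spec.methods[v]
            if meth == "pmm":
                delta = 0.0
                if scenario is not None:
                    delta = scenario.delta_for(v)
                imputed = pmm_impute_variable(
                    y, miss, X, spec.donor_k, spec.ridge, rng, delta=delta
                )
            else:
                levels = tuple(spec.levels.get(v, ITEM_LEVELS))
                theta = None
                if scenario is not None:
                    theta = scenario.theta_for(v, positive_items, levels)
                imputed = _categorical_draw(
                    y, miss, X, levels, spec.ridge, rng, theta=theta
                )
            work[v] = imputed
            vals = imputed[miss]
            trace_rows.append(
                {
                    "imputation": imp_index,
                    "iteration": it,
                    "variable": v,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=0)),
                }
            )
    return work


class MICEImputer(BaseEstimator):
    """Chained-equations multiple imputer for CES-D cohorts.

    Parameters
    ----------
    structure : {"items_parsimonious", "items_full", "score_pmm",
        "status_logreg"}
        Which variables are imputed and from what. Item-level structures
        impute each item from the 19 others (plus the covariate block for
        ``items_full``); the score/status structures impute a single derived
        variable from the covariates.
    method : {"pmm", "polyreg"}
        Elementary method for the item-level structures.
    m, n_iter, donor_k, ridge : engine controls (see :class:`ImputationSpec`).
    random_state : master seed; identical seeds give identical output.
    scenario : optional :class:`cesdimpute.mnar.MNARScenario` tilting the
        imputation distribution for nonresponders. ``None`` and the identity
        scenario produce bit-identical results under a shared seed.
    cutoff : hDS threshold used when refreshing derived columns.
    """

    def __init__(
        self,
        structure: str = "items_parsimonious",
        method: str = "pmm",
        m: int = 5,
        n_iter: int = 10,
        donor_k: int = 5,
        ridge: float = 1e-4,
        random_state: int | None = None,
        scenario=None,
        positive_items: tuple = DEFAULT_POSITIVE_ITEMS,
        cutoff: float = DEFAULT_CUTOFF,
    ):
        self.structure = structure
        self.method = method
        self.m = m
        self.n_iter = n_iter
        self.donor_k = donor_k
        self.ridge = ridge
        self.random_state = random_state
        self.scenario = scenario
        self.positive_items = positive_items
        self.cutoff = cutoff

    def fit(self, X: pd.DataFrame, y=None):
        validate_items(X)
        data = attach_score_columns(X, cutoff=self.cutoff)
        self.spec_ = build_model(
            self.structure,
            data,
            method=self.method,
            m=self.m,
            n_iter=self.n_iter,
            donor_k=self.donor_k,
            ridge=self.ridge,
            seed=self.random_state,
        )
        self.spec_.validate(data)
        return self

    def impute(self, X: pd.DataFrame) -> CompletedSets:
        """Run the chained equations and return the m completed datasets."""
        if not hasattr(self, "spec_"):
            self.fit(X)
        data = attach_score_columns(X, cutoff=self.cutoff)
        return mice_run(
            data,
            self.spec_,
            scenario=self.scenario,
            positive_items=self.positive_items,
            cutoff=self.cutoff,
        )

    def fit_impute(self, X: pd.DataFrame) -> CompletedSets:
        return self.fit(X).impute(X)


def mice_run(
    cohort: pd.DataFrame,
    spec: ImputationSpec,
    scenario=None,
    positive_items: tuple = DEFAULT_POSITIVE_ITEMS,
    cutoff: float = DEFAULT_CUTOFF,
) -> CompletedSets:
    """Execute one chained-equations run described by ``spec``.

    Missing cells of every target variable are initialised by uniform draws
    from that variable's observed values, then re-imputed over ``n_iter``
    cycles visiting targets in order of increasing missing count. The m
    imputations use independent child streams spawned from ``spec.seed``;
    identical seeds reproduce identical output. Observed cells are never
    altered.
    """
    if scenario is not None:
        scenario.validate()
    if "cesd_score" in spec.methods and "cesd_score" not in cohort.columns:
        cohort = attach_score_columns(cohort, cutoff=cutoff)
    if "hds" in spec.methods and "hds" not in cohort.columns:
        cohort = attach_score_columns(cohort, cutoff=cutoff)
    spec.validate(cohort)
    item_targets = [v for v in spec.targets() if v in ITEM_COLUMNS]
    children = np.random.SeedSequence(spec.seed).spawn(spec.m)
    datasets, trace_rows = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        completed = _impute_once(
            cohort, spec, scenario, positive_items, rng, trace_rows, i
        )
        if item_targets:
            completed = attach_score_columns(completed, cutoff=cutoff)
        datasets.append(completed)
    trace = pd.DataFrame(
        trace_rows, columns=["imputation", "iteration", "variable", "mean", "sd"]
    )
    return CompletedSets(datasets=datasets, spec=spec, trace=trace)


# ---------------------------------------------------------------------------
# Pooled summaries
# ---------------------------------------------------------------------------


def pooled_prevalence(
    sets: CompletedSets,
    cutoff: float = DEFAULT_CUTOFF,
    rows: np.ndarray | None = None,
    value_col: str | None = None,
) -> PooledEstimate:
    """Rubin-pooled hDS prevalence (proportion scale) over the m datasets.

    ``value_col`` selects the variable carrying the estimate: item totals by
    default, ``"cesd_score"`` for the score path or ``"hds"`` for the status
    path (where prevalence is the mean of the binary flag). ``rows`` is an
    optional boolean subject filter (a missing-count stratum).
    """
    ps, vs = [], []
    for ds in sets.datasets:
        sub = ds if rows is None else ds.loc[rows]
        if value_col == "hds":
            flag = sub["hds"].to_numpy(dtype=float)
        else:
            if value_col is None:
                total = validate_items(sub).sum(axis=1).to_numpy()
            else:
                total = sub[value_col].to_numpy(dtype=float)
            flag = (total >= cutoff).astype(float)
        n = len(flag)
        p = float(flag.mean())
        ps.append(p)
        vs.append(p * (1.0 - p) / n)
    return pool_rubin(ps, vs)


def pooled_score_summary(
    sets: CompletedSets,
    cutoff: float = DEFAULT_CUTOFF,
    rows: np.ndarray | None = None,
    value_col: str | None = None,
) -> dict:
    """Pooled mean, SD, SEM and prevalence %, one comparative-table row.

    SD is reported as the mean of the per-dataset SDs; the SEM comes from the
    Rubin total variance of the mean.
    """
    prev = pooled_prevalence(sets, cutoff=cutoff, rows=rows, value_col=value_col)
    if value_col == "hds":
        # status-level path carries no score; only the prevalence is defined
        sub = sets.datasets[0] if rows is None else sets.datasets[0].loc[rows]
        return {
            "n": len(sub),
            "mean": float("nan"),
            "sd": float("nan"),
            "sem": float("nan"),
            "prev_pct": 100.0 * prev.estimate,
            "prev_se_pct": 100.0 * prev.se,
        }
    means, mvars, sds = [], [], []
    n = None
    for ds in sets.datasets:
        sub = ds if rows is None else ds.loc[rows]
        if value_col is None:
            total = validate_items(sub).sum(axis=1).to_numpy()
        else:
            total = sub[value_col].to_numpy(dtype=float)
        n = len(total)
        means.append(float(total.mean()))
        sd = float(total.std(ddof=1))
        sds.append(sd)
        mvars.append(sd**2 / n)
    pooled_mean = pool_rubin(means, mvars)
    return {
        "n": n,
        "mean": pooled_mean.estimate,
        "sd": float(np.mean(sds)),
        "sem": pooled_mean.se,
        "prev_pct": 100.0 * prev.estimate,
        "prev_se_pct": 100.0 * prev.se,
    }
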