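"""Synthetic cohort generator and packaged qualitative-study counts.

Real item-level CES-D data from the source cohort are not publicly
deposited, so every stochastic study in this package runs on synthetic
cohorts engineered to share the aggregate structure reported for them:

* 20 ordinal items driven by one latent depressive trait through a
  graded-response mechanism (item propensity = loading x trait + noise, cut
  at per-item ordered thresholds), giving high internal consistency
  (Cronbach alpha ~ 0.89), a dominant first principal component, and an hDS
  prevalence near one quarter;
* a 17-column covariate block of depressive-symptom risk factors with mild
  associations to the trait (mixed continuous / binary / ordinal /
  categorical types);
* configurable MCAR / MAR / MNAR missingness in the items. MAR missingness
  is driven by fully observed covariates; MNAR missingness depends on the
  cell's own (to-be-deleted) scored category through log-odds offsets
  log(theta_c), which makes theta exactly the odds ratio of category c
  between missing and observed cells — the quantity the sensitivity-analysis
  tilt manipulates.

Covariate names mirror the risk-factor list of the emulated cohort for
readability; their distributions are documented inventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .scale import ITEM_COLUMNS, N_ITEMS, validate_items

#: Subject counts printed for the emulated cohort; used for derived defaults
#: such as the amputation fraction, never as data.
COHORT_PRINTED_COUNTS = {
    "questionnaires_sent": 94_503,
    "returned": 71_412,
    "complete_cases": 39_393,
    "person_mean_eligible": 69_242,
    "classifiable_cases": 55_964,
}


def q8_response_rate_pct() -> float:
    """Questionnaire response rate, % (returned / sent)."""
    c = COHORT_PRINTED_COUNTS
    return 100.0 * c["returned"] / c["questionnaires_sent"]


def observed_incomplete_fraction() -> float:
    """Fraction of returned questionnaires with any missing item."""
    c = COHORT_PRINTED_COUNTS
    return (c["returned"] - c["complete_cases"]) / c["returned"]


# ---------------------------------------------------------------------------
# Item-response model
# ---------------------------------------------------------------------------

# Default discriminations: moderately strong, varying across items. Together
# with the thresholds below they were calibrated once (by simulation at
# n = 200k) to hit alpha ~ 0.89, mean score ~ 12, SD ~ 8 and hDS prevalence
# ~ 26% under the standard-normal latent trait.
DEFAULT_LOADINGS = np.array(
    [
        0.81, 0.68, 0.94, 0.64, 0.85, 0.77, 0.98, 0.60, 0.89, 0.72,
        0.94, 0.68, 0.81, 0.85, 0.64, 0.72, 0.89, 0.77, 0.98, 0.81,
    ]
)

# Per-item cumulative marginal probabilities for categories <=0, <=1, <=2.
# Mild variation across items keeps the scale realistic (some symptoms are
# rarer than others).
_BASE_CUM = np.array([0.64, 0.86, 0.955])
_CUM_JITTER = np.array(
    [
        -0.06, 0.04, -0.02, 0.06, 0.00, -0.04, 0.02, 0.05, -0.05, 0.03,
        -0.03, 0.01, 0.00, -0.01, 0.04, 0.02, -0.04, 0.03, -0.02, 0.01,
    ]
)


def default_thresholds(loadings: np.ndarray = DEFAULT_LOADINGS) -> np.ndarray:
    """Ordered cut-points on the item propensity scale (20 x 3).

    Cut-points are normal quantiles of the target cumulative category
    probabilities, scaled by the propensity SD sqrt(loading^2 + 1).
    """
    cum = np.clip(_BASE_CUM[None, :] + _CUM_JITTER[:, None], 0.05, 0.995)
    sd = np.sqrt(np.asarray(loadings) ** 2 + 1.0)
    return norm.ppf(cum) * sd[:, None]


# Covariate block: (name, kind, params). ``assoc`` is the loading of the
# latent depressive trait in the covariate's latent index (log-odds scale for
# binaries).
COVARIATE_SPEC = (
    ("age", "continuous", {"loc": 65.0, "scale": 6.5, "assoc": 0.15}),
    ("marital_status", "categorical",
     {"labels": ("married", "widowed", "single"), "cum": (0.65, 0.90),
      "assoc": 0.15}),
    ("employed", "binary", {"p0": 0.25, "assoc": -0.10}),
    ("education_level", "ordinal", {"cuts": (-0.5, 0.8), "assoc": -0.15}),
    ("n_pregnancies", "ordinal", {"cuts": (-1.3, -0.4, 0.5, 1.4), "assoc": 0.0}),
    ("menopausal", "binary", {"p0": 0.95, "assoc": 0.0}),
    ("needs_help_completing", "binary", {"p0": 0.03, "assoc": 0.30}),
    ("depression_history", "binary", {"p0": 0.25, "assoc": 0.80}),
    ("current_depression_treatment", "binary", {"p0": 0.08, "assoc": 1.00}),
    ("psychotropic_drug_use", "binary", {"p0": 0.15, "assoc": 0.70}),
    ("menopause_mood_symptoms", "binary", {"p0": 0.30, "assoc": 0.50}),
    ("alcohol_g_day", "continuous", {"loc": 11.0, "scale": 9.0, "assoc": -0.05,
                                     "floor": 0.0}),
    ("smoking_status", "categorical",
     {"labels": ("never", "former", "current"), "cum": (0.55, 0.88),
      "assoc": 0.10}),
    ("sleep_duration_h", "continuous", {"loc": 7.3, "scale": 1.0,
                                        "assoc": -0.25}),
    ("recent_hospitalization", "binary", {"p0": 0.12, "assoc": 0.40}),
    ("psychiatric_hospitalization", "binary", {"p0": 0.02, "assoc": 0.80}),
    ("chronic_disease_count", "ordinal",
     {"cuts": (-0.2, 0.7, 1.4, 2.0), "assoc": 0.40}),
)


@dataclass
class GeneratorParams:
    """Controls for the synthetic cohort.

    n : number of subjects.
    loadings : 20 positive item discriminations on the latent trait.
    thresholds : 20 x 3 strictly increasing cut-points per item.
    covariate_spec : covariate definitions (name, kind, params).
    seed : generator seed; identical seeds give identical cohorts.
    """

    n: int = 5000
    loadings: np.ndarray = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    thresholds: np.ndarray | None = None
    covariate_spec: tuple = COVARIATE_SPEC
    seed: int | None = None

    def resolved_thresholds(self) -> np.ndarray:
        thr = (
            default_thresholds(self.loadings)
            if self.thresholds is None
            else np.asarray(self.thresholds, dtype=float)
        )
        if thr.shape != (N_ITEMS, 3):
            raise ValueError("thresholds must have shape (20, 3)")
        if not (np.diff(thr, axis=1) > 0).all():
            raise ValueError("thresholds must be strictly increasing per item")
        return thr

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        loadings = np.asarray(self.loadings, dtype=float)
        if loadings.shape != (N_ITEMS,) or not (loadings > 0).all():
            raise ValueError("loadings must be 20 positive values")
        self.resolved_thresholds()


def generate_cohort(params: GeneratorParams | None = None, **kwargs) -> pd.DataFrame:
    """Draw a complete cohort: 20 scored items + 17 covariates.

    Keyword arguments override :class:`GeneratorParams` fields, so
    ``generate_cohort(n=2000, seed=7)`` is the common call.
    """
    if params is None:
        params = GeneratorParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either params or keyword overrides, not both")
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n
    trait = rng.standard_normal(n)
    loadings = np.asarray(params.loadings, dtype=float)
    thr = params.resolved_thresholds()
    propensity = trait[:, None] * loadings[None, :] + rng.standard_normal(
        (n, N_ITEMS)
    )
    items = (propensity[:, :, None] > thr[None, :, :]).sum(axis=2)
    data = {c: items[:, j].astype(float) for j, c in enumerate(ITEM_COLUMNS)}
    for name, kind, p in params.covariate_spec:
        a = p.get("assoc", 0.0)
        if kind == "continuous":
            noise = rng.standard_normal(n)
            z = a * trait + np.sqrt(max(1.0 - a**2, 0.0)) * noise
            vals = p["loc"] + p["scale"] * z
            if "floor" in p:
                vals = np.maximum(vals, p["floor"])
            data[name] = vals
        elif kind == "binary":
            prob = expit(logit(p["p0"]) + a * trait)
            data[name] = (rng.random(n) < prob).astype(float)
        elif kind == "ordinal":
            latent = a * trait + rng.standard_normal(n)
            cuts = np.asarray(p["cuts"], dtype=float)
            data[name] = (latent[:, None] > cuts[None, :]).sum(axis=1).astype(float)
        elif kind == "categorical":
            latent = a * trait + rng.standard_normal(n)
            cuts = norm.ppf(np.asarray(p["cum"], dtype=float)) * np.sqrt(1 + a**2)
            idx = (latent[:, None] > cuts[None, :]).sum(axis=1)
            data[name] = pd.Categorical.from_codes(
                idx, categories=list(p["labels"])
            )
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Missingness generation
# ---------------------------------------------------------------------------


@dataclass
class MissingnessSpec:
    """How item cells go missing.

    mechanism : "MCAR" (independent of everything), "MAR" (cell missingness
        driven by fully observed covariates), or "MNAR" (driven by the
        cell's own scored category).
    overall_fraction : target fraction of subjects with >= 1 missing item.
    mar_drivers : covariate names whose standardised values enter the
        missingness log-odds (MAR only).
    mar_strength : log-odds per SD of the (summed, standardised) drivers.
    mnar_theta : odds-ratio triplet for scored categories (1, 2, 3) vs 0 of
        the negatively worded items (MNAR only).
    mnar_theta_positive : optional distinct triplet for positive items.
    positive_items : positions of the positively worded items.
    """

    mechanism: str = "MCAR"
    overall_fraction: float = field(
        default_factory=observed_incomplete_fraction
    )
    mar_drivers: tuple = ("age",)
    mar_strength: float = 1.0
    mnar_theta: tuple = (1.0, 1.0, 1.0)
    mnar_theta_positive: tuple | None = None
    positive_items: tuple = (4, 8, 12, 16)

    def validate(self) -> None:
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 <= self.overall_fraction <= 1.0:
            raise ValueError("overall_fraction must be in [0, 1]")
        for trip in (self.mnar_theta, self.mnar_theta_positive):
            if trip is not None:
                arr = np.asarray(trip, dtype=float)
                if arr.shape != (3,) or np.any(arr <= 0):
                    raise ValueError("theta triplets must be 3 positive values")


def _solve_intercept(offsets: np.ndarray, subject_fraction: float) -> float:
    """Bisection for the intercept alpha such that the expected fraction of
    subjects with at least one missing cell matches ``subject_fraction``.

    ``offsets`` is the n x 20 matrix of per-cell log-odds offsets; the
    subject-level fraction is mean_i[1 - prod_j(1 - expit(alpha + off_ij))].
    """
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        p_any = 1.0 - np.prod(1.0 - expit(mid + offsets), axis=1)
        if p_any.mean() < subject_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_missingness(
    cohort: pd.DataFrame,
    spec: MissingnessSpec | None = None,
    seed: int | None = None,
    **kwargs,
):
    """Delete item cells from a complete cohort under the chosen mechanism.

    Cell (i, j) goes missing with probability expit(alpha + offset_ij):
    offsets are zero for MCAR, a covariate-driven subject effect for MAR, and
    log(theta_c) for the cell's own scored category c for MNAR. The
    intercept alpha is solved so that the expected fraction of subjects with
    at least one missing item matches ``overall_fraction``.

    Returns ``(amputed, mask)`` where ``mask`` is a boolean DataFrame over
    the item columns (True = deleted); the input cohort is the ground truth.
    """
    if spec is None:
        spec = MissingnessSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either spec or keyword overrides, not both")
    spec.validate()
    items = validate_items(cohort)
    if items.isna().any().any():
        raise ValueError("cohort must be complete before missingness generation")
    n = len(cohort)
    rng = np.random.default_rng(seed)
    if spec.overall_fraction == 0:
        mask = pd.DataFrame(
            False, index=cohort.index, columns=list(ITEM_COLUMNS)
        )
        return cohort.copy(), mask
    if spec.mechanism == "MCAR":
        offsets = np.zeros((n, N_ITEMS))
    elif spec.mechanism == "MAR":
        z = np.zeros(n)
        for d in spec.mar_drivers:
            col = cohort[d].to_numpy(dtype=float)
            z += (col - col.mean()) / max(col.std(), 1e-12)
        z /= max(z.std(), 1e-12)
        offsets = np.repeat(
            (spec.mar_strength * z)[:, None], N_ITEMS, axis=1
        )
    else:  # MNAR: offset log(theta_c) for the cell's own category
        theta_n = np.concatenate([[1.0], np.asarray(spec.mnar_theta, float)])
        theta_p = (
            theta_n
            if spec.mnar_theta_positive is None
            else np.concatenate(
                [[1.0], np.asarray(spec.mnar_theta_positive, float)]
            )
        )
        vals = items.to_numpy().astype(int)
        offsets = np.log(theta_n)[vals]
        pos_idx = [i - 1 for i in spec.positive_items]
        offsets[:, pos_idx] = np.log(theta_p)[vals[:, pos_idx]]
    alpha = _solve_intercept(offsets, spec.overall_fraction)
    prob = expit(alpha + offsets)
    mask_arr = rng.random((n, N_ITEMS)) < prob
    amputed = cohort.copy()
    block = items.to_numpy(copy=True)
    block[mask_arr] = np.nan
    amputed[list(ITEM_COLUMNS)] = block
    mask = pd.DataFrame(mask_arr, index=cohort.index, columns=list(ITEM_COLUMNS))
    return amputed, mask


# ---------------------------------------------------------------------------
# Qualitative-study fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QualitativeStudyCounts:
    """Printed counts from the 183-questionnaire qualitative substudy.

    Complete responders are classified directly; incomplete responders are
    classified by the bound rule (hDS under every completion, NhDS under
    every completion, or undetermined). The two cross-tabs relate
    qualitative-study behaviour to the main-questionnaire behaviour of the
    same women (rows = main questionnaire, columns = qualitative study).
    """

    complete_nhds: int = 104
    complete_hds: int = 45
    incomplete_nhds: int = 12
    incomplete_hds: int = 14
    incomplete_undetermined: int = 8
    #: rows: main questionnaire {no MV, >=1 MV}; cols: qualitative {no MV, >=1 MV}
    q8_missingness_crosstab: tuple = ((91, 19), (57, 15))
    #: rows: main questionnaire {NhDS, hDS}; cols: qualitative {NhDS, hDS}
    q8_status_crosstab: tuple = ((79, 23), (19, 25))

    @property
    def complete_total(self) -> int:
        return self.complete_nhds + self.complete_hds

    @property
    def incomplete_total(self) -> int:
        return (
            self.incomplete_nhds
            + self.incomplete_hds
            + self.incomplete_undetermined
        )

    @property
    def total(self) -> int:
        return self.complete_total + self.incomplete_total


def fixture_table1() -> QualitativeStudyCounts:
    """The packaged qualitative-study count structure."""
    return QualitativeStudyCounts()
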