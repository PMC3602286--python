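# cesdimpute

Missing-data handling for the **CES-D** (Center for Epidemiologic Studies –
Depression) scale: a 20-item self-report screen, each item scored 0/1/2/3,
totals 0–60, with a total ≥ 16 flagging **high depressive symptoms (hDS)**.
Self-administered questionnaires in large cohorts routinely come back with
skipped items, and how those missing values are handled can move the
estimated prevalence of hDS by many percentage points.

`cesdimpute` is for epidemiologists and biostatisticians who need to score
such data honestly. It implements, end to end:

- **Scoring and classification** — reverse coding of the four positively
  worded items, totals, the hDS cut-off, and *bound-based* classification of
  partially observed subjects (a subject whose status is the same under
  every completion of their missing items is classifiable without any
  imputation; the rest are undetermined, yielding prevalence bounds).
- **Single imputation comparators** — minimum (0), maximum (3), and
  person-mean (the subject's own observed-item mean).
- **Multiple imputation by chained equations (MICE)** with predictive mean
  matching (`pmm`), logistic (`logreg`) and polytomous (`polyreg`)
  elementary methods; four model structures (total score from covariates,
  binary status from covariates, each item from the other 19 items alone or
  plus 17 covariates); Rubin's rules pooling
  (T = W̄ + (1 + 1/m)·B).
- **Nonignorable (MNAR) sensitivity analysis** — pattern-mixture tilting:
  the imputation model's category probabilities for nonresponders are
  multiplied by odds ratios θ = (θ₁, θ₂, θ₃) (categories 1–3 vs 0), or
  predictions shifted by δ on the continuous path, then re-imputed; four
  built-in scenarios of increasing severity.
- **MCAR amputation benchmarking** — delete exactly k items for a fixed
  fraction of subjects, re-impute by each method, compare mean, variance,
  SEM and prevalence against the pre-deletion truth.
- **A calibrated synthetic cohort generator** — a graded-response item model
  on one latent trait (Cronbach α ≈ 0.89, dominant first principal
  component, hDS prevalence ≈ 25%), 17 mixed-type risk-factor covariates,
  and configurable MCAR/MAR/MNAR missingness with known ground truth.

The imputers are scikit-learn-style estimators (`MICEImputer`,
`SingleImputer`, `MCARAmputer`) with thin functional wrappers, so they
compose with pipelines and `get_params`/`set_params` tooling.

## Worked example

```python
import cesdimpute as ci

# a complete synthetic cohort, then 44.8% of subjects lose 5 items MCAR
cohort = ci.generate_cohort(n=2000, seed=5)
amputed = ci.MCARAmputer(k=5, random_state=11).fit(cohort).transform(cohort)

truth = cohort[list(ci.ITEM_COLUMNS)].sum(axis=1)
print(f"truth: mean {truth.mean():.2f}, hDS {100*(truth>=16).mean():.2f}%")

sets = ci.MICEImputer(structure="items_parsimonious", method="pmm",
                      m=5, n_iter=5, random_state=3).fit_impute(amputed)
s = ci.pooled_score_summary(sets)
print(f"MI pooled: mean {s['mean']:.2f} (SEM {s['sem']:.3f}), "
      f"hDS {s['prev_pct']:.2f}% (SE {s['prev_se_pct']:.2f})")
```

prints

```
truth: mean 11.00, hDS 26.30%
MI pooled: mean 11.04 (SEM 0.209), hDS 25.93% (SE 1.01)
```

i.e. after deleting a quarter of the item cells for amputated subjects, the
pooled chained-equations estimate recovers the pre-deletion mean and
prevalence well within one pooled standard error — the behaviour the
amputation benchmark (`run_accuracy_study`) quantifies systematically, and
which degrades for the person-mean comparator as k grows.

The same machinery is scriptable from a shell:

```bash
cesdimpute generate --n 2000 --seed 5 --out cohort.csv
cesdimpute ampute cohort.csv --k 5 --seed 11 --out amputed.csv
cesdimpute table3 amputed.csv --seed 3 --out comparison.csv
cesdimpute sensitivity amputed.csv --seed 3 --out mnar.csv
cesdimpute table1   # qualitative-study counts and prevalence bounds
```

## Layout

| module | contents |
| --- | --- |
| `cesdimpute.scale` | item validation, reverse coding, scoring, bound classification |
| `cesdimpute.single` | min / max / person-mean imputation |
| `cesdimpute.mice` | chained-equations engine, model structures, Rubin pooling |
| `cesdimpute.mnar` | scenarios, probability tilting, sensitivity runs |
| `cesdimpute.amputation` | MCAR amputer and the accuracy benchmark |
| `cesdimpute.synthetic` | cohort generator, missingness mechanisms, packaged counts |
| `cesdimpute.psychometrics` | Cronbach α, PCA eigenvalue spectrum |
| `cesdimpute.report`, `cesdimpute.cli` | comparative tables and the `cesdimpute` command |

See `docs/methods.md` for the statistical details and design choices.
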