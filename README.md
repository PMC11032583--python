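# plasmaprob

Probability-density classification of CSF amyloid/tau (A/T) status from
plasma biomarkers.

Blood-based biomarkers — the plasma Aβ42/40 ratio and p-tau181 — track the
CSF changes that define biological Alzheimer's disease, and automated
immunoassay platforms make them measurable at clinical scale. `plasmaprob`
implements a probabilistic framework for turning those two plasma values
into A/T profile calls: instead of a bare threshold, every subject gets a
classification *probability*, so borderline results can be recognised and,
if desired, excluded.

The core construction: fit class-conditional densities to a biomarker in
the biomarker-positive and biomarker-negative groups (normal for Aβ42/40,
gamma for p-tau181) and convert a measurement x to the two-class posterior

    p(x) = π₊ f₊(x) / (π₊ f₊(x) + π₋ f₋(x)),     π₊ = π₋ = ½ by default.

On top of this the package builds:

* **probability-level cutoffs** — the biomarker values where p(x) crosses
  0.1/0.3/0.5/0.7/0.9, found by bracketed root-finding;
* **a bivariate classifier** mixing the two biomarker posteriors as
  k·p_ratio + (1−k)·p_ptau, with k selected by grid search maximizing
  100-fold cross-validated accuracy;
* **a serial trinomial caller** (A+/T+ model first, then A+ model) that
  assigns A+/T+, A+/T− or A−/T± profiles;
* **evaluation**: sensitivity/specificity/accuracy with and without the
  [0.3, 0.7] uncertainty zone, empirical ROC/AUC, Youden cutoffs, and
  stratified percentile-bootstrap CIs (2000 replicates);
* **assay QC calculators** (intra/inter-assay CV, spike recovery, dilution
  linearity, parallelism) with the standard acceptance windows (CV < 20%,
  agreement 80–120%);
* **a synthetic cohort generator** reproducing the published per-stratum
  structure of the 450-subject training cohort (strata 126/50/48/226) and
  the 80-subject case–control validation cohort, so the whole pipeline is
  testable without patient-level data.

Estimators follow the scikit-learn protocol (`fit`, `predict`,
`predict_proba`, fitted attributes with trailing underscores) and compose
with sklearn model selection.

## Worked example

```python
from plasmaprob import (CohortConfig, default_unipg_specs, generate_cohort,
                        train_univariate, train_bivariate, solve_cutoffs,
                        classify_trinomial)

# large synthetic cohort from the published stratum parameters
cohort = generate_cohort(CohortConfig(strata=default_unipg_specs(),
                                      scale=100, seed=1))

# univariate Aβ42/40 model for A+ vs A-, and its probability cutoffs
ratio_model = train_univariate(cohort, "A+vsA-", "ratio")
print(solve_cutoffs(ratio_model).levels)
# {0.1: 0.0968, 0.3: 0.0885, 0.5: 0.0816, 0.7: 0.0709, 0.9: None}

# bivariate models on the default-size cohort, then a trinomial call
small = generate_cohort(CohortConfig(strata=default_unipg_specs(), seed=1))
biv_at = train_bivariate(small, "A+T+vsRest", seed=1)
biv_a = train_bivariate(small, "A+vsA-", seed=1)
print(classify_trinomial(biv_at, biv_a, [0.070, 3.5]))
# TrinomialResult(p_at=0.685, p_a=None, label='A+/T+', uncertain=True)
```

Reading the output: a subject with Aβ42/40 below the 0.0816 cutoff is more
likely A+ than A−; 0.0709 marks 70% probability. The 0.9 level is reported
as `None` because, under these class distributions, the posterior never
reaches 0.9 — the overlap between classes caps the achievable certainty.
The trinomial call for (Aβ42/40 = 0.070, p-tau181 = 3.5 pg/mL) lands at
A+/T+ with probability 0.685: positive, but inside the [0.3, 0.7]
uncertainty zone, so it is flagged `uncertain=True` and would be excluded
under robust-outcome reporting. The second-stage probability `p_a` is
`None` because the serial algorithm stops after a positive first stage.

The same pipeline is scriptable from a shell:

```sh
plasmaprob simulate --seed 1 --out cohort.csv
plasmaprob train --input cohort.csv --contrast A+vsA- --out model.json
plasmaprob evaluate --input cohort.csv --model model.json \
    --contrast A+vsA- --out report.csv
```

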