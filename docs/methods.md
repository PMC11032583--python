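# Methods

## The classification model

`plasmaprob` converts plasma biomarker measurements — the Aβ42/40 ratio and
p-tau181 (pg/mL) — into the probability that a subject carries an abnormal
CSF amyloid/tau profile. For a binary contrast (A+ vs A−, or A+/T+ vs every
other profile) a density f₊ is fitted to the biomarker in the positive class
and f₋ in the negative class, and a measured value x is mapped to the
two-class posterior

    p(x) = π₊ f₊(x) / (π₊ f₊(x) + π₋ f₋(x)).

The class priors π₊, π₋ are **equal by default** (0.5/0.5). This is a
deliberate choice: the working cutoff at p = 0.5 then coincides with the
crossing point of the two fitted densities, which is how such cutoffs are
conventionally read off fitted-density plots, and it makes the cutoff
independent of the (referral-biased) composition of the training cohort.
Prevalence-weighted priors are available via the `priors` parameter; they
shift the p = 0.5 cutoff toward the minority-class mean.

Families follow the shape of the data: the Aβ42/40 ratio is approximately
normal within each A/T class, while p-tau181 is right-skewed and modelled as
gamma — in both classes of both contrasts (so the A+/T+ contrast uses
normal/normal fits for the ratio and the A+ contrast uses gamma/gamma fits
for p-tau181).

### Density estimation

* Normal MLE is closed form. σ uses the MLE divisor n (not n−1) for
  likelihood and AIC consistency; published per-group SDs are sample SDs,
  which differ by √((n−1)/n) — negligible at these group sizes.
* Gamma MLE (shape k, scale θ) profiles the likelihood on the shape: with
  θ = x̄/k concentrated out, k solves log k − ψ(k) = log x̄ − mean(log x),
  solved by bracketed Brent iteration from the moment-matched start
  k₀ = (x̄/s)², to gradient tolerance 1e−8. If bracketing fails the fit
  falls back to moment matching and sets `moment_fallback=True`.
* Goodness of fit is reported as the exact KS statistic against the fitted
  CDF plus Q–Q points at plotting positions (i − 0.5)/n, P–P points, and an
  empirical-vs-fitted CDF table; all are returned as coordinates for the
  caller to plot.

### Probability-level cutoffs

Cutoffs are the roots of p(x) = level for level ∈ {0.1, 0.3, 0.5, 0.7, 0.9}.
With unequal class variances the posterior is not globally monotone: it has
a mode between/near the class means and an extraneous 0.5-crossing far in
the tail of the wider class. The solver therefore brackets the p = 0.5 root
**between the two class means** (Brent, relative tolerance 1e−12) and
reaches other levels by expanding the bracket monotonically outward from
that root, stopping at the support boundary (0 for gamma). A level beyond
the posterior's peak is reported as unattained (`None`), never
extrapolated. On the moment-matched synthetic cohort the posterior maxima
are ≈ 0.75 (ratio) and ≈ 0.85 (p-tau181), so the 0.9 level is unattained
there; with real, less-overlapping data the level can be attainable. For the
same reason the coordinatewise monotonicity of the bivariate probability
holds on the interval between the class means, not in the extreme tails.

### Bivariate mixing and cross-validated k

The bivariate probability is the weighted average
p = k·p_ratio + (1−k)·p_ptau, k ∈ [0, 1]. k is chosen by grid search
(step 0.001, matching the three-decimal precision of the published
constants) maximizing the mean held-out accuracy over 100 stratified
cross-validation folds; the class-conditional densities are refit on each
fold's training part (the conservative reading of model-level CV), fold
assignment is seeded, and ties break toward the smallest k. "100-fold" is
read as 100 folds of the n = 450 cohort (4–5 subjects each), not 100
repeats of some other split.

A caveat this package documents rather than hides: accuracy is a
threshold-based score, insensitive to shrinking probabilities toward 0.5.
When one biomarker carries no signal, mixing in its ≈ 0.5 posterior barely
moves any ≥ 0.5 decision, so the expected accuracy curve is nearly flat in
k and the selected k is driven by cross-validation noise rather than pushed
to the informative extreme. A proper scoring rule (log-loss or Brier) would
identify the noise channel decisively; accuracy is retained because it is
the objective the method specifies.

### Classification rules

* Binomial: label positive iff p ≥ 0.5 (ties positive); a call is flagged
  *uncertain* iff p lies in the closed exclusion zone, default [0.3, 0.7].
* Trinomial: apply the A+/T+-vs-rest bivariate model first; a positive call
  ends there (A+/T+). Otherwise apply the A+-vs-A− model: positive → A+/T−,
  negative → A−/T±. The second stage is never evaluated after a positive
  first stage, and a result is uncertain iff any *evaluated* stage fell in
  the zone.
* Isoprobability curves solve, per grid line in p-tau181, the ratio at
  which the mixed probability equals the level (for k = 0, per ratio grid
  line instead); each returned point re-evaluates to within 1e−6 of the
  level, and an unattained level yields an empty curve.

## Evaluation

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/total, each computable before and after removing uncertain calls
(excluded counts are tracked; an empty class yields `None`, never a silent
0). The ROC is the empirical curve over all distinct thresholds; its
trapezoidal AUC equals the Mann–Whitney rank statistic scaled to [0, 1]
(ties counted ½). The Youden cutoff maximizes sens + spec − 1 and reports
the midpoint of the flat optimal-threshold interval. Confidence intervals
are percentile bootstrap over 2000 replicates by default, resampling within
each class (stratified) so every replicate retains both classes; degenerate
replicates are redrawn with a cap of 10·B attempts. Cohen's d uses the
pooled n−1-weighted SD.

## Synthetic cohort generator

The generator emulates the training cohort's published structure: four CSF
A/T strata of sizes 126/50/48/226 (n = 450) with the printed per-stratum
means and SDs for plasma Aβ40, Aβ42, Aβ42/40, p-tau181, age, sex ratio,
kidney-dysfunction prevalence and CSF/serum-albumin tertile shares, plus an
80-subject external validation cohort (40 AD-dementia cases drawing from
the A+/T+ distributions, 40 controls from A−/T− distributions with CSF
status recorded as unknown; 65 y mean age, 70% female in both arms).

Choices, in the order they matter:

* The ratio is drawn from a normal truncated to (0, 1) by resampling
  (truncation mass < 1e−8 at the printed parameters); p-tau181 from a gamma
  moment-matched to the printed mean/SD (k = (m/s)², θ = s²/m). These match
  the families the classifier assumes.
* The ratio is generated **directly** from its printed moments rather than
  as a quotient of simulated Aβ42 and Aβ40 (a quotient would not reproduce
  the printed ratio moments); Aβ40 is drawn from its normal and Aβ42 is
  back-derived as ratio × Aβ40 for schema completeness. Setting
  `generate_ratio_directly=False` flips to quotient generation.
* Biomarkers are independent within stratum by default — only marginal
  moments are published. An optional Gaussian-copula rank correlation
  between ratio and p-tau181 is available; leaving it at 0 may overstate
  what a bivariate model can add relative to real data.
* Records are labelled by stratum only; clinical-group labels (preAD,
  MCI-AD, ...) are left "unknown" in the default generator because the
  published clinical-group rows overlap the A/T strata — users who need
  clinical subsets supply those parameters explicitly.
* All randomness flows from one top-level seed through named substreams
  (cohort, folds, bootstrap), so identical config + seed reproduces a
  cohort byte-for-byte and stages are independently reproducible.

What passing tests on this generator do **not** show: the generator
reproduces marginal moments, not the real data's within-subject biomarker
correlation, assay batch effects, preanalytical variation, or departures
from the assumed families. Quantities that depend on the full empirical
distributions (e.g. the published per-subgroup sensitivities) are not
expected to reproduce; quantities determined by the printed moments (the
p = 0.5 cutoffs, the Youden cutoff for the ratio) are. In particular the
p-tau181 p = 0.5 cutoff computed from moment-matched gammas undershoots the
published 2.02 pg/mL by roughly 10% — the real sample's MLE gamma fit is
not determined by its first two moments — and this bias is documented
rather than corrected.

## Problem sizes and numerical conventions

Moment- and cutoff-recovery checks run on a scale-100 cohort (n = 45,000),
large enough that sampling error is well below the comparison tolerances
while fitting and root-finding stay interactive. MLE recovery tests use
n = 10⁵ draws at 2% tolerance; the brute-force cutoff oracle scans 10⁶ grid
points; bootstrap defaults to B = 2000. Root-finding tolerances: 1e−12
relative (cutoffs), gradient 1e−8 (gamma shape). Degenerate inputs fail
loudly: zero variance, non-positive gamma support, classes under 10
records, folds whose training part drops below that floor, single-class
ROC input.

## Known limitations

* Equal priors are an assumption, not an estimate; with strongly imbalanced
  deployment populations the probability scale is not a calibrated
  posterior for that population.
* The serial trinomial rule cannot output A−/T+ (no plasma marker
  distinguishes it); that profile is folded into A−/T±.
* Covariate adjustment (age, sex, kidney function) is out of scope; kidney
  dysfunction is generated as a flag but does not shift biomarker values in
  the synthetic cohort.
* The parallelism calculator uses the conventional slope-ratio definition
  (regression slope of measured vs expected, relative to a reference
  slope); consortium SOPs may compute it on other scales.
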