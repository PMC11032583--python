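import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plasmaprob import (CONTRASTS, DensityFit, DensityPosteriorClassifier,
                        SerialTrinomialClassifier, WeightedPosteriorClassifier,
                        classify_binomial, classify_trinomial,
                        combine_bivariate, isoprobability_curve,
                        posterior_probability, solve_cutoffs, train_bivariate,
                        train_univariate)
from plasmaprob.errors import ClassificationError, TrainingError
from plasmaprob.models import model_from_json, model_to_json


def make_uni(pos_params, neg_params, families=("normal", "normal"),
             priors=(0.5, 0.5)):
    """Assemble a univariate classifier from explicit density parameters."""
    m = DensityPosteriorClassifier(*families, priors=priors)
    m.pos_fit_ = DensityFit(families[0], pos_params, 100, 0.0, 0.0)
    m.neg_fit_ = DensityFit(families[1], neg_params, 100, 0.0, 0.0)
    m.orientation_ = ("positive_low" if m.pos_fit_.mean < m.neg_fit_.mean
                      else "positive_high")
    m.classes_ = np.array([0, 1])
    return m


def make_biv(ratio_model, ptau_model, k):
    m = WeightedPosteriorClassifier(k=k)
    m.k_ = k
    m.cv_accuracy_ = None
    m.ratio_model_ = ratio_model
    m.ptau_model_ = ptau_model
    m.classes_ = np.array([0, 1])
    return m


# ---------------------------------------------------------------------------
# posterior probability

def test_posterior_symmetry_and_closed_form():
    m = make_uni((2.0, 1.0), (0.0, 1.0))
    assert posterior_probability(m, 1.0) == pytest.approx(0.5)
    # at x = 0: phi(-2)/(phi(0)+phi(-2))
    assert posterior_probability(m, 0.0) == pytest.approx(
        0.05399097 / (0.39894228 + 0.05399097), abs=1e-6)


def test_posterior_degenerate_prior():
    m = make_uni((2.0, 1.0), (0.0, 1.0), priors=(1.0, 0.0))
    assert posterior_probability(m, -3.0) == pytest.approx(1.0)


def test_posterior_undefined_outside_joint_support():
    m = make_uni((5.0, 0.5), (9.0, 0.5), families=("gamma", "gamma"))
    with pytest.raises(ClassificationError):
        m.posterior(-1.0)


# ---------------------------------------------------------------------------
# training from cohort tables

def test_train_univariate_orientations(unipg_cohort):
    ratio = train_univariate(unipg_cohort, "A+vsA-", "ratio")
    assert ratio.pos_fit_.mean < ratio.neg_fit_.mean
    assert ratio.orientation_ == "positive_low"
    assert ratio.pos_fit_.family == "normal" == ratio.neg_fit_.family
    ptau = train_univariate(unipg_cohort, "A+T+vsRest", "ptau181")
    assert ptau.orientation_ == "positive_high"
    assert ptau.pos_fit_.family == "gamma" == ptau.neg_fit_.family


def test_train_univariate_class_size_guard(unipg_cohort):
    small = pd.concat([
        unipg_cohort[unipg_cohort["a_status"] == "A+"].head(3),
        unipg_cohort[unipg_cohort["a_status"] == "A-"].head(50),
    ])
    with pytest.raises(TrainingError):
        train_univariate(small, "A+vsA-", "ratio")


def test_posterior_monotone_between_class_means(ratio_model, ptau_model):
    for m in (ratio_model, ptau_model):
        lo, hi = sorted((m.pos_fit_.mean, m.neg_fit_.mean))
        xs = np.linspace(lo, hi, 10_000)
        p = m.posterior(xs)
        d = np.diff(p)
        assert (d >= -1e-12).all() or (d <= 1e-12).all()


# ---------------------------------------------------------------------------
# cutoffs

def test_equal_variance_midpoint_cutoff():
    m = make_uni((2.0, 1.0), (0.0, 1.0))
    assert m.solve_cutoff(0.5) == pytest.approx(1.0, abs=1e-10)


def test_cutoff_table_monotone_in_level(ratio_model, ptau_model):
    """Attained thresholds are strictly monotone in the probability level;
    levels beyond the posterior's peak (unequal variances cap the posterior
    below 1) are reported as unattained, not fabricated."""
    for m, orient in ((ratio_model, "positive_low"),
                      (ptau_model, "positive_high")):
        table = solve_cutoffs(m)
        assert all(table.levels[l] is not None for l in (0.1, 0.3, 0.5, 0.7))
        vals = [table.levels[l] for l in (0.1, 0.3, 0.5, 0.7, 0.9)
                if table.levels[l] is not None]
        diffs = np.diff(vals)
        assert (diffs < 0).all() if orient == "positive_low" \
            else (diffs > 0).all()


def grid_scan_crossings(model, level, lo, hi, n=1_000_000):
    """Brute-force oracle: linearly interpolated level crossings of the
    posterior on a dense grid."""
    xs = np.linspace(lo, hi, n)
    p = model.posterior(xs) - level
    idx = np.nonzero(np.sign(p[:-1]) * np.sign(p[1:]) < 0)[0]
    return [xs[i] - p[i] * (xs[i + 1] - xs[i]) / (p[i + 1] - p[i])
            for i in idx]


@pytest.mark.parametrize("level", [0.1, 0.3, 0.5, 0.7, 0.9])
def test_cutoff_solver_matches_grid_scan(ratio_model, ptau_model, level):
    for m, (lo, hi) in ((ratio_model, (0.02, 0.15)),
                        (ptau_model, (0.05, 12.0))):
        root = m.solve_cutoff(level)
        crossings = grid_scan_crossings(m, level, lo, hi)
        if root is None:
            # unattained level: the brute-force scan agrees there is no
            # crossing anywhere in the window
            assert not crossings
        else:
            assert min(abs(c - root) for c in crossings) < 1e-6


def test_prior_shifts_cutoff_toward_minority_mean():
    equal = make_uni((2.0, 1.0), (0.0, 1.0))
    weighted = make_uni((2.0, 1.0), (0.0, 1.0), priors=(0.75, 0.25))
    # positive class is the majority; the p=0.5 cutoff moves toward the
    # minority (negative) class mean at 0
    assert weighted.solve_cutoff(0.5) < equal.solve_cutoff(0.5)


def test_unattainable_level_reported_as_none():
    # gamma/gamma with positive_high orientation: very low levels fall
    # beyond the support boundary at 0
    m = make_uni((4.0, 1.0), (2.0, 1.0), families=("gamma", "gamma"))
    table = m.cutoff_table(levels=(1e-9, 0.5))
    assert table.levels[0.5] is not None
    # the near-zero level may or may not be attainable; posterior at the
    # support edge bounds it
    edge = m.posterior(1e-12)
    if edge > 1e-9:
        assert table.levels[1e-9] is None


# ---------------------------------------------------------------------------
# bivariate combination and training

@pytest.mark.parametrize("p_r,p_p,k,expected", [
    (0.2, 0.8, 1.0, 0.2),
    (0.2, 0.8, 0.0, 0.8),
    (0.2, 0.8, 0.5, 0.5),
])
def test_combine_bivariate_weighting(p_r, p_p, k, expected):
    assert combine_bivariate(p_r, p_p, k) == pytest.approx(expected)


@given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
@settings(derandomize=True, max_examples=50)
def test_combine_bivariate_stays_in_unit_interval(p_r, p_p, k):
    p = combine_bivariate(p_r, p_p, k)
    assert min(p_r, p_p) - 1e-12 <= p <= max(p_r, p_p) + 1e-12


def test_selected_k_beats_grid_endpoints(bivariate_models):
    """argmax definition: CV accuracy at the selected k is >= accuracy at
    k = 0 and k = 1 on the same folds."""
    for model in bivariate_models.values():
        acc = model.cv_accuracy_
        i = int(round(model.k_ * 1000))
        assert acc[i] >= acc[0] and acc[i] >= acc[-1]
        assert acc[i] == acc.max()


def test_bivariate_coordinatewise_monotone(bivariate_models):
    """Between the class means (where the posterior is monotone), the
    bivariate probability is non-increasing in the ratio and
    non-decreasing in p-tau181."""
    m = bivariate_models["A+vsA-"]
    ptau_fixed, ratio_fixed = 2.0, 0.08
    r_lo, r_hi = sorted((m.ratio_model_.pos_fit_.mean,
                         m.ratio_model_.neg_fit_.mean))
    ratios = np.linspace(r_lo, r_hi, 200)
    p = m.posterior(np.column_stack([ratios, np.full(200, ptau_fixed)]))
    assert (np.diff(p) <= 1e-12).all()  # positive_low in the ratio
    t_lo, t_hi = sorted((m.ptau_model_.pos_fit_.mean,
                         m.ptau_model_.neg_fit_.mean))
    ptaus = np.linspace(t_lo, t_hi, 200)
    p = m.posterior(np.column_stack([np.full(200, ratio_fixed), ptaus]))
    assert (np.diff(p) >= -1e-12).all()  # positive_high in p-tau181


def test_train_bivariate_fold_guard(unipg_cohort):
    tiny = pd.concat([
        unipg_cohort[unipg_cohort["a_status"] == "A+"].head(12),
        unipg_cohort[unipg_cohort["a_status"] == "A-"].head(12),
    ])
    with pytest.raises(TrainingError):
        train_bivariate(tiny, "A+vsA-", n_folds=100, seed=1)


def test_bivariate_missing_biomarker_rejected(bivariate_models):
    m = bivariate_models["A+vsA-"]
    with pytest.raises(ClassificationError):
        m.posterior(np.array([[0.08, np.nan]]))


# ---------------------------------------------------------------------------
# classification rules

@pytest.mark.parametrize("p,label,uncertain", [
    (0.71, "positive", False),
    (0.70, "positive", True),
    (0.50, "positive", True),
    (0.30, "negative", True),
    (0.29, "negative", False),
])
def test_binomial_zone_conventions(p, label, uncertain):
    # a k=1 model driven by the ratio alone lets us dial the probability
    uni = make_uni((2.0, 1.0), (0.0, 1.0))
    x = uni.solve_cutoff(p)
    res = classify_binomial(uni, x)
    assert res.probability == pytest.approx(p, abs=1e-9)
    assert res.label == label and res.uncertain == uncertain


def _trinomial_pair():
    at_ratio = make_uni((2.0, 1.0), (0.0, 1.0))
    at_ptau = make_uni((5.0, 2.0), (4.0, 2.0))
    a_ratio = make_uni((1.0, 1.0), (0.0, 1.0))
    a_ptau = make_uni((10.0, 1.0), (6.0, 1.0))
    return make_biv(at_ratio, at_ptau, k=1.0), make_biv(a_ratio, a_ptau, k=0.0)


@pytest.mark.parametrize("p_at,p_a,label", [
    (0.9, None, "A+/T+"),   # stage 2 short-circuited
    (0.2, 0.8, "A+/T-"),
    (0.2, 0.2, "A-/T±"),
])
def test_trinomial_rule_table(p_at, p_a, label):
    model_at, model_a = _trinomial_pair()
    x_ratio = model_at.ratio_model_.solve_cutoff(p_at)
    x_ptau = (model_a.ptau_model_.solve_cutoff(p_a)
              if p_a is not None else 5.0)
    res = classify_trinomial(model_at, model_a, [x_ratio, x_ptau])
    assert res.label == label
    assert res.p_at == pytest.approx(p_at, abs=1e-9)
    if p_a is None:
        assert res.p_a is None  # second stage never evaluated
    else:
        assert res.p_a == pytest.approx(p_a, abs=1e-9)


def test_trinomial_uncertainty_flags():
    model_at, model_a = _trinomial_pair()
    x = [model_at.ratio_model_.solve_cutoff(0.65), 5.0]
    assert classify_trinomial(model_at, model_a, x).uncertain


def test_trinomial_enrichment_on_cohort(unipg_cohort, bivariate_models):
    clf = SerialTrinomialClassifier(model_at=bivariate_models["A+T+vsRest"],
                                    model_a=bivariate_models["A+vsA-"])
    clf.model_at_ = bivariate_models["A+T+vsRest"]
    clf.model_a_ = bivariate_models["A+vsA-"]
    clf.classes_ = np.array(clf.LABELS)
    X = unipg_cohort[["ratio", "ptau181"]].to_numpy()
    pred = clf.predict(X)
    rates = {s: (pred[(unipg_cohort["stratum"] == s).to_numpy()] == "A+/T+").mean()
             for s in ("A-/T-", "A-/T+", "A+/T-", "A+/T+")}
    assert all(rates["A+/T+"] > rates[s] for s in rates if s != "A+/T+")


def test_trinomial_fit_from_stratum_labels(unipg_cohort):
    df = unipg_cohort
    clf = SerialTrinomialClassifier(n_folds=20, random_state=1)
    clf.fit(df[["ratio", "ptau181"]].to_numpy(), df["stratum"].to_numpy())
    pred = clf.predict(df[["ratio", "ptau181"]].to_numpy()[:5])
    assert set(pred) <= set(clf.LABELS)


# ---------------------------------------------------------------------------
# isoprobability curves

def test_isoprobability_points_re_evaluate(bivariate_models):
    m = bivariate_models["A+vsA-"]
    pts = isoprobability_curve(m, 0.5, (0.03, 0.13), (0.1, 9.0), grid_n=40)
    assert len(pts) > 0
    p = m.posterior(pts)
    assert np.max(np.abs(p - 0.5)) < 1e-6


def test_isoprobability_degenerate_k_is_vertical():
    model_at, _ = _trinomial_pair()  # k = 1: ratio only
    pts = isoprobability_curve(model_at, 0.7, (-5.0, 8.0), (0.0, 10.0),
                               grid_n=25)
    expected = model_at.ratio_model_.solve_cutoff(0.7)
    assert len(pts) == 25
    assert np.allclose(pts[:, 0], expected, atol=1e-9)


def test_isoprobability_unattained_level_empty(bivariate_models):
    m = bivariate_models["A+vsA-"]
    pts = isoprobability_curve(m, 0.999, (0.12, 0.15), (0.1, 0.5), grid_n=20)
    assert pts.shape == (0, 2)


# ---------------------------------------------------------------------------
# serialization

def test_model_json_round_trip(bivariate_models, ratio_model):
    for model in (bivariate_models["A+vsA-"], ratio_model):
        text = model_to_json(model, seed=1)
        back = model_from_json(text)
        if hasattr(model, "ratio_model_"):
            X = np.array([[0.08, 2.0], [0.07, 3.5]])
            assert np.allclose(back.posterior(X), model.posterior(X))
        else:
            xs = np.array([0.07, 0.08, 0.09])
            assert np.allclose(back.posterior(xs), model.posterior(xs))
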