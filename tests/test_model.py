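import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from uorfpred import (
    CoefficientSet,
    SimulationSpec,
    TranslationTargetClassifier,
    UTRFeatures,
    classify,
    fit_logistic,
    prescore,
    score,
    simulate_labeled,
    train,
)
from uorfpred.model import (
    SingleClassError,
    interaction_design,
    stratified_subsets,
)

FEATS = ["uorfs", "atf4like", "length", "gc_percent"]


def _zeros(intercept=0.0):
    return CoefficientSet(beta=(intercept,) + (0.0,) * 10)


def test_coefficient_set_validates_length_and_finiteness():
    with pytest.raises(ValueError):
        CoefficientSet(beta=(1.0,) * 10)
    with pytest.raises(ValueError):
        CoefficientSet(beta=(math.nan,) + (0.0,) * 10)


def test_coefficient_set_json_round_trip(tmp_path):
    c = CoefficientSet(beta=tuple(np.linspace(-1, 1, 11)))
    c.to_json(tmp_path / "m.json", seed=17, trained_on=100, penalty="none")
    assert CoefficientSet.from_json(tmp_path / "m.json") == c


def test_prescore_zero_and_intercept():
    f = UTRFeatures(uorfs=5, atf4like=2, length=100, gc_percent=60.0)
    assert prescore(f, _zeros()) == 0.0
    assert prescore(f, _zeros(1.0)) == 1.0


def test_prescore_term_by_term():
    # b1*A + b2*B + b3*C + b4*D + b5*A*B with (A,B,C,D) = (2,1,270,60):
    # 2 + 1 + 0.01*270 + 0.02*60 + 0.5*2*1 = 7.9
    c = CoefficientSet(beta=(0, 1, 1, 0.01, 0.02, 0.5, 0, 0, 0, 0, 0))
    f = UTRFeatures(uorfs=2, atf4like=1, length=270, gc_percent=60.0)
    assert prescore(f, c) == pytest.approx(7.9)


def test_score_logistic_identities():
    f = UTRFeatures(uorfs=1, atf4like=0, length=0, gc_percent=0.0)
    assert score(f, _zeros(0.0)) == pytest.approx(0.5)
    assert score(f, _zeros(1.0)) == pytest.approx(math.e / (1 + math.e))


def test_score_overflow_safe_and_monotone():
    f = UTRFeatures(uorfs=1, atf4like=0, length=0, gc_percent=0.0)
    lo, hi = score(f, _zeros(-1000.0)), score(f, _zeros(1000.0))
    assert 0.0 <= lo < 0.5 < hi <= 1.0
    grid = [score(f, _zeros(p)) for p in np.linspace(-20, 20, 41)]
    assert all(a < b for a, b in zip(grid, grid[1:]))


def test_classify_requires_uorf_and_strict_threshold():
    f_no_uorf = UTRFeatures(uorfs=0, atf4like=0, length=50, gc_percent=50.0)
    assert not classify(f_no_uorf, _zeros(10.0))  # score ~1 but no uORF
    f = UTRFeatures(uorfs=2, atf4like=0, length=50, gc_percent=50.0)
    assert classify(f, _zeros(1.1))  # score 0.75 > 0.7
    beta_at_threshold = _zeros(math.log(0.7 / 0.3))  # score exactly 0.7
    f3 = UTRFeatures(uorfs=3, atf4like=0, length=50, gc_percent=50.0)
    assert not classify(f3, beta_at_threshold)


def test_fit_logistic_single_class_error():
    X = np.tile([1, 0, 100, 50.0], (20, 1))
    with pytest.raises(SingleClassError):
        fit_logistic(X, np.ones(20))


def test_fit_logistic_recovers_parameters_within_3se(true_beta):
    df = simulate_labeled(SimulationSpec(n=5000, beta=true_beta, seed=3))
    c = fit_logistic(df[FEATS], df["label"])
    # independent oracle fit for estimates and their standard errors
    ref = sm.Logit(
        df["label"].to_numpy(float), interaction_design(df[FEATS])
    ).fit(disp=0)
    z = (np.array(c.beta) - np.array(true_beta.beta)) / ref.bse
    assert np.all(np.abs(z) < 3)


def test_fit_logistic_agrees_with_sklearn(true_beta):
    df = simulate_labeled(SimulationSpec(n=2000, beta=true_beta, seed=9))
    c = fit_logistic(df[FEATS], df["label"])
    sk = LogisticRegression(
        C=np.inf, solver="newton-cg", max_iter=5000, tol=1e-10
    ).fit(
        interaction_design(df[FEATS])[:, 1:], df["label"]
    )
    expected = np.concatenate([sk.intercept_, sk.coef_.ravel()])
    assert np.allclose(np.array(c.beta), expected, rtol=1e-3, atol=1e-4)


def test_fit_logistic_invariant_under_row_duplication(true_beta):
    df = simulate_labeled(SimulationSpec(n=400, beta=true_beta, seed=2))
    X, y = df[FEATS].to_numpy(), df["label"].to_numpy()
    c1 = fit_logistic(X, y)
    c2 = fit_logistic(np.vstack([X, X]), np.concatenate([y, y]))
    assert np.allclose(c1.beta, c2.beta, atol=1e-6)


def test_stratified_subsets_pigeonhole_counts():
    # 321 positives / 418 negatives dealt into 4 subsets
    y = np.array([1] * 321 + [0] * 418)
    subsets = stratified_subsets(y, 4, seed=17)
    pos = sorted(int(y[s].sum()) for s in subsets)
    neg = sorted(int((1 - y[s]).sum()) for s in subsets)
    assert pos == [80, 80, 80, 81]
    assert neg == [104, 104, 105, 105]
    all_idx = np.concatenate(subsets)
    assert len(all_idx) == 739 and len(set(all_idx.tolist())) == 739


def test_train_deterministic_and_averages_submodels(true_beta):
    df = simulate_labeled(SimulationSpec(n=400, beta=true_beta, seed=1))
    X, y = df[FEATS], df["label"]
    est1 = TranslationTargetClassifier(random_state=1).fit(X, y)
    est2 = TranslationTargetClassifier(random_state=1).fit(X, y)
    assert est1.coefficients_ == est2.coefficients_
    subs = np.array([c.beta for c in est1.submodel_coefficients_])
    assert subs.shape == (4, 11)
    assert np.array_equal(
        np.array(est1.coefficients_.beta), subs.mean(axis=0)
    )
    assert len(est1.fold_metrics_) == 4
    assert all(len(m) == 20 for m in est1.fold_metrics_)


def test_train_recovers_parameters_within_3se(true_beta):
    df = simulate_labeled(SimulationSpec(n=4000, beta=true_beta, seed=1))
    coefs, _ = train(df[FEATS], df["label"], seed=1)
    ref = sm.Logit(
        df["label"].to_numpy(float), interaction_design(df[FEATS])
    ).fit(disp=0)
    z = (np.array(coefs.beta) - np.array(true_beta.beta)) / ref.bse
    assert np.all(np.abs(z) < 3)


def test_train_rejects_uorf_free_examples(true_beta):
    df = simulate_labeled(SimulationSpec(n=100, beta=true_beta, seed=4))
    X = df[FEATS].to_numpy()
    X[0, 0] = 0
    with pytest.raises(ValueError, match="uORF"):
        TranslationTargetClassifier().fit(X, df["label"])


def test_predict_is_monotone_in_threshold(true_beta):
    df = simulate_labeled(SimulationSpec(n=500, beta=true_beta, seed=6))
    X = df[FEATS]
    est = TranslationTargetClassifier(random_state=0).fit(X, df["label"])
    counts = []
    for t in np.arange(0.0, 1.0, 0.05):
        est.threshold = t
        counts.append(int(est.predict(X).sum()))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_uorf_free_transcripts_never_positive(true_beta):
    est = TranslationTargetClassifier.from_coefficients(
        CoefficientSet(beta=(50.0,) + (0.0,) * 10)
    )
    X = pd.DataFrame(
        [[0, 0, 100, 50.0], [1, 0, 100, 50.0]], columns=FEATS
    )
    assert est.predict(X).tolist() == [0, 1]
    assert est.predict_score(X).tolist() == pytest.approx([1.0, 1.0])


def test_classifier_sklearn_protocol(true_beta):
    est = TranslationTargetClassifier(threshold=0.6, random_state=5)
    assert est.get_params()["threshold"] == 0.6
    est.set_params(threshold=0.7)
    df = simulate_labeled(SimulationSpec(n=300, beta=true_beta, seed=8))
    est.fit(df[FEATS], df["label"])
    proba = est.predict_proba(df[FEATS])
    assert proba.shape == (300, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert set(np.unique(est.predict(df[FEATS]))) <= {0, 1}
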