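"""Background-model layer: counting, stability selection, GLM, GBM, CV."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from driverscan import (
    ElementSet,
    GenomicElement,
    MutationCatalog,
    RegionMask,
    count_mutations,
    evaluate_cv,
    fit_binomial_glm,
    fit_gbm,
    gbm_importance,
    predict_expected,
    select_features_randomized_lasso,
)
from driverscan.bmr import GBMConfig, assign_mutations, read_mutations


def muts_df(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt", "donor_id"])
    df["is_indel"] = df["ref"].str.len() != df["alt"].str.len()
    return df


def make_catalog(y, L, N, n_d=None):
    ids = [f"e{i}" for i in range(len(y))]
    table = pd.DataFrame(
        {"y": y, "n_d": n_d if n_d is not None else np.minimum(y, N), "L": L},
        index=pd.Index(ids, name="element_id"),
    )
    return MutationCatalog(table, N)


# ---------------------------------------------------------------------------
# mutation counting conventions
# ---------------------------------------------------------------------------

def test_count_occurrences_and_distinct_donors():
    es = ElementSet("t")
    es.add(GenomicElement("e1", {"chr1": [(0, 100)]}))
    muts = muts_df([("chr1", 10, "A", "T", "d1"), ("chr1", 20, "C", "G", "d1")])
    cat = count_mutations(muts, es, hypermutator_cutoff=None)
    assert cat.y["e1"] == 2
    assert cat.n_d["e1"] == 1
    assert cat.n_donors == 1


def test_masked_base_not_counted():
    es = ElementSet("t")
    es.add(GenomicElement("e1", {"chr1": [(0, 100)]}))
    mask = RegionMask({"chr1": [(0, 50)]})
    muts = muts_df([("chr1", 10, "A", "T", "d1"), ("chr1", 60, "C", "G", "d1")])
    cat = count_mutations(muts, es, mask=mask, hypermutator_cutoff=None)
    assert cat.y["e1"] == 1
    assert cat.L["e1"] == 50


def test_half_open_end_excluded():
    es = ElementSet("t")
    es.add(GenomicElement("e1", {"chr1": [(0, 100)]}))
    muts = muts_df([("chr1", 100, "A", "T", "d1"), ("chr1", 99, "C", "G", "d2")])
    cat = count_mutations(muts, es, hypermutator_cutoff=None)
    assert cat.y["e1"] == 1


def test_overlapping_elements_both_counted():
    es = ElementSet("t")
    es.add(GenomicElement("e1", {"chr1": [(0, 100)]}))
    es.add(GenomicElement("e2", {"chr1": [(50, 150)]}))
    muts = muts_df([("chr1", 75, "A", "T", "d1")])
    cat = count_mutations(muts, es, hypermutator_cutoff=None)
    assert cat.y["e1"] == 1 and cat.y["e2"] == 1


def test_unknown_chromosome_warns_and_skips():
    es = ElementSet("t")
    es.add(GenomicElement("e1", {"chr1": [(0, 100)]}))
    muts = muts_df([("chrZ", 5, "A", "T", "d1"), ("chr1", 5, "A", "T", "d1")])
    with pytest.warns(UserWarning, match="unknown chromosomes"):
        cat = count_mutations(muts, es, hypermutator_cutoff=None)
    assert cat.y["e1"] == 1


def test_donor_roster_fixes_cohort_size():
    es = ElementSet("t")
    es.add(GenomicElement("e1", {"chr1": [(0, 100)]}))
    muts = muts_df([("chr1", 5, "A", "T", "d1")])
    cat = count_mutations(
        muts, es, donors=["d1", "d2", "d3"], hypermutator_cutoff=None
    )
    assert cat.n_donors == 3  # zero-mutation donors still count


def test_hypermutator_donor_excluded():
    es = ElementSet("t")
    es.add(GenomicElement("e1", {"chr1": [(0, 100)]}))
    # d1: 50 mutations over a 1 Mb genome = 50/Mb > 30/Mb cutoff
    rows = [("chr1", i, "A", "T", "d1") for i in range(50)]
    rows += [("chr1", 60, "C", "G", "d2")]
    cat = count_mutations(
        muts_df(rows), es, donors=["d1", "d2"], genome_bp=1e6,
        hypermutator_cutoff=30.0,
    )
    assert cat.excluded_donors == ("d1",)
    assert cat.n_donors == 1
    assert cat.y["e1"] == 1


def test_indel_assigned_by_start_position():
    es = ElementSet("t")
    es.add(GenomicElement("e1", {"chr1": [(0, 100)]}))
    muts = muts_df([("chr1", 99, "AT", "A", "d1")])  # deletion starting inside
    cat = count_mutations(muts, es, hypermutator_cutoff=None)
    assert cat.y["e1"] == 1


def test_read_mutations_with_and_without_header(tmp_path):
    body = "chr1\t5\tA\tT\td1\n"
    p1 = tmp_path / "no_header.tsv"
    p1.write_text(body)
    p2 = tmp_path / "header.tsv"
    p2.write_text("chrom\tpos0\tref\talt\tdonor_id\n" + body)
    for p in (p1, p2):
        df = read_mutations(str(p))
        assert df.iloc[0]["pos0"] == 5
        assert not df.iloc[0]["is_indel"]


# ---------------------------------------------------------------------------
# randomised lasso
# ---------------------------------------------------------------------------

def _lasso_cohort(seed, n=2000, n_noise=20, effect=0.8, exact=True):
    """One informative feature among independent noise features.

    With ``exact`` the response is (up to count rounding) a linear function
    of the informative feature; otherwise binomial sampling noise is added.
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, 1 + n_noise)),
        columns=["true"] + [f"noise{i}" for i in range(n_noise)],
        index=[f"e{i}" for i in range(n)],
    )
    L = np.full(n, 1000.0)
    N = 200
    rate = expit(-8.0 + effect * X["true"].to_numpy())
    if exact:
        y = np.round(N * L * rate - 0.5).astype(int)
    else:
        y = np.random.default_rng(seed + 1).binomial(
            np.round(N * L).astype(int), rate
        )
    cat = make_catalog(np.maximum(y, 0), L, N)
    cat.table.index = X.index
    return X, cat


def test_lasso_separates_determining_feature_from_noise():
    for seed in (0, 1, 2):
        X, cat = _lasso_cohort(seed, exact=True)
        sel = select_features_randomized_lasso(
            X, cat, n_repeats=150, seed=seed
        )
        assert sel.importance["true"] > 0.5
        assert sel.importance.drop("true").max() < 0.5
        assert sel.selected == ["true"]


def test_lasso_keeps_informative_feature_under_sampling_noise():
    X, cat = _lasso_cohort(3, exact=False)
    sel = select_features_randomized_lasso(X, cat, n_repeats=150, seed=3)
    assert "true" in sel.selected
    assert sel.importance["true"] == 1.0


def test_lasso_constant_response_selects_nothing():
    rng = np.random.default_rng(0)
    n = 300
    X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"),
                     index=[f"e{i}" for i in range(n)])
    cat = make_catalog(np.full(n, 10), np.full(n, 1000.0), 100)
    cat.table.index = X.index
    sel = select_features_randomized_lasso(X, cat, n_repeats=50, seed=3)
    assert sel.selected == []


def test_lasso_deterministic_under_seed():
    X, cat = _lasso_cohort(5, n=400)
    a = select_features_randomized_lasso(X, cat, n_repeats=40, seed=9)
    b = select_features_randomized_lasso(X, cat, n_repeats=40, seed=9)
    assert a.alpha == b.alpha
    assert a.importance.equals(b.importance)


def test_lasso_requires_enough_rows():
    X, cat = _lasso_cohort(0, n=2000)
    with pytest.raises(ValueError):
        select_features_randomized_lasso(
            X.iloc[:5], MutationCatalog(cat.table.iloc[:5], cat.n_donors)
        )


# ---------------------------------------------------------------------------
# binomial GLM
# ---------------------------------------------------------------------------

def test_glm_intercept_only_matches_pooled_rate():
    rng = np.random.default_rng(1)
    n, N = 500, 100
    L = rng.integers(500, 2000, n).astype(float)
    y = rng.poisson(N * L * 1e-5)
    cat = make_catalog(y, L, N)
    X = pd.DataFrame(index=cat.table.index)  # no features
    model = fit_binomial_glm(X, cat)
    p_hat = expit(model.beta["const"])
    assert p_hat == pytest.approx(y.sum() / (N * L).sum(), rel=1e-6)


def test_glm_rejects_counts_exceeding_trials():
    cat = make_catalog([200], [1.0], 100)  # y=200 > N*L=100
    with pytest.raises(ValueError, match="exceeds"):
        fit_binomial_glm(pd.DataFrame(index=cat.table.index), cat)


def test_glm_all_zero_response_warns_boundary():
    cat = make_catalog([0] * 50, [1000.0] * 50, 100)
    with pytest.warns(UserWarning, match="boundary"):
        model = fit_binomial_glm(pd.DataFrame(index=cat.table.index), cat)
    assert expit(model.beta["const"]) < 1e-6


def test_glm_recovers_known_coefficients():
    hits = 0
    reps = 5
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        n, N = 10_000, 200
        beta = np.array([-9.0, 0.4, -0.3])
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"],
                         index=[f"e{i}" for i in range(n)])
        L = np.full(n, 1000.0)
        ntr = np.round(N * L).astype(int)
        p = expit(beta[0] + X.to_numpy() @ beta[1:])
        y = rng.binomial(ntr, p)
        cat = make_catalog(y, L, N)
        cat.table.index = X.index
        model = fit_binomial_glm(X, cat)
        se = model.result.bse
        ok = all(
            abs(model.beta.iloc[k] - beta[k]) < 3 * se[k] for k in range(3)
        )
        hits += ok
    assert hits >= reps - 1


# ---------------------------------------------------------------------------
# gradient-boosted model
# ---------------------------------------------------------------------------

def test_gbm_constant_feature_converges_to_pooled_rate():
    rng = np.random.default_rng(2)
    n, N = 2000, 100
    L = rng.integers(500, 3000, n).astype(float)
    y = rng.poisson(N * L * 2e-5)
    cat = make_catalog(y, L, N)
    X = pd.DataFrame({"c": np.ones(n)}, index=cat.table.index)
    model = fit_gbm(X, cat, GBMConfig(nrounds=500), seed=0)
    yhat = predict_expected(model, X, cat.L, cat.n_donors)
    rates = yhat.to_numpy() / (N * L)
    pooled = y.sum() / (N * L).sum()
    assert np.allclose(rates, pooled, rtol=0.02)


def test_gbm_deterministic_under_seed():
    rng = np.random.default_rng(3)
    n, N = 500, 50
    L = np.full(n, 1000.0)
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"),
                     index=[f"e{i}" for i in range(n)])
    y = rng.poisson(N * L * 1e-5 * np.exp(0.3 * X["a"].to_numpy()))
    cat = make_catalog(y, L, N)
    cat.table.index = X.index
    m1 = fit_gbm(X, cat, GBMConfig(nrounds=100), seed=11)
    m2 = fit_gbm(X, cat, GBMConfig(nrounds=100), seed=11)
    p1 = predict_expected(m1, X, cat.L, cat.n_donors)
    p2 = predict_expected(m2, X, cat.L, cat.n_donors)
    assert np.array_equal(p1.to_numpy(), p2.to_numpy())


def test_gbm_importance_normalisation():
    rng = np.random.default_rng(4)
    n, N = 1000, 100
    L = np.full(n, 1000.0)
    X = pd.DataFrame(
        {"signal": rng.normal(size=n), "dead": np.zeros(n)},
        index=[f"e{i}" for i in range(n)],
    )
    y = rng.poisson(N * L * 1e-5 * np.exp(0.5 * X["signal"].to_numpy()))
    cat = make_catalog(y, L, N)
    cat.table.index = X.index
    model = fit_gbm(X, cat, GBMConfig(nrounds=100), seed=0)
    imp = gbm_importance(model)
    assert imp["share"].sum() == pytest.approx(1.0)
    assert imp.loc["signal", "normalized"] == 1.0
    assert imp.loc["dead", "share"] == 0.0  # constant feature never split on


def test_predict_expected_contracts():
    rng = np.random.default_rng(5)
    n, N = 200, 50
    L = np.full(n, 1000.0)
    L[0] = 0.0  # untestable
    X = pd.DataFrame({"a": rng.normal(size=n)},
                     index=[f"e{i}" for i in range(n)])
    y = rng.poisson(np.where(L > 0, N * L * 1e-5, 0))
    cat = make_catalog(y, L, N)
    cat.table.index = X.index
    model = fit_gbm(X, cat, GBMConfig(nrounds=50), seed=0)
    yhat = predict_expected(model, X, cat.L, cat.n_donors)
    assert np.isnan(yhat.iloc[0])
    assert (yhat.iloc[1:] > 0).all()
    with pytest.raises(ValueError, match="lacks model features"):
        predict_expected(model, X.rename(columns={"a": "zz"}), cat.L, N)


def test_training_balance_sum_yhat_close_to_sum_y():
    rng = np.random.default_rng(6)
    n, N = 2000, 100
    L = rng.integers(500, 3000, n).astype(float)
    X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"],
                     index=[f"e{i}" for i in range(n)])
    y = rng.poisson(N * L * 1e-5 * np.exp(0.3 * X["a"].to_numpy()))
    cat = make_catalog(y, L, N)
    cat.table.index = X.index
    for fit in (
        lambda: fit_gbm(X, cat, GBMConfig(nrounds=300), seed=0),
        lambda: fit_binomial_glm(X, cat),
    ):
        model = fit()
        yhat = predict_expected(model, X, cat.L, cat.n_donors)
        assert yhat.sum() == pytest.approx(y.sum(), rel=0.02)


def test_model_persistence_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    n, N = 300, 50
    L = np.full(n, 1000.0)
    X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"],
                     index=[f"e{i}" for i in range(n)])
    y = rng.poisson(N * L * 1e-5 * np.exp(0.3 * X["a"].to_numpy()))
    cat = make_catalog(y, L, N)
    cat.table.index = X.index
    from driverscan.bmr import load_model, save_model

    for model in (
        fit_gbm(X, cat, GBMConfig(nrounds=50), seed=0),
        fit_binomial_glm(X, cat),
    ):
        path = tmp_path / "model.json"
        save_model(model, path)
        restored = load_model(path)
        assert restored.feature_names == model.feature_names
        a = predict_expected(model, X, cat.L, N)
        b = predict_expected(restored, X, cat.L, N)
        assert np.allclose(a.to_numpy(), b.to_numpy())


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

def test_evaluate_cv_hand_checked_metrics():
    # the metric definitions themselves, against brute-force formulas
    from driverscan.bmr import _r2

    y = np.array([1.0, 3.0, 5.0, 2.0, 4.0])
    yhat = np.array([1.5, 2.5, 4.5, 2.5, 4.0])
    want = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
    assert _r2(y, yhat) == pytest.approx(want)
    assert _r2(y, y) == 1.0
    assert _r2(y, np.full_like(y, y.mean())) == 0.0


def test_evaluate_cv_modes_partition_folds():
    rng = np.random.default_rng(7)
    n, N = 1500, 100
    L = np.full(n, 2000.0)
    X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"],
                     index=[f"e{i}" for i in range(n)])
    y = rng.poisson(N * L * 1e-5 * np.exp(0.5 * X["a"].to_numpy()))
    cat = make_catalog(y, L, N)
    cat.table.index = X.index
    for mode in ("standard", "inverted"):
        out = evaluate_cv("glm", X, cat, k_folds=5, mode=mode, seed=1)
        assert len(out["fold_R2"]) == 5
        assert 0 < out["R2"] <= 1
        assert 0 < out["pearson_r"] <= 1
        assert out["sem_R2"] >= 0
    with pytest.raises(ValueError):
        evaluate_cv("glm", X, cat, k_folds=1)
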