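import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sigscreen as sg
from sigscreen.de import (
    build_design,
    filter_low_expression,
    fit_and_test,
    precision_weights,
    run_pairwise_de,
    tmm_factors,
)


# ---------------------------------------------------------------------------
# oracles (kept deliberately naive and separate from the implementation)


def tmm_oracle(X, logratio_trim=0.3, sum_trim=0.05):
    """Direct trimmed weighted M-value mean, via pandas ranks and loops."""
    X = np.asarray(X, dtype=float)
    lib = X.sum(axis=0)
    f75 = np.array([pd.Series(X[:, j] / lib[j]).quantile(0.75) for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    raw = []
    for j in range(X.shape[1]):
        rows = []
        for g in range(X.shape[0]):
            o, r = X[g, j], X[g, ref]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref]
                M = np.log2(po / pr)
                A = 0.5 * np.log2(po * pr)
                v = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
                rows.append((M, A, v))
        if not rows or max(abs(m) for m, _, _ in rows) < 1e-6:
            raw.append(1.0)
            continue
        df = pd.DataFrame(rows, columns=["M", "A", "v"])
        n = len(df)
        loL, hiL = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        loS, hiS = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        rM, rA = df["M"].rank(), df["A"].rank()
        keep = (rM >= loL) & (rM <= hiL) & (rA >= loS) & (rA <= hiS)
        sub = df[keep]
        f = (sub["M"] / sub["v"]).sum() / (1.0 / sub["v"]).sum()
        raw.append(2.0 ** f)
    raw = np.array(raw)
    return raw / np.exp(np.mean(np.log(raw)))


def weighted_ttest_oracle(y, X, w, c, df_resid):
    """Ordinary per-gene weighted least-squares t-test via explicit algebra."""
    pvals, tvals = [], []
    for g in range(y.shape[0]):
        W = np.diag(w[g])
        XtWX = X.T @ W @ X
        beta = np.linalg.solve(XtWX, X.T @ W @ y[g])
        resid = y[g] - X @ beta
        s2 = float(resid @ W @ resid) / df_resid
        se = np.sqrt(s2 * float(c @ np.linalg.solve(XtWX, c)))
        t = float(c @ beta) / se
        tvals.append(t)
        pvals.append(2 * stats.t.sf(abs(t), df_resid))
    return np.array(tvals), np.array(pvals)


# ---------------------------------------------------------------------------
# design matrices


def test_design_group_means():
    ann = pd.DataFrame({"Group": ["A", "A", "B", "B", "C", "C"]},
                       index=[f"s{i}" for i in range(6)])
    d = build_design(ann)
    assert d.matrix.shape == (6, 3)
    assert list(d.matrix.sum()) == [2.0, 2.0, 2.0]
    assert (d.matrix.sum(axis=1) == 1).all()  # one group column per sample


def test_design_with_batch():
    ann = pd.DataFrame(
        {"Group": ["A", "A", "B", "B", "C", "C"], "Batch": ["1", "1", "1", "2", "2", "2"]},
        index=[f"s{i}" for i in range(6)],
    )
    d = build_design(ann)
    assert d.matrix.shape == (6, 4)
    assert "batch_2" in d.matrix.columns


def test_design_confounded_batch_rejected():
    ann = pd.DataFrame(
        {"Group": ["A", "A", "B", "B"], "Batch": ["1", "1", "2", "2"]},
        index=[f"s{i}" for i in range(4)],
    )
    with pytest.raises(ValueError, match="rank deficient"):
        build_design(ann)


def test_design_single_group_rejected():
    ann = pd.DataFrame({"Group": ["A", "A"]}, index=["s1", "s2"])
    with pytest.raises(ValueError, match="2 groups"):
        build_design(ann)


# ---------------------------------------------------------------------------
# expression filtering


def test_filter_extremes(tiny_counts):
    values = tiny_counts.values.copy()
    values.loc["zero"] = 0
    values.loc["huge"] = 1000
    ds = sg.ExpressionDataset(values=values, scale="raw_counts",
                              annotations=tiny_counts.annotations)
    mask = filter_low_expression(ds)
    assert not mask["zero"]
    assert mask["huge"]


def test_filter_matches_direct_rule():
    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.integers(0, 60, size=(20, 5)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(5)],
    )
    ann = pd.DataFrame({"Group": ["A", "A", "B", "B", "B"]}, index=values.columns)
    ds = sg.ExpressionDataset(values=values, scale="raw_counts", annotations=ann)
    mask = filter_low_expression(ds, min_count=10, min_total=15)
    X = values.to_numpy(float)
    lib = X.sum(axis=0)
    cutoff = 10 / np.median(lib) * 1e6
    expected = (((X / lib * 1e6) >= cutoff).sum(axis=1) >= 2) & (X.sum(axis=1) >= 15)
    assert (mask.to_numpy() == expected).all()


# ---------------------------------------------------------------------------
# TMM


def test_tmm_identical_columns():
    X = np.tile(np.arange(1, 101)[:, None], (1, 4))
    assert np.allclose(tmm_factors(X), 1.0)


def test_tmm_pure_depth_difference():
    rng = np.random.default_rng(0)
    a = rng.integers(1, 500, size=300).astype(float)
    X = np.column_stack([a, 2 * a, 5 * a])
    assert np.allclose(tmm_factors(X), 1.0)


def test_tmm_matches_oracle():
    rng = np.random.default_rng(11)
    for _ in range(10):
        X = rng.negative_binomial(5, 0.1, size=(200, 4)).astype(float)
        up = rng.choice(200, 20, replace=False)
        X[up, -1] *= 8  # composition bias in the last sample
        got = tmm_factors(X)
        want = tmm_oracle(X)
        assert np.max(np.abs(got - want)) < 1e-10


def test_tmm_geometric_mean_is_one():
    rng = np.random.default_rng(5)
    X = rng.poisson(30, size=(150, 6)).astype(float)
    f = tmm_factors(X)
    assert abs(np.prod(f) ** (1 / len(f)) - 1.0) < 1e-12


def test_tmm_zero_library_rejected():
    X = np.zeros((10, 2))
    X[:, 0] = 5
    with pytest.raises(ValueError, match="zero total"):
        tmm_factors(X)


# ---------------------------------------------------------------------------
# precision weights


def test_weights_equal_for_equal_genes():
    ann = pd.DataFrame({"Group": ["A"] * 3 + ["B"] * 3}, index=[f"s{i}" for i in range(6)])
    design = build_design(ann)
    rng = np.random.default_rng(1)
    X = rng.poisson(100, size=(50, 6)).astype(float)
    X[0] = X[1]  # two genes identical in every sample
    w, y = precision_weights(X, design)
    assert np.allclose(w[0], w[1])
    assert np.all(w > 0) and np.all(np.isfinite(w))


def test_weights_increase_with_mean_count():
    """Mean-variance trend: high-count genes get larger average weights."""
    rng = np.random.default_rng(2)
    ann = pd.DataFrame({"Group": ["A"] * 4 + ["B"] * 4}, index=[f"s{i}" for i in range(8)])
    design = build_design(ann)
    means = np.repeat([5.0, 50.0, 500.0], 60)
    X = rng.poisson(means[:, None] * np.ones(8), size=(180, 8)).astype(float)
    w, _ = precision_weights(X, design)
    grp = w.mean(axis=1)
    assert grp[:60].mean() < grp[60:120].mean() < grp[120:].mean()


# ---------------------------------------------------------------------------
# moderated fitting and the threshold test


def _toy_fit_inputs(seed=0, G=40, var_spread=True):
    rng = np.random.default_rng(seed)
    ann = pd.DataFrame({"Group": ["A"] * 4 + ["B"] * 4}, index=[f"s{i}" for i in range(8)])
    design = build_design(ann)
    sd = rng.uniform(0.3, 1.5, size=G) if var_spread else np.ones(G)
    y = rng.normal(0, sd[:, None], size=(G, 8)) + 5
    w = rng.uniform(0.5, 2.0, size=(G, 8))
    return y, design, w


def test_prior_df_zero_equals_plain_weighted_ttest():
    y, design, w = _toy_fit_inputs()
    c = design.contrast("A", "B")
    res = fit_and_test(y, design, c, weights=w, lfc_threshold=0.0, prior_df=0)
    X = design.matrix.to_numpy()
    t_or, p_or = weighted_ttest_oracle(y, X, w, c, df_resid=8 - 2)
    assert np.max(np.abs(res["t"].to_numpy() - t_or)) < 1e-8
    assert np.max(np.abs(res["p_value"].to_numpy() - p_or)) < 1e-8


def test_zero_threshold_reduces_to_moderated_t():
    y, design, w = _toy_fit_inputs(seed=1)
    c = design.contrast("A", "B")
    plain = fit_and_test(y, design, c, weights=w, lfc_threshold=0.0)
    thr = fit_and_test(y, design, c, weights=w, lfc_threshold=0.0)
    assert np.allclose(plain["p_value"], thr["p_value"])


def test_equal_group_means_null_centered_under_treat():
    ann = pd.DataFrame({"Group": ["A"] * 3 + ["B"] * 3}, index=[f"s{i}" for i in range(6)])
    design = build_design(ann)
    rng = np.random.default_rng(4)
    y = rng.normal(0, 0.5, size=(30, 6))
    y[0] = [1.0, 2.0, 3.0, 3.0, 2.0, 1.0]  # identical group means
    res = fit_and_test(y, design, design.contrast("A", "B"), lfc_threshold=0.5)
    assert abs(res["logFC"].iloc[0]) < 1e-12
    assert res["p_value"].iloc[0] >= 0.5


def test_adjusted_p_dominates_raw():
    y, design, w = _toy_fit_inputs(seed=2)
    res = fit_and_test(y, design, design.contrast("A", "B"), weights=w)
    assert (res["adj_p_value"] >= res["p_value"] - 1e-15).all()
    assert res["p_value"].between(0, 1).all()


def test_invariance_to_noncontrast_relabeling(sim_dataset):
    ds, _ = sim_dataset
    cfg = sg.RunConfig(target_group="GA", seed=0, n_permutations=10)
    res1 = run_pairwise_de(ds, cfg)
    swapped = ds.annotations.copy()
    swapped["Group"] = swapped["Group"].map(
        {"GA": "GA", "GB": "GB", "GC": "GD", "GD": "GC"}
    )
    ds2 = sg.ExpressionDataset(values=ds.values, scale=ds.scale, annotations=swapped)
    res2 = run_pairwise_de(ds2, cfg)
    by_other1 = {r.other_group: r for r in res1}
    by_other2 = {r.other_group: r for r in res2}
    # the GB comparison is untouched by relabeling GC<->GD
    pd.testing.assert_frame_equal(by_other1["GB"].table, by_other2["GB"].table)
    # the GC comparison now lives under the name GD with identical statistics
    pd.testing.assert_frame_equal(by_other1["GC"].table, by_other2["GD"].table)


def test_invariance_to_sample_order(sim_dataset):
    ds, _ = sim_dataset
    rng = np.random.default_rng(9)
    perm = rng.permutation(ds.samples)
    shuffled = sg.ExpressionDataset(
        values=ds.values.loc[:, perm], scale=ds.scale, annotations=ds.annotations.loc[perm]
    )
    cfg = sg.RunConfig(target_group="GA", seed=0, n_permutations=10)
    r1 = run_pairwise_de(ds, cfg)[0].table
    r2 = run_pairwise_de(shuffled, cfg)[0].table
    pd.testing.assert_frame_equal(r1, r2, atol=1e-10, rtol=1e-8)


def test_pairwise_counts_and_planted_markers(sim_dataset):
    ds, truth = sim_dataset
    cfg = sg.RunConfig(target_group="GA", seed=0)
    results = run_pairwise_de(ds, cfg)
    assert len(results) == 3  # n-1 comparisons
    markers = [g for g in truth.marker_genes["GA"] if g in results[0].table.index]
    for r in results:
        # among target-up genes; the other group's own markers occupy the down tail
        up = r.table[r.table["logFC"] > 0]
        top = set(up.nsmallest(len(markers) + 15, "adj_p_value").index)
        overlap = len(top & set(markers)) / len(markers)
        assert overlap >= 0.9, f"{r.comparison}: planted markers not at the top"


def test_target_group_absent():
    ann = pd.DataFrame({"Group": ["A", "A", "B", "B"]}, index=[f"s{i}" for i in range(4)])
    values = pd.DataFrame(
        np.random.default_rng(0).poisson(50, size=(30, 4)),
        index=[f"g{i}" for i in range(30)],
        columns=ann.index,
    )
    ds = sg.ExpressionDataset(values=values, scale="raw_counts", annotations=ann)
    with pytest.raises(ValueError, match="not in the data|not in data"):
        run_pairwise_de(ds, sg.RunConfig(target_group="Z"))
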