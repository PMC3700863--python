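import itertools

import numpy as np
import pytest

from rangeshift.maxent import (
    Feature,
    FeatureSet,
    auc,
    build_features,
    fit,
    jackknife_importance,
    logistic_output,
    sample_background,
    split_train_test,
)
from rangeshift.synth import TruthModel, sample_occurrences
from rangeshift.varselect import VariableSelection


def toy_featureset(layer_values, name="f"):
    """Single linear feature over a 1-row grid with the given cell values."""
    layer = np.asarray(layer_values, dtype=float)[None, :]
    return FeatureSet(
        variables=[name],
        features=[Feature("linear", name)],
        vmin={name: float(layer.min())},
        vmax={name: float(layer.max())},
        layers={name: layer},
        grid_shape=layer.shape,
    )


THREE_CELLS = [(0, 0), (0, 1), (0, 2)]


# --- feature construction --------------------------------------------------

def test_linear_feature_is_minmax_scaled(bioclim10):
    cells = np.argwhere(bioclim10.valid_mask)
    fs = build_features(
        bioclim10, VariableSelection(["BIO1"]), cells, use_hinge=False, use_quadratic=False
    )
    vals = bioclim10["BIO1"][cells[:, 0], cells[:, 1]]
    expected = (vals - vals.min()) / (vals.max() - vals.min())
    np.testing.assert_allclose(fs.matrix(cells)[:, 0], expected)


def test_constant_variable_drops_quadratic_and_hinge(bioclim10, caplog):
    layers = dict(bioclim10.layers)
    layers["BIO1"] = np.full_like(layers["BIO1"], 5.0)
    import rangeshift.bioclim as bc

    stack = bc.BioclimStack(bioclim10.grid, layers)
    cells = np.argwhere(stack.valid_mask)
    with caplog.at_level("INFO"):
        fs = build_features(stack, VariableSelection(["BIO1", "BIO12"]), cells, use_hinge=True)
    kinds = {(f.variable, f.kind) for f in fs.features}
    assert ("BIO1", "quadratic") not in kinds
    assert not any(v == "BIO1" and k == "hinge" for v, k in kinds)
    assert ("BIO12", "quadratic") in kinds
    # fitting leaves the degenerate feature's weight at zero
    model = fit(fs, cells[:10], cells, beta=0.1)
    bio1_idx = [i for i, f in enumerate(fs.features) if f.variable == "BIO1"]
    assert all(model.lam[i] == 0.0 for i in bio1_idx)


def hand_decile_knots(values, k=10):
    """Quantiles by the explicit linear-interpolation formula."""
    v = np.sort(np.asarray(values, float))
    n = len(v)
    knots = []
    for j in range(k):
        pos = (j / k) * (n - 1)
        lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
        knots.append(v[lo] * (1 - frac) + v[min(lo + 1, n - 1)] * frac)
    return knots


def test_hinge_knots_at_deciles(grid10):
    import rangeshift.bioclim as bc

    vals = np.arange(100, dtype=float).reshape(10, 10)
    layers = {name: vals for name in bc.BIOCLIM_NAMES}
    stack = bc.BioclimStack(grid10, layers)
    cells = np.argwhere(np.ones((10, 10), bool))
    fs = build_features(stack, VariableSelection(["BIO1"]), cells, use_hinge=True, knots=10)
    knots = [f.knot for f in fs.features if f.kind == "hinge"]
    np.testing.assert_allclose(knots, hand_decile_knots(vals.ravel()), rtol=1e-12)


def test_projection_clamps_to_training_range():
    fs = toy_featureset([0.0, 5.0, 10.0])
    beyond = {"f": np.array([[-5.0, 12.0, 7.0]])}
    mat = fs.matrix(THREE_CELLS, layers=beyond, clamp=True)
    np.testing.assert_allclose(mat[:, 0], [0.0, 1.0, 0.7])


# --- fitting ---------------------------------------------------------------

def test_fit_uniform_limit():
    """Presence means equal to background means: weights 0, q uniform."""
    fs = toy_featureset([0.0, 0.5, 1.0])
    model = fit(fs, THREE_CELLS, THREE_CELLS, beta=0.0)
    np.testing.assert_allclose(model.lam, 0.0, atol=1e-8)
    np.testing.assert_allclose(model.raw_on_background(), 1 / 3, atol=1e-6)


def grid_search_lambda(f_values, pbar, beta=0.0, scale=0.0, lo=-30, hi=30, steps=600001):
    """Brute-force 1-D minimizer of the maxent objective."""
    lam = np.linspace(lo, hi, steps)
    scores = np.outer(lam, f_values)
    log_z = np.log(np.exp(scores).sum(axis=1))
    obj = -pbar * lam + log_z + beta * scale * np.abs(lam)
    return lam[np.argmin(obj)]


def test_fit_matches_1d_grid_search_oracle():
    fs = toy_featureset([0.0, 0.5, 1.0])
    presences = [(0, 2), (0, 2), (0, 1)]  # pbar = 5/6
    model = fit(fs, presences, THREE_CELLS, beta=0.0, tol=1e-12)
    oracle = grid_search_lambda(np.array([0.0, 0.5, 1.0]), 5 / 6)
    assert model.lam[0] == pytest.approx(oracle, abs=1e-3)


def test_fit_concentrates_on_best_cell():
    """All presences at the top cell: fitted q piles up there."""
    fs = toy_featureset([0.0, 0.5, 1.0])
    model = fit(fs, [(0, 2)] * 5, THREE_CELLS, beta=0.0)
    q = model.raw_on_background()
    assert q[2] > 0.99


def test_fit_regularized_matches_grid_search():
    fs = toy_featureset([0.0, 0.5, 1.0])
    presences = [(0, 2), (0, 2), (0, 1), (0, 0)]
    f_pres = np.array([1.0, 1.0, 0.5, 0.0])
    beta, m = 0.5, 4
    scale = f_pres.std() / np.sqrt(m)
    model = fit(fs, presences, THREE_CELLS, beta=beta, tol=1e-12)
    oracle = grid_search_lambda(np.array([0.0, 0.5, 1.0]), f_pres.mean(), beta, scale)
    assert model.lam[0] == pytest.approx(oracle, abs=1e-3)


def test_fit_requires_presences():
    fs = toy_featureset([0.0, 0.5, 1.0])
    with pytest.raises(ValueError):
        fit(fs, [], THREE_CELLS)


def test_raw_distribution_sums_to_one(bioclim10):
    cells = np.argwhere(bioclim10.valid_mask)
    fs = build_features(bioclim10, VariableSelection(["BIO1", "BIO12"]), cells, n_presences=30)
    rng = np.random.default_rng(0)
    presences = cells[rng.choice(len(cells), 30)]
    model = fit(fs, presences, cells)
    assert abs(model.raw_on_background().sum() - 1.0) < 1e-10
    assert 0.0 <= model.entropy <= np.log(len(cells)) + 1e-12


def test_objective_non_increasing(bioclim10):
    cells = np.argwhere(bioclim10.valid_mask)
    fs = build_features(bioclim10, VariableSelection(["BIO1", "BIO12"]), cells, n_presences=30)
    presences = cells[np.random.default_rng(1).choice(len(cells), 30)]
    model = fit(fs, presences, cells, beta=0.5)
    diffs = np.diff(model.objective_path)
    assert (diffs <= 1e-9).all()


def test_regularization_path_monotone(bioclim10):
    """Stronger L1 never increases the total weight mass."""
    cells = np.argwhere(bioclim10.valid_mask)
    fs = build_features(bioclim10, VariableSelection(["BIO1", "BIO12"]), cells, n_presences=30)
    presences = cells[np.random.default_rng(2).choice(len(cells), 30)]
    norms = [
        np.abs(fit(fs, presences, cells, beta=b, tol=1e-10).lam).sum()
        for b in (0.01, 0.1, 1.0, 10.0)
    ]
    assert all(a >= b - 1e-6 for a, b in zip(norms, norms[1:]))


def test_training_auc_beats_chance(bioclim10):
    truth = TruthModel(linear={"BIO1": 1.5})
    records = sample_occurrences(truth, bioclim10, 150, seed=3)
    cells = np.array([bioclim10.grid.cell_of(r.lon, r.lat) for r in records])
    background = np.argwhere(bioclim10.valid_mask)
    fs = build_features(bioclim10, VariableSelection(["BIO1", "BIO12"]), background, n_presences=len(cells))
    model = fit(fs, cells, background)
    scores_p = fs.matrix(cells) @ model.lam
    scores_b = fs.matrix(background) @ model.lam
    assert auc(scores_p, scores_b) > 0.5


# --- logistic output -------------------------------------------------------

def test_logistic_uniform_model_is_half():
    fs = toy_featureset([0.0, 0.5, 1.0])
    model = fit(fs, THREE_CELLS, THREE_CELLS, beta=0.0)
    np.testing.assert_allclose(logistic_output(model), 0.5, atol=1e-6)


def test_logistic_matches_hand_formula():
    fs = toy_featureset([0.0, 0.5, 1.0])
    model = fit(fs, [(0, 2), (0, 2), (0, 1)], THREE_CELLS, beta=0.0)
    lam = model.lam[0]
    f = np.array([0.0, 0.5, 1.0])
    q = np.exp(lam * f) / np.exp(lam * f).sum()
    h = -(q * np.log(q)).sum()
    expected = np.exp(h) * q / (1 + np.exp(h) * q)
    np.testing.assert_allclose(logistic_output(model)[0], expected, rtol=1e-9)
    assert np.nanmin(expected) >= 0 and np.nanmax(expected) <= 1


def test_logistic_low_score_goes_to_zero():
    fs = toy_featureset([0.0, 0.5, 1.0])
    model = fit(fs, [(0, 2)] * 8, THREE_CELLS, beta=0.0)
    p = logistic_output(model)[0]
    assert p[0] < 0.01
    assert p[2] > 0.5


# --- train/test split ------------------------------------------------------

def test_split_sizes():
    cells = np.array([(0, i) for i in range(100)])
    train, test = split_train_test(cells, seed=0)
    assert (len(train), len(test)) == (75, 25)


def test_split_partition_properties():
    cells = np.array([(0, i) for i in range(37)])
    train, test = split_train_test(cells, seed=1)
    merged = {tuple(c) for c in train} | {tuple(c) for c in test}
    assert merged == {tuple(c) for c in cells}
    assert len(train) + len(test) == 37
    assert not ({tuple(c) for c in train} & {tuple(c) for c in test})


def test_split_seed_behaviour():
    cells = np.array([(0, i) for i in range(40)])
    t1, _ = split_train_test(cells, seed=5)
    t2, _ = split_train_test(cells, seed=5)
    t3, _ = split_train_test(cells, seed=6)
    np.testing.assert_array_equal(t1, t2)
    assert not np.array_equal(t1, t3)


def test_split_too_few_presences_warns():
    cells = np.array([(0, 0), (0, 1), (0, 2)])
    with pytest.warns(UserWarning):
        train, test = split_train_test(cells, seed=0)
    assert len(train) == 3 and len(test) == 0


# --- AUC -------------------------------------------------------------------

def pair_counting_auc(pres, back):
    """Exhaustive concordant-pair oracle with half-credit for ties."""
    wins = sum(
        1.0 if p > b else 0.5 if p == b else 0.0
        for p, b in itertools.product(pres, back)
    )
    return wins / (len(pres) * len(back))


def test_auc_examples():
    assert auc([0.9, 0.8], [0.7, 0.85]) == pytest.approx(0.75)
    assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0
    assert auc([0.5] * 4, [0.5] * 7) == 0.5


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(9)
    for _ in range(200):
        m, n = rng.integers(1, 50, size=2)
        # draw from few distinct values so ties are common
        pres = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=m)
        back = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
        assert auc(pres, back) == pair_counting_auc(pres, back)


def test_auc_rejects_empty():
    with pytest.raises(ValueError):
        auc([], [0.5])


# --- background sampling ---------------------------------------------------

def test_sample_background(bioclim10):
    all_cells = sample_background(bioclim10, n=10_000, seed=0)
    assert len(all_cells) == int(bioclim10.valid_mask.sum())
    sub = sample_background(bioclim10, n=30, seed=0)
    assert len(sub) == 30
    assert len({tuple(c) for c in sub}) == 30  # without replacement
    np.testing.assert_array_equal(sub, sample_background(bioclim10, n=30, seed=0))


# --- jackknife -------------------------------------------------------------

def duplicated_featureset(layer):
    layer = np.asarray(layer, dtype=float)
    names = ["a", "b"]
    return FeatureSet(
        variables=names,
        features=[Feature("linear", n) for n in names],
        vmin={n: float(layer.min()) for n in names},
        vmax={n: float(layer.max()) for n in names},
        layers={n: layer for n in names},
        grid_shape=layer.shape,
    )


def test_jackknife_duplicated_variable_auc_unchanged():
    rng = np.random.default_rng(4)
    layer = rng.random((1, 40))
    fs = duplicated_featureset(layer)
    order = np.argsort(layer[0])
    presences = [(0, int(c)) for c in order[-8:]]
    background = [(0, c) for c in range(40)]
    table = jackknife_importance(fs, np.array(presences), np.array(background), beta=0.1)
    full_model = fit(fs, np.array(presences), np.array(background), beta=0.1)
    full_auc = auc(
        fs.matrix(np.array(presences)) @ full_model.lam,
        fs.matrix(np.array(background)) @ full_model.lam,
    )
    assert table.loc["a", "auc_without"] == pytest.approx(full_auc, abs=1e-6)


def test_jackknife_noise_vs_signal_and_contributions(bioclim10):
    import rangeshift.bioclim as bc

    rng = np.random.default_rng(8)
    layers = dict(bioclim10.layers)
    layers["BIO19"] = rng.random(bioclim10.grid.shape)  # pure-noise covariate
    stack = bc.BioclimStack(bioclim10.grid, layers)
    truth = TruthModel(linear={"BIO1": 2.0})
    records = sample_occurrences(truth, stack, 120, seed=10)
    cells = np.array([stack.grid.cell_of(r.lon, r.lat) for r in records])
    background = np.argwhere(stack.valid_mask)
    fs = build_features(
        stack, VariableSelection(["BIO1", "BIO19"]), background, use_hinge=False
    )
    table = jackknife_importance(fs, cells, background, beta=0.1)
    # dropping noise hurts no more than dropping the signal variable
    assert table.loc["BIO19", "auc_without"] >= table.loc["BIO1", "auc_without"]
    assert table["contribution_pct"].sum() == pytest.approx(100.0)
    assert table.loc["BIO1", "contribution_pct"] > table.loc["BIO19", "contribution_pct"]
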