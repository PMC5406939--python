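"""Thinning, balancing, logit fitting and the model battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from epiril import predict, synthetic


def _table(n, p_success=0.5, seed=0, spacing=500):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(n) * spacing,
        "outcome": rng.random(n) < p_success,
        "x": rng.normal(size=n)})


class TestThinning:
    def test_hand_trace_left_to_right(self):
        # a seed whose permutation is the identity order is emulated by
        # spacing the input so the greedy rule is order-independent here
        table = pd.DataFrame({"chrom": "chr1", "pos": [100, 250, 450],
                              "outcome": [True, False, True]})
        # left-to-right greedy keeps {100, 450}: 250 is within 200 of 100
        kept_sets = {tuple(predict.thin_sites(table, 200, seed=s)["pos"])
                     for s in range(20)}
        assert (100, 450) in kept_sets
        # whatever the order, the result is a maximal valid set
        for kept in kept_sets:
            assert all(b - a >= 200 for a, b in zip(kept, kept[1:]))

    def test_already_sparse_is_identity(self):
        table = _table(50, spacing=300)
        out = predict.thin_sites(table, 200, seed=1)
        assert len(out) == 50

    @settings(derandomize=True, max_examples=25)
    @given(hst.integers(0, 10_000))
    def test_postcondition_any_seed(self, seed):
        table = _table(80, seed=3, spacing=90)
        out = predict.thin_sites(table, 200, seed=seed)
        pos = out["pos"].to_numpy()
        assert (np.diff(pos) >= 200).all()


class TestBalancedSample:
    def test_exact_balance(self):
        table = _table(530, p_success=30 / 530, seed=2)
        n_succ = int(table["outcome"].sum())
        out = predict.balanced_sample(table, seed=0)
        assert len(out) == 2 * n_succ
        assert out["outcome"].sum() == n_succ

    def test_no_successes_raises(self):
        table = _table(50, p_success=0.0)
        with pytest.raises(predict.InsufficientDataError):
            predict.balanced_sample(table)

    def test_seeded_determinism(self):
        table = _table(300, p_success=0.1, seed=5)
        a = predict.balanced_sample(table, seed=7)
        b = predict.balanced_sample(table, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestFitAndScore:
    def test_perfect_separation_scores_100(self):
        n = 60
        df = pd.DataFrame({"outcome": [False] * 30 + [True] * 30,
                           "x": np.r_[np.zeros(30), np.ones(30)]})
        res = predict.fit_and_score(["x"], df, df)
        assert res["accuracy"] == 100.0
        assert res["penalized"]  # separation forces the ridge fallback

    def test_noise_predictor_near_chance(self):
        rng = np.random.default_rng(0)
        accs = []
        for i in range(40):
            df = pd.DataFrame({"outcome": [False] * 100 + [True] * 100,
                               "x": rng.normal(size=200)})
            test = pd.DataFrame({"outcome": [False] * 100 + [True] * 100,
                                 "x": rng.normal(size=200)})
            accs.append(predict.fit_and_score(["x"], df, test)["accuracy"])
        assert abs(np.median(accs) - 50) < 5

    def test_threshold_outcome_recovered(self):
        # outcome is a noiseless threshold on x: accuracy approaches 100%
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        df = pd.DataFrame({"outcome": x > 0, "x": x})
        res = predict.fit_and_score(["x"], df, df)
        assert res["accuracy"] >= 99.0

    def test_degenerate_constant_predictor_flagged(self):
        df = pd.DataFrame({"outcome": [False, True] * 20, "x": 1.0})
        res = predict.fit_and_score(["x"], df, df)
        assert res["degenerate"]
        assert 0 <= res["accuracy"] <= 100

    def test_categorical_predictor_one_hot(self):
        df = pd.DataFrame({"outcome": [False] * 40 + [True] * 40,
                           "variability_class6":
                           ["invariant_low"] * 40 + ["bimodal_med"] * 40})
        res = predict.fit_and_score(["variability_class6"], df, df)
        assert res["accuracy"] == 100.0

    def test_training_likelihood_nesting(self):
        """Adding a predictor never decreases training log-likelihood."""
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = (x1 + 0.5 * rng.normal(size=n)) > 0
        X1 = sm.add_constant(pd.DataFrame({"x1": x1}))
        X2 = sm.add_constant(pd.DataFrame({"x1": x1, "x2": x2}))
        ll1 = sm.Logit(y, X1).fit(disp=0).llf
        ll2 = sm.Logit(y, X2).fit(disp=0).llf
        assert ll2 >= ll1 - 1e-9


@pytest.fixture(scope="module")
def battery():
    cfg = synthetic.SimulationConfig(seed=21, chromosome_length=800_000,
                                     n_genes=240)
    parents = synthetic.simulate_parents(cfg)
    ril = synthetic.simulate_ril(cfg, parents, ril_id=1)
    tables = predict.tables_from_simulation(
        parents, ril, directions=("gain",),
        predictors=["local_cg", "noise"])
    results = predict.run_model_battery(
        tables, models={0: ["noise"], 1: ["local_cg"]},
        directions=("gain",), repeats=5, seed=9)
    return tables, results


class TestBattery:
    def test_bookkeeping_full_factorial(self, battery):
        tables, results = battery
        # 2 genotypes x 1 direction x 5 repeats x 2 models
        assert len(results) == 20
        assert set(results["repeat"]) == set(range(5))

    def test_determinism(self, battery):
        tables, results = battery
        again = predict.run_model_battery(
            tables, models={0: ["noise"], 1: ["local_cg"]},
            directions=("gain",), repeats=5, seed=9)
        pd.testing.assert_frame_equal(results, again)

    def test_signal_model_beats_noise(self, battery):
        tables, results = battery
        med = results.groupby("model_id")["accuracy"].median()
        assert med[1] > med[0] + 10

    def test_summary_shape(self, battery):
        tables, results = battery
        summary = predict.summarize_battery(results)
        assert "50%" in summary.columns


class TestLocalMethylation:
    def test_focal_site_excluded(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                              "parent_level": [0.0], "outcome": [False]})
        levels = pd.DataFrame({"chrom": ["chr1"] * 3,
                               "pos": [50, 100, 150],
                               "level": [0.2, 1.0, 0.4]})
        out = predict.assemble_predictors(
            "gain", sites, {"cg_levels": levels}, ["local_cg"])
        # neighbors at 50 and 150 only: (0.2 + 0.4) / 2
        assert out["local_cg"].iloc[0] == pytest.approx(0.3)

    def test_no_neighbors_is_missing(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                              "parent_level": [0.0], "outcome": [False]})
        levels = pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                               "level": [1.0]})
        out = predict.assemble_predictors(
            "gain", sites, {"cg_levels": levels}, ["local_cg"])
        assert np.isnan(out["local_cg"].iloc[0])

    def test_eligibility_filters(self):
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [0, 300, 600],
                              "parent_level": [0.7, 0.5, 0.1],
                              "outcome": [False, False, True]})
        levels = pd.DataFrame({"chrom": ["chr1"], "pos": [1000],
                               "level": [0.5]})
        gain = predict.assemble_predictors("gain", sites,
                                           {"cg_levels": levels},
                                           ["local_cg"])
        assert gain["pos"].tolist() == [300, 600]
        loss = predict.assemble_predictors("loss", sites,
                                           {"cg_levels": levels},
                                           ["local_cg"])
        assert loss["pos"].tolist() == [0, 300]

    def test_zero_srna_is_a_value(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                              "parent_level": [0.0], "outcome": [False]})
        track = pd.DataFrame({"chrom": ["chr1"], "start": [5000],
                              "end": [5100], "value": [2.0]})
        out = predict.assemble_predictors(
            "gain", sites, {"srna_parent1": track}, ["srna_rpm_parent1"])
        assert out["srna_rpm_parent1"].iloc[0] == 0.0
        assert not out["srna_rpm_parent1"].isna().any()


def test_small_panel_variant_local_meth_predicts_variability():
    """Variable-class sites vs unimodal-lo background: local CG methylation
    alone separates better than chance on a maize-like 5-strain panel."""
    rng = np.random.default_rng(6)
    n = 600
    is_variable = np.arange(n) < n // 2
    # variable sites sit in intermediate local methylation, invariant-low
    # sites in unmethylated surroundings
    local_cg = np.where(is_variable,
                        rng.normal(0.45, 0.1, n), rng.normal(0.05, 0.05, n))
    strain_levels = np.where(
        is_variable[:, None],
        rng.choice([0.05, 0.95], size=(n, 5)),
        np.clip(rng.normal(0.05, 0.03, size=(n, 5)), 0, 1))
    from epiril import variability
    class3 = variability.classify_panel_small(
        pd.DataFrame(strain_levels, index=range(n)))
    table = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(n) * 400,
        "outcome": (class3 == "variable").to_numpy(),
        "local_cg": np.clip(local_cg, 0, 1)})
    results = predict.run_model_battery(
        {("panel", "na", "gain"): table}, models={1: ["local_cg"]},
        directions=("gain",), repeats=10, seed=4)
    assert results["accuracy"].median() > 60
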