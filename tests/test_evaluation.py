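import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridgp import (
    RunConfig, SamplerSettings, SimulationScenario, UndefinedMetricError,
    build_spectral_matrix, compute_metrics, cor_metric, make_partitions,
    nrmse_metric, pm_metric, relative_efficiency, run_experiment,
    simulate_dataset, standardize_markers,
)
from hybridgp.evaluation import METRIC_NAMES


class TestPartitions:
    def test_sizes_and_disjointness(self):
        ids = [f"L{i}" for i in range(100)]
        parts = make_partitions(ids, n_partitions=5, test_fraction=0.2, seed=1)
        assert len(parts) == 5
        for p in parts:
            assert len(p.test_lines) == 20
            assert not set(p.test_lines) & set(p.train_lines)
            assert set(p.test_lines) | set(p.train_lines) == set(ids)

    def test_deterministic_given_seed(self):
        ids = [f"L{i}" for i in range(40)]
        a = make_partitions(ids, 3, 0.2, seed=7)
        b = make_partitions(ids, 3, 0.2, seed=7)
        assert [p.test_lines for p in a] == [p.test_lines for p in b]

    def test_partitions_are_independent_splits(self):
        ids = [f"L{i}" for i in range(40)]
        parts = make_partitions(ids, 4, 0.2, seed=3)
        assert len({p.test_lines for p in parts}) > 1

    def test_zero_test_lines_is_an_error(self):
        with pytest.raises(ValueError, match="0 test lines"):
            make_partitions([f"L{i}" for i in range(10)], 5, 0.01, seed=0)


class TestMetrics:
    def test_perfect_and_inverted_correlation(self):
        o = np.array([1.0, 2.0, 3.0, 4.0])
        assert cor_metric(o, o) == pytest.approx(1.0)
        assert cor_metric(o, -o) == pytest.approx(-1.0)

    def test_hand_computed_correlation(self):
        assert cor_metric([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            cor_metric([1, 1, 1], [1, 2, 3])

    def test_nrmse_hand_computation(self):
        assert nrmse_metric([1, 2, 3], [1, 2, 3]) == 0.0
        assert nrmse_metric([1, 2, 3], [2, 3, 4]) == pytest.approx(0.5)

    def test_nrmse_scale_invariant(self):
        o, p = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        assert nrmse_metric(3 * o, 3 * p) == pytest.approx(nrmse_metric(o, p))

    def test_nrmse_zero_mean_undefined(self):
        with pytest.raises(UndefinedMetricError):
            nrmse_metric([-1.0, 1.0], [0.0, 0.0])

    def test_pm_perfect_prediction(self):
        o = np.arange(20.0)
        assert pm_metric(o, o, 0.10) == 100.0

    def test_pm_partial_overlap_enumeration(self):
        # n=20, top 10% -> s=2; observed top-2 = {19, 18};
        # predicted ranks put 19 first and 5 second -> overlap 1 -> 50%
        o = np.arange(20.0)
        p = o.copy()
        p[5] = 100.0
        p[19] = 200.0
        p[18] = 0.0
        assert pm_metric(o, p, 0.10) == 50.0

    def test_pm_reversed_ranking_zero(self):
        o = np.arange(20.0)
        assert pm_metric(o, -o, 0.10) == 0.0

    def test_pm_smaller_is_better_orientation(self):
        o = np.arange(20.0)
        assert pm_metric(o, o, 0.10, larger_is_better=False) == 100.0

    def test_pm_tiny_test_set_is_an_error(self):
        with pytest.raises(UndefinedMetricError):
            pm_metric([1.0, 2.0], [1.0, 2.0], 0.10)

    @given(
        st.integers(0, 2**31 - 1),
        st.integers(10, 30),
        st.floats(0.1, 5.0),
        st.floats(-10, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_pm_invariant_under_monotone_transforms(self, seed, n, a, b):
        rng = np.random.default_rng(seed)
        o = rng.permutation(n).astype(float)
        pred = rng.permutation(n).astype(float)  # arbitrary distinct ranking
        before = pm_metric(o, pred, 0.20)
        after = pm_metric(o, a * pred + b, 0.20)  # strictly monotone transform
        assert before == after


class TestRelativeEfficiency:
    def test_identical_models_have_zero_re(self):
        for kind in METRIC_NAMES:
            assert relative_efficiency(0.5, 0.5, kind) == 0.0

    # worked single-environment comparisons from the published study
    @pytest.mark.parametrize("best,other,kind,expected", [
        (0.667, 0.549, "COR", 21.49),
        (0.836, 0.851, "NRMSE", 1.79),
    ])
    def test_published_worked_examples(self, best, other, kind, expected):
        assert relative_efficiency(best, other, kind) == pytest.approx(
            expected, abs=0.005
        )

    def test_nonpositive_comparison_value_undefined(self):
        with pytest.raises(UndefinedMetricError):
            relative_efficiency(0.5, 0.0, "COR")


@pytest.fixture(scope="module")
def small_experiment():
    sc = SimulationScenario(J=80, p=60, n_env=1, h2_g=0.5, sparsity=1.0,
                            phenomic_loading=0.5, seed=17)
    d = simulate_dataset(sc)
    X = standardize_markers(d["markers"]).X
    U = build_spectral_matrix(d["indices"])
    cfg = RunConfig(mode="single_env", models=("M1",), n_partitions=5, seed=17,
                    sampler=SamplerSettings(n_iter=1200, burn_in=300))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_experiment(cfg, d["phenotypes"], X, U)
    return report


class TestRunExperiment:
    def test_row_counts_one_model_one_env(self, small_experiment):
        rep = small_experiment
        assert len(rep.rows) == 5           # 5 partitions
        assert len(rep.averages) == 1       # one averaged row
        assert (rep.averages["partition"] == "avg").all()

    def test_averages_equal_mean_of_partition_rows(self, small_experiment):
        rep = small_experiment
        for m in METRIC_NAMES:
            assert rep.averages.iloc[0][m] == pytest.approx(
                rep.rows[m].mean(), abs=1e-12
            )

    def test_metric_ranges(self, small_experiment):
        rows = small_experiment.rows
        assert rows["COR"].between(-1, 1).all()
        assert (rows["NRMSE"] >= 0).all()
        assert rows["PM10"].between(0, 100).all()
        assert rows["PM20"].between(0, 100).all()

    def test_report_rows_recomputable_from_predictions(self, small_experiment):
        rep = small_experiment
        for (model, part), grp in rep.predictions.groupby(["model", "partition"]):
            recomputed = compute_metrics(grp["observed"].to_numpy(),
                                         grp["predicted"].to_numpy())
            row = rep.rows[(rep.rows["model"] == model)
                           & (rep.rows["partition"] == part)].iloc[0]
            for m in METRIC_NAMES:
                assert row[m] == pytest.approx(recomputed[m], abs=1e-12)

    def test_re_of_best_model_is_zero(self, small_experiment):
        re = small_experiment.re_tables
        best = re[re["model"] == re["best_model"]]
        assert (best["re_percent"].abs() < 1e-12).all()
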