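"""AICc arithmetic, Akaike weights, gating, model averaging, Jackknife."""

import numpy as np
import pandas as pd
import pytest

from tiapbms import (
    CohortDesign,
    ModelSelection,
    aicc,
    aicc_penalty,
    akaike_weights,
    bic,
    generate_cohort,
    jackknife,
    model_average_tia,
)
from tiapbms.selection import goodness_gate


class TestAICc:
    @pytest.mark.parametrize("K,expected", [(7, 17), (26, 126), (27, 138)])
    def test_penalty_values_at_n46(self, K, expected):
        """Penalty 2K + 2K(K+1)/(N-K-1) for the three methods' K at N=46."""
        assert round(aicc_penalty(K, 46)) == expected

    def test_penalty_exact_values(self):
        assert aicc_penalty(7, 46) == pytest.approx(16.947, abs=1e-3)
        assert aicc_penalty(26, 46) == pytest.approx(125.895, abs=1e-3)
        assert aicc_penalty(27, 46) == pytest.approx(138.0, abs=1e-9)

    def test_aicc_is_neg2ll_plus_penalty(self):
        assert aicc(10.0, 3, 20) == pytest.approx(10.0 + aicc_penalty(3, 20))

    def test_degenerate_denominator_raises(self):
        with pytest.raises(ValueError):
            aicc(0.0, 45, 46)

    def test_penalty_tends_to_aic_limit(self):
        # 2K + 2K(K+1)/(N-K-1) -> 2K as N -> infinity
        assert aicc_penalty(7, 10**9) == pytest.approx(14.0, abs=1e-5)

    def test_bic(self):
        assert bic(0.0, 1, int(np.e)) == pytest.approx(np.log(int(np.e)))
        assert bic(5.0, 0, 100) == 5.0
        with pytest.raises(ValueError):
            bic(0.0, 1, 0)


class TestAkaikeWeights:
    def test_single_function(self):
        np.testing.assert_allclose(akaike_weights([12.3]), [1.0])

    def test_two_equal(self):
        np.testing.assert_allclose(akaike_weights([5.0, 5.0]), [0.5, 0.5])

    def test_worked_example_large_deltas(self):
        """Equal -2lnP at N=46: the K=7 model takes essentially all weight;
        the K=27 model keeps ~5.2e-25 % (and K=26 a raw weight ~2.2e-24)."""
        a = [aicc_penalty(7, 46), aicc_penalty(26, 46), aicc_penalty(27, 46)]
        w = akaike_weights(a)
        assert w[0] == pytest.approx(1.0, abs=1e-20)
        assert w[1] == pytest.approx(2.2e-24, rel=0.05, abs=0.0)
        assert w[2] * 100 == pytest.approx(5.2e-25, rel=0.05, abs=0.0)

    def test_shift_invariance(self):
        a = np.array([3.0, 7.5, 20.0])
        np.testing.assert_allclose(akaike_weights(a), akaike_weights(a + 123.4), rtol=1e-12)

    def test_monotone_in_aicc(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 50, 10)
        w = akaike_weights(a)
        order = np.argsort(a)
        assert np.all(np.diff(w[order]) <= 1e-15)

    def test_sum_to_one_even_with_huge_deltas(self):
        w = akaike_weights([0.0, 500.0, 1000.0, 2000.0])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([1.0, np.inf])


class _FakeFit:
    def __init__(self, converged=True, cv_max=0.1):
        self.converged_ = converged
        self.cv_max_ = cv_max


class TestGoodnessGate:
    def test_cv_above_threshold_fails(self):
        gate = goodness_gate({"f4b": _FakeFit(cv_max=0.78)})
        assert not gate.loc["f4b", "passed_gate"]

    def test_cv_below_threshold_passes(self):
        gate = goodness_gate({"f3a": _FakeFit(cv_max=0.20)})
        assert gate.loc["f3a", "passed_gate"]

    def test_infinite_cv_fails(self):
        gate = goodness_gate({"f5a": _FakeFit(cv_max=np.inf)})
        assert not gate.loc["f5a", "passed_gate"]
        assert "singular" in gate.loc["f5a", "reason"]

    def test_nonconverged_fails(self):
        gate = goodness_gate({"f6a": _FakeFit(converged=False)})
        assert not gate.loc["f6a", "passed_gate"]

    def test_boundary_is_exclusive(self):
        gate = goodness_gate({"x": _FakeFit(cv_max=0.5)})
        assert not gate.loc["x", "passed_gate"]


class TestModelAverage:
    def test_single_function_identity(self):
        out = model_average_tia({"f": 1.0}, {"f": pd.Series({"a": 123.0})})
        assert out["a"] == 123.0

    def test_equal_weights_midpoint(self):
        tias = {"f": pd.Series({"a": 100.0}), "g": pd.Series({"a": 200.0})}
        out = model_average_tia({"f": 0.5, "g": 0.5}, tias)
        assert out["a"] == pytest.approx(150.0)

    def test_five_function_dot_product(self):
        rng = np.random.default_rng(3)
        w = rng.dirichlet(np.ones(5))
        names = list("abcde")
        patients = [f"P{i}" for i in range(4)]
        tias = {n: pd.Series(rng.uniform(50, 300, 4), index=patients) for n in names}
        out = model_average_tia(dict(zip(names, w)), tias)
        for j, pid in enumerate(patients):
            expected = sum(w[i] * tias[names[i]][pid] for i in range(5))
            assert out[pid] == pytest.approx(expected, rel=1e-12)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            model_average_tia({"f": 1.0}, {"g": pd.Series({"a": 1.0})})

    def test_unnormalised_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            model_average_tia({"f": 0.9}, {"f": pd.Series({"a": 1.0})})


class TestSelectionWorkflow:
    @pytest.fixture(scope="class")
    def fitted(self, default_sim):
        return ModelSelection(functions=("f2a", "f3a"), n_starts=1).fit(default_sim.cohort)

    def test_weights_sum_to_one_over_passers(self, fitted):
        assert sum(fitted.weights_.values()) == pytest.approx(1.0, abs=1e-9)

    def test_delta_minimum_zero(self, fitted):
        deltas = fitted.table_.loc[list(fitted.weights_), "delta"]
        assert deltas.min() == pytest.approx(0.0, abs=1e-12)

    def test_failed_candidates_get_zero_weight(self, default_sim):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = ModelSelection(functions=("f3a", "f5b"), n_starts=1).fit(default_sim.cohort)
        assert sel.table_.loc["f5b", "weight"] == 0.0
        assert not sel.table_.loc["f5b", "passed_gate"]
        assert sel.table_.loc["f5b", "reason"] != ""

    def test_no_passing_function_raises(self, default_sim):
        with pytest.raises(RuntimeError, match="no candidate"):
            ModelSelection(functions=("f2a",), cv_threshold=0.0,
                           n_starts=1).fit(default_sim.cohort)

    def test_oversized_k_excluded_before_fitting(self):
        sim = generate_cohort(CohortDesign(n_patients=4, n_extra_patients=0), seed=1)
        # N=12+1 extra on patient 1 = 13; f6a needs K=13 -> AICc undefined
        sel = ModelSelection(functions=("f2a", "f6a"), n_starts=1).fit(sim.cohort)
        assert "AICc undefined" in sel.table_.loc["f6a", "reason"]

    def test_ma_tia_is_weighted_sum(self, fitted):
        ma = fitted.model_average_tia()
        tias = {n: fitted.fits_[n].tia() for n in fitted.weights_}
        manual = sum(w * tias[n] for n, w in fitted.weights_.items())
        pd.testing.assert_series_equal(ma, manual, check_names=False)


class TestJackknife:
    def test_replicate_count_and_sizes(self, default_sim):
        """13 patients -> exactly 13 leave-one-out replicates of size 12."""
        out = jackknife(default_sim.cohort, functions=("f2a", "f3a"), n_starts=1)
        assert len(out["weights"]) == 13
        assert out["failed"] == {}
        assert set(out["weights"].index) == set(default_sim.cohort.patient_ids)
        assert set(out["summary"].columns) == {"mean", "sd", "median", "min", "max", "n_first"}

    def test_identical_patients_zero_spread(self):
        design = CohortDesign(n_patients=4, n_extra_patients=0,
                              base_schedule_h=((1.1, 0.0), (20.7, 0.0), (163.8, 0.0)),
                              truth_function="f2a",
                              truth_tvp={"A1": 0.04, "lambda1": 3e-4},
                              omega=0.0, sigma_res=0.1)
        sim = generate_cohort(design, seed=2)
        frame = sim.cohort.frame.copy()
        first = frame[frame["patient_id"] == "P01"]
        parts = [first.assign(patient_id=p) for p in ["P01", "P02", "P03", "P04"]]
        import pandas as pd
        from tiapbms.cohort import TimeActivityCohort
        clones = TimeActivityCohort._validated(pd.concat(parts, ignore_index=True))
        out = jackknife(clones, functions=("f2a",), n_starts=1)
        assert float(out["summary"].loc["f2a", "sd"]) == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_patients(self):
        sim = generate_cohort(CohortDesign(n_patients=2, n_extra_patients=0), seed=0)
        with pytest.raises(ValueError, match="3 patients"):
            jackknife(sim.cohort, functions=("f2a",))
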