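import numpy as np
import pandas as pd
import pytest

from prognet import ClinicalTable, ExpressionMatrix
from prognet.mcode import Module
from prognet.prognostic import (
    ResampleConfig,
    fit_cox_univariate,
    module_statistic,
    profile_all,
    profiles_to_frame,
    resample_cox,
)


def _survival_data(n, beta, seed, censor=0.3, ties=False):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    t = rng.exponential(100.0 * np.exp(-beta * x))
    if ties:
        t = np.ceil(t / 20.0) * 20.0
    c = rng.exponential(t.mean() / censor) if censor else np.full(n, np.inf)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return x, time, event


class TestCoxFit:
    @pytest.mark.parametrize("ties", [False, True])
    @pytest.mark.parametrize("beta", [0.0, 0.7])
    def test_matches_lifelines(self, beta, ties):
        # lifelines is the independent reference implementation
        from lifelines import CoxPHFitter

        x, time, event = _survival_data(120, beta, seed=31, ties=ties)
        fit = fit_cox_univariate(x, time, event)
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"t": time, "e": event, "x": x}), "t", "e")
        assert fit.converged
        # lifelines stops at a looser gradient tolerance than our Newton
        assert fit.coefficient == pytest.approx(cph.params_["x"], abs=2e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=2e-4)
        assert fit.p_value == pytest.approx(cph.summary["p"]["x"], rel=1e-2, abs=1e-4)

    def test_affine_invariance(self):
        # rescaling the covariate scales the coefficient inversely and
        # leaves the p-value unchanged
        x, time, event = _survival_data(100, 0.5, seed=32)
        f1 = fit_cox_univariate(x, time, event)
        f2 = fit_cox_univariate(3.0 * x + 7.0, time, event)
        assert f2.coefficient == pytest.approx(f1.coefficient / 3.0, rel=1e-6)
        assert f2.p_value == pytest.approx(f1.p_value, rel=1e-6)

    def test_degenerate_inputs_not_converged(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        assert not fit_cox_univariate(np.ones(4), time, np.array([1, 1, 0, 1])).converged
        assert not fit_cox_univariate(np.arange(4.0), time, np.zeros(4, int)).converged


class TestModuleStatistic:
    def test_single_gene_module_passthrough(self, tiny_expression):
        m = Module(1, frozenset(["g0"]), 1.0)
        s = module_statistic(tiny_expression, m)
        pd.testing.assert_series_equal(s.values, tiny_expression.data.loc["g0"],
                                       check_names=False)

    def test_two_gene_mean(self):
        data = pd.DataFrame([[1.0, 3.0], [3.0, 5.0]], index=["a", "b"],
                            columns=["s1", "s2"])
        s = module_statistic(ExpressionMatrix(data), Module(1, frozenset("ab"), 1.0))
        assert s.values.tolist() == [2.0, 4.0]

    def test_matches_independent_mean(self, tiny_expression):
        genes = ["g1", "g3", "g4", "g6"]
        s = module_statistic(tiny_expression, Module(2, frozenset(genes), 1.0))
        expected = tiny_expression.data.loc[genes].to_numpy().mean(axis=0)
        np.testing.assert_allclose(s.values.to_numpy(), expected)

    def test_missing_genes_dropped_error_if_none(self, tiny_expression):
        s = module_statistic(tiny_expression, Module(3, frozenset(["g0", "nope"]), 1.0))
        pd.testing.assert_series_equal(s.values, tiny_expression.data.loc["g0"],
                                       check_names=False)
        with pytest.raises(ValueError):
            module_statistic(tiny_expression, Module(4, frozenset(["zzz"]), 1.0))


def _cohort(n, beta, seed):
    from prognet.prognostic import ModuleStatistic

    x, time, event = _survival_data(n, beta, seed=seed)
    ids = [f"s{i}" for i in range(n)]
    stat = ModuleStatistic(1, pd.Series(x, index=ids))
    clin = ClinicalTable(pd.DataFrame({"time": time, "event": event},
                                      index=pd.Index(ids, name="sample")))
    return stat, clin


class TestResampleCox:
    def test_full_fraction_removes_randomness(self):
        stat, clin = _cohort(80, 0.8, seed=33)
        cfg = ResampleConfig(n_rep=2, sample_fraction=1.0, seed=0)
        prof = resample_cox(stat, clin, cfg)
        assert prof.sig_frequency in (0, 2)  # both reps identical

    def test_strong_effect_high_frequency(self):
        stat, clin = _cohort(300, 1.0, seed=34)
        prof = resample_cox(stat, clin, ResampleConfig(n_rep=50, seed=1))
        assert prof.sig_frequency / prof.n_rep >= 0.95
        assert prof.mean_coefficient > 0.5

    def test_initial_importance_identity(self):
        stat, clin = _cohort(100, 0.5, seed=35)
        prof = resample_cox(stat, clin, ResampleConfig(n_rep=20, seed=2))
        assert prof.initial_importance == prof.sig_frequency / 20

    def test_affine_rescaling_leaves_frequency(self):
        stat, clin = _cohort(100, 0.8, seed=36)
        cfg = ResampleConfig(n_rep=25, seed=3)
        p1 = resample_cox(stat, clin, cfg)
        stat.values = stat.values * 10.0 + 5.0
        p2 = resample_cox(stat, clin, cfg)
        assert p1.sig_frequency == p2.sig_frequency
        assert p2.mean_coefficient == pytest.approx(p1.mean_coefficient / 10.0, rel=1e-6)

    def test_guards(self):
        stat, clin = _cohort(10, 0.5, seed=37)
        with pytest.raises(ValueError, match="20"):
            resample_cox(stat, clin, ResampleConfig(n_rep=2))


class TestProfileAll:
    def _setup(self, seed=38):
        rng = np.random.default_rng(seed)
        n = 200
        ids = [f"s{i}" for i in range(n)]
        z = rng.standard_normal(n)  # prognostic latent
        genes, rows = [], []
        for g in range(10):
            genes.append(f"p{g}")
            rows.append(0.9 * z + 0.4 * rng.standard_normal(n))
        for g in range(20):
            genes.append(f"n{g}")
            rows.append(rng.standard_normal(n))
        expr = ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=ids))
        t = rng.exponential(100.0 * np.exp(-1.0 * z))
        c = rng.exponential(t.mean() / 0.3)
        clin = ClinicalTable(pd.DataFrame(
            {"time": np.minimum(t, c), "event": (t <= c).astype(int)},
            index=pd.Index(ids, name="sample")))
        mods = [Module(1, frozenset(f"p{g}" for g in range(10)), 3.0),
                Module(2, frozenset(f"n{g}" for g in range(10)), 2.0),
                Module(3, frozenset(f"n{g}" for g in range(10, 20)), 1.0)]
        return expr, mods, clin

    def test_planted_module_ranks_first(self):
        expr, mods, clin = self._setup()
        profiles = profile_all(expr, mods, clin, ResampleConfig(n_rep=40, seed=4))
        by_id = {p.module_id: p for p in profiles}
        assert by_id[1].sig_frequency > by_id[2].sig_frequency
        assert by_id[1].sig_frequency > by_id[3].sig_frequency
        assert by_id[1].sig_frequency / 40 >= 0.9

    def test_deterministic_under_seed(self):
        expr, mods, clin = self._setup()
        cfg = ResampleConfig(n_rep=10, seed=9)
        f1 = profiles_to_frame(profile_all(expr, mods, clin, cfg))
        f2 = profiles_to_frame(profile_all(expr, mods, clin, cfg))
        pd.testing.assert_frame_equal(f1, f2)

    def test_empty_module_list(self):
        expr, _, clin = self._setup()
        assert profile_all(expr, [], clin, ResampleConfig(n_rep=5, seed=0)) == []
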