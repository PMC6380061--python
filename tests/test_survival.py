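import numpy as np
import pandas as pd
import pytest

from prognet import ClinicalTable, ExpressionMatrix
from prognet.mcode import Module
from prognet.prognostic import PrognosticProfile
from prognet.survival import (
    dscore,
    random_geneset_test,
    risk_scores,
    split_and_test,
)


def _expr(values, genes):
    cols = [f"s{i}" for i in range(np.asarray(values).shape[1])]
    return ExpressionMatrix(pd.DataFrame(np.asarray(values, float), index=genes,
                                         columns=cols))


def _clin(time, event):
    ids = [f"s{i}" for i in range(len(time))]
    return ClinicalTable(pd.DataFrame({"time": time, "event": event},
                                      index=pd.Index(ids, name="sample")))


class TestRiskScores:
    def test_single_positive_module(self):
        expr = _expr([[1, 2, 3], [3, 4, 5]], ["a", "b"])
        mods = [Module(1, frozenset("ab"), 1.0)]
        prof = [PrognosticProfile(1, 300, 400, +1.0)]
        s = risk_scores(expr, mods, prof)
        np.testing.assert_allclose(s.to_numpy(), [2.0, 3.0, 4.0])

    def test_signed_difference(self):
        expr = _expr([[1, 2], [5, 9]], ["a", "b"])
        mods = [Module(1, frozenset("a"), 1.0), Module(2, frozenset("b"), 1.0)]
        prof = [PrognosticProfile(1, 300, 400, +0.8),
                PrognosticProfile(2, 300, 400, -0.5)]
        s = risk_scores(expr, mods, prof)
        np.testing.assert_allclose(s.to_numpy(), [1 - 5, 2 - 9])

    def test_matches_signed_sum_oracle(self):
        rng = np.random.default_rng(51)
        genes = [f"g{i}" for i in range(25)]
        expr = _expr(rng.standard_normal((25, 12)), genes)
        mods, prof, expected = [], [], np.zeros(12)
        for m in range(5):
            member = genes[m * 5:(m + 1) * 5]
            coef = float(rng.normal())
            mods.append(Module(m + 1, frozenset(member), 1.0))
            prof.append(PrognosticProfile(m + 1, 100, 400, coef))
            expected += np.sign(coef) * expr.data.loc[member].to_numpy().mean(axis=0)
        s = risk_scores(expr, mods, prof)
        np.testing.assert_allclose(s.to_numpy(), expected, atol=1e-12)

    def test_empty_selection_error(self):
        expr = _expr([[1, 2]], ["a"])
        with pytest.raises(ValueError):
            risk_scores(expr, [], [])


def _logrank_oracle(time, event, group):
    """Textbook two-sample log-rank chi-square, coded independently."""
    from scipy.stats import chi2

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    O_minus_E = 0.0
    V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = O_minus_E**2 / V
    return stat, chi2.sf(stat, 1)


class TestSplitAndTest:
    def test_perfect_risk_ordering(self):
        rng = np.random.default_rng(52)
        n = 60
        t = np.sort(rng.exponential(50, n))[::-1]  # longest survivors first
        clin = _clin(t, np.ones(n, int))
        scores = pd.Series(np.arange(n, dtype=float), index=clin.sample_ids)
        a = split_and_test(scores, clin)
        assert a.logrank_p < 1e-6
        assert a.hazard_ratio > 1
        assert a.n_high == 30 and a.n_low == 30

    def test_identical_curves_give_p_one(self):
        # high and low groups share the same event times by construction
        clin = _clin([5.0, 5.0, 10.0, 10.0], [1, 1, 1, 1])
        # scores chosen so each group holds one sample at time 5, one at 10
        scores = pd.Series([4.0, 1.0, 3.0, 2.0], index=clin.sample_ids)
        a = split_and_test(scores, clin)
        assert a.logrank_p == pytest.approx(1.0)

    def test_odd_sample_count_split(self):
        clin = _clin([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        scores = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=clin.sample_ids)
        a = split_and_test(scores, clin)
        assert a.n_high == 2 and a.n_low == 3

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(53)
        clin = _clin(rng.exponential(50, 40), rng.integers(0, 2, 40))
        scores = pd.Series(rng.standard_normal(40), index=clin.sample_ids)
        a1 = split_and_test(scores, clin)
        a2 = split_and_test(np.exp(scores * 2) + 3, clin)
        pd.testing.assert_series_equal(a1.group, a2.group)
        assert a1.logrank_p == a2.logrank_p

    def test_matches_textbook_logrank_oracle(self):
        rng = np.random.default_rng(54)
        n = 18
        clin = _clin(rng.exponential(30, n).round(1), rng.integers(0, 2, n))
        scores = pd.Series(rng.standard_normal(n), index=clin.sample_ids)
        a = split_and_test(scores, clin)
        group = (a.group == "high").astype(int).to_numpy()
        _, p = _logrank_oracle(clin.time.to_numpy(), clin.event.to_numpy(), group)
        assert a.logrank_p == pytest.approx(p, rel=1e-8)

    def test_constant_scores_error(self):
        clin = _clin([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError):
            split_and_test(pd.Series(1.0, index=clin.sample_ids), clin)


class TestDscore:
    def test_published_arithmetic(self):
        assert dscore([8.90e-04, 6.66e-08]) == pytest.approx(10.23, abs=0.01)
        assert dscore([0.0077, 3.37e-05]) == pytest.approx(6.586, abs=0.001)
        assert dscore([1.0]) == 0.0

    def test_additive_and_monotone(self):
        assert dscore([0.01, 0.001]) == pytest.approx(dscore([0.01]) + dscore([0.001]))
        assert dscore([0.01, 0.5]) > dscore([0.02, 0.5])

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.5], []])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            dscore(bad)


class TestRandomGenesetTest:
    def _dataset(self, seed, n=80, n_genes=60, beta=0.0):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        rows = [0.8 * z + 0.6 * rng.standard_normal(n) if g < 8
                else rng.standard_normal(n) for g in range(n_genes)]
        genes = [f"g{i}" for i in range(n_genes)]
        expr = _expr(np.asarray(rows), genes)
        t = rng.exponential(60 * np.exp(-beta * z))
        c = rng.exponential(t.mean() / 0.3)
        clin = _clin(np.minimum(t, c), (t <= c).astype(int))
        return expr, clin

    def test_zero_observed_gives_p_one(self):
        data = [self._dataset(55)]
        res = random_geneset_test(data, observed_dscore=0.0, gene_count=5,
                                  n_sets=50, seed=1)
        assert res.p_value == 1.0

    def test_seed_reproducible(self):
        data = [self._dataset(56)]
        r1 = random_geneset_test(data, 1.0, gene_count=5, n_sets=30, seed=2)
        r2 = random_geneset_test(data, 1.0, gene_count=5, n_sets=30, seed=2)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null_dscores, r2.null_dscores)

    def test_planted_signal_beats_random_sets(self):
        # the first 8 genes carry the survival signal; scoring them as one
        # module should outperform random sets of the same size
        data = [self._dataset(57, n=200, beta=1.2)]
        expr, clin = data[0]
        signal = expr.data.loc[[f"g{i}" for i in range(8)]].mean(axis=0)
        observed = dscore([split_and_test(signal, clin).logrank_p])
        res = random_geneset_test(data, observed, gene_count=8, n_sets=200, seed=3)
        assert res.p_value <= 0.05
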