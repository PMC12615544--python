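"""Selection, binomial chance probabilities, and group statistics."""

import math

import numpy as np
import pytest

import frontload as fl
from frontload.fitting import Engine, FitResult
from frontload.inference import TIE, Tails, _one_sample_power
from frontload.models import ModelName


def _fit(model, adj, engine=Engine.EXACT):
    return FitResult(
        model_name=model,
        level_time_estimates=(0.6, math.nan, 1.1),
        sse=0.1,
        r2=0.8,
        adjusted_r2=adj,
        n_cells_used=36,
        engine=engine,
    )


def _cohort(adj_by_subject):
    out = {}
    for sid, adjs in adj_by_subject.items():
        out[sid] = {m: _fit(m, a) for m, a in zip(ModelName, adjs)}
    return out


class TestSelectModel:
    def test_unanimous_winner(self):
        fits = _cohort({f"S{i}": (0.1, 0.2, 0.3, 0.9) for i in range(3)})
        sel = fl.select_model(fits)
        assert sel.top_model is ModelName.FAST_PRECRASTINATION
        assert sel.k_top == 3
        assert sel.counts[ModelName.FAST_PRECRASTINATION.value] == 3
        assert sel.binomial_point_p == pytest.approx(0.25**3)

    def test_exact_tie_recorded(self):
        fits = _cohort({"A": (0.5, 0.5, 0.1, 0.2), "B": (0.1, 0.2, 0.3, 0.9)})
        sel = fl.select_model(fits)
        assert sel.winners["A"] == TIE
        assert sel.counts[TIE] == 1
        assert sel.k_top == 1

    def test_missing_model_rejected(self):
        fits = _cohort({"A": (0.1, 0.2, 0.3, 0.9)})
        del fits["A"][ModelName.SLOW_PROCRASTINATION]
        with pytest.raises(ValueError, match="slow_procrastination"):
            fl.select_model(fits)

    def test_mixed_engines_rejected(self):
        fits = _cohort({"A": (0.1, 0.2, 0.3, 0.9), "B": (0.1, 0.2, 0.3, 0.9)})
        fits["B"][ModelName.FAST_PRECRASTINATION] = _fit(
            ModelName.FAST_PRECRASTINATION, 0.9, Engine.MONTE_CARLO
        )
        with pytest.raises(ValueError, match="engine"):
            fl.select_model(fits)


class TestBinomial:
    def test_published_point_masses(self):
        p37, _ = fl.binomial_point_p(37, 40, 0.25)
        assert p37 == pytest.approx(2.2066e-19, rel=1e-4)
        p28, _ = fl.binomial_point_p(28, 38, 0.25)
        assert p28 == pytest.approx(3.69e-10, rel=2e-3)

    def test_single_trial(self):
        point, tail = fl.binomial_point_p(1, 1, 0.25)
        assert point == pytest.approx(0.25)
        assert tail == pytest.approx(0.25)

    def test_tail_dominates_point(self):
        for k, n in [(0, 5), (3, 10), (37, 40)]:
            point, tail = fl.binomial_point_p(k, n, 0.25)
            assert tail >= point

    @pytest.mark.parametrize("n", [1, 7, 40, 60])
    def test_point_masses_sum_to_one(self, n):
        total = sum(fl.binomial_point_p(k, n, 0.25)[0] for k in range(n + 1))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestPairedT:
    def test_null_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.8, 0.1, 20)
        res = fl.paired_t_one_tailed(x, x + rng.normal(0, 0.01, 20), "greater")
        assert abs(res.statistic) < 3  # symmetric perturbation, near-null
        assert res.df == 19

    def test_closed_form_t(self):
        """Differences with mean 1 and sd 1 at n = 16 give t = 4."""
        diffs = np.array([0.0, 2.0] * 8)  # mean 1, sd 1.032... adjust
        diffs = 1.0 + (diffs - diffs.mean()) / diffs.std(ddof=1)
        x = 0.5 + diffs
        y = np.full(16, 0.5)
        res = fl.paired_t_one_tailed(x, y, "greater")
        assert res.statistic == pytest.approx(4.0)
        assert res.df == 15
        assert res.tails is Tails.ONE

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = fl.paired_t_one_tailed([1.0] * 5, [0.5] * 5)
        assert math.isnan(res.statistic)


class TestCohensDrm:
    def test_matches_direct_formula_on_fixture(self):
        rng = np.random.default_rng(5)
        x = rng.normal(1.0, 0.3, 10)
        y = rng.normal(0.7, 0.2, 10)
        r = np.corrcoef(x, y)[0, 1]
        sx, sy = x.std(ddof=1), y.std(ddof=1)
        direct = (
            (x.mean() - y.mean())
            / math.sqrt(sx**2 + sy**2 - 2 * r * sx * sy)
            * math.sqrt(2 * (1 - r))
        )
        assert fl.cohens_d_rm(x, y) == pytest.approx(direct)

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(1.0, 0.3, 12)
        y = rng.normal(0.7, 0.2, 12)
        assert fl.cohens_d_rm(x + 5, y + 5) == pytest.approx(fl.cohens_d_rm(x, y))

    def test_perfect_correlation_undefined(self):
        x = np.linspace(0, 1, 8)
        with pytest.warns(UserWarning):
            assert math.isnan(fl.cohens_d_rm(x, x + 0.3))


class TestRmAnova:
    def test_error_df_structure(self):
        rng = np.random.default_rng(1)
        omnibus, pairwise = fl.rm_anova(rng.normal(0.7, 0.1, (35, 6)))
        assert omnibus.df == 170
        assert len(pairwise) == 15
        assert (pairwise["p_bonferroni"] <= 1).all()
        assert (pairwise["p_bonferroni"] >= pairwise["p_uncorrected"] - 1e-15).all()

    def test_agrees_with_pingouin(self):
        """Independent oracle: same F and p from pingouin's rm_anova."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        m = rng.normal(0.7, 0.1, (12, 6)) + np.linspace(0, 0.1, 6)
        long = pd.DataFrame(
            {
                "y": m.ravel(),
                "subject": np.repeat(np.arange(12), 6),
                "cond": np.tile(np.arange(6), 12),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
        omnibus, _ = fl.rm_anova(m)
        assert omnibus.statistic == pytest.approx(float(ref["F"].iloc[0]))
        assert omnibus.p_value == pytest.approx(float(ref["p_unc"].iloc[0]))
        assert omnibus.df == float(ref["ddof2"].iloc[0])

    def test_power_at_study_scale(self):
        """A 0.1-s T1 offset at n = 35 and 0.05-s subject noise is
        detected at the .001 level."""
        rng = np.random.default_rng(3)
        m = rng.normal(0, 0.05, (35, 6)) + np.array([0.6, 0.7, 0.7, 0.7, 0.7, 0.7])
        omnibus, _ = fl.rm_anova(m)
        assert omnibus.p_value < 0.001

    def test_missing_cells_rejected(self):
        m = np.full((10, 6), 0.7)
        m[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fl.rm_anova(m)


class TestWelch:
    def test_symmetric_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = fl.welch_t(x, x.copy())
        assert res.statistic == pytest.approx(0.0)

    def test_summary_arithmetic_oracle(self):
        """Direct formula on the preview-time summaries: t ~ 1.95 with
        Welch-Satterthwaite df ~ 40.3."""
        res = fl.welch_t((4.08, 3.28, 35), (2.95, 1.48, 78))
        assert res.statistic == pytest.approx(1.9510, abs=1e-3)
        assert res.df == pytest.approx(40.35, abs=0.05)

    def test_df_bounded_by_pooled(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.normal(0, 1, rng.integers(3, 30))
            y = rng.normal(0, 2, rng.integers(3, 30))
            res = fl.welch_t(x, y)
            assert res.df <= x.size + y.size - 2 + 1e-9


class TestRequiredSampleSize:
    def test_moderate_effect_two_tailed(self):
        assert fl.required_sample_size(0.5, 0.05, 0.80, Tails.TWO) == 34

    def test_one_tailed_needs_fewer(self):
        two = fl.required_sample_size(0.5, 0.05, 0.80, Tails.TWO)
        one = fl.required_sample_size(0.5, 0.05, 0.80, Tails.ONE)
        assert one < two

    def test_power_nondecreasing_in_n(self):
        powers = [_one_sample_power(n, 0.5, 0.05, Tails.TWO) for n in range(5, 80)]
        assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.power")
        n_float = sm.TTestPower().solve_power(
            effect_size=0.5, alpha=0.05, power=0.80, alternative="two-sided"
        )
        assert fl.required_sample_size(0.5) == math.ceil(n_float)


class TestFisherZ:
    def test_values_and_symmetry(self):
        assert fl.fisher_z(0.0) == 0.0
        assert round(fl.fisher_z(0.99934), 3) == 4.008
        assert fl.fisher_z(-0.5) == -fl.fisher_z(0.5)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_out_of_range_rejected(self, r):
        with pytest.raises(ValueError):
            fl.fisher_z(r)


def test_statistics_invariant_to_subject_order():
    rng = np.random.default_rng(9)
    x = rng.normal(1.2, 0.3, 15)
    y = rng.normal(0.8, 0.3, 15)
    perm = rng.permutation(15)
    a = fl.paired_t_one_tailed(x, y)
    b = fl.paired_t_one_tailed(x[perm], y[perm])
    assert a.statistic == pytest.approx(b.statistic)
    assert fl.cohens_d_rm(x, y) == pytest.approx(fl.cohens_d_rm(x[perm], y[perm]))
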