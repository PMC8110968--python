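import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ecmatlas import diffexp
from ecmatlas import expression as expr
from tests.conftest import make_count_matrix


def _nm(counts, populations):
    cm = make_count_matrix(counts, populations)
    return expr.normalize_counts(
        cm, pd.Series(np.ones(len(populations)), index=cm.counts.columns)
    )


class TestEstimateDispersion:
    def test_poisson_like_gene_has_zero_alpha(self):
        # sample variance equals the mean: (8,10,12) has mean 10, var 4 < 10
        nm = _nm([[8, 10, 12, 9, 10, 11]], ["Basal"] * 3 + ["panDF"] * 3)
        alpha = diffexp.estimate_dispersion(nm, ["Basal", "panDF"])
        assert alpha.iloc[0] == 0.0

    def test_method_of_moments_value(self):
        # one group with mean 100 and sample variance 1100 → alpha = 0.1
        values = np.array([100 - np.sqrt(1100), 100, 100 + np.sqrt(1100)])
        counts = np.rint(np.concatenate([values, values])).astype(int)
        nm = _nm([counts], ["Basal"] * 3 + ["panDF"] * 3)
        x = nm.values.to_numpy()[0, :3]
        expected = (np.var(x, ddof=1) - x.mean()) / x.mean() ** 2
        alpha = diffexp.estimate_dispersion(nm, ["Basal", "panDF"])
        assert alpha.iloc[0] == pytest.approx(expected)
        assert alpha.iloc[0] == pytest.approx(0.1, rel=0.05)

    def test_alpha_never_negative(self, sim_dataset):
        alpha = diffexp.estimate_dispersion(sim_dataset["nm"], ["Basal", "panDF"])
        assert (alpha >= 0).all()

    def test_all_zero_gene_gets_zero(self):
        nm = _nm([[0, 0, 0, 0, 0, 0], [5, 6, 7, 5, 6, 7]], ["Basal"] * 3 + ["panDF"] * 3)
        alpha = diffexp.estimate_dispersion(nm, ["Basal", "panDF"])
        assert alpha.iloc[0] == 0.0


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            diffexp.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert diffexp.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert (diffexp.bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffexp.bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1,
                 max_size=30)
    )
    def test_matches_brute_force_step_up(self, p):
        p = np.asarray(p)
        m = len(p)
        # independent brute-force step-up: adj(i) = min over j with p(j)>=p(i)
        # of p(j)*m/rank(j), with ranks from the full sorted order
        order = np.argsort(p, kind="stable")
        brute = np.empty(m)
        running = np.inf
        for pos in range(m - 1, -1, -1):
            running = min(running, p[order[pos]] * m / (pos + 1))
            brute[order[pos]] = min(1.0, running)
        np.testing.assert_allclose(diffexp.bh_adjust(p), brute, atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=500)
        np.testing.assert_allclose(
            diffexp.bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


class TestWaldTwoGroup:
    def test_identical_group_means_null(self):
        nm = _nm([[50, 60, 70, 70, 60, 50]], ["Basal"] * 3 + ["panDF"] * 3)
        res = diffexp.wald_two_group(nm, "Basal", "panDF")
        assert res["log2fc"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_moderated_fold_change_value(self):
        # group means 80 and 5 with pseudocount 1 → log2(81/6)
        nm = _nm([[80, 80, 80, 5, 5, 5]], ["Basal"] * 3 + ["panDF"] * 3)
        res = diffexp.wald_two_group(nm, "Basal", "panDF")
        assert res["log2fc"].iloc[0] == pytest.approx(np.log2(81 / 6), abs=1e-12)

    def test_both_groups_zero_flagged(self):
        nm = _nm([[0] * 6, [10, 12, 9, 11, 10, 12]], ["Basal"] * 3 + ["panDF"] * 3)
        res = diffexp.wald_two_group(nm, "Basal", "panDF")
        assert res["flag"].iloc[0] == "all_zero"
        assert res["p"].iloc[0] == 1.0 and res["log2fc"].iloc[0] == 0.0

    def test_planted_effect_sensitivity(self):
        # genes with log2 effect 3 at mu=200, alpha=0.05, n=3/3 are recovered
        rng = np.random.default_rng(21)
        g, mu, alpha = 300, 200.0, 0.05
        r = 1 / alpha
        a = rng.negative_binomial(r, r / (r + 8 * mu), size=(g, 3))
        b = rng.negative_binomial(r, r / (r + mu), size=(g, 3))
        nm = _nm(np.hstack([a, b]), ["Basal"] * 3 + ["panDF"] * 3)
        res = diffexp.wald_two_group(nm, "Basal", "panDF")
        assert (res["padj"] < 0.05).mean() >= 0.9


class TestLRT:
    def _three_group_cm(self, rng, g=300, effect_group=None, effect=8.0):
        mu = np.full((g, 9), 100.0)
        if effect_group is not None:
            mu[:, effect_group * 3:(effect_group + 1) * 3] *= effect
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + mu))
        return make_count_matrix(counts, ["Basal"] * 3 + ["LI"] * 3 + ["UB"] * 3)

    def test_stat_nonnegative_and_shifted_group_detected(self):
        rng = np.random.default_rng(3)
        cm = self._three_group_cm(rng, g=50, effect_group=0, effect=10.0)
        factors = pd.Series(np.ones(9), index=cm.counts.columns)
        res = diffexp.lrt_multigroup(cm, factors, ["Basal", "LI", "UB"])
        assert (res["stat"] >= 0).all()
        # the F reference bounds how fast p can decay at 6 residual df
        assert (res["p"] < 1e-3).all()
        assert (res["p"] < 1e-4).mean() > 0.5

    def test_requires_three_groups(self):
        rng = np.random.default_rng(3)
        cm = self._three_group_cm(rng, g=10)
        factors = pd.Series(np.ones(9), index=cm.counts.columns)
        with pytest.raises(ValueError):
            diffexp.lrt_multigroup(cm, factors, ["Basal", "LI"])

    def test_rank_agreement_with_wald_on_strong_effects(self):
        # one group carries gene-specific effects; the other two are null, so
        # a two-group Wald (effect vs null) ranks genes like the LRT does
        rng = np.random.default_rng(17)
        g = 300
        effects = rng.uniform(0.0, 3.0, size=g)
        mu = np.full((g, 9), 100.0)
        mu[:, :3] *= 2 ** effects[:, None]
        r = 1 / 0.05
        cm = make_count_matrix(
            rng.negative_binomial(r, r / (r + mu)),
            ["Basal"] * 3 + ["LI"] * 3 + ["UB"] * 3,
        )
        factors = pd.Series(np.ones(9), index=cm.counts.columns)
        nm = expr.normalize_counts(cm, factors)
        wald = diffexp.wald_two_group(nm, "Basal", "LI")
        lrt = diffexp.lrt_multigroup(cm, factors, ["Basal", "LI", "UB"])
        rho = stats.spearmanr(wald["p"], lrt["p"]).statistic
        assert rho > 0.9


class TestCallOrigin:
    def _call(self, padj, log2fc):
        nm = _nm([[80, 80, 80, 10, 10, 10]], ["Basal"] * 3 + ["panDF"] * 3)
        de = pd.DataFrame(
            {"padj": [padj], "log2fc": [log2fc]}, index=nm.gene_ids
        )
        return diffexp.call_origin(de, nm)

    def test_significant_high_fold_change_is_epithelial(self):
        res = self._call(0.01, np.log2(8))
        assert res["verdict"].iloc[0] == "epithelial_enriched"
        assert res["basal_fraction"].iloc[0] == pytest.approx(240 / 270)

    def test_nonsignificant_is_shared(self):
        assert self._call(0.20, np.log2(8))["verdict"].iloc[0] == "shared"

    def test_fold_change_boundary_is_strict(self):
        assert self._call(0.01, np.log2(4.0))["verdict"].iloc[0] == "shared"

    def test_symmetric_dermal_call(self):
        assert self._call(0.01, -np.log2(8))["verdict"].iloc[0] == "dermal_enriched"
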