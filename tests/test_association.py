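import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata, spearmanr, wilcoxon

from vivovitro import association as assoc
from vivovitro.tables_io import ValidationError


class TestSpearman:
    def test_monotone_and_antitone(self):
        rho, _ = assoc.spearman([1, 2, 3], [1, 4, 9])
        assert rho == pytest.approx(1.0)
        rho, _ = assoc.spearman([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_pearson_on_midranks(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        rho, _ = assoc.spearman(x, y)
        rx, ry = rankdata(x), rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(brute)
        assert rho == pytest.approx(spearmanr(x, y).statistic)

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            rho, p = assoc.spearman(x, y)
            # independent enumeration over all permutations of y
            rx = rankdata(x) - rankdata(x).mean()
            ry = rankdata(y) - rankdata(y).mean()
            s_obs = abs((rx * ry).sum())
            count = 0
            total = 0
            for perm in itertools.permutations(range(6)):
                total += 1
                if abs((rx * ry[list(perm)]).sum()) >= s_obs - 1e-9:
                    count += 1
            assert p == pytest.approx(count / total)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        _, p = assoc.spearman(x, y)
        ref = spearmanr(x, y)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_series_flagged(self):
        with pytest.raises(ValidationError, match="constant"):
            assoc.spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=12, unique=True))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, x):
        y = list(np.arange(len(x), dtype=float))
        x = np.asarray(x, dtype=float)
        rho1, _ = assoc.spearman(x, y)
        rho2, _ = assoc.spearman(x**3, y)  # strictly monotone, exact in floats
        assert rho1 == pytest.approx(rho2)


class TestAdjustPvalues:
    def test_bh_hand_step_up(self):
        out = assoc.adjust_pvalues([0.01, 0.02, 0.04], "bh")
        assert out.tolist() == pytest.approx([0.03, 0.03, 0.04])

    def test_bh_identical_values_fixed_point(self):
        out = assoc.adjust_pvalues([0.2, 0.2, 0.2], "bh")
        assert out.tolist() == pytest.approx([0.2, 0.2, 0.2])

    def test_bonferroni_hand_values_with_cap(self):
        out = assoc.adjust_pvalues([0.4, 0.6], "bonferroni")
        assert out.tolist() == pytest.approx([0.8, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            assoc.adjust_pvalues([0.5, 1.2], "bh")

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw_and_bonferroni_dominates_bh(self, p):
        bh = assoc.adjust_pvalues(p, "bh")
        bonf = assoc.adjust_pvalues(p, "bonferroni")
        assert (bh >= np.asarray(p) - 1e-12).all()
        assert (bh <= 1 + 1e-12).all() and (bonf <= 1 + 1e-12).all()
        assert (bonf >= bh - 1e-12).all()
        # monotone in raw-p rank order
        order = np.argsort(p)
        assert (np.diff(bh[order]) >= -1e-12).all()


class TestWilcoxon:
    def test_all_positive_n3_exact(self):
        w, p = assoc.wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert w == 6.0
        assert p == pytest.approx(0.25)

    def test_antisymmetric_pair(self):
        _, p = assoc.wilcoxon_signed_rank([-1.0, 1.0])
        assert p == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        w1, p1 = assoc.wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0])
        w2, p2 = assoc.wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert (w1, p1) == (w2, p2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            assoc.wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_exact_p_matches_sign_enumeration(self, n):
        """Exact p equals brute-force enumeration of all 2^n sign
        assignments of the rank vector."""
        rng = np.random.default_rng(n)
        d = rng.normal(size=n)
        d[d == 0] = 0.5
        _, p = assoc.wilcoxon_signed_rank(d)
        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = np.array(
            [np.sum(ranks[list(signs)]) for signs in itertools.product([False, True], repeat=n)]
        )
        lower = np.mean(ws <= w_obs + 1e-9)
        upper = np.mean(ws >= w_obs - 1e-9)
        assert p == pytest.approx(min(1.0, 2 * min(lower, upper)))

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        d = rng.normal(size=15)
        _, p = assoc.wilcoxon_signed_rank(d)
        ref = wilcoxon(d, mode="exact")
        assert p == pytest.approx(ref.pvalue)

    def test_large_n_null_rejection_rate(self):
        """Normal-approximation branch holds its nominal level."""
        rng = np.random.default_rng(4)
        rej = 0
        reps = 2000
        for _ in range(reps):
            d = rng.normal(size=40)
            _, p = assoc.wilcoxon_signed_rank(d)
            rej += p < 0.05
        assert abs(rej / reps - 0.05) < 0.02


class TestCorrelationReport:
    def test_three_families_adjusted_separately(self, default_bundle):
        bundle, truth = default_bundle
        report = assoc.correlation_report(bundle, truth.planted_lags)
        t = report.table
        assert set(t["family"]) == {"alpha_diversity", "fb_ratio", "genera"}
        # pooled adjustment across everything differs from per-family
        env = t[t.environment == "in_vivo"]
        ok = env["p"].notna()
        pooled = assoc.adjust_pvalues(env.loc[ok, "p"], "bh")
        assert not np.allclose(pooled, env.loc[ok, "p_adj"])

    def test_planted_genus_exposure_pair_ranks_high(self, default_bundle):
        bundle, truth = default_bundle
        report = assoc.correlation_report(bundle, truth.planted_lags)
        t = report.table
        gen = t[(t.environment == "in_vivo") & (t.family == "genera")]
        strongest = gen.loc[gen["rho"].idxmax()]
        vivo_responders = {r.genus for r in truth.responders if r.slope_in_vivo > 0}
        assert strongest["descriptor"] in vivo_responders

    def test_rho_bounds_and_adjustment_order(self, default_bundle):
        bundle, truth = default_bundle
        t = assoc.correlation_report(bundle, truth.planted_lags).table
        ok = t["rho"].notna()
        assert t.loc[ok, "rho"].between(-1, 1).all()
        assert (t.loc[ok, "p_adj"] >= t.loc[ok, "p"] - 1e-12).all()


def test_environment_diversity_test_runs(default_bundle):
    bundle, _ = default_bundle
    w, p, n = assoc.environment_diversity_test(bundle, "chao1")
    assert 0 <= p <= 1 and n == 11
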