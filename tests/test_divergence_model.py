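import numpy as np
import pandas as pd
import pytest

from vivovitro import divergence_model as dm
from vivovitro.synthetic_data import SimulationConfig, generate_study
from vivovitro.tables_io import IN_VITRO, IN_VIVO, ValidationError


def synthetic_frame(seed=0, n_per_cell=4, beta=None, sd=1.0):
    """A balanced 2x2 (Environment x Probiotic) frame with orthogonal
    continuous diet scores and a known coefficient vector."""
    rng = np.random.default_rng(seed)
    env = np.repeat([1.0, -1.0], 2 * n_per_cell)
    prob = np.tile(np.repeat([1.0, -1.0], n_per_cell), 2)
    n = len(env)
    pc1 = rng.normal(size=n)
    pc2 = rng.normal(size=n)
    beta = beta or {}
    y = (
        beta.get("Intercept", 0.0)
        + beta.get("PC1_diet", 0.0) * pc1
        + beta.get("PC2_diet", 0.0) * pc2
        + beta.get("Probiotic", 0.0) * prob
        + beta.get("Environment", 0.0) * env
        + beta.get("PC1_diet:Environment", 0.0) * pc1 * env
        + beta.get("PC2_diet:Environment", 0.0) * pc2 * env
        + beta.get("Probiotic:Environment", 0.0) * prob * env
        + rng.normal(0, sd, size=n)
    )
    data = pd.DataFrame(
        {
            "PC1_micro": y,
            "PC2_micro": rng.normal(size=n),
            "PC1_diet": pc1,
            "PC2_diet": pc2,
            "Probiotic": (prob > 0).astype(int),
            "Environment": np.where(env > 0, IN_VIVO, IN_VITRO),
        }
    )
    return dm.ModelFrame(data=data, taxa=[], diet_exposures=[])


class TestZStandardize:
    @staticmethod
    def _meta(envs):
        return pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(envs))], "environment": envs}
        )

    def test_hand_z_scores(self):
        diet = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=["s0", "s1", "s2"])
        z = dm.z_standardize_by_environment(diet, self._meta([IN_VIVO] * 3))
        assert z["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_defining_property_per_environment(self):
        rng = np.random.default_rng(0)
        envs = [IN_VIVO] * 6 + [IN_VITRO] * 5
        diet = pd.DataFrame(
            rng.uniform(1, 100, size=(11, 3)), columns=list("abc"),
            index=[f"s{i}" for i in range(11)],
        )
        z = dm.z_standardize_by_environment(diet, self._meta(envs))
        for env, sl in ((IN_VIVO, slice(0, 6)), (IN_VITRO, slice(6, 11))):
            sub = z.iloc[sl]
            assert np.allclose(sub.mean(), 0.0, atol=1e-12)
            assert np.allclose(sub.std(ddof=1), 1.0, atol=1e-12)

    def test_unit_cancellation_across_scales(self):
        # same ranks and spacing, different units: identical z-values
        vivo = pd.DataFrame({"x": [10.0, 20.0, 30.0]}, index=["s0", "s1", "s2"])
        vitro = pd.DataFrame({"x": [0.1, 0.2, 0.3]}, index=["s3", "s4", "s5"])
        diet = pd.concat([vivo, vitro])
        z = dm.z_standardize_by_environment(
            diet, self._meta([IN_VIVO] * 3 + [IN_VITRO] * 3)
        )
        assert z["x"].iloc[:3].tolist() == pytest.approx(z["x"].iloc[3:].tolist())

    def test_constant_column_named_in_error(self):
        diet = pd.DataFrame({"flat": [1.0, 1.0, 1.0]}, index=["s0", "s1", "s2"])
        with pytest.raises(ValidationError, match="flat"):
            dm.z_standardize_by_environment(diet, self._meta([IN_VIVO] * 3))


class TestType3Anova:
    def test_matches_statsmodels_type3_oracle(self):
        """Cross-check every Type III SS, F and p against statsmodels on
        an unbalanced frame with sum-to-zero coding."""
        frame = synthetic_frame(seed=1, beta={"Environment": 1.0, "PC1_diet": 0.5}, sd=0.7)
        # unbalance it by dropping two rows
        frame = dm.ModelFrame(data=frame.data.iloc[2:], taxa=[], diet_exposures=[])
        ours = dm.fit_type3_anova(frame, "PC1_micro").table

        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = frame.data.copy()
        df["Env"] = np.where(df["Environment"] == IN_VIVO, "vivo", "vitro")
        model = smf.ols(
            "PC1_micro ~ (PC1_diet + PC2_diet + C(Probiotic, Sum)) * C(Env, Sum)", df
        ).fit()
        oracle = anova_lm(model, typ=3)
        mapping = {
            "PC1_diet": "PC1_diet",
            "PC2_diet": "PC2_diet",
            "Probiotic": "C(Probiotic, Sum)",
            "Environment": "C(Env, Sum)",
            "PC1_diet:Environment": "PC1_diet:C(Env, Sum)",
            "PC2_diet:Environment": "PC2_diet:C(Env, Sum)",
            "Probiotic:Environment": "C(Probiotic, Sum):C(Env, Sum)",
        }
        for term, sm_term in mapping.items():
            assert ours.loc[term, "sum_sq"] == pytest.approx(oracle.loc[sm_term, "sum_sq"]), term
            assert ours.loc[term, "F"] == pytest.approx(oracle.loc[sm_term, "F"]), term
            assert ours.loc[term, "p"] == pytest.approx(oracle.loc[sm_term, "PR(>F)"]), term
        assert ours.loc["Residual", "sum_sq"] == pytest.approx(oracle.loc["Residual", "sum_sq"])

    def test_balanced_design_type3_equals_sequential_type1(self):
        """On a balanced fully orthogonal design the sequential (Type I)
        SS from a brute-force nested-model comparison equal Type III
        for every term."""
        rng = np.random.default_rng(2)
        n_per_cell = 4
        env = np.repeat([1.0, -1.0], 2 * n_per_cell)
        prob = np.tile(np.repeat([1.0, -1.0], n_per_cell), 2)
        # within-cell contrast patterns: orthogonal to every factor
        # column and to each other, also after multiplying by env
        pc1 = np.tile([1.0, -1.0, 1.0, -1.0], 4)
        pc2 = np.tile([1.0, 1.0, -1.0, -1.0], 4)
        y = 0.8 * env + 0.5 * pc1 + rng.normal(0, 1, len(env))
        data = pd.DataFrame(
            {
                "PC1_micro": y,
                "PC2_micro": rng.normal(size=len(env)),
                "PC1_diet": pc1,
                "PC2_diet": pc2,
                "Probiotic": (prob > 0).astype(int),
                "Environment": np.where(env > 0, IN_VIVO, IN_VITRO),
            }
        )
        frame = dm.ModelFrame(data=data, taxa=[], diet_exposures=[])
        X = dm._design_matrix(frame.data)
        # verify the design really is orthogonal
        G = X.to_numpy().T @ X.to_numpy()
        assert np.allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-10)
        # brute-force sequential SS oracle
        seq = {}
        cols = ["Intercept"]
        prev = dm._sse(X[cols].to_numpy(), y)
        for t in [c for c in X.columns if c != "Intercept"]:
            cols.append(t)
            cur = dm._sse(X[cols].to_numpy(), y)
            seq[t] = prev - cur
            prev = cur
        ours = dm.fit_type3_anova(frame, "PC1_micro").table
        for t in dm.MODEL_TERMS:
            assert ours.loc[t, "sum_sq"] == pytest.approx(seq[t], abs=1e-8), t

    def test_term_order_invariance(self):
        frame = synthetic_frame(seed=3, beta={"PC1_diet:Environment": 1.2})
        shuffled = frame.data[list(frame.data.columns)[::-1]].iloc[::-1]
        frame2 = dm.ModelFrame(data=shuffled, taxa=[], diet_exposures=[])
        t1 = dm.fit_type3_anova(frame, "PC1_micro").table
        t2 = dm.fit_type3_anova(frame2, "PC1_micro").table
        pd.testing.assert_frame_equal(t1, t2)

    def test_ss_decomposition_on_orthogonal_design(self):
        frame = synthetic_frame(seed=4, beta={"Environment": 1.0, "Probiotic": 0.5})
        data = frame.data.copy()
        # use only the factor structure: drop diet columns' correlation
        data["PC1_diet"] = 0.0 * data["PC1_diet"]
        data["PC2_diet"] = 0.0 * data["PC2_diet"]
        # factors are balanced +-1, so term SS + residual SS = total SS
        # (diet terms contribute 0 and are aliased -> use reduced check)
        X = dm._design_matrix(data)[["Intercept", "Probiotic", "Environment", "Probiotic:Environment"]]
        y = data["PC1_micro"].to_numpy()
        sse_full = dm._sse(X.to_numpy(), y)
        total = ((y - y.mean()) ** 2).sum()
        parts = 0.0
        for t in ("Probiotic", "Environment", "Probiotic:Environment"):
            keep = [c for c in X.columns if c != t]
            parts += dm._sse(X[keep].to_numpy(), y) - sse_full
        assert parts + sse_full == pytest.approx(total)

    def test_environment_coefficient_recovery_within_3_se(self):
        d = 1.5
        hits = 0
        for s in range(100):
            frame = synthetic_frame(seed=s, beta={"Environment": d}, sd=1.0)
            report = dm.fit_type3_anova(frame, "PC1_micro")
            coef = report.coefficients["Environment"]
            mse = report.table.loc["Residual", "sum_sq"] / report.table.loc["Residual", "df"]
            se = np.sqrt(mse / len(frame.data))  # orthonormal +-1 column
            hits += abs(coef - d) <= 3 * se
        assert hits >= 95

    def test_rank_deficiency_identifies_aliased_term(self):
        frame = synthetic_frame(seed=5)
        data = frame.data.copy()
        data["PC2_diet"] = data["PC1_diet"]  # alias
        frame2 = dm.ModelFrame(data=data, taxa=[], diet_exposures=[])
        with pytest.raises(ValidationError, match="PC2_diet"):
            dm.fit_type3_anova(frame2, "PC1_micro")

    def test_variance_shares_in_unit_interval(self):
        frame = synthetic_frame(seed=6, beta={"Environment": 2.0})
        table = dm.fit_type3_anova(frame, "PC1_micro").table
        shares = table["var_share"].dropna()
        assert ((shares >= 0) & (shares <= 1)).all()


class TestBuildModelFrame:
    def test_one_row_per_retained_sample(self, default_bundle):
        bundle, truth = default_bundle
        frame = dm.build_model_frame(bundle, truth.planted_lags)
        assert len(frame.data) == bundle.n_retained
        assert frame.data["Environment"].nunique() == 2

    def test_probiotic_indicator_matches_supplementation_days(self, default_bundle):
        bundle, truth = default_bundle
        frame = dm.build_model_frame(bundle, truth.planted_lags)
        meta = bundle.metadata.set_index("sample_id")
        for sid, row in frame.data.iterrows():
            day = meta.loc[sid, "day"]
            assert row["Probiotic"] == (1 if 1 <= day <= 14 else 0)

    def test_genus_level_uses_shared_prevalent_taxa(self, default_bundle):
        bundle, truth = default_bundle
        frame = dm.build_model_frame(bundle, truth.planted_lags, level="genus")
        genera = {g for _, g in frame.taxa}
        # the shared core of the generator should dominate the selection
        assert len(genera & {"Bacteroides", "Bifidobacterium", "Akkermansia", "Alistipes"}) >= 3

    def test_phylum_level_runs_same_path(self, default_bundle):
        bundle, truth = default_bundle
        frame = dm.build_model_frame(bundle, truth.planted_lags, level="phylum")
        report = dm.fit_type3_anova(frame, "PC1_micro")
        assert report.table.loc["Residual", "df"] == len(frame.data) - 8
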