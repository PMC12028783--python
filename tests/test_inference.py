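"""ANOVA, Duncan letters, percent change, importance, PCA, radar scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from alleloscreen.errors import DataValidationError, DegenerateDataError
from alleloscreen.inference import (
    anova_oneway,
    biological_means,
    compare_groups,
    duncan_mrt,
    importance_ranking,
    pca_profiles,
    percent_change,
    radar_profile,
)

from _oracles import duncan_oracle


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        g = np.array([1.0, 2.0, 3.0])
        f, p = anova_oneway([g, g])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    @given(seed=st.integers(0, 2**16))
    def test_two_group_f_is_squared_t(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 8)
        f, p_f = anova_oneway([a, b])
        t, p_t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-9)
        assert p_f == pytest.approx(p_t, rel=1e-9)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateDataError):
            anova_oneway([np.ones(3), np.full(3, 2.0)])
        with pytest.raises(DataValidationError):
            anova_oneway([np.ones(3)])
        with pytest.raises(DataValidationError):
            anova_oneway([np.ones(3), np.array([1.0])])


class TestDuncan:
    def test_identical_groups_share_one_letter(self, rng):
        base = rng.normal(10, 1, 4)
        letters = duncan_mrt({"a": base, "b": base, "c": base})
        assert set(letters.values()) == {"a"}

    @given(seed=st.integers(0, 2**16))
    def test_two_groups_match_pooled_t_decision(self, seed):
        """For two groups Duncan's protection level collapses and the
        separation decision equals a pooled-variance t test at alpha."""
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 4), rng.normal(1.0, 1, 4)
        letters = duncan_mrt({"a": a, "b": b}, alpha=0.05)
        separated = letters["a"] != letters["b"]
        _, p = stats.ttest_ind(a, b)
        assert separated == (p < 0.05)

    def test_well_separated_means_get_distinct_letters(self, rng):
        groups = {g: rng.normal(mu, 0.1, 4) for g, mu in zip("abcd", [0, 5, 10, 15])}
        letters = duncan_mrt(groups)
        assert len(set(letters.values())) == 4

    def test_letters_match_exhaustive_span_oracle(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 7))
            sep = rng.uniform(0.0, 3.0)
            groups = {
                f"g{i}": rng.normal(sep * rng.integers(0, 3), 1.0, 4) for i in range(k)
            }
            assert duncan_mrt(groups) == duncan_oracle(groups)

    def test_unbalanced_groups_flagged(self, rng):
        res = compare_groups(
            {"a": rng.normal(0, 1, 4), "b": rng.normal(3, 1, 6)}, indicator="MDA"
        )
        assert res.unbalanced
        assert res.indicator == "MDA"
        assert set(res.letters) == {"a", "b"}


class TestPercentChange:
    @pytest.mark.parametrize("t,c,expected", [(2, 1, 100.0), (1, 2, -50.0), (1, 1, 0.0)])
    def test_hand_values(self, t, c, expected):
        assert percent_change(t, c) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(DataValidationError):
            percent_change(1.0, 0.0)

    @given(m=st.floats(0.01, 1e6), d=st.floats(0.0, 0.9))
    def test_zero_at_equality_and_antisymmetric_sign(self, m, d):
        assert percent_change(m, m) == 0.0
        assert percent_change(m * (1 + d), m) >= 0.0
        assert percent_change(m * (1 - d), m) <= 0.0


class TestImportance:
    def test_planted_dominant_feature_ranked_first(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (40, 4)), columns=list("abcd"))
        y = X["c"].to_numpy()  # response is an exact copy of one feature
        imp = importance_ranking(X, y, n_estimators=200, rng_seed=0)
        assert imp.iloc[0]["variable"] == "c"
        assert list(imp["rank"]) == [1, 2, 3, 4]

    def test_duplicated_feature_splits_importance_mass(self, rng):
        """A duplicated predictor shares splits with its copy, so neither
        column alone carries the full importance of the unduplicated one."""
        base = rng.normal(0, 1, 60)
        X = pd.DataFrame(
            {"x": base, "x_copy": base, "noise": rng.normal(0, 1, 60)}
        )
        y = base + rng.normal(0, 0.05, 60)
        imp = importance_ranking(X, y, n_estimators=200, rng_seed=1)
        imp = imp.set_index("variable")["importance"]
        solo = importance_ranking(
            X[["x", "noise"]], y, n_estimators=200, rng_seed=1
        ).set_index("variable")["importance"]
        assert imp["x"] < solo["x"]
        assert imp[["x", "x_copy"]].min() > imp["noise"]

    def test_constant_response_and_small_n_rejected(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (10, 3)))
        with pytest.raises(DegenerateDataError):
            importance_ranking(X, np.ones(10))
        with pytest.raises(DataValidationError, match="8 observations"):
            importance_ranking(X.iloc[:5], np.arange(5))


def _physio_frame(values_by_treatment, indicators=("MDA", "SOD", "Pro"), tech=2):
    rows = []
    for t, shift in values_by_treatment.items():
        for b in range(1, 5):
            for i_idx, ind in enumerate(indicators):
                for r in range(1, tech + 1):
                    rows.append(
                        {
                            "treatment": t,
                            "bio_rep": b,
                            "tech_rep": r,
                            "indicator": ind,
                            "value": shift + i_idx + 0.1 * b + 0.01 * r,
                        }
                    )
    return pd.DataFrame(rows)


class TestPca:
    def test_collinear_samples_put_all_variance_on_pc1(self):
        physio = _physio_frame({"CK": 0.0, "T1": 5.0, "T10": 10.0})
        res = pca_profiles(physio)
        assert res.var_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_sum_to_one_and_scores_centered(self, rng):
        rows = []
        for t in ("CK", "T1", "T10"):
            for b in range(1, 5):
                for ind in ("MDA", "SOD", "Pro", "SS"):
                    rows.append(
                        {
                            "treatment": t,
                            "bio_rep": b,
                            "tech_rep": 1,
                            "indicator": ind,
                            "value": float(rng.uniform(1, 10)),
                        }
                    )
        res = pca_profiles(pd.DataFrame(rows))
        assert res.var_explained.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(res.var_explained) <= 1e-12).all()
        comp = [c for c in res.scores.columns if c.startswith("PC")]
        assert np.allclose(res.scores[comp].mean(), 0.0, atol=1e-10)

    def test_zero_variance_indicator_dropped_with_warning(self, rng):
        physio = _physio_frame({"CK": 0.0, "T1": 3.0})
        flat = physio["indicator"] == "MDA"
        physio.loc[flat, "value"] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_profiles(physio)
        assert res.dropped == ("MDA",)
        assert "MDA" not in res.loadings.index

    def test_separated_treatments_cluster_on_first_two_scores(self, rng):
        """Well-separated planted treatment means give a silhouette > 0.5
        on the first two components."""
        from sklearn.metrics import silhouette_score

        rows = []
        centers = {"CK": (0, 0, 0, 0), "T1": (8, -8, 4, 0), "T10": (-8, 8, 0, 4)}
        for t, mu in centers.items():
            for b in range(1, 5):
                for ind, m in zip(("MDA", "SOD", "Pro", "SS"), mu):
                    rows.append(
                        {
                            "treatment": t,
                            "bio_rep": b,
                            "tech_rep": 1,
                            "indicator": ind,
                            "value": m + float(rng.normal(0, 0.5)),
                        }
                    )
        res = pca_profiles(pd.DataFrame(rows))
        score = silhouette_score(
            res.scores[["PC1", "PC2"]], res.scores["treatment"]
        )
        assert score > 0.5

    def test_technical_replicates_averaged_first(self):
        physio = _physio_frame({"CK": 0.0, "T1": 2.0}, tech=3)
        bio = biological_means(physio)
        assert len(bio) == 2 * 4 * 3  # treatments x bio reps x indicators
        merged = physio.groupby(["treatment", "bio_rep", "indicator"])["value"].mean()
        assert np.allclose(bio.set_index(["treatment", "bio_rep", "indicator"])["value"],
                           merged.loc[bio.set_index(["treatment", "bio_rep", "indicator"]).index])


class TestRadar:
    def test_three_treatments_map_to_unit_interval_ends(self):
        rows = [
            {"treatment": t, "bio_rep": 1, "tech_rep": 1, "indicator": "MDA", "value": v}
            for t, v in [("CK", 1.0), ("T1", 2.0), ("T10", 3.0)]
        ]
        out = radar_profile(pd.DataFrame(rows)).set_index("treatment")["value"]
        assert out["CK"] == 0.0 and out["T1"] == 0.5 and out["T10"] == 1.0

    def test_constant_indicator_maps_to_half_with_warning(self):
        rows = [
            {"treatment": t, "bio_rep": 1, "tech_rep": 1, "indicator": "SOD", "value": 4.0}
            for t in ("CK", "T1", "T10")
        ]
        with pytest.warns(UserWarning, match="constant"):
            out = radar_profile(pd.DataFrame(rows))
        assert (out["value"] == 0.5).all()

    def test_output_always_within_unit_interval(self, rng):
        physio = _physio_frame({"CK": 0.0, "T1": float(rng.uniform(0, 5))})
        out = radar_profile(physio)
        assert out["value"].between(0.0, 1.0).all()
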