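"""Landscape PCA, prey index and design assembly."""

import numpy as np
import pandas as pd
import pytest

from msdom import covariates as cov


def landscape(rng, n=50):
    """Correlated landscape table: development variables move together,
    forest moves against them."""
    dev = rng.normal(0, 1, n)
    return pd.DataFrame({
        "forest_cover": np.clip(0.6 - 0.2 * dev + 0.05 * rng.normal(size=n), 0, 1),
        "residential": np.clip(0.2 + 0.15 * dev + 0.04 * rng.normal(size=n), 0, 1),
        "road_density": np.clip(2 + dev + 0.3 * rng.normal(size=n), 0, None),
        "housing": np.clip(100 + 80 * dev + 20 * rng.normal(size=n), 0, None),
    }, index=[f"site_{i}" for i in range(n)]).rename_axis("site_id")


class TestCorrelationScreen:
    def test_negated_column_is_minus_one(self, rng):
        x = rng.normal(size=20)
        tab = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=20), "d": rng.normal(size=20)})
        corr, max_abs = cov.correlation_screen(tab)
        assert corr.loc["a", "b"] == pytest.approx(-1)
        assert max_abs == pytest.approx(1)

    def test_independent_columns_nearly_uncorrelated(self, rng):
        tab = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        corr, _ = cov.correlation_screen(tab)
        assert abs(corr.loc["a", "b"]) < 0.05

    def test_identical_columns_are_one(self, rng):
        x = rng.normal(size=15)
        corr, _ = cov.correlation_screen(pd.DataFrame({"a": x, "b": x.copy()}))
        assert corr.loc["a", "b"] == pytest.approx(1)

    def test_zero_variance_flagged(self, rng):
        tab = pd.DataFrame({"a": np.ones(10), "b": rng.normal(size=10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, _ = cov.correlation_screen(tab)
        assert np.isnan(corr.loc["a", "b"])


class TestPCAScore:
    def test_collinear_columns_explain_everything(self):
        x = np.arange(10, dtype=float)
        tab = pd.DataFrame({"forest_cover": x, "residential": -x,
                            "road_density": 2 * x, "housing": -3 * x})
        _, var = cov.compute_pca_score(tab)
        assert var == pytest.approx(1.0)

    def test_forest_rich_sites_score_positive(self, rng):
        tab = landscape(rng)
        scores, var = cov.compute_pca_score(tab)
        assert 0.5 < var <= 1.0
        rich = tab["forest_cover"].idxmax()
        poor = tab["forest_cover"].idxmin()
        assert scores[rich] > 0 > scores[poor]
        assert scores.mean() == pytest.approx(0, abs=1e-10)

    def test_orientation_invariant_to_row_order(self, rng):
        tab = landscape(rng)
        s1, v1 = cov.compute_pca_score(tab)
        shuffled = tab.sample(frac=1, random_state=0)
        s2, v2 = cov.compute_pca_score(shuffled)
        assert v2 == pytest.approx(v1)
        pd.testing.assert_series_equal(s2.sort_index(), s1.sort_index(),
                                       check_exact=False, atol=1e-8)

    def test_constant_column_raises(self, rng):
        tab = landscape(rng)
        tab["housing"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            cov.compute_pca_score(tab)


class TestPreyIndex:
    effort = pd.DataFrame({"site_id": ["A", "A", "B"], "season": ["summer", "winter", "summer"],
                           "trap_nights": [42, 42, 0]})

    def make_records(self, n_day, n_night):
        rows = []
        for i in range(n_day):
            rows.append(("A", "gray_squirrel", "summer", "day"))
        for i in range(n_night):
            rows.append(("A", "gray_squirrel", "summer", "night"))
        return pd.DataFrame(rows, columns=["site_id", "species", "season", "diel"])

    def test_half_detection_per_trap_night(self):
        with pytest.warns(UserWarning):
            out = cov.compute_prey_index(self.make_records(21, 0), self.effort)
        row = out[(out.site_id == "A") & (out.season == "summer")].iloc[0]
        assert row["prey_day"] == pytest.approx(0.5)
        assert row["prey_night"] == 0

    def test_no_prey_detections_is_zero(self):
        rec = pd.DataFrame([("A", "coyote", "summer", "day")],
                           columns=["site_id", "species", "season", "diel"])
        with pytest.warns(UserWarning):
            out = cov.compute_prey_index(rec, self.effort)
        assert (out.loc[out.site_id == "A", ["prey_day", "prey_night"]].to_numpy() == 0).all()

    def test_scale_invariance(self):
        effort2 = self.effort.assign(trap_nights=self.effort.trap_nights * 2)
        with pytest.warns(UserWarning):
            a = cov.compute_prey_index(self.make_records(10, 6), self.effort)
        b = cov.compute_prey_index(pd.concat([self.make_records(10, 6)] * 2),
                                   effort2[effort2.trap_nights > 0])
        ra = a[(a.site_id == "A") & (a.season == "summer")]
        rb = b[(b.site_id == "A") & (b.season == "summer")]
        assert ra["prey_day"].iloc[0] == pytest.approx(rb["prey_day"].iloc[0])

    def test_zero_trap_nights_flagged_missing(self):
        with pytest.warns(UserWarning, match="zero trap-nights"):
            out = cov.compute_prey_index(self.make_records(1, 1), self.effort)
        assert out[(out.site_id == "B")]["prey_day"].isna().all()


class TestAssembleDesign:
    def index(self, n=6):
        return pd.MultiIndex.from_product(
            [[f"s{i}" for i in range(n)], ["summer", "winter"]],
            names=["site_id", "season"])

    def pca(self, rng, n=6):
        return pd.Series(rng.normal(size=n), index=pd.Index([f"s{i}" for i in range(n)], name="site_id"))

    def test_null_form_intercept_only(self):
        d = cov.assemble_design(self.index(), form="null")
        assert d.state_columns["day"] == ["intercept"]
        assert "winter" in d.frame.columns  # detection still needs the season

    def test_interaction_form_columns(self, rng):
        d = cov.assemble_design(self.index(), pca=self.pca(rng), form="season*pca")
        assert d.state_columns["night"] == ["intercept", "winter", "pca", "winter:pca"]
        np.testing.assert_allclose(d.frame["winter:pca"],
                                   d.frame["winter"] * d.frame["pca"])

    def test_prey_form_is_state_matched(self, rng):
        prey = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(6)] * 2,
            "season": ["summer"] * 6 + ["winter"] * 6,
            "prey_day": rng.uniform(0, 1, 12), "prey_night": rng.uniform(0, 1, 12),
        })
        d = cov.assemble_design(self.index(), prey=prey, form="prey+season")
        assert d.state_columns["day"] == ["intercept", "winter", "prey_day"]
        assert d.state_columns["night"] == ["intercept", "winter", "prey_night"]
        assert d.state_columns["daynight"] == ["intercept", "winter", "prey_mean"]
        vals = np.concatenate([d.frame["prey_day"], d.frame["prey_night"]])
        assert vals.mean() == pytest.approx(0, abs=1e-10)
        assert vals.std() == pytest.approx(1, abs=1e-10)

    def test_unknown_form_raises(self):
        with pytest.raises(ValueError, match="unknown model form"):
            cov.assemble_design(self.index(), form="pca^2")

    def test_full_column_rank_on_nondegenerate_data(self, rng):
        d = cov.assemble_design(self.index(20), pca=self.pca(rng, 20), form="season*pca")
        X = d.matrix("day")
        assert np.linalg.matrix_rank(X) == X.shape[1]
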