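"""Centering, term construction and the named model specifications."""

import numpy as np
import pandas as pd
import pytest

import snvppv as sp
from snvppv.design import build_design, center, named_spec, term


@pytest.fixture
def small_table():
    return pd.DataFrame(
        {
            "y": [90, 80, 70, 60],
            "n": [100, 100, 100, 100],
            "titv": [2.0, 3.0, 4.0, 3.0],
            "hethom": [1.5, 2.0, 2.5, 2.0],
            "med_dp": [10.0, 20.0, 30.0, 20.0],
            "dp_lt5": [0.1, 0.2, 0.3, 0.2],
            "wes_indicator": [0, 1, 0, 1],
        }
    )


class TestCenter:
    def test_centers_to_zero_mean_and_stores_constants(self, small_table):
        centered, consts = center(small_table, ["titv"])
        assert consts["titv"] == pytest.approx(3.0)
        np.testing.assert_allclose(centered["titv"], [-1, 0, 1, 0])

    def test_idempotent(self, small_table):
        once, _ = center(small_table)
        twice, _ = center(once)
        for cov in ("titv", "hethom", "med_dp", "dp_lt5"):
            np.testing.assert_allclose(once[cov], twice[cov], atol=1e-12)

    def test_stored_constants_reproduce_training_scale(self, small_table):
        _, consts = center(small_table)
        new_row = pd.DataFrame([{"titv": 2.5, "hethom": 2.0, "med_dp": 15.0, "dp_lt5": 0.15}])
        reapplied, _ = center(new_row, ["titv"], constants=consts)
        assert reapplied["titv"].iloc[0] == pytest.approx(2.5 - 3.0)

    def test_missing_covariate_errors(self, small_table):
        with pytest.raises(KeyError, match="absent"):
            center(small_table.drop(columns=["titv"]))


class TestBuildDesign:
    def test_interaction_uses_centered_values(self, small_table):
        spec = sp.ModelSpec(tuple(term(t) for t in ["1", "wes_indicator", "titv", "wes_indicator:titv"]))
        dm = build_design(small_table, spec)
        # row 1: centered titv = 0 -> interaction 0; row 3: centered 0, wes 1
        col = dm.x_names.index("wes_indicator:titv")
        np.testing.assert_allclose(dm.X[:, col], [0.0, 0.0, 0.0, 0.0])
        # shift titv so centered value is nonzero for a WES row
        tab = small_table.assign(titv=[2.0, 3.5, 4.0, 3.0])
        dm2 = build_design(tab, spec)
        assert dm2.X[1, col] == pytest.approx(3.5 - tab["titv"].mean())

    def test_m11_6_column_counts(self, small_table):
        dm = build_design(small_table, named_spec("m11_6"))
        assert dm.X.shape[1] == 11
        assert dm.Z.shape[1] == 6

    def test_wes_indicator_not_centered(self, small_table):
        dm = build_design(small_table, named_spec("m11_6"))
        col = dm.x_names.index("wes_indicator")
        np.testing.assert_allclose(dm.X[:, col], small_table["wes_indicator"])

    def test_mean_covariate_row_keeps_only_intercept_and_wes(self, small_table):
        """A row at the covariate means has zeros in every centered column."""
        means = {
            c: small_table[c].mean() for c in ("titv", "hethom", "med_dp", "dp_lt5")
        }
        row = pd.DataFrame([{**means, "wes_indicator": 1, "y": 1, "n": 2}])
        dm = build_design(row, named_spec("m11_6"), centering=means)
        x = dm.X[0]
        nonzero = {dm.x_names[i] for i in np.flatnonzero(np.abs(x) > 1e-12)}
        assert nonzero == {"(Intercept)", "wes_indicator"}

    def test_missing_interaction_covariate_errors(self, small_table):
        spec = sp.ModelSpec(tuple(term(t) for t in ["1", "titv", "titv:hethom"]))
        with pytest.raises(KeyError, match="hethom"):
            build_design(small_table.drop(columns=["hethom"]), spec)

    def test_deterministic_and_order_preserving(self, small_table):
        spec = named_spec("m11_6")
        dm1 = build_design(small_table, spec)
        dm2 = build_design(small_table, spec)
        np.testing.assert_array_equal(dm1.X, dm2.X)
        assert dm1.x_names == dm2.x_names

    def test_factor_expansion_treatment_coding(self, small_table):
        tab = small_table.assign(
            kit_label=["WGS", "WES-Nextera", "WGS", "WES-TrueSeq"]
        )
        spec = sp.ModelSpec(tuple(term(t) for t in ["1", "titv", "kit_label"]))
        dm = build_design(tab, spec)
        assert dm.x_names == ["(Intercept)", "titv", "kit_label[WES-Nextera]", "kit_label[WES-TrueSeq]"]
        np.testing.assert_allclose(dm.X[:, 2], [0, 1, 0, 0])
        np.testing.assert_allclose(dm.X[:, 3], [0, 0, 0, 1])


class TestNamedSpecs:
    @pytest.mark.parametrize(
        "name,p,q",
        [("m11_6", 11, 6), ("m11_1", 11, 1), ("m15_1", 15, 1), ("global_mean_18", 18, 1)],
    )
    def test_dimensions(self, name, p, q):
        spec = named_spec(name)
        assert (spec.p, spec.q) == (p, q)

    def test_m11_6_term_lists(self):
        spec = named_spec("m11_6")
        mean_names = {t.name for t in spec.mean_terms}
        assert mean_names == {
            "1", "wes_indicator", "titv", "med_dp", "dp_lt5", "titv^2", "med_dp^2",
            "wes_indicator:titv", "wes_indicator:med_dp", "wes_indicator:dp_lt5",
            "titv:med_dp",
        }
        disp_names = {t.name for t in spec.dispersion_terms}
        assert disp_names == {
            "1", "wes_indicator", "titv", "dp_lt5", "titv^2", "wes_indicator:titv"
        }

    def test_global_18_contains_squares_and_wes_interactions(self):
        spec = named_spec("global_mean_18")
        names = {t.name for t in spec.mean_terms}
        assert {"titv^2", "hethom^2", "med_dp^2", "dp_lt5^2"} <= names
        assert {
            "wes_indicator:titv", "wes_indicator:hethom",
            "wes_indicator:med_dp", "wes_indicator:dp_lt5",
        } <= names
        assert {"med_dp:hethom", "titv:med_dp", "titv:dp_lt5"} <= names

    def test_18th_term_overridable(self):
        spec = named_spec("global_mean_18", extra_18th_term="hethom:dp_lt5")
        assert term("hethom:dp_lt5") in spec.mean_terms
        assert term("titv:hethom") not in spec.mean_terms
        assert spec.p == 18

    def test_dispersion_subset_invariant(self):
        for name in ("m11_6", "m11_1", "m15_1", "global_mean_18"):
            spec = named_spec(name)
            assert set(spec.dispersion_terms) <= set(spec.mean_terms)

    def test_unknown_name_lists_known(self):
        with pytest.raises(KeyError, match="m11_6"):
            named_spec("nope")

    def test_wes_square_rejected(self):
        with pytest.raises(ValueError, match="quantitative"):
            term("wes_indicator^2")


class TestTrainingTableIO:
    def test_roundtrip_and_column_map(self, small_table, tmp_path):
        path = tmp_path / "t.tsv"
        sp.write_training_table(small_table, path)
        back = sp.read_training_table(path)
        pd.testing.assert_frame_equal(back, small_table, check_dtype=False)
        renamed = small_table.rename(columns={"y": "TP", "n": "N"})
        path2 = tmp_path / "t2.tsv"
        sp.write_training_table(renamed, path2)
        back2 = sp.read_training_table(path2, column_map={"TP": "y", "N": "n"})
        assert list(back2["y"]) == list(small_table["y"])

    def test_invalid_counts_rejected(self, small_table, tmp_path):
        bad = small_table.assign(y=[101, 80, 70, 60])
        path = tmp_path / "bad.tsv"
        sp.write_training_table(bad, path)
        with pytest.raises(ValueError, match="y <= n"):
            sp.read_training_table(path)
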