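"""Loading, validation, standardization, and the inverse-covariance screen."""

import numpy as np
import pandas as pd
import pytest

from knockdag.dataset import (
    Dataset,
    VariableMeta,
    load_dataset,
    precision_screen,
    standardize,
    write_dataset,
)


def _write(tmp_path, df, meta_entries, name="t.tsv"):
    import yaml

    table = tmp_path / name
    meta = tmp_path / "meta.yaml"
    df.to_csv(table, sep="\t", index=False)
    meta.write_text(yaml.safe_dump(meta_entries))
    return table, meta


class TestLoad:
    def test_identity_load_all_continuous(self, tmp_path):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.5, -1.0, 2.5]})
        table, meta = _write(tmp_path, df, [{"name": "a", "kind": "continuous"},
                                            {"name": "b", "kind": "continuous"}])
        d = load_dataset(table, meta)
        assert d.continuous_names == ["a", "b"] and d.ordinal_names == []
        np.testing.assert_allclose(d.values, df.to_numpy())

    def test_ordinal_codes_follow_declared_order(self, tmp_path):
        df = pd.DataFrame({"a": [0.1, 0.2, 0.3], "g": [3, 1, 2]})
        table, meta = _write(tmp_path, df, [{"name": "a", "kind": "continuous"},
                                            {"name": "g", "kind": "ordinal", "levels": [1, 2, 3]}])
        d = load_dataset(table, meta)
        np.testing.assert_array_equal(d.column("g"), [2, 0, 1])

    def test_unknown_level_code_rejected(self, tmp_path):
        df = pd.DataFrame({"a": [0.1, 0.2, 0.3], "g": [1, 2, 4]})
        table, meta = _write(tmp_path, df, [{"name": "a", "kind": "continuous"},
                                            {"name": "g", "kind": "ordinal", "levels": [1, 2, 3]}])
        with pytest.raises(ValueError, match="unknown level"):
            load_dataset(table, meta)

    def test_missing_value_and_undeclared_column_rejected(self, tmp_path):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 2.0, 3.0]})
        table, meta = _write(tmp_path, df, [{"name": "a", "kind": "continuous"},
                                            {"name": "b", "kind": "continuous"}])
        with pytest.raises(ValueError, match="missing"):
            load_dataset(table, meta)
        table2, meta2 = _write(tmp_path, df.fillna(0.0), [{"name": "a", "kind": "continuous"}], name="t2.tsv")
        with pytest.raises(ValueError, match="missing from metadata"):
            load_dataset(table2, meta2)

    def test_round_trip_is_lossless(self, tmp_path, rng):
        values = rng.standard_normal((20, 4))
        codes = rng.integers(0, 3, 20).astype(float)
        meta = [VariableMeta(f"v{i}", "continuous") for i in range(4)]
        meta.append(VariableMeta("g", "ordinal", ("lo", "mid", "hi")))
        d = Dataset(np.column_stack([values, codes]), meta)
        write_dataset(d, tmp_path / "w.tsv", tmp_path / "w.yaml")
        d2 = load_dataset(tmp_path / "w.tsv", tmp_path / "w.yaml")
        np.testing.assert_allclose(d2.values, d.values, atol=1e-12)
        assert [v.name for v in d2.meta] == [v.name for v in d.meta]
        assert d2.sample_ids == d.sample_ids


class TestValidation:
    def test_nominal_kind_rejected(self):
        with pytest.raises(ValueError, match="nominal"):
            VariableMeta("x", "nominal", ("a", "b"))

    def test_ordinal_needs_two_levels(self):
        with pytest.raises(ValueError, match=">= 2 levels"):
            VariableMeta("x", "ordinal", (1,))

    def test_duplicate_names_rejected(self, rng):
        meta = [VariableMeta("a", "continuous"), VariableMeta("a", "continuous")]
        with pytest.raises(ValueError, match="unique"):
            Dataset(rng.standard_normal((3, 2)), meta)

    def test_out_of_range_ordinal_code_rejected(self):
        meta = [VariableMeta("a", "continuous"), VariableMeta("g", "ordinal", (0, 1))]
        with pytest.raises(ValueError, match="codes"):
            Dataset(np.array([[0.0, 0.0], [1.0, 2.0]]), meta)


class TestStandardize:
    def test_unit_moments_and_idempotence(self, gaussian_dataset):
        std, params = standardize(gaussian_dataset, which="all")
        np.testing.assert_allclose(std.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(std.values.std(axis=0, ddof=1), 1.0, atol=1e-12)
        std2, _ = standardize(std, which="all")
        np.testing.assert_allclose(std2.values, std.values, atol=1e-10)

    def test_inverse_recovers_input(self, gaussian_dataset):
        std, params = standardize(gaussian_dataset, which="all")
        back = params.inverse(std)
        np.testing.assert_allclose(back.values, gaussian_dataset.values, atol=1e-10)

    def test_constant_column_error_names_column(self, rng):
        d = Dataset.from_dataframe(pd.DataFrame({"a": rng.standard_normal(5), "flat": np.ones(5)}))
        with pytest.raises(ValueError, match="flat"):
            standardize(d, which="all")

    def test_continuous_only_leaves_ordinal_codes(self, mixed_dataset):
        std, _ = standardize(mixed_dataset, which="continuous_only")
        np.testing.assert_array_equal(std.column("g"), mixed_dataset.column("g"))
        assert std.var_meta("g").kind == "ordinal"


class TestPrecisionScreen:
    def test_independent_columns_pass_nothing(self, rng):
        d = Dataset.from_dataframe(pd.DataFrame(rng.standard_normal((500, 4)), columns=list("abcd")))
        # raise tol above estimation noise of the inverse covariance
        assert precision_screen(d, tol=0.2) == set()

    def test_correlated_pair_admissible_closed_form(self, rng):
        # 2x2: Omega off-diagonal = -rho / (1 - rho^2) under unit variances
        z = rng.standard_normal((2000, 2))
        x = np.column_stack([z[:, 0], 0.9 * z[:, 0] + np.sqrt(1 - 0.81) * z[:, 1]])
        d = Dataset.from_dataframe(pd.DataFrame(x, columns=["a", "b"]))
        assert ("a", "b") in precision_screen(d, tol=1e-4)
        cov = np.cov(x, rowvar=False)
        omega = np.linalg.inv(cov)
        assert abs(omega[0, 1]) > 1.0  # 0.9/(1-0.81) ~ 4.7 in the population

    def test_tol_zero_is_vacuous_and_monotone(self, gaussian_dataset):
        m = gaussian_dataset.n_variables
        all_pairs = precision_screen(gaussian_dataset, tol=0.0)
        assert len(all_pairs) == m * (m - 1) // 2
        loose = precision_screen(gaussian_dataset, tol=1e-4)
        tight = precision_screen(gaussian_dataset, tol=0.3)
        assert tight <= loose <= all_pairs

    def test_singular_without_ridge_raises(self, rng):
        d = Dataset.from_dataframe(pd.DataFrame(rng.standard_normal((4, 6))))
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            precision_screen(d, ridge=0)
        # the automatic ridge makes the same call succeed
        precision_screen(d, ridge="auto")
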