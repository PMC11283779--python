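"""Size correction, fossil mass imputation, and covariance PCA."""

import numpy as np
import pandas as pd
import pytest

from ouregimes.morphometrics import (TraitTable, estimate_fossil_mass,
                                     log_shape_ratios, pca)


def table_from(rows, traits):
    return TraitTable(pd.DataFrame(rows), traits)


class TestLogShapeRatios:
    def test_worked_values(self):
        t = table_from([
            {"species": "a", "x": 10.0},
            {"species": "b", "x": 50.0},
        ], ("x",))
        out = log_shape_ratios(t, {"a": 1000.0, "b": 125.0})
        assert out.ratios.loc["a", "x"] == pytest.approx(0.0)
        assert out.ratios.loc["b", "x"] == pytest.approx(1.0)

    def test_specimens_averaged_before_transform(self):
        t = table_from([
            {"species": "a", "x": 9.0},
            {"species": "a", "x": 11.0},
        ], ("x",))
        out = log_shape_ratios(t, {"a": 8.0})
        assert out.ratios.loc["a", "x"] == pytest.approx(np.log10(10.0 / 2.0))

    def test_missing_mass_names_species(self):
        t = table_from([{"species": "a", "x": 1.0}], ("x",))
        with pytest.raises(KeyError, match="a"):
            log_shape_ratios(t, {"b": 5.0})

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            table_from([{"species": "a", "x": -1.0}], ("x",))

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(min_value=1e-3, max_value=1e4))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_unit_rescaling_invariance(self, c):
        """mm -> c*mm together with g -> c^3*g leaves ratios unchanged."""
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 100, size=5)
        rows = [{"species": f"s{i}", "x": v} for i, v in enumerate(vals)]
        masses = {f"s{i}": m for i, m in enumerate(rng.uniform(10, 1e4, 5))}
        base = log_shape_ratios(table_from(rows, ("x",)), masses)
        scaled_rows = [{"species": r["species"], "x": c * r["x"]} for r in rows]
        scaled_masses = {k: c ** 3 * v for k, v in masses.items()}
        scaled = log_shape_ratios(table_from(scaled_rows, ("x",)), scaled_masses)
        assert np.allclose(base.ratios.to_numpy(), scaled.ratios.to_numpy())


class TestFossilMass:
    def _extant(self, masses, gms, n_traits=4):
        # build measurement vectors whose geometric mean is exactly gm
        rows = [{"species": f"s{i}", **{f"t{j}": g for j in range(n_traits)}}
                for i, g in enumerate(gms)]
        traits = tuple(f"t{j}" for j in range(n_traits))
        return table_from(rows, traits), {f"s{i}": m for i, m in enumerate(masses)}

    def test_isometric_slope_three_exact(self):
        gms = np.array([2.0, 5.0, 10.0, 20.0])
        masses = 0.7 * gms ** 3
        table, mdict = self._extant(masses, gms)
        fossils = pd.DataFrame({f"t{j}": [8.0] for j in range(4)}, index=["F"])
        pred = estimate_fossil_mass(table, mdict, fossils)
        assert pred.attrs["regression"]["slope"] == pytest.approx(3.0, abs=1e-6)
        assert pred["F"] == pytest.approx(0.7 * 8.0 ** 3, rel=1e-9)

    def test_known_slope_intercept_recovered(self):
        rng = np.random.default_rng(1)
        gms = rng.uniform(1, 50, 10)
        masses = 10 ** (-1.0 + 2.5 * np.log10(gms))
        table, mdict = self._extant(masses, gms)
        fossils = pd.DataFrame({f"t{j}": [3.0] for j in range(4)}, index=["F"])
        pred = estimate_fossil_mass(table, mdict, fossils)
        reg = pred.attrs["regression"]
        assert reg["slope"] == pytest.approx(2.5, abs=1e-9)
        assert reg["intercept"] == pytest.approx(-1.0, abs=1e-9)

    def test_fossil_at_design_point_matches_fitted_value(self):
        gms = np.array([2.0, 4.0, 8.0, 16.0])
        masses = np.array([10.0, 90.0, 600.0, 5000.0])  # noisy allometry
        table, mdict = self._extant(masses, gms)
        fossils = pd.DataFrame({f"t{j}": [4.0] for j in range(4)}, index=["F"])
        pred = estimate_fossil_mass(table, mdict, fossils)
        reg = pred.attrs["regression"]
        fitted = 10 ** (reg["intercept"] + reg["slope"] * np.log10(4.0))
        assert pred["F"] == pytest.approx(fitted, rel=1e-12)

    def test_missing_fossil_measurement_rejected(self):
        table, mdict = self._extant([10, 20, 30], [2.0, 3.0, 4.0])
        fossils = pd.DataFrame({f"t{j}": [np.nan if j == 0 else 1.0]
                                for j in range(4)}, index=["F"])
        with pytest.raises(ValueError, match="missing"):
            estimate_fossil_mass(table, mdict, fossils)


class TestPCA:
    def test_perfect_collinearity(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]},
                         index=list("wxyz"))
        res = pca(X)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_matches_sklearn_oracle(self):
        from sklearn.decomposition import PCA as SkPCA
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(5, 4)),
                         index=[f"s{i}" for i in range(5)],
                         columns=[f"t{j}" for j in range(4)])
        res = pca(X)
        sk = SkPCA().fit(X.to_numpy())
        # variance fractions are divisor-independent
        assert np.allclose(res.variance_fractions[:len(sk.explained_variance_ratio_)],
                           sk.explained_variance_ratio_, atol=1e-9)
        # scores agree up to component sign
        sk_scores = sk.transform(X.to_numpy())
        for j in range(sk_scores.shape[1]):
            ours = res.scores.iloc[:, j].to_numpy()
            assert (np.allclose(ours, sk_scores[:, j], atol=1e-8)
                    or np.allclose(ours, -sk_scores[:, j], atol=1e-8))

    def test_scores_centered_and_variance_preserved(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(8, 3)))
        res = pca(X)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-12)
        cov = np.cov(X.to_numpy().T, ddof=0)
        assert res.scores.to_numpy().var(axis=0, ddof=0).sum() == \
            pytest.approx(np.trace(cov))
        # loadings orthonormal
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(3), atol=1e-10)

    def test_missing_entries_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            pca(X)
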