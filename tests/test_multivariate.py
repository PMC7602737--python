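"""PCA / PLS-DA machinery: normalization, NIPALS, Q2, CV-ANOVA, VIP, clusters."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from lactoflow import multivariate as mva


def _noise_df(rng, n, p):
    return pd.DataFrame(rng.normal(size=(n, p)),
                        columns=[f"g{j}" for j in range(p)])


class TestNormalizeByPeriod:
    def test_single_period_equals_global_standardization(self, rng):
        df = _noise_df(rng, 12, 4)
        norm = mva.normalize_by_period(df, ["L12"] * 12)
        expected = (df - df.mean()) / df.std(ddof=1)
        pd.testing.assert_frame_equal(norm.values, expected)

    def test_constant_period_offset_is_annihilated(self, rng):
        df = _noise_df(rng, 12, 4)
        periods = ["L12"] * 6 + ["L18"] * 6
        shifted = df.copy()
        shifted.iloc[6:] += 37.0
        a = mva.normalize_by_period(df, periods)
        b = mva.normalize_by_period(shifted, periods)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_within_period_moments(self, rng):
        df = _noise_df(rng, 18, 5)
        periods = np.repeat(["L12", "L18", "Inv1"], 6)
        norm = mva.normalize_by_period(df, periods)
        for per in ("L12", "L18", "Inv1"):
            sub = norm.values[np.asarray(periods) == per]
            assert np.abs(sub.mean()).max() < 1e-8
            assert np.abs(sub.std(ddof=1) - 1).max() < 1e-8

    def test_diet_contrast_preserved_period_means_removed(self, rng):
        # periods far apart, diet effect nested within each period
        n = 8
        periods = np.repeat(["L12", "L18"], n)
        diet = np.tile(np.repeat(["CTL", "FEN"], n // 2), 2)
        base = rng.normal(size=(2 * n, 3)) * 0.1
        base[periods == "L18"] += 50.0
        base[diet == "FEN"] += 1.0
        norm = mva.normalize_by_period(pd.DataFrame(base), periods)
        v = norm.values.to_numpy()
        per_means = [v[periods == p].mean(axis=0) for p in ("L12", "L18")]
        assert np.abs(np.diff(per_means, axis=0)).max() < 1e-10
        assert (v[diet == "FEN"].mean(axis=0) - v[diet == "CTL"].mean(axis=0)).min() > 0.5

    def test_zero_variance_gene_dropped(self, rng, caplog):
        df = _noise_df(rng, 8, 3)
        df["g1"] = [1.0] * 4 + list(rng.normal(size=4))
        with caplog.at_level("WARNING"):
            norm = mva.normalize_by_period(df, ["L12"] * 4 + ["L18"] * 4)
        assert "g1" not in norm.values.columns


class TestPca:
    def test_dominant_factor_captured(self, rng):
        t = rng.normal(size=50)
        X = np.outer(t, rng.normal(size=6)) + rng.normal(scale=1e-3, size=(50, 6))
        pca = mva.fit_pca(pd.DataFrame(X), 2)
        assert pca.explained_variance_ratio[0] > 0.99

    def test_full_reconstruction(self, rng):
        df = _noise_df(rng, 10, 4)
        pca = mva.fit_pca(df, 4)
        Z = (df - df.mean()) / df.std(ddof=1)
        recon = pca.scores @ pca.loadings.T
        np.testing.assert_allclose(recon, Z.to_numpy(), atol=1e-10)

    def test_trace_conservation_on_uv_scaled_data(self, rng):
        df = _noise_df(rng, 20, 6)
        pca = mva.fit_pca(df, 6)
        assert pca.explained_variance.sum() == pytest.approx(6.0, rel=1e-10)

    def test_deterministic_sign_convention(self, rng):
        df = _noise_df(rng, 15, 5)
        p1 = mva.fit_pca(df, 3)
        p2 = mva.fit_pca(df, 3)
        np.testing.assert_array_equal(p1.loadings, p2.loadings)
        for a in range(3):
            j = np.argmax(np.abs(p1.loadings[:, a]))
            assert p1.loadings[j, a] > 0

    def test_longitudinal_structure_dominates_first_two_components(
        self, noiseless_expression
    ):
        """With the study's printed effect structure, the first two
        components carry most of the variance, consistent with the strong
        reported longitudinal separation."""
        pca = mva.fit_pca(noiseless_expression.values, 2)
        assert pca.explained_variance_ratio[:2].sum() >= 0.71


class TestPlsda:
    def test_single_informative_gene_separates(self, rng):
        n = 20
        X = _noise_df(rng, n, 5) * 0.01
        labels = np.array(["A"] * 10 + ["B"] * 10)
        X.iloc[:10, 2] += 4.0
        m = mva.fit_plsda(X, labels, 1)
        w = np.abs(m.x_weights[:, 0])
        assert w[2] > 0.99
        assert m.r2y_cum > 0.95

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            mva.fit_plsda(_noise_df(rng, 6, 3), ["A"] * 6, 1)

    def test_scores_match_independent_pls_implementation(self, rng):
        """NIPALS scores must agree (up to sign) with an independent PLS
        fit of the centered class indicator."""
        X = _noise_df(rng, 10, 5)
        labels = np.array(["A"] * 5 + ["B"] * 5)
        m = mva.fit_plsda(X, labels, 2)
        y = (labels == "B").astype(float)
        sk = PLSRegression(n_components=2, scale=False).fit(
            X - X.mean(), y - y.mean()
        )
        for a in range(2):
            t1, t2 = m.x_scores[:, a], sk.x_scores_[:, a]
            sign = np.sign(t1 @ t2)
            np.testing.assert_allclose(t1, sign * t2, atol=1e-8)

    def test_scores_orthogonal_and_r2_monotone(self, rng):
        X = _noise_df(rng, 24, 8)
        labels = np.array(["A", "B"] * 12)
        m = mva.fit_plsda(X, labels, 4)
        gram = m.x_scores.T @ m.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert np.all(m.r2x >= -1e-12) and np.all(m.r2y >= -1e-12)
        assert 0 <= m.r2x_cum <= 1 and 0 <= m.r2y_cum <= 1


class TestQ2:
    def test_separable_data_has_high_q2(self, rng):
        X = _noise_df(rng, 56, 6)
        labels = np.array(["A"] * 28 + ["B"] * 28)
        X.iloc[:28, 0] += 12.0
        q2 = mva.q2_cv(X, labels, 2, seed=0)
        assert q2 > 0.9

    def test_q2_never_exceeds_r2y(self, rng):
        for i in range(5):
            r = np.random.default_rng(i)
            X = _noise_df(r, 21, 6)
            labels = np.array(["A"] * 10 + ["B"] * 11)
            X.iloc[:10, 0] += r.uniform(0, 3)
            m = mva.fit_plsda(X, labels, 2)
            q2 = mva.q2_cv(X, labels, 2, seed=i, model=m)
            assert q2 <= m.r2y_cum + 1e-12

    def test_null_labels_rarely_positive(self):
        hits = 0
        runs = 40
        for i in range(runs):
            r = np.random.default_rng(i)
            X = _noise_df(r, 24, 12)
            labels = r.permutation(np.array(["A", "B"] * 12))
            hits += mva.q2_cv(X, labels, 2, seed=i) <= 0
        assert hits >= int(0.85 * runs)


class TestCvAnova:
    def test_separated_classes_highly_significant(self, rng):
        X = _noise_df(rng, 28, 6)
        labels = np.array(["A"] * 14 + ["B"] * 14)
        X.iloc[:14, 0] += 5.0
        m = mva.fit_plsda(X, labels, 2)
        mva.q2_cv(X, labels, 2, seed=0, model=m)
        assert mva.cv_anova(m, class_labels=labels) < 1e-3

    def test_monotone_in_separation(self):
        ps = []
        for sep in (0.0, 1.0, 2.5, 5.0):
            r = np.random.default_rng(7)
            X = _noise_df(r, 28, 6)
            labels = np.array(["A"] * 14 + ["B"] * 14)
            X.iloc[:14, 0] += sep
            m = mva.fit_plsda(X, labels, 2)
            mva.q2_cv(X, labels, 2, seed=0, model=m)
            ps.append(mva.cv_anova(m, class_labels=labels))
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_permutation_method_agrees_on_strong_signal(self, rng):
        X = _noise_df(rng, 21, 5)
        labels = np.array(["A"] * 10 + ["B"] * 11)
        X.iloc[:10, 1] += 5.0
        m = mva.fit_plsda(X, labels, 1)
        p = mva.cv_anova(m, X, labels, method="permutation", n_permutations=99, seed=0)
        assert p <= 0.05

    def test_requires_cv_residuals(self, rng):
        X = _noise_df(rng, 12, 4)
        labels = np.array(["A", "B"] * 6)
        m = mva.fit_plsda(X, labels, 1)
        with pytest.raises(ValueError, match="q2_cv"):
            mva.cv_anova(m)


class TestVip:
    def test_single_informative_gene_closed_form(self, rng):
        p = 6
        X = _noise_df(rng, 30, p) * 1e-6
        X.iloc[:15, 3] += 2.0
        labels = np.array(["A"] * 15 + ["B"] * 15)
        m = mva.fit_plsda(X, labels, 1)
        vip = mva.vip_scores(m)
        assert vip[3] == pytest.approx(np.sqrt(p), rel=1e-3)
        assert np.all(vip[np.arange(p) != 3] < 0.05)

    def test_symmetric_genes_all_unit_vip(self, rng):
        n = 20
        t = np.repeat([1.0, -1.0], n // 2)
        X = pd.DataFrame(np.outer(t, np.ones(4)))
        labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        vip = mva.vip_scores(mva.fit_plsda(X, labels, 1))
        np.testing.assert_allclose(vip, 1.0, atol=1e-10)

    def test_mean_squared_vip_is_one(self):
        for i in range(5):
            r = np.random.default_rng(i)
            X = _noise_df(r, 18, 7)
            labels = np.array(["A"] * 9 + ["B"] * 9)
            vip = mva.vip_scores(mva.fit_plsda(X, labels, 2))
            assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)


class TestCorrelationClusters:
    def _template_data(self, rng, noise=0.0):
        # three orthogonal temporal templates over 12 samples
        t1 = np.array([1.0, 1, 1, 1, 0, 0, 0, 0, -1, -1, -1, -1])
        t2 = np.roll(t1, 4)
        t3 = np.roll(t1, 8)
        genes = {}
        for name, t in (("seedA", t1), ("seedB", t2), ("seedC", t3)):
            genes[name] = t
            for k in range(3):
                genes[f"{name}_kin{k}"] = t + rng.normal(0, noise, size=t.size)
        return pd.DataFrame(genes)

    def test_noise_free_recovery(self, rng):
        df = self._template_data(rng, noise=0.0)
        out = mva.correlation_clusters(df, ["seedA", "seedB", "seedC"], 0.7)
        for gene, cluster in out.items():
            assert cluster == gene[:5]

    def test_noisy_recovery_rate(self):
        correct = total = 0
        for i in range(100):
            r = np.random.default_rng(i)
            df = self._template_data(r, noise=0.05)
            out = mva.correlation_clusters(df, ["seedA", "seedB", "seedC"], 0.7)
            for gene, cluster in out.items():
                total += 1
                correct += cluster == gene[:5]
        assert correct / total >= 0.95

    def test_subthreshold_gene_unassigned(self, rng):
        df = self._template_data(rng)
        df["stray"] = rng.normal(size=12)
        out = mva.correlation_clusters(df, ["seedA", "seedB", "seedC"], 0.7)
        assert pd.isna(out["stray"])

    def test_missing_seed_rejected(self, rng):
        with pytest.raises(ValueError):
            mva.correlation_clusters(self._template_data(rng), ["nope"], 0.7)
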