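import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from nirstrial import preproc, synthgen
from nirstrial.features import AnalysisWindow, feature_matrix
from nirstrial.epochs_stats import epoch
from nirstrial.flda_search import (CombinationSpec, _loocv_batched,
                                   enumerate_subsets, exhaustive_search,
                                   flda_fit, loocv_accuracy)

from conftest import QUIET


class TestFldaFit:
    def test_hand_computed_1d(self):
        """{0,1} vs {10,11}: S_w = 1, m_a - m_b = -10, midpoint 5.5."""
        model = flda_fit([[0.0], [1.0]], [[10.0], [11.0]], ridge=0.0)
        assert model.weights[0] == pytest.approx(-10.0, abs=1e-9)
        assert model.threshold == pytest.approx(-10.0 * 5.5, abs=1e-9)
        # projected midpoint: threshold / w recovers 5.5 on the axis
        assert model.threshold / model.weights[0] == pytest.approx(5.5)
        preds = model.predict([[0.0], [1.0], [10.0], [11.0]])
        assert preds.tolist() == ["a", "a", "b", "b"]

    def test_identical_classes_chance(self, rng):
        X = rng.normal(size=(10, 2))
        model = flda_fit(X, X, ridge=1e-8)
        np.testing.assert_allclose(model.threshold,
                                   model.weights @ X.mean(axis=0), atol=1e-6)
        acc = np.mean(np.concatenate([model.predict(X) == "a",
                                      model.predict(X) == "b"]))
        assert acc == pytest.approx(0.5, abs=1e-9)

    def test_affine_equivariance(self, rng):
        """Invertible affine feature transforms leave classifications
        unchanged (ridge ~ 0)."""
        for _ in range(20):
            d = rng.integers(1, 5)
            Xa = rng.normal(size=(8, d))
            Xb = rng.normal(1.0, 1.0, size=(8, d))
            A = rng.normal(size=(d, d)) + 2 * np.eye(d)
            b = rng.normal(size=d)
            test = rng.normal(0.5, 1.5, size=(30, d))
            m1 = flda_fit(Xa, Xb, ridge=1e-10)
            m2 = flda_fit(Xa @ A + b, Xb @ A + b, ridge=1e-10)
            assert m1.predict(test).tolist() == m2.predict(test @ A + b).tolist()

    def test_singular_scatter_needs_ridge(self):
        Xa = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        Xb = np.array([[3.0, 6.0], [3.0, 6.0], [3.0, 6.0]])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            flda_fit(Xa, Xb, ridge=0.0)
        flda_fit(Xa, Xb, ridge=1e-8)   # regularized fit succeeds

    def test_min_samples(self):
        with pytest.raises(ValueError):
            flda_fit([[0.0]], [[1.0], [2.0]])

    def test_sklearn_oracle_equivalence(self, rng):
        """Label-identical to sklearn LDA (equal priors) on 100 random
        small instances."""
        for _ in range(100):
            d = int(rng.integers(1, 5))
            na, nb = int(rng.integers(4, 16)), int(rng.integers(4, 16))
            Xa = rng.normal(0, 1, size=(na, d))
            Xb = rng.normal(rng.normal(0, 2), 1.2, size=(nb, d))
            test = rng.normal(0, 2, size=(25, d))
            model = flda_fit(Xa, Xb, ridge=1e-8, labels=(0, 1))
            ref = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
            ref.fit(np.vstack([Xa, Xb]), np.r_[np.zeros(na), np.ones(nb)])
            assert model.predict(test).tolist() == ref.predict(test).astype(int).tolist()


class TestLoocv:
    def test_separable_perfect(self, rng):
        Xa = rng.normal(0, 0.1, size=(12, 2))
        Xb = rng.normal(10, 0.1, size=(12, 2))
        X = np.vstack([Xa, Xb])
        y = np.array(["s"] * 12 + ["c"] * 12, dtype=object)
        assert loocv_accuracy(X, y) == 1.0

    def test_quantization(self, rng):
        for _ in range(10):
            X = rng.normal(size=(24, 3))
            y = np.array(["s", "c"] * 12, dtype=object)
            acc = loocv_accuracy(X, y)
            assert (acc * 24) == pytest.approx(round(acc * 24), abs=1e-9)

    def test_22_of_24_percentage(self):
        """22/24 prints as 91.7% at one decimal."""
        assert f"{100 * 22 / 24:.1f}%" == "91.7%"

    def test_single_member_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array(["s", "c", "c", "c", "c"], dtype=object)
        with pytest.raises(ValueError):
            loocv_accuracy(X, y)

    def test_batched_matches_naive(self, rng):
        for _ in range(20):
            n, d = int(rng.integers(6, 16)) * 2, int(rng.integers(1, 5))
            X = rng.normal(size=(n, d)) + rng.normal(size=(n, 1))
            y = np.array(["s", "c"] * (n // 2), dtype=object)
            naive = loocv_accuracy(X, y, ridge=1e-8)
            batched = _loocv_batched(X[None], y == "c", 1e-8)[0]
            assert batched == pytest.approx(naive, abs=1e-12)

    def test_permutation_null_mean_half(self, rng):
        Xa = rng.normal(0, 1, size=(12, 2))
        Xb = rng.normal(3, 1, size=(12, 2))
        X = np.vstack([Xa, Xb])
        accs = []
        for _ in range(100):
            y = np.array(["s"] * 12 + ["c"] * 12, dtype=object)
            y = y[rng.permutation(24)]
            accs.append(loocv_accuracy(X, y))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.06)

    def test_monotone_separability(self, rng):
        """Mean LOOCV accuracy never decreases as the class gap grows."""
        gaps = [0.0, 0.5, 1.0, 2.0, 4.0]
        means = []
        for gap in gaps:
            accs = []
            for s in range(30):
                r = np.random.default_rng(1000 + s)
                Xa = r.normal(0, 1, size=(12, 1))
                Xb = r.normal(gap, 1, size=(12, 1))
                y = np.array(["s"] * 12 + ["c"] * 12, dtype=object)
                accs.append(loocv_accuracy(np.vstack([Xa, Xb]), y))
            means.append(np.mean(accs))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


class TestExhaustiveSearch:
    def test_combination_count(self):
        assert len(enumerate_subsets()) == 15
        # full default space: 3 channels x 93 windows x 15 subsets
        assert 3 * 93 * 15 == 4185

    def _search_random(self, rng, n_trials=12):
        F = rng.normal(size=(3, 4, n_trials, 4))
        y = np.array(["s", "c"] * (n_trials // 2), dtype=object)
        wins = [AnalysisWindow(1, 5), AnalysisWindow(1, 6),
                AnalysisWindow(2, 6), AnalysisWindow(9, 15)]
        return exhaustive_search(F, y, wins), F, y, wins

    def test_table_size_and_best(self, rng):
        res, F, y, wins = self._search_random(rng)
        assert len(res.per_combination) == 3 * 4 * 15
        assert res.accuracy == pytest.approx(res.per_combination.accuracy.max())
        assert res.best in res.tie_set
        # quantization of every accuracy
        accs = res.per_combination.accuracy.dropna().to_numpy()
        np.testing.assert_allclose(accs * 12, np.round(accs * 12), atol=1e-9)

    def test_best_matches_naive_loocv(self, rng):
        res, F, y, wins = self._search_random(rng)
        ci = res.best.channel - 1
        wi = wins.index(res.best.window)
        idx = [("mean", 0), ("variance", 1), ("skewness", 2), ("kurtosis", 3)]
        cols = [j for name, j in idx if name in res.best.features]
        assert loocv_accuracy(F[ci, wi][:, cols], y) == pytest.approx(res.accuracy)

    def test_determinism(self, rng):
        F = rng.normal(size=(3, 4, 12, 4))
        y = np.array(["s", "c"] * 6, dtype=object)
        wins = [AnalysisWindow(1, 5), AnalysisWindow(2, 6),
                AnalysisWindow(3, 7), AnalysisWindow(4, 8)]
        r1 = exhaustive_search(F, y, wins)
        r2 = exhaustive_search(F, y, wins)
        assert r1.best == r2.best
        assert r1.tie_set == r2.tie_set
        assert r1.per_combination.equals(r2.per_combination)

    def test_tie_breaking_prefers_simplest(self):
        """Perfectly separable single feature everywhere -> many ties; the
        winner must be a single-feature, shortest, earliest, lowest-channel
        combination."""
        n = 8
        y = np.array(["s", "c"] * (n // 2), dtype=object)
        sep = np.where(y == "s", 0.0, 10.0)[:, None] + np.arange(4) * 0.0
        F = np.broadcast_to(sep, (2, 3, n, 4)).copy()
        wins = [AnalysisWindow(1, 5), AnalysisWindow(1, 6), AnalysisWindow(2, 6)]
        res = exhaustive_search(F, y, wins)
        assert res.accuracy == 1.0
        assert len(res.best.features) == 1
        assert res.best.window == AnalysisWindow(1, 5)
        assert res.best.channel == 1
        assert res.tie_set == sorted(res.tie_set, key=CombinationSpec.sort_key)

    def test_nan_combinations_skipped(self, rng):
        F = rng.normal(size=(1, 2, 8, 4))
        F[0, 0, :, 2] = np.nan                 # skewness undefined in window 0
        y = np.array(["s", "c"] * 4, dtype=object)
        wins = [AnalysisWindow(1, 5), AnalysisWindow(2, 6)]
        res = exhaustive_search(F, y, wins)
        tab = res.per_combination
        bad = tab[(tab.start_s == 1) & tab.features.str.contains("skewness")]
        assert bad.accuracy.isna().all()
        good = tab[~((tab.start_s == 1) & tab.features.str.contains("skewness"))]
        assert good.accuracy.notna().all()

    def test_all_nan_rejected(self):
        F = np.full((1, 1, 8, 4), np.nan)
        y = np.array(["s", "c"] * 4, dtype=object)
        with pytest.raises(ValueError, match="rejected"):
            exhaustive_search(F, y, [AnalysisWindow(1, 5)])

    def test_informative_channel_selected(self, small_config):
        """Complex amplitude 2x simple on channel 1 only -> channel 1 wins
        in >= 90% of seeded runs (generator truth as oracle)."""
        base = small_config.replace(
            amp_o2hb={"MI-simple": (0.1, 0.1, 0.1), "MI-complex": (0.2, 0.1, 0.1)},
            amp_hhb={"MI-simple": (0.0, 0.0, 0.0), "MI-complex": (0.0, 0.0, 0.0)},
            white_noise_sd=0.02, osc_components=((0.1, 0.01),))
        wins = None
        hits = 0
        n_runs = 25
        rng = np.random.default_rng(11)
        for _ in range(n_runs):
            cfg = base.replace(seed=int(rng.integers(2**31)))
            raw, _ = synthgen.simulate(cfg)
            hemo = preproc.preprocess(raw)
            F, labels, channels, wins = feature_matrix(epoch(hemo), wins)
            res = exhaustive_search(F, labels, wins, channels)
            hits += res.best.channel == 1
        assert hits >= 0.9 * n_runs

    def test_null_subject_selection_bias(self, small_config):
        """No condition difference: the selected best is optimistically
        > 0.5 while the median combination sits near chance."""
        zeros = {c: (0.05, 0.05, 0.05) for c in small_config.conditions}
        base = small_config.replace(amp_o2hb=zeros,
                                    amp_hhb={c: (0.0,) * 3 for c in small_config.conditions})
        best, median = [], []
        rng = np.random.default_rng(13)
        wins = None
        for _ in range(10):
            cfg = base.replace(seed=int(rng.integers(2**31)))
            raw, _ = synthgen.simulate(cfg)
            hemo = preproc.preprocess(raw)
            F, labels, channels, wins = feature_matrix(epoch(hemo), wins)
            res = exhaustive_search(F, labels, wins, channels)
            best.append(res.accuracy)
            median.append(np.nanmedian(res.per_combination.accuracy))
        assert np.mean(best) > 0.5          # documented selection bias
        assert np.mean(median) == pytest.approx(0.5, abs=0.08)
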