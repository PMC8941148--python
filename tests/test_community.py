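"""Count filtering, VST, Bray-Curtis, DistLM and dbRDA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from aapflux.community import (
    DistLM,
    bray_curtis,
    dbrda,
    rare_filter,
    size_factors,
    vst,
)


def _counts(matrix, prefix="ASV"):
    m = np.asarray(matrix)
    return pd.DataFrame(
        m,
        index=[f"S{i}" for i in range(m.shape[0])],
        columns=[f"{prefix}{j}" for j in range(m.shape[1])],
    )


class TestRareFilter:
    def test_boundary_count_exactly_three_removed(self):
        counts = _counts(np.full((5, 1), 3))
        with pytest.raises(ValueError, match="every ASV"):
            rare_filter(counts)  # > 3 is strict

    def test_all_zero_asv_removed(self):
        counts = _counts(np.column_stack([np.zeros(5), np.full(5, 10)]))
        out = rare_filter(counts)
        assert list(out.columns) == ["ASV1"]

    def test_matches_exhaustive_rule_on_fixture(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(0, 8, size=(5, 5))
        counts = _counts(mat)
        out = rare_filter(counts, min_count=3, prevalence=0.20)
        need = math.ceil(0.20 * 5)
        expected = [
            f"ASV{j}" for j in range(5) if (mat[:, j] > 3).sum() >= need
        ]
        assert list(out.columns) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        counts = _counts(rng.integers(0, 30, size=(10, 20)))
        once = rare_filter(counts)
        assert rare_filter(once).equals(once)


class TestVst:
    def test_identical_samples_have_unit_size_factors(self):
        counts = _counts(np.tile([5, 10, 20, 40], (6, 1)))
        assert size_factors(counts) == pytest.approx(np.ones(6))

    def test_monotone_in_counts(self):
        counts = _counts(
            np.vstack([np.arange(1, 21), np.arange(1, 21)])
        )
        t = vst(counts)
        assert np.all(np.diff(t.to_numpy()[0]) > 0)

    def test_stabilizes_nb_variance_across_mean_gradient(self):
        """NB counts with means 10-fold apart: transformed group variances
        within 25% of each other, untransformed > 400% apart."""
        rng = np.random.default_rng(42)
        n, k = 300, 40
        alpha = 0.2
        means = np.array([30.0] * (k // 2) + [300.0] * (k // 2))
        # gamma-Poisson mixture = NB with dispersion alpha
        lam = rng.gamma(1 / alpha, alpha * means, size=(n, k))
        counts = _counts(rng.poisson(lam))
        raw_var = counts.var(axis=0).to_numpy()
        t = vst(counts)
        tv = t.var(axis=0).to_numpy()
        lo, hi = tv[: k // 2].mean(), tv[k // 2 :].mean()
        assert max(lo, hi) / min(lo, hi) - 1 < 0.25
        raw_lo, raw_hi = raw_var[: k // 2].mean(), raw_var[k // 2 :].mean()
        assert max(raw_lo, raw_hi) / min(raw_lo, raw_hi) - 1 > 4.0

    def test_underdispersed_fallback_warns(self):
        rng = np.random.default_rng(3)
        counts = _counts(rng.integers(50, 55, size=(20, 10)))
        with pytest.warns(UserWarning, match="dispersion"):
            t = vst(counts)
        assert np.isfinite(t.to_numpy()).all()


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = _counts([[1, 2, 3], [1, 2, 3]])
        assert bray_curtis(t)[("S0", "S1")] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        t = _counts([[5, 0, 0], [0, 3, 2]])
        assert bray_curtis(t)[("S0", "S1")] == pytest.approx(1.0)

    def test_hand_example(self):
        t = _counts([[1, 2, 3], [3, 2, 1]])
        assert bray_curtis(t)[("S0", "S1")] == pytest.approx(1 / 3, rel=1e-12)

    def test_two_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(_counts([[0, 0], [0, 0], [1, 2]]))

    def test_negative_values_clipped_with_warning(self):
        t = _counts([[1.0, -0.5, 3.0], [2.0, 1.0, 0.5]])
        with pytest.warns(UserWarning, match="clipped"):
            dm = bray_curtis(t)
        assert 0.0 <= dm[("S0", "S1")] <= 1.0


def _euclidean_dm(y):
    y = np.asarray(y, float)
    return np.abs(y[:, None] - y[None, :])


class TestDistLM:
    def test_euclidean_univariate_equals_classical_f(self):
        """With Euclidean distances on a scalar response, pseudo-F must
        equal the classical regression F statistic."""
        rng = np.random.default_rng(0)
        n = 15
        x = rng.normal(size=n)
        y = 2.0 + 0.8 * x + rng.normal(size=n)
        model = DistLM(_euclidean_dm(y), pd.DataFrame({"x": x}))
        res = model.fit(n_perms=49, seed=1)
        f_distlm = res.marginal.loc[0, "pseudo_F"]
        # classical F computed from scratch
        xc = x - x.mean()
        beta = (xc @ (y - y.mean())) / (xc @ xc)
        yhat = y.mean() + beta * xc
        ssr = ((yhat - y.mean()) ** 2).sum()
        sse = ((y - yhat) ** 2).sum()
        f_classical = ssr / (sse / (n - 2))
        assert f_distlm == pytest.approx(f_classical, rel=1e-9)
        assert res.marginal.loc[0, "pct_explained"] == pytest.approx(
            100 * ssr / (ssr + sse), rel=1e-9
        )

    def test_exhaustive_permutation_p_matches_enumeration(self):
        """n = 5: all 120 label permutations enumerated; the reported p
        must equal an independent brute-force enumeration exactly."""
        rng = np.random.default_rng(5)
        y = rng.normal(size=5)
        x = rng.normal(size=5)
        d = _euclidean_dm(y)
        res = DistLM(d, pd.DataFrame({"x": x})).fit(n_perms=10_000, seed=0)

        # independent oracle: explicit Gower centring and trace ratios
        n = 5
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ (d * d) @ j

        def brute_f(xv):
            xc = (xv - xv.mean()) / xv.std(ddof=1)
            xc = xc - xc.mean()
            h = np.outer(xc, xc) / (xc @ xc)
            num = np.trace(h @ g @ h)
            den = np.trace(g) - num
            return num / (den / (n - 2))

        f_obs = brute_f(x)
        count = sum(
            brute_f(x[np.array(p)]) >= f_obs - 1e-12
            for p in itertools.permutations(range(n))
        )
        assert res.marginal.loc[0, "p_value"] == pytest.approx(
            count / 120, abs=1e-12
        )

    def test_null_type_one_error(self):
        """Predictor independent of D: rejection rate at 0.05 within
        [2%, 9%] over 200 replicates."""
        rejections = 0
        for s in range(200):
            rng = np.random.default_rng(1000 + s)
            y = rng.normal(size=12)
            x = rng.normal(size=12)
            res = DistLM(_euclidean_dm(y), pd.DataFrame({"x": x})).fit(
                n_perms=199, seed=s
            )
            rejections += res.marginal.loc[0, "p_value"] <= 0.05
        assert 0.02 <= rejections / 200 <= 0.09

    def test_orthogonal_trace_decomposition(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(10, 4))
        d = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(-1))
        x = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        model = DistLM(d, x)
        from aapflux.community import _hat

        h = _hat(model.x)
        g = model.g
        res_tr = np.trace((np.eye(10) - h) @ g @ (np.eye(10) - h))
        assert np.trace(g) == pytest.approx(
            np.trace(h @ g @ h) + res_tr, rel=1e-9
        )

    def test_sample_order_invariance_of_statistics(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=10)
        x = rng.normal(size=10)
        d = _euclidean_dm(y)
        res1 = DistLM(d, pd.DataFrame({"x": x})).fit(n_perms=49, seed=3)
        perm = rng.permutation(10)
        res2 = DistLM(
            d[np.ix_(perm, perm)], pd.DataFrame({"x": x[perm]})
        ).fit(n_perms=49, seed=3)
        assert res1.marginal.loc[0, "pseudo_F"] == pytest.approx(
            res2.marginal.loc[0, "pseudo_F"], rel=1e-9
        )

    def test_constant_predictor_rejected(self):
        d = _euclidean_dm(np.arange(6.0))
        with pytest.raises(ValueError, match="constant"):
            DistLM(d, pd.DataFrame({"x": np.ones(6)}))

    def test_asymmetric_distance_rejected(self):
        d = _euclidean_dm(np.arange(6.0))
        d[0, 1] += 0.1
        with pytest.raises(ValueError, match="symmetric"):
            DistLM(d, pd.DataFrame({"x": np.arange(6.0)}))

    def test_forward_selection_reports_trace(self):
        rng = np.random.default_rng(11)
        n = 20
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = x1 + 0.1 * rng.normal(size=n)
        res = DistLM(
            _euclidean_dm(y), pd.DataFrame({"x1": x1, "x2": x2})
        ).fit(n_perms=99, seed=0)
        assert res.sequential.loc[0, "predictor"] == "x1"
        assert 0.0 <= res.total_pct_explained <= 100.0
        assert "DistLM" in res.summary()


class TestDbRDA:
    def test_eigenvalue_sum_equals_fitted_trace(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(12, 5))
        d = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(-1))
        x = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        out = dbrda(d, x)
        assert out.eigenvalues.sum() == pytest.approx(
            out.explained_trace, rel=1e-9
        )

    def test_euclidean_equivalence_to_rda(self):
        """With Euclidean distances, dbRDA axes are the principal axes of
        the fitted values of a least-squares fit of Y on X (classical
        redundancy analysis), up to sign."""
        rng = np.random.default_rng(8)
        n = 14
        x = rng.normal(size=(n, 2))
        beta = rng.normal(size=(2, 4))
        y = x @ beta + 0.1 * rng.normal(size=(n, 4))
        d = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(-1))
        out = dbrda(d, pd.DataFrame(x, columns=["a", "b"]))

        yc = y - y.mean(axis=0)
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        h = xs @ np.linalg.solve(xs.T @ xs, xs.T)
        fitted = h @ yc
        u, s, _ = np.linalg.svd(fitted, full_matrices=False)
        for k in range(2):
            ours = out.scores[:, k]
            ref = u[:, k] * s[k]
            assert min(
                np.abs(ours - ref).max(), np.abs(ours + ref).max()
            ) < 1e-8

    def test_biplot_correlations_bounded(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(10, 3))
        d = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(-1))
        out = dbrda(d, pd.DataFrame({"a": rng.normal(size=10)}))
        assert (out.biplot.abs() <= 1 + 1e-9).all().all()
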