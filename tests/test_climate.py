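import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from domus.climate import (DEFAULT_PCA_VARIABLES, StateMatrix,
                           _varimax_rotation, box_cox_normalize, colwell,
                           discretize_series, environmental_composites,
                           summarize_climate, varimax_pca)


def entropy_oracle(counts):
    """Independent -sum p log p evaluation of P, C, M for a state matrix."""
    counts = np.asarray(counts, dtype=float)
    N = counts.sum()
    s = counts.shape[1]

    def h(p):
        p = np.asarray(p, float).ravel()
        return -sum(pi * np.log(pi) for pi in p if pi > 0)

    hx = h(counts.sum(axis=1) / N)
    hy = h(counts.sum(axis=0) / N)
    hxy = h(counts / N)
    c = 1 - hy / np.log(s)
    m = (hx + hy - hxy) / np.log(s)
    return c + m, c, m


def seasonal_series(n_years=10, amp=10.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base = amp * np.sin(2 * np.pi * np.arange(12) / 12)
    return base[None, :] + noise * rng.normal(size=(n_years, 12))


class _Rec:
    def __init__(self, temp, precip, elev=100.0, slope=2.0):
        self.temp_monthly = temp
        self.precip_monthly = precip
        self.elevation_m = elev
        self.slope_deg = slope


class TestDiscretize:
    def test_constant_month_lands_in_one_state(self):
        x = np.zeros((10, 12))
        x[:, 0] = 5.0
        x[:, 1:] = np.linspace(6, 17, 11)[None, :]
        sm = discretize_series(x, n_states=4)
        jan = sm.counts[0]
        assert jan.max() == 10 and (jan > 0).sum() == 1

    def test_rows_sum_to_n_years(self):
        rng = np.random.default_rng(1)
        sm = discretize_series(rng.normal(size=(7, 12)), n_states=5)
        assert (sm.counts.sum(axis=1) == 7).all()

    def test_matches_brute_force_tally(self):
        x = seasonal_series(n_years=8, noise=2.0, seed=3)
        n_states = 4
        sm = discretize_series(x, n_states=n_states)
        lo, hi = x.min(), x.max()
        edges = np.linspace(lo, hi, n_states + 1)
        brute = np.zeros((12, n_states), dtype=int)
        for y in range(8):
            for m in range(12):
                k = n_states - 1
                for j in range(n_states):  # last bin closed on the right
                    if x[y, m] < edges[j + 1]:
                        k = j
                        break
                brute[m, k] += 1
        assert (sm.counts == brute).all()

    def test_constant_series_single_state(self):
        sm = discretize_series(np.full((5, 12), 3.0), n_states=6)
        assert (sm.counts[:, 0] == 5).all() and sm.counts[:, 1:].sum() == 0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            discretize_series(np.zeros((5, 12)), n_states=1)
        with pytest.raises(ValueError):
            discretize_series(np.zeros((1, 12)), n_states=4)


class TestColwell:
    def test_uniform_table_fully_unpredictable(self):
        p, c, m = colwell(StateMatrix(np.full((12, 4), 10), 10))
        assert p == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(0.0, abs=1e-12)
        assert m == pytest.approx(0.0, abs=1e-12)

    def test_strict_periodicity_fully_predictable(self):
        counts = np.zeros((12, 4), dtype=int)
        for mth in range(12):
            counts[mth, mth % 4] = 10
        p, c, m = colwell(StateMatrix(counts, 10))
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_small_matrix_against_frozen_oracle_values(self):
        # [[10, 0], [5, 5]]: expected values computed with entropy_oracle
        p, c, m = colwell(StateMatrix(np.array([[10, 0], [5, 5]]), 10))
        assert p == pytest.approx(0.5, abs=1e-12)
        assert c == pytest.approx(0.18872187554086717, abs=1e-12)
        assert m == pytest.approx(0.3112781244591329, abs=1e-12)

    def test_matches_entropy_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            t = rng.integers(2, 13)
            s = rng.integers(2, 6)
            counts = rng.integers(0, 8, size=(t, s))
            counts[0, 0] += 1  # ensure positive total
            got = colwell(StateMatrix(counts, int(counts.sum(1).max())))
            exp = entropy_oracle(counts)
            np.testing.assert_allclose(got, exp, atol=1e-10)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.lists(st.integers(0, 12), min_size=3, max_size=3),
                    min_size=4, max_size=8), st.integers(2, 9))
    def test_invariances(self, rows, mult):
        counts = np.asarray(rows)
        if counts.sum() == 0:
            counts[0, 0] = 1
        p, c, m = colwell(StateMatrix(counts, 1))
        assert p == pytest.approx(c + m, abs=1e-9)
        assert -1e-12 <= p <= 1 + 1e-12
        # permuting state labels leaves P unchanged
        perm = counts[:, ::-1]
        assert colwell(StateMatrix(perm, 1))[0] == pytest.approx(p, abs=1e-10)
        # multiplying all counts by a constant leaves P unchanged
        assert colwell(StateMatrix(counts * mult, 1))[0] == \
            pytest.approx(p, abs=1e-10)

    def test_single_state_space_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            colwell(StateMatrix(np.full((12, 1), 5), 5))


class TestSummarize:
    def test_constant_series_constancy_one(self):
        rec = _Rec(np.full((6, 12), 20.0), np.full((6, 12), 50.0))
        s = summarize_climate(rec)
        assert s.temp_mean == 20.0 and s.temp_var == 0.0
        assert s.temp_c == pytest.approx(1.0)
        assert s.temp_p == pytest.approx(1.0)

    @pytest.mark.parametrize("n_states", [2, 5, 10])
    @pytest.mark.parametrize("scheme", ["equal_width", "log_equal_width"])
    def test_exact_repeating_cycle_fully_predictable(self, n_states, scheme):
        base = 10 + 8 * np.sin(2 * np.pi * np.arange(12) / 12)
        x = np.tile(base, (7, 1))
        p, _, _ = colwell(discretize_series(x, n_states, scheme))
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_moments_match_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        temp = rng.normal(15, 6, (9, 12))
        precip = rng.gamma(2.0, 30.0, (9, 12))
        s = summarize_climate(_Rec(temp, precip))
        assert s.temp_mean == pytest.approx(temp.ravel().mean())
        assert s.temp_var == pytest.approx(
            ((temp.ravel() - temp.mean()) ** 2).sum() / (temp.size - 1))
        assert s.precip_mean == pytest.approx(precip.mean())

    def test_missing_series_flagged(self):
        s = summarize_climate(_Rec(None, None))
        assert s.missing

    def test_predictability_ordering_robust_to_bin_count(self):
        """Colwell P ranks societies consistently at 8 vs 12 states."""
        rng = np.random.default_rng(11)
        p8, p12 = [], []
        for i in range(100):
            noise = rng.uniform(0.2, 12.0)
            x = seasonal_series(n_years=10, noise=noise, seed=100 + i)
            p8.append(colwell(discretize_series(x, 8))[0])
            p12.append(colwell(discretize_series(x, 12))[0])
        rho = stats.spearmanr(p8, p12).statistic
        assert rho > 0.9


class TestBoxCox:
    def test_lambda_one_is_shift_only(self):
        x = np.linspace(1.0, 9.0, 40)
        y, lam, off = box_cox_normalize(x)
        # direct check of the transform at a fixed lambda
        from scipy.special import boxcox as bc
        np.testing.assert_allclose(bc(x, 1.0), x - 1.0)

    def test_lognormal_recovers_log_transform(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(1.0, 0.8, 5000))
        _, lam, _ = box_cox_normalize(x)
        assert abs(lam) < 0.15

    def test_shift_applied_for_nonpositive(self):
        x = np.concatenate([[0.0], np.linspace(0.5, 10, 30)])
        y, lam, off = box_cox_normalize(x)
        assert off == pytest.approx(1.0)
        with pytest.raises(ValueError):
            box_cox_normalize(x, shift="off")

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            box_cox_normalize(np.full(10, 3.0))


class TestVarimax:
    def test_rotation_is_orthonormal(self):
        rng = np.random.default_rng(3)
        L = rng.normal(size=(8, 3))
        R = _varimax_rotation(L)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-8)

    def test_communalities_preserved(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 6))
        X[:, 3] += X[:, 0]
        comp = varimax_pca(X, k=3)
        # unrotated top-3 loadings from an independent SVD
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        L = vt[:3].T * (s[:3] / np.sqrt(len(X) - 1))
        np.testing.assert_allclose(
            (comp.loadings.to_numpy() ** 2).sum(axis=0),
            (L ** 2).sum(axis=1), atol=1e-8)

    def test_scores_standardized(self):
        rng = np.random.default_rng(5)
        comp = varimax_pca(rng.normal(size=(150, 5)), k=3)
        sc = comp.scores.to_numpy()
        np.testing.assert_allclose(sc.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(sc.std(axis=0), 1.0, atol=1e-6)

    def test_block_structure_recovered(self):
        rng = np.random.default_rng(6)
        n = 600
        f = rng.normal(size=(n, 3))
        noise = 0.35
        X = np.column_stack([
            f[:, 0] + noise * rng.normal(size=n),   # temp block
            f[:, 0] + noise * rng.normal(size=n),
            f[:, 0] + noise * rng.normal(size=n),
            f[:, 2] + noise * rng.normal(size=n),   # precip block
            f[:, 2] + noise * rng.normal(size=n),
            f[:, 2] + noise * rng.normal(size=n),
            f[:, 1] + noise * rng.normal(size=n),   # terrain block
            f[:, 1] + noise * rng.normal(size=n),
        ])
        comp = varimax_pca(X, k=3, var_names=DEFAULT_PCA_VARIABLES)
        L = comp.loadings
        assert np.abs(L.loc["temperature_harshness",
                            ["temp_mean", "temp_var", "temp_p"]]).min() > 0.7
        assert np.abs(L.loc["xeric_harshness",
                            ["precip_mean", "precip_var", "precip_p"]]).min() > 0.7
        assert np.abs(L.loc["mountain_dwelling",
                            ["elevation_m", "slope_deg"]]).min() > 0.7

    def test_orientation_cold_sites_score_high(self):
        """Cold sites with variable, unpredictable temperature score high."""
        rng = np.random.default_rng(7)
        n = 500
        coldness = rng.normal(size=n)
        terr = rng.normal(size=n)
        dry = rng.normal(size=n)
        e = lambda: 0.4 * rng.normal(size=n)
        X = np.column_stack([
            10 - 2 * coldness + e(),        # temp_mean: colder -> lower
            1 + coldness + e(),             # temp_var: colder -> higher
            -coldness + e(),                # temp_p: colder -> less predictable
            5 - dry + e(), 1 + dry + e(), -dry + e(),
            terr + e(), terr + e(),
        ])
        comp = varimax_pca(X, k=3, var_names=DEFAULT_PCA_VARIABLES)
        th = comp.scores["temperature_harshness"].to_numpy()
        assert np.corrcoef(th, X[:, 0])[0, 1] < -0.5
        md = comp.scores["mountain_dwelling"].to_numpy()
        assert np.corrcoef(md, X[:, 6])[0, 1] > 0.5
        xh = comp.scores["xeric_harshness"].to_numpy()
        assert np.corrcoef(xh, X[:, 3])[0, 1] < -0.5

    def test_too_few_variables_rejected(self):
        with pytest.raises(ValueError):
            varimax_pca(np.random.default_rng(0).normal(size=(50, 2)), k=3)


def test_environmental_composites_records_lambdas():
    rng = np.random.default_rng(8)
    import pandas as pd
    n = 200
    df = pd.DataFrame({v: np.abs(rng.normal(5, 2, n)) + 0.1
                       for v in DEFAULT_PCA_VARIABLES})
    comp = environmental_composites(df)
    assert set(comp.boxcox_lambdas.index) == set(DEFAULT_PCA_VARIABLES)
    assert comp.scores.shape == (n, 3)
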