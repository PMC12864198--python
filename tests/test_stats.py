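import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from swilift import (
    jzs_bf_regression,
    jzs_bf_ttest,
    paired_t,
    power_paired_t,
    required_n_paired_t,
    rm_anova_ratings,
    shapiro_wilk_gate,
    simple_regression,
    wilcoxon_signed_rank,
    winsorize,
)
from swilift.stats import DegenerateInputError


# ---------------------------------------------------------------------------
# winsorisation


class TestWinsorize:
    def test_inliers_untouched(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.array_equal(winsorize(x), x)

    def test_single_extreme_clipped_to_boundary(self):
        x = np.r_[np.zeros(100), 1e6]
        w = winsorize(x)
        bound = x.mean() + 3.29 * x.std(ddof=1)
        assert w[-1] == pytest.approx(bound)
        assert np.array_equal(w[:100], np.zeros(100))

    def test_zero_variance_returned_unchanged(self):
        x = np.full(10, 7.0)
        assert np.array_equal(winsorize(x), x)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
            min_size=3,
            max_size=50,
        )
    )
    def test_idempotent_with_original_bounds(self, values):
        x = np.asarray(values)
        mu, sd = x.mean(), x.std(ddof=1)
        w = winsorize(x)
        if sd > 0:
            lo, hi = mu - 3.29 * sd, mu + 3.29 * sd
            assert np.array_equal(np.clip(w, lo, hi), w)
        assert len(w) == len(x)


# ---------------------------------------------------------------------------
# paired t


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t([1, 2, 3], [1, 3, 5], with_bf=False)
        assert res.t == pytest.approx(-math.sqrt(3), rel=1e-9)
        assert res.df == 2
        assert res.mean_diff == pytest.approx(-1.0)

    def test_identical_samples_are_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_dz_times_sqrt_n_equals_t(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x, y = rng.normal(0, 1, n), rng.normal(0.3, 1, n)
            res = paired_t(x, y, with_bf=False)
            assert res.d_z * math.sqrt(n) == pytest.approx(res.t, rel=1e-10)

    def test_ci_p_duality_at_alpha(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            x, y = rng.normal(0.2, 1, n), rng.normal(0, 1, n)
            res = paired_t(x, y, with_bf=False)
            excludes_zero = res.ci95[0] > 0 or res.ci95[1] < 0
            assert excludes_zero == (res.p < 0.05)
            assert res.ci95[0] <= res.mean_diff <= res.ci95[1]


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def wilcoxon_enumeration(d):
    """Exact null distribution of V by enumerating all sign assignments."""
    d = np.asarray(d, dtype=float)
    ranks = sps.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    vs = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    vs = np.asarray(vs, dtype=float)
    # two-sided: doubled smaller tail, capped at 1
    p = min(1.0, 2 * min((vs <= v_obs).mean(), (vs >= v_obs).mean()))
    return v_obs, p


class TestWilcoxon:
    def test_small_sample_hand_example(self):
        # d = [1,2,3] has V = 6 and exact two-sided p = 2/8
        v, p = wilcoxon_signed_rank([2.0, 3.0, 4.0, 5.0, 6.0], [1.0, 1.0, 1.0, 1.0, 1.0])
        assert v == 15.0
        assert p == pytest.approx(2 * (1 / 32), rel=1e-9)

    def test_all_negative_differences_give_zero_v(self):
        v, _ = wilcoxon_signed_rank([-1.0, -2.0, -3.0, -4.0, -5.0], np.zeros(5))
        assert v == 0.0

    def test_matches_enumeration_for_tie_free_small_n(self, rng):
        for n in (5, 6, 7, 8):
            for _ in range(10):
                d = rng.normal(0, 1, n)
                while len(np.unique(np.abs(d))) < n or np.any(d == 0):
                    d = rng.normal(0, 1, n)
                v, p = wilcoxon_signed_rank(d)
                v_exp, p_exp = wilcoxon_enumeration(d)
                assert v == v_exp
                assert p == pytest.approx(p_exp, rel=1e-9)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank(np.zeros(6))


# ---------------------------------------------------------------------------
# Shapiro-Wilk gate


class TestShapiroGate:
    def test_skewed_data_routed_to_nonparametric(self):
        rejections = 0
        for seed in range(200):
            x = np.random.default_rng(seed).lognormal(0, 1, 24)
            rejections += shapiro_wilk_gate(x)[0]
        assert rejections / 200 > 0.5

    def test_normal_data_rejection_rate_near_alpha(self):
        rejections = 0
        for seed in range(400):
            x = np.random.default_rng(seed).normal(0, 1, 24)
            rejections += shapiro_wilk_gate(x)[0]
        # binomial 99% band around 0.05 at 400 draws
        assert 0.02 <= rejections / 400 <= 0.09

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            shapiro_wilk_gate(np.full(10, 3.0))


# ---------------------------------------------------------------------------
# within-subjects ANOVA


def _cells_table(values):
    """values: dict (pid, size, weight, condition) -> z value."""
    rows = [
        {"participant_id": p, "size": s, "weight": w, "condition": c, "z_rating": v}
        for (p, s, w, c), v in values.items()
    ]
    return pd.DataFrame(rows)


def _random_cells(rng, n_sub=6, effects=None):
    effects = effects or {}
    values = {}
    for p in range(1, n_sub + 1):
        base = rng.normal(0, 1)
        for s in ("small", "large"):
            for w in ("light", "heavy"):
                for c in ("real", "virtual"):
                    v = base + rng.normal(0, 0.5)
                    v += effects.get("weight", 0.0) * (w == "heavy")
                    v += effects.get("size", 0.0) * (s == "large")
                    values[(p, s, w, c)] = v
    return _cells_table(values)


class TestRmAnova:
    def test_each_effect_equals_squared_contrast_t(self):
        # every 1-df within-subject effect is a paired t on its contrast scores
        rng2 = np.random.default_rng(99)
        cells = _random_cells(rng2, n_sub=8, effects={"weight": 1.0, "size": 0.4})
        tab = rm_anova_ratings(cells)
        piv = cells.set_index(["participant_id", "size", "weight", "condition"])[
            "z_rating"
        ]

        def contrast(signs):
            out = []
            for p in sorted(cells["participant_id"].unique()):
                tot = 0.0
                for (s, w, c), sign in signs.items():
                    tot += sign * piv[(p, s, w, c)]
                out.append(tot / len(signs))
            return np.asarray(out)

        combos = list(
            itertools.product(("small", "large"), ("light", "heavy"), ("real", "virtual"))
        )
        sign_maps = {
            "weight": {k: (1 if k[1] == "heavy" else -1) for k in combos},
            "size": {k: (1 if k[0] == "large" else -1) for k in combos},
            "condition": {k: (1 if k[2] == "virtual" else -1) for k in combos},
            "size:weight": {
                k: (1 if k[0] == "large" else -1) * (1 if k[1] == "heavy" else -1)
                for k in combos
            },
            "size:weight:condition": {
                k: (1 if k[0] == "large" else -1)
                * (1 if k[1] == "heavy" else -1)
                * (1 if k[2] == "virtual" else -1)
                for k in combos
            },
        }
        terms = {t: row for t, row in tab.set_index("term").iterrows()}
        for name, signs in sign_maps.items():
            scores = contrast(signs)
            t = scores.mean() / (scores.std(ddof=1) / math.sqrt(len(scores)))
            f_expected = t * t
            assert terms[name]["F"] == pytest.approx(f_expected, rel=1e-6), name
            assert terms[name]["df_num"] == 1
            assert terms[name]["df_den"] == len(scores) - 1

    def test_location_invariance(self, rng):
        cells = _random_cells(np.random.default_rng(5), n_sub=6)
        t0 = rm_anova_ratings(cells)
        shifted = cells.copy()
        shifted["z_rating"] += 42.0
        t1 = rm_anova_ratings(shifted)
        assert np.allclose(t0["F"], t1["F"], rtol=1e-8)

    def test_partial_eta_sq_identity_and_range(self, rng):
        tab = rm_anova_ratings(_random_cells(np.random.default_rng(6), n_sub=7))
        eta = (tab["F"] * tab["df_num"]) / (tab["F"] * tab["df_num"] + tab["df_den"])
        assert np.allclose(tab["partial_eta_sq"], eta)
        assert ((tab["partial_eta_sq"] >= 0) & (tab["partial_eta_sq"] <= 1)).all()

    def test_missing_cell_reported(self, rng):
        cells = _random_cells(np.random.default_rng(7), n_sub=4)
        broken = cells[
            ~(
                (cells["participant_id"] == 2)
                & (cells["size"] == "small")
                & (cells["weight"] == "light")
                & (cells["condition"] == "real")
            )
        ]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova_ratings(broken)

    def test_generative_power_and_size(self):
        # a pure weight effect must be detected; null terms reject at ~alpha
        n_rep = 120
        weight_sig = 0
        size_rej = 0
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            cells = _random_cells(rng, n_sub=10, effects={"weight": 1.2})
            tab = rm_anova_ratings(cells).set_index("term")
            weight_sig += tab.loc["weight", "p"] < 0.01
            size_rej += tab.loc["size", "p"] < 0.05
        assert weight_sig / n_rep > 0.95
        assert 0.01 <= size_rej / n_rep <= 0.11  # binomial band around 0.05


# ---------------------------------------------------------------------------
# Bayes factors


class TestJZSTtest:
    def test_null_favoured_at_t_zero_and_monotone_in_t(self):
        bfs = [jzs_bf_ttest(t, 20) for t in np.linspace(0, 6, 13)]
        assert bfs[0] < 1.0
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_monte_carlo_marginal_likelihood_oracle(self):
        rng = np.random.default_rng(77)
        draws = rng.standard_cauchy(200_000) * 0.707
        for t, n in [(0.0, 10), (1.0, 24), (2.05, 25)]:
            df = n - 1
            like = sps.nct.pdf(t, df, draws * math.sqrt(n))
            bf_mc = like.mean() / sps.t.pdf(t, df)
            se = like.std(ddof=1) / math.sqrt(len(like)) / sps.t.pdf(t, df)
            assert abs(jzs_bf_ttest(t, n) - bf_mc) < 3 * se

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf_ttest(math.nan, 10)
        with pytest.raises(ValueError):
            jzs_bf_ttest(1.0, 1)


class TestJZSRegression:
    def test_null_favoured_at_zero_r_sq(self):
        assert jzs_bf_regression(0.0, 25) < 1.0

    def test_monotone_in_r_sq(self):
        bfs = [jzs_bf_regression(r, 25) for r in np.linspace(0.0, 0.9, 10)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_bad_r_sq_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf_regression(1.0, 25)


# ---------------------------------------------------------------------------
# regression and power


class TestSimpleRegression:
    def test_perfect_fit(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = simple_regression(x, 2 * x)
        assert res.r_sq == pytest.approx(1.0)
        assert res.p < 1e-10

    def test_slope_matches_normal_equations(self):
        x = np.array([0.0, 1.0, 3.0, 4.0, 7.0])
        y = np.array([2.0, 3.0, 5.0, 4.0, 9.0])
        res = simple_regression(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert res.slope == pytest.approx(sxy / sxx, rel=1e-12)
        assert res.F == pytest.approx(
            (res.r_sq / 1) / ((1 - res.r_sq) / (len(x) - 2)), rel=1e-9
        )

    def test_null_slope_type_one_error(self):
        rej = 0
        n_rep = 500
        for seed in range(n_rep):
            rng = np.random.default_rng(40_000 + seed)
            x = rng.normal(0, 1, 20)
            y = rng.normal(0, 1, 20)
            rej += simple_regression(x, y).p < 0.05
        assert 0.03 <= rej / n_rep <= 0.075

    def test_constant_predictor_degenerate(self):
        with pytest.raises(DegenerateInputError):
            simple_regression(np.ones(6), np.arange(6.0))


class TestPower:
    def test_huge_effect_floor(self):
        assert required_n_paired_t(10.0) == 3

    def test_normal_approximation_brackets_exact_n(self):
        for dz in np.linspace(0.3, 1.2, 10):
            n_exact = required_n_paired_t(dz, 0.05, 0.90)
            z = sps.norm.ppf
            n_approx = ((z(0.975) + z(0.90)) / dz) ** 2
            # the t-distribution correction costs a handful of participants
            assert n_approx <= n_exact <= n_approx + 3.5

    def test_returned_n_is_minimal(self):
        n = required_n_paired_t(0.5, 0.05, 0.90)
        assert power_paired_t(n, 0.5) >= 0.90
        assert power_paired_t(n - 1, 0.5) < 0.90

    def test_nonpositive_effect_rejected(self):
        with pytest.raises(ValueError):
            required_n_paired_t(0.0)
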