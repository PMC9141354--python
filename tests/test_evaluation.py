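import itertools

import numpy as np
import pytest

from t2biexp.evaluation import (
    _signed_rank_lower_quantile,
    accuracy_table,
    component_accuracy,
    map_snr,
    mse_map,
    pseudomedian_ci,
    walsh_averages,
    wilcoxon_signed_rank,
)
from t2biexp.signal_model import (
    BiexpParams,
    FitResult,
    MultiEchoImage,
    OutcomeClass,
    biexp_signal,
)
from tests.conftest import ECHO_TIMES


def _enumerated_two_sided_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p-value by brute-force enumeration of
    all 2^n sign assignments (oracle for small n, tie-free data)."""
    d = diffs[diffs != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    stats = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ])
    p_le = np.mean(stats <= w_obs)
    p_ge = np.mean(stats >= w_obs)
    return min(2 * min(p_le, p_ge), 1.0)


def _enumerated_lower_quantile(n: int, alpha: float) -> int:
    stats = np.array([
        sum(r for r, s in zip(range(1, n + 1), signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ])
    k = -1
    for c in range(n * (n + 1) // 2 + 1):
        if np.mean(stats <= c) <= alpha:
            k = c
    return k


class TestWilcoxon:
    @pytest.mark.parametrize("seed,n", [(0, 5), (1, 8), (2, 10), (3, 12)])
    def test_exact_p_matches_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.4, 1.0, n)
        assert wilcoxon_signed_rank(d) == pytest.approx(
            _enumerated_two_sided_p(d), abs=1e-12
        )

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_critical_rank_matches_enumeration(self, n):
        for alpha in (0.025, 0.05):
            assert _signed_rank_lower_quantile(n, alpha) == \
                _enumerated_lower_quantile(n, alpha)

    def test_constant_positive_shift_is_significant(self):
        d = np.full(20, 3.0) + np.arange(20) * 1e-6  # break rank ties
        assert wilcoxon_signed_rank(d) < 1e-3

    def test_all_zero_differences(self):
        assert wilcoxon_signed_rank(np.zeros(10)) == 1.0

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.0, 1.0, 200)
        p = wilcoxon_signed_rank(d)
        assert 0.0 <= p <= 1.0


class TestPseudomedian:
    def test_walsh_averages_of_three(self):
        ws = walsh_averages(np.array([1.0, 2.0, 3.0]))
        assert list(ws) == [1.0, 1.5, 2.0, 2.0, 2.5, 3.0]
        pm, lo, hi = pseudomedian_ci(np.array([1.0, 2.0, 3.0]))
        assert pm == 2.0
        assert lo <= pm <= hi

    def test_constant_shift_pseudomedian(self):
        d = np.full(20, 2.5)
        pm, lo, hi = pseudomedian_ci(d)
        assert pm == 2.5

    def test_symmetric_sample_pseudomedian_equals_median(self):
        rng = np.random.default_rng(11)
        half = rng.normal(0, 1, 500)
        d = np.concatenate([half, -half])  # exactly symmetric about 0
        pm, _, _ = pseudomedian_ci(d)
        assert pm == pytest.approx(np.median(d), abs=1e-12)

    def test_ci_narrows_with_sample_size(self):
        rng = np.random.default_rng(13)
        d_small = rng.normal(1, 1, 20)
        d_big = rng.normal(1, 1, 500)
        _, lo_s, hi_s = pseudomedian_ci(d_small)
        _, lo_b, hi_b = pseudomedian_ci(d_big)
        assert (hi_b - lo_b) < (hi_s - lo_s)


def _fit(t_s, t_l, a_s=1200.0, a_l=1800.0,
         outcome=OutcomeClass.BIEXPONENTIAL):
    return FitResult(
        BiexpParams(a_s=a_s, a_l=a_l, t_s=t_s, t_l=t_l), 0.0, outcome, 1, True
    )


class TestAccuracyTable:
    def test_perfect_recovery(self):
        truth = [BiexpParams(1200, 1800, 10, 50)] * 6
        fits = [_fit(10, 50)] * 6
        table = accuracy_table(fits, truth)
        assert (table["mean_diff"] == 0).all()
        assert (table["sd"] == 0).all()

    def test_known_shift(self):
        rng = np.random.default_rng(3)
        truth = [BiexpParams(1200, 1800, 10, 50) for _ in range(30)]
        fits = [_fit(10 + 2 + rng.normal(0, 0.1), 50 - 1 + rng.normal(0, 0.1))
                for _ in range(30)]
        table = accuracy_table(fits, truth).set_index("component")
        assert table.loc["T_S", "mean_diff"] == pytest.approx(2.0, abs=0.1)
        assert table.loc["T_L", "mean_diff"] == pytest.approx(-1.0, abs=0.1)
        assert table.loc["T_S", "p"] < 1e-3

    def test_constant_class_voxels_excluded(self):
        truth = [BiexpParams(1200, 1800, 10, 50)] * 4
        fits = [_fit(10, 50), _fit(10, 50),
                _fit(4000, 4500, outcome=OutcomeClass.CONSTANT), _fit(10, 50)]
        table = accuracy_table(fits, truth)
        assert (table["n"] == 3).all()

    def test_clamp_saturated_component_excluded(self):
        truth = [BiexpParams(1200, 1800, 10, 50)] * 3
        fits = [_fit(10, 50), _fit(10, 5000,
                outcome=OutcomeClass.MONOEXPONENTIAL), _fit(10, 50)]
        table = accuracy_table(fits, truth).set_index("component")
        assert table.loc["T_S", "n"] == 3
        assert table.loc["T_L", "n"] == 2
        full = accuracy_table(fits, truth, include_degenerate=True)
        assert (full.set_index("component")["n"] == 3).all()

    def test_empty_voxel_set_rejected(self):
        with pytest.raises(ValueError):
            accuracy_table([], [])

    def test_report_invariants(self):
        rng = np.random.default_rng(5)
        rep = component_accuracy(rng.normal(1, 2, 50), "T_S")
        assert rep.ci_low <= rep.pseudomedian <= rep.ci_high
        assert 0 <= rep.p_value <= 1


class TestMseMap:
    def _maps(self, shape, t_s=5.0, t_l=40.0, a_s=1200.0, a_l=1800.0, n=0.0):
        return {
            "t_s": np.full(shape, t_s), "t_l": np.full(shape, t_l),
            "a_s": np.full(shape, a_s), "a_l": np.full(shape, a_l),
            "n": np.full(shape, n),
        }

    def test_perfect_fit_zero_everywhere(self):
        p = BiexpParams(1200, 1800, 5, 40)
        data = np.broadcast_to(biexp_signal(p, ECHO_TIMES), (4, 4, 8)).copy()
        img = MultiEchoImage(data=data, echo_times=ECHO_TIMES)
        grid, mean, sd = mse_map(img, self._maps((4, 4)))
        assert np.allclose(grid, 0.0, atol=1e-16)
        assert mean == 0 and sd == 0

    def test_constant_residual(self):
        p = BiexpParams(1200, 1800, 5, 40)
        data = np.broadcast_to(biexp_signal(p, ECHO_TIMES) + 10.0, (3, 3, 8)).copy()
        img = MultiEchoImage(data=data, echo_times=ECHO_TIMES)
        grid, mean, _ = mse_map(img, self._maps((3, 3)))
        assert np.allclose(grid, 800.0)
        assert mean == pytest.approx(800.0)

    def test_summary_sample_sd(self):
        p = BiexpParams(1200, 1800, 5, 40)
        clean = biexp_signal(p, ECHO_TIMES)
        data = np.stack([[clean + np.sqrt(100.0 / 8), clean + np.sqrt(300.0 / 8)]])
        img = MultiEchoImage(data=data, echo_times=ECHO_TIMES)
        _, mean, sd = mse_map(img, self._maps((1, 2)))
        assert mean == pytest.approx(200.0)
        assert sd == pytest.approx(np.sqrt(2) * 100, rel=1e-6)  # sample divisor

    def test_empty_mask_rejected(self):
        img = MultiEchoImage(data=np.zeros((2, 2, 8)), echo_times=ECHO_TIMES)
        with pytest.raises(ValueError):
            mse_map(img, self._maps((2, 2)), mask=np.zeros((2, 2), bool))


class TestMapSnr:
    def test_ratio(self):
        m = np.zeros((4, 4))
        sig = np.zeros((4, 4), bool); sig[:2] = True
        bg = ~sig
        m[sig] = 80.0; m[bg] = 4.0
        assert map_snr(m, sig, bg) == 20.0

    def test_zero_background_is_infinite(self):
        m = np.zeros((4, 4))
        sig = np.zeros((4, 4), bool); sig[:2] = True
        m[sig] = 80.0
        with pytest.warns(UserWarning):
            assert map_snr(m, sig, ~sig) == np.inf

    def test_overlapping_masks_rejected(self):
        m = np.ones((4, 4))
        sig = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            map_snr(m, sig, sig)
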