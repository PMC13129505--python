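"""Permutation entropy against a naive enumeration oracle, plus BEN features."""

from itertools import permutations
from math import factorial, log

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from benage.entropy import (
    EmptyFeatureError,
    EntropyError,
    PEParams,
    WindowParams,
    build_feature_matrix,
    dynamic_ben,
    permutation_entropy,
    static_ben,
    windowed_entropy,
)
from tests.conftest import make_hemo


def oracle_counts(x, d=3, tau=1):
    """Naive oracle: count each of the d! patterns by explicit check.

    A window matches permutation pi iff applying pi's index order yields a
    nondecreasing sequence, with ties resolved in favor of temporal order
    (the earlier index ranks lower) — checked pairwise, independently of
    any argsort implementation.
    """
    x = list(map(float, x))
    n_vec = len(x) - (d - 1) * tau
    counts = {}
    for t in range(n_vec):
        window = [x[t + k * tau] for k in range(d)]
        for pi in permutations(range(d)):
            ok = True
            for a, b in zip(pi, pi[1:]):
                if window[a] > window[b] or (window[a] == window[b] and a > b):
                    ok = False
                    break
            if ok:
                counts[pi] = counts.get(pi, 0) + 1
                break
    return counts


def oracle_pe(x, d=3, tau=1, normalize=True):
    """Entropy of the enumerated pattern distribution."""
    counts = oracle_counts(x, d, tau)
    n_vec = sum(counts.values())
    h = -sum(c / n_vec * log(c / n_vec) for c in counts.values())
    return h / log(factorial(d)) if normalize else h


class TestPermutationEntropy:
    def test_matches_oracle_on_random_series(self, rng):
        """Exact agreement with enumeration on 200 short random series,
        including integer-valued (tie-rich) ones and d/tau variations."""
        for i in range(200):
            n = int(rng.integers(10, 51))
            if i % 3 == 0:
                x = rng.integers(0, 4, size=n).astype(float)  # many ties
            else:
                x = rng.standard_normal(n)
            d = int(rng.integers(2, 5))
            tau = int(rng.integers(1, 3))
            if n < (d - 1) * tau + 2:
                continue
            params = PEParams(embed_d=d, lag_tau=tau)
            assert permutation_entropy(x, params) == pytest.approx(
                oracle_pe(x, d, tau), abs=1e-12
            )

    def test_hand_worked_example(self):
        # five embedded vectors -> pattern counts {2, 2, 1}
        x = [4, 7, 9, 10, 6, 11, 3]
        h = permutation_entropy(x, PEParams(normalize=False))
        expected = -(2 * 0.4 * log(0.4) + 0.2 * log(0.2))
        assert h == pytest.approx(expected, abs=1e-12)
        assert permutation_entropy(x) == pytest.approx(expected / log(6), abs=1e-12)

    def test_monotone_series_is_zero(self):
        assert permutation_entropy([1, 2, 3, 4, 5, 6]) == 0.0

    def test_constant_series_is_zero_under_stable_ties(self):
        assert permutation_entropy(np.zeros(50)) == 0.0

    def test_white_noise_near_maximal(self):
        for seed in range(5):
            x = np.random.default_rng(seed).uniform(size=2000)
            assert permutation_entropy(x) >= 0.995

    def test_vectorized_matches_per_row(self, rng):
        x = rng.standard_normal((7, 120))
        batch = permutation_entropy(x)
        singles = [permutation_entropy(row) for row in x]
        np.testing.assert_allclose(batch, singles, atol=1e-14)

    def test_too_short_series_rejected(self):
        with pytest.raises(EntropyError):
            permutation_entropy([1.0, 2.0], PEParams(embed_d=3))

    def test_nonfinite_rejected(self):
        with pytest.raises(EntropyError):
            permutation_entropy([1.0, np.nan, 2.0, 3.0, 0.0])

    def test_jitter_tie_rule_close_to_stable_on_tie_free_data(self, rng):
        x = rng.standard_normal(500)
        a = permutation_entropy(x, PEParams(tie_rule="stable-order"))
        b = permutation_entropy(x, PEParams(tie_rule="noise-jitter"))
        assert a == pytest.approx(b, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        x=hnp.arrays(
            float,
            st.integers(8, 60),
            # two-decimal grid keeps tie structure exact under a*x + b
            elements=st.floats(-100, 100, allow_nan=False).map(
                lambda v: round(v, 2)
            ),
        ),
        a=st.floats(0.01, 50),
        b=st.floats(-10, 10),
    )
    def test_affine_invariance_and_bounds(self, x, a, b):
        """PE(a*x + b) == PE(x) for a > 0, and 0 <= normalized PE <= 1."""
        h = permutation_entropy(x)
        assert 0.0 <= h <= 1.0
        assert permutation_entropy(a * x + b) == pytest.approx(h, abs=1e-9)


class TestStaticBEN:
    def test_26_channels_yield_78_values(self, rng):
        rec = make_hemo(rng.standard_normal((26, 300)))
        df = static_ben(rec)
        assert df.shape == (26, 3)
        assert df.notna().to_numpy().sum() == 78

    def test_identical_channels_identical_entropy(self, rng):
        row = rng.standard_normal(300)
        rec = make_hemo(np.tile(row, (4, 1)))
        df = static_ben(rec)
        assert df["HbO"].nunique() == 1

    def test_affine_rescaled_channel_unchanged(self, rng):
        hbo = rng.standard_normal((2, 300))
        rec1 = make_hemo(hbo)
        hbo2 = hbo.copy()
        hbo2[1] = 1000 * hbo2[1] + 5
        rec2 = make_hemo(hbo2)
        a, b = static_ben(rec1), static_ben(rec2)
        assert a.loc["CH2", "HbO"] == pytest.approx(b.loc["CH2", "HbO"], abs=1e-12)

    def test_excluded_channels_are_nan(self, rng):
        rec = make_hemo(rng.standard_normal((3, 300)), qc=[True, False, True])
        df = static_ben(rec)
        assert df.loc["CH2"].isna().all() and df.loc["CH1"].notna().all()

    def test_no_retained_channels_raises(self, rng):
        rec = make_hemo(rng.standard_normal((2, 300)), qc=[False, False])
        with pytest.raises(EmptyFeatureError):
            static_ben(rec)


class TestDynamicBEN:
    def test_single_full_window_equals_static(self, rng):
        n = 300
        rec = make_hemo(rng.standard_normal((3, n)))
        stat = static_ben(rec)
        dyn = dynamic_ben(rec, win=WindowParams(window_len=n, step=n))
        np.testing.assert_allclose(dyn.to_numpy(), stat.to_numpy(), atol=1e-14)

    def test_stationary_series_dynamic_close_to_static(self, rng):
        rec = make_hemo(rng.standard_normal((3, 2000)))
        stat = static_ben(rec)
        dyn = dynamic_ben(rec)
        assert np.abs(dyn.to_numpy() - stat.to_numpy()).max() <= 0.05

    def test_nonstationary_series_summaries(self, rng):
        n = 400
        first = np.arange(n // 2, dtype=float)  # monotone: PE 0
        second = rng.permutation(np.arange(n // 2).astype(float))
        x = np.concatenate([first, second])
        win = WindowParams(window_len=n // 2, step=n // 2)
        rec = make_hemo(x[None, :])
        sd = dynamic_ben(rec, win=WindowParams(n // 2, n // 2, "sd"))
        mean = dynamic_ben(rec, win=win)
        pe_first = permutation_entropy(first)
        pe_second = permutation_entropy(second)
        assert sd.loc["CH1", "HbO"] > 0
        lo, hi = sorted([pe_first, pe_second])
        assert lo < mean.loc["CH1", "HbO"] < hi

    def test_window_longer_than_series_rejected(self, rng):
        rec = make_hemo(rng.standard_normal((1, 100)))
        with pytest.raises(EntropyError):
            dynamic_ben(rec, win=WindowParams(window_len=200, step=100))

    def test_window_count(self, rng):
        x = rng.standard_normal(2000)
        w = windowed_entropy(x, PEParams(), WindowParams(200, 100))
        assert w.shape == (19,)  # starts 0, 100, ..., 1800


class TestFeatureMatrix:
    def test_full_dimensions_and_sets(self, rng):
        recs = [
            make_hemo(rng.standard_normal((26, 300)), subject_id=f"s{i}")
            for i in range(4)
        ]
        fm = build_feature_matrix(recs, win=WindowParams(150, 75))
        assert fm.values.shape == (4, 156)
        assert len(fm.set_columns("Static_all")) == 78
        assert len(fm.set_columns("ALL")) == 156
        assert set(fm.set_columns("ALL")) == set(
            fm.set_columns("Static_all") + fm.set_columns("Dynamic_all")
        )
        assert all(
            0 <= v <= 1 for v in fm.values.to_numpy().ravel()
        )

    def test_complete_case_channel_drop(self, rng):
        recs = [
            make_hemo(rng.standard_normal((6, 300)), subject_id=f"s{i}")
            for i in range(3)
        ]
        recs[1].qc_mask[4] = False  # CH5 lost for one subject
        fm = build_feature_matrix(recs, win=WindowParams(150, 75))
        assert fm.dropped_channels == ["CH5"]
        assert not any("CH5_" in c for c in fm.feature_names)
        assert fm.values.shape == (3, 5 * 3 * 2)

    def test_no_common_channel_raises(self, rng):
        recs = [
            make_hemo(rng.standard_normal((2, 300)), subject_id=f"s{i}")
            for i in range(2)
        ]
        recs[0].qc_mask[:] = [True, False]
        recs[1].qc_mask[:] = [False, True]
        with pytest.raises(EmptyFeatureError):
            build_feature_matrix(recs, win=WindowParams(150, 75))
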