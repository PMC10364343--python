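"""Krippendorff's alpha (vs a brute-force oracle), bins, and R²."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cevast.agreement_stats import (
    UndefinedStatisticError,
    agreement_report,
    interpret_alpha,
    krippendorff_alpha,
    r_squared,
)


def alpha_bruteforce(R):
    """Independent oracle: enumerate all pairable value pairs explicitly."""
    R = np.asarray(R, dtype=float)
    units = []
    for j in range(R.shape[1]):
        vals = R[~np.isnan(R[:, j]), j]
        if vals.size >= 2:
            units.append(vals)
    if not units:
        raise ValueError("nothing pairable")
    n = sum(v.size for v in units)
    do = 0.0
    for vals in units:
        m = vals.size
        for i in range(m):
            for j in range(m):
                if i != j:
                    do += (vals[i] - vals[j]) ** 2 / (m - 1)
    do /= n
    pooled = np.concatenate(units)
    de = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                de += (pooled[i] - pooled[j]) ** 2
    de /= n * (n - 1)
    if de == 0:
        return 1.0
    return 1.0 - do / de


def _random_matrix(rng, continuous=False):
    n_r = rng.integers(2, 6)
    n_i = rng.integers(2, 11)
    if continuous:
        R = rng.uniform(0, 3, (n_r, n_i))
    else:
        R = rng.integers(0, 4, (n_r, n_i)).astype(float)
    mask = rng.uniform(size=R.shape) < 0.2
    R[mask] = np.nan
    counts = np.sum(~np.isnan(R), axis=0)
    vals = R[~np.isnan(R)]
    if not np.any(counts >= 2) or np.unique(vals).size < 2:
        return None
    return R


class TestKrippendorffAlpha:
    def test_identical_raters_perfect_agreement(self, rng):
        row = rng.integers(0, 4, 15).astype(float)
        assert krippendorff_alpha(np.vstack([row, row, row])) == pytest.approx(1.0)

    def test_all_values_equal_convention(self):
        assert krippendorff_alpha(np.full((3, 8), 2.0)) == 1.0

    def test_matches_bruteforce_with_missing_cells(self, rng):
        R = np.array(
            [
                [0, 1, 2, 3, 1, np.nan, 2, 0],
                [0, 1, 3, 3, np.nan, 2, 2, 1],
                [1, 1, 2, 3, 1, 2, 3, 0],
            ],
            dtype=float,
        )
        assert krippendorff_alpha(R) == pytest.approx(alpha_bruteforce(R), abs=1e-10)

    def test_oracle_equivalence_many_random_matrices(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 200:
            R = _random_matrix(rng, continuous=bool(checked % 2))
            if R is None:
                continue
            assert krippendorff_alpha(R) == pytest.approx(alpha_bruteforce(R), abs=1e-10)
            checked += 1

    def test_no_pairable_items_raises(self):
        R = np.array([[1.0, np.nan], [np.nan, 2.0]])
        with pytest.raises(UndefinedStatisticError):
            krippendorff_alpha(R)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        shift=st.floats(-5, 5),
        scale=st.floats(0.1, 4.0),
        seed=st.integers(0, 10_000),
    )
    def test_interval_shift_and_scale_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        R = _random_matrix(rng)
        if R is None:
            return
        base = krippendorff_alpha(R)
        assert krippendorff_alpha(R + shift) == pytest.approx(base, abs=1e-9)
        assert krippendorff_alpha(R * scale) == pytest.approx(base, abs=1e-9)

    def test_item_reordering_invariance(self, rng):
        R = _random_matrix(rng)
        perm = rng.permutation(R.shape[1])
        assert krippendorff_alpha(R[:, perm]) == pytest.approx(krippendorff_alpha(R), abs=1e-12)

    def test_noise_on_one_rater_lowers_alpha(self):
        drops = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            row = rng.uniform(0, 3, 40)
            clean = np.vstack([row, row + rng.normal(0, 0.1, 40)])
            noisy = clean.copy()
            noisy[1] += rng.normal(0, 0.8, 40)
            if krippendorff_alpha(noisy) < krippendorff_alpha(clean):
                drops += 1
        assert drops >= 18


class TestInterpretAlpha:
    @pytest.mark.parametrize(
        "alpha,label",
        [
            (0.924, "almost perfect agreement"),
            (0.85, "almost perfect agreement"),
            (0.7, "substantial agreement"),
            (0.5, "moderate agreement"),
            (0.3, "fair agreement"),
            (0.15, "slight agreement"),
            (0.05, "no agreement"),
            (-0.4, "no agreement"),
        ],
    )
    def test_bins(self, alpha, label):
        assert interpret_alpha(alpha) == label

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            interpret_alpha(1.2)


class TestRSquared:
    def test_perfect_linearity(self):
        x = np.arange(10, dtype=float)
        assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(5)
        assert r_squared(rng.normal(size=10_000), rng.normal(size=10_000)) < 0.01

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            r_squared(np.ones(10), np.arange(10, dtype=float))

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2, 3, np.nan, 5])
        y = 2 * x
        assert r_squared(x, y) == pytest.approx(1.0)


class TestAgreementReport:
    def _tables(self, rng, jitter=0.0):
        items = [f"pt{i}:{k}" for i in range(6) for k in range(10)]
        vals = rng.uniform(0, 3, len(items))
        reader_points = pd.DataFrame(
            [
                {"rater": f"r{r}", "item": it, "value": v + jitter * rng.normal()}
                for r in range(3)
                for it, v in zip(items, vals)
            ]
        )
        mla_points = pd.DataFrame({"item": items, "value": vals})
        metrics = pd.DataFrame(
            [
                {"patient_id": f"pt{i}", "metric": m, "value": rng.uniform(0, 3)}
                for i in range(6)
                for m in ["first_tertile_mean", "first_tertile_max", "si_mean"]
            ]
        )
        return reader_points, mla_points, metrics

    def test_identical_tables_give_perfect_agreement(self, rng):
        rp, mp, metrics = self._tables(rng)
        rep = agreement_report(rp, mp, metrics, metrics.copy())
        alphas = rep[rep.statistic == "alpha"]["value"]
        r2s = rep[rep.statistic == "r_squared"]["value"]
        assert np.allclose(alphas, 1.0)
        assert np.allclose(r2s, 1.0)

    def test_expected_comparisons_present(self, rng):
        rp, mp, metrics = self._tables(rng, jitter=0.05)
        rep = agreement_report(rp, mp, metrics, metrics.copy())
        names = set(rep[rep.statistic == "alpha"]["comparison"])
        assert names == {
            "inter_reader_curves",
            "mean_reader_vs_mla_curves",
            "first_tertile_mean",
            "first_tertile_max",
            "si_mean",
        }

    def test_missing_tolerant_when_one_reader_dropped(self, rng):
        rp, mp, metrics = self._tables(rng, jitter=0.05)
        rep = agreement_report(rp[rp.rater != "r2"], mp, metrics, metrics.copy())
        assert len(rep) > 0

    def test_disjoint_items_raise(self, rng):
        rp, mp, metrics = self._tables(rng)
        mp = mp.assign(item="other:" + mp["item"])
        with pytest.raises(ValueError):
            agreement_report(rp, mp, metrics, metrics.copy())
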