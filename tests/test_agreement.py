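"""Agreement statistics against independent oracles and exact band tables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from cmspose.agreement import (
    RatingMatrix,
    RatingPair,
    agreement_report,
    cohen_kappa,
    confusion_matrix,
    difference_summary,
    icc_oneway,
    interpret_icc,
    interpret_kappa,
)


def kappa_oracle(a, b):
    """Direct-formula kappa: observed vs marginal-product chance agreement."""
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    cats = sorted(set(a) | set(b))
    pe = sum(
        (sum(x == c for x in a) / n) * (sum(y == c for y in b) / n) for c in cats
    )
    return (po - pe) / (1 - pe)


def icc_oracle(x):
    """One-way ANOVA sums of squares computed element by element."""
    n, k = x.shape
    grand = x.sum() / x.size
    ssb = ssw = 0.0
    for i in range(n):
        m = sum(x[i]) / k
        ssb += k * (m - grand) ** 2
        for j in range(k):
            ssw += (x[i, j] - m) ** 2
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestCohenKappa:
    def test_identical_nonconstant_ratings_give_one(self):
        k, p = cohen_kappa(RatingPair(np.array([1, 2, 3, 1]), np.array([1, 2, 3, 1])))
        assert k == pytest.approx(1.0)
        assert p < 0.05

    def test_known_2x2_table(self):
        # agreement table [[20, 5], [10, 15]]: po=0.7, pe=0.5 -> kappa=0.4
        a = [0] * 25 + [1] * 25
        b = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        k, _ = cohen_kappa(RatingPair(np.array(a), np.array(b)))
        assert k == pytest.approx(0.4, abs=1e-12)

    def test_chance_level_agreement_is_zero(self):
        # po = pe by construction: independent uniform marginals
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        k, _ = cohen_kappa(RatingPair(a, b))
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_both_raters_constant_returns_sentinel(self):
        with pytest.warns(UserWarning):
            k, p = cohen_kappa(RatingPair(np.array([2, 2, 2]), np.array([2, 2, 2])))
        assert np.isnan(k) and np.isnan(p)

    def test_matches_oracles_on_random_tables(self, rng):
        # 20 random 5-category rating pairs; two independent oracles
        for _ in range(20):
            a = rng.integers(0, 5, size=40)
            b = np.where(rng.random(40) < 0.6, a, rng.integers(0, 5, size=40))
            k, _ = cohen_kappa(RatingPair(a, b))
            assert k == pytest.approx(kappa_oracle(a.tolist(), b.tolist()), abs=1e-10)
            assert k == pytest.approx(cohen_kappa_score(a, b), abs=1e-10)

    @given(st.permutations(list(range(5))))
    def test_invariant_under_category_relabeling(self, perm):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 5, size=30)
        b = rng.integers(0, 5, size=30)
        k0, _ = cohen_kappa(RatingPair(a, b))
        perm = np.array(perm)
        k1, _ = cohen_kappa(RatingPair(perm[a], perm[b]))
        assert k1 == pytest.approx(k0, abs=1e-12)


class TestIcc:
    def test_rater_identical_matrix_gives_one(self):
        x = np.array([[1.0, 1.0], [4.0, 4.0], [2.0, 2.0], [9.0, 9.0]])
        icc, p = icc_oneway(RatingMatrix(x))
        assert icc == pytest.approx(1.0)
        assert p == 0.0

    def test_subjects_identical_raters_differ_nonpositive(self):
        x = np.array([[1.0, 5.0], [1.0, 5.0], [1.0, 5.0]])
        icc, _ = icc_oneway(RatingMatrix(x))
        assert icc <= 0.0

    def test_small_matrix_matches_hand_anova(self):
        x = np.array([[7.0, 9.0], [4.0, 6.0], [2.0, 1.0], [8.0, 7.0]])
        icc, _ = icc_oneway(RatingMatrix(x))
        assert icc == pytest.approx(icc_oracle(x), abs=1e-12)

    def test_matches_oracle_on_random_5rater_tables(self, rng):
        for _ in range(20):
            subj = rng.normal(size=(8, 1))
            x = subj + 0.5 * rng.normal(size=(8, 5))
            icc, _ = icc_oneway(RatingMatrix(x))
            assert icc == pytest.approx(icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_icc1(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        icc, p = icc_oneway(RatingMatrix(x))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 3),
                "rater": np.tile(np.arange(3), 10),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"].isin(["ICC1", "ICC(1,1)"])].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-10)
        assert p == pytest.approx(row["pval"], abs=1e-10)

    def test_invariant_under_shift_and_positive_scale(self, rng):
        x = rng.normal(size=(6, 4)) + rng.normal(size=(6, 1))
        base, _ = icc_oneway(RatingMatrix(x))
        shifted, _ = icc_oneway(RatingMatrix(x + 13.0))
        scaled, _ = icc_oneway(RatingMatrix(2.7 * x))
        assert shifted == pytest.approx(base, abs=1e-10)
        assert scaled == pytest.approx(base, abs=1e-10)

    def test_zero_variance_sentinel(self):
        with pytest.warns(UserWarning):
            icc, p = icc_oneway(RatingMatrix(np.full((3, 2), 4.0)))
        assert np.isnan(icc)


class TestInterpretationBands:
    @pytest.mark.parametrize(
        "kappa, band",
        [
            (-0.1, "poor"), (0.0, "poor"), (0.05, "slight"), (0.20, "slight"),
            (0.21, "fair"), (0.40, "fair"), (0.41, "moderate"), (0.60, "moderate"),
            (0.61, "substantial"), (0.707, "substantial"), (0.80, "substantial"),
            (0.81, "almost perfect"), (1.0, "almost perfect"),
        ],
    )
    def test_kappa_bands_exact_cutpoints(self, kappa, band):
        assert interpret_kappa(kappa) == band

    @pytest.mark.parametrize(
        "icc, band",
        [
            (0.10, "unacceptable"), (0.199, "unacceptable"), (0.20, "questionable"),
            (0.40, "questionable"), (0.405, "questionable"), (0.41, "good"),
            (0.50, "good"), (0.60, "good"), (0.61, "very good"), (0.80, "very good"),
            (0.81, "excellent"), (0.906, "excellent"), (1.0, "excellent"),
        ],
    )
    def test_icc_bands_exact_cutpoints(self, icc, band):
        assert interpret_icc(icc) == band

    def test_kappa_band_domain(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.2)


class TestDifferences:
    def test_identical_lists(self):
        assert difference_summary([1, 2, 3], [1, 2, 3]) == (0.0, 0.0)

    def test_constant_offset(self):
        m, s = difference_summary([3, 4, 5], [1, 2, 3])
        assert (m, s) == (2.0, 0.0)

    def test_hand_computed_sd_with_n_minus_1(self):
        m, s = difference_summary([1, -1, 3, -3], [0, 0, 0, 0])
        assert m == 0.0
        assert s == pytest.approx(2.582, abs=1e-3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            difference_summary([1, 2], [1, 2, 3])


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = [0, 1, 2, 1, 0]
        table, acc = confusion_matrix(y, y, [0, 1, 2])
        assert acc == 1.0
        assert np.all(np.diag(table.to_numpy()) == [2, 2, 1])
        assert table.to_numpy().sum() == len(y)

    def test_counts_match_brute_force_tally(self, rng):
        truth = rng.integers(0, 3, size=50)
        pred = rng.integers(0, 3, size=50)
        table, acc = confusion_matrix(truth, pred, [0, 1, 2])
        for t in range(3):
            for p in range(3):
                assert table.iloc[t, p] == int(np.sum((truth == t) & (pred == p)))
        assert acc == pytest.approx(np.mean(truth == pred))
        # marginals reproduce each rater's category counts
        assert table.sum(axis=1).tolist() == [int((truth == c).sum()) for c in range(3)]
        assert table.sum(axis=0).tolist() == [int((pred == c).sum()) for c in range(3)]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix([0, 3], [0, 1], [0, 1, 2])


def test_agreement_report_shape():
    rng = np.random.default_rng(3)
    gold = rng.integers(0, 5, size=25)
    pred = np.where(rng.random(25) < 0.7, gold, rng.integers(0, 5, size=25))
    rep = agreement_report({"er": (pred, gold), "ir": (gold, gold)})
    assert list(rep["variable"]) == ["er", "ir"]
    assert rep.loc[1, "kappa"] == pytest.approx(1.0)
    assert rep.loc[1, "icc"] == pytest.approx(1.0)
    assert {"n", "kappa", "kappa_p", "icc", "icc_p", "mean_diff", "sd_diff"} <= set(rep.columns)
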