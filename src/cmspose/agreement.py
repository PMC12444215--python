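"""Inter-rater agreement statistics: Cohen kappa, ICC(1,1), differences.

The validation layer compares automated scores with human gold-standard
ratings.  Cohen's unweighted kappa quantifies chance-corrected categorical
agreement; the intraclass correlation ICC(1,1) — one-way random-effects,
single rater, absolute agreement — quantifies reliability of the ordinal
scores; mean (SD) differences summarize bias.  Interpretation follows the
Landis-Koch kappa bands and a five-level ICC convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: returned when the statistic is undefined (e.g. zero variance)
UNDEFINED = float("nan")


@dataclass
class RatingPair:
    """Two raters' scores for the same subjects, on a shared category set."""

    ratings_a: np.ndarray
    ratings_b: np.ndarray
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ratings_a = np.asarray(self.ratings_a)
        self.ratings_b = np.asarray(self.ratings_b)
        if len(self.ratings_a) != len(self.ratings_b):
            raise ValueError("rating lists must have equal length")
        if len(self.ratings_a) < 2:
            raise ValueError("need at least 2 rated subjects")


def cohen_kappa(p: RatingPair) -> tuple[float, float]:
    """Unweighted Cohen kappa with a large-sample normal test.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement and
    p_e the chance agreement from marginal products.  The p-value tests
    H0: kappa = 0 with the Fleiss standard error (the convention of the
    R irr package's kappa2).  Returns (nan, nan) with a warning when both
    raters are constant on the same category (p_e = 1).
    """
    a, b = p.ratings_a, p.ratings_b
    n = len(a)
    cats = np.unique(np.concatenate([a, b]))
    ia = np.searchsorted(cats, a)
    ib = np.searchsorted(cats, b)
    k = len(cats)
    table = np.zeros((k, k))
    np.add.at(table, (ia, ib), 1.0)
    prop = table / n
    po = float(prop.trace())
    row = prop.sum(axis=1)
    col = prop.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0:
        warnings.warn("kappa undefined: both raters constant on one category")
        return UNDEFINED, UNDEFINED
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss SE under H0
    se0 = math.sqrt(pe + pe**2 - float(((row + col) * row * col).sum())) / (
        (1.0 - pe) * math.sqrt(n)
    )
    if se0 == 0.0:
        return kappa, UNDEFINED
    z = kappa / se0
    pval = 2.0 * stats.norm.sf(abs(z))
    return float(kappa), float(pval)


@dataclass
class RatingMatrix:
    """Subjects x raters numeric scores with no missing cells."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] < 2 or self.scores.shape[1] < 2:
            raise ValueError("need >= 2 subjects and >= 2 raters")
        if not np.isfinite(self.scores).all():
            raise ValueError("missing cells are not allowed")


def icc_oneway(m: RatingMatrix) -> tuple[float, float]:
    """ICC(1,1): one-way random-effects, single-rater, absolute agreement.

    ICC = (MSB - MSW) / (MSB + (k-1) MSW), with MSB/MSW the between- and
    within-subject mean squares; p-value from F = MSB/MSW on
    (n-1, n(k-1)) degrees of freedom.  Zero total variance returns
    (nan, nan) with a warning.
    """
    x = m.scores
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    ssb = k * float(((row_means - grand) ** 2).sum())
    ssw = float(((x - row_means[:, None]) ** 2).sum())
    if ssb + ssw == 0.0:
        warnings.warn("ICC undefined: zero total variance")
        return UNDEFINED, UNDEFINED
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    icc = (msb - msw) / (msb + (k - 1) * msw)
    if msw == 0.0:
        return float(icc), 0.0
    f = msb / msw
    pval = stats.f.sf(f, n - 1, n * (k - 1))
    return float(icc), float(pval)


#: Landis-Koch kappa bands; boundaries belong to the lower band.
_KAPPA_BANDS = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
)


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch agreement band for a kappa value."""
    if not (-1.0 <= kappa <= 1.0):
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    for hi, label in _KAPPA_BANDS:
        if kappa <= hi:
            return label
    return "almost perfect"


def interpret_icc(icc: float) -> str:
    """Five-level ICC band: unacceptable (<0.20), questionable (0.20-0.40),
    good (0.41-0.60), very good (0.61-0.80), excellent (0.81-1.00).

    Values in the unlabeled gap (0.40, 0.41) map to questionable.
    """
    if icc > 1.0:
        raise ValueError(f"ICC {icc} exceeds 1")
    if icc < 0.20:
        return "unacceptable"
    if icc <= 0.40 or icc < 0.41:
        return "questionable"
    if icc <= 0.60:
        return "good"
    if icc <= 0.80:
        return "very good"
    return "excellent"


def difference_summary(scores_a, scores_b) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of elementwise a - b."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score lists must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired scores")
    d = a - b
    return float(d.mean()), float(d.std(ddof=1))


def confusion_matrix(truth, predicted, categories) -> tuple[pd.DataFrame, float]:
    """Counts table (rows = truth, columns = predicted) plus accuracy."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    cats = list(categories)
    unknown = set(truth.tolist()) | set(predicted.tolist())
    unknown -= set(cats)
    if unknown:
        raise ValueError(f"labels outside the category set: {sorted(unknown)}")
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)), dtype=int)
    for t, p in zip(truth, predicted):
        table[idx[t], idx[p]] += 1
    df = pd.DataFrame(table, index=cats, columns=cats)
    acc = float(np.trace(table) / len(truth))
    return df, acc


def agreement_report(
    variables: dict[str, tuple[np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """Reliability table: one row per variable with n, kappa, kappa p,
    ICC, ICC p and mean (SD) difference between predictions and gold.
    """
    rows = []
    for name, (pred, gold) in variables.items():
        pred = np.asarray(pred)
        gold = np.asarray(gold)
        kap, kp = cohen_kappa(RatingPair(pred, gold))
        icc, ip = icc_oneway(RatingMatrix(np.column_stack([pred, gold]).astype(float)))
        md, sd = difference_summary(pred.astype(float), gold.astype(float))
        rows.append(
            {
                "variable": name,
                "n": len(pred),
                "kappa": kap,
                "kappa_p": kp,
                "icc": icc,
                "icc_p": ip,
                "mean_diff": md,
                "sd_diff": sd,
            }
        )
    return pd.DataFrame(rows)
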