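"""Ordinal agreement and accuracy statistics for the grading validation.

Two graders (e.g. 4D flow vs echo, or two readers) are cross-tabulated
on the five ordered categories (normal < indeterminate < grade I < II
< III). Agreement is summarised by Cohen's weighted kappa (linear
disagreement weights |i-j|/(k-1) by default) with the Fleiss-Cohen-
Everitt asymptotic-variance confidence interval; directional
disagreement by the Bowker test of symmetry, the k x k generalisation
of McNemar's test, with category pairs that contain no discordant
subjects excluded from the degrees of freedom. Binary cutoff-prediction
accuracies carry exact Clopper-Pearson intervals; interobserver
reliability of continuous parameters uses the two-way single-measure
absolute-agreement intraclass correlation ICC(A,1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DiastolicGrade, GRADE_ORDER, default_cutoffs
from .calibration import PAIRED_PARAMETERS, bland_altman, paired_series

__all__ = [
    "ContingencyTable5",
    "AgreementResult",
    "build_contingency",
    "weighted_kappa",
    "bowker_symmetry",
    "agreement_summary",
    "accuracy_ci",
    "icc_absolute_single",
    "parameter_report",
    "correlation_label",
]

K = len(GRADE_ORDER)  # five ordered categories


@dataclass(frozen=True)
class ContingencyTable5:
    """5x5 cross-classification of grades; rows = method A, columns = method B."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (K, K):
            raise ValueError(f"expected a {K}x{K} table, got shape {c.shape}")
        if np.any(c < 0) or not np.all(np.equal(np.mod(c, 1), 0)):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    @property
    def n_discordant(self) -> int:
        return self.n - self.trace

    def transpose(self) -> "ContingencyTable5":
        return ContingencyTable5(self.counts.T)

    def to_frame(self) -> pd.DataFrame:
        labels = [g.label for g in GRADE_ORDER]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def build_contingency(grades_a: Sequence[DiastolicGrade],
                      grades_b: Sequence[DiastolicGrade]) -> ContingencyTable5:
    """Cross-tabulate two equal-length grade series (A in rows, B in columns)."""
    if len(grades_a) != len(grades_b):
        raise ValueError("grade series must have equal length")
    if len(grades_a) == 0:
        raise ValueError("empty grade series")
    counts = np.zeros((K, K), dtype=np.int64)
    for a, b in zip(grades_a, grades_b):
        if a is None or b is None:
            raise ValueError("missing grade in series")
        counts[int(a), int(b)] += 1
    return ContingencyTable5(counts)


@dataclass(frozen=True)
class AgreementResult:
    kappa_weighted: float
    kappa_ci: tuple[float, float]
    kappa_se: float
    weights: str
    symmetry_chi2: float
    symmetry_df: int
    symmetry_p: float
    n_discordant: int
    n: int


def _disagreement_weights(scheme: str) -> np.ndarray:
    i, j = np.indices((K, K))
    v = np.abs(i - j) / (K - 1)
    if scheme == "linear":
        return v
    if scheme == "quadratic":
        return v ** 2
    raise ValueError(f"unknown weight scheme: {scheme!r}")


def weighted_kappa(table: ContingencyTable5, weights: str = "linear",
                   ) -> tuple[float, tuple[float, float], float]:
    """Cohen's weighted kappa with asymptotic-normal CI.

    kappa = 1 - sum(v_ij p_ij) / sum(v_ij p_i q_j) with disagreement
    weights v_ij; the standard error is the large-sample (non-null)
    variance of weighted kappa evaluated with agreement weights
    w_ij = 1 - v_ij.

    Returns (kappa, (ci_low, ci_high), se).
    """
    n = table.n
    if n <= 0:
        raise ValueError("empty table")
    P = table.counts / n
    p = P.sum(axis=1)   # row margins (rater A)
    q = P.sum(axis=0)   # column margins (rater B)
    if np.count_nonzero(p) < 2 or np.count_nonzero(q) < 2:
        raise ValueError("need at least two categories with nonzero margin")
    v = _disagreement_weights(weights)
    expected_dis = float((v * np.outer(p, q)).sum())
    if expected_dis == 0.0:
        raise ValueError("expected weighted disagreement is zero; kappa undefined")
    kappa = 1.0 - float((v * P).sum()) / expected_dis

    w = 1.0 - v
    pe = float((w * np.outer(p, q)).sum())
    wbar_row = w @ q            # \bar w_{i.} = sum_j q_j w_ij
    wbar_col = p @ w            # \bar w_{.j} = sum_i p_i w_ij
    centred = w - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - kappa)
    var = ((P * centred ** 2).sum() - (kappa - pe * (1.0 - kappa)) ** 2) \
        / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(0.0, float(var)))
    lo = max(-1.0, kappa - 1.96 * se)
    hi = min(1.0, kappa + 1.96 * se)
    return kappa, (lo, hi), se


def bowker_symmetry(table: ContingencyTable5) -> tuple[float, int, float]:
    """Bowker test of symmetry: chi2 = sum (n_ij - n_ji)^2 / (n_ij + n_ji)
    over category pairs i < j with at least one discordant subject; df is
    the number of such pairs. With no discordant pairs at all, returns
    (0, 0, 1) by convention.
    """
    c = table.counts
    chi2 = 0.0
    df = 0
    for i in range(K):
        for j in range(i + 1, K):
            s = c[i, j] + c[j, i]
            if s > 0:
                chi2 += (c[i, j] - c[j, i]) ** 2 / s
                df += 1
    if df == 0:
        return 0.0, 0, 1.0
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


def agreement_summary(table: ContingencyTable5,
                      weights: str = "linear") -> AgreementResult:
    kappa, ci, se = weighted_kappa(table, weights)
    chi2, df, p = bowker_symmetry(table)
    return AgreementResult(kappa_weighted=kappa, kappa_ci=ci, kappa_se=se,
                           weights=weights, symmetry_chi2=chi2,
                           symmetry_df=df, symmetry_p=p,
                           n_discordant=table.n_discordant, n=table.n)


def accuracy_ci(n_correct: int, n_total: int,
                ) -> tuple[float, tuple[float, float]]:
    """Accuracy in percent with its exact two-sided 95% Clopper-Pearson CI.

    Returns unrounded percentages; round to integers for report output.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_correct <= n_total:
        raise ValueError("need 0 <= n_correct <= n_total")
    k, n = n_correct, n_total
    lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    return 100.0 * k / n, (100.0 * lo, 100.0 * hi)


def icc_absolute_single(ratings) -> tuple[float, tuple[float, float]]:
    """ICC(A,1): two-way model, single measure, absolute agreement.

    ``ratings`` is an n x 2 array-like (subjects x raters). Point estimate
    from the two-way ANOVA mean squares
    (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)); the CI is
    the standard F-based interval with Satterthwaite degrees of freedom.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("ratings must be an n x 2 table")
    n, k = X.shape
    if n < 5:
        raise ValueError(f"need n >= 5 subjects, got {n}")
    if np.isnan(X).any():
        raise ValueError("ratings must be complete")

    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((X - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr <= mse and ssr == 0.0:
        raise ValueError("zero between-subject variance; ICC undefined")

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    # F-based CI (two-way absolute-agreement single-measure form)
    fj = msc / mse if mse > 0 else math.inf
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else math.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else math.inf
    if not math.isfinite(a) or not math.isfinite(fj):
        return float(icc), (float(icc), float(icc))
    v_num = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    v_den = (n - 1) * k ** 2 * icc ** 2 * fj ** 2 \
        + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = v_num / v_den
    f_l = stats.f.ppf(0.975, n - 1, v)
    f_u = stats.f.ppf(0.975, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), (float(lower), float(upper))


def correlation_label(r: float) -> str:
    """Verbal strength of a correlation coefficient magnitude."""
    a = abs(r)
    if a > 0.90:
        return "very high"
    if a >= 0.70:
        return "high"
    if a >= 0.50:
        return "moderate"
    return "low"


# Cutoff-prediction criteria per parameter: (echo threshold attr on the echo
# cutoff set, flow threshold attr on the 4D set, direction).
_ACCURACY_CRITERIA: dict[str, list[tuple[str, str, str]]] = {
    "ef": [("ef_low", "ef_low", "<")],
    "lavi": [("lavi_high", "lavi_high", ">")],
    "e": [("e_high", "e_high", ">")],
    "e_over_a": [("ea_low", "ea_low", ">"), ("ea_high", "ea_high", "<")],
    "e_prime_septal": [("e_prime_septal_low", "e_prime_septal_low", "<")],
    "e_prime_lateral": [("e_prime_lateral_low", "e_prime_lateral_low", "<")],
    "e_over_eprime": [("e_over_eprime_high", "e_over_eprime_high", ">")],
}


def parameter_report(records, echo_cutoffs=None, flow_cutoffs=None) -> pd.DataFrame:
    """Per-parameter method-comparison summary.

    One row per parameter/criterion: echo and 4D-flow mean +/- SD, bias
    (echo - 4D) with its test p-value, Pearson r with a verbal strength
    label, and the accuracy (with exact CI) of the 4D-flow criterion for
    predicting the corresponding echo criterion.
    """
    if echo_cutoffs is None:
        echo_cutoffs = default_cutoffs("echo")
    if flow_cutoffs is None:
        flow_cutoffs = default_cutoffs("flow4d")
    rows = []
    for param in PAIRED_PARAMETERS:
        echo_v, flow_v = paired_series(records, param)
        if len(echo_v) < 3:   # e.g. E/A with A peaks absent cohort-wide
            continue
        ba = bland_altman(echo_v, flow_v)
        for echo_attr, flow_attr, op in _ACCURACY_CRITERIA[param]:
            ec = getattr(echo_cutoffs, echo_attr)
            fc = getattr(flow_cutoffs, flow_attr)
            echo_pos = echo_v < ec if op == "<" else echo_v > ec
            flow_pos = flow_v < fc if op == "<" else flow_v > fc
            acc, (alo, ahi) = accuracy_ci(int((echo_pos == flow_pos).sum()),
                                          len(echo_v))
            rows.append({
                "parameter": param,
                "criterion": f"{param} {op} {ec:g} (4D: {op} {fc:g})",
                "echo_mean": echo_v.mean(), "echo_sd": echo_v.std(ddof=1),
                "flow_mean": flow_v.mean(), "flow_sd": flow_v.std(ddof=1),
                "bias": ba.bias, "bias_p": ba.bias_p, "test_used": ba.test_used,
                "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                "r": ba.r,
                "r_label": correlation_label(ba.r) if not math.isnan(ba.r)
                else "undefined",
                "n": ba.n,
                "accuracy_pct": acc, "accuracy_lo": alo, "accuracy_hi": ahi,
            })
    return pd.DataFrame(rows)
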