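"""Paired-comparison statistics for helix-metric tables.

Wilcoxon signed-rank and Pearson correlation are delegated to
``scipy.stats``; Bland–Altman bias / limits of agreement and the
two-way-random absolute-agreement single-measurement intraclass
correlation (ICC(2,1)) are computed from the standard formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats as sps

from .errors import DomainError

__all__ = ["PairedMeasurements", "AgreementReport", "bland_altman",
           "wilcoxon_signed_rank", "pearson_r", "icc_agreement",
           "agreement_report"]


@dataclass
class PairedMeasurements:
    """One metric measured under two conditions on the same subjects."""

    value_a: np.ndarray
    value_b: np.ndarray
    subject_ids: Optional[list] = None
    units: str = ""

    def __post_init__(self):
        self.value_a = np.asarray(self.value_a, dtype=float)
        self.value_b = np.asarray(self.value_b, dtype=float)
        if self.value_a.shape != self.value_b.shape or self.value_a.ndim != 1:
            raise DomainError("paired values must be 1D arrays of equal length")
        if len(self.value_a) < 3:
            raise DomainError("need at least 3 pairs")
        if not (np.all(np.isfinite(self.value_a)) and np.all(np.isfinite(self.value_b))):
            raise DomainError("paired values must be finite")

    @property
    def differences(self) -> np.ndarray:
        return self.value_a - self.value_b


@dataclass
class AgreementReport:
    wilcoxon_p: float
    wilcoxon_all_zero: bool
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float
    icc: Optional[float]
    icc_undefined: bool
    units: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def bland_altman(pairs: PairedMeasurements) -> tuple:
    """(bias, loa_low, loa_high): mean difference and bias ± 1.96 sample SD."""
    d = pairs.differences
    if len(d) < 2:
        raise DomainError("need at least 2 pairs")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def wilcoxon_signed_rank(pairs: PairedMeasurements) -> tuple:
    """Two-sided Wilcoxon signed-rank p-value.

    Exact null distribution for n <= 25 without zero differences, normal
    approximation (with tie correction) otherwise; zero differences handled
    by the Pratt method.  All-zero differences return p = 1 with a flag.

    Returns (p_value, all_zero_flag).
    """
    d = pairs.differences
    if np.all(d == 0):
        return 1.0, True
    n_nonzero = int(np.count_nonzero(d))
    has_zeros = n_nonzero < len(d)
    if not has_zeros and n_nonzero <= 25:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(d, zero_method="pratt", alternative="two-sided",
                       method=method, correction=False)
    return float(res.pvalue), False


def pearson_r(pairs: PairedMeasurements) -> float:
    return float(sps.pearsonr(pairs.value_a, pairs.value_b).statistic)


def icc_agreement(ratings: np.ndarray) -> tuple:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measurement, from the mean-squares decomposition.

    Parameters
    ----------
    ratings : ndarray (n_subjects, n_raters)

    Returns
    -------
    (icc, undefined_flag) — undefined (icc None) when the between-subject
    variance vanishes.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise DomainError("ratings must be a subjects x raters matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise DomainError("need >= 3 subjects and >= 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)            # subjects
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)            # raters
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))                                 # residual
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    scale = max(abs(x).max(), 1.0)
    # no between-subject spread (or a fully constant table): ICC undefined
    if msr <= 1e-24 * scale**2 or abs(denom) <= 1e-24 * scale**2:
        return None, True
    return float((msr - mse) / denom), False


def agreement_report(pairs: PairedMeasurements) -> AgreementReport:
    """Full paired-agreement summary for one metric."""
    bias, lo, hi = bland_altman(pairs)
    p, all_zero = wilcoxon_signed_rank(pairs)
    r = pearson_r(pairs)
    icc, undef = icc_agreement(np.column_stack([pairs.value_a, pairs.value_b]))
    return AgreementReport(wilcoxon_p=p, wilcoxon_all_zero=all_zero,
                           pearson_r=r, bias=bias, loa_low=lo, loa_high=hi,
                           icc=icc, icc_undefined=undef, units=pairs.units)
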