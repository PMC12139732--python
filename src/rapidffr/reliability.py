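"""Group-level statistics: outlier screening, ICC, and a permutation test
on ICC differences.

Two intraclass-correlation variants are provided, matching how agreement
between FFR measurement methods and between repeated runs is usually
quantified:

* ``oneway`` — one-way random-effects, single-measure ICC(1):
  ``(MSB - MSW) / (MSB + (k-1) MSW)`` with an F test on
  ``(n-1, n(k-1))`` degrees of freedom. Appropriate when the "raters"
  (methods) are regarded as fixed and only subjects are random.
* ``twoway`` — two-way random-effects, absolute-agreement, single-measure
  ICC(A,1) (McGraw & Wong). Its denominator degrees of freedom use the
  Satterthwaite approximation evaluated at the estimated coefficient, which
  is why they are generally non-integer; the 95% CI uses the standard
  F-bound construction for this variant.

The permutation test compares two ICCs (e.g. test-retest ICC of two
methods): in each iteration the second column of each matrix is shuffled
across subjects independently, both ICCs are recomputed, and their
difference forms the null distribution. The two-tailed p-value is the
fraction of null differences whose absolute value strictly exceeds the
absolute observed difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pipeline import ChunkResult, chunk_series, result_table  # noqa: F401  (re-export)

__all__ = [
    "IccResult",
    "PermTestResult",
    "reject_outliers",
    "icc",
    "permute_icc_difference",
    "holm_correction",
    "chunk_series",
    "result_table",
]


def reject_outliers(values: np.ndarray, k: float = 2.5) -> np.ndarray:
    """Keep-mask: False where ``|x - mean| > k * sd`` (leave-in z-score).

    Mean and SD (ddof=1) are computed over the whole group including the
    candidate. A zero SD means all values are equal, so everything is kept.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("outlier screening needs at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.ones(x.size, dtype=bool)
    return np.abs(x - x.mean()) <= k * sd


@dataclass
class IccResult:
    icc: float
    model: str
    df: tuple[float, float]
    ci95: tuple[float, float]
    p: float
    n: int
    k: int
    meta: dict = field(default_factory=dict)


def _complete_matrix(data: np.ndarray) -> np.ndarray:
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("data must be an (n_subjects, k_raters) matrix")
    x = x[~np.isnan(x).any(axis=1)]  # listwise deletion
    if x.shape[0] < 3:
        raise ValueError("ICC inference needs at least 3 complete subjects")
    if x.shape[1] < 2:
        raise ValueError("ICC needs at least 2 raters/methods")
    return x


def _mean_squares(x: np.ndarray) -> tuple[float, float, float, float]:
    """(MSR, MSC, MSE, MSW) from the two-way layout."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    ssw = sst - ssr
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    msw = ssw / (n * (k - 1))
    return msr, msc, mse, msw


def icc(data: np.ndarray, model: str = "oneway", alpha: float = 0.05) -> IccResult:
    """Single-measure ICC with F-based p-value and 95% CI.

    Rows are subjects, columns raters/methods/runs; rows containing NaN are
    dropped (listwise deletion).
    """
    x = _complete_matrix(data)
    n, k = x.shape
    msr, msc, mse, msw = _mean_squares(x)

    if model == "oneway":
        denom = msr + (k - 1) * msw
        coeff = (msr - msw) / denom if denom > 0 else 1.0
        df1, df2 = n - 1.0, n * (k - 1.0)
        if msw > 0:
            fvalue = msr / msw
            p = float(stats.f.sf(fvalue, df1, df2))
            fl = fvalue / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = fvalue * stats.f.ppf(1 - alpha / 2, df2, df1)
            ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
        else:  # perfect within-subject agreement
            p, ci = 0.0, (1.0, 1.0)
        return IccResult(float(coeff), model, (df1, df2),
                         (float(ci[0]), float(ci[1])), p, n, k,
                         meta={"MSR": msr, "MSW": msw})

    if model != "twoway":
        raise ValueError(f"unknown ICC model {model!r}")

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    coeff = (msr - mse) / denom if denom > 0 else 1.0
    df1 = n - 1.0
    if mse > 0 and coeff < 1.0:
        a = (k * coeff) / (n * (1 - coeff))
        b = 1 + (k * coeff * (n - 1)) / (n * (1 - coeff))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        fvalue = msr / mse
        p = float(stats.f.sf(fvalue, df1, v))
        fl = stats.f.ppf(1 - alpha / 2, df1, v)
        fu = stats.f.ppf(1 - alpha / 2, v, df1)
        lb = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
        ub = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
        ci = (float(lb), float(ub))
        df2 = float(v)
    else:
        p, ci, df2 = 0.0, (1.0, 1.0), (n - 1.0) * (k - 1.0)
    return IccResult(float(coeff), model, (df1, df2), ci, p, n, k,
                     meta={"MSR": msr, "MSC": msc, "MSE": mse})


def _icc_value_stack(x: np.ndarray, model: str) -> np.ndarray:
    """Coefficient-only ICC over a stack of matrices, shape (B, n, k)."""
    n, k = x.shape[-2], x.shape[-1]
    grand = x.mean(axis=(-2, -1), keepdims=True)
    row_means = x.mean(axis=-1, keepdims=True)
    ssr = k * ((row_means - grand) ** 2).sum(axis=(-2, -1))
    sst = ((x - grand) ** 2).sum(axis=(-2, -1))
    msr = ssr / (n - 1)
    if model == "oneway":
        msw = (sst - ssr) / (n * (k - 1))
        return (msr - msw) / (msr + (k - 1) * msw)
    col_means = x.mean(axis=-2, keepdims=True)
    ssc = n * ((col_means - grand) ** 2).sum(axis=(-2, -1))
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    msc = ssc / (k - 1)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


@dataclass
class PermTestResult:
    obs: float
    null_values: np.ndarray
    n_perm: int
    p_c: float
    seed: int | None
    meta: dict = field(default_factory=dict)


def permute_icc_difference(runs_a: np.ndarray, runs_b: np.ndarray,
                           n_perm: int = 1000, seed: int | None = None,
                           model: str = "twoway") -> PermTestResult:
    """Two-tailed permutation test on ``icc(runs_a) - icc(runs_b)``.

    Each iteration scrambles the pairing between run 1 and run 2 by
    shuffling the second column across subjects, independently within each
    matrix, and recomputes both ICCs. ``p_c`` counts strictly greater
    absolute null differences.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = _complete_matrix(runs_a)
    b = _complete_matrix(runs_b)
    rng = np.random.default_rng(seed)
    obs = float(_icc_value_stack(a[None], model)[0]
                - _icc_value_stack(b[None], model)[0])

    def shuffled_stack(m: np.ndarray) -> np.ndarray:
        n = m.shape[0]
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        stack = np.broadcast_to(m, (n_perm,) + m.shape).copy()
        stack[..., 1] = m[perms, 1]
        return stack

    # one RNG stream, A then B within each logical iteration block
    icc_a = _icc_value_stack(shuffled_stack(a), model)
    icc_b = _icc_value_stack(shuffled_stack(b), model)
    null = icc_a - icc_b
    p_c = float(np.count_nonzero(np.abs(null) > abs(obs)) / n_perm)
    return PermTestResult(obs=obs, null_values=null, n_perm=n_perm, p_c=p_c,
                          seed=seed, meta={"model": model})


def holm_correction(pvals) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p-values and rejections at alpha=0.05."""
    from statsmodels.stats.multitest import multipletests

    reject, adj, _, _ = multipletests(np.asarray(pvals, float), method="holm")
    return adj, reject
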