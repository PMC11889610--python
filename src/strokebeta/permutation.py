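"""Non-parametric permutation tests.

Every significance statement in the analysis rests on one of two resampling
schemes: sign-flip permutation for "does this quantity deviate from zero"
(one-sample) and row-shuffle permutation for "do these two groups differ"
(two-sample). Null distributions are built from the absolute t statistic;
decisions use the 95th and 99th percentiles of the null, and p-values use
the add-one formula so that p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "PermutationResult",
    "one_sample_t",
    "two_sample_t",
    "one_sample_perm",
    "two_sample_perm",
    "summarize_family",
]


@dataclass
class PermutationResult:
    mode: str                   # "sign_flip" or "row_shuffle"
    observed_t: float
    df: int
    null_samples: np.ndarray    # |t| under the null
    threshold_95: float
    threshold_99: float
    p_value: float
    significant_at: float | None   # None, 0.05 or 0.01

    @property
    def thresholds(self) -> dict:
        return {0.95: self.threshold_95, 0.99: self.threshold_99}


def one_sample_t(values: np.ndarray) -> float:
    """Textbook one-sample t statistic, mean / (sd / sqrt(n)), df = n-1."""
    x = np.asarray(values, dtype=float)
    n = x.size
    sd = x.std(ddof=1)
    m = x.mean()
    if sd == 0.0:
        return 0.0 if m == 0.0 else np.sign(m) * np.inf
    return m / (sd / np.sqrt(n))


def two_sample_t(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-variance two-sample t statistic, df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        return 0.0 if diff == 0.0 else np.sign(diff) * np.inf
    return diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def _finalize(mode, t_obs, df, null_abs, n_perm) -> PermutationResult:
    thr95 = float(np.percentile(null_abs, 95))
    thr99 = float(np.percentile(null_abs, 99))
    p = (1.0 + np.count_nonzero(null_abs >= abs(t_obs))) / (n_perm + 1.0)
    # percentile-threshold decision; the p-value condition guards the
    # degenerate case of a null massed at the threshold itself
    sig = None
    if abs(t_obs) >= thr99 and p <= 0.01 + 1.0 / (n_perm + 1.0):
        sig = 0.01
    elif abs(t_obs) >= thr95 and p <= 0.05 + 1.0 / (n_perm + 1.0):
        sig = 0.05
    return PermutationResult(mode=mode, observed_t=float(t_obs), df=df,
                             null_samples=null_abs, threshold_95=thr95,
                             threshold_99=thr99, p_value=float(p),
                             significant_at=sig)


def one_sample_perm(values, n_perm: int = 5000,
                    seed=None) -> PermutationResult:
    """Sign-flip permutation test of mean deviation from zero (two-sided).

    The null is built by flipping the sign of each subject's value with
    probability 1/2, ``n_perm`` times, and recomputing |t|.

    Parameters
    ----------
    values : array-like, one statistic per subject, n >= 5
    n_perm : int
    seed : int, numpy Generator, or None

    Notes
    -----
    A zero-variance input with zero mean returns p = 1. A zero-variance
    input with nonzero mean falls back to exact enumeration of all 2^n
    sign patterns (n <= 20), where t is +-inf for the all-same-sign
    patterns and finite otherwise.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 values")
    rng = np.random.default_rng(seed)
    t_obs = one_sample_t(x)

    if x.std(ddof=1) == 0.0:
        if x.mean() == 0.0:
            null_abs = np.zeros(n_perm)
            return _finalize("sign_flip", 0.0, n - 1, null_abs, n_perm)
        if n > 20:
            raise ValueError("exact enumeration fallback limited to n <= 20")
        null_abs = np.array([
            abs(one_sample_t(np.array(sgn) * x))
            for sgn in product((-1.0, 1.0), repeat=n)
        ])
        return _finalize("sign_flip", t_obs, n - 1, null_abs,
                         null_abs.size)

    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    flipped = signs * x
    m = flipped.mean(axis=1)
    sd = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(sd > 0, m / (sd / np.sqrt(n)), np.inf)
    return _finalize("sign_flip", t_obs, n - 1, np.abs(t_null), n_perm)


def two_sample_perm(group_a, group_b, n_perm: int = 5000,
                    seed=None) -> PermutationResult:
    """Row-shuffle permutation test of a group difference (two-sided).

    Group labels are randomly reassigned (preserving group sizes) and the
    pooled-variance t recomputed ``n_perm`` times.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 3 or nb < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([a, b])
    df = na + nb - 2
    t_obs = two_sample_t(a, b)
    if pooled.std(ddof=1) == 0.0:
        null_abs = np.zeros(n_perm)
        return _finalize("row_shuffle", 0.0, df, null_abs, n_perm)

    rng = np.random.default_rng(seed)
    # vectorized relabeling: argsort of uniform draws is a random permutation
    order = np.argsort(rng.random((n_perm, na + nb)), axis=1)
    shuffled = pooled[order]
    pa, pb = shuffled[:, :na], shuffled[:, na:]
    va = pa.var(axis=1, ddof=1)
    vb = pb.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    diff = pa.mean(axis=1) - pb.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(sp2 > 0,
                          diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb)),
                          np.inf)
    return _finalize("row_shuffle", t_obs, df, np.abs(t_null), n_perm)


def summarize_family(tests: dict, correction: str = "per_test") -> pd.DataFrame:
    """Annotate a family of tests with a multiple-comparison policy.

    Parameters
    ----------
    tests : dict mapping name -> PermutationResult
        All members must share the permutation mode and ``n_perm``.
    correction : {"per_test", "max_stat"}
        ``per_test`` reports each test's own percentile decision (the
        default, matching per-connection reporting). ``max_stat``
        re-thresholds every observed |t| against the null distribution of
        the maximum |t| across the family, which controls family-wise
        error; it assumes the members' null samples are aligned
        permutation-by-permutation (use a shared seed).
    """
    if correction not in ("per_test", "max_stat"):
        raise ValueError(f"unknown correction {correction!r}")
    results = list(tests.values())
    modes = {r.mode for r in results}
    if len(modes) > 1:
        raise ValueError("mixed permutation modes in one family")
    n_perms = {r.null_samples.size for r in results}
    if len(n_perms) > 1:
        raise ValueError("family members differ in n_perm")

    rows = []
    if correction == "max_stat":
        max_null = np.max(np.vstack([r.null_samples for r in results]),
                          axis=0)
        thr95 = float(np.percentile(max_null, 95))
        thr99 = float(np.percentile(max_null, 99))
        n_perm = max_null.size
        for name, r in tests.items():
            p = (1.0 + np.count_nonzero(max_null >= abs(r.observed_t))) \
                / (n_perm + 1.0)
            sig = (0.01 if abs(r.observed_t) >= thr99
                   else 0.05 if abs(r.observed_t) >= thr95 else None)
            rows.append((name, r.mode, r.observed_t, r.df, p, sig))
    else:
        for name, r in tests.items():
            rows.append((name, r.mode, r.observed_t, r.df, r.p_value,
                         r.significant_at))
    out = pd.DataFrame(rows, columns=["name", "mode", "t", "df", "p",
                                      "sig_level"])
    # object dtype keeps all-None families concatenation-safe
    out["sig_level"] = out["sig_level"].astype(object)
    return out
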