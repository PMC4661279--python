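"""Group-level behavioral statistics for uncertainty attitudes.

Single-pass 3-SD outlier exclusion on the model-free attitude scores, one-sample
and paired t-tests reported with Cohen's d = t/sqrt(n) (the convention the
printed effect sizes follow), and Pearson correlations among attitudes using
ln(gamma_A) (ambiguity attitudes are log-normal across subjects) and raw
gamma_C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    t: float
    df: int
    p: float
    d: float            # Cohen's d = t / sqrt(n)
    n: int
    mean: float = float("nan")
    se: float = float("nan")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"t({self.df}) = {self.t:.3f}, p = {self.p:.4g}, d = {self.d:.3f}, n = {self.n}"


def cohens_d(t: float, n: int) -> float:
    """Effect size from a one-sample or paired t statistic: d = t / sqrt(n)."""
    return t / math.sqrt(n)


def flag_outliers(values, k: float = 3.0) -> np.ndarray:
    """Mask of points farther than k sample SDs from the mean (single pass).

    The mean and SD include every point (no leave-one-out, no iteration); a
    zero-SD vector flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise StatsError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - x.mean()) > k * sd


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError("need at least 2 values")
    if x.std(ddof=1) == 0:
        raise StatsError("degenerate input: zero standard deviation")
    t, p = stats.ttest_1samp(x, mu0)
    n = x.size
    return TestResult(
        float(t), n - 1, float(p), cohens_d(float(t), n), n,
        mean=float(x.mean()), se=float(x.std(ddof=1) / math.sqrt(n)),
    )


def paired_t(a, b) -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StatsError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def pearson_r(a, b) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise StatsError("need equal-length sequences of at least 3 values")
    if a.std() == 0 or b.std() == 0:
        raise StatsError("zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def attitude_summary(subjects: pd.DataFrame, k_outlier: float = 3.0):
    """Group attitude analysis of a cohort table.

    ``subjects`` needs columns ra, aa, ca, gamma_a, gamma_c.  Subjects whose AA
    or CA lies more than ``k_outlier`` SDs from the respective mean are
    excluded from all further analyses.  Reports one-sample tests of RA/AA/CA
    against 0, of ln(gamma_A) against 0 and gamma_C against 1, and pairwise
    Pearson correlations among (RA, AA, CA, ln gamma_A, gamma_C).

    Returns (tests: DataFrame, correlations: DataFrame, excluded: index array).
    """
    req = {"ra", "aa", "ca", "gamma_a", "gamma_c"}
    if not req <= set(subjects.columns):
        raise StatsError(f"missing columns: {sorted(req - set(subjects.columns))}")
    if len(subjects) < 3:
        raise StatsError("need at least 3 subjects")
    out = flag_outliers(subjects["aa"], k_outlier) | flag_outliers(subjects["ca"], k_outlier)
    kept = subjects.loc[~out].copy()
    if len(kept) < 3:
        raise StatsError("all (or nearly all) subjects excluded")
    kept["ln_gamma_a"] = np.log(kept["gamma_a"])

    tests = {}
    for name, mu0 in (("ra", 0.0), ("aa", 0.0), ("ca", 0.0),
                      ("ln_gamma_a", 0.0), ("gamma_c", 1.0)):
        tests[name] = one_sample_t(kept[name], mu0)
    test_df = pd.DataFrame(
        {
            "n": {k: v.n for k, v in tests.items()},
            "mean": {k: v.mean for k, v in tests.items()},
            "se": {k: v.se for k, v in tests.items()},
            "t": {k: v.t for k, v in tests.items()},
            "df": {k: v.df for k, v in tests.items()},
            "p": {k: v.p for k, v in tests.items()},
            "d": {k: v.d for k, v in tests.items()},
        }
    )

    cols = ["ra", "aa", "ca", "ln_gamma_a", "gamma_c"]
    corr = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            r, _ = pearson_r(kept[a], kept[b])
            corr.loc[a, b] = corr.loc[b, a] = r
    excluded = subjects.index[out].to_numpy()
    return test_df, corr, excluded
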