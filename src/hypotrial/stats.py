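"""Statistical procedures of the two-arm trial analysis.

Group comparisons follow the conventions the trial report used and that its
printed tables reproduce under:

* means — pooled two-sample t-test; the mean-difference CI uses the
  t-critical value at the pooled degrees of freedom (with n = 30 per arm the
  printed "large-sample" intervals match t, not z, critical values);
* medians — Mann-Whitney U (exact enumeration for groups of up to 8,
  tie-corrected normal approximation otherwise, no continuity correction)
  with the Hodges-Lehmann median-of-pairwise-differences estimate and its
  Moses rank-based confidence interval;
* proportions — Pearson chi-square without continuity correction, switching
  to Fisher's exact test (two-sided by summing point probabilities no larger
  than the observed table's) when at least half of the expected cell counts
  fall below 5; difference-in-proportion CIs are continuity-corrected Wald
  on the percentage scale;
* the sample-size calculation inverts the noncentral-t power function of
  the pooled t-test, then inflates for dropout rounding up to an even total
  for 1:1 allocation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class StatResult:
    """One table row: estimate, confidence interval, p-value, provenance."""

    test_name: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    method_notes: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class PowerSpec:
    """Design assumptions of the sample-size calculation (primary outcome
    means per arm, common SD, two-sided alpha, target power, dropout)."""

    mu_intervention: float = 0.15
    mu_control: float = 0.40
    sd: float = 0.32
    alpha: float = 0.05
    power: float = 0.80
    dropout: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def _check_samples(*samples: Sequence[float]) -> list[np.ndarray]:
    out = []
    for s in samples:
        a = np.asarray(s, dtype=float)
        if a.size == 0:
            raise ValueError("empty sample")
        out.append(a)
    return out


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 #{ties}."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 exact_max_n: int = 8) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all C(n+m, n) group assignments (a permutation
    test on the U statistic, valid under ties) when both groups have at
    most `exact_max_n` observations; otherwise the tie-corrected normal
    approximation without continuity correction.  The estimate reported is
    the Hodges-Lehmann shift (median of pairwise differences y - x).
    """
    xa, ya = _check_samples(x, y)
    n, m = xa.size, ya.size
    diffs = (ya[None, :] - xa[:, None]).ravel()
    shift = float(np.median(diffs))

    if n <= exact_max_n and m <= exact_max_n:
        pooled = np.concatenate([xa, ya])
        u_obs = _u_statistic(xa, ya)
        dev = abs(u_obs - n * m / 2.0)
        hits = total = 0
        idx_all = range(n + m)
        for comb in combinations(idx_all, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - n * m / 2.0) >= dev - 1e-12:
                hits += 1
        p = hits / total
        notes = f"exact enumeration of {total} assignments"
    else:
        res = sps.mannwhitneyu(xa, ya, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        p = float(res.pvalue)
        notes = "normal approximation, tie-corrected variance, no continuity correction"
    return StatResult("mann_whitney_u", shift, math.nan, math.nan, min(p, 1.0), notes)


def hodges_lehmann(x: Sequence[float], y: Sequence[float],
                   conf: float = 0.95) -> StatResult:
    """Hodges-Lehmann estimate of the shift y - x with the Moses CI.

    The estimate is the median of all n*m pairwise differences; the CI takes
    the k-th smallest and k-th largest pairwise difference, with k from the
    normal approximation to the Wilcoxon rank-sum null distribution.  The
    p-value is the Mann-Whitney test's.
    """
    xa, ya = _check_samples(x, y)
    n, m = xa.size, ya.size
    diffs = np.sort((ya[None, :] - xa[:, None]).ravel())
    est = float(np.median(diffs))

    z = sps.norm.ppf(0.5 + conf / 2.0)
    nm = n * m
    k = int(math.floor(nm / 2.0 - z * math.sqrt(nm * (n + m + 1) / 12.0)))
    k = max(k, 0)
    lo = float(diffs[k]) if k < nm else float(diffs[0])
    hi = float(diffs[nm - 1 - k]) if k < nm else float(diffs[-1])
    p = mann_whitney(x, y).p_value
    return StatResult("hodges_lehmann", est, lo, hi, p,
                      f"Moses CI, k={k}, conf={conf}")


def t_test_from_summary(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int,
                        conf: float = 0.95) -> StatResult:
    """Pooled two-sample t-test from group summaries.

    Estimate and CI are for mean2 - mean1 with the t critical value at
    df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = mean2 - mean1
    tstat = diff / se
    p = 2.0 * sps.t.sf(abs(tstat), df)
    tcrit = sps.t.ppf(0.5 + conf / 2.0, df)
    return StatResult("pooled_t", diff, diff - tcrit * se, diff + tcrit * se,
                      min(p, 1.0), f"pooled df={df}, t-critical CI")


def _check_2x2(a: int, b: int, c: int, d: int) -> np.ndarray:
    t = np.array([[a, b], [c, d]], dtype=float)
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("cells must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    return t


def chi_square_2x2(a: int, b: int, c: int, d: int) -> StatResult:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction.

    Estimate is the difference in row-1 proportions (row1 - row2), percent.
    """
    t = _check_2x2(a, b, c, d)
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    p1 = a / (a + b)
    p2 = c / (c + d)
    return StatResult("chi_square", 100.0 * (p1 - p2), math.nan, math.nan,
                      float(p), f"Pearson chi2={float(chi2):.4f}, df=1, no continuity correction")


def fisher_2x2(a: int, b: int, c: int, d: int) -> StatResult:
    """Fisher's exact test, two-sided by summing point probabilities <= observed."""
    t = _check_2x2(a, b, c, d)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    p1 = a / (a + b)
    p2 = c / (c + d)
    return StatResult("fisher_exact", 100.0 * (p1 - p2), math.nan, math.nan,
                      float(p), f"two-sided (point-probability sum), OR={float(odds):.4f}")


def expected_counts(a: int, b: int, c: int, d: int) -> np.ndarray:
    t = _check_2x2(a, b, c, d)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def select_test(a: int, b: int, c: int, d: int) -> str:
    """'fisher' when >= 50% of expected cell counts are < 5, else 'chi_square'."""
    exp = expected_counts(a, b, c, d)
    return "fisher" if (exp < 5).mean() >= 0.5 else "chi_square"


def compare_proportions(a: int, b: int, c: int, d: int) -> StatResult:
    """Run the test chosen by the expected-count rule."""
    fn = fisher_2x2 if select_test(a, b, c, d) == "fisher" else chi_square_2x2
    return fn(a, b, c, d)


def proportion_diff_ci(x1: int, n1: int, x2: int, n2: int,
                       conf: float = 0.95, p_value: float = math.nan) -> StatResult:
    """Difference in proportions (group1 - group2) with continuity-corrected
    Wald CI, on the percentage scale."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    diff = p1 - p2
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z = sps.norm.ppf(0.5 + conf / 2.0)
    half = z * se + (1.0 / (2 * n1) + 1.0 / (2 * n2))
    return StatResult("proportion_diff", 100.0 * diff, 100.0 * (diff - half),
                      100.0 * (diff + half), p_value,
                      "continuity-corrected Wald, percentage scale")


def power_two_means(n_per_group: int, delta: float, sd: float, alpha: float) -> float:
    """Power of the two-sided pooled t-test at equal group size n (noncentral t)."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    ncp = abs(delta) / sd * math.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2.0, df)
    return float(1 - sps.nct.cdf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def sample_size_two_means(spec: PowerSpec, n_max: int = 10_000) -> dict:
    """Smallest equal per-group n whose noncentral-t power reaches the target."""
    delta = spec.mu_control - spec.mu_intervention
    if delta == 0:
        raise ValueError("zero mean difference: power target unreachable")
    for n in range(2, n_max + 1):
        pw = power_two_means(n, delta, spec.sd, spec.alpha)
        if pw >= spec.power:
            return {"n_per_group": n, "n_total": 2 * n, "power": pw}
    raise ValueError(f"power {spec.power} unreachable below n={n_max} per group")


def inflate_for_dropout(n_total: int, dropout: float) -> int:
    """Inflate a total sample size for dropout, rounding up to an even total."""
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    n = math.ceil(n_total / (1.0 - dropout))
    return n + (n % 2)


def bonferroni(p_values: Sequence[float], family_size: Optional[int] = None,
               alpha: float = 0.05) -> list[dict]:
    """Bonferroni adjustment: p_adj = min(1, p * family size), decision at alpha."""
    ps = list(p_values)
    k = family_size if family_size is not None else len(ps)
    if k < 1:
        raise ValueError("family_size must be >= 1")
    return [{"p": p, "p_adjusted": min(1.0, p * k),
             "significant": min(1.0, p * k) < alpha} for p in ps]
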