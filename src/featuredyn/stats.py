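"""Group-level Bayesian inference and latency estimation.

Evidence for above-chance decoding (or above-zero correlation) is
quantified with a one-sample Bayes factor: point null at the chance value
versus an interval alternative — a Cauchy prior (scale 0.707) on the
standardized effect size, truncated to effects of at least 0.5 so that
trivially small deviations from chance do not count as evidence.  The
marginal likelihood under the alternative is the noncentral-t likelihood
of the observed t statistic integrated over the truncated prior.

Onset latency is the first of three consecutive post-stimulus timepoints
with BF10 > 10; peak latency is the post-stimulus maximum of the group
mean.  Confidence intervals for both come from a leave-two-subjects-out
jackknife over all C(n, 2) subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import atan, comb, pi

import numpy as np
from scipy import integrate
from scipy.stats import nct
from scipy.stats import t as t_dist

DEFAULT_PRIOR_SCALE = 0.707
DEFAULT_PRIOR_LOWER = 0.5
DEFAULT_BF_THRESHOLD = 10.0


@dataclass
class BFSeries:
    times: np.ndarray
    bf10: np.ndarray
    null_value: float
    descriptor: str

    def __post_init__(self):
        self.bf10 = np.asarray(self.bf10, dtype=float)
        if np.any(self.bf10 <= 0):
            raise ValueError("Bayes factors must be positive")
        if len(self.bf10) != len(self.times):
            raise ValueError("bf10 and times must have equal length")

    @property
    def log10_bf(self) -> np.ndarray:
        return np.log10(self.bf10)


@dataclass
class OnsetPeakEstimate:
    estimate_ms: float | None
    ci_low: float | None
    ci_high: float | None
    n_jackknife: int
    n_missing: int
    kind: str  # onset | peak


def _truncated_cauchy_mass(lower: float, scale: float) -> float:
    # P(delta >= lower) under Cauchy(0, scale)
    return 0.5 - atan(lower / scale) / pi


def interval_bf(
    sample,
    null_value: float = 0.0,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    prior_lower: float = DEFAULT_PRIOR_LOWER,
    two_sided: bool = False,
) -> float:
    """One-sample Bayes factor with a truncated-Cauchy interval alternative.

    H0: the population mean equals ``null_value``.  H1: the standardized
    effect delta follows Cauchy(0, prior_scale) truncated to
    delta >= prior_lower (or |delta| >= prior_lower if ``two_sided``).
    BF10 is the ratio of marginal likelihoods of the observed t statistic,
    computed by adaptive quadrature.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or len(x) < 3 or not np.all(np.isfinite(x)):
        raise ValueError("sample must be 1-D with at least 3 finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("sample has zero variance")
    n = len(x)
    t_obs = (x.mean() - null_value) / (sd / np.sqrt(n))
    return _interval_bf_from_t(t_obs, n, prior_scale, prior_lower, two_sided)


def _interval_bf_from_t(
    t_obs: float,
    n: int,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    prior_lower: float = DEFAULT_PRIOR_LOWER,
    two_sided: bool = False,
) -> float:
    df = n - 1
    sqrt_n = np.sqrt(n)
    mass = _truncated_cauchy_mass(prior_lower, prior_scale)
    if two_sided:
        mass *= 2

    def integrand(u):
        # map u in (0, 1) to delta in (prior_lower, inf)
        delta = prior_lower + u / (1 - u)
        jac = 1 / (1 - u) ** 2
        prior = prior_scale / (pi * (prior_scale**2 + delta**2)) / mass
        like = nct.pdf(t_obs, df, delta * sqrt_n)
        if two_sided:
            like = like + nct.pdf(t_obs, df, -delta * sqrt_n)
        return prior * like * jac

    # breakpoint where the noncentral-t likelihood peaks (delta ~ t / sqrt(n))
    d_star = max(t_obs / sqrt_n, prior_lower)
    u_star = (d_star - prior_lower) / (1 + d_star - prior_lower)
    m1, _ = integrate.quad(
        integrand, 0, 1, points=[u_star], limit=200, epsabs=0, epsrel=1e-9
    )
    m0 = t_dist.pdf(t_obs, df)
    return float(m1 / m0)


def bf_timecourse(
    timecourses,
    times,
    null_value: float,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    prior_lower: float = DEFAULT_PRIOR_LOWER,
    descriptor: str = "",
) -> BFSeries:
    """Per-timepoint interval Bayes factors across subjects.

    ``timecourses``: (n_subjects, n_times) array of per-subject accuracies
    or correlations on a shared time grid.
    """
    data = np.asarray(timecourses, dtype=float)
    times = np.asarray(times)
    if data.ndim != 2 or data.shape[1] != len(times):
        raise ValueError("timecourses must be subjects x times on the shared grid")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 subjects")

    def one(col):
        if col.std(ddof=1) == 0:
            # degenerate spread (e.g. every subject saturated at ceiling):
            # unanimous displacement is overwhelming evidence either way
            if col.mean() == null_value:
                return _interval_bf_from_t(0.0, len(col), prior_scale, prior_lower)
            return np.inf if col.mean() > null_value else np.finfo(float).tiny
        return interval_bf(col, null_value, prior_scale, prior_lower)

    bf = np.array([one(data[:, t]) for t in range(data.shape[1])])
    return BFSeries(times=times, bf10=bf, null_value=null_value, descriptor=descriptor)


def detect_onset(
    bf: BFSeries,
    threshold: float = DEFAULT_BF_THRESHOLD,
    n_consecutive: int = 3,
) -> float | None:
    """First timepoint of the earliest run of >= 3 consecutive BF10 > 10.

    Restricted to post-stimulus times (t >= 0); None when no such run
    exists (no reliable onset).
    """
    post = bf.times >= 0
    times = np.asarray(bf.times)[post]
    above = bf.bf10[post] > threshold
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= n_consecutive:
            return float(times[i - n_consecutive + 1])
    return None


def peak_time(times, group_mean) -> float:
    """Post-stimulus time of the maximum group mean; ties -> earliest."""
    times = np.asarray(times)
    group_mean = np.asarray(group_mean)
    post = times >= 0
    if not post.any():
        raise ValueError("no post-stimulus timepoints")
    return float(times[post][np.argmax(group_mean[post])])


def jackknife_ci(
    per_subject,
    times,
    estimator: str,
    null_value: float = 0.0,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    prior_lower: float = DEFAULT_PRIOR_LOWER,
    bf_threshold: float = DEFAULT_BF_THRESHOLD,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> OnsetPeakEstimate:
    """Leave-two-subjects-out jackknife CI for onset or peak latency.

    The estimator is recomputed on every C(n, 2) subset: for ``onset``
    the Bayes-factor series is recomputed on the reduced group and the
    onset rule reapplied; for ``peak`` the reduced group mean's maximum is
    taken.  The CI is the [2.5, 97.5] percentile range of the defined
    subset estimates; subsets with no defined onset are counted as missing.
    """
    data = np.asarray(per_subject, dtype=float)
    n = data.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects for a leave-two-out jackknife")
    if estimator == "onset" and n < 5:
        # leave-two-out subsets must still support a group Bayes factor
        raise ValueError("onset jackknife needs at least 5 subjects")
    if estimator not in ("onset", "peak"):
        raise ValueError("estimator must be 'onset' or 'peak'")

    def estimate(rows: np.ndarray):
        sub = data[rows]
        if estimator == "peak":
            return peak_time(times, sub.mean(axis=0))
        bf = bf_timecourse(sub, times, null_value, prior_scale, prior_lower)
        return detect_onset(bf, bf_threshold)

    point = estimate(np.arange(n))
    values = []
    n_missing = 0
    for drop in combinations(range(n), 2):
        keep = np.setdiff1d(np.arange(n), drop)
        est = estimate(keep)
        if est is None:
            n_missing += 1
        else:
            values.append(est)
    n_jack = comb(n, 2)
    if values:
        lo, hi = np.percentile(values, percentiles)
        ci = (float(lo), float(hi))
    else:
        ci = (None, None)
    return OnsetPeakEstimate(
        estimate_ms=point,
        ci_low=ci[0],
        ci_high=ci[1],
        n_jackknife=n_jack,
        n_missing=n_missing,
        kind=estimator,
    )


def subject_baseline_threshold(tc, percentile: float = 95.0):
    """Subject-level significance marks from the pre-stimulus baseline.

    The threshold is the given percentile of the subject's pre-stimulus
    (t < 0) accuracies; post-stimulus timepoints strictly above it are
    marked.  Returns (threshold, marked_times).
    """
    times = np.asarray(tc.times)
    acc = np.asarray(tc.accuracy)
    base = acc[times < 0]
    if len(base) < 5:
        raise ValueError("need at least 5 pre-stimulus timepoints")
    threshold = float(np.percentile(base, percentile))
    post = times >= 0
    marked = times[post][acc[post] > threshold]
    return threshold, marked


def compare_levels_bf(
    peak_window_means,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    prior_lower: float = DEFAULT_PRIOR_LOWER,
    threshold: float = DEFAULT_BF_THRESHOLD,
):
    """Pairwise paired-difference Bayes factors across conditions.

    ``peak_window_means``: (n_subjects, n_conditions).  For each condition
    pair a two-sided interval BF on the within-subject differences (null
    0) is computed.  Returns (bf_matrix, flags) with BF on the off-diagonal
    (NaN diagonal) and flags marking pairs with BF10 > threshold.
    """
    data = np.asarray(peak_window_means, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need subjects x >=2 conditions")
    k = data.shape[1]
    n = data.shape[0]
    bf = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i):
            diff = data[:, i] - data[:, j]
            if diff.std(ddof=1) == 0:
                # degenerate paired differences: exactly-identical conditions
                # carry no evidence for an effect; an exact constant shift is
                # infinitely strong evidence
                val = (
                    _interval_bf_from_t(0.0, n, prior_scale, prior_lower, True)
                    if diff.mean() == 0
                    else np.inf
                )
            else:
                val = interval_bf(diff, 0.0, prior_scale, prior_lower, two_sided=True)
            bf[i, j] = bf[j, i] = val
    flags = bf > threshold
    return bf, flags
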