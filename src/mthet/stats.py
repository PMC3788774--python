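"""Proportion estimates, ratio summaries and association tests.

Frequencies are reported as ``FrequencyEstimate`` objects carrying the raw
count, denominator, percentage and a 95% interval.  The default interval is
the Wilson score interval; a Jeffreys-prior (Bayesian) interval is available
as an alternative.  Percentages are held unrounded internally; rounding is a
display concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .errors import ValidationError


@dataclass(frozen=True)
class FrequencyEstimate:
    """A count k out of n with its percentage and 95% interval (in %)."""

    k: int
    n: int
    pct: float
    ci_low: float
    ci_high: float
    method: str = "wilson"

    def __str__(self) -> str:  # e.g. "61.39 (51.6-70.3)"
        return f"{self.pct:.2f} ({self.ci_low:.1f}-{self.ci_high:.1f})"


def freq_with_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> FrequencyEstimate:
    """Binomial proportion with a two-sided confidence/credible interval.

    ``method`` is "wilson" (score interval, default) or "jeffreys"
    (Beta(1/2,1/2)-prior equal-tailed credible interval).
    """
    if n < 1:
        raise ValidationError("denominator n must be >= 1")
    if not (0 <= k <= n):
        raise ValidationError(f"count k={k} outside 0..{n}")
    if method not in ("wilson", "jeffreys"):
        raise ValidationError(f"unknown interval method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method=method)
    p = k / n
    # guard the interval invariants against floating-point fuzz at 0/1
    lo = min(max(float(lo), 0.0), p)
    hi = max(min(float(hi), 1.0), p)
    return FrequencyEstimate(
        k=k, n=n, pct=100.0 * p, ci_low=100.0 * lo, ci_high=100.0 * hi,
        method=method,
    )


# -- ratio summaries (transition:transversion etc.) ------------------------


def format_ratio(a: int, b: int, sigfigs: int = 3) -> str:
    """Express a:b scaled so the smaller side is 1 ("15.5:1" or "1:1.31").

    A zero denominator yields the sentinel "∞:1" (or "1:∞"), never a
    division failure; 0:0 is reported as "0:0".
    """
    if a == 0 and b == 0:
        return "0:0"
    if b == 0:
        return "∞:1"
    if a == 0:
        return "1:∞"

    def fmt(x: float) -> str:
        s = f"{x:.{max(sigfigs - int(math.floor(math.log10(abs(x)))) - 1, 0)}f}"
        return s.rstrip("0").rstrip(".") if "." in s else s

    if a >= b:
        return f"{fmt(a / b)}:1"
    return f"1:{fmt(b / a)}"


@dataclass(frozen=True)
class RatioSummary:
    """Mutational-spectrum counts and their headline ratios."""

    ts: int  # transitions
    tv: int  # transversions
    purine_ts: int
    pyrimidine_ts: int
    ns: int  # non-synonymous events (protein positions)
    syn: int  # synonymous events

    def __post_init__(self):
        if self.ts != self.purine_ts + self.pyrimidine_ts:
            raise ValidationError(
                "transitions must split into purine + pyrimidine transitions"
            )
        if min(self.ts, self.tv, self.ns, self.syn) < 0:
            raise ValidationError("counts must be nonnegative")

    @property
    def ts_tv(self) -> float:
        return self.ts / self.tv if self.tv else math.inf

    @property
    def purine_pyrimidine(self) -> float:
        return self.purine_ts / self.pyrimidine_ts if self.pyrimidine_ts else math.inf

    @property
    def ns_syn(self) -> float:
        return self.ns / self.syn if self.syn else math.inf

    @property
    def ts_tv_str(self) -> str:
        return format_ratio(self.ts, self.tv)

    @property
    def purine_pyrimidine_str(self) -> str:
        return format_ratio(self.purine_ts, self.pyrimidine_ts)

    @property
    def ns_syn_str(self) -> str:
        return format_ratio(self.ns, self.syn)


def ratio_summary(classified) -> RatioSummary:
    """Summarise a collection of :class:`~mthet.genome_map.SubstitutionClass`.

    Non-synonymous counts stop-gain/stop-loss events together with amino-acid
    replacements; synonymous counts only exact amino-acid conservation.
    """
    ts = tv = pur = pyr = ns = syn = 0
    for c in classified:
        if c.change_kind == "transition":
            ts += 1
            if c.base_class == "purine":
                pur += 1
            else:
                pyr += 1
        else:
            tv += 1
        if c.coding_effect is not None:
            if c.coding_effect.effect == "synonymous":
                syn += 1
            else:
                ns += 1
    return RatioSummary(ts=ts, tv=tv, purine_ts=pur, pyrimidine_ts=pyr, ns=ns, syn=syn)


# -- hypothesis tests ------------------------------------------------------


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided z test for the difference of two proportions (pooled variance)."""
    if n1 < 1 or n2 < 1:
        raise ValidationError("both sample sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("counts outside their denominators")
    if k1 == k2 == 0 or (k1 == n1 and k2 == n2):
        return 0.0, 1.0  # pooled variance is zero; proportions are equal
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def chi_squared_2x2(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared test; no continuity correction by default."""
    t = np.asarray(table, dtype=float)
    _check_table(t)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("degenerate margins: a row or column sums to zero")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=correction)
    return float(chi2), int(df), float(p)


def fisher_exact(
    table, n_mc: int = 20000, seed: int | None = None, force_mc: bool = False
) -> float:
    """Fisher's exact test p-value for an r x c contingency table.

    Exact for 2x2 tables; larger tables use a Monte-Carlo estimate over
    ``n_mc`` tables drawn from the null (fixed-margins) distribution, with an
    explicit ``seed`` for reproducibility.  The Monte-Carlo p-value uses the
    standard (1 + more-extreme) / (1 + n_mc) estimator on the null
    probability ordering.  ``force_mc`` runs the Monte-Carlo path on a 2x2
    table too (used to validate the estimator against the exact value).
    """
    t = np.asarray(table, dtype=int)
    _check_table(t)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("degenerate margins: a row or column sums to zero")
    if t.shape == (2, 2) and not force_mc:
        return float(sps.fisher_exact(t)[1])
    rng = np.random.default_rng(seed)
    dist = sps.random_table(t.sum(axis=1), t.sum(axis=0))
    logp_obs = _table_log_prob(t)
    draws = dist.rvs(n_mc, random_state=rng).astype(int)
    logps = np.array([_table_log_prob(d) for d in draws])
    hits = int((logps <= logp_obs + 1e-9).sum())
    return (1 + hits) / (1 + n_mc)


def _table_log_prob(t: np.ndarray) -> float:
    """Log null probability of a table with fixed margins (hypergeometric)."""
    from scipy.special import gammaln

    n = t.sum()
    return float(
        gammaln(t.sum(axis=1) + 1).sum()
        + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def _check_table(t: np.ndarray) -> None:
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValidationError("contingency table entries must be nonnegative")


def bonferroni(p_values, m: int | None = None):
    """Bonferroni-adjusted p-values: min(1, m*p).

    Accepts a scalar or a sequence; ``m`` defaults to the number of p-values
    supplied and must be at least that number.
    """
    arr = np.atleast_1d(np.asarray(p_values, dtype=float))
    if ((arr < 0) | (arr > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if m is None:
        m = arr.size
    if m < arr.size:
        raise ValidationError("m must be >= the number of tests")
    adj = np.minimum(1.0, m * arr)
    return float(adj[0]) if np.isscalar(p_values) else adj
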