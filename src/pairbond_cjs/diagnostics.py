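"""Monte-Carlo performance metrics and overdispersion diagnostics.

Three families of checks on the CJS fits:

* coverage metrics for replicated simulations — mean relative bias
  B = (mean(phi_hat) - phi) / phi, mean relative 95% CI width
  R = mean(UB - LB) / phi, and coverage C = fraction of intervals
  containing the truth;
* the likelihood-ratio test of a sex effect, G^2 = 2 * (general - reduced
  log-likelihood), referred to chi-square with df equal to the parameter
  difference;
* the deviance variance-inflation factor c-hat = deviance / df, its
  chi-square(df)/df null reference, the median-c-hat point estimator, and
  a split-by-sex diagnostic that localizes overdispersion caused by
  within-pair correlation (it inflates the pooled c-hat but not the
  single-sex ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cjs import (
    CJSFit,
    HistoryCounts,
    ModelStructure,
    expected_history_probabilities,
    fit_cjs,
)
from .simulator import CaptureDataset

__all__ = [
    "MonteCarloMetrics",
    "LRTResult",
    "ChatEstimate",
    "SexSplitChat",
    "relative_bias",
    "relative_ci_width",
    "ci_coverage",
    "summarize_interval_estimates",
    "likelihood_ratio_test",
    "chat_deviance",
    "chat_median",
    "chat_reference_density",
    "chat_reference_median",
    "split_by_sex_chat_diagnostic",
    "pearson_chat",
]


@dataclass(frozen=True)
class MonteCarloMetrics:
    """Replicated-simulation summary for one interval estimator."""

    mean_estimate: float
    relative_bias: float
    mean_relative_ci_width: float
    coverage: float
    mc_std_error: float
    n_replicates: int


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.size == 0:
        raise ValueError(f"{name} must be nonempty")
    return a


def relative_bias(estimates: Sequence[float], truth: float) -> float:
    """(mean(estimates) - truth) / truth."""
    if truth <= 0:
        raise ValueError("truth must be positive")
    return float(_as_array(estimates, "estimates").mean() - truth) / truth


def relative_ci_width(
    lower: Sequence[float], upper: Sequence[float], truth: float
) -> float:
    """mean(upper - lower) / truth."""
    if truth <= 0:
        raise ValueError("truth must be positive")
    lo = _as_array(lower, "lower")
    hi = _as_array(upper, "upper")
    if lo.shape != hi.shape:
        raise ValueError("lower and upper must have equal lengths")
    if (lo > hi).any():
        raise ValueError("found an interval with lower > upper")
    return float((hi - lo).mean()) / truth


def ci_coverage(
    lower: Sequence[float], upper: Sequence[float], truth: float
) -> float:
    """Fraction of intervals [lower_k, upper_k] containing the truth."""
    lo = _as_array(lower, "lower")
    hi = _as_array(upper, "upper")
    if lo.shape != hi.shape:
        raise ValueError("lower and upper must have equal lengths")
    return float(((lo <= truth) & (truth <= hi)).mean())


def summarize_interval_estimates(
    estimates: Sequence[float],
    lower: Sequence[float],
    upper: Sequence[float],
    truth: float,
) -> MonteCarloMetrics:
    """Bundle B, R, C and the Monte-Carlo standard error of the mean."""
    est = _as_array(estimates, "estimates")
    return MonteCarloMetrics(
        mean_estimate=float(est.mean()),
        relative_bias=relative_bias(est, truth),
        mean_relative_ci_width=relative_ci_width(lower, upper, truth),
        coverage=ci_coverage(lower, upper, truth),
        mc_std_error=float(est.std(ddof=1) / np.sqrt(est.size)) if est.size > 1 else 0.0,
        n_replicates=int(est.size),
    )


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of a general against a nested CJS structure."""

    deviance_stat: float
    df: int
    p_value: float
    reliable: bool = True


def likelihood_ratio_test(general: CJSFit, reduced: CJSFit) -> LRTResult:
    """G^2 = 2 * (general - reduced log-likelihood) against chi-square(df).

    ``reduced`` must be strictly nested in ``general``; both fits must come
    from the same data.  A non-converged input flags the result as
    unreliable rather than raising.
    """
    if not reduced.structure.is_nested_in(general.structure):
        raise ValueError(
            f"{reduced.structure.name} is not nested in {general.structure.name}"
        )
    df = general.n_parameters - reduced.n_parameters
    if df <= 0:
        raise ValueError("general model must have strictly more parameters")
    g2 = 2.0 * (general.log_lik - reduced.log_lik)
    if g2 < -1e-8:
        warnings.warn(
            f"negative LRT statistic {g2:.3g}; check convergence", stacklevel=2
        )
    g2 = max(g2, 0.0)
    return LRTResult(
        deviance_stat=g2,
        df=df,
        p_value=float(stats.chi2.sf(g2, df)),
        reliable=general.converged and reduced.converged,
    )


@dataclass
class ChatEstimate:
    """Per-replicate deviance c-hat values for one model structure."""

    chat_samples: np.ndarray
    model: ModelStructure

    def __post_init__(self):
        self.chat_samples = np.asarray(self.chat_samples, dtype=float)
        if self.chat_samples.size == 0:
            raise ValueError("need at least one c-hat sample")

    @property
    def chat_median(self) -> float:
        return float(np.median(self.chat_samples))


def chat_deviance(fit: CJSFit) -> float:
    """Deviance variance-inflation factor, deviance / df."""
    if fit.df_deviance <= 0:
        raise ValueError("df_deviance must be positive")
    return fit.deviance / fit.df_deviance


def chat_median(samples: Sequence[float]) -> float:
    """Median of a sample of c-hat values (the median-c-hat estimator)."""
    return float(np.median(_as_array(samples, "samples")))


def chat_reference_density(
    df: int, draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws from the chi-square(df)/df null reference for c-hat."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return rng.chisquare(df, size=draws) / df


def chat_reference_median(df: int) -> float:
    """Analytic median of chi-square(df)/df."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(0.5, df) / df)


@dataclass(frozen=True)
class SexSplitChat:
    """Pooled and per-sex deviance c-hat values under the pooled model."""

    pooled: float
    female: float | None
    male: float | None


def split_by_sex_chat_diagnostic(data: CaptureDataset) -> SexSplitChat:
    """c-hat for the full data and for each single-sex subset under (phi,p).

    Overdispersion caused by within-pair correlation inflates only the
    pooled value: each single-sex subset contains one member per pair, so
    its fates are independent and its c-hat sits near 1.  If both the
    pooled and the per-sex values are elevated, the extra-binomial
    variation has another source.
    """
    pooled_model = ModelStructure(False, False)
    counts = HistoryCounts.from_dataset(data)
    result: dict[str, float | None] = {"F": None, "M": None}
    for g in ("F", "M"):
        if g not in counts.groups:
            warnings.warn(f"sex {g!r} absent from the data", stacklevel=2)
            continue
        sub = HistoryCounts(counts.n_occasions, {g: counts.counts[g].copy()})
        result[g] = chat_deviance(fit_cjs(sub, pooled_model))
    return SexSplitChat(
        pooled=chat_deviance(fit_cjs(counts, pooled_model)),
        female=result["F"],
        male=result["M"],
    )


def pearson_chat(fit: CJSFit, counts: HistoryCounts) -> float:
    """Pearson X^2 / df overdispersion estimate at the fitted parameters.

    Cells with essentially zero expected count are pooled into the
    never-seen-again cell of their group to avoid division blow-ups.
    """
    T = counts.n_occasions
    never_seen = "1" + "0" * (T - 1)
    x2 = 0.0
    for g, vec in counts.counts.items():
        phi = fit.estimates.get("phi", fit.estimates.get(f"phi_{g.lower()}"))
        p = fit.estimates.get("p", fit.estimates.get(f"p_{g.lower()}"))
        probs = expected_history_probabilities(phi, p, T)
        n = vec.sum()
        expected = {h: n * probs[h] for h in counts.histories}
        observed = dict(zip(counts.histories, vec.astype(float)))
        for h in counts.histories:
            if h != never_seen and expected[h] < 1e-9:
                expected[never_seen] += expected.pop(h)
                observed[never_seen] += observed.pop(h)
        for h, e in expected.items():
            if e > 0:
                x2 += (observed[h] - e) ** 2 / e
    if fit.df_deviance <= 0:
        raise ValueError("df_deviance must be positive")
    return x2 / fit.df_deviance
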