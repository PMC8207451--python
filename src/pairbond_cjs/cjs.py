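"""Single-cohort Cormack-Jolly-Seber likelihood and maximum-likelihood fitter.

The data are the counts of the 2**(T-1) observable encounter histories
(all beginning with 1) for each sex group.  With constant survival phi and
recapture p, the probability of a history factorizes into per-interval
survival/capture terms times the probability of never being seen after the
last capture (the chi recursion):

    chi_T = 1,   chi_t = (1 - phi) + phi * (1 - p) * chi_{t+1}

Four model structures are supported: survival and/or recapture may carry a
sex effect, giving {(phi,p), (phiG,p), (phi,pG), (phiG,pG)} with 2-4 free
parameters.  Estimation is by quasi-Newton maximization of the
product-multinomial likelihood on the logit scale with analytic gradients;
Wald 95% intervals are formed on the logit scale from the inverse observed
information and back-transformed.

The deviance is measured against the saturated multinomial over the
*observed* encounter histories: per sex group when the structure carries
any sex effect, and over the sexes pooled for the fully pooled (phi,p)
structure (which treats the data as a single undifferentiated sample).
df_deviance = (number of observed distinct histories - 1 per saturated
group) - (number of model parameters); unobserved cells contribute
neither to the saturated likelihood (0*log 0 = 0) nor to the df.  This
bookkeeping is what makes duplicated data (perfect pair correlation)
double the pooled model's variance-inflation factor.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logit
from statsmodels.tools import numdiff

from .simulator import CaptureDataset

__all__ = [
    "ModelStructure",
    "ALL_STRUCTURES",
    "structure_from_name",
    "HistoryCounts",
    "CJSFit",
    "observable_histories",
    "history_probability",
    "expected_history_probabilities",
    "negative_log_likelihood",
    "saturated_log_likelihood",
    "fit_cjs",
]

#: Estimates within this distance of 0 or 1 are flagged as boundary fits.
BOUNDARY_TOL = 1e-6

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ModelStructure:
    """Which CJS parameters carry a sex-specific effect."""

    survival_by_sex: bool = False
    recapture_by_sex: bool = False

    @property
    def name(self) -> str:
        phi = "phiG" if self.survival_by_sex else "phi"
        p = "pG" if self.recapture_by_sex else "p"
        return f"({phi},{p})"

    @property
    def parameter_names(self) -> tuple[str, ...]:
        phi = ("phi_f", "phi_m") if self.survival_by_sex else ("phi",)
        p = ("p_f", "p_m") if self.recapture_by_sex else ("p",)
        return phi + p

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def is_nested_in(self, other: "ModelStructure") -> bool:
        return (
            self.survival_by_sex <= other.survival_by_sex
            and self.recapture_by_sex <= other.recapture_by_sex
        )


ALL_STRUCTURES = (
    ModelStructure(False, False),
    ModelStructure(True, False),
    ModelStructure(False, True),
    ModelStructure(True, True),
)

_NAME_TO_STRUCTURE = {s.name: s for s in ALL_STRUCTURES}
# convenient aliases: "phi.p", "phiG.pG", ...
_NAME_TO_STRUCTURE.update(
    {s.name.strip("()").replace(",", "."): s for s in ALL_STRUCTURES}
)


def structure_from_name(name: str) -> ModelStructure:
    try:
        return _NAME_TO_STRUCTURE[name]
    except KeyError:
        raise ValueError(
            f"unknown model structure {name!r}; choose from "
            f"{sorted(set(_NAME_TO_STRUCTURE))}"
        ) from None


def observable_histories(n_occasions: int) -> list[str]:
    """The 2**(T-1) single-cohort histories, all released at occasion 1."""
    if n_occasions < 2:
        raise ValueError("need at least two occasions")
    return [
        "1" + "".join(bits)
        for bits in itertools.product("01", repeat=n_occasions - 1)
    ]


def _chi(phi: float, p: float, T: int) -> np.ndarray:
    """chi[t] = P(never seen after occasion t | alive at t), 1-based index."""
    chi = np.ones(T + 1)
    for t in range(T - 1, 0, -1):
        chi[t] = (1.0 - phi) + phi * (1.0 - p) * chi[t + 1]
    return chi


def history_probability(history: str, phi: float, p: float) -> float:
    """Probability of one encounter history given release at occasion 1."""
    if not history or history[0] != "1":
        raise ValueError(
            f"history {history!r} must begin with 1 (single-cohort conditioning)"
        )
    if not (0.0 < phi <= 1.0 and 0.0 < p <= 1.0):
        raise ValueError("phi and p must lie in (0, 1]")
    T = len(history)
    x = np.array([int(c) for c in history])
    last = int(np.max(np.flatnonzero(x))) + 1  # 1-based last capture
    chi = _chi(phi, p, T)
    prob = chi[last]
    for t in range(2, last + 1):
        prob *= phi * (p if x[t - 1] else 1.0 - p)
    return float(prob)


def expected_history_probabilities(
    phi: float, p: float, n_occasions: int = 4
) -> dict[str, float]:
    """Map each observable history to its cell probability (sums to 1)."""
    return {
        h: history_probability(h, phi, p)
        for h in observable_histories(n_occasions)
    }


# --------------------------------------------------------------------------
# Sufficient statistics


@dataclass
class HistoryCounts:
    """Per-sex counts of the observable single-cohort histories.

    Counts are held as floats so that expectation-valued pseudo-data
    (expected cell counts) can be fitted as well as integer tallies.
    """

    n_occasions: int
    counts: dict[str, np.ndarray]  # group label -> vector over histories

    def __post_init__(self):
        self.histories = observable_histories(self.n_occasions)
        for g, c in self.counts.items():
            c = np.asarray(c, dtype=np.float64)
            if c.shape != (len(self.histories),) or (c < 0).any():
                raise ValueError(
                    f"group {g!r} counts must be nonnegative with one cell "
                    f"per observable history"
                )
            self.counts[g] = c

    @classmethod
    def from_dataset(cls, data: CaptureDataset) -> "HistoryCounts":
        hist_index = {h: i for i, h in enumerate(observable_histories(data.n_occasions))}
        counts: dict[str, np.ndarray] = {}
        for g in ("F", "M"):
            mask = data.sex == g
            if not mask.any():
                continue
            vec = np.zeros(len(hist_index), dtype=np.int64)
            for row in np.asarray(data.histories)[mask]:
                vec[hist_index["".join(map(str, row))]] += 1
            counts[g] = vec
        return cls(data.n_occasions, counts)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def total(self, group: str) -> float:
        return float(self.counts[group].sum())

    def pooled(self) -> np.ndarray:
        return sum(self.counts.values())


# --------------------------------------------------------------------------
# Likelihood


def _history_design(T: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-history (last capture occasion, number of recaptures <= last)."""
    last = []
    caps = []
    for h in observable_histories(T):
        x = [int(c) for c in h]
        l = max(i for i, v in enumerate(x) if v) + 1
        last.append(l)
        caps.append(sum(x[1:l]))
    return np.array(last), np.array(caps)


_DESIGN_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _cell_logprobs(phi: float, p: float, T: int):
    """Log cell probabilities and their gradients w.r.t. (phi, p).

    Returns (logp, dlogp_dphi, dlogp_dp), each a vector over the
    observable histories.  Valid for phi, p strictly inside (0, 1).
    """
    if T not in _DESIGN_CACHE:
        _DESIGN_CACHE[T] = _history_design(T)
    last, caps = _DESIGN_CACHE[T]

    chi = np.ones(T + 1)
    dchi_phi = np.zeros(T + 1)
    dchi_p = np.zeros(T + 1)
    for t in range(T - 1, 0, -1):
        dchi_phi[t] = -1.0 + (1.0 - p) * chi[t + 1] + phi * (1.0 - p) * dchi_phi[t + 1]
        dchi_p[t] = -phi * chi[t + 1] + phi * (1.0 - p) * dchi_p[t + 1]
        chi[t] = (1.0 - phi) + phi * (1.0 - p) * chi[t + 1]

    n_int = last - 1  # survival intervals up to last capture
    logp = (
        n_int * math.log(phi)
        + caps * math.log(p)
        + (n_int - caps) * math.log(1.0 - p)
        + np.log(chi[last])
    )
    dphi = n_int / phi + dchi_phi[last] / chi[last]
    dp = caps / p - (n_int - caps) / (1.0 - p) + dchi_p[last] / chi[last]
    return logp, dphi, dp


def _unpack(theta: np.ndarray, structure: ModelStructure):
    """Map the logit-scale vector to per-group (phi, p) and slot indices."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (structure.n_parameters,):
        raise ValueError(
            f"expected {structure.n_parameters} parameters for "
            f"{structure.name}, got {theta.shape}"
        )
    # clip keeps logs and divisions finite at extreme logits
    probs = np.clip(expit(theta), 1e-12, 1.0 - 1e-12)
    off = 2 if structure.survival_by_sex else 1

    def phi_idx(group: str) -> int:
        return {"F": 0, "M": 1}[group] if structure.survival_by_sex else 0

    def p_idx(group: str) -> int:
        return off + ({"F": 0, "M": 1}[group] if structure.recapture_by_sex else 0)

    return probs, phi_idx, p_idx


def _nll_and_grad(theta, counts: HistoryCounts, structure: ModelStructure):
    probs, phi_idx, p_idx = _unpack(theta, structure)
    T = counts.n_occasions
    nll = 0.0
    grad_prob = np.zeros(structure.n_parameters)
    for g, vec in counts.counts.items():
        phi, p = probs[phi_idx(g)], probs[p_idx(g)]
        logp, dphi, dp = _cell_logprobs(phi, p, T)
        nll -= float(vec @ logp)
        grad_prob[phi_idx(g)] -= float(vec @ dphi)
        grad_prob[p_idx(g)] -= float(vec @ dp)
    grad = grad_prob * probs * (1.0 - probs)  # chain rule through expit
    return nll, grad


def negative_log_likelihood(
    params, counts: HistoryCounts, structure: ModelStructure
) -> float:
    """Negative log-likelihood at a logit-scale parameter vector.

    Returns +inf (rather than raising) when a positive-count cell has zero
    probability, so optimizers can probe freely.
    """
    try:
        value, _ = _nll_and_grad(np.asarray(params, dtype=float), counts, structure)
    except (FloatingPointError, ZeroDivisionError):
        return math.inf
    return value if np.isfinite(value) else math.inf


def saturated_log_likelihood(counts: HistoryCounts) -> float:
    """Log-likelihood of the per-group saturated multinomial.

    Each group's cell probability is its empirical frequency; 0*log(0) = 0.
    This upper-bounds the log-likelihood of every CJS structure.
    """
    total = 0.0
    for vec in counts.counts.values():
        n = vec.sum()
        if n == 0:
            continue
        pos = vec[vec > 0]
        total += float(pos @ np.log(pos / n))
    return total


# --------------------------------------------------------------------------
# Fitting


@dataclass
class CJSFit:
    """Maximum-likelihood fit of one CJS structure."""

    structure: ModelStructure
    estimates: dict[str, float]
    std_errors: dict[str, float]  # on the logit (estimation) scale
    ci_lower: dict[str, float]  # back-transformed 95% bounds
    ci_upper: dict[str, float]
    log_lik: float
    deviance: float
    df_deviance: int
    converged: bool
    boundary: bool = False
    n_released: dict[str, int] = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return self.structure.n_parameters

    def to_row(self) -> dict[str, float | str | bool]:
        """Flatten into one serializable report row."""
        row: dict[str, float | str | bool] = {
            "model": self.structure.name,
            "log_lik": self.log_lik,
            "deviance": self.deviance,
            "df_deviance": self.df_deviance,
            "converged": self.converged,
            "boundary": self.boundary,
        }
        for name in self.structure.parameter_names:
            row[name] = self.estimates[name]
            row[f"se_logit_{name}"] = self.std_errors[name]
            row[f"lcl_{name}"] = self.ci_lower[name]
            row[f"ucl_{name}"] = self.ci_upper[name]
        return row


def _starting_points(counts: HistoryCounts, k: int) -> list[np.ndarray]:
    """Three deterministic starts: neutral, data heuristic, and random."""
    starts = [np.zeros(k)]
    pooled = counts.pooled()
    total = pooled.sum()
    if total > 0:
        # fraction of released animals ever seen again
        seen_again = sum(
            c
            for h, c in zip(counts.histories, pooled)
            if "1" in h[1:]
        )
        frac = min(max(seen_again / total, 0.05), 0.95)
        starts.append(np.full(k, logit(frac)))
    starts.append(np.random.default_rng(878986).normal(0.0, 1.5, size=k))
    return starts


def fit_cjs(
    data: HistoryCounts | CaptureDataset, structure: ModelStructure
) -> CJSFit:
    """Fit one CJS structure by maximum likelihood.

    Quasi-Newton (BFGS) on the logit scale with analytic gradients and
    three starting points; standard errors from the numerically
    differentiated observed information at the optimum.
    """
    counts = (
        data if isinstance(data, HistoryCounts) else HistoryCounts.from_dataset(data)
    )
    if not counts.counts or all(v.sum() == 0 for v in counts.counts.values()):
        raise ValueError("no released animals in the data")
    if (structure.survival_by_sex or structure.recapture_by_sex) and len(
        counts.groups
    ) < 2:
        raise ValueError(
            f"structure {structure.name} needs both sexes present; "
            f"got groups {counts.groups}"
        )
    k = structure.n_parameters

    best = None
    for x0 in _starting_points(counts, k):
        res = optimize.minimize(
            _nll_and_grad,
            x0,
            args=(counts, structure),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta = best.x
    grad_norm = float(np.linalg.norm(best.jac))
    converged = bool(best.success) or grad_norm < 1e-5

    probs = expit(theta)
    boundary = bool(np.any(probs < BOUNDARY_TOL) | np.any(probs > 1 - BOUNDARY_TOL))

    hess = numdiff.approx_hess1(
        theta, lambda th: _nll_and_grad(th, counts, structure)[0]
    )
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.diag(cov))
            se = np.where(np.isfinite(se), se, np.inf)
        except np.linalg.LinAlgError:
            se = np.full(k, np.inf)

    names = structure.parameter_names
    estimates = dict(zip(names, expit(theta)))
    std_errors = dict(zip(names, se))
    ci_lower = dict(zip(names, expit(theta - _Z95 * se)))
    ci_upper = dict(zip(names, expit(theta + _Z95 * se)))

    log_lik = -float(best.fun)
    # The fully pooled structure sees the data as one undifferentiated
    # sample, so its saturated reference pools the sexes; any sex-effect
    # structure is referred to the per-group saturated model.  Only
    # observed histories enter the saturated cell count.
    if structure.survival_by_sex or structure.recapture_by_sex:
        sat_counts = counts
    else:
        sat_counts = HistoryCounts(counts.n_occasions, {"all": counts.pooled()})
    sat = saturated_log_likelihood(sat_counts)
    deviance = max(2.0 * (sat - log_lik), 0.0)
    df = (
        sum(int((v > 0).sum()) - 1 for v in sat_counts.counts.values() if v.sum())
        - k
    )

    return CJSFit(
        structure=structure,
        estimates=estimates,
        std_errors=std_errors,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        log_lik=log_lik,
        deviance=deviance,
        df_deviance=df,
        converged=converged,
        boundary=boundary,
        n_released={g: counts.total(g) for g in counts.groups},
    )
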