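"""Disproportionality statistics on 2x2 report/reaction tables.

Four families of signal statistics are provided, each with an interval
estimate:

* ROR — reporting odds ratio (a·d)/(b·c) with a Wald interval on the log
  scale, exp(ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d)).
* PRR — proportional reporting ratio [a/(a+b)]/[c/(c+d)] with
  exp(ln PRR ± z·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d))), plus the Pearson
  chi-square on the 2x2.
* BCPNN information component — IC = log2 of the observed-to-expected
  reporting ratio p11/(p1·p2) under independent Beta posteriors for the
  cell and margin probabilities, with the joint-cell prior scaled so the
  prior expectation of IC is zero.  The closed form uses the exact
  digamma/trigamma posterior moments; a Monte-Carlo evaluator of the same
  posterior is provided as an independent route.  IC025 is the lower
  credibility bound mean − z·sd.
* MGPS — empirical-Bayes gamma-Poisson shrinkage of a/E, where
  E = (a+b)(a+c)/N.  The prior is a two-component gamma mixture
  (shape/rate) fitted by maximum likelihood of the implied
  negative-binomial mixture over all cells of an analysis; EBGM is the
  posterior geometric mean of the reporting-rate ratio and EB05 its 5th
  percentile.

Zero-cell policy: when a table contains a zero, ROR/PRR intervals are
computed from Haldane–Anscombe +0.5-corrected cells and flagged
``corrected``; the raw point estimate is kept whenever it is defined
(e.g. a = 0 gives a raw estimate of 0).  The Bayesian statistics need no
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, PositiveFloat
from scipy import optimize, special
from scipy import stats as sps

from .contingency import ContingencyTable
from .exceptions import ConvergenceError, UndefinedResultError, ValidationError

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Estimate:
    """Point estimate with a two-sided interval."""

    value: float
    low: float
    high: float
    corrected: bool = False


def _corrected_cells(table: ContingencyTable) -> tuple:
    return (table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5)


def ror(table: ContingencyTable, *, z: float = 1.96,
        zero_cell: Literal["correct", "error"] = "correct") -> Estimate:
    """Reporting odds ratio with its Wald 95% (z=1.96) interval."""
    if table.n <= 0:
        raise UndefinedResultError("empty table")
    a, b, c, d = table.as_tuple()
    has_zero = min(a, b, c, d) == 0
    if b * c == 0 and zero_cell == "error":
        raise UndefinedResultError(
            "ROR undefined for b*c = 0 with the continuity correction disabled"
        )
    if has_zero:
        ca, cb, cc, cd = _corrected_cells(table)
        value = (a * d) / (b * c) if b * c > 0 else (ca * cd) / (cb * cc)
        log_est = math.log((ca * cd) / (cb * cc))
        se = math.sqrt(1 / ca + 1 / cb + 1 / cc + 1 / cd)
        return Estimate(value=value, low=math.exp(log_est - z * se),
                        high=math.exp(log_est + z * se), corrected=True)
    value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return Estimate(value=value, low=value * math.exp(-z * se),
                    high=value * math.exp(z * se))


def prr(table: ContingencyTable, *, z: float = 1.96,
        zero_cell: Literal["correct", "error"] = "correct") -> Estimate:
    """Proportional reporting ratio with its Wald 95% interval."""
    a, b, c, d = table.as_tuple()
    if a + b == 0 or c + d == 0:
        raise UndefinedResultError("PRR needs positive row margins")
    has_zero = min(a, b, c, d) == 0
    if c == 0 and zero_cell == "error":
        raise UndefinedResultError(
            "PRR undefined for c = 0 with the continuity correction disabled"
        )
    if has_zero:
        ca, cb, cc, cd = _corrected_cells(table)
        value = (a / (a + b)) / (c / (c + d)) if c > 0 else \
            (ca / (ca + cb)) / (cc / (cc + cd))
        log_est = math.log((ca / (ca + cb)) / (cc / (cc + cd)))
        se = math.sqrt(1 / ca - 1 / (ca + cb) + 1 / cc - 1 / (cc + cd))
        return Estimate(value=value, low=math.exp(log_est - z * se),
                        high=math.exp(log_est + z * se), corrected=True)
    value = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return Estimate(value=value, low=value * math.exp(-z * se),
                    high=value * math.exp(z * se))


def chi_square(table: ContingencyTable, yates: bool = False) -> tuple:
    """Pearson chi-square (df = 1) on the 2x2; optional Yates correction."""
    a, b, c, d = table.as_tuple()
    arr = np.array([[a, b], [c, d]], dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("chi-square needs positive margins")
    res = sps.chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------

class BCPNNConfig(BaseModel):
    """Hyperparameters of the Bayesian information-component model.

    ``alpha1``/``beta1`` shape the marginal Beta priors, ``alpha``/``beta``
    their totals; ``gamma11`` is the joint-cell prior count whose
    companion total is scaled so the prior IC expectation is zero.
    ``method`` switches between the exact posterior moments and the
    one-parameter gamma approximation IC = log2((a+0.5)/(E+0.5)).
    """

    model_config = ConfigDict(frozen=True)

    alpha1: PositiveFloat = 1.0
    beta1: PositiveFloat = 1.0
    alpha: PositiveFloat = 2.0
    beta: PositiveFloat = 2.0
    gamma11: PositiveFloat = 1.0
    z: PositiveFloat = 1.96
    method: Literal["moments", "gamma-approx"] = "moments"


DEFAULT_BCPNN = BCPNNConfig()


@dataclass(frozen=True)
class ICResult:
    """Posterior mean of IC, its variance, and the lower credibility bound."""

    ic: float
    variance: float
    ic025: float


def _beta_parameters(table: ContingencyTable, config: BCPNNConfig):
    """Posterior Beta parameters for (p11, p1, p2)."""
    c11 = table.a
    c1 = table.a + table.b
    c2 = table.a + table.c
    n = table.n
    gamma = config.gamma11 * (n + config.alpha) * (n + config.beta) \
        / ((c1 + config.alpha1) * (c2 + config.beta1))
    return (
        (c11 + config.gamma11, n - c11 + gamma - config.gamma11),
        (c1 + config.alpha1, n - c1 + config.alpha - config.alpha1),
        (c2 + config.beta1, n - c2 + config.beta - config.beta1),
    )


def bcpnn_ic(table: ContingencyTable, config: BCPNNConfig = DEFAULT_BCPNN) -> ICResult:
    """Closed-form posterior mean/variance of the information component."""
    if table.n <= 0:
        raise UndefinedResultError("empty table")
    if config.method == "gamma-approx":
        e = table.expected
        ic = math.log2((table.a + 0.5) / (e + 0.5))
        q025 = special.gammaincinv(table.a + 0.5, 0.025) / (e + 0.5)
        # Delta-method variance of log2(lambda) for a Gamma(a+1/2) posterior.
        return ICResult(ic=ic, variance=1.0 / ((table.a + 0.5) * LN2 ** 2),
                        ic025=math.log2(q025))
    (a11, b11), (a1, b1), (a2, b2) = _beta_parameters(table, config)
    mean = (
        special.digamma(a11) - special.digamma(a11 + b11)
        - special.digamma(a1) + special.digamma(a1 + b1)
        - special.digamma(a2) + special.digamma(a2 + b2)
    ) / LN2
    var = (
        special.polygamma(1, a11) - special.polygamma(1, a11 + b11)
        + special.polygamma(1, a1) - special.polygamma(1, a1 + b1)
        + special.polygamma(1, a2) - special.polygamma(1, a2 + b2)
    ) / LN2 ** 2
    return ICResult(ic=float(mean), variance=float(var),
                    ic025=float(mean - config.z * math.sqrt(var)))


def bcpnn_ic_montecarlo(table: ContingencyTable,
                        config: BCPNNConfig = DEFAULT_BCPNN,
                        n_draws: int = 1_000_000,
                        rng=None) -> tuple:
    """Sampling evaluator of the same posterior: (mean, variance, mc_se).

    Draws the three posterior Beta variables and averages
    log2(p11/(p1·p2)); serves as an independent oracle for the closed
    form.
    """
    rng = np.random.default_rng(rng)
    (a11, b11), (a1, b1), (a2, b2) = _beta_parameters(table, config)
    draws = (
        np.log2(rng.beta(a11, b11, size=n_draws))
        - np.log2(rng.beta(a1, b1, size=n_draws))
        - np.log2(rng.beta(a2, b2, size=n_draws))
    )
    mean = float(draws.mean())
    var = float(draws.var(ddof=1))
    return mean, var, math.sqrt(var / n_draws)


# ---------------------------------------------------------------------------
# MGPS: two-component gamma-Poisson shrinker
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MGPSPrior:
    """Two-component gamma mixture prior on the reporting-rate ratio.

    Shape/rate parameterization; ``p`` is the weight of the first
    component.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float

    def __post_init__(self):
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.p <= 1:
            raise ValidationError("mixture weight p must be in (0, 1]")

    @property
    def mean(self) -> float:
        return self.p * self.alpha1 / self.beta1 \
            + (1 - self.p) * self.alpha2 / self.beta2

    def density(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        d1 = sps.gamma.pdf(lam, a=self.alpha1, scale=1 / self.beta1)
        d2 = sps.gamma.pdf(lam, a=self.alpha2, scale=1 / self.beta2)
        return self.p * d1 + (1 - self.p) * d2

    def log_marginal_components(self, a, e) -> tuple:
        """Per-component negative-binomial log pmfs of the observed counts.

        Written with gammaln directly (equivalent to nbinom.logpmf with
        success probability beta/(beta+E)) to keep the prior fit cheap.
        """
        a = np.asarray(a, dtype=float)
        e = np.asarray(e, dtype=float)

        def nb_logpmf(alpha, beta):
            return (
                special.gammaln(a + alpha) - special.gammaln(alpha)
                - special.gammaln(a + 1)
                + alpha * np.log(beta / (beta + e))
                + a * np.log(e / (beta + e))
            )

        return nb_logpmf(self.alpha1, self.beta1), nb_logpmf(self.alpha2, self.beta2)

    def log_marginal(self, a, e) -> np.ndarray:
        l1, l2 = self.log_marginal_components(a, e)
        if self.p >= 1.0:
            return l1
        return np.logaddexp(math.log(self.p) + l1, math.log1p(-self.p) + l2)


#: DuMouchel's canonical starting point for the prior fit.
CANONICAL_PRIOR = MGPSPrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, p=1 / 3)

_EXTRA_STARTS = (
    MGPSPrior(1.0, 1.0, 1.0, 1.0, 0.5),
    MGPSPrior(0.5, 0.5, 4.0, 8.0, 0.2),
    MGPSPrior(2.0, 4.0, 0.2, 0.1, 2 / 3),
    MGPSPrior(1.0, 2.0, 3.0, 1.0, 0.4),
)


@dataclass(frozen=True)
class MGPSFit:
    prior: MGPSPrior
    converged: bool
    loglik: float


def _pack(prior: MGPSPrior, fix_p) -> np.ndarray:
    x = [math.log(prior.alpha1), math.log(prior.beta1),
         math.log(prior.alpha2), math.log(prior.beta2)]
    if fix_p is None:
        x.append(special.logit(min(max(prior.p, 1e-6), 1 - 1e-6)))
    return np.array(x)


def _unpack(x: np.ndarray, fix_p) -> MGPSPrior:
    x = np.clip(x, -20, 20)
    p = float(special.expit(x[4])) if fix_p is None else float(fix_p)
    return MGPSPrior(alpha1=math.exp(x[0]), beta1=math.exp(x[1]),
                     alpha2=math.exp(x[2]), beta2=math.exp(x[3]), p=p)


def mgps_fit_prior(tables: Sequence[ContingencyTable], *,
                   fix_p: float | None = None,
                   tol: float = 1e-8) -> MGPSFit:
    """Maximum-likelihood fit of the gamma-mixture prior over all cells.

    The objective is the summed log of the two-component negative-binomial
    mixture of the ``a`` counts given their expectations E; optimization
    runs on log/logit-transformed parameters from five deterministic
    starts (the canonical start first).  ``fix_p`` freezes the mixture
    weight (``fix_p=1`` reduces the fit to a single gamma component).
    """
    if len(tables) < 20:
        raise ValidationError(
            f"need >= 20 tables to identify 5 prior parameters, got {len(tables)}"
        )
    # Accept full tables or bare (a, E) pairs.
    a = np.array([t.a if hasattr(t, "a") else t[0] for t in tables], dtype=float)
    e = np.array([t.expected if hasattr(t, "expected") else t[1]
                  for t in tables], dtype=float)
    keep = e > 0
    a, e = a[keep], e[keep]

    def nll(x):
        prior = _unpack(x, fix_p)
        val = -float(prior.log_marginal(a, e).sum())
        return val if np.isfinite(val) else 1e12

    starts = (CANONICAL_PRIOR,) + _EXTRA_STARTS
    best = None
    any_converged = False
    for start in starts:
        s = start if fix_p is None else replace(start, p=fix_p)
        x0 = _pack(s, fix_p)
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"fatol": tol, "xatol": 1e-6,
                                         "maxiter": 5000, "maxfev": 10000})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    prior = _unpack(best.x, fix_p)
    fit = MGPSFit(prior=prior, converged=any_converged, loglik=-float(best.fun))
    if not any_converged:
        raise ConvergenceError("MGPS prior fit did not converge from any start",
                               best=prior, loglik=fit.loglik)
    return fit


def _posterior_mixture(table: ContingencyTable, prior: MGPSPrior):
    """Posterior weight Q and the two posterior gamma components."""
    e = table.expected
    if e <= 0:
        raise UndefinedResultError("expected count E must be positive")
    a = table.a
    if prior.p >= 1.0:
        q = 1.0
    else:
        l1, l2 = prior.log_marginal_components(a, e)
        lw1 = math.log(prior.p) + float(l1)
        lw2 = math.log1p(-prior.p) + float(l2)
        m = max(lw1, lw2)
        q = math.exp(lw1 - m) / (math.exp(lw1 - m) + math.exp(lw2 - m))
    comp1 = (prior.alpha1 + a, prior.beta1 + e)
    comp2 = (prior.alpha2 + a, prior.beta2 + e)
    return q, comp1, comp2


def mgps_ebgm(table: ContingencyTable, prior: MGPSPrior,
              *, tol: float = 1e-6) -> tuple:
    """(EBGM, EB05) for one table under a fitted prior.

    EBGM = 2^{E[log2 λ]} from the digamma expectations of the posterior
    gamma mixture; EB05 solves mixture CDF(λ) = 0.05 by bracketed
    root-finding.
    """
    q, (s1, r1), (s2, r2) = _posterior_mixture(table, prior)
    mean_log = q * (special.digamma(s1) - math.log(r1))
    if q < 1.0:
        mean_log += (1 - q) * (special.digamma(s2) - math.log(r2))
    ebgm = math.exp(mean_log)

    def cdf(lam):
        val = q * special.gammainc(s1, r1 * lam)
        if q < 1.0:
            val += (1 - q) * special.gammainc(s2, r2 * lam)
        return val

    lo = special.gammaincinv(s1, 0.05) / r1
    hi = lo
    if q < 1.0:
        other = special.gammaincinv(s2, 0.05) / r2
        lo, hi = min(lo, other), max(lo, other)
    # Component quantiles bracket the mixture quantile in exact arithmetic;
    # widen defensively against rounding at near-identical components.
    for _ in range(60):
        if cdf(lo) < 0.05:
            break
        lo *= 0.5
    for _ in range(60):
        if cdf(hi) > 0.05:
            break
        hi *= 1.5
    if hi - lo < tol:
        eb05 = (lo + hi) / 2
    else:
        eb05 = optimize.brentq(lambda lam: cdf(lam) - 0.05, lo, hi, xtol=tol)
    return float(ebgm), float(eb05)


# ---------------------------------------------------------------------------
# Combined per-(drug, SOC) result
# ---------------------------------------------------------------------------

@dataclass
class SignalResult:
    """All four statistics for one (drug, SOC) comparison."""

    drug: str
    soc: str
    table: ContingencyTable
    ror: Estimate
    prr: Estimate
    chi2: float
    chi2_p: float
    ic: ICResult
    ebgm: float
    eb05: float
    flags: dict | None = None


def compute_signal(drug: str, soc: str, table: ContingencyTable,
                   prior: MGPSPrior,
                   bcpnn_config: BCPNNConfig = DEFAULT_BCPNN) -> SignalResult:
    """Evaluate ROR, PRR, chi-square, IC and EBGM/EB05 on one table."""
    try:
        chi2_stat, chi2_p = chi_square(table)
    except ValidationError:
        chi2_stat, chi2_p = float("nan"), float("nan")
    ebgm, eb05 = mgps_ebgm(table, prior)
    return SignalResult(
        drug=drug,
        soc=soc,
        table=table,
        ror=ror(table),
        prr=prr(table),
        chi2=chi2_stat,
        chi2_p=chi2_p,
        ic=bcpnn_ic(table, bcpnn_config),
        ebgm=ebgm,
        eb05=eb05,
    )
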