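"""Disproportionality statistics: ROR, PRR, BCPNN information component, MGPS.

All four estimators compare the observed count ``a`` of a drug-term pair with
what independence of drug and term would predict from the table margins:

* **ROR** — reporting odds ratio (a d)/(b c) with Wald log-scale 95% CI;
* **PRR** — proportional reporting ratio [a/(a+b)]/[c/(c+d)] with the Pearson
  chi-squared statistic (no continuity correction);
* **IC** — information component log2(a N / ((a+b)(a+c))) with a lower bound
  ``IC025`` (delta-method by default, gamma-posterior variant available);
* **EBGM** — empirical-Bayes geometric mean of the observed/expected ratio.
  The ``simplified`` mode is the raw relative ratio a N/((a+b)(a+c)) (equal to
  2^IC) with a Wald-style lower bound; the ``shrinkage`` mode fits DuMouchel's
  two-component gamma-Poisson mixture across the whole table collection and
  reports the posterior geometric mean and 5th percentile.

Each algorithm has a conventional signal criterion; a term is an "all-four"
signal when every criterion is met simultaneously, and is *unexpected* when
it is absent from the product-label term list.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .cohort import normalize_term
from .contingency import ContingencyTable

__all__ = [
    "RorResult",
    "PrrResult",
    "IcResult",
    "EbgmResult",
    "SignalEstimates",
    "SignalFlags",
    "Thresholds",
    "GammaPoissonModel",
    "compute_ror",
    "compute_prr",
    "compute_ic",
    "compute_ebgm",
    "compute_estimates",
    "apply_criteria",
]

_LN2 = math.log(2.0)


def _cells(t: ContingencyTable, haldane: bool) -> tuple[float, float, float, float]:
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane and min(a, b, c, d) == 0:
        # Haldane-Anscombe: add 0.5 to every cell when any is zero
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d


@dataclasses.dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float


@dataclasses.dataclass(frozen=True)
class PrrResult:
    prr: float
    chi2: float


@dataclasses.dataclass(frozen=True)
class IcResult:
    ic: float
    ic025: float


@dataclasses.dataclass(frozen=True)
class EbgmResult:
    ebgm: float
    ebgm05: float


def compute_ror(t: ContingencyTable, *, haldane: bool = False) -> RorResult:
    """Reporting odds ratio with Wald 95% CI.

    A zero cell without the Haldane correction yields NaN (an
    undefined-signal marker), never an exception.
    """
    a, b, c, d = _cells(t, haldane)
    if min(a, b, c, d) <= 0:
        return RorResult(math.nan, math.nan, math.nan)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = 1.96 * se
    return RorResult(ror, ror * math.exp(-half), ror * math.exp(half))


def compute_prr(t: ContingencyTable, *, haldane: bool = False) -> PrrResult:
    """Proportional reporting ratio and Pearson chi-squared (uncorrected)."""
    a, b, c, d = _cells(t, haldane)
    n = a + b + c + d
    if (a + b) <= 0 or (c + d) <= 0 or c <= 0:
        return PrrResult(math.nan, math.nan)
    prr = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = n * (a * d - b * c) ** 2 / denom if denom > 0 else math.nan
    return PrrResult(prr, chi2)


def compute_ic(
    t: ContingencyTable,
    *,
    haldane: bool = False,
    variant: str = "delta",
) -> IcResult:
    """BCPNN information component with its lower 95% bound.

    ``variant='delta'`` (default): IC = log2 of observed/expected and
    IC025 = IC - 1.96 * sd with the delta-method variance of ln(O/E),
    var = 1/a - 1/(a+b) - 1/(a+c) + 1/N, scaled to the log2 scale.

    ``variant='gamma'``: posterior-based bound in the style of the shrinkage
    observed-to-expected ratio used at the Uppsala Monitoring Centre,
    IC = log2((a+0.5)/(E+0.5)) and IC025 the 2.5% quantile of a
    Gamma(a+0.5, rate E+0.5) posterior on the log2 scale.
    """
    a, b, c, d = _cells(t, haldane)
    n = a + b + c + d
    exp_a = (a + b) * (a + c) / n
    if variant == "gamma":
        ic = math.log2((a + 0.5) / (exp_a + 0.5))
        q = stats.gamma.ppf(0.025, a + 0.5, scale=1.0 / (exp_a + 0.5))
        return IcResult(ic, math.log2(q) if q > 0 else -math.inf)
    if variant != "delta":
        raise ValueError(f"unknown IC variant {variant!r}")
    if a <= 0 or exp_a <= 0:
        return IcResult(math.nan, math.nan)
    ic = math.log2(a * n / ((a + b) * (a + c)))
    var_ln = 1 / a - 1 / (a + b) - 1 / (a + c) + 1 / n
    if var_ln <= 0:
        # the margin corrections assume a << margins; when a drug covers a
        # sizeable fraction of the corpus they can overshoot — fall back to
        # the leading 1/a term
        var_ln = 1 / a
    sd = math.sqrt(var_ln) / _LN2
    return IcResult(ic, ic - 1.96 * sd)


@dataclasses.dataclass(frozen=True)
class GammaPoissonModel:
    """DuMouchel's two-component gamma-Poisson mixture prior.

    Counts a_i are modelled Poisson(lambda_i * E_i) with the relative ratio
    lambda drawn from p * Gamma(alpha1, beta1) + (1-p) * Gamma(alpha2, beta2)
    (rate parameterization).  Hyperparameters are estimated by maximum
    marginal likelihood over the full table collection; each table's
    posterior is again a two-component gamma mixture.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float

    MIN_TABLES: int = 50

    @staticmethod
    def _log_nb(a, alpha, beta, e):
        # marginal of a Poisson(lambda E) count with Gamma(alpha, beta) prior
        return (
            special.gammaln(alpha + a)
            - special.gammaln(alpha)
            - special.gammaln(a + 1)
            + alpha * np.log(beta / (beta + e))
            + a * np.log(e / (beta + e))
        )

    @classmethod
    def fit(cls, tables: Sequence[ContingencyTable]) -> "GammaPoissonModel":
        """Fit hyperparameters by maximum likelihood across all tables.

        Refuses collections smaller than ``MIN_TABLES`` — with too few
        drug-term pairs the five hyperparameters are not identifiable.
        """
        if len(tables) < cls.MIN_TABLES:
            raise ValueError(
                f"shrinkage fit needs >= {cls.MIN_TABLES} tables, "
                f"got {len(tables)}"
            )
        a = np.array([t.a for t in tables], dtype=float)
        e = np.array([t.expected for t in tables], dtype=float)
        keep = e > 0
        a, e = a[keep], e[keep]

        def nll(theta: np.ndarray) -> float:
            a1, b1, a2, b2 = np.exp(theta[:4])
            p = special.expit(theta[4])
            l1 = cls._log_nb(a, a1, b1, e)
            l2 = cls._log_nb(a, a2, b2, e)
            m = np.maximum(l1, l2)
            ll = m + np.log(p * np.exp(l1 - m) + (1 - p) * np.exp(l2 - m))
            return -float(ll.sum())

        # DuMouchel's conventional starting point
        x0 = np.array([np.log(0.2), np.log(0.1), np.log(2.0), np.log(4.0), 0.0])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
        a1, b1, a2, b2 = np.exp(res.x[:4])
        p = float(special.expit(res.x[4]))
        return cls(alpha1=float(a1), beta1=float(b1),
                   alpha2=float(a2), beta2=float(b2), p=p)

    def posterior(self, a: float, e: float) -> EbgmResult:
        """Posterior EBGM (geometric mean) and 5th percentile for one table."""
        l1 = float(self._log_nb(a, self.alpha1, self.beta1, e))
        l2 = float(self._log_nb(a, self.alpha2, self.beta2, e))
        m = max(l1, l2)
        w1 = self.p * math.exp(l1 - m)
        w2 = (1 - self.p) * math.exp(l2 - m)
        q1 = w1 / (w1 + w2)
        q2 = 1.0 - q1
        s1, r1 = self.alpha1 + a, self.beta1 + e
        s2, r2 = self.alpha2 + a, self.beta2 + e
        mean_log = q1 * (special.digamma(s1) - math.log(r1)) + q2 * (
            special.digamma(s2) - math.log(r2)
        )
        ebgm = math.exp(mean_log)

        def cdf(x: float) -> float:
            return q1 * stats.gamma.cdf(x, s1, scale=1 / r1) + q2 * stats.gamma.cdf(
                x, s2, scale=1 / r2
            )

        hi = max(stats.gamma.ppf(0.999, s1, scale=1 / r1),
                 stats.gamma.ppf(0.999, s2, scale=1 / r2), 1e-6)
        lo = 1e-12
        ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi)
        return EbgmResult(ebgm, float(ebgm05))


def compute_ebgm(
    t: ContingencyTable,
    *,
    mode: str = "simplified",
    model: GammaPoissonModel | None = None,
    haldane: bool = False,
    z: float = 1.645,
) -> EbgmResult:
    """Empirical-Bayes geometric mean with its lower bound EBGM05.

    ``simplified``: the raw relative reporting ratio a N / ((a+b)(a+c)) —
    identically 2^IC — with EBGM05 = exp(ln EBGM - z * sqrt(1/a+1/b+1/c+1/d)).
    ``z`` defaults to 1.645 (one-sided 95%); 1.96 is accepted for the
    two-sided convention some analyses print.

    ``shrinkage``: posterior summaries under a fitted
    :class:`GammaPoissonModel` (pass the model fitted on the full collection).
    """
    if mode == "shrinkage":
        if model is None:
            raise ValueError("shrinkage mode requires a fitted GammaPoissonModel")
        return model.posterior(t.a, t.expected)
    if mode != "simplified":
        raise ValueError(f"unknown ebgm mode {mode!r}")
    a, b, c, d = _cells(t, haldane)
    n = a + b + c + d
    exp_a = (a + b) * (a + c) / n
    if a <= 0 or exp_a <= 0 or min(b, c, d) <= 0:
        return EbgmResult(math.nan, math.nan)
    ebgm = a / exp_a
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EbgmResult(ebgm, math.exp(math.log(ebgm) - z * se))


@dataclasses.dataclass(frozen=True)
class SignalEstimates:
    """The four statistics with their interval bounds for one table."""

    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float

    @property
    def ror_ci(self) -> tuple[float, float]:
        return (self.ror_low, self.ror_high)


def compute_estimates(
    t: ContingencyTable,
    *,
    haldane: bool = False,
    ic_variant: str = "delta",
    ebgm_mode: str = "simplified",
    ebgm_model: GammaPoissonModel | None = None,
    ebgm_z: float = 1.645,
) -> SignalEstimates:
    """All four estimators on one table, sharing the Haldane setting."""
    r = compute_ror(t, haldane=haldane)
    p = compute_prr(t, haldane=haldane)
    i = compute_ic(t, haldane=haldane, variant=ic_variant)
    e = compute_ebgm(t, mode=ebgm_mode, model=ebgm_model, haldane=haldane, z=ebgm_z)
    return SignalEstimates(
        ror=r.ror, ror_low=r.ci_low, ror_high=r.ci_high,
        prr=p.prr, chi2=p.chi2,
        ic=i.ic, ic025=i.ic025,
        ebgm=e.ebgm, ebgm05=e.ebgm05,
    )


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Signal criteria of the four algorithms (the conventional defaults)."""

    min_a: int = 3
    ror_lower_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class SignalFlags:
    ror_sig: bool
    prr_sig: bool
    ic_sig: bool
    ebgm_sig: bool
    expected: bool

    @property
    def all_four(self) -> bool:
        return self.ror_sig and self.prr_sig and self.ic_sig and self.ebgm_sig

    @property
    def any_sig(self) -> bool:
        return self.ror_sig or self.prr_sig or self.ic_sig or self.ebgm_sig


def apply_criteria(
    e: SignalEstimates,
    a: float,
    th: Thresholds,
    label_terms: Iterable[str] = (),
    term: str = "",
) -> SignalFlags:
    """Per-algorithm significance flags plus labeled/unexpected status.

    ROR: a >= min_a and CI lower bound strictly > 1.  PRR: a >= min_a,
    PRR >= 2 and chi2 >= 4.  BCPNN: IC025 > 0.  MGPS: EBGM05 > 2.
    NaN estimates never flag.  ``expected`` is case-insensitive exact-term
    membership in the label list (PTs are controlled vocabulary).
    """
    min_a_ok = a >= th.min_a
    ror_sig = bool(min_a_ok and e.ror_low > th.ror_lower_gt)
    prr_sig = bool(min_a_ok and e.prr >= th.prr_ge and e.chi2 >= th.chi2_ge)
    ic_sig = bool(e.ic025 > th.ic025_gt)
    ebgm_sig = bool(e.ebgm05 > th.ebgm05_gt)
    labels = {normalize_term(x) for x in label_terms}
    return SignalFlags(
        ror_sig=ror_sig,
        prr_sig=prr_sig,
        ic_sig=ic_sig,
        ebgm_sig=ebgm_sig,
        expected=normalize_term(term) in labels if term else False,
    )
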