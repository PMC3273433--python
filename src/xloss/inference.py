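"""Invert the forward model: multinomial MLE of (d, l) from progeny counts.

The scored classes are collapsed to {X0 son, XXY daughter, other}.  Under
default sperm and viability their probabilities are

    f0 = (d/2 + l/4) / D,   f2 = (d/2) / D,   D = 2 - d - l/4,

which is a bijection from the admissible (d, l) region, so the MLE has the
closed form

    d_hat = 4 f2 / (1 + f0 + f2),   l_hat = 8 (f0 - f2) / (1 + f0 + f2)

with f0 = n_x0/N, f2 = n_xxy/N.  When f0 < f2 the loss rate is clamped to
the boundary l = 0 and d re-estimated.  Every closed-form fit is polished by
a constrained numeric re-maximization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps
from scipy.special import gammaln

from .errors import (
    BoundaryFitWarning,
    ConfigurationError,
    InconsistentCountsError,
    UndefinedRateError,
)
from .model import SegregationParams, egg_class_probabilities, progeny_class_probabilities
from .stats import CrossCounts

__all__ = [
    "MleFit",
    "LrtResult",
    "log_likelihood",
    "fit_mle",
    "confidence_intervals",
    "compare_to_control",
]

_EPS = 1e-12


@dataclass(frozen=True)
class MleFit:
    """Maximum-likelihood estimates of the two mis-segregation rates."""

    d_hat: float
    l_hat: float
    loglik: float
    ci_d: tuple[float, float] | None = None
    ci_l: tuple[float, float] | None = None
    at_boundary: tuple[bool, bool] = (False, False)

    @property
    def params(self) -> SegregationParams:
        return SegregationParams(d=self.d_hat, l=self.l_hat)


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio comparison of a test cross against a control."""

    statistic: float
    p_value: float | None
    df: int
    statistic_l_only: float | None = None
    p_value_l_only: float | None = None
    degenerate: bool = False


def _class_probs(d: float, l: float) -> tuple[float, float, float]:
    dist = progeny_class_probabilities(
        egg_class_probabilities(SegregationParams(d=d, l=l))
    )
    f0 = dist.f_x0_son
    f2 = dist.f_xxy_daughter
    return f0, f2, 1.0 - f0 - f2


def _multinomial_constant(counts: CrossCounts) -> float:
    n = counts.total_progeny
    return float(
        gammaln(n + 1)
        - gammaln(counts.n_x0 + 1)
        - gammaln(counts.n_xxy + 1)
        - gammaln(counts.n_other + 1)
    )


def _loglik_core(d: float, l: float, counts: CrossCounts) -> float:
    """Log-likelihood kernel without the multinomial constant; -inf allowed."""
    f0, f2, f_other = _class_probs(d, l)
    total = 0.0
    for n, p in ((counts.n_x0, f0), (counts.n_xxy, f2), (counts.n_other, f_other)):
        if n > 0:
            if p <= 0.0:
                return -math.inf
            total += n * math.log(p)
    return total


def log_likelihood(params: SegregationParams, counts: CrossCounts) -> float:
    """Multinomial log-likelihood of (n_x0, n_xxy, n_other) at the given rates.

    Returns ``-inf`` when a zero-probability class carries a nonzero count.
    """
    if counts.total_progeny == 0:
        raise UndefinedRateError(f"{counts.label}: no progeny scored")
    core = _loglik_core(params.d, params.l, counts)
    if core == -math.inf:
        return -math.inf
    return core + _multinomial_constant(counts)


def _closed_form(counts: CrossCounts) -> tuple[float, float, bool]:
    """Closed-form MLE, with boundary clamping; returns (d, l, clamped)."""
    n = counts.total_progeny
    f0 = counts.n_x0 / n
    f2 = counts.n_xxy / n
    if f0 >= f2:
        denom = 1.0 + f0 + f2
        return 4.0 * f2 / denom, 8.0 * (f0 - f2) / denom, False
    # f0 < f2: the interior stationary point has l < 0; clamp to l = 0,
    # where f_x0 = f_xxy = (d/2)/(2-d) and the 1-D MLE is also closed-form.
    q = (counts.n_x0 + counts.n_xxy) / (2.0 * n)
    return 4.0 * q / (1.0 + 2.0 * q), 0.0, True


def _polish(
    d0: float, l0: float, counts: CrossCounts, fix_l_zero: bool
) -> tuple[float, float]:
    """Constrained numeric re-maximization from the closed-form start."""

    def neg(x: np.ndarray) -> float:
        d, l = (x[0], 0.0) if fix_l_zero else (float(x[0]), float(x[1]))
        d = min(max(float(d), 0.0), 1.0)
        l = min(max(float(l), 0.0), 1.0 - d)
        return -_loglik_core(d, l, counts)

    if fix_l_zero:
        res = optimize.minimize_scalar(
            lambda d: -_loglik_core(min(max(d, 0.0), 1.0), 0.0, counts),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return float(min(max(res.x, 0.0), 1.0)), 0.0
    res = optimize.minimize(
        neg,
        x0=np.array([d0, l0]),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000},
    )
    d = float(min(max(res.x[0], 0.0), 1.0))
    l = float(min(max(res.x[1], 0.0), 1.0 - d))
    return d, l


def fit_mle(counts: CrossCounts, polish: bool = True) -> MleFit:
    """Estimate (d, l) from one cross by multinomial maximum likelihood.

    The closed-form estimate is the exact optimum whenever it is admissible;
    the numeric re-maximization is a guard and must agree to ~1e-8 in the
    interior.  ``polish=False`` skips it (used by bootstrap loops).
    """
    if counts.total_progeny == 0:
        raise UndefinedRateError(f"{counts.label}: no progeny scored")
    d_cf, l_cf, clamped = _closed_form(counts)
    if d_cf + l_cf > 1.0 + 1e-9:
        raise InconsistentCountsError(
            f"{counts.label}: counts imply d + l = {d_cf + l_cf:.4f} > 1; "
            "not reachable by the segregation model"
        )
    d_hat, l_hat = d_cf, min(l_cf, 1.0 - d_cf)
    if polish and counts.total_progeny > 0:
        d_num, l_num = _polish(d_hat, l_hat, counts, fix_l_zero=clamped)
        # keep whichever attains the higher likelihood (they agree in the interior)
        if _loglik_core(d_num, l_num, counts) > _loglik_core(d_hat, l_hat, counts):
            d_hat, l_hat = d_num, l_num
    if clamped:
        warnings.warn(
            f"{counts.label}: l estimate clamped to 0 (n_xxy > n_x0)",
            BoundaryFitWarning,
            stacklevel=2,
        )
    at_boundary = (
        d_hat <= _EPS or d_hat >= 1.0 - _EPS,
        clamped or l_hat <= _EPS or d_hat + l_hat >= 1.0 - _EPS,
    )
    fit = MleFit(
        d_hat=d_hat,
        l_hat=l_hat,
        loglik=log_likelihood(SegregationParams(d=d_hat, l=l_hat), counts),
        at_boundary=at_boundary,
    )
    return fit


def _profile_loglik(
    which: str, value: float, counts: CrossCounts
) -> float:
    """Maximize the kernel over the nuisance parameter at a fixed d or l."""
    if which == "d":
        hi = 1.0 - value

        def neg(l: float) -> float:
            return -_loglik_core(value, min(max(l, 0.0), hi), counts)

    else:
        hi = 1.0 - value

        def neg(d: float) -> float:
            return -_loglik_core(min(max(d, 0.0), hi), value, counts)

    if hi <= 0.0:
        return _loglik_core(value if which == "d" else 0.0,
                            0.0 if which == "d" else value, counts)
    res = optimize.minimize_scalar(
        neg, bounds=(0.0, hi), method="bounded", options={"xatol": 1e-10}
    )
    return -float(res.fun)


def _profile_interval(
    which: str, fit: MleFit, counts: CrossCounts, level: float
) -> tuple[float, float]:
    cutoff = float(sps.chi2.ppf(level, df=1)) / 2.0
    best = _loglik_core(fit.d_hat, fit.l_hat, counts)
    hat = fit.d_hat if which == "d" else fit.l_hat

    def deficit(value: float) -> float:
        return (best - _profile_loglik(which, value, counts)) - cutoff

    lower = 0.0
    if hat > 0.0 and deficit(0.0) > 0.0:
        lower = float(optimize.brentq(deficit, 0.0, hat, xtol=1e-9))
    upper = 1.0
    if hat < 1.0 and deficit(1.0 - 1e-12) > 0.0:
        upper = float(optimize.brentq(deficit, hat, 1.0 - 1e-12, xtol=1e-9))
    return lower, upper


def confidence_intervals(
    fit: MleFit,
    counts: CrossCounts,
    level: float = 0.95,
    method: str = "profile",
    seed: int | None = None,
    n_boot: int = 1000,
) -> MleFit:
    """Attach confidence intervals for d and l to a fit.

    ``profile`` inverts the likelihood-ratio test with a chi-square(1)
    cutoff; ``bootstrap`` takes percentile intervals over parametric
    multinomial resamples and requires an explicit seed.  Boundary-clamped
    parameters yield one-sided intervals (lower bound 0).
    """
    if not (0.0 < level < 1.0):
        raise ConfigurationError(f"confidence level must lie in (0, 1), got {level}")
    if method == "profile":
        ci_d = _profile_interval("d", fit, counts, level)
        ci_l = (
            (0.0, _profile_interval("l", fit, counts, level)[1])
            if fit.at_boundary[1]
            else _profile_interval("l", fit, counts, level)
        )
    elif method == "bootstrap":
        if seed is None:
            raise ConfigurationError("bootstrap intervals require an explicit seed")
        if n_boot < 2:
            raise ConfigurationError("n_boot must be at least 2")
        rng = np.random.default_rng(seed)
        f0, f2, f_other = _class_probs(fit.d_hat, fit.l_hat)
        n = counts.total_progeny
        draws = rng.multinomial(n, [f0, f2, f_other], size=n_boot)
        ds = np.empty(n_boot)
        ls = np.empty(n_boot)
        for i, (x0, xxy, other) in enumerate(draws):
            d_b, l_b, _ = _closed_form(
                CrossCounts(
                    label="boot",
                    mothers=counts.mothers,
                    total_progeny=n,
                    n_x0=int(x0),
                    n_xxy=int(xxy),
                    n_other=int(other),
                )
            )
            ds[i], ls[i] = min(d_b, 1.0), min(l_b, 1.0 - min(d_b, 1.0))
        alpha = 1.0 - level
        qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
        ci_d = tuple(float(q) for q in np.percentile(ds, qs))
        ci_l = tuple(float(q) for q in np.percentile(ls, qs))
        if fit.at_boundary[1]:
            ci_l = (0.0, ci_l[1])
    else:
        raise ConfigurationError(f"unknown CI method {method!r}")
    return MleFit(
        d_hat=fit.d_hat,
        l_hat=fit.l_hat,
        loglik=fit.loglik,
        ci_d=ci_d,
        ci_l=ci_l,
        at_boundary=fit.at_boundary,
    )


def _pooled(test: CrossCounts, control: CrossCounts) -> CrossCounts:
    return CrossCounts(
        label="pooled",
        mothers=test.mothers + control.mothers,
        total_progeny=test.total_progeny + control.total_progeny,
        n_x0=test.n_x0 + control.n_x0,
        n_xxy=test.n_xxy + control.n_xxy,
        n_other=test.n_other + control.n_other,
    )


def _shared_d_loglik(test: CrossCounts, control: CrossCounts) -> float:
    """Maximized kernel of the shared-d, separate-l model (numeric, 3 params)."""

    def neg(x: np.ndarray) -> float:
        d = min(max(float(x[0]), 0.0), 1.0)
        l1 = min(max(float(x[1]), 0.0), 1.0 - d)
        l2 = min(max(float(x[2]), 0.0), 1.0 - d)
        return -(_loglik_core(d, l1, test) + _loglik_core(d, l2, control))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BoundaryFitWarning)
        f_test = fit_mle(test, polish=False)
        f_ctrl = fit_mle(control, polish=False)
    d0 = (f_test.d_hat + f_ctrl.d_hat) / 2.0
    x0 = np.array([d0, f_test.l_hat, f_ctrl.l_hat])
    res = optimize.minimize(
        neg, x0=x0, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    return -float(res.fun)


def compare_to_control(
    test: CrossCounts, control: CrossCounts, l_only: bool = True
) -> LrtResult:
    """Likelihood-ratio tests of a cross against a control.

    The main statistic compares shared-(d, l) against separate-(d, l)
    (df = 2).  When ``l_only`` is set, the l-only statistic (shared d,
    separate l vs. everything shared, df = 1) is reported as well; it
    isolates the chromosome-loss rate, the analogue of the excess-nullo
    chi test.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BoundaryFitWarning)
        try:
            ll_sep = (
                _loglik_core(*_mle_pair(test), test)
                + _loglik_core(*_mle_pair(control), control)
            )
            ll_shared = _loglik_core(*_mle_pair(_pooled(test, control)),
                                     _pooled(test, control))
        except InconsistentCountsError:
            return LrtResult(
                statistic=math.nan, p_value=None, df=2, degenerate=True
            )
    stat = max(0.0, 2.0 * (ll_sep - ll_shared))
    p = float(sps.chi2.sf(stat, df=2))
    stat_l = p_l = None
    if l_only:
        ll_shared_d = _shared_d_loglik(test, control)
        # guard: the 3-parameter optimum can never fall below the fully
        # shared model nor exceed the separate model
        ll_shared_d = min(max(ll_shared_d, ll_shared), ll_sep)
        stat_l = max(0.0, 2.0 * (ll_shared_d - ll_shared))
        p_l = float(sps.chi2.sf(stat_l, df=1))
    return LrtResult(
        statistic=stat,
        p_value=p,
        df=2,
        statistic_l_only=stat_l,
        p_value_l_only=p_l,
    )


def _mle_pair(counts: CrossCounts) -> tuple[float, float]:
    d, l, _ = _closed_form(counts)
    if d + l > 1.0 + 1e-9:
        raise InconsistentCountsError(
            f"{counts.label}: counts imply d + l > 1"
        )
    return d, min(l, 1.0 - d)
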