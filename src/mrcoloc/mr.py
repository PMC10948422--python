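"""Causal-effect estimators for two-sample Mendelian randomization.

Given harmonized per-variant effect pairs (beta_X, beta_Y), each estimator
combines the per-variant Wald ratios beta_Y / beta_X into a single causal
estimate under different validity assumptions:

* ``ivw`` — inverse-variance weighted mean of the ratios; efficient when all
  instruments are valid.  Default is multiplicative random effects (the
  standard error is inflated by sqrt(Q / (k-1)) under excess heterogeneity).
* ``mr_egger`` — weighted regression of beta_Y on beta_X *with* an intercept;
  a nonzero intercept estimates directional pleiotropy, and the slope remains
  consistent under the InSIDE assumption.  The I2_GX statistic quantifies
  regression-dilution risk (values below 0.9 flag attenuation).
* ``weighted_median`` / ``simple_median`` — consistent when at least half the
  weight comes from valid instruments.
* ``weighted_mode`` — consistent when the largest homogeneous cluster of
  ratios is valid (zero modal pleiotropy assumption).

Estimates for binary outcomes are reported on the log-odds scale and can be
exponentiated to odds ratios with 95% confidence bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, EmptySetError, InsufficientInstrumentsError
from .sumstats import HarmonizedSet

log = logging.getLogger(__name__)

Z_975 = 1.959964  # two-sided 95% normal quantile, as used in reported CIs


@dataclass(frozen=True)
class MrEstimate:
    """One method's causal estimate.

    ``beta`` is a log odds ratio when the outcome is binary.  The odds-ratio
    fields are populated only for binary outcomes (see :meth:`with_or`).
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    or_value: float | None = None
    or_lci: float | None = None
    or_uci: float | None = None

    def with_or(self) -> "MrEstimate":
        """Copy with the exp-transformed estimate and 95% bounds filled in."""
        orv, lci, uci = to_odds_ratio(self.beta, self.se)
        return replace(self, or_value=orv, or_lci=lci, or_uci=uci)


def _two_sided_normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MrEstimate:
    """Single-instrument causal estimate beta_Y / beta_X.

    The standard error is the first-order delta-method approximation
    ``|se_Y / beta_X|``, which ignores uncertainty in beta_X.
    """
    if beta_x == 0:
        raise DomainError("Wald ratio undefined for beta_x = 0")
    beta = beta_y / beta_x
    se = abs(se_y / beta_x)
    return MrEstimate("wald_ratio", float(beta), float(se), _two_sided_normal_p(beta, se), 1)


def _ratios(hs: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    bx, sy = hs.beta_exposure, hs.se_outcome
    if np.any(bx == 0):
        bad = [p.variant_id for p in hs.pairs if p.beta_exposure == 0]
        raise DomainError(f"Wald ratio undefined for beta_exposure = 0: {bad}")
    r = hs.beta_outcome / bx
    se_r = np.abs(sy / bx)
    return r, se_r


def ivw(hs: HarmonizedSet, mode: str = "random_multiplicative") -> MrEstimate:
    """Inverse-variance weighted average of Wald ratios.

    Equivalent to the weighted through-origin regression of beta_Y on beta_X.
    ``mode="fixed"`` uses the fixed-effect standard error; the default
    multiplicative random-effects model inflates it by sqrt(Q / (k-1)) when
    Cochran's Q exceeds its degrees of freedom.
    """
    if mode not in ("fixed", "random_multiplicative"):
        raise DomainError(f"unknown IVW mode {mode!r}")
    k = hs.n_snps
    if k == 0:
        raise EmptySetError("IVW requires at least one instrument")
    if k == 1:
        log.info("IVW with a single instrument degrades to the Wald ratio")
        p = hs.pairs[0]
        est = wald_ratio(p.beta_exposure, p.se_exposure, p.beta_outcome, p.se_outcome)
        return replace(est, method="ivw")
    r, se_r = _ratios(hs)
    w = 1.0 / se_r**2
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    if mode == "random_multiplicative":
        q = float(np.sum(w * (r - beta) ** 2))
        if q > k - 1:
            se *= (q / (k - 1)) ** 0.5
    return MrEstimate("ivw", beta, se, _two_sided_normal_p(beta, se), k)


@dataclass(frozen=True)
class EggerResult:
    """Slope and intercept of the MR-Egger regression, plus I2_GX."""

    slope: MrEstimate
    intercept: MrEstimate
    i2_gx: float


def i2_gx(hs: HarmonizedSet) -> float:
    """Heterogeneity of the exposure associations: max(0, (Q_GX - (k-1)) / Q_GX).

    Q_GX is the inverse-variance weighted sum of squared deviations of the
    exposure betas from their weighted mean.  Values below 0.9 indicate that
    measurement error in beta_X will bias the Egger slope toward the null
    (violation of the no-measurement-error assumption).
    """
    bx, sx = np.abs(hs.beta_exposure), hs.se_exposure
    w = 1.0 / sx**2
    mean_w = np.sum(w * bx) / np.sum(w)
    q_gx = float(np.sum((bx - mean_w) ** 2 / sx**2))
    if q_gx == 0:
        return 0.0
    return float(max(0.0, (q_gx - (hs.n_snps - 1)) / q_gx))


def mr_egger(hs: HarmonizedSet) -> EggerResult:
    """Weighted linear regression of beta_Y on beta_X with an intercept.

    Pairs are first orientation-standardized so that all beta_X are
    non-negative (both betas of a pair are sign-flipped together), which the
    intercept's interpretation as average directional pleiotropy requires.
    Weights are 1/se_Y^2; inference uses a t distribution with k-2 degrees of
    freedom and the residual dispersion is not allowed below 1.
    """
    k = hs.n_snps
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 instruments, got {k}")
    sign = np.where(hs.beta_exposure < 0, -1.0, 1.0)
    bx = hs.beta_exposure * sign
    by = hs.beta_outcome * sign
    sy = hs.se_outcome
    w = 1.0 / sy**2

    x = np.column_stack([np.ones(k), bx])
    xtw = x.T * w
    cov_unscaled = np.linalg.inv(xtw @ x)
    coef = cov_unscaled @ (xtw @ by)
    resid = by - x @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    # multiplicative overdispersion, floored at 1 (no shrinking below fixed-effect)
    se = np.sqrt(np.diag(cov_unscaled) * max(1.0, sigma2))
    tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=k - 2)

    intercept = MrEstimate("egger_intercept", float(coef[0]), float(se[0]), float(pvals[0]), k)
    slope = MrEstimate("egger_slope", float(coef[1]), float(se[1]), float(pvals[1]), k)
    i2 = i2_gx(hs)
    if i2 < 0.9:
        log.warning(
            "I2_GX = %.3f < 0.9: Egger slope is at risk of attenuation bias (NOME violation)",
            i2,
        )
    return EggerResult(slope=slope, intercept=intercept, i2_gx=i2)


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by linear interpolation of cumulative weights at 0.5."""
    order = np.argsort(r)
    r_s = r[order]
    w_s = w[order] / np.sum(w)
    cum = np.cumsum(w_s) - 0.5 * w_s
    if cum[0] >= 0.5:
        return float(r_s[0])
    if cum[-1] <= 0.5:
        return float(r_s[-1])
    below = int(np.searchsorted(cum, 0.5, side="right")) - 1
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(r_s[below] + frac * (r_s[below + 1] - r_s[below]))


def _bootstrap_se(
    point_fn, r: np.ndarray, se_r: np.ndarray, n_boot: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=r, scale=se_r, size=(n_boot, r.size))
    estimates = np.array([point_fn(d) for d in draws])
    return float(np.std(estimates, ddof=0))


def weighted_median(
    hs: HarmonizedSet, n_boot: int = 1000, seed: int = 0, simple: bool = False
) -> MrEstimate:
    """Weighted (or simple) median of the Wald ratios.

    Weights are inverse ratio variances (equal for ``simple=True``).  The
    standard error comes from a seeded parametric bootstrap: each ratio is
    resampled from Normal(r_j, se_j) and the median recomputed.
    """
    k = hs.n_snps
    if k < 3:
        raise InsufficientInstrumentsError(f"median estimators require >= 3 instruments, got {k}")
    r, se_r = _ratios(hs)
    w = np.ones(k) if simple else 1.0 / se_r**2
    beta = _weighted_median_point(r, w)
    se = _bootstrap_se(lambda d: _weighted_median_point(d, w), r, se_r, n_boot, seed)
    if se == 0:
        se = float(np.finfo(float).tiny)
    method = "simple_median" if simple else "weighted_median"
    return MrEstimate(method, beta, se, _two_sided_normal_p(beta, se), k)


def simple_median(hs: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Unweighted median of the Wald ratios with bootstrap standard error."""
    return weighted_median(hs, n_boot=n_boot, seed=seed, simple=True)


def _mode_bandwidth(r: np.ndarray, phi: float) -> float:
    """Modified Silverman rule: 0.9 min(sd, mad) k^(-1/5), scaled by phi."""
    sd = float(np.std(r, ddof=1))
    mad = float(stats.median_abs_deviation(r, scale="normal"))
    s = 0.9 * min(sd, mad if mad > 0 else sd) * r.size ** (-1 / 5)
    return phi * s


def _weighted_mode_point(r: np.ndarray, w: np.ndarray, h: float) -> float:
    if h <= 0 or np.ptp(r) == 0:
        return float(r[0])

    def neg_density(x: float) -> float:
        return -float(np.sum(w * np.exp(-0.5 * ((x - r) / h) ** 2)))

    grid = np.linspace(r.min(), r.max(), 2001)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2)).sum(axis=1)
    i = int(np.argmax(dens))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(neg_density, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def weighted_mode(
    hs: HarmonizedSet, bandwidth_phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Mode-based estimate: maximizer of a weighted Gaussian KDE over ratios.

    The bandwidth is ``bandwidth_phi`` times a modified Silverman rule over
    the ratios; weights are inverse ratio variances.  Consistent when the
    largest cluster of agreeing ratios comes from valid instruments.
    """
    k = hs.n_snps
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted mode requires >= 3 instruments, got {k}")
    if bandwidth_phi <= 0:
        raise DomainError("bandwidth_phi must be > 0")
    r, se_r = _ratios(hs)
    w = 1.0 / se_r**2
    h = _mode_bandwidth(r, bandwidth_phi)
    beta = _weighted_mode_point(r, w, h)

    def point(d: np.ndarray) -> float:
        return _weighted_mode_point(d, w, _mode_bandwidth(d, bandwidth_phi))

    se = _bootstrap_se(point, r, se_r, n_boot, seed)
    if se == 0:
        se = float(np.finfo(float).tiny)
    return MrEstimate("weighted_mode", beta, se, _two_sided_normal_p(beta, se), k)


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate: OR and 95% CI bounds."""
    if not se > 0:
        raise DomainError("se must be > 0")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z_975 * se)),
        float(np.exp(beta + Z_975 * se)),
    )


def wald_p_from_or_ci(or_value: float, or_lci: float, or_uci: float) -> float:
    """Two-sided Wald p implied by a reported OR and its 95% CI.

    Inverts the standard reporting convention: the log-scale standard error
    is the CI width divided by 2 * 1.959964 and the p-value follows from the
    normal z of log(OR).  Useful for internal-consistency checks of published
    tables.
    """
    if not (0.0 < or_lci < or_value < or_uci):
        raise DomainError(
            f"need 0 < lci < or < uci, got ({or_lci}, {or_value}, {or_uci})"
        )
    se = (np.log(or_uci) - np.log(or_lci)) / (2.0 * Z_975)
    z = np.log(or_value) / se
    return float(2.0 * stats.norm.sf(abs(z)))


#: Methods offered by :func:`run_all_methods`, in reporting order.
ALL_METHODS = ("ivw", "egger", "weighted_median", "simple_median", "weighted_mode")


def run_all_methods(
    hs: HarmonizedSet,
    methods: tuple[str, ...] = ALL_METHODS,
    binary_outcome: bool = True,
    ivw_mode: str = "random_multiplicative",
    n_boot: int = 1000,
    seed: int = 0,
    bandwidth_phi: float = 1.0,
) -> list[MrEstimate]:
    """All requested estimators on one harmonized set.

    Methods whose instrument-count requirement is not met are silently
    skipped (e.g. Egger with two instruments).  Odds-ratio fields are filled
    when the outcome is binary.
    """
    out: list[MrEstimate] = []
    for m in methods:
        try:
            if m == "ivw":
                out.append(ivw(hs, mode=ivw_mode))
            elif m == "egger":
                egger = mr_egger(hs)
                out.extend([egger.slope, egger.intercept])
            elif m == "weighted_median":
                out.append(weighted_median(hs, n_boot=n_boot, seed=seed))
            elif m == "simple_median":
                out.append(simple_median(hs, n_boot=n_boot, seed=seed + 1))
            elif m == "weighted_mode":
                out.append(weighted_mode(hs, bandwidth_phi=bandwidth_phi,
                                         n_boot=n_boot, seed=seed + 2))
            else:
                raise DomainError(f"unknown method {m!r}")
        except InsufficientInstrumentsError as exc:
            log.info("skipping %s: %s", m, exc)
    if binary_outcome:
        out = [e.with_or() if e.method != "egger_intercept" else e for e in out]
    return out
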