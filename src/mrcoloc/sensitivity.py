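"""Heterogeneity, pleiotropy, and influence diagnostics for an MR analysis.

The validity of an IVW estimate rests on every instrument being valid; these
diagnostics probe that assumption from different angles:

* Cochran's Q — excess dispersion of the per-variant Wald ratios around the
  pooled estimate (chi-square with k-1 df; p < 0.05 flags heterogeneity).
* The MR-Egger intercept test and I2_GX (see :mod:`mrcoloc.mr`).
* MR-PRESSO — a simulation-based residual-sum-of-squares test for horizontal
  pleiotropy with per-variant outlier detection and an outlier-corrected
  re-estimate; applicable when at least half the instruments are valid.
* Leave-one-out — the IVW estimate with each instrument removed in turn,
  exposing single variants that drive the pooled result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .mr import EggerResult, MrEstimate, ivw, mr_egger
from .sumstats import ExclusionReason, HarmonizedSet

log = logging.getLogger(__name__)


def cochran_q(hs: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q over Wald ratios: (Q, df, upper-tail chi-square p).

    Q = sum_j w_j (r_j - beta_fixed)^2 with w_j the inverse ratio variances
    and beta_fixed the fixed-effect IVW estimate; df = k - 1.
    """
    k = hs.n_snps
    if k < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q requires >= 2 instruments, got {k}")
    bx, by, sy = hs.beta_exposure, hs.beta_outcome, hs.se_outcome
    r = by / bx
    w = (bx / sy) ** 2
    beta_fixed = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta_fixed) ** 2))
    return q, k - 1, float(stats.chi2.sf(q, df=k - 1))


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out weighted through-origin slopes, vectorized over j."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx**2)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global test, outlier flags, and corrected estimate."""

    global_p: float
    global_rss: float
    outliers: list[str]
    outlier_pvalues: dict[str, float]  # Bonferroni-corrected per-variant p
    corrected: MrEstimate | None
    n_sim: int


def mr_presso(
    hs: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Pleiotropy residual sum and outlier test.

    Global test: the observed residual sum of squares around leave-one-out
    through-origin fits is compared with its distribution under ``n_sim``
    seeded simulations of outcome betas drawn from the no-pleiotropy model.
    Outlier test: each variant's squared residual is compared with its own
    simulated distribution; per-variant empirical p-values are Bonferroni
    corrected by k and flagged below ``outlier_alpha``.  The corrected
    estimate is the IVW recomputed without the flagged variants.

    Both p-values carry the +1/(n_sim + 1) continuity correction, so they are
    never exactly zero.  The method assumes at least 50% of instruments are
    valid; a warning is emitted when more than half get flagged.
    """
    k = hs.n_snps
    if k < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO requires >= 4 instruments, got {k}")
    bx, by, sy = hs.beta_exposure, hs.beta_outcome, hs.se_outcome
    w = 1.0 / sy**2

    slopes_obs = _loo_slopes(bx, by, w)
    resid_obs = by - slopes_obs * bx
    e_obs = w * resid_obs**2
    rss_obs = float(np.sum(e_obs))

    rng = np.random.default_rng(seed)
    y_sim = rng.normal(loc=slopes_obs * bx, scale=sy, size=(n_sim, k))
    s_xy = y_sim @ (w * bx)
    s_xx = float(np.sum(w * bx**2))
    slopes_sim = (s_xy[:, None] - (w * bx)[None, :] * y_sim) / (s_xx - (w * bx**2)[None, :])
    resid_sim = y_sim - slopes_sim * bx[None, :]
    e_sim = w[None, :] * resid_sim**2
    rss_sim = e_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_raw = (1 + np.sum(e_sim >= e_obs[None, :], axis=0)) / (n_sim + 1)
    p_bonf = np.minimum(1.0, p_raw * k)
    flagged = [hs.pairs[j].variant_id for j in range(k) if p_bonf[j] < outlier_alpha]
    outlier_p = {hs.pairs[j].variant_id: float(p_bonf[j]) for j in range(k)}

    if len(flagged) > k / 2:
        log.warning(
            "MR-PRESSO flagged %d of %d instruments; the 50%%-valid assumption "
            "underlying the test is doubtful here",
            len(flagged), k,
        )

    corrected: MrEstimate | None = None
    if flagged and len(flagged) < k:
        cleaned = hs.drop(flagged, ExclusionReason.PRESSO_OUTLIER)
        corrected = ivw(cleaned)

    return PressoResult(
        global_p=global_p,
        global_rss=rss_obs,
        outliers=flagged,
        outlier_pvalues=outlier_p,
        corrected=corrected,
        n_sim=n_sim,
    )


def leave_one_out(hs: HarmonizedSet, mode: str = "random_multiplicative") -> pd.DataFrame:
    """IVW estimate excluding each variant in turn.

    Returns a DataFrame with one row per excluded variant:
    (variant_id, beta, se, pvalue, n_snps).
    """
    k = hs.n_snps
    if k < 2:
        raise InsufficientInstrumentsError(f"leave-one-out requires >= 2 instruments, got {k}")
    rows = []
    ids = hs.variant_ids
    for vid in ids:
        est = ivw(hs.subset([v for v in ids if v != vid]), mode=mode)
        rows.append({"variant_id": vid, "beta": est.beta, "se": est.se,
                     "pvalue": est.pvalue, "n_snps": est.n_snps})
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Full diagnostic bundle for one exposure-outcome pair."""

    q_stat: float
    q_df: int
    q_pvalue: float
    egger: EggerResult | None
    presso: PressoResult | None
    loo_table: pd.DataFrame

    def to_dict(self) -> dict:
        d: dict = {
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_pvalue": self.q_pvalue,
        }
        if self.egger is not None:
            d["egger_intercept"] = {
                "value": self.egger.intercept.beta,
                "se": self.egger.intercept.se,
                "pvalue": self.egger.intercept.pvalue,
            }
            d["i2_gx"] = self.egger.i2_gx
        if self.presso is not None:
            d["presso_global_p"] = self.presso.global_p
            d["presso_outliers"] = list(self.presso.outliers)
            if self.presso.corrected is not None:
                c = self.presso.corrected
                d["presso_corrected"] = {"beta": c.beta, "se": c.se,
                                         "pvalue": c.pvalue, "n_snps": c.n_snps}
        d["leave_one_out"] = self.loo_table.to_dict(orient="records")
        return d


def sensitivity_report(
    hs: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    ivw_mode: str = "random_multiplicative",
) -> SensitivityReport:
    """Run the full diagnostic suite; stages whose instrument-count minimum
    is not met are reported as absent rather than raising."""
    q, df, qp = cochran_q(hs)
    egger = mr_egger(hs) if hs.n_snps >= 3 else None
    presso = (
        mr_presso(hs, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
        if hs.n_snps >= 4
        else None
    )
    loo = leave_one_out(hs, mode=ivw_mode)
    return SensitivityReport(q_stat=q, q_df=df, q_pvalue=qp,
                             egger=egger, presso=presso, loo_table=loo)
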