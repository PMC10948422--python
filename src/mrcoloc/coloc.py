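"""Bayesian colocalization of two traits in a genomic region.

Tests whether two traits share a single causal variant within a region
(conventionally the lead variant plus/minus 500 kb) by enumerating five
hypotheses under a one-causal-variant-per-trait assumption:

* H0 — no association with either trait,
* H1 / H2 — association with trait 1 / trait 2 only,
* H3 — both traits associated, through *distinct* causal variants,
* H4 — both traits associated through a *shared* causal variant.

Per-variant evidence enters through Wakefield's approximate Bayes factor,
computed from each variant's estimate, standard error, and a prior standard
deviation on true effect sizes.  Hypothesis sums are accumulated in log space
for numerical stability.  A posterior for H4 at or above 0.75 is read as
strong evidence of colocalization, between 0.5 and 0.75 as moderate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import DomainError, EmptySetError
from .sumstats import GwasRecord

#: Default priors: per-variant probability of association with trait 1 only,
#: trait 2 only, and both traits.
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5


@dataclass(frozen=True)
class ColocPriors:
    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2)):
            raise DomainError("need 0 < p12 <= p1, p2")
        if not (self.p1 < 1 and self.p2 < 1 and self.p1 + self.p2 + self.p12 < 1):
            raise DomainError("priors must sum to less than 1")


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int
    priors: ColocPriors
    classification: str
    lead_variant: str
    window_bp: int = 500_000

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])

    def to_dict(self) -> dict:
        return {
            "pph0": self.pph0, "pph1": self.pph1, "pph2": self.pph2,
            "pph3": self.pph3, "pph4": self.pph4,
            "n_snps": self.n_snps,
            "priors": {"p1": self.priors.p1, "p2": self.priors.p2, "p12": self.priors.p12},
            "classification": self.classification,
            "lead_variant": self.lead_variant,
            "window_bp": self.window_bp,
        }


def extract_region(
    records: Iterable[GwasRecord], lead: str, window_bp: int = 500_000
) -> list[GwasRecord]:
    """All records on the lead's chromosome within window_bp of it (inclusive)."""
    records = list(records)
    lead_rec = next((r for r in records if r.variant_id == lead), None)
    if lead_rec is None:
        raise EmptySetError(f"lead variant {lead!r} absent from records")
    return [
        r
        for r in records
        if r.chrom == lead_rec.chrom and abs(r.pos - lead_rec.pos) <= window_bp
    ]


def wakefield_log_abf(beta, se, prior_sd: float):
    """Log approximate Bayes factor for a single association.

    With z = beta/se, V = se^2 and W = prior_sd^2:
    log ABF = 0.5 log(V / (V + W)) + 0.5 z^2 W / (V + W).
    Accepts scalars or arrays.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DomainError("se must be > 0")
    if prior_sd <= 0:
        raise DomainError("prior_sd must be > 0")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    out = 0.5 * np.log(v / (v + w)) + 0.5 * z2 * w / (v + w)
    return float(out) if out.ndim == 0 else out


def effects_from_pvalues(pvalues, maf, n, case_fraction: float | None = None):
    """Reconstruct (|beta|, se) from p-values for files lacking standard errors.

    Uses se = 1 / sqrt(2 MAF (1-MAF) N) for quantitative traits, additionally
    scaled by sqrt(phi (1-phi)) for case-control studies with case fraction
    phi; |z| from the two-sided p.  Signs are lost, which is immaterial for
    Bayes-factor computation.
    """
    p = np.asarray(pvalues, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must be in (0, 1]")
    if np.any((maf <= 0) | (maf >= 1)):
        raise DomainError("maf must be in (0, 1)")
    var = 2.0 * maf * (1.0 - maf) * n
    if case_fraction is not None:
        if not (0.0 < case_fraction < 1.0):
            raise DomainError("case_fraction must be in (0, 1)")
        var = var * case_fraction * (1.0 - case_fraction)
    se = 1.0 / np.sqrt(var)
    z = norm.isf(p / 2.0)
    return z * se, se


def _as_effect_arrays(region) -> tuple[list[str], np.ndarray, np.ndarray]:
    ids, beta, se = [], [], []
    for item in region:
        if isinstance(item, GwasRecord):
            ids.append(item.variant_id)
            beta.append(item.beta)
            se.append(item.se)
        else:
            vid, b, s = item
            ids.append(str(vid))
            beta.append(float(b))
            se.append(float(s))
    return ids, np.asarray(beta), np.asarray(se)


def classify_coloc(pph4: float) -> str:
    """'strong' (pph4 >= 0.75), 'moderate' (0.5 < pph4 < 0.75), else 'none'."""
    if not (0.0 <= pph4 <= 1.0):
        raise DomainError(f"pph4 must be in [0, 1], got {pph4}")
    if pph4 >= 0.75:
        return "strong"
    if pph4 > 0.5:
        return "moderate"
    return "none"


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)); -inf when the difference is non-positive."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    region1: Sequence,
    region2: Sequence,
    priors: ColocPriors = ColocPriors(),
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
    window_bp: int = 500_000,
) -> ColocResult:
    """Enumerate the five colocalization hypotheses over a shared region.

    ``region1`` and ``region2`` are sequences of GwasRecord or
    (variant_id, beta, se) tuples; the analysis is restricted to the variant
    IDs present in both.  ``prior_sd1``/``prior_sd2`` are the effect-size
    prior standard deviations per trait (0.15 is conventional for
    quantitative traits, 0.2 on the log-odds scale for case-control).

    Effect signs must be coherent across traits (harmonize the regions with
    :func:`mrcoloc.sumstats.harmonize` first when they come from different
    studies); Bayes factors depend only on z^2, so orientation affects
    nothing here, but upstream harmonization guards against duplicate or
    incompatible variant records.
    """
    ids1, beta1, se1 = _as_effect_arrays(region1)
    ids2, beta2, se2 = _as_effect_arrays(region2)
    idx2 = {v: i for i, v in enumerate(ids2)}
    shared = [v for v in ids1 if v in idx2]
    if not shared:
        raise EmptySetError("regions share no variant IDs")
    i1 = [ids1.index(v) for v in shared]
    i2 = [idx2[v] for v in shared]
    labf1 = wakefield_log_abf(beta1[i1], se1[i1], prior_sd1)
    labf2 = wakefield_log_abf(beta2[i2], se2[i2], prior_sd2)
    for name, arr in (("trait1", labf1), ("trait2", labf2)):
        if not np.all(np.isfinite(arr)):
            bad = shared[int(np.argmax(~np.isfinite(arr)))]
            raise DomainError(f"non-finite ABF for {name} at variant {bad}")

    lsum1 = float(logsumexp(labf1))
    lsum2 = float(logsumexp(labf2))
    l12 = float(logsumexp(labf1 + labf2))

    lh = np.array([
        0.0,
        np.log(priors.p1) + lsum1,
        np.log(priors.p2) + lsum2,
        np.log(priors.p1) + np.log(priors.p2) + _log_diff_exp(lsum1 + lsum2, l12),
        np.log(priors.p12) + l12,
    ])
    post = np.exp(lh - logsumexp(lh))
    post /= post.sum()

    lead = shared[int(np.argmax(labf1 + labf2))]
    return ColocResult(
        pph0=float(post[0]), pph1=float(post[1]), pph2=float(post[2]),
        pph3=float(post[3]), pph4=float(post[4]),
        n_snps=len(shared), priors=priors,
        classification=classify_coloc(float(post[4])),
        lead_variant=lead, window_bp=window_bp,
    )
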