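"""Orchestration: multi-phenotype bidirectional MR, FDR, and table checking.

Runs the full chain per exposure-outcome pair — instrument selection,
harmonization, exclusion filters, MR-PRESSO outlier purge, all estimators,
and the sensitivity suite — then applies Benjamini-Hochberg FDR to the IVW
p-values within declared phenotype families and assigns significance tiers:
``significant`` when the adjusted p is below 0.1, ``nominal`` when the raw
IVW p is below 0.05 but the adjusted p is not, else ``null``.

Also houses :func:`consistency_check`, which recomputes the Wald p implied by
reported (OR, CI) or (beta, se) rows of a published-style results table and
flags triplets that cannot be reconciled within their printed rounding.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .errors import DomainError, EmptySetError
from .instruments import (
    LdReference,
    SelectionConfig,
    apply_exclusions,
    select_instruments,
)
from .mr import ALL_METHODS, MrEstimate, run_all_methods, wald_p_from_or_ci
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import ExclusionReason, GwasRecord, HarmonizedSet, harmonize

log = logging.getLogger(__name__)


def bh_adjust(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``m`` is the family size; it defaults to the number of p-values but may
    be larger when the family includes tests not passed in (adjusted value
    for rank i is then m * p_(i) / i before the monotonicity pass).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must be in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise DomainError(f"family size m={m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def classify_tier(p_ivw: float, p_fdr: float) -> str:
    """'significant' (p_fdr < 0.1), 'nominal' (p < 0.05, p_fdr >= 0.1), 'null'."""
    if p_fdr < 0.1:
        return "significant"
    if p_ivw < 0.05:
        return "nominal"
    return "null"


@dataclass
class AnalysisResultRow:
    """All results for one exposure-outcome pair in one direction."""

    exposure: str
    outcome: str
    direction: str
    family: str
    estimates: list[MrEstimate]
    sensitivity: SensitivityReport
    harmonized: HarmonizedSet
    p_fdr: float = float("nan")
    tier: str = "null"

    @property
    def ivw(self) -> MrEstimate:
        est = next((e for e in self.estimates if e.method == "ivw"), None)
        if est is None:
            raise EmptySetError(f"no IVW estimate for {self.exposure} -> {self.outcome}")
        return est


def analyze_pair(
    exposure_records: Iterable[GwasRecord],
    outcome_records: Iterable[GwasRecord],
    ld: LdReference,
    config: SelectionConfig,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    direction: str = "forward",
    family: str = "default",
    blocklist: Iterable[str] = (),
    binary_outcome: bool = True,
    seed: int = 0,
    n_boot: int = 1000,
    presso_nsim: int = 1000,
    methods: tuple[str, ...] = ALL_METHODS,
) -> AnalysisResultRow:
    """Full single-pair chain: select, harmonize, exclude, purge, estimate."""
    instruments = select_instruments(exposure_records, ld, config)
    hs = harmonize(instruments, list(outcome_records), exposure_name, outcome_name)
    hs = apply_exclusions(hs, blocklist, config)

    if hs.n_snps >= 4:
        from .sensitivity import mr_presso

        presso = mr_presso(hs, n_sim=presso_nsim, seed=seed)
        if presso.outliers and len(presso.outliers) < hs.n_snps:
            hs = hs.drop(presso.outliers, ExclusionReason.PRESSO_OUTLIER)

    estimates = run_all_methods(
        hs, methods=methods, binary_outcome=binary_outcome, n_boot=n_boot, seed=seed
    )
    sens = sensitivity_report(hs, n_sim=presso_nsim, seed=seed) if hs.n_snps >= 2 else None
    if sens is None:
        raise EmptySetError(
            f"{exposure_name} -> {outcome_name}: fewer than 2 instruments survive exclusion"
        )
    return AnalysisResultRow(
        exposure=exposure_name,
        outcome=outcome_name,
        direction=direction,
        family=family,
        estimates=estimates,
        sensitivity=sens,
        harmonized=hs,
    )


def apply_fdr(rows: list[AnalysisResultRow],
              family_sizes: Mapping[str, int] | None = None) -> list[AnalysisResultRow]:
    """BH-adjust IVW p-values within each family and assign tiers in place."""
    family_sizes = dict(family_sizes or {})
    by_family: dict[str, list[int]] = {}
    for i, row in enumerate(rows):
        by_family.setdefault(row.family, []).append(i)
    for fam, idx in by_family.items():
        p = [rows[i].ivw.pvalue for i in idx]
        m = max(family_sizes.get(fam, len(p)), len(p))
        adj = bh_adjust(p, m=m)
        for i, a in zip(idx, adj):
            rows[i].p_fdr = float(a)
            rows[i].tier = classify_tier(rows[i].ivw.pvalue, float(a))
    return rows


def run_bidirectional(
    exposures: Mapping[str, Iterable[GwasRecord]],
    outcome: Iterable[GwasRecord],
    ld: LdReference,
    forward_config: SelectionConfig,
    reverse_config: SelectionConfig,
    outcome_name: str = "outcome",
    blocklist: Iterable[str] = (),
    binary_outcome: bool = True,
    families: Mapping[str, str] | None = None,
    family_sizes: Mapping[str, int] | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    presso_nsim: int = 1000,
    reverse: bool = True,
) -> list[AnalysisResultRow]:
    """Forward MR of every exposure on the outcome, then (optionally) reverse
    MR of the outcome on every exposure, followed by family-wise FDR.

    ``families`` maps exposure name to FDR family label (default: one family
    per direction); ``family_sizes`` declares nominal family sizes larger
    than the number of rows actually run.  Results are returned sorted by
    (direction, exposure name) so the output does not depend on input order.
    """
    outcome_records = list(outcome)
    families = dict(families or {})
    rows: list[AnalysisResultRow] = []
    for name in sorted(exposures):
        fam = families.get(name, "forward")
        try:
            rows.append(
                analyze_pair(
                    exposures[name], outcome_records, ld, forward_config,
                    exposure_name=name, outcome_name=outcome_name,
                    direction="forward", family=fam, blocklist=blocklist,
                    binary_outcome=binary_outcome, seed=seed,
                    n_boot=n_boot, presso_nsim=presso_nsim,
                )
            )
        except EmptySetError as exc:
            log.warning("forward %s skipped: %s", name, exc)
    if reverse:
        for name in sorted(exposures):
            fam = families.get(f"reverse:{name}", "reverse")
            try:
                rows.append(
                    analyze_pair(
                        outcome_records, exposures[name], ld, reverse_config,
                        exposure_name=outcome_name, outcome_name=name,
                        direction="reverse", family=fam, blocklist=blocklist,
                        binary_outcome=False, seed=seed,
                        n_boot=n_boot, presso_nsim=presso_nsim,
                    )
                )
            except EmptySetError as exc:
                log.warning("reverse %s skipped: %s", name, exc)
    rows.sort(key=lambda r: (r.direction, r.exposure, r.outcome))
    return apply_fdr(rows, family_sizes)


def results_frame(rows: list[AnalysisResultRow]) -> pd.DataFrame:
    """Wide results table: one row per (pair, method)."""
    out = []
    for row in rows:
        for est in row.estimates:
            out.append({
                "exposure": row.exposure,
                "outcome": row.outcome,
                "direction": row.direction,
                "family": row.family,
                "method": est.method,
                "nsnp": est.n_snps,
                "beta": est.beta,
                "se": est.se,
                "pvalue": est.pvalue,
                "or": est.or_value,
                "or_lci95": est.or_lci,
                "or_uci95": est.or_uci,
                "p_fdr": row.p_fdr if est.method == "ivw" else np.nan,
                "tier": row.tier if est.method == "ivw" else "",
                "q_pvalue": row.sensitivity.q_pvalue,
                "presso_global_p": (
                    row.sensitivity.presso.global_p
                    if row.sensitivity.presso is not None else np.nan
                ),
            })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# printed-table consistency checking


def _round_interval(text: str) -> tuple[float, float]:
    """Interval of real values that round to the printed decimal string."""
    text = text.strip()
    value = float(text)
    if "." in text:
        digits = len(text.split(".")[1])
    elif "e" in text.lower():
        mantissa = text.lower().split("e")[0]
        digits = len(mantissa.split(".")[1]) if "." in mantissa else 0
    else:
        digits = 0
    half = 0.5 * 10.0 ** (-digits)
    return value - half, value + half


def _implied_p_or_ci(or_s: str, lci_s: str, uci_s: str) -> tuple[float, float, float]:
    """(point implied p, min, max) over the rounding intervals of the inputs."""
    orv, lci, uci = float(or_s), float(lci_s), float(uci_s)
    point = wald_p_from_or_ci(orv, lci, uci)
    ps = []
    for o in _round_interval(or_s):
        for l in _round_interval(lci_s):
            for u in _round_interval(uci_s):
                if 0 < l < o < u:
                    ps.append(wald_p_from_or_ci(o, l, u))
    return point, min(ps, default=point), max(ps, default=point)


def _implied_p_beta_se(beta_s: str, se_s: str) -> tuple[float, float, float]:
    beta, se = float(beta_s), float(se_s)
    point = float(2.0 * stats.norm.sf(abs(beta) / se))
    ps = []
    for b in _round_interval(beta_s):
        for s in _round_interval(se_s):
            if s > 0:
                ps.append(float(2.0 * stats.norm.sf(abs(b) / s)))
    return point, min(ps, default=point), max(ps, default=point)


def consistency_check(table: pd.DataFrame) -> pd.DataFrame:
    """Check printed (OR, 95% CI, p) or (beta, se, p) rows for coherence.

    For each row the implied two-sided Wald p is recomputed from the interval
    estimate; ``flag`` is True when no combination of values consistent with
    the printed rounding can reproduce the printed p.  The table must carry
    string-typed columns so printed precision is preserved: either
    (``or``, ``or_lci95``, ``or_uci95``) or (``beta``, ``se``), plus
    ``pvalue``.
    """
    out = []
    for _, row in table.iterrows():
        p_s = str(row["pvalue"])
        has_or = "or" in row and str(row.get("or", "")).strip() not in ("", "nan")
        if has_or:
            point, lo, hi = _implied_p_or_ci(
                str(row["or"]), str(row["or_lci95"]), str(row["or_uci95"])
            )
        else:
            point, lo, hi = _implied_p_beta_se(str(row["beta"]), str(row["se"]))
        p_lo, p_hi = _round_interval(p_s)
        flag = (hi < p_lo) or (lo > p_hi)
        rec = dict(row)
        rec.update({"implied_p": point, "implied_p_min": lo, "implied_p_max": hi,
                    "flag": flag})
        out.append(rec)
    return pd.DataFrame(out)


def load_reported_results() -> pd.DataFrame:
    """Shipped example table of published-style MR estimates (brain-structure
    phenotypes vs ALS risk) for the consistency checker; values are kept as
    strings so printed precision is preserved."""
    from importlib.resources import files

    path = files("mrcoloc").joinpath("data/reported_mr_results.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# run manifests


@dataclass
class RunManifest:
    """Auditable record of a pipeline run: config digest, seeds, counts."""

    config_digest: str
    seeds: dict[str, int]
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )
    record_counts: dict[str, int] = field(default_factory=dict)

    @classmethod
    def for_config(cls, config_obj, seeds: Mapping[str, int],
                   record_counts: Mapping[str, int] | None = None) -> "RunManifest":
        canonical = json.dumps(config_obj, sort_keys=True, default=str)
        digest = hashlib.sha256(canonical.encode()).hexdigest()
        return cls(config_digest=digest, seeds=dict(seeds),
                   record_counts=dict(record_counts or {}))

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_digest": self.config_digest,
                    "seeds": self.seeds,
                    "version": self.version,
                    "timestamp": self.timestamp,
                    "record_counts": self.record_counts,
                },
                fh,
                indent=2,
            )
            fh.write("\n")
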