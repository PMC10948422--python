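"""Instrument selection: significance threshold, LD clumping, strength filters.

A valid MR instrument must be (i) robustly associated with the exposure,
(ii) independent of other instruments, and (iii) free of pathways to the
outcome other than through the exposure.  This module implements the
summary-level selection machinery: p-value thresholding, greedy LD clumping
against a reference r-squared matrix, minor-allele-frequency filtering,
confounder blocklist and outcome-association exclusion, and the F-statistic
weak-instrument filter (F < 10 removed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError, EmptySetError
from .sumstats import ExclusionReason, GwasRecord, HarmonizedSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable thresholds of the instrument-selection stage.

    Defaults are the forward-direction settings (brain-structure exposures);
    use :data:`REVERSE_PRESET` for the disease-as-exposure direction, which
    uses the conventional genome-wide 5e-8 threshold and a 250 kb window.
    """

    p_threshold: float = 5e-6
    r2_threshold: float = 0.001
    window_bp: int = 10_000_000
    maf_min: float = 0.01
    f_min: float = 10.0
    outcome_p_exclude: float = 0.05
    r2_method: str = "z"  # per-SNP variance explained: "z" or "maf"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ConfigurationError("r2_threshold must be in [0, 1]")
        if self.window_bp <= 0:
            raise ConfigurationError("window_bp must be > 0")
        if not (0.0 <= self.maf_min < 0.5):
            raise ConfigurationError("maf_min must be in [0, 0.5)")
        if self.r2_method not in ("z", "maf"):
            raise ConfigurationError("r2_method must be 'z' or 'maf'")


FORWARD_PRESET = SelectionConfig()
REVERSE_PRESET = SelectionConfig(p_threshold=5e-8, window_bp=250_000)
PRESETS: dict[str, SelectionConfig] = {"forward": FORWARD_PRESET, "reverse": REVERSE_PRESET}


@dataclass
class LdReference:
    """Pairwise LD r-squared matrix over a panel of variants.

    Stands in for a population reference panel: ``r2`` is symmetric with a
    unit diagonal, and ``positions`` maps each variant to (chrom, pos).
    """

    variant_ids: list[str]
    r2: np.ndarray
    positions: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ConfigurationError("r2 matrix shape does not match variant count")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ConfigurationError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ConfigurationError("r2 matrix diagonal is not 1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def from_tsv(cls, matrix_path: str, positions_path: str) -> "LdReference":
        """Square r2 TSV with variant-ID header row/column + positions TSV."""
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        ids = [str(c) for c in mat.columns]
        if [str(i) for i in mat.index] != ids:
            raise ConfigurationError("LD matrix row and column variant IDs differ")
        pos = pd.read_csv(positions_path, sep="\t", dtype={"variant_id": str, "chrom": str})
        positions = {
            str(r.variant_id): (str(r.chrom), int(r.pos)) for r in pos.itertuples(index=False)
        }
        return cls(ids, mat.to_numpy(dtype=float), positions)

    @classmethod
    def from_dosages(cls, dosage_path: str, positions_path: str) -> "LdReference":
        """Variants-by-samples dosage TSV; r2 = squared Pearson correlation."""
        df = pd.read_csv(dosage_path, sep="\t", index_col=0)
        ids = [str(i) for i in df.index]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(df.to_numpy(dtype=float))
        r2 = np.nan_to_num(corr, nan=0.0) ** 2
        np.fill_diagonal(r2, 1.0)
        pos = pd.read_csv(positions_path, sep="\t", dtype={"variant_id": str, "chrom": str})
        positions = {
            str(r.variant_id): (str(r.chrom), int(r.pos)) for r in pos.itertuples(index=False)
        }
        return cls(ids, r2, positions)

    def write(self, matrix_path: str, positions_path: str) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            matrix_path, sep="\t"
        )
        pd.DataFrame(
            [(v, c, p) for v, (c, p) in self.positions.items()],
            columns=["variant_id", "chrom", "pos"],
        ).to_csv(positions_path, sep="\t", index=False)


@dataclass(frozen=True)
class FStatResult:
    """Instrument-strength F-statistic and its ingredients."""

    r2_total: float
    n: float
    k: int
    f: float


def compute_f_statistic(r2_total: float, n: float, k: int) -> FStatResult:
    """F = R^2 (N - 1 - k) / ((1 - R^2) k).

    ``r2_total`` is the variance in the exposure explained jointly by the
    ``k`` instruments, ``n`` the exposure GWAS sample size.  F below 10 is
    the conventional weak-instrument flag.
    """
    if not (0.0 <= r2_total < 1.0):
        raise DomainError(f"r2_total must be in [0, 1), got {r2_total}")
    if k < 1 or n <= k + 1:
        raise DomainError(f"need n > k + 1 >= 2, got n={n}, k={k}")
    f = r2_total * (n - 1 - k) / ((1.0 - r2_total) * k)
    return FStatResult(r2_total=float(r2_total), n=float(n), k=int(k), f=float(f))


def snp_variance_explained(record: GwasRecord, method: str = "z") -> float:
    """Per-SNP variance in the exposure explained by one variant.

    ``"z"`` (default) uses z^2 / (z^2 + n - 2) with z = beta/se, which needs
    only summary fields; ``"maf"`` uses 2 MAF (1 - MAF) beta^2, valid for
    standardized traits.
    """
    if method == "z":
        if not record.n > 2:
            raise DomainError("n must be > 2 for z-based variance explained")
        if not record.se > 0:
            raise DomainError("se must be > 0")
        z = record.beta / record.se
        return float(z * z / (z * z + record.n - 2.0))
    if method == "maf":
        if not (0.0 < record.eaf < 1.0):
            raise DomainError("eaf must be in (0, 1) for maf-based variance explained")
        maf = record.maf
        return float(2.0 * maf * (1.0 - maf) * record.beta**2)
    raise ConfigurationError("method must be 'z' or 'maf'")


def ld_clump(
    candidates: Iterable[GwasRecord],
    ld: LdReference,
    config: SelectionConfig = FORWARD_PRESET,
    on_missing: str = "drop",
) -> list[GwasRecord]:
    """Greedy LD clumping: keep the strongest variant per LD neighborhood.

    Candidates are ranked by ascending p-value (ties by variant_id); the best
    remaining variant is kept, and all remaining variants on the same
    chromosome within ``window_bp`` of it with r2 above ``r2_threshold`` are
    discarded.  The kept set is mutually independent under that criterion and
    does not depend on input order.

    ``on_missing`` controls candidates absent from the LD reference:
    ``"drop"`` (default, with a warning) or ``"error"``.
    """
    if on_missing not in ("drop", "error"):
        raise ConfigurationError("on_missing must be 'drop' or 'error'")
    pool: list[GwasRecord] = []
    for rec in candidates:
        if rec.variant_id not in ld:
            if on_missing == "error":
                raise ConfigurationError(f"{rec.variant_id} absent from LD reference")
            log.warning("%s absent from LD reference; dropped from clumping", rec.variant_id)
            continue
        pool.append(rec)

    pool.sort(key=lambda r: (r.pvalue, r.variant_id))
    kept: list[GwasRecord] = []
    while pool:
        index = pool.pop(0)
        kept.append(index)
        survivors = []
        for rec in pool:
            if (
                rec.chrom == index.chrom
                and abs(rec.pos - index.pos) <= config.window_bp
                and ld.r2_between(rec.variant_id, index.variant_id) > config.r2_threshold
            ):
                continue
            survivors.append(rec)
        pool = survivors
    return kept


def select_instruments(
    records: Iterable[GwasRecord],
    ld: LdReference,
    config: SelectionConfig = FORWARD_PRESET,
    on_missing: str = "drop",
) -> list[GwasRecord]:
    """Significance + MAF filter followed by LD clumping."""
    candidates = [
        r for r in records if r.pvalue < config.p_threshold and r.maf > config.maf_min
    ]
    if not candidates:
        raise EmptySetError(
            f"no variants pass p < {config.p_threshold} and MAF > {config.maf_min}"
        )
    return ld_clump(candidates, ld, config, on_missing=on_missing)


def read_blocklist(path: str) -> list[str]:
    """One variant_id per line; '#' starts a comment; extra columns ignored."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            ids.append(line.split()[0])
    return ids


def _single_snp_f(beta: float, se: float, n: float) -> float:
    """Single-instrument F via the closed form; equals (beta/se)^2."""
    z = beta / se
    if math.isfinite(n) and n > 3:
        r2 = z * z / (z * z + n - 2.0)
        return compute_f_statistic(r2, n, 1).f
    return float(z * z)


def apply_exclusions(
    instruments: HarmonizedSet,
    confounder_blocklist: Iterable[str] = (),
    config: SelectionConfig = FORWARD_PRESET,
) -> HarmonizedSet:
    """Outcome-association, confounder-blocklist, and weak-instrument filters.

    Pairs whose outcome p-value is below ``outcome_p_exclude`` may act on the
    outcome directly and are removed; blocklisted variants (known confounder
    associations) are removed; pairs whose single-SNP F-statistic falls below
    ``f_min`` are removed as weak instruments.
    """
    if instruments.n_snps == 0:
        raise EmptySetError("apply_exclusions received an empty harmonized set")
    hs = instruments

    outcome_assoc = []
    for p in hs.pairs:
        p_out = p.pval_outcome
        if math.isnan(p_out):
            p_out = float(2.0 * stats.norm.sf(abs(p.beta_outcome) / p.se_outcome))
        if p_out < config.outcome_p_exclude:
            outcome_assoc.append(p.variant_id)
    hs = hs.drop(outcome_assoc, ExclusionReason.OUTCOME_ASSOCIATED)

    blocked = set(confounder_blocklist) & {p.variant_id for p in hs.pairs}
    hs = hs.drop(blocked, ExclusionReason.CONFOUNDER)

    weak = [
        p.variant_id
        for p in hs.pairs
        if _single_snp_f(p.beta_exposure, p.se_exposure, p.n_exposure) < config.f_min
    ]
    hs = hs.drop(weak, ExclusionReason.WEAK_INSTRUMENT)

    if hs.n_snps == 0:
        raise EmptySetError(
            f"all instruments for '{instruments.exposure_name}' vs "
            f"'{instruments.outcome_name}' were excluded"
        )
    return hs
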