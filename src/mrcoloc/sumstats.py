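"""Reading, validation, and allele harmonization of GWAS summary statistics.

Two-sample Mendelian randomization combines per-variant association estimates
from two independent GWAS.  Before any causal estimate can be formed, both
studies must report their effects relative to the *same* effect allele.  This
module reads tab-separated summary tables into :class:`GwasRecord` collections
and aligns an exposure study with an outcome study into a
:class:`HarmonizedSet`, the container every downstream estimator consumes.

Strand-ambiguous (palindromic, A/T or G/C) variants are excluded outright by
default because the reporting strand cannot be inferred from the alleles
alone; an optional allele-frequency rescue exists but is off by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from .errors import ConfigurationError, EmptySetError

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")
_PALINDROMIC = ({"A", "T"}, {"C", "G"})

#: Default header names, matching the most common summary-statistics dialect.
DEFAULT_COLUMNS: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}


class ExclusionReason(str, Enum):
    """Why a variant was removed from a harmonized instrument set."""

    PALINDROMIC = "palindromic"
    INCOMPATIBLE_ALLELES = "incompatible_alleles"
    MISSING_IN_OUTCOME = "missing_in_outcome"
    OUTCOME_ASSOCIATED = "outcome_associated"
    CONFOUNDER = "confounder"
    WEAK_INSTRUMENT = "weak_instrument"
    PRESSO_OUTLIER = "presso_outlier"


@dataclass(frozen=True)
class GwasRecord:
    """One variant's association summary in one GWAS.

    ``beta`` is a log odds ratio for binary traits and is in trait units for
    quantitative traits.  ``eaf`` is the frequency of ``effect_allele``.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))

    @property
    def is_palindromic(self) -> bool:
        return set(self.alleles) in _PALINDROMIC

    def validation_error(self) -> str | None:
        """Return a short reason string if the record is invalid, else None."""
        if (
            self.effect_allele not in _VALID_BASES
            or self.other_allele not in _VALID_BASES
        ):
            return "allele not a single base (indels/multi-allelic rejected)"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not (self.se > 0 and math.isfinite(self.se)):
            return "se must be > 0"
        if not (0.0 <= self.eaf <= 1.0):
            return "eaf outside [0, 1]"
        if not (0.0 < self.pvalue <= 1.0):
            return "pvalue outside (0, 1]"
        if self.pos < 1:
            return "pos must be >= 1"
        if not self.n > 0:
            return "n must be > 0"
        return None


class ReadResult(Sequence):
    """Records parsed from a summary file plus the rows that were skipped.

    Behaves as a sequence of :class:`GwasRecord`; ``skipped`` carries
    ``(line_number, reason)`` tuples for rows that failed validation.
    """

    def __init__(self, records: list[GwasRecord], skipped: list[tuple[int, str]]):
        self.records = records
        self.skipped = skipped

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[GwasRecord]:
        return iter(self.records)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def read_sumstats(
    path: str,
    column_map: Mapping[str, str] | None = None,
) -> ReadResult:
    """Read a (optionally gzip-compressed) TSV of GWAS summary statistics.

    Parameters
    ----------
    path:
        TSV file with a header row.
    column_map:
        Maps canonical field names (keys of :data:`DEFAULT_COLUMNS`) to the
        header names actually present.  Missing entries fall back to the
        defaults.

    Rows that fail validation (non-SNP alleles, ``se <= 0``, frequency outside
    [0, 1], ...) are skipped, counted, and logged with their line numbers.
    Records are returned sorted by (chrom, pos).
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown canonical fields in column_map: {sorted(unknown)}")
        cmap.update(column_map)

    df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    missing = [h for h in cmap.values() if h not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required columns {missing}; present: {list(df.columns)}"
        )

    records: list[GwasRecord] = []
    skipped: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        d = dict(zip(df.columns, row))
        try:
            rec = GwasRecord(
                variant_id=str(d[cmap["variant_id"]]).strip(),
                chrom=str(d[cmap["chrom"]]).strip(),
                pos=int(float(d[cmap["pos"]])),
                effect_allele=str(d[cmap["effect_allele"]]).strip().upper(),
                other_allele=str(d[cmap["other_allele"]]).strip().upper(),
                eaf=float(d[cmap["eaf"]]),
                beta=float(d[cmap["beta"]]),
                se=float(d[cmap["se"]]),
                pvalue=float(d[cmap["pvalue"]]),
                n=float(d[cmap["n"]]),
            )
        except (TypeError, ValueError) as exc:
            skipped.append((line_no, f"unparseable field: {exc}"))
            continue
        err = rec.validation_error()
        if err is not None:
            skipped.append((line_no, err))
            continue
        records.append(rec)

    for line_no, reason in skipped:
        log.warning("%s line %d skipped: %s", path, line_no, reason)
    records.sort(key=lambda r: (r.chrom, r.pos, r.variant_id))
    return ReadResult(records, skipped)


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects for one variant on a common effect allele."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float = float("nan")
    eaf_outcome: float = float("nan")
    pval_exposure: float = float("nan")
    pval_outcome: float = float("nan")
    n_exposure: float = float("nan")
    n_outcome: float = float("nan")


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a shared effect-allele orientation.

    This is the unit all MR estimators consume.  ``exclusions`` records every
    variant removed on the way here together with a machine-readable reason.
    """

    exposure_name: str
    outcome_name: str
    pairs: list[HarmonizedPair]
    exclusions: list[tuple[str, ExclusionReason]] = field(default_factory=list)

    def __post_init__(self) -> None:
        paired = {p.variant_id for p in self.pairs}
        dup = paired & {v for v, _ in self.exclusions}
        if dup:
            raise ValueError(f"variants both paired and excluded: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_snps(self) -> int:
        return len(self.pairs)

    @property
    def variant_ids(self) -> list[str]:
        return [p.variant_id for p in self.pairs]

    def _arr(self, attr: str) -> np.ndarray:
        return np.array([getattr(p, attr) for p in self.pairs], dtype=float)

    @property
    def beta_exposure(self) -> np.ndarray:
        return self._arr("beta_exposure")

    @property
    def se_exposure(self) -> np.ndarray:
        return self._arr("se_exposure")

    @property
    def beta_outcome(self) -> np.ndarray:
        return self._arr("beta_outcome")

    @property
    def se_outcome(self) -> np.ndarray:
        return self._arr("se_outcome")

    def subset(self, keep_ids: Iterable[str]) -> "HarmonizedSet":
        """New set restricted to ``keep_ids``; no exclusion bookkeeping."""
        keep = set(keep_ids)
        return HarmonizedSet(
            self.exposure_name,
            self.outcome_name,
            [p for p in self.pairs if p.variant_id in keep],
            list(self.exclusions),
        )

    def drop(self, ids: Iterable[str], reason: ExclusionReason) -> "HarmonizedSet":
        """Move ``ids`` from pairs to exclusions under ``reason``."""
        ids = set(ids)
        kept = [p for p in self.pairs if p.variant_id not in ids]
        dropped = [p.variant_id for p in self.pairs if p.variant_id in ids]
        return HarmonizedSet(
            self.exposure_name,
            self.outcome_name,
            kept,
            list(self.exclusions) + [(v, reason) for v in dropped],
        )

    @classmethod
    def from_arrays(
        cls,
        beta_exposure,
        se_exposure,
        beta_outcome,
        se_outcome,
        variant_ids: Sequence[str] | None = None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
        **extra_arrays,
    ) -> "HarmonizedSet":
        """Build a set directly from parallel numeric arrays (tests, sims)."""
        bx = np.asarray(beta_exposure, dtype=float)
        k = bx.size
        if variant_ids is None:
            variant_ids = [f"rs{i + 1}" for i in range(k)]
        cols = {
            "beta_exposure": bx,
            "se_exposure": np.asarray(se_exposure, dtype=float),
            "beta_outcome": np.asarray(beta_outcome, dtype=float),
            "se_outcome": np.asarray(se_outcome, dtype=float),
        }
        for name, arr in extra_arrays.items():
            cols[name] = np.asarray(arr, dtype=float)
        pairs = [
            HarmonizedPair(variant_id=variant_ids[j], **{c: float(a[j]) for c, a in cols.items()})
            for j in range(k)
        ]
        return cls(exposure_name, outcome_name, pairs)

    def to_frame(self) -> pd.DataFrame:
        """Pair table with columns suffixed ``.exposure`` / ``.outcome``."""
        rows = [
            {
                "variant_id": p.variant_id,
                "beta.exposure": p.beta_exposure,
                "se.exposure": p.se_exposure,
                "eaf.exposure": p.eaf_exposure,
                "pval.exposure": p.pval_exposure,
                "n.exposure": p.n_exposure,
                "beta.outcome": p.beta_outcome,
                "se.outcome": p.se_outcome,
                "eaf.outcome": p.eaf_outcome,
                "pval.outcome": p.pval_outcome,
                "n.outcome": p.n_outcome,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(rows)

    def write(self, pairs_path: str, exclusions_path: str | None = None) -> None:
        self.to_frame().to_csv(pairs_path, sep="\t", index=False)
        if exclusions_path is not None:
            pd.DataFrame(
                [(v, r.value) for v, r in self.exclusions],
                columns=["variant_id", "reason"],
            ).to_csv(exclusions_path, sep="\t", index=False)


def read_harmonized(
    path: str, exposure_name: str = "exposure", outcome_name: str = "outcome"
) -> HarmonizedSet:
    """Read a pair table written by :meth:`HarmonizedSet.write`."""
    df = pd.read_csv(path, sep="\t")
    pairs = [
        HarmonizedPair(
            variant_id=str(r["variant_id"]),
            beta_exposure=float(r["beta.exposure"]),
            se_exposure=float(r["se.exposure"]),
            beta_outcome=float(r["beta.outcome"]),
            se_outcome=float(r["se.outcome"]),
            eaf_exposure=float(r.get("eaf.exposure", np.nan)),
            eaf_outcome=float(r.get("eaf.outcome", np.nan)),
            pval_exposure=float(r.get("pval.exposure", np.nan)),
            pval_outcome=float(r.get("pval.outcome", np.nan)),
            n_exposure=float(r.get("n.exposure", np.nan)),
            n_outcome=float(r.get("n.outcome", np.nan)),
        )
        for _, r in df.iterrows()
    ]
    return HarmonizedSet(exposure_name, outcome_name, pairs)


def harmonize(
    exposure: Iterable[GwasRecord],
    outcome: Iterable[GwasRecord],
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    palindromic_rescue: bool = False,
    ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele, variant by variant.

    Matching is by ``variant_id``.  When the outcome's alleles are swapped
    relative to the exposure, the outcome beta is negated and its eaf replaced
    by ``1 - eaf``.  Palindromic variants are excluded (reason
    ``palindromic``) unless ``palindromic_rescue`` is set, in which case
    allele frequencies clear of the ``ambiguity_band`` are used to infer
    strand.  Allele sets matching neither directly nor after swap are excluded
    as ``incompatible_alleles``; variants absent from the outcome as
    ``missing_in_outcome``.
    """
    exposure = list(exposure)
    out_by_id: dict[str, GwasRecord] = {}
    for rec in outcome:
        if rec.variant_id in out_by_id:
            log.warning("duplicate outcome variant %s; keeping first", rec.variant_id)
            continue
        out_by_id[rec.variant_id] = rec

    pairs: list[HarmonizedPair] = []
    exclusions: list[tuple[str, ExclusionReason]] = []
    for ex in exposure:
        out = out_by_id.get(ex.variant_id)
        if out is None:
            exclusions.append((ex.variant_id, ExclusionReason.MISSING_IN_OUTCOME))
            continue
        if ex.is_palindromic or out.is_palindromic:
            if not palindromic_rescue:
                exclusions.append((ex.variant_id, ExclusionReason.PALINDROMIC))
                continue
            lo, hi = ambiguity_band
            if (lo <= ex.eaf <= hi) or (lo <= out.eaf <= hi):
                exclusions.append((ex.variant_id, ExclusionReason.PALINDROMIC))
                continue
            # frequencies are informative: align by minor/major concordance
            flip = (ex.eaf < 0.5) != (out.eaf < 0.5)
        elif ex.alleles != out.alleles:
            exclusions.append((ex.variant_id, ExclusionReason.INCOMPATIBLE_ALLELES))
            continue
        else:
            if out.effect_allele == ex.effect_allele:
                flip = False
            elif out.effect_allele == ex.other_allele:
                flip = True
            else:  # pragma: no cover - same allele set guarantees one branch
                exclusions.append((ex.variant_id, ExclusionReason.INCOMPATIBLE_ALLELES))
                continue
        if ex.pos != out.pos or ex.chrom != out.chrom:
            log.warning(
                "%s: position differs between studies (%s:%d vs %s:%d); matched by id",
                ex.variant_id, ex.chrom, ex.pos, out.chrom, out.pos,
            )
        beta_out = -out.beta if flip else out.beta
        eaf_out = 1.0 - out.eaf if flip else out.eaf
        pairs.append(
            HarmonizedPair(
                variant_id=ex.variant_id,
                beta_exposure=ex.beta,
                se_exposure=ex.se,
                beta_outcome=beta_out,
                se_outcome=out.se,
                eaf_exposure=ex.eaf,
                eaf_outcome=eaf_out,
                pval_exposure=ex.pvalue,
                pval_outcome=out.pvalue,
                n_exposure=ex.n,
                n_outcome=out.n,
            )
        )

    if not pairs:
        raise EmptySetError(
            f"no harmonizable variants shared between '{exposure_name}' and '{outcome_name}'"
        )
    return HarmonizedSet(exposure_name, outcome_name, pairs, exclusions)
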