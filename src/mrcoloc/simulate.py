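"""Synthetic GWAS summary statistics with known ground truth.

The generator instantiates the statistical model the MR machinery assumes:
each instrument j has a true effect b_j on the exposure, the exposure has a
causal effect theta on the outcome, and an optional direct (pleiotropic)
effect alpha_j bypasses the exposure.  Observed summary betas are the truths
plus sampling noise with standard errors scaled as 1/sqrt(2 MAF (1-MAF) N)
for standardized quantitative traits, additionally shrunk by the case/control
split for binary outcomes on the log-odds scale.

Default sample sizes mirror a large brain-morphometry exposure GWAS
(23,909 European-ancestry individuals) against an ALS case-control outcome
(20,806 cases / 59,804 controls).  Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError
from .instruments import LdReference
from .sumstats import GwasRecord

#: ALS outcome study composition used for default scaling.
DEFAULT_N_CASES = 20_806
DEFAULT_N_CONTROLS = 59_804


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth configuration for a paired exposure/outcome GWAS.

    ``theta`` is the causal effect of the exposure on the outcome.  Variant
    effects on the exposure follow a spike-and-slab: a fraction ``pi_causal``
    draws from Normal(0, slab_sd^2), the rest are exactly zero, so that a
    p-value selection stage behaves realistically.  Pleiotropy modes: "none"
    (alpha_j = 0), "balanced" (Normal(0, pleiotropy_sd)), "directional"
    (Normal(pleiotropy_mean, pleiotropy_sd)), violating instrument validity
    controllably while preserving InSIDE.
    """

    n_snps: int = 50
    n_exposure: int = 23_909
    n_outcome: int = DEFAULT_N_CASES + DEFAULT_N_CONTROLS
    theta: float = 0.0
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.02
    pleiotropy_mean: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    pi_causal: float = 0.3
    slab_sd: float = 0.15
    outcome_binary: bool = True
    case_fraction: float = DEFAULT_N_CASES / (DEFAULT_N_CASES + DEFAULT_N_CONTROLS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise DomainError("n_snps must be >= 1")
        if self.n_exposure <= 2 or self.n_outcome <= 2:
            raise DomainError("sample sizes must exceed 2")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise DomainError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise DomainError("pleiotropy_mode must be none|balanced|directional")
        if not (0.0 <= self.pi_causal <= 1.0):
            raise DomainError("pi_causal must be in [0, 1]")
        if abs(self.ld_rho) >= 1.0:
            raise DomainError("|ld_rho| must be < 1")
        if self.ld_block_size < 1 or self.ld_block_size > self.n_snps:
            raise DomainError("ld_block_size must be in [1, n_snps]")
        if not (0.0 < self.case_fraction < 1.0):
            raise DomainError("case_fraction must be in (0, 1)")


def _se_quantitative(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _se_binary(maf: np.ndarray, n: float, case_fraction: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * case_fraction * (1.0 - case_fraction))


def _records(
    ids: Sequence[str],
    chrom: Sequence[str],
    pos: np.ndarray,
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: float,
) -> list[GwasRecord]:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return [
        GwasRecord(
            variant_id=ids[j], chrom=chrom[j], pos=int(pos[j]),
            effect_allele="A", other_allele="G",
            eaf=float(eaf[j]), beta=float(beta[j]), se=float(se[j]),
            pvalue=float(p[j]), n=float(n),
        )
        for j in range(len(ids))
    ]


def _grid_positions(n_snps: int, block_size: int) -> tuple[list[str], np.ndarray]:
    """Positions on an LD-block grid: 10 kb spacing within a block, blocks
    1 Mb apart, all on chromosome 1."""
    block = np.arange(n_snps) // block_size
    within = np.arange(n_snps) % block_size
    pos = 1 + block * 1_000_000 + within * 10_000
    return ["1"] * n_snps, pos


def simulate_gwas_pair(
    config: SimConfig,
) -> tuple[list[GwasRecord], list[GwasRecord], dict]:
    """Draw a paired exposure/outcome GWAS under the configured truth.

    Returns (exposure records, outcome records, truth) where the truth dict
    carries theta, the per-variant exposure effects ``b``, the pleiotropic
    effects ``alpha``, and the seed.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_snps
    maf = rng.uniform(*config.maf_range, size=k)
    causal = rng.random(k) < config.pi_causal
    # effect alleles are coded as exposure-increasing (half-normal slab), the
    # orientation in which a directional pleiotropy mean is interpretable
    b = np.where(causal, np.abs(rng.normal(0.0, config.slab_sd, size=k)), 0.0)

    if config.pleiotropy_mode == "none":
        alpha = np.zeros(k)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, size=k)
    else:
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k)

    se_x = _se_quantitative(maf, config.n_exposure)
    if config.outcome_binary:
        se_y = _se_binary(maf, config.n_outcome, config.case_fraction)
    else:
        se_y = _se_quantitative(maf, config.n_outcome)

    beta_x = rng.normal(b, se_x)
    beta_y = rng.normal(config.theta * b + alpha, se_y)

    ids = [f"rs{j + 1:06d}" for j in range(k)]
    chrom, pos = _grid_positions(k, config.ld_block_size)
    exposure = _records(ids, chrom, pos, maf, beta_x, se_x, config.n_exposure)
    outcome = _records(ids, chrom, pos, maf, beta_y, se_y, config.n_outcome)
    truth = {
        "theta": config.theta,
        "b": b.tolist(),
        "alpha": alpha.tolist(),
        "causal": causal.tolist(),
        "seed": config.seed,
    }
    return exposure, outcome, truth


def simulate_multi_exposure_study(
    thetas: dict[str, float],
    base_config: SimConfig = SimConfig(),
    seed: int = 0,
) -> tuple[dict[str, list[GwasRecord]], list[GwasRecord], dict]:
    """Several exposures against one shared outcome GWAS.

    Each exposure gets its own instruments (disjoint variant IDs, as distinct
    phenotypes have largely distinct association signals) with its own causal
    effect ``thetas[name]`` on the common outcome; the outcome GWAS is the
    concatenation of the per-exposure contributions.  Returns
    (exposures, outcome records, truth-by-exposure).
    """
    from dataclasses import replace as _replace

    exposures: dict[str, list[GwasRecord]] = {}
    outcome: list[GwasRecord] = []
    truth: dict[str, dict] = {}
    for i, name in enumerate(sorted(thetas)):
        cfg = _replace(base_config, theta=thetas[name], seed=seed + 1000 * (i + 1))
        ex, out, t = simulate_gwas_pair(cfg)
        renamed_ex, renamed_out = [], []
        for rec_ex, rec_out in zip(ex, out):
            vid = f"{name}_{rec_ex.variant_id}"
            chrom = str(i + 1)  # one chromosome per exposure keeps blocks apart
            renamed_ex.append(_replace(rec_ex, variant_id=vid, chrom=chrom))
            renamed_out.append(_replace(rec_out, variant_id=vid, chrom=chrom))
        exposures[name] = renamed_ex
        outcome.extend(renamed_out)
        truth[name] = t
    return exposures, outcome, truth


def identity_ld(records: Sequence[GwasRecord]) -> LdReference:
    """LD reference treating every listed variant as independent (r2 = 0)."""
    ids = [r.variant_id for r in records]
    positions = {r.variant_id: (r.chrom, r.pos) for r in records}
    return LdReference(ids, np.eye(len(ids)), positions)


def make_ld_fixture(
    n_snps: int, block_size: int, rho: float, seed: int = 0
) -> LdReference:
    """Block-diagonal LD reference: within-block r2 = rho^2, unit diagonal.

    Positions are spaced 10 kb apart within 1 Mb-separated blocks, matching
    :func:`simulate_gwas_pair`'s position grid.  ``seed`` is accepted for
    interface symmetry with the stochastic generators; the fixture itself is
    deterministic.
    """
    if block_size > n_snps:
        raise DomainError("block_size must be <= n_snps")
    block = np.arange(n_snps) // block_size
    same_block = block[:, None] == block[None, :]
    r2 = np.where(same_block, rho**2, 0.0)
    np.fill_diagonal(r2, 1.0)
    ids = [f"rs{j + 1:06d}" for j in range(n_snps)]
    chrom, pos = _grid_positions(n_snps, block_size)
    positions = {ids[j]: (chrom[j], int(pos[j])) for j in range(n_snps)}
    return LdReference(ids, r2, positions)


def simulate_coloc_region(
    scenario: str,
    n_variants: int = 50,
    ld_rho: float = 0.3,
    n1: float = 23_909,
    n2: float = DEFAULT_N_CASES + DEFAULT_N_CONTROLS,
    effect_z: float = 8.0,
    seed: int = 0,
    case_fraction2: float | None = DEFAULT_N_CASES / (DEFAULT_N_CASES + DEFAULT_N_CONTROLS),
) -> tuple[list[GwasRecord], list[GwasRecord], dict]:
    """Paired association signals over one region with a known causal layout.

    ``scenario``: "shared" (one causal variant driving both traits),
    "distinct" (a different causal variant per trait), or "null" (no signal).
    Marginal z-scores propagate through an exchangeable-correlation LD
    structure: z_j = r(j, causal) * effect_z + correlated noise, then betas
    and standard errors are reconstructed from z and the sample sizes.
    """
    if scenario not in ("shared", "distinct", "null"):
        raise DomainError("scenario must be shared|distinct|null")
    if n_variants < 3:
        raise DomainError("n_variants must be >= 3")
    rng = np.random.default_rng(seed)

    # exchangeable correlation among variants in the region
    corr = np.full((n_variants, n_variants), ld_rho, dtype=float)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_variants))

    if scenario == "null":
        c1 = c2 = None
    elif scenario == "shared":
        c1 = c2 = int(rng.integers(n_variants))
    else:
        c1, c2 = rng.choice(n_variants, size=2, replace=False)
        c1, c2 = int(c1), int(c2)

    def draw_z(causal: int | None) -> np.ndarray:
        mean = np.zeros(n_variants) if causal is None else corr[:, causal] * effect_z
        return mean + chol @ rng.standard_normal(n_variants)

    z1 = draw_z(c1)
    z2 = draw_z(c2)

    maf = rng.uniform(0.05, 0.5, size=n_variants)
    se1 = _se_quantitative(maf, n1)
    if case_fraction2 is not None:
        se2 = _se_binary(maf, n2, case_fraction2)
    else:
        se2 = _se_quantitative(maf, n2)

    ids = [f"rs{j + 1:06d}" for j in range(n_variants)]
    chrom = ["1"] * n_variants
    pos = 1 + np.arange(n_variants) * 10_000
    region1 = _records(ids, chrom, pos, maf, z1 * se1, se1, n1)
    region2 = _records(ids, chrom, pos, maf, z2 * se2, se2, n2)
    truth = {"scenario": scenario, "causal1": c1, "causal2": c2, "seed": seed}
    return region1, region2, truth
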