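"""Synthetic cohort generator.

Emulates the data structure the pipeline assumes: a candidate-system SNP
panel organised in gene-based LD blocks (with optional two-subpopulation
stratification), a three-wave continuous outcome following linear latent
growth, and a latent parenting environment measured by three informants
at each of three waves.  Ground truth (causal polygenic score, latent
environment, growth factors, subpopulation labels) is recorded so that
downstream estimators can be checked by parameter recovery.

The genotype model draws, per gene block, two latent Gaussian haplotype
vectors with exchangeable within-block correlation, thresholds each at the
per-SNP allele-frequency quantile, and sums the two haplotypes to additive
0/1/2 codes.  This yields Hardy-Weinberg-consistent genotypes with a
controllable LD-like block correlation.  Population structure uses
Balding-Nichols Beta-distributed subpopulation allele frequencies around
the ancestral frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_parenting",
    "simulate_trajectories",
    "inject_missingness",
    "simulate_cohort",
]

INFORMANTS = ("self", "mother", "father")
N_WAVES = 3


def _default_block_sizes() -> list[int]:
    # 14 gene blocks summing to 223 SNPs, sizes spread like a candidate panel
    return [35, 30, 25, 22, 20, 18, 16, 14, 12, 10, 8, 6, 4, 3]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the cohort shape the pipeline targets: ~1000
    subjects, 223 SNPs in 14 gene blocks, moderate within-block LD,
    a 1-5-scale outcome with linear growth over 3 annual waves, and a
    parenting factor measured by 3 informants x 3 waves with loadings 0.7
    on unit-variance indicators.
    """

    n_subjects: int = 1000
    n_snps: int = 223
    block_sizes: list[int] = field(default_factory=_default_block_sizes)
    within_block_r: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 1
    fst: float = 0.0
    causal_weights: np.ndarray | None = None
    effect_intercept_g: float = 0.0
    effect_intercept_e: float = 0.0
    effect_intercept_gxe: float = 0.0
    effect_slope_g: float = 0.0
    effect_slope_e: float = 0.0
    effect_slope_gxe: float = 0.0
    # quadratic generation terms (intercept equation only); used to study the
    # spurious-interaction hazard when squared effects are left unmodelled
    effect_intercept_g2: float = 0.0
    effect_intercept_e2: float = 0.0
    rge: float = 0.0
    growth_means: tuple[float, float] = (2.5, 0.1)
    growth_sds: tuple[float, float] = (0.6, 0.2)
    residual_sd_outcome: float = 0.4
    parenting_loadings: tuple[float, ...] = (0.7,) * 9
    # residual SD for unit indicator variance given loading 0.7: sqrt(1 - 0.49)
    parenting_residual_sds: tuple[float, ...] = (0.51**0.5,) * 9
    missing_genotype_rate: float = 0.01
    missing_outcome_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_snps <= 0:
            raise ValueError("n_subjects and n_snps must be positive")
        if sum(self.block_sizes) != self.n_snps:
            raise ValueError(
                f"block_sizes sum to {sum(self.block_sizes)}, expected n_snps={self.n_snps}"
            )
        if not 0 <= self.within_block_r < 1:
            raise ValueError("within_block_r must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        for r in (self.missing_genotype_rate, self.missing_outcome_rate):
            if not 0 <= r <= 1:
                raise ValueError(f"missingness rate {r} outside [0, 1]")
        if any(s <= 0 for s in self.growth_sds) or self.residual_sd_outcome <= 0:
            raise ValueError("growth_sds and residual_sd_outcome must be > 0")
        if len(self.parenting_loadings) != 9 or len(self.parenting_residual_sds) != 9:
            raise ValueError("parenting loadings/residual SDs must have length 9")
        if any(s < 0 for s in self.parenting_residual_sds):
            raise ValueError("parenting residual SDs must be non-negative")
        if not -1 < self.rge < 1:
            raise ValueError("rge must be in (-1, 1)")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Per-subject latent quantities recorded for recovery tests."""

    true_score: np.ndarray
    true_parenting_factor: np.ndarray
    true_intercept: np.ndarray
    true_slope: np.ndarray
    subpop_labels: np.ndarray
    config: SimulationConfig

    def as_frame(self, subject_ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": list(subject_ids),
                "true_score": self.true_score,
                "true_parenting_factor": self.true_parenting_factor,
                "true_intercept": self.true_intercept,
                "true_slope": self.true_slope,
                "subpop": self.subpop_labels,
            }
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per simulation stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, stream]))


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw the additive-coded genotype panel.

    Returns the genotype matrix (with annotation assigning each block a
    distinct gene label and chromosome) and the subpopulation labels.
    """
    config.validate()
    import warnings

    if config.n_subpops == 1 and config.fst > 0:
        warnings.warn("fst has no effect with n_subpops = 1", UserWarning, stacklevel=2)
    rng = _rng(config, stream=1)
    n, j = config.n_subjects, config.n_snps
    lo, hi = config.maf_range
    base_freq = rng.uniform(lo, hi, size=j)

    labels = np.arange(n) % config.n_subpops
    if config.n_subpops > 1 and config.fst > 0:
        a = base_freq * (1 - config.fst) / config.fst
        b = (1 - base_freq) * (1 - config.fst) / config.fst
        pop_freq = rng.beta(a, b, size=(config.n_subpops, j))
        pop_freq = np.clip(pop_freq, 1e-4, 1 - 1e-4)
    else:
        pop_freq = np.tile(base_freq, (config.n_subpops, 1))

    geno = np.zeros((n, j), dtype=float)
    r = config.within_block_r
    col = 0
    for size in config.block_sizes:
        # exchangeable correlation: z = sqrt(r)*shared + sqrt(1-r)*unique
        shared = rng.standard_normal((n, 2, 1))
        unique = rng.standard_normal((n, 2, size))
        z = np.sqrt(r) * shared + np.sqrt(1 - r) * unique
        thresh = _norm_ppf(pop_freq[labels, col : col + size])  # (n, size)
        alleles = z < thresh[:, None, :]  # allele present per haplotype
        geno[:, col : col + size] = alleles.sum(axis=1)
        col += size

    snp_ids = [f"rs{100000 + k}" for k in range(j)]
    genes, chroms, positions = [], [], []
    pos = 0
    for b, size in enumerate(config.block_sizes):
        gene = f"GENE{b + 1:02d}"
        chrom = str((b % 22) + 1)
        for s in range(size):
            genes.append(gene)
            chroms.append(chrom)
            positions.append(1_000_000 * (b + 1) + 5_000 * s)
        pos += size
    annotation = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": positions,
            "gene": genes,
            "ref": ["A"] * j,
            "alt": ["G"] * j,
        }
    )
    subject_ids = [f"S{i + 1:05d}" for i in range(n)]
    gm = GenotypeMatrix(values=geno, subject_ids=subject_ids, annotation=annotation)
    return gm, labels


def _norm_ppf(p: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(p)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def true_polygenic_score(config: SimulationConfig, genotypes: GenotypeMatrix) -> np.ndarray:
    """Standardized causal score G @ w over the (pre-missingness) panel."""
    w = config.causal_weights
    if w is None:
        # spread small weights over all SNPs, reproducibly from the seed
        w = _rng(config, stream=5).normal(0, 1, size=config.n_snps) / np.sqrt(config.n_snps)
    w = np.asarray(w, dtype=float)
    if w.shape != (config.n_snps,):
        raise ValueError("causal_weights must have length n_snps")
    return _standardize(genotypes.values @ w)


def simulate_parenting(
    config: SimulationConfig,
    n_subjects: int | None = None,
    true_score: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Latent parenting factor and its 3-informant x 3-wave indicators.

    The factor is standard normal; when ``config.rge`` is non-zero and a
    true polygenic score is supplied, the factor correlates with the score
    at exactly that coefficient (gene-environment correlation).
    """
    config.validate()
    n = config.n_subjects if n_subjects is None else n_subjects
    rng = _rng(config, stream=2)
    u = rng.standard_normal(n)
    if config.rge != 0 and true_score is not None:
        factor = config.rge * _standardize(true_score) + np.sqrt(1 - config.rge**2) * u
    else:
        factor = u
    loadings = np.asarray(config.parenting_loadings, dtype=float)
    res_sd = np.asarray(config.parenting_residual_sds, dtype=float)
    noise = rng.standard_normal((n, 9)) * res_sd
    indicators = factor[:, None] * loadings + noise
    cols = [f"par_{inf}_w{w + 1}" for inf in INFORMANTS for w in range(N_WAVES)]
    return pd.DataFrame(indicators, columns=cols), factor


def simulate_trajectories(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    parenting_factor: np.ndarray,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Three-wave outcomes from latent linear growth.

    intercept_i = mu_I + gI*g + gE*e + gGxE*g*e (+ quadratic terms) + zeta_I
    slope_i     = mu_S + sI*g + sE*e + sGxE*g*e + zeta_S
    y_it        = intercept_i + t * slope_i + eps_it,  t = 0, 1, 2

    The polygenic score g and environment e are standardized before the
    product is formed, so the structural coefficients are per-SD effects
    on the outcome scale.
    """
    config.validate()
    n = config.n_subjects
    if genotypes.values.shape[0] != n or parenting_factor.shape[0] != n:
        raise ValueError("genotype/parenting dimensions do not match config.n_subjects")
    rng = _rng(config, stream=3)
    g = true_polygenic_score(config, genotypes)
    e = _standardize(parenting_factor)
    gxe = g * e
    mu_i, mu_s = config.growth_means
    sd_i, sd_s = config.growth_sds
    intercept = (
        mu_i
        + config.effect_intercept_g * g
        + config.effect_intercept_e * e
        + config.effect_intercept_gxe * gxe
        + config.effect_intercept_g2 * (g**2 - 1)
        + config.effect_intercept_e2 * (e**2 - 1)
        + rng.standard_normal(n) * sd_i
    )
    slope = (
        mu_s
        + config.effect_slope_g * g
        + config.effect_slope_e * e
        + config.effect_slope_gxe * gxe
        + rng.standard_normal(n) * sd_s
    )
    t = np.arange(N_WAVES, dtype=float)
    eps = rng.standard_normal((n, N_WAVES)) * config.residual_sd_outcome
    y = intercept[:, None] + slope[:, None] * t[None, :] + eps
    out = pd.DataFrame(y, columns=[f"y_w{w + 1}" for w in range(N_WAVES)])
    return out, g, intercept, slope


def inject_missingness(
    genotypes: GenotypeMatrix,
    outcomes: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Set entries missing completely at random at the configured rates."""
    config.validate()
    rng = _rng(config, stream=4)
    g = genotypes.values.astype(float).copy()
    if config.missing_genotype_rate > 0:
        mask = rng.random(g.shape) < config.missing_genotype_rate
        g[mask] = np.nan
    y = outcomes.copy()
    if config.missing_outcome_rate > 0:
        mask = rng.random(y.shape) < config.missing_outcome_rate
        vals = y.to_numpy(dtype=float)
        vals[mask] = np.nan
        y = pd.DataFrame(vals, columns=y.columns, index=y.index)
    gm = GenotypeMatrix(values=g, subject_ids=genotypes.subject_ids, annotation=genotypes.annotation)
    return gm, y


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame, GroundTruth]:
    """Full cohort draw: genotypes (with MCAR missingness), a wide cohort
    table (outcomes, parenting indicators, covariates), and ground truth.

    Covariates mirror the target design: sex ~ Bernoulli(0.5) coded 0/1,
    age ~ N(13.8, 0.94) years at wave 1, family structure ~ Bernoulli(0.21)
    coded 1 for non-intact.  Covariates carry no causal effect.
    """
    config.validate()
    genotypes, labels = simulate_genotypes(config)
    g_score = true_polygenic_score(config, genotypes)
    indicators, factor = simulate_parenting(config, true_score=g_score)
    outcomes, g_score, intercept, slope = simulate_trajectories(config, genotypes, factor)
    genotypes_m, outcomes_m = inject_missingness(genotypes, outcomes, config)

    rng = _rng(config, stream=6)
    n = config.n_subjects
    covars = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),
            "age": rng.normal(13.8, 0.94, size=n),
            "fam_structure": (rng.random(n) < 0.21).astype(int),
        }
    )
    table = pd.concat(
        [
            pd.DataFrame({"subject_id": genotypes.subject_ids}),
            outcomes_m.reset_index(drop=True),
            indicators.reset_index(drop=True),
            covars,
        ],
        axis=1,
    )
    truth = GroundTruth(
        true_score=g_score,
        true_parenting_factor=factor,
        true_intercept=intercept,
        true_slope=slope,
        subpop_labels=labels,
        config=config,
    )
    return genotypes_m, table, truth
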