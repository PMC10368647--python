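"""Forward-in-time family simulator with genetic nurture and assortative mating.

The simulator produces unlinked diploid genotypes over discrete generations.
Every generation is paired into monogamous couples (optionally assorting on
the phenotype), each couple has exactly two children, and the phenotype of a
child is

    Y = sqrt(h2) * G_st + sqrt(n2) * P_st + e,

where ``G_st`` is the individual's true direct polygenic factor
(sum_j beta_j SNP_j, standardized to mean 0 / variance 1 within the
generation), ``P_st`` is the parental genetic-nurture factor
(sum_j gamma_j (SNP_j^F + SNP_j^M), also standardized within generation and
zero for founders), and ``e`` is independent Gaussian noise scaled so that
Var(Y) = 1 in expectation. With independent direct and nurture effects the
SNP-based heritability of Y equals ``h2 + 0.5 * n2``.

The final generation is partitioned into two GWAS discovery samples and one
prediction sample; imperfect genetic correlation between partitions is
realized by giving each partition its own (correlated) direct-effect vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pgicorr._numutil import binomial2, chunked_dot, mendelian_children

__all__ = [
    "SimConfig",
    "EffectSet",
    "Population",
    "SimulatedStudy",
    "ConfigError",
    "PhenotypeVarianceError",
    "draw_effects",
    "draw_founders",
    "mate",
    "reproduce",
    "assign_phenotype",
    "simulate",
    "true_target_coefficient",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class PhenotypeVarianceError(RuntimeError):
    """The requested variance shares leave no room for environmental noise."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation scenario.

    Parameters
    ----------
    n_snps
        Number of unlinked SNPs (M).
    n_families_discovery1, n_families_discovery2, n_families_prediction
        Families in the final generation assigned to each partition. A
        between-family GWAS uses one sibling per discovery family, so the
        per-GWAS sample size equals the discovery family count; the
        prediction sample keeps both siblings (N = 2 * families).
    h2
        Phenotypic variance share of direct genetic effects.
    n2
        Phenotypic variance share of genetic nurture.
    am_rho
        Target phenotypic correlation between mates, in [0, 1].
    rg_disc_pred
        Genetic correlation between both discovery samples and the
        prediction sample (the two discovery samples stay perfectly
        correlated), in (0, 1].
    rg_disc_disc
        Genetic correlation between discovery sample 1 and discovery
        sample 2 (discovery 2 stays perfectly correlated with the
        prediction sample), in (0, 1].
    n_generations
        Number of post-founder generations; ``None`` resolves to 1 when
        ``am_rho == 0`` and to 10 otherwise (assortative mating needs a few
        generations to equilibrate).
    founder_maf_range
        Founder allele frequencies are drawn uniformly from this interval,
        a sub-interval of (0, 0.5].
    seed
        Seed for the single random source driving the whole run.
    standardize_each_generation
        Standardize the latent factors within every generation (keeps the
        target coefficient fixed under assortative mating).
    """

    n_snps: int
    n_families_discovery1: int
    n_families_discovery2: int
    n_families_prediction: int
    h2: float = 0.25
    n2: float = 0.0
    am_rho: float = 0.0
    rg_disc_pred: float = 1.0
    rg_disc_disc: float = 1.0
    n_generations: int | None = None
    founder_maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0
    standardize_each_generation: bool = True

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        for name in ("n_families_discovery1", "n_families_discovery2",
                     "n_families_prediction"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.h2 < 0 or self.n2 < 0:
            raise ConfigError("h2 and n2 must be non-negative")
        if self.h2 + 0.5 * self.n2 > 1:
            raise ConfigError(
                "h2 + 0.5*n2 (the SNP-heritability of the outcome) exceeds 1"
            )
        if not 0.0 <= self.am_rho <= 1.0:
            raise ConfigError("am_rho must lie in [0, 1]")
        for name in ("rg_disc_pred", "rg_disc_disc"):
            rg = getattr(self, name)
            if not 0.0 < rg <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1]")
        if self.rg_disc_pred < 1.0 and self.rg_disc_disc < 1.0:
            raise ConfigError(
                "at most one of rg_disc_pred / rg_disc_disc may be < 1"
            )
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("founder_maf_range must lie within (0, 0.5]")
        if self.n_generations is not None and self.n_generations < 1:
            raise ConfigError("n_generations must be >= 1")

    @property
    def n_families_total(self) -> int:
        return (self.n_families_discovery1 + self.n_families_discovery2
                + self.n_families_prediction)

    @property
    def resolved_generations(self) -> int:
        if self.n_generations is not None:
            return self.n_generations
        return 1 if self.am_rho == 0.0 else 10


@dataclass
class EffectSet:
    """Per-SNP effect vectors.

    ``direct`` is the direct-effect vector used during the forward
    simulation (identical to ``variants['prediction']``); ``nurture`` is the
    parental-nurture vector (equal maternal and paternal weights), drawn
    independently of the direct effects. ``variants`` holds the correlated
    direct-effect vectors realizing imperfect genetic correlation between
    partitions.
    """

    direct: np.ndarray
    nurture: np.ndarray
    variants: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Population:
    """State of the current generation plus the accumulated pedigree.

    ``genotypes`` holds allele counts for the *current* generation only (the
    full multi-generation matrix would be prohibitively large); identifier
    and phenotype columns for every generation simulated so far are kept and
    exposed as a flat pedigree table.
    """

    genotypes: np.ndarray            # (n_current, M) int8
    iid: np.ndarray                  # (n_current,) int64
    fid: np.ndarray
    pat: np.ndarray                  # 0 = founder (no parent recorded)
    mat: np.ndarray
    generation: int
    parent_genotype_sum: np.ndarray | None = None   # (n_current, M) int8
    phenotype: np.ndarray | None = None
    true_pgi: np.ndarray | None = None
    true_pgi_nurture: np.ndarray | None = None
    _noise: np.ndarray | None = None
    _nurture_scale: tuple[float, float] | None = None  # (mean, sd) of raw P
    _history: list[pd.DataFrame] = field(default_factory=list)
    _next_iid: int = 0
    _next_fid: int = 0

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def current_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iid": self.iid,
            "fid": self.fid,
            "pat": self.pat,
            "mat": self.mat,
            "generation": np.full(self.n, self.generation, dtype=np.int64),
            "phenotype": self.phenotype if self.phenotype is not None
            else np.full(self.n, np.nan),
            "true_pgi": self.true_pgi if self.true_pgi is not None
            else np.full(self.n, np.nan),
            "true_pgi_nurture": self.true_pgi_nurture
            if self.true_pgi_nurture is not None
            else np.full(self.n, np.nan),
        })

    def pedigree(self) -> pd.DataFrame:
        """Flat table over every generation simulated so far."""
        frames = list(self._history) + [self.current_frame()]
        return pd.concat(frames, ignore_index=True)


@dataclass
class SimulatedStudy:
    """Partition of the final generation into analysis samples.

    Index arrays are positional row indices into the final generation's
    arrays. ``gwas_subset1/2`` select one randomly chosen sibling per
    discovery family; the prediction partition keeps both siblings.
    """

    discovery1: np.ndarray
    discovery2: np.ndarray
    prediction: np.ndarray
    gwas_subset1: np.ndarray
    gwas_subset2: np.ndarray
    config: SimConfig
    effects: EffectSet


def draw_effects(config: SimConfig, rng: np.random.Generator) -> EffectSet:
    """Draw direct, nurture, and partition-variant effect vectors.

    Direct and nurture effects are i.i.d. standard normal and mutually
    independent; the three partition variants are jointly Gaussian with the
    configured genetic correlations. Effect magnitudes are irrelevant: the
    phenotype model rescales the aggregated factors to the target variance
    shares.
    """
    m = config.n_snps
    base = rng.standard_normal(m)
    extra = rng.standard_normal(m)
    nurture = rng.standard_normal(m)

    if config.rg_disc_pred < 1.0:
        rg = config.rg_disc_pred
        disc = base
        pred = rg * base + math.sqrt(1.0 - rg * rg) * extra
        variants = {"discovery1": disc, "discovery2": disc.copy(),
                    "prediction": pred}
    elif config.rg_disc_disc < 1.0:
        rg = config.rg_disc_disc
        d2 = base
        d1 = rg * base + math.sqrt(1.0 - rg * rg) * extra
        variants = {"discovery1": d1, "discovery2": d2,
                    "prediction": d2.copy()}
    else:
        variants = {"discovery1": base.copy(), "discovery2": base.copy(),
                    "prediction": base}
    return EffectSet(direct=variants["prediction"], nurture=nurture,
                     variants=variants)


def draw_founders(config: SimConfig, rng: np.random.Generator,
                  effects: EffectSet | None = None) -> Population:
    """Create the founder generation (no pedigree links, nurture term 0).

    Founder genotypes are binomial(2, p_j) with p_j uniform on the
    configured frequency range. Phenotypes are assigned immediately so the
    founders can mate.
    """
    n = 2 * config.n_families_total
    m = config.n_snps
    lo, hi = config.founder_maf_range
    p = rng.uniform(lo, hi, size=m)
    geno = binomial2(p, n, rng)
    iid = np.arange(1, n + 1, dtype=np.int64)
    pop = Population(
        genotypes=geno,
        iid=iid,
        fid=iid.copy(),          # founders are singleton families
        pat=np.zeros(n, dtype=np.int64),
        mat=np.zeros(n, dtype=np.int64),
        generation=0,
        _next_iid=n + 1,
        _next_fid=n + 1,
    )
    if effects is not None:
        assign_phenotype(pop, effects, config.h2, config.n2, rng,
                         standardize=config.standardize_each_generation)
    return pop


def mate(population: Population, am_rho: float,
         rng: np.random.Generator) -> np.ndarray:
    """Pair the current generation into couples assorting on the phenotype.

    Gaussian-coupling rank matching: the generation is split at random into
    two pools; pool A is sorted by phenotype, pool B by a noisy copy of its
    phenotype with correlation ``am_rho``, and ranks are paired. ``am_rho``
    equal to 0 or 1 reduces to random pairing and exact phenotypic-rank
    pairing respectively.

    Returns an array of shape (n/2, 2) of positional indices (col 0 acts as
    father, col 1 as mother — pools are random, there are no sexes).
    """
    if not 0.0 <= am_rho <= 1.0:
        raise ConfigError("am_rho must lie in [0, 1]")
    if population.phenotype is None:
        raise ValueError("phenotypes must be assigned before mating")
    n = population.n
    if n % 2:
        raise ValueError("need an even number of eligible individuals")
    perm = rng.permutation(n)
    pool_a, pool_b = perm[: n // 2], perm[n // 2:]
    y = population.phenotype
    key_b = am_rho * y[pool_b]
    if am_rho < 1.0:
        key_b = key_b + math.sqrt(1.0 - am_rho ** 2) * \
            rng.standard_normal(n // 2)
    a_sorted = pool_a[np.argsort(y[pool_a], kind="stable")]
    b_sorted = pool_b[np.argsort(key_b, kind="stable")]
    return np.column_stack([a_sorted, b_sorted])


def reproduce(couples: np.ndarray, population: Population,
              rng: np.random.Generator,
              need_parent_sum: bool = True) -> Population:
    """Produce the next generation: exactly two children per couple.

    Transmission is Mendelian and unlinked: at every SNP each parent passes
    one of their two alleles uniformly at random, independently across SNPs
    and children.
    """
    geno = population.genotypes
    n_c = couples.shape[0]
    if couples.size and (couples.min() < 0 or couples.max() >= population.n):
        raise ValueError("couples reference individuals outside the population")
    child_geno, psum = mendelian_children(
        geno, couples[:, 0], couples[:, 1], 2, rng,
        need_psum=need_parent_sum)
    fa_pos = np.repeat(couples[:, 0], 2)
    mo_pos = np.repeat(couples[:, 1], 2)
    n_children = 2 * n_c
    iid = np.arange(population._next_iid,
                    population._next_iid + n_children, dtype=np.int64)
    fid = np.repeat(
        np.arange(population._next_fid, population._next_fid + n_c,
                  dtype=np.int64), 2)
    history = population._history + [population.current_frame()]
    return Population(
        genotypes=child_geno,
        iid=iid,
        fid=fid,
        pat=population.iid[fa_pos],
        mat=population.iid[mo_pos],
        generation=population.generation + 1,
        parent_genotype_sum=psum,
        _history=history,
        _next_iid=int(iid[-1]) + 1,
        _next_fid=population._next_fid + n_c,
    )


def _standardized_factor(raw: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(raw.mean())
    sd = float(raw.std())
    if sd == 0.0:
        raise PhenotypeVarianceError("latent factor is constant")
    return (raw - mu) / sd, mu, sd


def assign_phenotype(population: Population, effects: EffectSet,
                     h2: float, n2: float, rng: np.random.Generator,
                     standardize: bool = True) -> Population:
    """Fill phenotypes for the current generation.

    The direct factor uses the individual's own genotypes; the nurture
    factor uses the sum of both parents' genotypes (zero for founders).
    Environmental noise is scaled so Var(Y) = 1 in expectation, accounting
    for the realized covariance between the two standardized factors (which
    emerges under assortative mating combined with genetic nurture).
    """
    g_raw = chunked_dot(population.genotypes, effects.direct)
    if standardize:
        g_st, _, _ = _standardized_factor(g_raw)
    else:
        g_st = g_raw

    has_nurture = n2 > 0 and population.parent_genotype_sum is not None
    if has_nurture:
        p_raw = chunked_dot(population.parent_genotype_sum, effects.nurture)
        p_st, p_mu, p_sd = _standardized_factor(p_raw)
        population._nurture_scale = (p_mu, p_sd)
        c = float(np.corrcoef(g_st, p_st)[0, 1])
        n2_eff = n2
    else:
        p_st = np.zeros(population.n)
        c = 0.0
        n2_eff = 0.0

    sigma2_e = 1.0 - h2 - n2_eff - 2.0 * math.sqrt(h2 * n2_eff) * c
    if sigma2_e < 0.0:
        raise PhenotypeVarianceError(
            f"variance budget exceeded: h2={h2}, n2={n2_eff}, "
            f"corr(G_st, P_st)={c:.4f} leaves environmental variance "
            f"{sigma2_e:.4f} < 0"
        )
    noise = rng.standard_normal(population.n)
    population.phenotype = (math.sqrt(h2) * g_st
                            + math.sqrt(n2_eff) * p_st
                            + math.sqrt(sigma2_e) * noise)
    population.true_pgi = g_st
    population.true_pgi_nurture = p_st
    population._noise = noise
    return population


def _partition(population: Population, config: SimConfig,
               rng: np.random.Generator, effects: EffectSet) -> SimulatedStudy:
    """Split the final generation's families into the three samples."""
    n_fam = population.n // 2
    need = config.n_families_total
    if need > n_fam:
        raise ConfigError(
            f"partition requires {need} families but the final generation "
            f"has {n_fam}"
        )
    fam_order = rng.permutation(n_fam)
    d1_fam = fam_order[: config.n_families_discovery1]
    d2_fam = fam_order[config.n_families_discovery1:
                       config.n_families_discovery1
                       + config.n_families_discovery2]
    pr_fam = fam_order[config.n_families_discovery1
                       + config.n_families_discovery2: need]

    def members(fams: np.ndarray) -> np.ndarray:
        # children of family f occupy rows 2f and 2f+1
        return np.sort(np.concatenate([2 * fams, 2 * fams + 1]))

    def one_per_family(fams: np.ndarray) -> np.ndarray:
        pick = rng.integers(0, 2, size=fams.size)
        return np.sort(2 * fams + pick)

    return SimulatedStudy(
        discovery1=members(d1_fam),
        discovery2=members(d2_fam),
        prediction=members(pr_fam),
        gwas_subset1=one_per_family(d1_fam),
        gwas_subset2=one_per_family(d2_fam),
        config=config,
        effects=effects,
    )


def _apply_variant_phenotypes(population: Population, study: SimulatedStudy,
                              config: SimConfig) -> None:
    """Re-generate discovery phenotypes with partition-specific effects.

    Uses the same noise draw and nurture factor as the base assignment, so
    with perfect genetic correlation the phenotypes are unchanged
    bit-for-bit.
    """
    effects = study.effects
    h2, n2 = config.h2, config.n2
    has_nurture = (n2 > 0 and population.parent_genotype_sum is not None)
    n2_eff = n2 if has_nurture else 0.0
    p_st = population.true_pgi_nurture
    for name, idx in (("discovery1", study.discovery1),
                      ("discovery2", study.discovery2)):
        beta = effects.variants[name]
        if beta is effects.direct or np.array_equal(beta, effects.direct):
            continue
        g_raw = chunked_dot(population.genotypes, beta)
        g_st, _, _ = _standardized_factor(g_raw)
        c = float(np.corrcoef(g_st, p_st)[0, 1]) if n2_eff > 0 else 0.0
        sigma2_e = 1.0 - h2 - n2_eff - 2.0 * math.sqrt(h2 * n2_eff) * c
        if sigma2_e < 0.0:
            raise PhenotypeVarianceError(
                f"variance budget exceeded for partition {name}"
            )
        y_k = (math.sqrt(h2) * g_st + math.sqrt(n2_eff) * p_st
               + math.sqrt(sigma2_e) * population._noise)
        population.phenotype[idx] = y_k[idx]


def simulate(config: SimConfig) -> tuple[Population, SimulatedStudy]:
    """Run the full forward simulation and partition the final generation.

    Deterministic given the config (including its seed): the same config
    yields bit-identical genotypes, pedigree, and phenotypes.
    """
    rng = np.random.default_rng(config.seed)
    effects = draw_effects(config, rng)
    pop = draw_founders(config, rng, effects)
    for _ in range(config.resolved_generations):
        couples = mate(pop, config.am_rho, rng)
        pop = reproduce(couples, pop, rng, need_parent_sum=config.n2 > 0)
        assign_phenotype(pop, effects, config.h2, config.n2, rng,
                         standardize=config.standardize_each_generation)
    study = _partition(pop, config, rng, effects)
    _apply_variant_phenotypes(pop, study, config)
    return pop, study


def true_target_coefficient(population: Population, study: SimulatedStudy,
                            scope: str = "between") -> float:
    """Target coefficient a consistent estimator should recover.

    ``within`` scope returns sqrt(h2), the standardized direct genetic
    effect. ``between`` scope returns the standardized coefficient of the
    outcome on the total latent additive SNP factor in the prediction
    sample. Without assortative mating this equals sqrt(h2 + 0.5 * n2) in
    closed form; with assortative mating and genetic nurture combined, the
    emergent direct/nurture covariance is absorbed by regressing the
    phenotype on the realized latent factor.
    """
    config = study.config
    if scope == "within":
        return math.sqrt(config.h2)
    if scope != "between":
        raise ValueError("scope must be 'between' or 'within'")
    if config.am_rho == 0.0 or config.n2 == 0.0:
        return math.sqrt(config.h2 + 0.5 * config.n2)

    # latent additive SNP factor: the individual's own genotypes predict the
    # nurture factor through transmitted alleles
    idx = study.prediction
    q_raw = chunked_dot(population.genotypes[idx], study.effects.nurture)
    _, p_sd = population._nurture_scale
    q = (q_raw - q_raw.mean()) / p_sd
    u = (math.sqrt(config.h2) * population.true_pgi[idx]
         + math.sqrt(config.n2) * q)
    u_st = (u - u.mean()) / u.std()
    y = population.phenotype[idx]
    return float(np.cov(y, u_st, ddof=0)[0, 1] / u_st.var())
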