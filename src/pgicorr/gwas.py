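"""Between-family GWAS, meta-analysis, and polygenic-index construction.

Each SNP is tested with a simple (single-regressor) OLS of the standardized
phenotype on the allele count; because the simulated SNPs are unlinked, the
polygenic index is just the genotype matrix times the GWAS coefficient
vector. Two summary-statistic sets from non-overlapping discovery samples
can be combined by fixed-effects inverse-variance meta-analysis.

The ORIV scaling transform divides each standardized PGI by the square root
of the correlation between the two PGIs, so that the subsequent IV
regression targets the effect of one standard deviation of the *true*
latent PGI rather than of the noisy observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pgicorr._numutil import chunked_crossprod, chunked_dot, column_moments

__all__ = [
    "SUMSTAT_COLUMNS",
    "PGISet",
    "run_gwas",
    "meta_analyze",
    "build_pgi",
    "standardize",
    "scale_for_oriv",
]

SUMSTAT_COLUMNS = ["SNP", "EAF", "BETA", "SE", "N"]


@dataclass
class PGISet:
    """Standardized and ORIV-scaled polygenic indices for one sample.

    ``pgi1_st``/``pgi2_st``/``pgi_meta_st`` have mean 0, variance 1 in the
    analysis sample. ``rhat`` is the sample correlation between the two
    independent standardized PGIs; the scaled scores ``pgi1_plus`` and
    ``pgi2_plus`` equal the standardized scores divided by sqrt(rhat), so
    each has variance 1/rhat.
    """

    pgi1_st: np.ndarray
    pgi2_st: np.ndarray
    pgi_meta_st: np.ndarray
    pgi1_plus: np.ndarray
    pgi2_plus: np.ndarray
    rhat: float


def run_gwas(genotypes: np.ndarray, phenotype: np.ndarray,
             snp_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-SNP simple regression of the phenotype on allele count.

    Expects at most one individual per family (a between-family design);
    the caller is responsible for the subsetting. Returns a summary table
    with columns SNP, EAF, BETA, SE, N. Monomorphic SNPs get BETA 0 and an
    infinite SE, which downstream weighting treats as zero weight.
    """
    geno = np.asarray(genotypes)
    y = np.asarray(phenotype, dtype=np.float64)
    n, m = geno.shape
    if y.shape[0] != n:
        raise ValueError("genotypes and phenotype have different lengths")
    if n < 3:
        raise ValueError("need at least 3 individuals for per-SNP SEs")

    g_sum, g_ss = column_moments(geno)
    g_mean = g_sum / n
    ssq_g = g_ss - n * g_mean ** 2          # sum (g - gbar)^2
    yc = y - y.mean()
    gy = chunked_crossprod(geno, yc)        # sum g * (y - ybar)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ssq_g > 0, gy / ssq_g, 0.0)
        rss = np.maximum(yc @ yc - beta ** 2 * ssq_g, 0.0)
        sigma2 = rss / (n - 2)
        se = np.where(ssq_g > 0, np.sqrt(sigma2 / np.where(ssq_g > 0, ssq_g, 1.0)),
                      np.inf)
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    return pd.DataFrame({
        "SNP": snp_ids,
        "EAF": g_mean / 2.0,
        "BETA": beta,
        "SE": se,
        "N": np.full(m, n, dtype=np.int64),
    })


def meta_analyze(ss1: pd.DataFrame, ss2: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects inverse-variance meta-analysis of two GWAS tables.

    Requires identical SNP sets in identical order (same effect-allele
    orientation by construction in the simulator). SNPs with infinite SE in
    one input receive zero weight there; if both inputs failed the SNP is
    flagged with an infinite combined SE.
    """
    if list(ss1["SNP"]) != list(ss2["SNP"]):
        bad = sorted(set(ss1["SNP"]).symmetric_difference(set(ss2["SNP"])))
        raise ValueError(
            f"mismatched SNP sets between summary statistics: {bad[:10]}"
            + ("..." if len(bad) > 10 else "")
        )
    w1 = np.where(np.isfinite(ss1["SE"]), 1.0 / np.square(ss1["SE"]), 0.0)
    w2 = np.where(np.isfinite(ss2["SE"]), 1.0 / np.square(ss2["SE"]), 0.0)
    wsum = w1 + w2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(wsum > 0,
                        (w1 * ss1["BETA"] + w2 * ss2["BETA"])
                        / np.where(wsum > 0, wsum, 1.0),
                        0.0)
        se = np.where(wsum > 0, 1.0 / np.sqrt(np.where(wsum > 0, wsum, 1.0)),
                      np.inf)
    n1 = np.asarray(ss1["N"])
    n2 = np.asarray(ss2["N"])
    eaf = (n1 * ss1["EAF"] + n2 * ss2["EAF"]) / (n1 + n2)
    return pd.DataFrame({
        "SNP": ss1["SNP"].to_numpy(),
        "EAF": eaf,
        "BETA": beta,
        "SE": se,
        "N": n1 + n2,
    })


def build_pgi(genotypes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted allele-count sum per individual.

    Non-finite weights (failed SNPs) contribute zero, so the same SNPs are
    dropped from every PGI symmetrically.
    """
    w = np.asarray(weights, dtype=np.float64)
    if genotypes.shape[1] != w.shape[0]:
        raise ValueError(
            f"weight vector length {w.shape[0]} does not match "
            f"{genotypes.shape[1]} genotype columns"
        )
    w = np.where(np.isfinite(w), w, 0.0)
    return chunked_dot(genotypes, w)


def standardize(scores: np.ndarray) -> np.ndarray:
    """Standardize to sample mean 0, variance 1 (SD with denominator N-1)."""
    x = np.asarray(scores, dtype=np.float64)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant score vector")
    return (x - x.mean()) / sd


def scale_for_oriv(pgi1_st: np.ndarray, pgi2_st: np.ndarray,
                   pgi_meta_st: np.ndarray | None = None,
                   rhat: float | None = None) -> PGISet:
    """Divide the two standardized PGIs by the square root of their correlation.

    ``rhat`` may be supplied externally (e.g. the between-family correlation
    when scaling PGIs for a within-family analysis); by default it is the
    sample correlation of the two inputs. A non-positive correlation means
    the instruments carry no usable signal and is an error.
    """
    if rhat is None:
        rhat = float(np.corrcoef(pgi1_st, pgi2_st)[0, 1])
    if not rhat > 0:
        raise ValueError(
            f"correlation between the two PGIs is {rhat:.4f}; ORIV scaling "
            "requires a positive correlation"
        )
    s = np.sqrt(rhat)
    if pgi_meta_st is None:
        pgi_meta_st = np.full_like(np.asarray(pgi1_st, dtype=float), np.nan)
    return PGISet(
        pgi1_st=np.asarray(pgi1_st, dtype=np.float64),
        pgi2_st=np.asarray(pgi2_st, dtype=np.float64),
        pgi_meta_st=np.asarray(pgi_meta_st, dtype=np.float64),
        pgi1_plus=np.asarray(pgi1_st, dtype=np.float64) / s,
        pgi2_plus=np.asarray(pgi2_st, dtype=np.float64) / s,
        rhat=rhat,
    )
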