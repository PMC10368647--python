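"""OLS, ORIV, and PGI-repository-correction estimators.

All three estimators target the standardized effect of the true latent
polygenic index on a standardized outcome:

* ``ols_pgi`` — OLS of the outcome on a standardized (typically
  meta-analysis) PGI; attenuated by measurement error, with the attenuation
  factor sqrt(R^2 / h2_SNP).
* ``oriv`` — stacked two-stage least squares using two independently
  constructed, ORIV-scaled PGIs as mutual instruments. The stacked system
  duplicates each observation; its estimate equals the average of the two
  directed just-identified IV estimates, and standard errors are clustered
  (individuals appear twice).
* ``pgi_rc`` — rescales an OLS coefficient by sqrt(h2_SNP / R^2) using a
  GREML estimate of the SNP-based heritability; in the univariate
  standardized case the point estimate collapses to sqrt(h2_hat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from pgicorr.heritability import HeritabilityEstimate

__all__ = [
    "EstimateResult",
    "expected_r2",
    "first_stage_f",
    "ols_pgi",
    "oriv",
    "pgi_rc",
]

_Z95 = 1.96
H2_DROP_THRESHOLD = 0.01


@dataclass
class EstimateResult:
    """One estimator's output for one sample."""

    method: str
    beta_st_hat: float
    se: float
    n_obs: int
    n_clusters: int
    within_family: bool = False
    first_stage_coef: float | None = None
    first_stage_F: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def ci_low(self) -> float:
        return self.beta_st_hat - _Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta_st_hat + _Z95 * self.se

    @property
    def implied_h2(self) -> float:
        return self.beta_st_hat ** 2

    @property
    def implied_h2_se(self) -> float:
        """Delta-method SE of the squared coefficient."""
        return 2.0 * abs(self.beta_st_hat) * self.se


def expected_r2(h2_snp: float, m_snps: int, n_gwas: int) -> float:
    """Expected out-of-sample R^2 of a PGI from a finite-sample GWAS.

    Under equal per-SNP contributions to the heritability,

        R^2 = h2_SNP * h2_SNP / (h2_SNP + M / N_GWAS).
    """
    if not 0.0 <= h2_snp <= 1.0:
        raise ValueError("h2_snp must lie in [0, 1]")
    if m_snps < 1 or n_gwas < 1:
        raise ValueError("m_snps and n_gwas must be >= 1")
    return h2_snp * h2_snp / (h2_snp + m_snps / n_gwas)


def first_stage_f(corr_pgi: float, n: int) -> float:
    """First-stage F statistic for two standardized PGIs.

    Equals the squared t statistic of the slope in a simple regression of
    one standardized PGI on the other: F = r^2 (N - 2) / (1 - r^2).
    """
    if n <= 2:
        raise ValueError("n must exceed 2")
    if abs(corr_pgi) >= 1.0:
        raise ValueError("first-stage F is undefined at |correlation| = 1")
    r2 = corr_pgi * corr_pgi
    return r2 * (n - 2) / (1.0 - r2)


def _cluster_cov(zx_inv: np.ndarray, z: np.ndarray, resid: np.ndarray,
                 groups: np.ndarray, k_model: int) -> np.ndarray:
    """CR1 cluster-robust sandwich for a (possibly IV) linear model.

    ``zx_inv`` is (Z'X)^{-1}; for OLS pass Z = X. ``k_model`` is the number
    of estimated mean parameters including any absorbed fixed effects, used
    in the CR1 small-sample factor G/(G-1) * (N-1)/(N-K).
    """
    n = z.shape[0]
    ze = z * resid[:, None]
    order = np.argsort(groups, kind="stable")
    zes = ze[order]
    gs = np.asarray(groups)[order]
    cuts = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])
    sums = np.add.reduceat(zes, cuts, axis=0)
    meat = sums.T @ sums
    g = len(cuts)
    if g < 2:
        raise ValueError("need at least 2 clusters for clustered SEs")
    c = (g / (g - 1.0)) * ((n - 1.0) / max(n - k_model, 1))
    return c * (zx_inv @ meat @ zx_inv.T)


def _demean_by_group(arrs: list[np.ndarray],
                     groups: np.ndarray) -> tuple[list[np.ndarray], int]:
    """Demean each array within groups; returns arrays and group count."""
    uniq, inv = np.unique(groups, return_inverse=True)
    counts = np.bincount(inv)
    out = []
    for a in arrs:
        means = np.bincount(inv, weights=a) / counts
        out.append(a - means[inv])
    return out, len(uniq)


def ols_pgi(y: np.ndarray, pgi_st: np.ndarray, family_ids: np.ndarray,
            within_family: bool = False,
            method: str = "ols_meta") -> EstimateResult:
    """OLS of the outcome on a standardized PGI with family-clustered SEs.

    With ``within_family`` the regression is demeaned within family (the
    fixed-effects projection), using only families with at least two
    members; the CR1 degrees-of-freedom correction counts the absorbed
    family means so that the SEs match an explicit dummy-variable fit.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(pgi_st, dtype=np.float64)
    fam = np.asarray(family_ids)
    if within_family:
        uniq, inv, counts = np.unique(fam, return_inverse=True,
                                      return_counts=True)
        keep = counts[inv] >= 2
        if not keep.any():
            raise ValueError("within-family estimation needs multi-member "
                             "families; all families are singletons")
        y, x, fam = y[keep], x[keep], fam[keep]
        (y, x), n_fam = _demean_by_group([y, x], fam)
        design = x[:, None]
        k_model = n_fam + 1
    else:
        design = np.column_stack([np.ones_like(x), x])
        n_fam = len(np.unique(fam))
        k_model = 2
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ (design.T @ y)
    resid = y - design @ beta
    cov = _cluster_cov(xtx_inv, design, resid, fam, k_model)
    slope_i = design.shape[1] - 1
    return EstimateResult(
        method=method,
        beta_st_hat=float(beta[slope_i]),
        se=float(np.sqrt(cov[slope_i, slope_i])),
        n_obs=y.shape[0],
        n_clusters=n_fam,
        within_family=within_family,
    )


def oriv(y: np.ndarray, pgi1_plus: np.ndarray, pgi2_plus: np.ndarray,
         family_ids: np.ndarray, within_family: bool = False,
         rhat: float | None = None) -> EstimateResult:
    """Stacked 2SLS with the two scaled PGIs as mutual instruments.

    The data are duplicated into two stacks; in stack 1 the regressor is
    ``pgi1_plus`` instrumented by ``pgi2_plus`` and in stack 2 the roles are
    reversed. Between families the model has stack-specific intercepts and
    SEs clustered on the individual. Within families the stack x family
    fixed effects are absorbed by demeaning and SEs are clustered on the
    family (individuals are nested in families, so two-way clustering on
    individual and family reduces to the family level).

    ``rhat`` (the correlation of the standardized PGIs) is only used for
    the reported first-stage F; if omitted it is recovered from the scaled
    inputs, whose correlation is unchanged by the common scaling.
    """
    y = np.asarray(y, dtype=np.float64)
    p1 = np.asarray(pgi1_plus, dtype=np.float64)
    p2 = np.asarray(pgi2_plus, dtype=np.float64)
    fam = np.asarray(family_ids)
    n = y.shape[0]
    if rhat is None:
        rhat = float(np.corrcoef(p1, p2)[0, 1])

    y_s = np.concatenate([y, y])
    x_s = np.concatenate([p1, p2])
    z_s = np.concatenate([p2, p1])
    ind = np.concatenate([np.arange(n), np.arange(n)])
    stack = np.concatenate([np.zeros(n, dtype=np.int64),
                            np.ones(n, dtype=np.int64)])
    fam_s = np.concatenate([fam, fam])

    if within_family:
        uniq, inv, counts = np.unique(fam, return_inverse=True,
                                      return_counts=True)
        keep1 = counts[inv] >= 2
        if not keep1.any():
            raise ValueError("within-family ORIV needs multi-member families")
        keep = np.concatenate([keep1, keep1])
        y_s, x_s, z_s = y_s[keep], x_s[keep], z_s[keep]
        ind, stack, fam_s = ind[keep], stack[keep], fam_s[keep]
        cell = fam_s * 2 + stack
        (y_s, x_s, z_s), n_cells = _demean_by_group([y_s, x_s, z_s], cell)
        design_x = x_s[:, None]
        design_z = z_s[:, None]
        k_model = n_cells + 1
        groups = fam_s
        n_clusters = len(np.unique(fam_s))
    else:
        d1 = (stack == 0).astype(np.float64)
        d2 = (stack == 1).astype(np.float64)
        design_x = np.column_stack([d1, d2, x_s])
        design_z = np.column_stack([d1, d2, z_s])
        k_model = 3
        groups = ind
        n_clusters = n

    zx = design_z.T @ design_x
    zx_inv = np.linalg.inv(zx)
    beta = zx_inv @ (design_z.T @ y_s)
    resid = y_s - design_x @ beta
    cov = _cluster_cov(zx_inv, design_z, resid, groups, k_model)
    slope_i = design_x.shape[1] - 1

    # first-stage slope of the stacked regressor on the stacked instrument
    zz = design_z.T @ design_z
    fs = np.linalg.solve(zz, design_z.T @ x_s)
    n_eff = len(np.unique(ind))
    f_stat = (math.inf if abs(rhat) >= 1.0
              else first_stage_f(rhat, n_eff))
    return EstimateResult(
        method="oriv",
        beta_st_hat=float(beta[slope_i]),
        se=float(np.sqrt(cov[slope_i, slope_i])),
        n_obs=y_s.shape[0],
        n_clusters=n_clusters,
        within_family=within_family,
        first_stage_coef=float(fs[slope_i]),
        first_stage_F=f_stat,
    )


def pgi_rc(beta_st_hat: float, se_beta: float, r2_hat: float,
           h2_est: HeritabilityEstimate,
           ) -> tuple[EstimateResult, EstimateResult]:
    """PGI repository correction: rescale OLS by sqrt(h2_SNP / R^2).

    Returns the two standard-error variants: the default SE scales the OLS
    standard error by the same disattenuation factor (treating the factor
    as fixed), while the GREML-uncertainty SE propagates the sampling error
    of the heritability estimate, se(h2) / (2 * sqrt(h2)).

    Estimates based on a heritability below 0.01 are flagged
    ``h2_below_threshold`` so that scenario aggregation can drop them.
    """
    if r2_hat <= 0:
        raise ValueError("r2_hat must be positive")
    h2_hat = h2_est.h2_hat
    if h2_hat < 0:
        raise ValueError("h2_hat must be non-negative")
    factor = math.sqrt(h2_hat / r2_hat)
    point = beta_st_hat * factor
    flags = []
    if h2_hat < H2_DROP_THRESHOLD:
        flags.append("h2_below_threshold")
    if h2_est.boundary:
        flags.append("h2_boundary")
    default = EstimateResult(
        method="pgi_rc_default",
        beta_st_hat=point,
        se=factor * se_beta,
        n_obs=h2_est.n_used,
        n_clusters=h2_est.n_used,
        flags=list(flags),
    )
    greml_unc = EstimateResult(
        method="pgi_rc_greml_unc",
        beta_st_hat=point,
        se=h2_est.se_sqrt_h2,
        n_obs=h2_est.n_used,
        n_clusters=h2_est.n_used,
        flags=list(flags),
    )
    return default, greml_unc
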