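"""Scenario runner and aggregation for the simulation study.

A scenario is a :class:`~pgicorr.simulate.SimConfig` run for a number of
replications; every replication simulates a fresh cohort, runs the two
between-family GWASs, builds the three PGIs, and applies every requested
estimator. Aggregation reports per-method means, confidence intervals
(mean estimate +/- 1.96 times the mean standard error), empirical SDs and
the RMSE against the scenario's true target coefficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pgicorr.estimators import EstimateResult, ols_pgi, oriv, pgi_rc
from pgicorr.gwas import build_pgi, meta_analyze, run_gwas, scale_for_oriv, standardize
from pgicorr.heritability import GRM, compute_grm, prune_related, reml_h2
from pgicorr.simulate import SimConfig, simulate, true_target_coefficient

logger = logging.getLogger(__name__)

__all__ = [
    "RunRecord",
    "ScenarioSummary",
    "baseline_config",
    "run_replication",
    "run_scenario",
    "summarize",
    "table1",
]

# scenario base seeds are spread out so grid points never share streams
_SCENARIO_STRIDE = 100003


def baseline_config(n_gwas_total: int, n_prediction: int,
                    m_snps: int = 5000, h2: float = 0.25, n2: float = 0.0,
                    am_rho: float = 0.0, rg_disc_pred: float = 1.0,
                    rg_disc_disc: float = 1.0, seed: int = 0,
                    **kwargs) -> SimConfig:
    """Scenario config in the study's conventions.

    ``n_gwas_total`` is split into two equal non-overlapping discovery
    GWASs (one sibling per family), and ``n_prediction`` counts prediction
    *individuals* (both siblings of ``n_prediction / 2`` families).
    """
    if n_gwas_total % 2 or n_prediction % 2:
        raise ValueError("n_gwas_total and n_prediction must be even")
    return SimConfig(
        n_snps=m_snps,
        n_families_discovery1=n_gwas_total // 2,
        n_families_discovery2=n_gwas_total // 2,
        n_families_prediction=n_prediction // 2,
        h2=h2, n2=n2, am_rho=am_rho,
        rg_disc_pred=rg_disc_pred, rg_disc_disc=rg_disc_disc,
        seed=seed, **kwargs)


@dataclass
class RunRecord:
    """All estimator outputs for one replication of one scenario."""

    scenario_id: str
    replication: int
    seed: int
    estimates: dict[str, EstimateResult]
    target_between: float
    target_within: float
    rhat: float | None = None       # correlation of the two standardized PGIs
    h2_hat: float | None = None
    h2_se: float | None = None
    excluded: bool = False          # h2_hat below the 0.01 drop rule
    errors: dict[str, str] = field(default_factory=dict)


@dataclass
class ScenarioSummary:
    """Per-method aggregate over the included replications of a scenario."""

    scenario_id: str
    target: float
    table: pd.DataFrame
    n_replications: int


def run_replication(config: SimConfig, seed: int,
                    scenario_id: str = "scenario", replication: int = 0,
                    within: bool = False, greml: bool = False,
                    one_sib_between: bool = False,
                    greml_sample: str = "cutoff",
                    grm_cutoff: float = 0.05) -> RunRecord:
    """One full simulate -> GWAS -> PGI -> estimate pass.

    ``greml_sample`` selects how the GREML sample is formed from the
    prediction set: ``"cutoff"`` prunes the GRM at ``grm_cutoff`` (default,
    removes one sibling of every pair plus incidental high-relatedness
    pairs), ``"one_sib"`` keeps one sibling per family first and then
    applies the cutoff.
    """
    cfg = replace(config, seed=seed)
    pop, study = simulate(cfg)

    ss1 = run_gwas(pop.genotypes[study.gwas_subset1],
                   pop.phenotype[study.gwas_subset1])
    ss2 = run_gwas(pop.genotypes[study.gwas_subset2],
                   pop.phenotype[study.gwas_subset2])
    meta = meta_analyze(ss1, ss2)

    geno_pred = pop.genotypes[study.prediction]
    y_pred = pop.phenotype[study.prediction]
    fam_pred = pop.fid[study.prediction]
    # one matmul for the three PGIs (the weight matrix shares the genotypes)
    weights = np.column_stack([ss1["BETA"].to_numpy(),
                               ss2["BETA"].to_numpy(),
                               meta["BETA"].to_numpy()])
    scores = build_pgi(geno_pred, weights)
    pgi1 = standardize(scores[:, 0])
    pgi2 = standardize(scores[:, 1])
    pgi_meta = standardize(scores[:, 2])

    estimates: dict[str, EstimateResult] = {}
    errors: dict[str, str] = {}
    try:
        pgis = scale_for_oriv(pgi1, pgi2, pgi_meta)
    except ValueError as exc:
        # unusable instruments (non-positive PGI correlation): keep the OLS
        # track alive and flag every ORIV-based method for this run
        errors["oriv"] = f"{type(exc).__name__}: {exc}"
        logger.warning("%s rep %d: ORIV scaling failed: %s",
                       scenario_id, replication, exc)
        pgis = None

    if one_sib_between:
        # deterministic first-child selection for the between-family runs
        first = np.flatnonzero(np.r_[True, fam_pred[1:] != fam_pred[:-1]])
        b_idx = first
    else:
        b_idx = np.arange(y_pred.shape[0])

    def attempt(name, fn):
        try:
            estimates[name] = fn()
        except Exception as exc:  # estimator failures flag the run
            errors[name] = f"{type(exc).__name__}: {exc}"
            logger.warning("%s rep %d: %s failed: %s",
                           scenario_id, replication, name, exc)

    attempt("ols_meta", lambda: ols_pgi(
        y_pred[b_idx], pgi_meta[b_idx], fam_pred[b_idx]))
    if pgis is not None:
        attempt("oriv", lambda: oriv(
            y_pred[b_idx], pgis.pgi1_plus[b_idx], pgis.pgi2_plus[b_idx],
            fam_pred[b_idx], rhat=pgis.rhat))
    if within:
        attempt("ols_meta_within", lambda: ols_pgi(
            y_pred, pgi_meta, fam_pred, within_family=True,
            method="ols_meta"))
        if pgis is not None:
            # within-family ORIV keeps the between-family rhat scaling
            attempt("oriv_within", lambda: oriv(
                y_pred, pgis.pgi1_plus, pgis.pgi2_plus, fam_pred,
                within_family=True, rhat=pgis.rhat))

    h2_hat = h2_se = None
    excluded = False
    if greml:
        try:
            if greml_sample == "one_sib":
                first = np.flatnonzero(
                    np.r_[True, fam_pred[1:] != fam_pred[:-1]])
                g_idx = first
            elif greml_sample == "cutoff":
                g_idx = np.arange(y_pred.shape[0])
            else:
                raise ValueError(f"unknown greml_sample {greml_sample!r}")
            grm = compute_grm(geno_pred[g_idx],
                              ids=pop.iid[study.prediction][g_idx])
            keep = prune_related(grm, cutoff=grm_cutoff)
            sub = GRM(matrix=grm.matrix[np.ix_(keep, keep)],
                      ids=grm.ids[keep], n_snps=grm.n_snps)
            h2_est = reml_h2(sub, y_pred[g_idx][keep])
            h2_hat, h2_se = h2_est.h2_hat, h2_est.se_h2
            base = estimates["ols_meta"]
            rc_def, rc_unc = pgi_rc(base.beta_st_hat, base.se,
                                    base.beta_st_hat ** 2, h2_est)
            estimates["pgi_rc_default"] = rc_def
            estimates["pgi_rc_greml_unc"] = rc_unc
            excluded = "h2_below_threshold" in rc_def.flags
        except Exception as exc:
            errors["pgi_rc"] = f"{type(exc).__name__}: {exc}"
            logger.warning("%s rep %d: GREML/PGI-RC failed: %s",
                           scenario_id, replication, exc)

    return RunRecord(
        scenario_id=scenario_id,
        replication=replication,
        seed=seed,
        estimates=estimates,
        target_between=true_target_coefficient(pop, study, "between"),
        target_within=true_target_coefficient(pop, study, "within"),
        rhat=None if pgis is None else pgis.rhat,
        h2_hat=h2_hat,
        h2_se=h2_se,
        excluded=excluded,
        errors=errors,
    )


def run_scenario(config: SimConfig, replications: int, base_seed: int,
                 scenario_id: str = "scenario",
                 **kwargs) -> list[RunRecord]:
    """Run a scenario for ``replications`` runs with seeds base_seed + i."""
    if replications < 1:
        raise ValueError("replications must be >= 1")
    records = []
    for i in range(replications):
        records.append(run_replication(
            config, seed=base_seed + i, scenario_id=scenario_id,
            replication=i, **kwargs))
        logger.debug("%s: replication %d/%d done", scenario_id, i + 1,
                     replications)
    return records


def summarize(records: list[RunRecord],
              target: float | None = None) -> ScenarioSummary:
    """Aggregate replications into per-method means, CIs and RMSE.

    PGI-RC aggregates exclude runs flagged by the h2 < 0.01 drop rule.
    Within-family methods are scored against the within-family target
    (sqrt(h2)); everything else against the between-family target.
    """
    if not records:
        raise ValueError("no run records to summarize")
    methods: list[str] = []
    for rec in records:
        for name in rec.estimates:
            if name not in methods:
                methods.append(name)
    t_between = (target if target is not None
                 else float(np.mean([r.target_between for r in records])))
    t_within = float(np.mean([r.target_within for r in records]))
    rows = []
    for name in methods:
        pairs = []
        for rec in records:
            if name not in rec.estimates:
                continue
            if name.startswith("pgi_rc") and rec.excluded:
                continue
            pairs.append(rec.estimates[name])
        if not pairs:
            raise ValueError(f"zero included runs for method {name!r}")
        est = np.array([p.beta_st_hat for p in pairs])
        ses = np.array([p.se for p in pairs])
        tgt = t_within if pairs[0].within_family else t_between
        mean = est.mean()
        mean_se = ses.mean()
        rows.append({
            "method": name,
            "within_family": pairs[0].within_family,
            "mean": mean,
            "mean_se": mean_se,
            "ci_low": mean - 1.96 * mean_se,
            "ci_high": mean + 1.96 * mean_se,
            "empirical_sd": est.std(ddof=0),
            "target": tgt,
            "bias": mean - tgt,
            "rmse": math.sqrt(np.mean((est - tgt) ** 2)),
            "n_total": len(records),
            "n_included": len(pairs),
        })
    return ScenarioSummary(
        scenario_id=records[0].scenario_id,
        target=t_between,
        table=pd.DataFrame(rows),
        n_replications=len(records),
    )


# Table 1 layout: two GWAS sizes (meta-PGI R^2 of 4.2% and 15.4% at M = 5000)
# crossed with three prediction sample sizes
TABLE1_CELLS = [
    ("~EA2", 4000, 1000), ("~EA2", 4000, 4000), ("~EA2", 4000, 16000),
    ("~EA4", 32000, 1000), ("~EA4", 32000, 4000), ("~EA4", 32000, 16000),
]


def table1(replications: int = 100, base_seed: int = 0,
           m_snps: int = 5000, greml: bool = True,
           cells=None, **kwargs) -> pd.DataFrame:
    """Reproduce the baseline-scenario table (between-family analyses).

    Returns one row per (GWAS size, prediction size) cell and method, with
    mean estimates and mean-SE confidence intervals over replications.
    """
    cells = TABLE1_CELLS if cells is None else cells
    frames = []
    for i, (label, n_gwas, n_pred) in enumerate(cells):
        cfg = baseline_config(n_gwas, n_pred, m_snps=m_snps)
        sid = f"{label}_N{n_pred}"
        recs = run_scenario(cfg, replications,
                            base_seed + _SCENARIO_STRIDE * i,
                            scenario_id=sid, greml=greml, **kwargs)
        summ = summarize(recs, target=math.sqrt(cfg.h2 + 0.5 * cfg.n2))
        tab = summ.table.copy()
        tab.insert(0, "gwas", label)
        tab.insert(1, "n_prediction", n_pred)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
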