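"""Shared fixtures.

The light fixtures build small cohorts for unit tests. The session-scoped
scenario fixtures run the desk-scale study conditions once and are shared
between the acceptance tests and the module-level property tests, so each
heavy simulation happens at most once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from pgicorr.experiments import baseline_config, run_scenario
from pgicorr.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def tiny_study():
    """Small two-generation cohort for structural and format tests."""
    cfg = SimConfig(n_snps=400, n_families_discovery1=150,
                    n_families_discovery2=150, n_families_prediction=300,
                    n_generations=2, seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def gn_study():
    """Genetic-nurture cohort (h2 = 0.2, n2 = 0.1) at unit-test scale."""
    cfg = SimConfig(n_snps=400, n_families_discovery1=100,
                    n_families_discovery2=100, n_families_prediction=400,
                    h2=0.2, n2=0.1, seed=23)
    return simulate(cfg)


# ---------------------------------------------------------------------------
# desk-scale scenario runs (shared by acceptance and property tests)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def ea2_pred16k_records():
    """Baseline, GWAS 2 x 2000, N_pred = 16,000; meta-PGI R^2 ~ 4.2%."""
    cfg = baseline_config(4000, 16000)
    return run_scenario(cfg, 100, base_seed=1000, scenario_id="ea2_16k")


@pytest.fixture(scope="session")
def ea2_pred4k_records():
    """Baseline, GWAS 2 x 2000, N_pred = 4000, with GREML for PGI-RC."""
    cfg = baseline_config(4000, 4000)
    return run_scenario(cfg, 40, base_seed=2000, scenario_id="ea2_4k",
                        greml=True)


@pytest.fixture(scope="session")
def ea2_pred1k_records():
    """Baseline, GWAS 2 x 2000, N_pred = 1000."""
    cfg = baseline_config(4000, 1000)
    return run_scenario(cfg, 100, base_seed=3000, scenario_id="ea2_1k")


@pytest.fixture(scope="session")
def ea4_pred1k_records():
    """Baseline, GWAS 2 x 16,000, N_pred = 1000; meta-PGI R^2 ~ 15.4%."""
    cfg = baseline_config(32000, 1000)
    return run_scenario(cfg, 20, base_seed=4000, scenario_id="ea4_1k")


@pytest.fixture(scope="session")
def ea4_pred4k_records():
    """Baseline, GWAS 2 x 16,000, N_pred = 4000."""
    cfg = baseline_config(32000, 4000)
    return run_scenario(cfg, 20, base_seed=5000, scenario_id="ea4_4k")


@pytest.fixture(scope="session")
def ea4_pred16k_records():
    """Baseline, GWAS 2 x 16,000, N_pred = 16,000."""
    cfg = baseline_config(32000, 16000)
    return run_scenario(cfg, 20, base_seed=6000, scenario_id="ea4_16k")


@pytest.fixture(scope="session")
def am075_records():
    """Assortative mating 0.75 (no nurture), ten generations, with GREML."""
    cfg = baseline_config(4000, 4000, am_rho=0.75)
    return run_scenario(cfg, 6, base_seed=7000, scenario_id="am075",
                        greml=True)


@pytest.fixture(scope="session")
def rg05_records():
    """Genetic correlation 0.5 between discovery and prediction samples."""
    cfg = baseline_config(8000, 4000, rg_disc_pred=0.5)
    return run_scenario(cfg, 4, base_seed=8000, scenario_id="rg05",
                        greml=True)


@pytest.fixture(scope="session")
def gn_records():
    """Genetic nurture h2 = 0.2, n2 = 0.1, with GREML and within-family."""
    cfg = baseline_config(4000, 4000, h2=0.2, n2=0.1)
    return run_scenario(cfg, 4, base_seed=9000, scenario_id="gn",
                        greml=True, within=True)


def method_means(records, name):
    """Mean point estimate of one method over (included) records."""
    vals = [r.estimates[name].beta_st_hat for r in records
            if name in r.estimates
            and not (name.startswith("pgi_rc") and r.excluded)]
    return float(np.mean(vals))
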