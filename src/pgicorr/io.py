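"""Readers and writers for the plain-text exchange formats.

All files are header-carrying, UTF-8, LF, tab-separated; missing values are
written as '.'. The genotype table follows the PLINK ``.raw`` column layout
(FID, IID, PAT, MAT, then one 0/1/2 column per SNP); the GRM is persisted
as the GCTA text layout (lower triangle: ID1, ID2, n_snps, value).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pgicorr.estimators import EstimateResult
from pgicorr.gwas import SUMSTAT_COLUMNS
from pgicorr.heritability import GRM
from pgicorr.simulate import ConfigError, Population, SimConfig

__all__ = [
    "load_config", "save_config",
    "write_genotypes", "read_genotypes",
    "write_pedigree", "read_pedigree",
    "write_sumstats", "read_sumstats",
    "write_pgi", "read_pgi",
    "write_grm", "read_grm",
    "write_estimates",
]

MISSING = "."


def load_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from a JSON or YAML file (seed is mandatory)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    if "seed" not in data:
        raise ConfigError("config is missing required field 'seed'")
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    if "founder_maf_range" in data:
        data["founder_maf_range"] = tuple(data["founder_maf_range"])
    try:
        return SimConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: SimConfig, path: str | Path) -> None:
    data = {k: getattr(config, k) for k in SimConfig.__dataclass_fields__}
    data["founder_maf_range"] = list(data["founder_maf_range"])
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def write_genotypes(population: Population, path: str | Path,
                    snp_ids: list[str] | None = None) -> None:
    """Write the current generation's allele counts in the .raw layout."""
    m = population.n_snps
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    df = pd.DataFrame({
        "FID": population.fid,
        "IID": population.iid,
        "PAT": population.pat,
        "MAT": population.mat,
    })
    geno = pd.DataFrame(population.genotypes, columns=snp_ids)
    pd.concat([df, geno], axis=1).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a .raw-style table; returns (id columns, int8 genotype matrix)."""
    df = pd.read_csv(path, sep="\t")
    idcols = ["FID", "IID", "PAT", "MAT"]
    missing = [c for c in idcols if c not in df.columns]
    if missing:
        raise ValueError(f"genotype file lacks required columns {missing}")
    geno = df.drop(columns=idcols).to_numpy(dtype=np.int8)
    return df[idcols], geno


def write_pedigree(population: Population, path: str | Path) -> None:
    ped = population.pedigree()
    out = pd.DataFrame({
        "IID": ped["iid"],
        "FID": ped["fid"],
        "PAT": ped["pat"],
        "MAT": ped["mat"],
        "GENERATION": ped["generation"],
        "Y": ped["phenotype"].round(6),
        "TRUE_PGI": ped["true_pgi"].round(6),
    })
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=MISSING)


def write_sumstats(ss: pd.DataFrame, path: str | Path) -> None:
    ss[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False,
                               float_format="%.6g", na_rep=MISSING)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    ss = pd.read_csv(path, sep="\t", na_values=MISSING)
    missing = [c for c in SUMSTAT_COLUMNS if c not in ss.columns]
    if missing:
        raise ValueError(f"summary statistics lack columns {missing}")
    return ss


def write_pgi(iid: np.ndarray, fid: np.ndarray, pgi1: np.ndarray,
              pgi2: np.ndarray, pgi_meta: np.ndarray,
              path: str | Path) -> None:
    pd.DataFrame({
        "IID": iid, "FID": fid,
        "PGI1": np.round(pgi1, 6),
        "PGI2": np.round(pgi2, 6),
        "PGI_META": np.round(pgi_meta, 6),
    }).to_csv(path, sep="\t", index=False)


def read_pgi(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = ["IID", "FID", "PGI1", "PGI2", "PGI_META"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"PGI file lacks columns {missing}")
    return df


def write_grm(grm: GRM, path: str | Path) -> None:
    """Lower-triangle text GRM (ID1, ID2, n_snps, value)."""
    n = grm.n
    i, j = np.tril_indices(n)
    pd.DataFrame({
        "ID1": grm.ids[i],
        "ID2": grm.ids[j],
        "N_SNPS": grm.n_snps,
        "VALUE": np.round(grm.matrix[i, j], 6),
    }).to_csv(path, sep="\t", index=False)


def read_grm(path: str | Path) -> GRM:
    df = pd.read_csv(path, sep="\t")
    ids = pd.unique(df["ID1"])
    n = len(ids)
    pos = {v: k for k, v in enumerate(ids)}
    a = np.zeros((n, n))
    i = df["ID1"].map(pos).to_numpy()
    j = df["ID2"].map(pos).to_numpy()
    a[i, j] = df["VALUE"]
    a[j, i] = df["VALUE"]
    return GRM(matrix=a, ids=np.asarray(ids),
               n_snps=int(df["N_SNPS"].iloc[0]))


def write_estimates(results: list[EstimateResult], path: str | Path) -> None:
    rows = []
    for r in results:
        rows.append({
            "METHOD": r.method,
            "SCOPE": "within" if r.within_family else "between",
            "BETA": round(r.beta_st_hat, 6),
            "SE": round(r.se, 6),
            "CI_LOW": round(r.ci_low, 6),
            "CI_HIGH": round(r.ci_high, 6),
            "IMPLIED_H2": round(r.implied_h2, 6),
            "FIRST_STAGE_F": (round(r.first_stage_F, 6)
                              if r.first_stage_F is not None else MISSING),
            "N": r.n_obs,
            "N_CLUSTERS": r.n_clusters,
            "FLAGS": ",".join(r.flags) if r.flags else MISSING,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
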