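"""Readers and writers for the plain-text dialects the package speaks.

* phased haplotype panels: one haplotype per row of 0/1 alleles, whitespace
  or comma separated, optional header of SNP ids; a two-rows-per-individual
  layout is the same format read in pairs.
* genotype tables: TSV with a ``phenotype`` column (0/1) followed by one
  additive 0/1/2 column per SNP, and the PLINK ``.raw`` dialect
  (``FID IID PAT MAT SEX PHENOTYPE`` then allele counts, phenotype 1/2).
* SNP-set membership files: two tab-separated columns, set_id and snp_id.
* scenario configurations: YAML or JSON with :class:`ScenarioSpec` fields.
* fitted haplotype models: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .settests import SetTestResult
from .sim import GenotypeDataset, HaplotypeModel, ScenarioSpec

__all__ = [
    "read_haplotypes",
    "write_haplotypes",
    "haplotypes_to_genotypes",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_plink_raw",
    "write_plink_raw",
    "read_genotypes",
    "read_snp_sets",
    "load_scenario",
    "save_scenario",
    "save_model",
    "load_model",
    "results_to_frame",
    "write_results",
    "write_loadings",
]


def read_haplotypes(path) -> tuple[np.ndarray, list[str] | None]:
    """Read a phased haplotype panel; returns (matrix, snp_ids or None)."""
    lines = Path(path).read_text().strip().splitlines()
    if not lines:
        raise ValueError(f"empty haplotype file: {path}")
    first = lines[0].replace(",", " ").split()
    snp_ids = None
    if not set("".join(first)) <= {"0", "1"}:
        snp_ids = first
        lines = lines[1:]
    rows = [
        [int(tok) for tok in line.replace(",", " ").split()]
        for line in lines
        if line.strip()
    ]
    H = np.asarray(rows, dtype=np.int8)
    if not np.isin(H, [0, 1]).all():
        raise ValueError("haplotype entries must be 0 or 1")
    return H, snp_ids


def write_haplotypes(path, haplotypes, snp_ids=None) -> None:
    with open(path, "w") as fh:
        if snp_ids is not None:
            fh.write(" ".join(snp_ids) + "\n")
        for row in np.asarray(haplotypes, dtype=int):
            fh.write(" ".join(map(str, row)) + "\n")


def haplotypes_to_genotypes(haplotypes) -> np.ndarray:
    """Pair consecutive rows of a two-rows-per-individual phased panel."""
    H = np.asarray(haplotypes)
    if H.shape[0] % 2:
        raise ValueError("two-row-per-individual panel needs an even row count")
    return H[0::2] + H[1::2]


def write_genotype_tsv(path, dataset: GenotypeDataset) -> None:
    df = pd.DataFrame(
        np.asarray(dataset.genotypes, dtype=int), columns=dataset.snp_ids
    )
    df.insert(0, "phenotype", np.asarray(dataset.phenotype, dtype=int))
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t")
    if "phenotype" not in df.columns:
        raise ValueError("genotype TSV must have a 'phenotype' column")
    snp_ids = [c for c in df.columns if c != "phenotype"]
    return GenotypeDataset(
        genotypes=df[snp_ids].to_numpy(dtype=np.int8),
        phenotype=df["phenotype"].to_numpy(dtype=np.int8),
        snp_ids=snp_ids,
    )


def write_plink_raw(path, dataset: GenotypeDataset) -> None:
    """PLINK .raw dialect; PHENOTYPE coded 1 (control) / 2 (case)."""
    n = dataset.n_individuals
    df = pd.DataFrame(
        {
            "FID": [f"F{i + 1}" for i in range(n)],
            "IID": [f"I{i + 1}" for i in range(n)],
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": np.asarray(dataset.phenotype, dtype=int) + 1,
        }
    )
    geno = pd.DataFrame(
        np.asarray(dataset.genotypes, dtype=int),
        columns=[f"{s}_A" for s in dataset.snp_ids],
    )
    pd.concat([df, geno], axis=1).to_csv(path, sep=" ", index=False)


def read_plink_raw(path) -> GenotypeDataset:
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f".raw file lacks column(s) {missing}")
    snp_cols = [c for c in df.columns if c not in meta]
    snp_ids = [c[:-2] if c.endswith("_A") else c for c in snp_cols]
    pheno = df["PHENOTYPE"].to_numpy(dtype=int)
    if not np.isin(pheno, [1, 2]).all():
        raise ValueError(".raw PHENOTYPE must be coded 1/2")
    return GenotypeDataset(
        genotypes=df[snp_cols].to_numpy(dtype=np.int8),
        phenotype=(pheno - 1).astype(np.int8),
        snp_ids=snp_ids,
    )


def read_genotypes(path) -> GenotypeDataset:
    """Dispatch on extension: ``.raw`` -> PLINK dialect, else genotype TSV."""
    if str(path).endswith(".raw"):
        return read_plink_raw(path)
    return read_genotype_tsv(path)


def read_snp_sets(path) -> dict[str, list[str]]:
    """Two-column tab-separated membership file: set_id <tab> snp_id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_id", "snp_id"],
                     dtype=str, comment="#")
    sets: dict[str, list[str]] = {}
    for set_id, snp_id in df.itertuples(index=False):
        sets.setdefault(set_id, []).append(snp_id)
    return sets


# ---------------------------------------------------------------------------
# scenario / model serialisation
# ---------------------------------------------------------------------------


def _spec_to_dict(spec: ScenarioSpec) -> dict:
    return {
        "scenario_id": spec.scenario_id,
        "n_snps": spec.n_snps,
        "mafs": list(spec.mafs),
        "r2": spec.r2 if np.isscalar(spec.r2) else [list(r) for r in spec.r2],
        "causal_indices": list(spec.causal_indices),
        "grrs": list(spec.grrs),
        "n_cases": spec.n_cases,
        "n_controls": spec.n_controls,
        "baseline_prevalence": spec.baseline_prevalence,
    }


def save_scenario(path, spec: ScenarioSpec) -> None:
    payload = _spec_to_dict(spec)
    if str(path).endswith((".yaml", ".yml")):
        Path(path).write_text(yaml.safe_dump(payload))
    else:
        Path(path).write_text(json.dumps(payload, indent=2))


def load_scenario(path) -> ScenarioSpec:
    text = Path(path).read_text()
    data = (
        yaml.safe_load(text)
        if str(path).endswith((".yaml", ".yml"))
        else json.loads(text)
    )
    if "mafs" in data:
        data["mafs"] = tuple(data["mafs"])
    if isinstance(data.get("r2"), list):
        data["r2"] = tuple(tuple(row) for row in data["r2"])
    data["causal_indices"] = tuple(data.get("causal_indices", ()))
    data["grrs"] = tuple(data.get("grrs", ()))
    return ScenarioSpec(**data)


def save_model(path, model: HaplotypeModel) -> None:
    payload = {
        "mafs": model.mafs.tolist(),
        "latent_corr": model.latent_corr.tolist(),
        "target_r2": model.target_r2.tolist(),
        "repair_distance": model.repair_distance,
        "flipped": list(model.flipped),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> HaplotypeModel:
    from scipy import stats as _st

    data = json.loads(Path(path).read_text())
    mafs = np.asarray(data["mafs"], dtype=float)
    return HaplotypeModel(
        mafs=mafs,
        latent_corr=np.asarray(data["latent_corr"], dtype=float),
        thresholds=_st.norm.ppf(mafs),
        target_r2=np.asarray(data["target_r2"], dtype=float),
        repair_distance=float(data.get("repair_distance", 0.0)),
        flipped=tuple(data.get("flipped", ())),
    )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def results_to_frame(results: dict[str, dict[str, SetTestResult]]):
    """Flatten {set_id: {method: result}} into the per-set results table."""
    rows = []
    for set_id, by_method in results.items():
        for res in by_method.values():
            rows.append(
                {
                    "set_id": set_id,
                    "method": res.method,
                    "statistic": res.statistic,
                    "df": res.df if res.df is not None else "",
                    "p_value": res.p_value,
                    "n_components": res.n_components,
                    "selected_snps": (
                        ",".join(map(str, res.selected_snps))
                        if res.selected_snps
                        else ""
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "set_id", "method", "statistic", "df", "p_value",
            "n_components", "selected_snps",
        ],
    )


def write_results(path, results: dict[str, dict[str, SetTestResult]]) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def write_loadings(path, snp_ids, loadings) -> None:
    """SNP x component loading table (for principal-component reports)."""
    L = np.atleast_2d(np.asarray(loadings, dtype=float))
    if L.shape[0] != len(snp_ids):
        L = L.T
    df = pd.DataFrame(
        L, index=snp_ids, columns=[f"PC{j + 1}" for j in range(L.shape[1])]
    )
    df.index.name = "snp_id"
    df.to_csv(path, sep="\t")
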