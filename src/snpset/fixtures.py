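"""Deterministic toy-input generators.

Everything the test-suite and the examples consume is generated on the fly
from a seed — toy phased haplotype panels drawn from a known model, small
case-control datasets with planted effects, and degenerate edge-case files
(monomorphic SNP, duplicated SNP, single-class phenotype).  Generation is
idempotent: the same (kind, parameters, seed) always yields the same bytes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import io
from .sim import (
    GenotypeDataset,
    HaplotypeModel,
    ScenarioSpec,
    build_haplotype_model,
    draw_haplotypes,
    simulate_case_control,
)

__all__ = [
    "make_panel",
    "make_dataset",
    "edge_case_dataset",
    "toy_model",
]


def toy_model(
    n_snps: int = 8, maf: float = 0.3, r2: float = 0.5
) -> HaplotypeModel:
    """Small equicorrelated haplotype model used across tests and examples."""
    return build_haplotype_model([maf] * n_snps, r2)


def make_panel(
    model: HaplotypeModel, m: int, seed: int, path=None
) -> np.ndarray:
    """Draw an m-haplotype panel from ``model``; optionally write it to disk."""
    rng = np.random.default_rng(seed)
    H = draw_haplotypes(model, m, rng)
    if path is not None:
        ids = [f"snp{j + 1}" for j in range(model.n_snps)]
        io.write_haplotypes(path, H, ids)
    return H


def make_dataset(
    spec: ScenarioSpec, seed: int, out_dir=None, stem: str = "dataset"
) -> GenotypeDataset:
    """Simulate one dataset; optionally write matched TSV + PLINK .raw files."""
    rng = np.random.default_rng(seed)
    ds = simulate_case_control(spec, rng)
    if out_dir is not None:
        out = Path(out_dir)
        io.write_genotype_tsv(out / f"{stem}.tsv", ds)
        io.write_plink_raw(out / f"{stem}.raw", ds)
    return ds


def edge_case_dataset(kind: str, n: int = 80, seed: int = 0) -> GenotypeDataset:
    """Degenerate datasets for error-path testing.

    kinds: ``monomorphic`` (one constant SNP), ``duplicated`` (two identical
    SNPs), ``single_class`` (phenotype all controls).
    """
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 3, size=(n, 4)).astype(np.int8)
    y = (rng.random(n) < 0.5).astype(np.int8)
    y[0], y[1] = 0, 1  # guarantee both classes unless overridden below
    if kind == "monomorphic":
        g[:, 1] = 1
    elif kind == "duplicated":
        g[:, 2] = g[:, 1]
    elif kind == "single_class":
        y[:] = 0
    else:
        raise ValueError(f"unknown edge case '{kind}'")
    return GenotypeDataset(g, y, [f"snp{j + 1}" for j in range(4)])
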