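"""Fit the simulator to a phased haplotype reference panel.

Real studies anchor the simulator to a reference panel (e.g. phased
haplotypes of a gene region) instead of an artificial equicorrelated
design.  Here a toy panel stands in for such a download: we write it to
disk, fit the latent-Gaussian model back from the file, and verify the fit
recovers the panel's MAF and LD structure.
"""

import tempfile
from pathlib import Path

import numpy as np

from snpset import (
    build_haplotype_model,
    draw_haplotypes,
    empirical_ld,
    fit_model_from_haplotypes,
)
from snpset.fixtures import make_panel
from snpset.io import read_haplotypes

truth = build_haplotype_model([0.1, 0.15, 0.25, 0.3, 0.4], r2=0.15)
with tempfile.TemporaryDirectory() as tmp:
    panel_path = Path(tmp) / "panel.txt"
    make_panel(truth, m=5000, seed=3, path=panel_path)
    panel, snp_ids = read_haplotypes(panel_path)

model = fit_model_from_haplotypes(panel)
print("panel:", panel.shape[0], "haplotypes x", panel.shape[1], "SNPs", snp_ids)
print("fitted MAFs:   ", np.round(model.mafs, 3))
print("true   MAFs:   ", np.round(truth.mafs, 3))
print("PD repair distance:", model.repair_distance)

resim = draw_haplotypes(model, 50_000, np.random.default_rng(4))
print("panel R^2[0,1]:", round(empirical_ld(panel)[0, 1], 3),
      " resimulated:", round(empirical_ld(resim)[0, 1], 3))
# The refitted model reproduces the panel's allele frequencies and pairwise
# R^2, so datasets simulated from it inherit the reference LD structure.
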