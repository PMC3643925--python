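"""Scenario registry and type-I-error / power evaluation harness.

The built-in scenario grid covers nine virtual designs (A1-A9): three MAF
levels (0.05, 0.1, 0.2) crossed with null, single-causal (per-allele GRR 1.3)
and two-causal (GRR 1.2 each) disease models, each available at pairwise LD
R^2 of 0.2, 0.5 or 0.8 and with 10 or 100 SNPs, 1,000 cases and 1,000
controls.  ``run_replicates`` simulates datasets replicate by replicate
(seeded as ``base_seed + i``), runs every requested method on the *same*
dataset, and summarises rejection rates with their Monte-Carlo standard
errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .settests import TestConfig, run_set_tests
from .sim import ScenarioSpec, _scenario_model, simulate_case_control

__all__ = [
    "RejectionSummary",
    "builtin_scenarios",
    "get_scenario",
    "run_replicates",
    "collect_pvalues",
    "summarize_to_table",
]

logger = logging.getLogger("snpset")

_MAFS = {"A1": 0.05, "A2": 0.1, "A3": 0.2,
         "A4": 0.05, "A5": 0.1, "A6": 0.2,
         "A7": 0.05, "A8": 0.1, "A9": 0.2}
_EFFECTS: dict[str, tuple[tuple[int, ...], tuple[float, ...]]] = {
    "A1": ((), ()), "A2": ((), ()), "A3": ((), ()),
    "A4": ((0,), (1.3,)), "A5": ((0,), (1.3,)), "A6": ((0,), (1.3,)),
    "A7": ((0, 1), (1.2, 1.2)), "A8": ((0, 1), (1.2, 1.2)),
    "A9": ((0, 1), (1.2, 1.2)),
}
_LD_LEVELS = (0.2, 0.5, 0.8)


@dataclass(frozen=True)
class RejectionSummary:
    """Rejection-rate estimate for one scenario x method x alpha cell."""

    scenario_id: str
    method: str
    alpha: float
    n_replicates: int
    n_rejections: int
    base_seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_rejections <= self.n_replicates:
            raise ValueError("rejection count outside [0, n_replicates]")

    @property
    def rejection_rate(self) -> float:
        return self.n_rejections / self.n_replicates

    @property
    def mc_se(self) -> float:
        r = self.rejection_rate
        return float(np.sqrt(r * (1 - r) / self.n_replicates))


def get_scenario(
    scenario_id: str, ld: float, n_snps: int = 10
) -> ScenarioSpec:
    """One built-in scenario by id ("A1".."A9"), LD level and SNP count."""
    sid = scenario_id.upper()
    if sid not in _MAFS:
        raise KeyError(f"unknown scenario '{scenario_id}' (expected A1-A9)")
    if ld not in _LD_LEVELS:
        raise ValueError(f"LD must be one of {_LD_LEVELS}")
    causal, grrs = _EFFECTS[sid]
    return ScenarioSpec(
        scenario_id=f"{sid}-LD{ld}-p{n_snps}",
        n_snps=n_snps,
        mafs=(_MAFS[sid],) * n_snps,
        r2=float(ld),
        causal_indices=causal,
        grrs=grrs,
        n_cases=1000,
        n_controls=1000,
    )


def builtin_scenarios(n_snps: int = 10) -> list[ScenarioSpec]:
    """All 27 built-in scenarios (A1-A9 x LD 0.2/0.5/0.8) at one SNP count."""
    return [
        get_scenario(sid, ld, n_snps)
        for sid in sorted(_MAFS)
        for ld in _LD_LEVELS
    ]


def _one_replicate(spec, model, methods, config, seed, on_error):
    rng = np.random.default_rng(seed)
    try:
        ds = simulate_case_control(spec, rng, model=model)
        res = run_set_tests(ds.genotypes, ds.phenotype, methods, config, rng)
        return [res[m.lower()].p_value for m in methods]
    except Exception:
        if on_error == "abort":
            raise
        logger.exception("replicate seed %d failed; skipping", seed)
        return [np.nan] * len(methods)


def collect_pvalues(
    spec: ScenarioSpec,
    methods: Sequence[str],
    n_replicates: int,
    base_seed: int = 0,
    config: TestConfig = TestConfig(),
    on_error: str = "abort",
    progress_every: int = 100,
    n_workers: int = 1,
) -> dict[str, np.ndarray]:
    """Simulate ``n_replicates`` datasets and run every method on each.

    Replicate ``i`` uses ``np.random.default_rng(base_seed + i)`` for both the
    dataset and any permutation stream, so results are identical for any
    execution order or worker count.  Returns per-method p-value arrays (NaN
    where a replicate failed and ``on_error="skip"``).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if on_error not in ("abort", "skip"):
        raise ValueError("on_error must be 'abort' or 'skip'")
    model, _ = _scenario_model(spec)
    pvals = {m: np.full(n_replicates, np.nan) for m in methods}
    if n_workers > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_workers)(
            delayed(_one_replicate)(
                spec, model, methods, config, base_seed + i, on_error
            )
            for i in range(n_replicates)
        )
        for i, row in enumerate(rows):
            for m, p in zip(methods, row):
                pvals[m][i] = p
        return pvals
    for i in range(n_replicates):
        row = _one_replicate(spec, model, methods, config, base_seed + i, on_error)
        for m, p in zip(methods, row):
            pvals[m][i] = p
        if progress_every and (i + 1) % progress_every == 0:
            logger.info(
                "%s: %d/%d replicates done", spec.scenario_id, i + 1, n_replicates
            )
    return pvals


def run_replicates(
    spec: ScenarioSpec,
    methods: Sequence[str],
    n_replicates: int,
    alphas: Sequence[float] = (0.05,),
    base_seed: int = 0,
    config: TestConfig = TestConfig(),
    on_error: str = "abort",
) -> list[RejectionSummary]:
    """Rejection-rate summaries per method and significance level."""
    pvals = collect_pvalues(
        spec, methods, n_replicates, base_seed, config, on_error
    )
    summaries = []
    for m in methods:
        pv = pvals[m]
        valid = ~np.isnan(pv)
        for alpha in alphas:
            summaries.append(
                RejectionSummary(
                    scenario_id=spec.scenario_id,
                    method=m.upper(),
                    alpha=float(alpha),
                    n_replicates=int(valid.sum()),
                    n_rejections=int(np.sum(pv[valid] < alpha)),
                    base_seed=base_seed,
                )
            )
    return summaries


def summarize_to_table(summaries: Sequence[RejectionSummary], wide: bool = True):
    """Rejection-rate table keyed by scenario.

    ``wide=True`` (default) gives one rejection-rate column per method —
    the layout of the published type-I-error tables; ``wide=False`` gives
    the long format (one row per scenario x method x alpha, with mc_se),
    convenient for power-vs-(LD, MAF) plots.
    """
    import pandas as pd

    if not summaries:
        return pd.DataFrame(
            columns=["scenario_id", "alpha", "n_replicates"]
        )
    rows = [
        {
            "scenario_id": s.scenario_id,
            "method": s.method,
            "alpha": s.alpha,
            "n_replicates": s.n_replicates,
            "rejection_rate": s.rejection_rate,
            "mc_se": s.mc_se,
        }
        for s in summaries
    ]
    long = pd.DataFrame(rows)
    if not wide:
        return long
    table = long.pivot_table(
        index=["scenario_id", "alpha", "n_replicates"],
        columns="method",
        values="rejection_rate",
    ).reset_index()
    table.columns.name = None
    return table
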