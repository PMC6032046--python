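"""Synthetic GWAS summary statistics with the model's exact generative structure.

A scenario fixes the truth: m SNPs, of which a Bernoulli(pi_true) subset
is disease-associated with effects drawn from a discrete distribution
g_true; per-SNP variances come from an allele-frequency model via the
standard asymptotic allele-count log-OR variance

    V_j = 1 / (2 f_j (1 - f_j)) * (1/n_cases + 1/n_controls),

with f_j drawn from the MAF model (default uniform on (0.05, 0.5), a
common-SNP-like spectrum); observed estimates are Y_j ~ N(beta_j, V_j).
Every generator is a pure function of (scenario, seed): the scenario seed
spawns fixed sub-streams for frequencies, truth labels and noise, so
:func:`draw_variances` and :func:`draw_truth` are reproducible both alone
and inside :func:`emit_dataset`.

Block LD fixtures (:func:`make_block_ld`) provide cliques of correlated
ids for exercising the pruning contract without genotype data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EffectDistribution, EffectGrid, make_grid
from .gwas_io import LdTable, SummaryTable

__all__ = [
    "SyntheticScenario",
    "SyntheticDataset",
    "DEFAULT_COLUMN_MAP",
    "draw_variances",
    "draw_truth",
    "emit_dataset",
    "make_block_ld",
    "write_dataset",
]

# column_map under which emitted files round-trip through read_summary_table
DEFAULT_COLUMN_MAP = {
    "snp": "SNP",
    "a1": "A1",
    "a2": "A2",
    "beta": "BETA",
    "var": "VAR",
    "frq": "FRQ",
}


@dataclass
class SyntheticScenario:
    """Ground truth for one simulated GWAS."""

    m: int
    pi_true: float
    g_true: EffectDistribution
    n_r: int
    n_s: int
    maf_model: tuple[str, tuple[float, float]] = ("uniform", (0.05, 0.5))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not (0.0 <= self.pi_true <= 1.0):
            raise ValueError("pi_true must lie in [0, 1]")
        if self.n_r < 1 or self.n_s < 1:
            raise ValueError("sample sizes must be >= 1")
        name, params = self.maf_model
        if name != "uniform":
            raise ValueError(f"unknown maf_model {name!r}")
        lo, hi = params
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("uniform maf bounds must satisfy 0 < lo < hi <= 0.5")

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "pi_true": self.pi_true,
            "g_grid": self.g_true.grid.points.tolist(),
            "g_masses": self.g_true.masses.tolist(),
            "n_r": self.n_r,
            "n_s": self.n_s,
            "maf_model": [self.maf_model[0], list(self.maf_model[1])],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        g = EffectDistribution(EffectGrid(np.array(d["g_grid"])), np.array(d["g_masses"]))
        name, params = d.get("maf_model", ["uniform", [0.05, 0.5]])
        return cls(
            m=int(d["m"]),
            pi_true=float(d["pi_true"]),
            g_true=g,
            n_r=int(d["n_r"]),
            n_s=int(d["n_s"]),
            maf_model=(name, tuple(params)),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class SyntheticDataset:
    """Emitted summary table plus the per-SNP ground truth that made it."""

    table: SummaryTable
    truth: pd.DataFrame  # snp_id, is_nonnull, beta_true
    scenario: SyntheticScenario

    def __post_init__(self) -> None:
        if len(self.truth) != self.table.m:
            raise ValueError("truth must align with the summary table")


def _stream(scenario: SyntheticScenario, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(scenario.seed, spawn_key=(key,)))


def _draw_maf(scenario: SyntheticScenario) -> np.ndarray:
    lo, hi = scenario.maf_model[1]
    f = _stream(scenario, 0).uniform(lo, hi, scenario.m)
    if np.any((f <= 0.0) | (f >= 1.0)):
        raise ValueError("maf_model produced frequencies outside (0, 1)")
    return f


def draw_variances(scenario: SyntheticScenario, return_maf: bool = False):
    """Per-SNP estimate variances from the MAF/sample-size model."""
    f = _draw_maf(scenario)
    v = (1.0 / (2.0 * f * (1.0 - f))) * (1.0 / scenario.n_r + 1.0 / scenario.n_s)
    if return_maf:
        return v, f
    return v


def draw_truth(scenario: SyntheticScenario) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (is_nonnull, beta_true): Bernoulli labels, effects from g_true."""
    rng = _stream(scenario, 1)
    nonnull = rng.random(scenario.m) < scenario.pi_true
    beta = np.zeros(scenario.m)
    n = int(nonnull.sum())
    if n:
        beta[nonnull] = rng.choice(scenario.g_true.grid.points, size=n, p=scenario.g_true.masses)
    return nonnull, beta


def emit_dataset(scenario: SyntheticScenario) -> SyntheticDataset:
    """Compose the generative layers into a parseable summary table.

    Y_j = beta_true_j + sqrt(V_j) * eps_j with standard-normal eps.  The
    effect allele column holds the derived allele, so the table is already
    oriented and needs no harmonisation.
    """
    v, f = draw_variances(scenario, return_maf=True)
    nonnull, beta = draw_truth(scenario)
    eps = _stream(scenario, 2).standard_normal(scenario.m)
    y = beta + np.sqrt(v) * eps
    ids = [f"snp{j:07d}" for j in range(scenario.m)]
    df = pd.DataFrame(
        {
            "snp_id": ids,
            "effect_allele": "A",
            "other_allele": "G",
            "beta_hat": y,
            "var_hat": v,
            "p_value": np.nan,
            "maf": f,
        }
    )
    table = SummaryTable(
        df=df,
        n_cases=scenario.n_r,
        n_controls=scenario.n_s,
        provenance=f"synthetic(seed={scenario.seed})",
    )
    truth = pd.DataFrame({"snp_id": ids, "is_nonnull": nonnull, "beta_true": beta})
    return SyntheticDataset(table=table, truth=truth, scenario=scenario)


def write_dataset(dataset: SyntheticDataset, summary_path: str | Path, truth_path: str | Path | None = None) -> None:
    """Write the summary table (and optional truth sidecar) as TSV.

    Floats are written at full repr precision, so reading the file back
    with :func:`sphmm.gwas_io.read_summary_table` under
    ``DEFAULT_COLUMN_MAP`` reproduces beta_hat and var_hat bit-exactly.
    """
    df = dataset.table.df
    out = pd.DataFrame(
        {
            "SNP": df["snp_id"],
            "A1": df["effect_allele"],
            "A2": df["other_allele"],
            "BETA": df["beta_hat"],
            "VAR": df["var_hat"],
            "FRQ": df["maf"],
        }
    )
    out.to_csv(summary_path, sep="\t", index=False, float_format="%.17g")
    if truth_path is not None:
        dataset.truth.to_csv(truth_path, sep="\t", index=False, float_format="%.17g")


def make_block_ld(
    n_blocks: int,
    block_size: int,
    within_r2: float = 0.9,
    seed: int = 0,
) -> tuple[LdTable, list[str]]:
    """Clique-structured LD fixture: full correlation within blocks, none across.

    Returns the pair table and the full ordered id list
    (``block{i}_snp{k}``); pruning at a threshold below ``within_r2``
    must retain exactly one id per block.
    """
    if n_blocks < 1 or block_size < 1:
        raise ValueError("n_blocks and block_size must be >= 1")
    if not (0.0 < within_r2 <= 1.0):
        raise ValueError("within_r2 must lie in (0, 1]")
    ids: list[str] = []
    rows_a: list[str] = []
    rows_b: list[str] = []
    for i in range(n_blocks):
        block = [f"block{i:03d}_snp{k:03d}" for k in range(block_size)]
        ids.extend(block)
        for a in range(block_size):
            for b in range(a + 1, block_size):
                rows_a.append(block[a])
                rows_b.append(block[b])
    pairs = pd.DataFrame({"snp_a": rows_a, "snp_b": rows_b, "r2": within_r2})
    return LdTable(pairs=pairs), ids
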