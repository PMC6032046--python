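"""End-to-end orchestration: read -> harmonise -> filter -> prune -> fit -> predict.

A :class:`RunConfig` holds every input path and setting; a single master
seed deterministically spawns per-stage seeds (numpy ``SeedSequence``
spawn keys: 0 = pruning, 1 = EM, 2 = bootstrap, 3 = simulation), so every
artifact on disk is reconstructible from the config and master seed
alone.  Each stage logs its SNP counts and drop reasons, and the run
manifest records seeds, counts and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import gwas_io
from .bootstrap import bootstrap_k_ci
from .core import EmConfig, SphmmFit, fit_em
from .gwas_io import LdTable, PrunedSet, SummaryTable, count_significant, ld_prune
from .prediction import PredictionConfig, predict_num_significant

__all__ = ["RunConfig", "PipelineError", "run_fit_pipeline", "run_validation", "stage_seed"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def stage_seed(master_seed: int, key: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int(np.random.SeedSequence(master_seed, spawn_key=(key,)).generate_state(1)[0])


@dataclass
class RunConfig:
    """Inputs and settings for one analysis run.

    Defaults follow common GWAS practice: pruning at r² > 0.1, genome-wide
    significance 5e-8, m* = 100,000 target SNPs, effect grid -0.3 ... 0.3
    at step 0.005, 100 bootstrap replicates.
    """

    summary_path: str
    ld_path: str
    column_map: Mapping[str, str]
    n_cases: int
    n_controls: int
    panel_path: str | None = None
    allele_map_path: str | None = None
    r2_threshold: float = 0.1
    em: EmConfig = field(default_factory=EmConfig)
    em_boot: EmConfig | None = None  # replicate refits; defaults to `em`
    p_c: float = 5e-8
    m_star: int = 100_000
    n_r_star: int | None = None
    n_s_star: int | None = None
    n_boot: int = 100
    ci_level: float = 0.95
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["column_map"] = dict(self.column_map)
        d["em"] = dict(self.em.__dict__)
        d["em_boot"] = dict(self.em_boot.__dict__) if self.em_boot else None
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def run_fit_pipeline(cfg: RunConfig) -> tuple[SphmmFit, PrunedSet, dict]:
    """Execute read -> harmonise -> panel-filter -> prune -> fit.

    Returns the fit, the pruned SNP set, and a manifest recording every
    seed, stage count and drop report.  When ``cfg.outdir`` is set the
    fit, pruned table and manifest are written there.
    """
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.seed,
        "stage_seeds": {"prune": stage_seed(cfg.seed, 0), "em": stage_seed(cfg.seed, 1)},
        "stages": {},
    }

    try:
        table, report = gwas_io.read_summary_table(
            cfg.summary_path, cfg.column_map, cfg.n_cases, cfg.n_controls
        )
    except OSError as exc:
        raise PipelineError("read_summary_table", str(exc)) from exc
    manifest["stages"]["read"] = {"n_snps": table.m, "dropped": report.to_dict()}
    log.info("stage=read n=%d dropped=%d", table.m, report.total)

    if cfg.allele_map_path is not None:
        try:
            amap = gwas_io.read_allele_map(cfg.allele_map_path)
            table, report = gwas_io.harmonize_to_derived(table, amap)
        except (OSError, ValueError) as exc:
            raise PipelineError("harmonize_to_derived", str(exc)) from exc
        manifest["stages"]["harmonize"] = {"n_snps": table.m, "dropped": report.to_dict()}
        log.info("stage=harmonize n=%d dropped=%d", table.m, report.total)

    if cfg.panel_path is not None:
        try:
            panel = gwas_io.read_panel(cfg.panel_path)
            table = gwas_io.filter_to_panel(table, panel)
        except (OSError, ValueError) as exc:
            raise PipelineError("filter_to_panel", str(exc)) from exc
        manifest["stages"]["panel_filter"] = {"n_snps": table.m}
        log.info("stage=panel_filter n=%d", table.m)

    try:
        ld = gwas_io.read_ld_table(cfg.ld_path)
        pruned = ld_prune(table, ld, cfg.r2_threshold, seed=manifest["stage_seeds"]["prune"])
    except (OSError, ValueError) as exc:
        raise PipelineError("ld_prune", str(exc)) from exc
    manifest["stages"]["prune"] = {
        "n_snps": pruned.m,
        "n_input": pruned.n_input,
        "r2_threshold": cfg.r2_threshold,
        "seed": pruned.seed,
    }
    log.info("stage=prune n=%d of %d seed=%d", pruned.m, pruned.n_input, pruned.seed)

    em_cfg = cfg.em
    if em_cfg.seed == 0:
        em_cfg = EmConfig(**{**em_cfg.__dict__, "seed": manifest["stage_seeds"]["em"]})
    fit = fit_em(pruned, em_cfg)
    manifest["stages"]["fit"] = {
        "pi_hat": fit.pi,
        "loglik": fit.loglik,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "init_label": fit.init_label,
    }
    log.info("stage=fit pi_hat=%.4f loglik=%.3f iters=%d", fit.pi, fit.loglik, fit.n_iter)

    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        fit.save(out / "fit.json")
        pruned.table.to_tsv(out / "pruned.tsv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float) + "\n")
    return fit, pruned, manifest


def run_validation(
    current_cfg: RunConfig,
    future_table: SummaryTable,
    future_ld: LdTable,
) -> dict:
    """Fit on a 'current' study, predict the 'future' one, compare observed.

    The model is fitted to the current data; m* is set to the future
    pruned-set size; K is predicted at the future sample sizes with a
    parametric-bootstrap 95% prediction interval (replicate refits plus
    count-level sampling noise, so the interval targets the count one
    would actually observe); the observed significant count in the future
    pruned set sits beside it in the report.
    """
    fit, pruned, manifest = run_fit_pipeline(current_cfg)

    future_seed = stage_seed(current_cfg.seed, 3)
    future_pruned = ld_prune(future_table, future_ld, current_cfg.r2_threshold, seed=future_seed)

    pred_cfg = PredictionConfig(
        n_r=current_cfg.n_cases,
        n_s=current_cfg.n_controls,
        n_r_star=future_table.n_cases,
        n_s_star=future_table.n_controls,
        p_c=current_cfg.p_c,
        m_star=future_pruned.m,
    )
    k_hat = predict_num_significant(fit, pruned, pred_cfg)
    boot = bootstrap_k_ci(
        fit,
        pruned,
        em_cfg=current_cfg.em_boot or current_cfg.em,
        pred_cfg=pred_cfg,
        n_boot=current_cfg.n_boot,
        level=current_cfg.ci_level,
        seed=stage_seed(current_cfg.seed, 2),
        include_count_noise=True,
    )
    observed = count_significant(future_pruned, current_cfg.p_c)
    report = {
        "manifest": manifest,
        "m_star": future_pruned.m,
        "p_c": current_cfg.p_c,
        "future_sizes": {"n_r_star": future_table.n_cases, "n_s_star": future_table.n_controls},
        "k_hat": k_hat,
        "k_ci": list(boot.k_ci),
        "ci_level": current_cfg.ci_level,
        "interval_type": "prediction",
        "observed_significant": observed,
        "observed_in_ci": bool(boot.k_ci[0] <= observed <= boot.k_ci[1]),
        "n_boot": boot.n_boot,
        "bootstrap_failures": boot.n_failed,
    }
    log.info(
        "validation: observed=%d predicted=%.2f ci=(%.2f, %.2f)",
        observed,
        k_hat,
        *boot.k_ci,
    )
    return report
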