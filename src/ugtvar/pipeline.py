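"""End-to-end wiring: read/validate -> select -> normalise -> fit -> report.

One :func:`run_pipeline` call executes the whole analysis for every
requested route x parameter combination, writing each intermediate artifact
(normalised observations, posterior draws, diagnostics, report tables,
forest-plot data) plus a manifest with SHA-256 checksums.  Inputs are never
mutated; everything lands in the configured output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dbio
from .io import Parameter, PKDatabase, Route
from .model import (
    McmcConfig,
    PosteriorDraws,
    PriorConfig,
    build_model_spec,
    run_mcmc,
)
from .simulate import make_isoform_preset, simulate_study_summaries, write_truth
from .standardize import NormalizationConfig, normalize_record
from .uf import VariabilitySummary, build_report_table, format_report_text, summarize_variability

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "export_forest_data",
    "load_model_config",
]

logger = logging.getLogger("ugtvar")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; exactly one input source."""

    out_dir: Path
    input_path: Path | None = None
    preset: str | None = None
    norm_config: NormalizationConfig = field(default_factory=NormalizationConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    chains: int = 4
    warmup_draws: int = 1000
    kept_draws: int = 2500
    substrates: list[str] | None = None
    routes: list[Route] = field(default_factory=lambda: [Route.ORAL, Route.IV])
    parameters: list[Parameter] = field(
        default_factory=lambda: [Parameter.AUC, Parameter.CLEARANCE, Parameter.CMAX]
    )
    percentiles: tuple[float, float] = (95.0, 97.5)
    include_patients: bool = False
    include_repeated: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("provide exactly one of input_path or preset")
        for p in self.percentiles:
            if not 50.0 < p < 100.0:
                raise ValueError("percentiles must lie in (50, 100)")


def load_model_config(path: str | Path) -> tuple[PriorConfig, dict]:
    """Read prior and MCMC settings from a YAML file.

    Keys: ``priors`` (mu_prior, sigma_ind_scale, sigma_study_scale,
    hyper_m_prior, hyper_s_scale, informative_overrides) and ``mcmc``
    (chains, warmup_draws, kept_draws, rhat_threshold, min_ess).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pk = dict(raw.get("priors", {}))
    if "mu_prior" in pk:
        pk["mu_prior"] = tuple(pk["mu_prior"])
    if "hyper_m_prior" in pk:
        pk["hyper_m_prior"] = tuple(pk["hyper_m_prior"])
    if "informative_overrides" in pk:
        pk["informative_overrides"] = {
            str(k): tuple(v) for k, v in pk["informative_overrides"].items()
        }
    return PriorConfig(**pk), dict(raw.get("mcmc", {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _combo_seeds(master: int, n: int) -> list[int]:
    # stable derived seeds, kept below 2**31
    state = np.random.SeedSequence(master).generate_state(2 * n)
    return [int(s % (2**31)) for s in state[:n]]


def export_forest_data(summaries: list[VariabilitySummary]) -> pd.DataFrame:
    """Point estimates and 95% bounds for GM, CV and UFs, one row per scope.

    Column layout is the data behind a forest plot; ordering is stable
    (sorted by scope, route, parameter) regardless of input order.
    """
    if not summaries:
        raise ValueError("no summaries to export")
    rows = []
    for s in sorted(summaries, key=lambda s: (s.scope, s.route.value, s.parameter.value)):
        row: dict = {"scope": s.scope, "route": s.route.value, "parameter": s.parameter.value,
                     "nst": s.nst, "n": s.n_total}
        for name, iv in (("gm", s.gm), ("cv", s.cv), ("uf95", s.uf95), ("uf975", s.uf975)):
            row[f"{name}_median"] = None if iv is None else iv.median
            row[f"{name}_low95"] = None if iv is None else iv.low95
            row[f"{name}_high95"] = None if iv is None else iv.high95
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; return the artifact manifest (also written).

    The manifest lists every artifact with its checksum, the seeds used, and
    whether every fit passed convergence diagnostics.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict] = {}
    manifest: dict = {"seed": cfg.seed, "artifacts": artifacts, "stages": []}

    def register(kind: str, path: Path) -> None:
        artifacts[path.name] = {"kind": kind, "path": str(path), "sha256": _sha256(path)}

    # ---- load ----
    if cfg.preset is not None:
        scenario = make_isoform_preset(cfg.preset, seed=cfg.seed)
        db, truth = simulate_study_summaries(scenario)
        db_path = out / "database.csv"
        dbio.write_pk_database(db, db_path)
        write_truth(truth, out / "truth.json")
        register("input_database", db_path)
        register("ground_truth", out / "truth.json")
    else:
        db = dbio.read_pk_database(cfg.input_path)
    logger.info("loaded %d records (seed=%d)", len(db), cfg.seed)
    manifest["stages"].append({"stage": "read", "records": len(db)})

    # ---- validate ----
    violations = dbio.validate_records(db)
    if violations:
        raise ValueError(
            "validation failed: " + "; ".join(str(v) for v in violations[:10])
        )
    manifest["stages"].append({"stage": "validate", "violations": 0})

    # ---- per-combination analysis ----
    combos = [
        (r, p)
        for r in cfg.routes
        for p in cfg.parameters
        if any(rec.route is r and rec.parameter is p for rec in db)
    ]
    if not combos:
        raise ValueError("no records after filtering: nothing to analyse")
    seeds = _combo_seeds(cfg.seed, len(combos))
    all_summaries: list[VariabilitySummary] = []
    all_normalized: list[dict] = []
    diagnostics_ok = True

    for (route, parameter), combo_seed in zip(combos, seeds):
        substrates = cfg.substrates or sorted(
            {r.substrate_id for r in db if r.route is route and r.parameter is parameter}
        )
        selected_records = []
        counts: dict[str, tuple[int, int]] = {}
        for sub in substrates:
            sel = dbio.select_analysis_set(
                db, sub, route, parameter,
                include_patients=cfg.include_patients,
                include_repeated=cfg.include_repeated,
            )
            if sel.records:
                counts[sub] = (len(sel.records), sum(r.n_subjects for r in sel.records))
                selected_records.extend(sel.records)
        if not selected_records:
            raise ValueError(
                f"no records after filtering for {route.value} {parameter.value}"
            )
        observations = [normalize_record(r, cfg.norm_config) for r in selected_records]
        for o in observations:
            all_normalized.append(
                {
                    "substrate_id": o.substrate_id,
                    "route": o.route.value,
                    "parameter": o.parameter.value,
                    "n_subjects": o.n_subjects,
                    "ln_gm": o.ln_gm,
                    "ln_gsd": o.ln_gsd,
                    "source_study_id": o.source_study_id,
                }
            )
        spec = build_model_spec(observations, cfg.priors)
        mcmc_cfg = McmcConfig(
            chains=cfg.chains,
            warmup_draws=cfg.warmup_draws,
            kept_draws=cfg.kept_draws,
            seed=combo_seed,
        )
        logger.info(
            "fitting %s %s: %d substrates, %d studies, combo seed %d",
            route.value, parameter.value, spec.n_substrates, len(observations), combo_seed,
        )
        draws = run_mcmc(spec, mcmc_cfg)
        diagnostics_ok &= bool(draws.converged)
        tag = f"{route.value}_{parameter.value}"

        posterior_path = out / f"posterior_{tag}.csv"
        draws.to_long_dataframe().to_csv(posterior_path, index=False)
        register("posterior", posterior_path)
        diag_path = out / f"diagnostics_{tag}.json"
        diag_path.write_text(json.dumps(draws.diagnostics.to_dict(), indent=2))
        register("diagnostics", diag_path)

        rng = np.random.default_rng(np.random.SeedSequence(combo_seed, spawn_key=(1000,)))
        summaries = [
            summarize_variability(
                draws, sub, counts[sub], route=route, parameter=parameter,
                percentiles=cfg.percentiles,
            )
            for sub in spec.substrate_ids
        ]
        total = (sum(c[0] for c in counts.values()), sum(c[1] for c in counts.values()))
        summaries.append(
            summarize_variability(
                draws, "overall", total, route=route, parameter=parameter,
                rng=rng, percentiles=cfg.percentiles,
            )
        )
        table = build_report_table(summaries)
        report_path = out / f"report_{tag}.csv"
        table.to_csv(report_path, index=False)
        register("report_table", report_path)
        text_path = out / f"report_{tag}.txt"
        text_path.write_text(format_report_text(table))
        register("report_text", text_path)
        all_summaries.extend(summaries)
        manifest["stages"].append(
            {
                "stage": f"fit_{tag}",
                "seed": combo_seed,
                "observations": len(observations),
                "converged": bool(draws.converged),
            }
        )

    norm_path = out / "normalized_observations.csv"
    pd.DataFrame(all_normalized).to_csv(norm_path, index=False)
    register("normalized_observations", norm_path)

    forest_path = out / "forest.csv"
    export_forest_data(all_summaries).to_csv(forest_path, index=False, float_format="%.6g")
    register("forest_data", forest_path)

    manifest["diagnostics_ok"] = diagnostics_ok
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
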