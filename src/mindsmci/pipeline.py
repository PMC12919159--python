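"""End-to-end pipeline: simulate -> preprocess -> subtype -> survival ->
effects -> report, with deterministic stage seeding and a run manifest.

Every stage writes plain CSV/JSON artifacts into the output directory and
records an entry (inputs, outputs, content hashes, seed, wall time) in
``manifest.json``; identical config + seed reproduces identical hashes.
The global seed is split into per-stage seeds by fixed offsets so stages
can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .causal import TreatmentEffectModel
from .minds import MindsConfig, MindsModel, select_k
from .preprocess import standardize_continuous
from .simulate import (
    BINARY_COLUMNS,
    CONTINUOUS_COLUMNS,
    TREATMENT_COLUMNS,
    GeneratorConfig,
    generate_cohort,
)
from .survival import cox_fit, hr_table, km_estimate, main_effects_spec

__all__ = ["PipelineConfig", "run_pipeline", "report"]

_STAGE_OFFSETS = {
    "simulate": 11,
    "preprocess": 23,
    "subtype": 37,
    "survival": 53,
    "effects": 71,
    "report": 89,
}


@dataclass
class PipelineConfig:
    """Configuration of a full run."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: list = field(
        default_factory=lambda: ["simulate", "preprocess", "subtype", "survival", "effects", "report"]
    )
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    minds: MindsConfig = field(default_factory=MindsConfig)
    k_range: list | None = None  # e.g. [3, 4, 5, 6] to scan; None fits minds.n_clusters
    tau: float = 48.0
    dml_learners: str = "default"
    dml_folds: int = 5
    use_true_subtypes_downstream: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        gen = GeneratorConfig.from_dict(d.pop("generator", {}))
        minds = MindsConfig(**d.pop("minds", {}))
        return cls(generator=gen, minds=minds, **d)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 101 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; return the manifest dict.

    A stage failure aborts the run with the failing stage named; artifacts
    written so far stay on disk next to a ``FAILED`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": []}
    ctx: dict = {}
    for stage in config.stages:
        t0 = time.time()
        try:
            outputs = _STAGE_FNS[stage](config, ctx, out)
        except Exception as err:
            (out / "FAILED").write_text(f"stage {stage}: {err}\n")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": config.stage_seed(stage),
                "outputs": {p.name: _sha(p) for p in outputs},
                "rows": ctx.get("n_rows"),
                "wall_seconds": round(time.time() - t0, 3),
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _stage_simulate(config, ctx, out):
    gen = dataclasses.replace(config.generator, seed=config.stage_seed("simulate"))
    cohort, truth = generate_cohort(gen)
    ctx["cohort"], ctx["truth"] = cohort, truth
    ctx["n_rows"] = len(cohort)
    cohort.to_csv(out / "cohort.csv", index=False)
    truth.to_json(out / "truth.json")
    return [out / "cohort.csv", out / "truth.json"]


def _stage_preprocess(config, ctx, out):
    cohort = ctx.get("cohort")
    if cohort is None:
        cohort = pd.read_csv(out / "cohort.csv")
    std, params = standardize_continuous(cohort)
    ctx["analytic"] = std
    ctx["n_rows"] = len(std)
    std.to_csv(out / "analytic_cohort.csv", index=False)
    return [out / "analytic_cohort.csv"]


def _stage_subtype(config, ctx, out):
    data = ctx["analytic"]
    mc = dataclasses.replace(config.minds, seed=config.stage_seed("subtype"))
    if config.k_range:
        best_k, table, fits = select_k(
            data[BINARY_COLUMNS], data[CONTINUOUS_COLUMNS], config.k_range, mc
        )
        fit = fits[best_k]
        table.to_csv(out / "ic_table.csv", index=False)
    else:
        fit = MindsModel(data[BINARY_COLUMNS], data[CONTINUOUS_COLUMNS], mc).fit()
        pd.DataFrame(
            {"K": [mc.n_clusters], "IC": [fit.information_criterion()]}
        ).to_csv(out / "ic_table.csv", index=False)
    ctx["fit"] = fit
    assignments = pd.DataFrame(
        {"subject_id": data["subject_id"], "subtype": fit.map_assignments}
    )
    ctx["assignments"] = assignments
    assignments.to_csv(out / "assignments.csv", index=False)
    loadings, _ = fit.loading_summary()
    loadings.to_csv(out / "loading_matrix.csv")
    pd.DataFrame({"iteration": np.arange(len(fit.ll_trace)), "loglik": fit.ll_trace}).to_csv(
        out / "trace.csv", index=False
    )
    with open(out / "fit_summary.json", "w") as fh:
        json.dump(
            {
                "n_clusters": fit.config.n_clusters,
                "ic": fit.information_criterion(),
                "mixing_weights": fit.mixing_mean.tolist(),
                "cluster_sizes": np.bincount(
                    fit.map_assignments - 1, minlength=fit.config.n_clusters
                ).tolist(),
            },
            fh,
            indent=1,
        )
    ctx["n_rows"] = len(assignments)
    return [out / p for p in ("ic_table.csv", "assignments.csv", "loading_matrix.csv", "trace.csv", "fit_summary.json")]


def _subtype_column(config, ctx):
    data = ctx["analytic"].copy()
    if config.use_true_subtypes_downstream or "assignments" not in ctx:
        data["subtype"] = data["true_subtype"]
    else:
        data["subtype"] = ctx["assignments"]["subtype"].to_numpy()
    return data


def _stage_survival(config, ctx, out):
    data = _subtype_column(config, ctx)
    curves = km_estimate(
        data["observed_time_months"], data["event_indicator"], data["subtype"]
    )
    pd.concat([c.as_frame() for c in curves.values()]).to_csv(out / "km_curves.csv", index=False)
    spec = main_effects_spec(subtype_col="subtype")
    result = cox_fit(data, spec)
    ctx["cox"] = result
    result.table.to_csv(out / "cox_table.csv")
    hr_table(result).to_csv(out / "cox_report.csv", index=False)
    ctx["n_rows"] = len(data)
    return [out / "km_curves.csv", out / "cox_table.csv", out / "cox_report.csv"]


def _stage_effects(config, ctx, out):
    data = _subtype_column(config, ctx)
    rows = []
    ctx["effects"] = {}
    for trt in TREATMENT_COLUMNS:
        model = TreatmentEffectModel(
            data,
            trt,
            subtype_col="subtype",
            tau=config.tau,
            learners=config.dml_learners,
            n_folds=config.dml_folds,
        )
        res = model.fit(seed=config.stage_seed("effects"))
        ctx["effects"][trt] = res
        lo, hi = res.time_ratio_conf_int
        rows.append(
            {
                "treatment": trt,
                "group": "overall",
                "theta": res.theta,
                "se": res.se,
                "time_ratio": res.time_ratio,
                "tr_ci_low": lo,
                "tr_ci_high": hi,
            }
        )
        for k, g in res.gates.iterrows():
            rows.append(
                {
                    "treatment": trt,
                    "group": f"subtype_{k}",
                    "theta": g["theta"],
                    "se": g["se"],
                    "time_ratio": g["time_ratio"],
                    "tr_ci_low": g["tr_ci_low"],
                    "tr_ci_high": g["tr_ci_high"],
                }
            )
    effects = pd.DataFrame(rows)
    ctx["effects_table"] = effects
    effects.to_csv(out / "effects_table.csv", index=False)
    ctx["n_rows"] = len(effects)
    return [out / "effects_table.csv"]


def _stage_report(config, ctx, out):
    return report(config, ctx, out)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "subtype": _stage_subtype,
    "survival": _stage_survival,
    "effects": _stage_effects,
    "report": _stage_report,
}


def report(config, ctx, out):
    """Summary JSON + markdown: subtype characterization, Cox table, effects
    table, loading matrix, and truth-vs-estimate recovery deltas when the
    generator truth is available."""
    out = Path(out)
    summary: dict = {"seed": config.seed}
    lines = ["# Pipeline run summary", ""]
    if "fit" in ctx:
        fit = ctx["fit"]
        summary["n_clusters"] = fit.config.n_clusters
        summary["ic"] = fit.information_criterion()
        lines += [f"Selected clusters: {fit.config.n_clusters} (IC {summary['ic']:.1f})", ""]
    if "cox" in ctx:
        hrs = ctx["cox"].subtype_hazard_ratios()
        summary["subtype_hazard_ratios"] = hrs["hr"].to_dict()
        lines += ["## Subtype hazard ratios", hrs.to_string(), ""]
    if "effects_table" in ctx:
        summary["effects"] = ctx["effects_table"].to_dict(orient="records")
        lines += ["## Treatment effects (geometric-mean time ratios)", ctx["effects_table"].to_string(index=False), ""]
    truth = ctx.get("truth")
    if truth is not None:
        recovery = {}
        if "cox" in ctx:
            est = ctx["cox"].subtype_hazard_ratios()["hr"].to_numpy()
            tru = truth.subtype_hazard_ratios[1:]
            m = min(len(est), len(tru))
            recovery["subtype_hr_delta"] = (est[:m] - tru[:m]).tolist()
        if "effects" in ctx:
            deltas = {}
            for c, trt in enumerate(TREATMENT_COLUMNS):
                if trt in ctx["effects"]:
                    res = ctx["effects"][trt]
                    gates = res.gates["time_ratio"].to_numpy()
                    tru = truth.time_ratios[c][: len(gates)]
                    deltas[trt] = (gates - tru).tolist()
            recovery["gate_time_ratio_delta"] = deltas
        summary["recovery"] = recovery
        lines += ["## Recovery vs generator truth", json.dumps(recovery, indent=1), ""]
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    (out / "report.md").write_text("\n".join(lines))
    return [out / "report.json", out / "report.md"]
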