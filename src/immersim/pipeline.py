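"""Orchestration: simulate -> metrics -> synthesize -> stats -> mediate -> predict.

Each stage reads the previous stage's CSV/JSON artifacts from the output
directory and writes its own, so a run is fully reproducible from
(config, seed) and any stage can be rerun in isolation.  A single global
seed is expanded into per-stage child seeds through a fixed
``numpy.random.SeedSequence`` spawn order (simulate, synthesize, mediate,
predict), so changing one stage's inputs never perturbs another stage's
randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import signal_metrics as sm
from . import synthetic_data as sd
from . import tabular_synthesis as ts
from . import stats_battery as sb
from . import mediation as med
from . import purchase_prediction as pp

log = logging.getLogger("immersim")

STAGES = ("simulate", "metrics", "synthesize", "stats", "mediate", "predict")


@dataclass
class PipelineConfig:
    out_dir: str = "immersim_run"
    seed: int = sd.DEFAULT_SEED
    n_ws: int = 31
    n_ms: int = 25
    n_synthetic: int = 10000
    visit_order: list[str] | None = None
    mediation_covariates: list[str] = field(default_factory=list)
    mediation_bootstrap_reps: int = 5000
    prediction_features: list[str] = field(default_factory=lambda: list(pp.DEFAULT_FEATURES))
    n_folds: int = 5
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    store_profiles: list[dict] | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def profiles(self) -> list[sd.StoreProfile]:
        if self.store_profiles is not None:
            return sd.profiles_from_dict(self.store_profiles)
        return sd.default_store_profiles(self.n_ws, self.n_ms)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _child_seeds(seed: int) -> dict[str, int]:
    names = ("simulate", "synthesize", "mediate", "predict")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seconds: dict[str, float]
    outputs: dict[str, str]
    package_version: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order; returns the run manifest."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}

    def record(name: str, path: Path) -> None:
        outputs[name] = str(path)

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, timings[name])

    sessions_csv = out / "sessions.csv"
    traces_csv = out / "traces.csv"
    metrics_csv = out / "metrics.csv"
    synthetic_csv = out / "synthetic.csv"

    if stage_enabled("simulate"):
        def _simulate():
            table, traces = sd.generate_cohort(config.profiles(), seeds["simulate"])
            table.to_csv(sessions_csv, index=False, float_format="%.10g")
            sm.write_traces_csv(traces, traces_csv)
            log.info("simulated %d sessions (%d traces)", len(table), len(traces))
            record("sessions", sessions_csv)
            record("traces", traces_csv)
        run_stage("simulate", _simulate)

    if stage_enabled("metrics"):
        def _metrics():
            traces = sm.read_traces_csv(traces_csv)
            m = sm.metrics_table(traces)
            m.to_csv(metrics_csv, index=False, float_format="%.10g")
            record("metrics", metrics_csv)
        run_stage("metrics", _metrics)

    def _joined() -> pd.DataFrame:
        sessions = pd.read_csv(sessions_csv)
        metrics = pd.read_csv(metrics_csv)
        return sessions.merge(metrics, on="session_id")

    if stage_enabled("synthesize"):
        def _synthesize():
            df = _joined()
            synth = ts.synthesize_by_store(
                ts.add_incidence(df), config.n_synthetic, seeds["synthesize"],
                visit_order=config.visit_order,
            )
            synth.to_csv(synthetic_csv, index=False, float_format="%.10g")
            fid = {}
            obs = ts.add_incidence(df)
            for store in obs["store"].unique():
                rep = ts.fidelity_report(
                    obs[obs["store"] == store], synth[synth["store"] == store],
                    columns=[c for c in ts.DEFAULT_VISIT_ORDER if c in synth.columns],
                )
                fid[store] = rep.to_dict()
            with open(out / "fidelity.json", "w") as fh:
                json.dump(fid, fh, indent=2)
            record("synthetic", synthetic_csv)
            record("fidelity", out / "fidelity.json")
        run_stage("synthesize", _synthesize)

    if stage_enabled("stats"):
        def _stats():
            df = _joined()
            rows = []
            store_order = [s for s in ("WS", "MS") if s in set(df["store"])] or sorted(
                df["store"].unique()
            )
            for var in ("dwell_min", "purchase_usd", "avg_immersion", "peak_immersion"):
                for store in store_order:
                    g = df[df["store"] == store]
                    rows.append({
                        "label": var, "group": store, "n": len(g),
                        "mean": g[var].mean(), "sd": g[var].std(ddof=1),
                    })
            results = sb.summary_battery(pd.DataFrame(rows))
            results.to_csv(out / "tests.csv", index=False, float_format="%.10g")
            record("tests", out / "tests.csv")
        run_stage("stats", _stats)

    if stage_enabled("mediate"):
        def _mediate():
            source = synthetic_csv if synthetic_csv.exists() and "synthesize" in config.stages else None
            if source is not None:
                df = pd.read_csv(source)
            else:
                df = _joined()
                log.warning(
                    "mediation running on the small observed-scale cohort (n=%d); "
                    "path estimates will be low-powered", len(df),
                )
            for store, g in df.groupby("store"):
                spec = med.MediationSpec(
                    covariates=tuple(config.mediation_covariates),
                    bootstrap_reps=config.mediation_bootstrap_reps,
                    rng_seed=seeds["mediate"],
                )
                res = med.fit_mediation(g, spec)
                path = out / f"mediation_{store}.json"
                with open(path, "w") as fh:
                    json.dump(res.to_dict(), fh, indent=2)
                record(f"mediation_{store}", path)
        run_stage("mediate", _mediate)

    if stage_enabled("predict"):
        def _predict():
            source = synthetic_csv if synthetic_csv.exists() and "synthesize" in config.stages else None
            df = pd.read_csv(source) if source is not None else _joined()
            df = pp.discretize_purchase(df) if "purchased" not in df.columns else df
            spec = pp.PredictionSpec(
                features=tuple(config.prediction_features),
                n_folds=config.n_folds,
                rng_seed=seeds["predict"],
            )
            reports = {}
            for store, g in df.groupby("store"):
                reports[store] = pp.tune_and_evaluate(g, spec).to_dict()
            with open(out / "prediction_report.json", "w") as fh:
                json.dump(reports, fh, indent=2)
            record("prediction_report", out / "prediction_report.json")
        run_stage("predict", _predict)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        stage_seconds=timings,
        outputs=outputs,
        package_version=__version__,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def summarize_results(manifest: RunManifest) -> str:
    """Human-readable markdown report of a pipeline run."""
    lines = [
        "# immersim run report",
        f"config hash: {manifest.config_hash}",
        f"seed: {manifest.seed}",
        "",
    ]
    for name, path in manifest.outputs.items():
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"missing artifact: {path}")
        lines.append(f"- {name}: {path}")
    tests = manifest.outputs.get("tests")
    if tests:
        df = pd.read_csv(tests)
        lines += ["", "## Store comparisons (pooled t)", df.to_markdown(index=False)]
    for store in ("WS", "MS"):
        key = f"mediation_{store}"
        if key in manifest.outputs:
            with open(manifest.outputs[key]) as fh:
                r = json.load(fh)
            lines += [
                "",
                f"## Mediation ({store}, n={r['n']})",
                f"a (peak->dwell): {r['a_path']['estimate']:.4g} (p={r['a_path']['p_value']:.3g})",
                f"b (dwell->purchase): {r['b_path']['estimate']:.4g} (p={r['b_path']['p_value']:.3g})",
                f"direct c': {r['c_prime']['estimate']:.4g} (p={r['c_prime']['p_value']:.3g})",
                f"indirect a*b: {r['indirect']['estimate']:.4g} "
                f"[{r['indirect']['ci_low']:.4g}, {r['indirect']['ci_high']:.4g}]",
            ]
    pred = manifest.outputs.get("prediction_report")
    if pred:
        with open(pred) as fh:
            rep = json.load(fh)
        lines += ["", "## Purchase prediction (pooled CV)"]
        for store, r in rep.items():
            p = r["pooled"]
            lines.append(
                f"{store}: acc {p['accuracy']:.3f}, sens {p['sensitivity']:.3f}, "
                f"spec {p['specificity']:.3f}, AUC {p['auc']:.3f}, MSE {p['mse']:.4f}"
            )
    return "\n".join(lines) + "\n"
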