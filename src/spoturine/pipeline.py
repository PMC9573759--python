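"""End-to-end orchestration: simulate → QC → split → fit → estimate → validate.

Each stage is also runnable standalone (see :mod:`spoturine.cli`) on the
canonical delimited-text schema, consuming the previous stage's artifacts.
``run_pipeline`` executes the whole chain and writes every artifact at the
end in one pass, so a crashing stage leaves either a complete output
directory or a partial one with a ``FAILED`` marker; all randomness flows
from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import estimators, model_fit, specimen_qc, synthetic_data, validation
from .estimators import EstimatorId

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; partial artifacts are preserved."""


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of ``input_path``/``synthetic``."""

    input_path: str | None = None
    synthetic: synthetic_data.SyntheticParams | None = None
    qc: specimen_qc.QcConfig = field(default_factory=specimen_qc.QcConfig)
    train_fraction: float = 0.7
    seed: int = 0
    stepwise: bool = False
    entry_p: float = 0.05
    stay_p: float = 0.10
    estimators: tuple[str, ...] = ("new", "kawasaki", "intersalt", "tanaka")
    reference: str = "new"
    out_dir: str = "spoturine_run"

    def __post_init__(self):
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("configure exactly one input source "
                             "(input_path or synthetic)")
        known = {e.value for e in EstimatorId}
        bad = [e for e in self.estimators if e not in known]
        if bad:
            raise ValueError(f"unknown estimator name(s): {bad}")
        if self.reference not in known:
            raise ValueError(f"unknown reference estimator {self.reference!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, default=lambda o: str(o)))

    def digest(self) -> str:
        # the hash identifies the analysis, not where it is written
        d = self.to_dict()
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path, seed: int | None = None, out_dir: str | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file, with CLI overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = raw.get("synthetic")
    kwargs = dict(
        input_path=raw.get("input_path"),
        synthetic=synthetic_data.SyntheticParams(**syn) if syn is not None else None,
        train_fraction=raw.get("train_fraction", 0.7),
        seed=raw.get("seed", 0),
        stepwise=raw.get("stepwise", False),
        entry_p=raw.get("entry_p", 0.05),
        stay_p=raw.get("stay_p", 0.10),
        estimators=tuple(raw.get("estimators",
                                 ("new", "kawasaki", "intersalt", "tanaka"))),
        reference=raw.get("reference", "new"),
        out_dir=raw.get("out_dir", "spoturine_run"),
    )
    if raw.get("qc"):
        qc = dict(raw["qc"])
        for key in ("cr24_bounds_female", "cr24_bounds_male"):
            if key in qc:
                qc[key] = tuple(qc[key])
        kwargs["qc"] = specimen_qc.QcConfig(**qc)
    if seed is not None:
        kwargs["seed"] = seed
    if out_dir is not None:
        kwargs["out_dir"] = out_dir
    return RunConfig(**kwargs)


def _methods_for(config: RunConfig) -> dict:
    wanted = [EstimatorId(e) for e in config.estimators]
    return {
        "na": [m for m in validation._METHODS_BY_ANALYTE["na"] if m in wanted],
        "k": [m for m in validation._METHODS_BY_ANALYTE["k"] if m in wanted],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; write artifacts; return them in memory too.

    Artifacts: cohort (if simulated), QC report and summary, train/test
    manifests, fitted-model coefficient tables, per-record estimates, the
    validation summary with its long-format cutoff table, Bland–Altman
    plotting pairs per (analyte, formula), and a run log carrying the seed
    and a config hash.  On a stage failure whatever was produced is written
    alongside a ``FAILED`` marker and :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {}
    log: list[str] = [f"config_hash: {config.digest()}", f"seed: {config.seed}"]
    stage = "load"
    try:
        if config.synthetic is not None:
            cohort = synthetic_data.generate_cohort(config.synthetic,
                                                    seed=config.seed)
            records = cohort.records
            artifacts["cohort.csv"] = records
            artifacts["cohort_provenance.json"] = cohort.provenance()
            log.append(f"simulated n={len(records)} "
                       f"residual_sd={ {k: round(v, 3) for k, v in cohort.residual_sd.items()} }")
        else:
            records = estimators.read_cohort(config.input_path)
            log.append(f"loaded {config.input_path} n={len(records)}")

        stage = "qc"
        report = specimen_qc.apply_exclusions(records, config.qc)
        artifacts["qc_report.csv"] = report.to_frame()
        artifacts["qc_summary.txt"] = report.summary()
        flow = specimen_qc.flowchart_counts(report)
        log.append(f"qc kept {flow['kept']}/{flow['initial']} ({flow['kept_pct']}%)")

        stage = "split"
        train, test = model_fit.split_train_test(report.kept,
                                                 config.train_fraction,
                                                 seed=config.seed)
        artifacts["train.csv"] = train
        artifacts["test.csv"] = test
        log.append(f"split train={len(train)} test={len(test)}")

        stage = "fit"
        models = model_fit.fit_paper_models(train, stepwise=config.stepwise,
                                            entry_p=config.entry_p,
                                            stay_p=config.stay_p)
        artifacts["models.csv"] = model_fit.models_to_frame(models)
        artifacts["models.txt"] = "\n\n".join(m.to_text() for m in models.values())
        log.append(f"fitted {len(models)} models")

        stage = "estimate"
        wanted = [EstimatorId(e) for e in config.estimators]
        est_df = estimators.estimate_batch(test, methods=wanted)
        artifacts["estimates.csv"] = est_df
        log.append(f"estimated {len(est_df)} test records "
                   f"with {[e.value for e in wanted]}")

        stage = "validate"
        metrics = validation.validate_all(test,
                                          reference=EstimatorId(config.reference),
                                          methods_by_analyte=_methods_for(config))
        artifacts["validation.csv"] = validation.metrics_to_frame(metrics)
        artifacts["cutoffs.csv"] = validation.cutoffs_to_frame(metrics)
        for m in metrics:
            col = f"est_{m.analyte}_{m.method}"
            meas_col = "u24_na_mmol" if m.analyte == "na" else "u24_k_mmol"
            pair = est_df[[meas_col, col]].dropna()
            series = validation.PairedSeries(pair[meas_col], pair[col],
                                             method=m.method, analyte=m.analyte)
            _, _, _, ba = validation.bland_altman(series)
            artifacts[f"bland_altman_{m.analyte}_{m.method}.csv"] = ba
        log.append(f"validated {len(metrics)} (analyte, formula) rows")
    except Exception as exc:
        log.append(f"FAILED at stage {stage}: {exc}")
        artifacts["FAILED"] = f"stage {stage}: {exc}"
        artifacts["run.log"] = "\n".join(log)
        _write_artifacts(out, artifacts)
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    artifacts["run.log"] = "\n".join(log)
    artifacts["config_used.yaml"] = yaml.safe_dump(config.to_dict(),
                                                   sort_keys=True)
    _write_artifacts(out, artifacts)
    return artifacts


def _write_artifacts(out: Path, artifacts: dict) -> None:
    for name, obj in artifacts.items():
        path = out / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
        elif isinstance(obj, dict):
            path.write_text(json.dumps(obj, indent=2))
        else:
            path.write_text(str(obj))
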