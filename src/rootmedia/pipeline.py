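"""End-to-end reproduction pipeline.

Runs the whole study workflow from the packaged treatment tables: verify the
salt→ion stoichiometry, expand replicate datasets, train one surrogate per
response, run the sensitivity analysis and the GA optimization, and write
the fit-statistics / importance-rank / optimal-medium tables plus
observed-vs-predicted scatter data.  Every stage is seeded from the single
pipeline seed and recorded in a run manifest with file checksums, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ann, ga, media, sensitivity
from .media import ION_ORDER
from .modeling import DatasetBundle, prepare_dataset, train_response_model
from .synth import RESPONSES, SplitSpec, treatments_from_reference

__all__ = ["PipelineConfig", "RunManifest", "reproduce", "export_scatter"]

log = logging.getLogger("rootmedia")


@dataclass
class PipelineConfig:
    """Everything a full reproduction run needs."""

    seed: int = 0
    responses: list[str] = field(default_factory=lambda: list(RESPONSES))
    n_reps: int = 6
    n_train: int = 130
    n_test: int = 86
    cl_convention: str = "per_salt"
    sensitivity_mode: str = "hold_at_mean"
    table9_path: str | None = None  # None -> packaged fixture
    table6_path: str | None = None
    output_dir: str = "results/pipeline"
    training: ann.TrainingConfig = field(default_factory=ann.TrainingConfig)
    ga: ga.GAConfig = field(default_factory=ga.GAConfig)

    def __post_init__(self) -> None:
        unknown = set(self.responses) - set(RESPONSES)
        if unknown:
            raise ValueError(f"unknown response(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("training"), dict):
            d["training"] = ann.TrainingConfig(**d["training"])
        if isinstance(d.get("ga"), dict):
            d["ga"] = ga.GAConfig(**d["ga"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        """Digest of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def response_seed(base_seed: int, response: str) -> int:
    """Stable per-response sub-seed (< 2**31)."""
    idx = list(RESPONSES).index(response)
    return (base_seed * 97 + idx * 1009) % (2**31 - 1)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict[str, float]  # stage -> wall seconds
    files: dict[str, str]  # relative path -> sha256
    responses: dict[str, dict]  # response -> output file references

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def export_scatter(model: ann.ResponseModel, partition_rows: pd.DataFrame) -> dict:
    """Observed-vs-predicted pairs plus the fitted simple regression line.

    ``partition_rows`` are original-scale replicate rows (ion columns +
    ``value``).  Returns the pair table and least-squares slope/intercept/R²
    of predicted on observed.
    """
    if len(partition_rows) == 0:
        raise ValueError("empty partition")
    X = partition_rows[list(ION_ORDER)].to_numpy()
    observed = partition_rows["value"].to_numpy()
    predicted = model.predict(X)
    slope, intercept = np.polyfit(observed, predicted, 1)
    return {
        "table": pd.DataFrame({"observed": observed, "predicted": predicted}),
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": ann.r_squared(observed, predicted),
    }


def reproduce(config: PipelineConfig) -> RunManifest:
    """Run every stage and write all outputs under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    files: dict[str, str] = {}
    responses: dict[str, dict] = {}

    def _record(path: Path) -> str:
        rel = str(path.relative_to(out))
        files[rel] = _sha256(path)
        return rel

    def _stage(name: str, t0: float) -> None:
        stages[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %-18s %6.2fs", name, stages[name])

    stage_name = "media_verification"
    try:
        t0 = time.perf_counter()
        formulations = media.load_formulations(config.table9_path)
        reference = media.reference_ion_profiles(config.table6_path)
        report = media.verify_against_reference(
            formulations, reference, tol=0.02, cl_convention=config.cl_convention
        )
        ions_csv = out / "ion_profiles.csv"
        media.ion_table(formulations, cl_convention=config.cl_convention).to_csv(
            ions_csv, index=False
        )
        report.to_json(out / "stoichiometry_check.json")
        _record(ions_csv)
        _record(out / "stoichiometry_check.json")
        _stage(stage_name, t0)

        table = media.load_reference_table(config.table6_path)
        treatments = treatments_from_reference(table, n_reps=config.n_reps)

        fit_rows, sens_reports, opt_rows = [], [], []
        bounds = ga.SearchBounds.from_reference()
        for resp in config.responses:
            stage_name = f"model_{resp}"
            t0 = time.perf_counter()
            rseed = response_seed(config.seed, resp)
            bundle = prepare_dataset(
                resp,
                treatments,
                seed=rseed,
                split_spec=SplitSpec(config.n_train, config.n_test, seed=rseed + 1),
            )
            tconf = dataclasses.replace(config.training, seed=rseed + 2)
            model, fit = train_response_model(bundle, tconf)
            slug = RESPONSES[resp][0]
            refs: dict[str, str] = {}

            bundle.rows.to_csv(out / f"replicates_{slug}.csv", index=False)
            refs["replicates"] = _record(out / f"replicates_{slug}.csv")
            model.save(out / f"model_{slug}.json")
            refs["model"] = _record(out / f"model_{slug}.json")
            fit.save(out / f"fit_{slug}.json")
            refs["fit_report"] = _record(out / f"fit_{slug}.json")
            for part in ("train", "test"):
                scatter = export_scatter(model, bundle.rows[bundle.rows.partition == part])
                scat_path = out / f"scatter_{slug}_{part}.csv"
                scatter["table"].to_csv(scat_path, index=False)
                refs[f"scatter_{part}"] = _record(scat_path)
            fit_rows.append(
                {
                    "response": resp,
                    **{f"train_{k}": v for k, v in fit.train.items()},
                    **{f"test_{k}": v for k, v in fit.test.items()},
                    "epochs": fit.epochs,
                    "stop_reason": fit.stop_reason,
                }
            )
            _stage(stage_name, t0)

            stage_name = f"sensitivity_{resp}"
            t0 = time.perf_counter()
            sens = sensitivity.sensitivity_report(
                model.weights, bundle, tconf, mode=config.sensitivity_mode
            )
            sens.save(out / f"sensitivity_{slug}.json")
            refs["sensitivity"] = _record(out / f"sensitivity_{slug}.json")
            sens_reports.append(sens)
            _stage(stage_name, t0)

            stage_name = f"optimize_{resp}"
            t0 = time.perf_counter()
            gconf = dataclasses.replace(config.ga, seed=rseed + 3)
            opt = ga.optimize(model.predict, bounds, gconf)
            opt.save(out / f"optimum_{slug}.json")
            refs["optimum"] = _record(out / f"optimum_{slug}.json")
            traj = pd.DataFrame(
                {"generation": np.arange(len(opt.trajectory)), "best_fitness": opt.trajectory}
            )
            traj.to_csv(out / f"trajectory_{slug}.csv", index=False)
            refs["trajectory"] = _record(out / f"trajectory_{slug}.csv")
            opt_rows.append(
                {
                    "response": resp,
                    **{f"{ion}_mm": getattr(opt.best_ions, ion) for ion in ION_ORDER},
                    "predicted_optimum": opt.predicted_response,
                }
            )
            responses[resp] = refs
            _stage(stage_name, t0)

        stage_name = "summary_tables"
        t0 = time.perf_counter()
        pd.DataFrame(fit_rows).to_csv(out / "fit_statistics.csv", index=False)
        _record(out / "fit_statistics.csv")
        sensitivity.report_table(sens_reports).to_csv(out / "sensitivity_ranks.csv", index=False)
        _record(out / "sensitivity_ranks.csv")
        pd.DataFrame(opt_rows).to_csv(out / "optimal_media.csv", index=False)
        _record(out / "optimal_media.csv")
        config.to_yaml(out / "config.yaml")
        _record(out / "config.yaml")
        _stage(stage_name, t0)
    except Exception:
        # persist a partial manifest naming the failed stage, then re-raise
        manifest = RunManifest(config.hash(), config.seed, stages, files, responses)
        manifest.stages[f"FAILED:{stage_name}"] = -1.0
        manifest.save(out / "manifest.partial.json")
        log.exception("pipeline stage %r failed", stage_name)
        raise

    manifest = RunManifest(config.hash(), config.seed, stages, files, responses)
    manifest.save(out / "manifest.json")
    return manifest
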