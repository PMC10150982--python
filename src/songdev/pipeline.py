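"""End-to-end orchestration: data -> maturity -> density models -> entropy ->
simulation -> overnight shifts, from a single YAML-serializable config.

Per syllable, the pipeline applies the same 80/20 train/evaluation split to
both learned models, trains the predicted-age regressor and the Gaussian
density network on the training side, samples entropy on the supported query
grid, simulates baseline and fixed-entropy datasets at the held-out
observation times, scores them with the predicted-age network, and fits the
hierarchical shift and entropy regressions.  All stage outputs are written as
CSV/JSON under the configured output directory and checksummed into a run
manifest, so identical (config, seed) pairs can be verified to reproduce.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import devmodel as dv
from . import entropy as en
from . import maturity as mt
from . import shifts as sh
from . import synthetic as syn

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_pipeline", "validate_dataset"]

log = logging.getLogger(__name__)

STAGES = ["synthetic", "maturity", "devmodel", "entropy", "simulate", "shifts"]
_DEPS = {
    "synthetic": [],
    "maturity": ["data"],
    "devmodel": ["data"],
    "entropy": ["devmodel"],
    "simulate": ["devmodel", "entropy"],
    "shifts": ["maturity", "simulate"],
}


class MaturityConfig(BaseModel):
    architecture: str = "pyramid"
    l2_weight: float | None = None
    eval_fraction: float = 0.2
    n_permutations: int = 1000
    max_iter: int = 500


class DevModelConfig(BaseModel):
    architecture: str | list[int] = "wide"
    lr: float = 1e-3
    batch_size: int = 512
    max_epochs: int = 300
    patience: int = 10
    eps: float = 1e-4
    n_permutations: int = 1000


class EntropyConfig(BaseModel):
    interval_h: float = 5.0 / 60.0
    window_h: float = 0.5
    min_count: int = 30
    variant: str = "tod_only"


class ShiftsConfig(BaseModel):
    bin_width: float = 0.1
    max_gap: float = 0.6
    levels: tuple[float, ...] = sh.DEFAULT_LEVELS
    min_n: int = 30


class RunConfig(BaseModel):
    """Full pipeline configuration (YAML round-trippable)."""

    seed: int = 0
    outdir: str = "runs/default"
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    dataset_path: str | None = None  # if set, replaces the synthetic stage
    synthetic: dict = Field(default_factory=dict)  # GroundTruthParams overrides
    maturity: MaturityConfig = Field(default_factory=MaturityConfig)
    devmodel: DevModelConfig = Field(default_factory=DevModelConfig)
    entropy: EntropyConfig = Field(default_factory=EntropyConfig)
    shifts: ShiftsConfig = Field(default_factory=ShiftsConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True)
        if path:
            Path(path).write_text(text)
        return text

    def validate_stages(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise PipelineError("config", f"unknown stages {unknown}")
        have = set(self.stages)
        if self.dataset_path is not None:
            have.add("data")
        if "synthetic" in have:
            have.add("data")
        for s in self.stages:
            missing = [d for d in _DEPS[s] if d not in have]
            if missing:
                raise PipelineError(s, f"stage '{s}' requires {missing}; "
                                       f"selected stages: {self.stages}")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages_run: list[str] = dfield(default_factory=list)
    outputs: dict[str, str] = dfield(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = dfield(default_factory=dict)
    warnings: list[str] = dfield(default_factory=list)

    def to_json(self, path: str) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.outputs[path.name] = _sha256(path)


def _write_json(obj, path: Path, manifest: RunManifest) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))
    manifest.outputs[path.name] = _sha256(path)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _lmm_summary(res) -> dict:
    return {
        "formula": res.formula, "params": res.params, "bse": res.bse,
        "pvalues": res.pvalues, "conf_int": res.conf_int,
        "random_effect_sd": res.random_effect_sd, "n_obs": res.n_obs,
        "converged": res.converged, "singular": res.singular,
        "method": res.method, "notes": res.notes,
    }


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the selected stages in dependency order and write the manifest."""
    config.validate_stages()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(str(out / "config.yaml"))
    # hash the semantic config only (output location does not affect results)
    hashed = config.model_dump()
    hashed.pop("outdir", None)
    manifest = RunManifest(
        config_hash=hashlib.sha256(json.dumps(hashed, sort_keys=True, default=str).encode()).hexdigest(),
        version=__import__("songdev").__version__,
        seed=config.seed,
    )
    t_all = time.perf_counter()
    state: dict = {}
    try:
        for stage in [s for s in STAGES if s in config.stages]:
            t0 = time.perf_counter()
            _run_stage(stage, config, state, out, manifest)
            manifest.timings[stage] = round(time.perf_counter() - t0, 3)
            manifest.stages_run.append(stage)
    except PipelineError:
        manifest.to_json(str(out / "manifest.json"))
        raise
    except Exception as exc:
        manifest.to_json(str(out / "manifest.json"))
        raise PipelineError(stage, str(exc)) from exc
    manifest.timings["total"] = round(time.perf_counter() - t_all, 3)
    manifest.to_json(str(out / "manifest.json"))
    return manifest


def _get_data(config: RunConfig, state: dict, out: Path, manifest: RunManifest) -> pd.DataFrame:
    if "data" not in state:
        if config.dataset_path is None:
            raise PipelineError("data", "no dataset: include the synthetic stage or set dataset_path")
        df, _ = syn.read_dataset(config.dataset_path)
        report = validate_dataset(df)
        if not report["ok"]:
            raise PipelineError("data", f"dataset validation failed: {report['errors']}")
        state["data"] = df
    return state["data"]


def _syllable_groups(df: pd.DataFrame):
    return df.groupby(["bird_id", "syllable_id"], sort=True)


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path, manifest: RunManifest) -> None:
    seed = config.seed
    if stage == "synthetic":
        params = syn.GroundTruthParams(**{"seed": seed, **config.synthetic})
        df = syn.generate_dataset(params)
        state["data"] = df
        state["params"] = params
        syn.write_dataset(df, str(out / "dataset.csv"), params)
        manifest.outputs["dataset.csv"] = _sha256(out / "dataset.csv")
        return

    data = _get_data(config, state, out, manifest)

    if stage == "maturity":
        preds, reports = [], {}
        state["splits"], state["age_models"] = {}, {}
        for (bird, syl), sub in _syllable_groups(data):
            train, ev = mt.split_dataset(sub, config.maturity.eval_fraction, seed)
            state["splits"][(bird, syl)] = (train, ev)
            model = mt.train_age_net(train, config.maturity.architecture,
                                     config.maturity.l2_weight, seed=seed,
                                     max_iter=config.maturity.max_iter)
            state["age_models"][(bird, syl)] = model
            preds.append(mt.attach_predicted_age(model, ev))
            reports[f"{bird}/{syl}"] = {
                "l2_weight": model.l2_weight, "param_count": model.param_count,
                **{k: v for k, v in model.metadata.items() if k != "history"},
            }
        state["eval_pred"] = pd.concat(preds, ignore_index=True)
        _write_csv(state["eval_pred"], out / "predicted_age_eval.csv", manifest)
        _write_json(reports, out / "maturity_models.json", manifest)
        return

    if stage == "devmodel":
        if "splits" not in state:  # devmodel without maturity stage
            state["splits"] = {k: mt.split_dataset(sub, 0.2, seed)
                               for k, sub in _syllable_groups(data)}
        state["dev_models"], reports = {}, {}
        for key, (train, ev) in state["splits"].items():
            model = dv.train_dev_model(
                train, architecture=config.devmodel.architecture, seed=seed,
                lr=config.devmodel.lr, batch_size=config.devmodel.batch_size,
                max_epochs=config.devmodel.max_epochs, patience=config.devmodel.patience,
                eps=config.devmodel.eps)
            state["dev_models"][key] = model
            reports["/".join(key)] = {k: v for k, v in model.metadata.items() if k != "history"}
        _write_json(reports, out / "dev_models.json", manifest)
        return

    if stage == "entropy":
        window = None
        if "params" in state:
            window = tuple(state["params"].day_window)
        else:
            tod = data["time_of_day_h"]
            window = (float(np.floor(tod.min())), float(np.ceil(tod.max())))
        samples, state["query_times"] = [], {}
        for key, (train, _ev) in state["splits"].items():
            q = en.sample_query_times(train, window, config.entropy.interval_h,
                                      config.entropy.window_h, config.entropy.min_count)
            state["query_times"][key] = q
            if len(q) == 0:
                manifest.warnings.append(f"no supported query times for {key}")
                continue
            samples.append(en.entropy_trajectory(state["dev_models"][key], q,
                                                 bird_id=key[0], syllable_id=key[1]))
        if not samples:
            raise PipelineError("entropy", "no syllable had supported query times")
        ent = pd.concat(samples, ignore_index=True)
        state["entropy_samples"] = ent
        _write_csv(ent, out / "entropy_samples.csv", manifest)
        res = en.fit_entropy_lmm(ent, config.entropy.variant)
        manifest.warnings.extend(f"entropy LMM: {n}" for n in res.notes)
        _write_json(_lmm_summary(res), out / "entropy_lmm.json", manifest)
        state["entropy_lmm"] = res
        return

    if stage == "simulate":
        sims = []
        for key, (train, ev) in state["splits"].items():
            model = state["dev_models"][key]
            q = state["query_times"][key]
            if len(q) == 0:
                manifest.warnings.append(f"simulate: skipping {key} (no query support)")
                continue
            targets = en.daily_targets(model, q)
            base_cols = ["bird_id", "syllable_id", "age_dph", "time_of_day_h", "day_index"]
            obs = ev[base_cols]
            for mode in ("baseline", "fixed_entropy"):
                sims.append(en.simulate_development(model, obs, mode, seed=seed, targets=targets))
        state["simulated"] = pd.concat(sims, ignore_index=True)
        _write_csv(state["simulated"], out / "simulated_renditions.csv", manifest)
        return

    if stage == "shifts":
        cfg = config.shifts
        # real-data shifts from held-out predicted ages
        real_bins = sh.bin_and_quantile(state["eval_pred"], bin_width=cfg.bin_width,
                                        levels=tuple(cfg.levels), min_n=cfg.min_n)
        real_recs = sh.overnight_shifts(real_bins, max_gap=cfg.max_gap)
        _write_csv(real_recs, out / "shifts_real.csv", manifest)
        results = {}
        if len(real_recs):
            res_real = sh.fit_shift_lmm(real_recs)
            results["real"] = _lmm_summary(res_real)
            state["shift_lmm_real"] = res_real
        # simulated baseline vs fixed-entropy comparison
        sim = state["simulated"]
        scored = []
        for key, sub in sim.groupby(["bird_id", "syllable_id"], sort=True):
            scored.append(mt.attach_predicted_age(state["age_models"][key], sub))
        sim_pred = pd.concat(scored, ignore_index=True)
        sim_bins = sh.bin_and_quantile(sim_pred, bin_width=cfg.bin_width,
                                       levels=tuple(cfg.levels), min_n=cfg.min_n)
        sim_recs = sh.overnight_shifts(sim_bins, max_gap=cfg.max_gap)
        _write_csv(sim_recs, out / "shifts_simulated.csv", manifest)
        if len(sim_recs) and sim_recs["condition"].nunique() == 2:
            res_sim = sh.fit_shift_lmm(sim_recs, with_condition=True)
            results["simulated_condition_contrast"] = _lmm_summary(res_sim)
            state["shift_lmm_sim"] = res_sim
            manifest.warnings.extend(f"shift LMM: {n}" for n in res_sim.notes)
        _write_json(results, out / "shift_lmm.json", manifest)
        return

    raise PipelineError(stage, "unknown stage")  # pragma: no cover


# ---------------------------------------------------------------------------
# dataset validation
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ["bird_id", "syllable_id", "age_dph", "time_of_day_h", "day_index"]


def validate_dataset(data: pd.DataFrame | str) -> dict:
    """Schema and consistency report for a rendition table.

    Checks column presence, time-of-day range, age/day consistency and
    per-syllable latent dimensionality; summarizes per-syllable counts and
    age ranges.  Returns ``{"ok": bool, "errors": [...], "summary": df}``.
    """
    if isinstance(data, str):
        data, _ = syn.read_dataset(data)
    errors = []
    for col in REQUIRED_COLUMNS:
        if col not in data.columns:
            errors.append(f"missing required column {col!r}")
    if errors:
        return {"ok": False, "errors": errors, "summary": None}
    zcols = syn.latent_columns(data)
    if not zcols:
        errors.append("no latent columns (z1..zk) found")
    bad_tod = data.index[(data["time_of_day_h"] < 0) | (data["time_of_day_h"] >= 24)]
    if len(bad_tod):
        errors.append(f"time_of_day_h outside [0, 24) at rows {list(bad_tod[:5])}"
                      + ("..." if len(bad_tod) > 5 else ""))
    bad_day = data.index[np.floor(data["age_dph"]).astype(int) != data["day_index"].astype(int)]
    if len(bad_day):
        errors.append(f"floor(age_dph) != day_index at rows {list(bad_day[:5])}"
                      + ("..." if len(bad_day) > 5 else ""))
    for col in zcols:
        if not np.isfinite(data[col].to_numpy(dtype=float)).all():
            errors.append(f"non-finite or missing values in latent column {col}")
    for (bird, syl), sub in data.groupby(["bird_id", "syllable_id"]):
        n_na = sub[zcols].isna().any(axis=1).sum() if zcols else 0
        if n_na:
            errors.append(f"mixed latent dimensionality within syllable {bird}/{syl}")
    summary = (
        data.groupby(["bird_id", "syllable_id"])
        .agg(n=("age_dph", "size"), age_min=("age_dph", "min"), age_max=("age_dph", "max"))
        .reset_index()
    )
    return {"ok": not errors, "errors": errors, "summary": summary}
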