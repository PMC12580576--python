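"""End-to-end orchestration: simulate -> estimate -> IAF -> correlate -> report.

A run is described by a YAML/dict config (see ``mpiaf/data/default_config.yaml``)
with a single master seed; each stage draws from its own named substream
so stages are independently reproducible and re-running any stage on the
previous stage's files reproduces the monolithic run.  Every stage
writes plain CSV/JSON (EDF for recordings) into the run directory, and a
manifest records the config hash, per-stage seeds and output paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import substream
from .cohort import (
    CORRELATED_TRAITS,
    ILLUSIONS,
    CohortSpec,
    RecordingSpec,
    cohort_from_frame,
    cohort_to_frame,
    make_cohort,
    planted_correlation,
    synthesize_eeg,
)
from .edf import read_recording_edf, write_recording_edf
from .iaf import SpectralSettings, estimate_iaf
from .magnitudes import estimate_all, estimates_to_wide, exclusion_summary
from .staircases import STAIRCASE_DESIGNS, run_illusion_session
from .stats import correlation_battery

log = logging.getLogger("mpiaf")

__all__ = [
    "RunConfig",
    "RunManifest",
    "PipelineError",
    "validate_config",
    "run_pipeline",
    "default_config",
    "pooled_battery",
]

IAF_MEASURES = ("paf", "cog", "f_paf")

_SCHEMA = {
    "master_seed": int,
    "cohort": {
        "n_observers": int,
        "planted_correlations": dict,
        "trait_means": dict,
        "trait_sds": dict,
        "lapse_max": float,
        "attention_fail_rate": float,
        "invalid_response_rate": float,
    },
    "behaviour": {"n_sessions": int, "illusions": list, "staircases": dict},
    "recording": {
        "fs": float, "n_channels": int, "n_epochs": int, "epoch_seconds": float,
    },
    "iaf": {"electrode_set": str, "min_channels": int},
    "stats": {
        "family": (str, int), "B": int, "alpha": float,
        "partial_age": bool, "reliabilities": dict,
    },
    "io": {"out_dir": str},
}


def default_config() -> dict:
    from importlib.resources import files

    text = files("mpiaf").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class RunConfig:
    raw: dict

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls, **overrides) -> "RunConfig":
        cfg = default_config()
        for key, val in overrides.items():
            section, _, name = key.partition(".")
            if name:
                cfg.setdefault(section, {})[name] = val
            else:
                cfg[section] = val
        return cls(cfg)

    def __post_init__(self) -> None:
        issues = validate_config(self.raw)
        errors = [i for i in issues if i["level"] == "error"]
        if errors:
            msgs = "; ".join(f"{i['field']}: {i['message']}" for i in errors)
            raise ValueError(f"invalid config: {msgs}")

    # -- typed views -------------------------------------------------------
    @property
    def master_seed(self) -> int:
        return int(self.raw["master_seed"])

    def cohort_spec(self) -> CohortSpec:
        c = self.raw.get("cohort", {})
        corr = None
        planted = c.get("planted_correlations") or {}
        if planted:
            pairs = {}
            for key, r in planted.items():
                a, b = key.split("~")
                pairs[(a.strip(), b.strip())] = float(r)
            corr = planted_correlation(pairs)
        spec = CohortSpec(
            n_observers=int(c.get("n_observers", 60)),
            trait_correlation=corr,
            seed=self.master_seed,
            lapse_max=float(c.get("lapse_max", 0.05)),
            attention_fail_rate=float(c.get("attention_fail_rate", 0.0)),
            invalid_response_rate=float(c.get("invalid_response_rate", 0.0)),
        )
        spec.trait_means.update(c.get("trait_means") or {})
        spec.trait_sds.update(c.get("trait_sds") or {})
        return spec

    def recording_spec(self) -> RecordingSpec:
        r = self.raw.get("recording", {})
        return RecordingSpec(
            fs=float(r.get("fs", 256)),
            n_channels=int(r.get("n_channels", 19)),
            n_epochs=int(r.get("n_epochs", 5)),
            epoch_seconds=float(r.get("epoch_seconds", 60)),
        )

    def spectral_settings(self) -> SpectralSettings:
        i = self.raw.get("iaf", {})
        return SpectralSettings(
            electrode_set=str(i.get("electrode_set", "all_19")),
            min_channels=int(i.get("min_channels", 9)),
        )

    def illusions(self) -> list[str]:
        return list(self.raw.get("behaviour", {}).get("illusions", ILLUSIONS))

    def n_sessions(self) -> int:
        return int(self.raw.get("behaviour", {}).get("n_sessions", 1))

    def out_dir(self) -> Path:
        return Path(self.raw.get("io", {}).get("out_dir", "mpiaf_run"))


@dataclass
class RunManifest:
    config_hash: str
    version: str
    master_seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)
    completed: bool = False

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: RunManifest):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _check_section(section: str, mapping: dict, schema: dict, issues: list) -> None:
    for key, val in mapping.items():
        if key not in schema:
            issues.append(
                dict(level="error", field=f"{section}.{key}", message="unknown key")
            )
            continue
        expected = schema[key]
        if isinstance(expected, dict):
            if not isinstance(val, dict):
                issues.append(
                    dict(level="error", field=f"{section}.{key}",
                         message="expected a mapping")
                )
            else:
                _check_section(f"{section}.{key}" if section else key, val,
                               expected, issues)
        elif expected is float:
            if not isinstance(val, (int, float)) or isinstance(val, bool):
                issues.append(
                    dict(level="error", field=f"{section}.{key}",
                         message=f"expected a number, got {type(val).__name__}")
                )
        elif not isinstance(val, expected):
            name = (
                expected.__name__
                if isinstance(expected, type)
                else "/".join(t.__name__ for t in expected)
            )
            issues.append(
                dict(level="error", field=f"{section}.{key}",
                     message=f"expected {name}, got {type(val).__name__}")
            )


def validate_config(raw: dict) -> list[dict]:
    """Schema and invariant checks; returns a list of error/warning dicts."""
    issues: list[dict] = []
    if not isinstance(raw, dict):
        return [dict(level="error", field="", message="config must be a mapping")]
    _check_section("", raw, _SCHEMA, issues)
    if "master_seed" not in raw:
        issues.append(dict(level="error", field="master_seed", message="required"))

    cohort = raw.get("cohort", {})
    if isinstance(cohort, dict):
        n = cohort.get("n_observers", 60)
        if isinstance(n, int) and n <= 0:
            issues.append(dict(level="error", field="cohort.n_observers",
                               message="must be positive"))
        for key in (cohort.get("planted_correlations") or {}):
            parts = [p.strip() for p in str(key).split("~")]
            if len(parts) != 2 or any(p not in CORRELATED_TRAITS for p in parts):
                issues.append(dict(
                    level="error", field=f"cohort.planted_correlations.{key}",
                    message=f"expected 'traitA~traitB' over {CORRELATED_TRAITS}",
                ))
    behaviour = raw.get("behaviour", {})
    if isinstance(behaviour, dict):
        for il in behaviour.get("illusions", []):
            if il not in ILLUSIONS:
                issues.append(dict(level="error", field="behaviour.illusions",
                                   message=f"unknown illusion {il!r}"))
        for il, block in (behaviour.get("staircases") or {}).items():
            prefix = f"behaviour.staircases.{il}"
            if il not in STAIRCASE_DESIGNS:
                issues.append(dict(level="error", field=prefix,
                                   message="not a staircase illusion"))
                continue
            if not isinstance(block, dict):
                issues.append(dict(level="error", field=prefix,
                                   message="expected a mapping"))
                continue
            for key, val in block.items():
                field = f"{prefix}.{key}"
                if key == "n_trials" and (not isinstance(val, int) or val <= 0):
                    issues.append(dict(level="error", field=field,
                                       message="must be a positive integer"))
                elif key == "step_schedule":
                    steps = [s for _, s in val] if isinstance(val, list) else []
                    if not steps or any(
                        not isinstance(s, (int, float)) or s <= 0 for s in steps
                    ):
                        issues.append(dict(
                            level="error", field=field,
                            message="step sizes must be positive numbers",
                        ))
                elif key not in ("n_trials", "step_schedule", "start_value"):
                    issues.append(dict(level="error", field=field,
                                       message="unknown key"))
    stats_cfg = raw.get("stats", {})
    if isinstance(stats_cfg, dict):
        fam = stats_cfg.get("family", "full")
        if isinstance(fam, str) and fam not in ("full", "illusions"):
            issues.append(dict(level="error", field="stats.family",
                               message="expected 'full', 'illusions' or an integer"))
        if isinstance(fam, int):
            n_ill = len(behaviour.get("illusions", ILLUSIONS)) if isinstance(behaviour, dict) else len(ILLUSIONS)
            n_vars = n_ill + len(IAF_MEASURES)
            expected = {n_vars * (n_vars - 1) // 2, n_ill * (n_ill - 1) // 2}
            if fam not in expected:
                issues.append(dict(
                    level="warning", field="stats.family",
                    message=(
                        f"family size {fam} matches neither the full battery "
                        f"nor the illusions-only pair count {sorted(expected)}"
                    ),
                ))
    rec = raw.get("recording", {})
    if isinstance(rec, dict):
        fs = rec.get("fs", 256)
        if isinstance(fs, (int, float)) and fs <= 80:
            issues.append(dict(level="error", field="recording.fs",
                               message="must exceed twice the 40 Hz band edge"))
    return issues


# ---------------------------------------------------------------------------
# Stages (each runs standalone on the previous stage's files)


def stage_cohort(cfg: RunConfig, out: Path) -> Path:
    profiles = make_cohort(cfg.cohort_spec())
    path = out / "cohort.csv"
    cohort_to_frame(profiles).to_csv(path, index=False)
    log.info("cohort: %d observers -> %s", len(profiles), path)
    return path


def stage_behaviour(cfg: RunConfig, out: Path, cohort_csv: Path) -> Path:
    profiles = cohort_from_frame(pd.read_csv(cohort_csv))
    overrides = cfg.raw.get("behaviour", {}).get("staircases") or {}
    frames = []
    for i, prof in enumerate(profiles):
        for s in range(1, cfg.n_sessions() + 1):
            rng = substream(cfg.master_seed, "staircase", index=i * 16 + s)
            for il in cfg.illusions():
                session = run_illusion_session(
                    il, prof, rng, staircase_overrides=overrides.get(il)
                )
                frames.append(session.to_frame(session=s))
    trials = pd.concat(frames, ignore_index=True)
    path = out / "trials.csv"
    trials.to_csv(path, index=False)
    log.info("behaviour: %d trials -> %s", len(trials), path)
    return path


def stage_eeg(cfg: RunConfig, out: Path, cohort_csv: Path) -> Path:
    profiles = cohort_from_frame(pd.read_csv(cohort_csv))
    rec_spec = cfg.recording_spec()
    eeg_dir = out / "eeg"
    eeg_dir.mkdir(exist_ok=True)
    for i, prof in enumerate(profiles):
        rng = substream(cfg.master_seed, "eeg", index=i)
        rec = synthesize_eeg(prof, rec_spec, seed=rng)
        write_recording_edf(rec, eeg_dir / f"{prof.observer_id}.edf", profile=prof)
    log.info("eeg: %d recordings -> %s", len(profiles), eeg_dir)
    return eeg_dir


def stage_magnitudes(cfg: RunConfig, out: Path, trials_csv: Path) -> Path:
    trials = pd.read_csv(trials_csv)
    estimates = estimate_all(trials)
    path = out / "estimates.csv"
    estimates.to_csv(path, index=False)
    (out / "exclusions.json").write_text(
        json.dumps(exclusion_summary(estimates), indent=1)
    )
    for _, row in estimates[estimates["excluded"]].iterrows():
        log.info(
            "excluded %s from %s (%s)",
            row["observer_id"], row["illusion"], row["exclusion_reason"],
        )
    return path


def stage_iaf(cfg: RunConfig, out: Path, eeg_dir: Path) -> Path:
    settings = cfg.spectral_settings()
    rows = []
    diagnostics = {}
    for edf_path in sorted(Path(eeg_dir).glob("*.edf")):
        rec = read_recording_edf(edf_path)
        est = estimate_iaf(rec, settings)
        diagnostics[est.observer_id] = {
            "channel_paf": {k: None if np.isnan(v) else v
                            for k, v in est.channel_paf.items()},
            "channel_cog": {k: None if np.isnan(v) else v
                            for k, v in est.channel_cog.items()},
        }
        rows.append(
            dict(
                observer_id=est.observer_id, paf=est.paf, cog=est.cog,
                f_paf=est.f_paf, n_channels_paf=est.n_channels_paf,
                n_channels_cog=est.n_channels_cog,
                n_trials_fpaf=est.n_trials_fpaf,
                electrode_set=est.electrode_set,
            )
        )
    path = out / "iaf.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    (out / "iaf_channels.json").write_text(json.dumps(diagnostics, indent=1))
    log.info("iaf: %d observers -> %s", len(rows), path)
    return path


def merge_tables(
    estimates_csv: Path, iaf_csv: Path, cohort_csv: Path
) -> pd.DataFrame:
    wide = estimates_to_wide(pd.read_csv(estimates_csv))
    iaf = pd.read_csv(iaf_csv).set_index("observer_id")[list(IAF_MEASURES)]
    age = pd.read_csv(cohort_csv).set_index("observer_id")["age"]
    return wide.join(iaf, how="outer").join(age, how="left")


def stage_correlate(
    cfg: RunConfig, out: Path, estimates_csv: Path, iaf_csv: Path, cohort_csv: Path
) -> Path:
    merged = merge_tables(estimates_csv, iaf_csv, cohort_csv)
    merged.to_csv(out / "merged.csv")
    s = cfg.raw.get("stats", {})
    variables = [c for c in merged.columns if c != "age"]
    fam_cfg = s.get("family", "full")
    if fam_cfg == "illusions":
        variables = [v for v in variables if v not in IAF_MEASURES]
        family = len(variables) * (len(variables) - 1) // 2
    elif fam_cfg == "full":
        family = len(variables) * (len(variables) - 1) // 2
    else:
        family = int(fam_cfg)
    report = correlation_battery(
        merged[variables],
        reliabilities=s.get("reliabilities") or {},
        age=merged["age"],
        family_size=family,
        B=int(s.get("B", 1000)),
        alpha=float(s.get("alpha", 0.05)),
        seed=cfg.master_seed,
        partial_age=bool(s.get("partial_age", False)),
    )
    path = out / "correlations.json"
    path.write_text(report.to_json())
    for name, mat in (
        ("rho", report.rho),
        ("ci_lo", report.ci_lo),
        ("ci_hi", report.ci_hi),
        ("p_holm", report.p_holm),
        ("rho_disattenuated", report.rho_disattenuated),
    ):
        mat.to_csv(out / f"{name}.csv")
    log.info("correlate: %d variables, family %d -> %s",
             len(variables), family, path)
    return path


def run_pipeline(config: RunConfig | dict) -> RunManifest:
    """Run all stages; aborts with the failing stage's name on error."""
    cfg = config if isinstance(config, RunConfig) else RunConfig(config)
    out = cfg.out_dir()
    out.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(cfg.raw, sort_keys=True).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(blob).hexdigest(),
        version=__version__,
        master_seed=cfg.master_seed,
        stage_seeds={"cohort": cfg.master_seed, "eeg": cfg.master_seed,
                     "staircase": cfg.master_seed, "bootstrap": cfg.master_seed},
    )

    def _run(stage: str, fn, *args):
        t0 = time.time()
        try:
            result = fn(cfg, out, *args)
        except Exception as err:
            manifest.save(out / "manifest.partial.json")
            raise PipelineError(stage, err, manifest) from err
        manifest.outputs[stage] = str(result)
        manifest.timestamps[stage] = time.time() - t0
        return result

    cohort_csv = _run("cohort", stage_cohort)
    trials_csv = _run("behaviour", stage_behaviour, cohort_csv)
    eeg_dir = _run("eeg", stage_eeg, cohort_csv)
    estimates_csv = _run("magnitudes", stage_magnitudes, trials_csv)
    iaf_csv = _run("iaf", stage_iaf, eeg_dir)
    _run("correlate", stage_correlate, estimates_csv, iaf_csv, cohort_csv)
    manifest.completed = True
    manifest.save(out / "manifest.json")
    return manifest


def pooled_battery(tables: list[pd.DataFrame], **battery_kwargs):
    """Concatenate observer tables from several cohorts and run the battery.

    Mirrors pooling participants across studies before the illusion
    inter-correlation analysis; indices are made unique per cohort.
    """
    renamed = []
    for c, t in enumerate(tables):
        t = t.copy()
        t.index = [f"c{c}_{i}" for i in t.index]
        renamed.append(t)
    pooled = pd.concat(renamed, axis=0)
    age = pooled.pop("age") if "age" in pooled.columns else None
    return correlation_battery(pooled, age=age, **battery_kwargs), pooled
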