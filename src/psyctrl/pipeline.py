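"""End-to-end orchestration: study -> effects -> models -> control -> statistics.

``run_pipeline`` executes every analysis stage, writes each module's tabular
interface files into the output directory, and aggregates a machine-readable
``report.json``: effect summaries on both marginal axes, the association grid
(AC/MC/energy x sensitivity/specificity x model provenance), and
prediction-accuracy summaries.  The report contains no wall-clock content, so
a rerun with an identical configuration produces a byte-identical file;
timings go to the log only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .control import cohort_control_profiles
from .effects import effect_tensor, summarize_effects
from .models import DMDC, SELF_CONSTRUCTED, DEFAULT_RCOND, cohort_models, predict_cohort
from .stats import metric_effect_association, prediction_accuracy
from .study_data import StudyConfig, StudyData, read_study
from .synth import GeneratorConfig, generate_cohort, write_synthetic

logger = logging.getLogger("psyctrl")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    input_mode: str = "synthetic"  # "synthetic" | "real"
    input_dir: Optional[str] = None  # study directory for input_mode="real"
    output_dir: str = "psyctrl_out"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    study: StudyConfig = field(default_factory=StudyConfig)
    provenances: tuple[str, ...] = (SELF_CONSTRUCTED, DMDC)
    K: int = 1
    rho: float = 1.0
    rcond: float = DEFAULT_RCOND
    alpha: float = 0.05
    energy_input: str = "canonical"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "real"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode == "real" and not self.input_dir:
            raise ValueError("input_mode='real' requires input_dir")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        bad = [p for p in self.provenances if p not in (SELF_CONSTRUCTED, DMDC)]
        if bad:
            raise ValueError(f"unknown provenance(s) {bad}")


def _clean(obj):
    """JSON-serializable copy with arrays listed and NaN encoded as None."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _clean(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _stage(name: str, fn, warnings: list[str]):
    logger.info("stage %s: start", name)
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done in %.3fs", name, time.perf_counter() - t0)
    return result


def _write_effect_files(study: StudyData, eff, out: Path) -> None:
    n = study.n_items
    rows = [
        (study.participants[i], study.items[s], study.items[k], eff.effect[i, s, k])
        for i in range(study.n_participants)
        for s in range(n)
        for k in range(n)
    ]
    pd.DataFrame(rows, columns=["participant", "scenario", "item", "effect"]).to_csv(
        out / "effects.csv", index=False
    )
    rows = [
        (study.participants[i], study.items[s], eff.sensitivity[i, s])
        for i in range(study.n_participants)
        for s in range(n)
    ]
    pd.DataFrame(rows, columns=["participant", "scenario", "sensitivity"]).to_csv(
        out / "sensitivity.csv", index=False
    )
    rows = [
        (
            study.participants[i],
            study.items[s],
            eff.specificity[i, s],
            bool(eff.valid_mask[i, s]),
        )
        for i in range(study.n_participants)
        for s in range(n)
    ]
    pd.DataFrame(rows, columns=["participant", "scenario", "specificity", "valid"]).to_csv(
        out / "specificity.csv", index=False
    )


def _write_profiles(study: StudyData, profiles, provenance: str, out: Path) -> None:
    prof_rows, energy_rows = [], []
    for pid, prof in profiles.items():
        for j in range(study.n_items):
            prof_rows.append((pid, provenance, study.items[j], prof.ac[j], prof.mc[j]))
            energy_rows.append(
                (pid, provenance, study.items[j], prof.energy[j], bool(prof.feasible[j]))
            )
    mode = "a" if (out / "control_profiles.csv").exists() else "w"
    pd.DataFrame(prof_rows, columns=["participant", "provenance", "node", "ac", "mc"]).to_csv(
        out / "control_profiles.csv", index=False, mode=mode, header=mode == "w"
    )
    pd.DataFrame(
        energy_rows, columns=["participant", "provenance", "scenario", "energy", "feasible"]
    ).to_csv(out / "energies.csv", index=False, mode=mode, header=mode == "w")


def report_schema() -> dict:
    with resources.files("psyctrl.schemas").joinpath("report.schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: Optional[dict] = None) -> list[str]:
    """Check a report against the shipped schema subset; returns violations."""
    schema = schema or report_schema()
    errors: list[str] = []

    def _walk(node, sch, path):
        types = {
            "object": dict,
            "array": list,
            "string": str,
            "number": (int, float),
            "integer": int,
            "boolean": bool,
        }
        t = sch.get("type")
        if t:
            allowed = types[t] if not isinstance(t, list) else tuple(types[x] if x != "null" else type(None) for x in t)
            if t == "number" and isinstance(node, bool):
                errors.append(f"{path}: boolean where number expected")
            elif not isinstance(node, allowed):
                errors.append(f"{path}: expected {t}, got {type(node).__name__}")
                return
        for key in sch.get("required", []):
            if key not in node:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in sch.get("properties", {}).items():
            if isinstance(node, dict) and key in node:
                _walk(node[key], sub, f"{path}.{key}")
        if "items" in sch and isinstance(node, list):
            for idx, entry in enumerate(node):
                _walk(entry, sch["items"], f"{path}[{idx}]")

    _walk(report, schema, "report")
    return errors


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the aggregated report dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    warnings: list[str] = []

    for stale in ("control_profiles.csv", "energies.csv"):
        if (out / stale).exists():
            (out / stale).unlink()

    if config.input_mode == "synthetic":
        sim = _stage("generate", lambda: generate_cohort(config.generator), warnings)
        study = sim.study
        _stage("write_synthetic", lambda: write_synthetic(sim, out / "study"), warnings)
    else:
        study = _stage("read_study", lambda: read_study(config.input_dir, config.study), warnings)

    eff = _stage(
        "effects", lambda: effect_tensor(study, epsilon=config.study.epsilon_specificity), warnings
    )
    _write_effect_files(study, eff, out)
    effect_summaries = {
        axis: summarize_effects(eff, axis) for axis in ("participants", "items")
    }
    (out / "summary_effects.json").write_text(
        json.dumps(_clean(effect_summaries), indent=2, sort_keys=True) + "\n"
    )

    associations = []
    accuracy = {}
    pred_rows = []
    for provenance in config.provenances:
        models, skipped = _stage(
            f"models[{provenance}]",
            lambda prov=provenance: cohort_models(study, prov, rcond=config.rcond),
            warnings,
        )
        if skipped:
            warnings.append(f"{provenance}: no model for participants {skipped}")
        if not models:
            warnings.append(f"{provenance}: no models available, provenance skipped")
            continue
        profiles = _stage(
            f"control[{provenance}]",
            lambda m=models: cohort_control_profiles(
                study, m, K=config.K, rho=config.rho, energy_input=config.energy_input
            ),
            warnings,
        )
        for pid, prof in profiles.items():
            if prof.stabilization:
                warnings.append(
                    f"{provenance}/{pid}: A rescaled for controllability "
                    f"(spectral radius {prof.stabilization['original_spectral_radius']:.3g})"
                )
        _write_profiles(study, profiles, provenance, out)
        for metric in ("ac", "mc", "energy"):
            for outcome in ("sensitivity", "specificity"):
                res = _stage(
                    f"association[{metric}~{outcome},{provenance}]",
                    lambda m=metric, o=outcome, pr=profiles: metric_effect_association(
                        study, eff, pr, m, o, provenance=provenance, alpha=config.alpha
                    ),
                    warnings,
                )
                associations.append(res)
        pred, pred_skipped = _stage(
            f"predict[{provenance}]",
            lambda prov=provenance, m=models: predict_cohort(study, prov, rcond=config.rcond, models=m),
            warnings,
        )
        if pred_skipped:
            warnings.append(f"{provenance}: predictions skipped for {pred_skipped}")
        acc = _stage(
            f"accuracy[{provenance}]",
            lambda p=pred: prediction_accuracy(p, study.post.astype(float)),
            warnings,
        )
        accuracy[provenance] = acc
        for i, pid in enumerate(study.participants):
            for s in range(study.n_items):
                for k in range(study.n_items):
                    pred_rows.append(
                        (pid, provenance, study.items[s], study.items[k], pred[i, s, k])
                    )

    pd.DataFrame(
        pred_rows, columns=["participant", "provenance", "scenario", "item", "predicted"]
    ).to_csv(out / "predictions.csv", index=False)

    assoc_rows = []
    for res in associations:
        for pid, tau, p in zip(res.participants, res.tau, res.p):
            assoc_rows.append((res.pairing, res.provenance, pid, tau, p))
    pd.DataFrame(assoc_rows, columns=["pairing", "provenance", "participant", "tau", "p"]).to_csv(
        out / "associations.csv", index=False
    )

    assoc_report = [
        {
            "pairing": res.pairing,
            "provenance": res.provenance,
            "mean_tau": res.mean_tau,
            "std_tau": res.std_tau,
            "group_p": res.group_p,
            "n_significant": res.n_significant,
            "n_participants": len(res.participants),
            "n_excluded": res.n_excluded,
            "alpha": res.alpha,
        }
        for res in associations
    ]
    (out / "associations_group.json").write_text(
        json.dumps(_clean(assoc_report), indent=2, sort_keys=True) + "\n"
    )

    acc_rows = []
    for provenance, acc in accuracy.items():
        for i, pid in enumerate(study.participants):
            acc_rows.append((provenance, "participant", pid, acc["per_participant"][i]))
        for k, item in enumerate(study.items):
            acc_rows.append((provenance, "item", item, acc["per_item"][k]))
    pd.DataFrame(acc_rows, columns=["provenance", "unit_axis", "unit", "r"]).to_csv(
        out / "prediction_accuracy.csv", index=False
    )

    config_echo = dataclasses.asdict(config)
    config_echo.pop("output_dir")  # where results land does not shape them
    report = {
        "psyctrl_version": __version__,
        "config": _clean(config_echo),
        "n_participants": study.n_participants,
        "n_items": study.n_items,
        "excluded": list(study.excluded),
        "effects": _clean(
            {
                axis: {
                    metric: {
                        "mean": effect_summaries[axis][metric]["mean"],
                        "std": effect_summaries[axis][metric]["std"],
                        "n_units": effect_summaries[axis][metric]["n_units"],
                    }
                    for metric in ("sensitivity", "specificity")
                }
                for axis in ("participants", "items")
            }
        ),
        "associations": _clean(assoc_report),
        "prediction_accuracy": _clean(
            {
                prov: {
                    "participants": acc["participants"],
                    "items": acc["items"],
                }
                for prov, acc in accuracy.items()
            }
        ),
        "warnings": warnings,
    }
    problems = validate_report(report)
    if problems:  # pragma: no cover - guards future schema drift
        raise PipelineError(f"report failed schema validation: {problems}")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
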