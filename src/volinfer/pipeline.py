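"""End-to-end orchestration: simulate a cohort, analyze it, fit it.

A single YAML config drives every stage; a single global seed fans out to
per-stage, per-participant child seeds through ``numpy``'s seed-sequence
mechanism, so each stage is independently reproducible and a completed run
is re-executable from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fitting, latents as lat, psychometrics as psy, stats as bst
from .observer import ModelParams, simulate_agent, write_responses
from .task import C_MINUS, C_PLUS, TaskConfig, generate_session, write_session

STAGE_IDS = {
    "simulate": 0,
    "psychometrics": 1,
    "stats": 2,
    "fit": 3,
    "validate": 4,
    "latents": 5,
    "recovery": 6,
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {"n_participants": 12},
    "task": {},
    "params": {
        # controllability lowers the perceived hazard rate; other
        # parameters shared across conditions
        "C-": {"hazard": 0.15, "sigma_inf": 1.0, "conf_threshold": 1.5,
               "sigma_meta": 0.8, "conf_gain": 1.0},
        "C+": {"hazard": 0.06, "sigma_inf": 1.0, "conf_threshold": 1.5,
               "sigma_meta": 0.8, "conf_gain": 1.0},
    },
    "stages": {"fit": False, "validate": False, "latents": True,
               "recovery": False, "figures": False},
    "fit_spec": {},
    "latents": {"n_particles": 500},
    "recovery": {"n_datasets": 10},
}


class PipelineError(RuntimeError):
    """A stage failed; the manifest records completed stages."""


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = _merge(DEFAULT_CONFIG, user)
    if cfg["cohort"]["n_participants"] < 1:
        raise PipelineError("empty cohort: n_participants must be >= 1")
    return cfg


def stage_rng(seed: int, stage: str, participant: int = 0) -> np.random.Generator:
    """Counter-based child stream: global seed x stage id x participant."""
    return np.random.default_rng([seed, STAGE_IDS[stage], participant])


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict("records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def run_end_to_end(config, out_dir: str | Path) -> dict:
    """Run simulate -> psychometrics -> stats (-> fit/validate/latents/
    recovery) and write the JSON/CSV report bundle to ``out_dir``.

    Returns the report dictionary.  Deterministic: rerunning with the same
    config yields byte-identical report files.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    completed: list[str] = []
    manifest: dict = {"config": cfg, "completed_stages": completed, "outputs": {}}
    report: dict = {}
    try:
        # ------------------------------------------------ simulate cohort
        n_part = cfg["cohort"]["n_participants"]
        params = {c: ModelParams(**cfg["params"][c]) for c in (C_MINUS, C_PLUS)}
        sessions, responses = [], []
        for p in range(n_part):
            rng = stage_rng(seed, "simulate", p)
            task_cfg = TaskConfig(**{**cfg["task"], "seed": int(rng.integers(2**31 - 1))})
            session = generate_session(task_cfg)
            _, resp = simulate_agent(session, params, rng)
            sessions.append(session)
            responses.append(resp)
            write_session(session, out / f"session_p{p:02d}.csv")
            write_responses(resp, out / f"responses_p{p:02d}.csv")
        completed.append("simulate")

        # ------------------------------------------------ psychometrics
        psych: list[dict] = []
        for p, (session, resp) in enumerate(zip(sessions, responses)):
            row: dict = {"participant": p}
            ev = psy.signed_evidence_series(session, resp)
            rep = psy.repeat_flags(resp)
            for c in (C_MINUS, C_PLUS):
                mask = resp["condition"].to_numpy() == c
                curve = psy.build_reversal_curve(resp, session, condition=c)
                conf_curve = psy.build_reversal_curve(
                    resp, session, condition=c, event="high_conf"
                )
                row[f"reversal:{c}"] = psy.fit_reversal_exponential(curve).to_dict()
                row[f"confidence_reversal:{c}"] = psy.fit_confidence_reversal(
                    conf_curve
                ).to_dict()
                row[f"repetition:{c}"] = psy.fit_repetition_logistic(
                    ev[mask], rep[mask]
                ).to_dict()
                row[f"confidence_dual:{c}"] = psy.fit_confidence_dual_sigmoid(
                    ev[mask], resp["confidence"].to_numpy()[mask], rep[mask]
                ).to_dict()
            psych.append(row)
        report["psychometrics"] = psych
        completed.append("psychometrics")

        # ------------------------------------------------ behavioral stats
        cells = []
        for p, resp in enumerate(responses):
            table = bst.change_of_mind_metrics(resp).table
            table["participant"] = p
            cells.append(table)
        cell_df = pd.concat(cells, ignore_index=True)
        hc = cell_df[cell_df["measure"] == "high_conf"].rename(
            columns={"condition": "B", "level": "A", "fraction": "value"}
        )
        anova = bst.rm_anova_2x2(hc, within=("A", "B"))
        pse = {
            c: [r[f"repetition:{c}"]["params"]["choice_PSE"] for r in psych]
            for c in (C_MINUS, C_PLUS)
        }
        pse_arrays = {
            c: np.array([v for v in vals if v is not None]) for c, vals in pse.items()
        }
        report["stats"] = {
            "anova_high_conf": anova.to_dict("index"),
            "pse_by_condition_mean": {c: float(np.nanmean(v)) for c, v in pse_arrays.items()},
            "pse_paired_test": bst.group_level_tests(
                pse_arrays[C_PLUS], paired_with=pse_arrays[C_MINUS]
            )
            if min(len(v) for v in pse_arrays.values()) >= 2
            and len(pse_arrays[C_MINUS]) == len(pse_arrays[C_PLUS])
            else None,
            "cells": cell_df,
        }
        completed.append("stats")

        # ------------------------------------------------ optional stages
        spec = fitting.FitSpec(**cfg["fit_spec"])
        if cfg["stages"].get("fit"):
            fits = fitting.fit_model_per_condition(
                sessions[0], responses[0], spec, stage_rng(seed, "fit")
            )
            report["fit"] = {
                c: {"params": asdict(f.params), "nll": f.nll, "converged": f.converged}
                for c, f in fits.items()
            }
            completed.append("fit")
        if cfg["stages"].get("validate"):
            p0 = params if "fit" not in report else {
                c: ModelParams(**report["fit"][c]["params"]) for c in report["fit"]
            }
            curves = fitting.validate_model(
                p0, sessions[0], responses[0], spec, rng=stage_rng(seed, "validate")
            )
            report["validate"] = {
                name: {"fraction": cs.fraction, "n_total": cs.n_total}
                for name, cs in curves.items()
            }
            completed.append("validate")
        if cfg["stages"].get("latents"):
            cell_rows = []
            for p, (session, resp) in enumerate(zip(sessions, responses)):
                _, traj = lat.particle_filter(
                    session, resp, params,
                    n_particles=int(cfg["latents"]["n_particles"]),
                    rng=stage_rng(seed, "latents", p),
                )
                summ = lat.summarize_latents(traj, resp)
                summ["participant"] = p
                cell_rows.append(summ)
            lat_cells = pd.concat(cell_rows, ignore_index=True)
            lat_anova = bst.rm_anova_2x2(
                lat_cells.rename(
                    columns={"response_type": "A", "condition": "B",
                             "prior_belief": "value"}
                ),
                within=("A", "B"),
            )
            report["latents"] = {
                "cells": lat_cells,
                "anova_prior_belief": lat_anova.to_dict("index"),
            }
            completed.append("latents")
        if cfg["stages"].get("recovery"):
            rec = fitting.parameter_recovery(
                n_datasets=int(cfg["recovery"]["n_datasets"]),
                spec=spec,
                rng=stage_rng(seed, "recovery"),
            )
            rec.correlations.to_csv(out / "recovery_confusion.csv")
            report["recovery"] = {
                "diagonal": rec.diagonal.to_dict(),
                "n_failed": rec.n_failed,
            }
            completed.append("recovery")
        if cfg["stages"].get("figures"):
            _write_figure(sessions[0], responses[0], out / "reversal_curves.png")
    except PipelineError:
        raise
    except Exception as exc:  # abort with partial manifest
        (out / "manifest.json").write_text(
            json.dumps(_jsonable({**manifest, "error": str(exc)}), indent=2, sort_keys=True)
        )
        raise PipelineError(f"stage failed after {completed}: {exc}") from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    for f in sorted(out.glob("*.csv")) + [report_path]:
        manifest["outputs"][f.name] = _digest(f)
    (out / "manifest.json").write_text(
        json.dumps(_jsonable(manifest), indent=2, sort_keys=True)
    )
    return report


def _write_figure(session, resp, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for c, color in ((C_MINUS, "tab:blue"), (C_PLUS, "tab:pink")):
        curve = psy.build_reversal_curve(resp, session, condition=c)
        ax.plot(curve.bin_centers, curve.fraction, "o-", color=color, label=c)
    ax.axhline(0.5, ls=":", c="gray")
    ax.axvline(0.5, ls="-", c="gray", lw=0.8)
    ax.set_xlabel("trials from reversal")
    ax.set_ylabel("fraction post-reversal state reported")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
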