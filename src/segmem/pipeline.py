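"""End-to-end orchestration: simulate -> score -> analyze -> report.

Owns all file I/O. Data tables are UTF-8 CSV with mandatory headers; times
are seconds as decimals; sessions are coded ``pre``/``post`` and activities
``gyoza``/``taichi``. Model output is JSON (coefficients, AIC, chosen random
structure) plus an ``emmeans.csv`` of predicted cell means, and a markdown
report laying out the predicted group x time x activity means per outcome.
A run manifest records the config hash, master seed, package version and
per-file checksums, so a run can be reproduced and verified byte-for-byte.
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

from . import __version__
from .models import (
    FACTORS,
    OUTCOMES,
    build_model_spec,
    fit_multilevel,
    marginal_means,
    select_random_structure,
)
from .scoring import RECALL_TOTALS, score_dataset
from .segmentation import KernelSpec, compute_all_agreements
from .simulate import (
    OutcomeParams,
    RecallParams,
    SegmentationParams,
    SimConfig,
    StudyDataset,
    simulate_study,
)
from .videos import ACTIVITIES, default_videos

log = logging.getLogger("segmem")

TABLE_FILES = {
    "design": "design.csv",
    "presses": "presses.csv",
    "survey": "survey.csv",
    "trials": "trials.csv",
    "recall": "recall.csv",
}


# ---------------------------------------------------------------------------
# Config


def sim_config_from_dict(raw: dict) -> SimConfig:
    """Build a SimConfig from a (YAML-loaded) nested mapping.

    Unknown keys are rejected so config typos fail loudly. Omitted sections
    keep the calibrated defaults.
    """
    raw = dict(raw or {})
    kwargs: dict = {}
    for key in ("seed", "counterbalance", "practice_gate"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if "group_sizes" in raw:
        kwargs["group_sizes"] = {str(k): int(v) for k, v in raw.pop("group_sizes").items()}
    config = SimConfig(**kwargs)
    if "segmentation" in raw:
        seg = raw.pop("segmentation")
        config.segmentation = dataclasses.replace(config.segmentation, **seg)
    if "outcomes" in raw:
        for name, overrides in raw.pop("outcomes").items():
            if name not in config.outcomes:
                raise ValueError(f"unknown outcome {name!r} in config")
            config.outcomes[name] = dataclasses.replace(
                config.outcomes[name], **overrides
            )
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return config


def load_sim_config(path: str | Path) -> SimConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return sim_config_from_dict(yaml.safe_load(fh))


def config_to_dict(config: SimConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {
                k: clean(v)
                for k, v in dataclasses.asdict(obj).items()
            }
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return {
        "seed": config.seed,
        "counterbalance": config.counterbalance,
        "practice_gate": config.practice_gate,
        "group_sizes": dict(config.group_sizes),
        "segmentation": clean(config.segmentation),
        "outcomes": {k: clean(v) for k, v in config.outcomes.items()},
    }


# ---------------------------------------------------------------------------
# Export / ingest


def export_dataset(dataset: StudyDataset, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in dataset.tables().items():
        path = out_dir / TABLE_FILES[name]
        frame.to_csv(path, index=False, float_format="%.6f")
        paths[name] = path
    return paths


REQUIRED_COLUMNS = {
    "design": ["participant", "group", "pre_first", "post_first"],
    "presses": ["participant", "session", "activity", "press_time"],
    "survey": ["participant", "session", "activity", "item", "correct"],
    "trials": ["participant", "session", "activity", "task", "trial", "correct"],
    "recall": ["participant", "session", "activity", "grain", "n_recalled", "n_total"],
}


class SchemaError(ValueError):
    """Raised when an ingested table violates the documented schema."""


def ingest_external(
    data_dir: str | Path,
    *,
    column_map: dict[str, dict[str, str]] | None = None,
    videos=None,
) -> StudyDataset:
    """Read and validate a directory of study CSVs into a StudyDataset.

    ``column_map`` optionally renames columns per table (a mapping layer for
    external deposits whose headers differ from ours). Row-level violations
    (out-of-range presses, recalled > total, unknown session/activity labels,
    duplicate keys) are collected and raised together.
    """
    data_dir = Path(data_dir)
    videos = videos or default_videos()
    tables = {}
    problems: list[str] = []
    for name, filename in TABLE_FILES.items():
        path = data_dir / filename
        if not path.exists():
            raise SchemaError(f"missing table: {filename}")
        frame = pd.read_csv(path)
        if column_map and name in column_map:
            frame = frame.rename(columns=column_map[name])
        missing = set(REQUIRED_COLUMNS[name]) - set(frame.columns)
        if missing:
            problems.append(f"{filename}: missing columns {sorted(missing)}")
            continue
        tables[name] = frame
    if problems:
        raise SchemaError("; ".join(problems))

    for name in ("presses", "survey", "trials", "recall"):
        bad = ~tables[name]["session"].isin(["pre", "post"])
        for idx in tables[name].index[bad]:
            problems.append(f"{TABLE_FILES[name]} row {idx}: bad session label")
        bad = ~tables[name]["activity"].isin(list(videos))
        for idx in tables[name].index[bad]:
            problems.append(f"{TABLE_FILES[name]} row {idx}: bad activity label")
    for idx, row in tables["presses"].iterrows():
        video = videos.get(row["activity"])
        if video and not (0.0 <= row["press_time"] <= video.duration):
            problems.append(
                f"presses.csv row {idx}: press_time {row['press_time']} outside "
                f"[0, {video.duration}]"
            )
    for idx, row in tables["recall"].iterrows():
        if row["n_recalled"] > row["n_total"] or row["n_recalled"] < 0:
            problems.append(
                f"recall.csv row {idx}: n_recalled outside [0, n_total]"
            )
    dup = tables["design"]["participant"].duplicated()
    for idx in tables["design"].index[dup]:
        problems.append(f"design.csv row {idx}: duplicate participant")
    if problems:
        raise SchemaError("; ".join(problems[:50]))
    return StudyDataset(videos=videos, **tables)


def audit_completeness(dataset: StudyDataset) -> pd.DataFrame:
    """Per-participant cell counts for every measure; flags incomplete ones.

    A complete participant has both sessions x both activities in survey,
    trials (both tasks) and recall. (A press log may legitimately be empty,
    so presses are not audited.)
    """
    expected = {
        "survey": 4,
        "recall": 4,
        "recognition": 4,
        "order": 4,
    }
    rows = []
    for pid in dataset.design["participant"]:
        counts = {
            "survey": len(
                dataset.survey[dataset.survey["participant"] == pid]
                .groupby(["session", "activity"])
            ),
            "recall": len(
                dataset.recall[dataset.recall["participant"] == pid]
                .groupby(["session", "activity"])
            ),
        }
        tr = dataset.trials[dataset.trials["participant"] == pid]
        for task in ("recognition", "order"):
            counts[task] = len(
                tr[tr["task"] == task].groupby(["session", "activity"])
            )
        complete = all(counts[k] == v for k, v in expected.items())
        rows.append({"participant": pid, **counts, "complete": complete})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Analysis assembly


def _attach_group(frame: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    return frame.merge(design[["participant", "group"]], on="participant", how="left")


def outcome_model_data(
    outcome: str, outcomes: pd.DataFrame, agreement: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Complete-case long table for one outcome model."""
    if outcome in ("survey", "recall", "recognition", "order"):
        data = outcomes[outcomes["outcome"] == outcome].copy()
    elif outcome == "segmentation_count":
        data = agreement[["participant", "session", "activity", "count"]].copy()
    elif outcome == "segmentation_agreement":
        data = agreement[agreement["status"] == "ok"][
            ["participant", "session", "activity", "count", "r"]
        ].copy()
        data = data.rename(columns={"count": "seg_count"})
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    data = _attach_group(data, design)
    # listwise deletion of participants missing any cell for this outcome
    cells = data.groupby("participant").size()
    expected = cells.max()
    complete = cells[cells == expected].index
    dropped = sorted(set(cells.index) - set(complete))
    if dropped:
        log.warning(
            "%s: dropping %d incomplete participant(s): %s",
            outcome, len(dropped), ", ".join(map(str, dropped)),
        )
    return data[data["participant"].isin(complete)].reset_index(drop=True)


def analyze_outcomes(
    outcomes: pd.DataFrame,
    agreement: pd.DataFrame,
    design: pd.DataFrame,
    *,
    select: bool = True,
) -> dict[str, dict]:
    """Fit all six outcome models; returns per-outcome fit + marginal means."""
    results = {}
    for outcome in OUTCOMES:
        spec = build_model_spec(outcome)
        data = outcome_model_data(outcome, outcomes, agreement, design)
        if select and len(spec.candidate_structures) > 1:
            fit = select_random_structure(spec, data)
        else:
            fit = fit_multilevel(spec, data, random=spec.candidate_structures[0])
        emm = marginal_means(fit, FACTORS)
        results[outcome] = {"fit": fit, "emm": emm, "n_rows": len(data)}
        log.info(
            "%s: structure=%s AIC=%.1f", outcome, fit.chosen_structure, fit.aic
        )
    return results


def model_summary(results: dict[str, dict]) -> dict:
    summary = {}
    for outcome, parts in results.items():
        fit = parts["fit"]
        summary[outcome] = {
            "family": fit.spec.family,
            "random_structure": fit.chosen_structure,
            "candidate_aics": {k: float(v) for k, v in fit.candidate_aics.items()},
            "aic": float(fit.aic),
            "loglik": float(fit.result.loglik),
            "converged": bool(fit.result.converged),
            "n_rows": int(parts["n_rows"]),
            "variance_components": fit.result.variance_components,
            "coefficients": fit.coef_table().to_dict("records"),
        }
    return summary


def emmeans_table(results: dict[str, dict]) -> pd.DataFrame:
    frames = []
    for outcome, parts in results.items():
        table = parts["emm"].cells.copy()
        table.insert(0, "outcome", outcome)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def write_report(results: dict[str, dict], path: Path) -> None:
    """Markdown report: predicted cell means per outcome (figure layout)."""
    lines = ["# Study report", ""]
    for outcome, parts in results.items():
        fit = parts["fit"]
        lines.append(f"## {outcome}")
        lines.append("")
        lines.append(
            f"family: {fit.spec.family}; random structure: {fit.chosen_structure}; "
            f"AIC: {fit.aic:.1f}"
        )
        lines.append("")
        lines.append("| group | time | activity | M | SE |")
        lines.append("|---|---|---|---|---|")
        for _, row in parts["emm"].cells.iterrows():
            lines.append(
                f"| {row['group']} | {row['time']} | {row['activity']} "
                f"| {row['M']:.3f} | {row['SE']:.3f} |"
            )
        lines.append("")
        coef = fit.coef_table()
        stat = fit.result.stat_name
        lines.append(f"| term | B | SE | {stat} | p |")
        lines.append("|---|---|---|---|---|")
        for _, row in coef.iterrows():
            lines.append(
                f"| {row['term']} | {row['B']:.4g} | {row['SE']:.3g} "
                f"| {row[stat]:.2f} | {row['p']:.3g} |"
            )
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Manifest and full run


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    files: dict[str, str] = field(default_factory=dict)
    timestamp: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_study(
    config: SimConfig | str | Path,
    out_dir: str | Path,
    *,
    kernel: KernelSpec = KernelSpec(),
    seed: int | None = None,
    select: bool = True,
) -> RunManifest:
    """Full chain: simulate, export, score, agreements, models, report.

    Any stage failure aborts with the stage named; artifacts written before
    the failure are left in place for debugging.
    """
    if not isinstance(config, SimConfig):
        config = load_sim_config(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        dataset = simulate_study(config)
        paths = export_dataset(dataset, out_dir)
        stage = "score"
        outcomes = score_dataset(dataset.survey, dataset.trials, dataset.recall)
        outcomes_path = out_dir / "outcomes.csv"
        outcomes.to_csv(outcomes_path, index=False, float_format="%.6f")
        paths["outcomes"] = outcomes_path
        stage = "score-segmentation"
        agreement = compute_all_agreements(dataset, kernel)
        agreement_path = out_dir / "agreement.csv"
        agreement.to_csv(agreement_path, index=False, float_format="%.6f")
        paths["agreement"] = agreement_path
        stage = "analyze"
        results = analyze_outcomes(
            outcomes, agreement, dataset.design, select=select
        )
        summary_path = out_dir / "model_summary.json"
        summary_path.write_text(
            json.dumps(model_summary(results), indent=2), encoding="utf-8"
        )
        paths["model_summary"] = summary_path
        emmeans_path = out_dir / "emmeans.csv"
        emmeans_table(results).to_csv(emmeans_path, index=False, float_format="%.6f")
        paths["emmeans"] = emmeans_path
        stage = "report"
        report_path = out_dir / "report.md"
        write_report(results, report_path)
        paths["report"] = report_path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config_json = json.dumps(config_to_dict(config), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_json.encode()).hexdigest(),
        seed=config.seed,
        version=__version__,
        files={name: _sha256(p) for name, p in paths.items()},
        timestamp=time.time(),
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2), encoding="utf-8"
    )
    return manifest
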