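"""Pipeline orchestration: simulate → code-trials → classify → quantify →
morphometry → stats → report, with a manifest for reproducibility.

A single global seed fans out to per-stage seeds through a counter-based
hash, so any stage can be rerun in isolation and still see the same
stream. No stage mutates its inputs; every intermediate is written once
into the run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging import ImageStack, quantify_compartment
from .maze import MazeConfig, read_event_log, summaries_to_frame, write_event_log, code_trial
from .morphometry import BoxCountConfig, analyse_cell, cells_to_frame, segment_cells, summarise_roi
from .phenotype import (assign_behavioural_groups, bin_weekly, classify_cohort,
                        cohort_phenotype_counts, daily_measure_table,
                        remove_outliers)
from .stats import build_report, mixed_anova, posthoc_holm
from .synthetic import (CohortConfig, EffectProfile, MorphParams, PlantedCell,
                        ZStackPlan, generate_microglia_mask, generate_zstack,
                        simulate_cohort, simulate_sensory_motor)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "load_config"]

STAGES = ("simulate", "code_trials", "classify", "quantify",
          "morphometry", "stats", "report")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    seed: int = 0
    maze: MazeConfig = field(default_factory=MazeConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    effects: EffectProfile = field(default_factory=EffectProfile)
    boxcount: BoxCountConfig = field(default_factory=BoxCountConfig)
    morph_cells_per_group: int = 20
    morph_branch_depth: dict[str, int] = field(default_factory=lambda: {
        "sham_vehicle": 4, "sham_minocycline": 3,
        "cci_vehicle": 2, "cci_minocycline": 4,
    })
    gg_correct: str = "auto"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            v = data[f.name]
            if f.name in ("maze", "cohort", "effects", "boxcount") and isinstance(v, dict):
                typ = {"maze": MazeConfig, "cohort": CohortConfig,
                       "effects": EffectProfile, "boxcount": BoxCountConfig}[f.name]
                allowed = {ff.name for ff in fields(typ)}
                bad = set(v) - allowed
                if bad:
                    raise ValueError(f"unknown keys under {f.name}: {sorted(bad)}")
                v = typ(**v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, frozenset):
                return sorted(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return {f.name: enc(getattr(self, f.name)) for f in fields(self)}

    def content_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage into ``outdir``; idempotent for a given seed.

    On failure the partial outputs are retained and a ``FAILED_<stage>``
    marker file names the failed stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for stale in out.glob("FAILED_*"):
        stale.unlink()
    timings: dict[str, float] = {}
    current = ""
    try:
        # --- simulate ------------------------------------------------
        current = "simulate"
        t0 = time.perf_counter()
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=stage_seed(config.seed, "simulate"))
        timelines = simulate_cohort(cohort_cfg, config.effects, config.maze)
        write_event_log((t for tl in timelines for t in tl.trials),
                        out / "events.csv")
        truth = pd.DataFrame([{"rat_id": tl.rat_id, "group": tl.group,
                               "latent_affected": tl.affected}
                              for tl in timelines])
        truth.to_csv(out / "latent_truth.csv", index=False)
        sens, motor = simulate_sensory_motor(cohort_cfg)
        sens.to_csv(out / "sensory.csv", index=False)
        motor.to_csv(out / "motor.csv", index=False)
        timings[current] = time.perf_counter() - t0

        # --- code trials ----------------------------------------------
        current = "code_trials"
        t0 = time.perf_counter()
        trials = read_event_log(out / "events.csv", config.maze)
        summaries = summaries_to_frame([code_trial(t, config.maze) for t in trials])
        summaries.to_csv(out / "summaries.csv", index=False)
        timings[current] = time.perf_counter() - t0

        # --- classify -------------------------------------------------
        current = "classify"
        t0 = time.perf_counter()
        tidy = daily_measure_table(summaries)
        calls = classify_cohort(tidy)
        calls_df = pd.DataFrame([{
            "rat_id": c.rat_id, "group": c.group, "affected": c.affected,
            **{f"exceedance_w{i+1}": e for i, e in enumerate(c.exceedance_days)},
            **{f"evaluable_w{i+1}": e for i, e in enumerate(c.evaluable_days)},
        } for c in calls])
        calls_df.to_csv(out / "calls.csv", index=False)
        counts = cohort_phenotype_counts(calls)
        counts.to_csv(out / "weekly_counts.csv", index=False)
        # group analyses use the five behavioural groups (affected and
        # unaffected vehicle CCI rats are separate groups)
        tidy = assign_behavioural_groups(tidy, calls)
        cleaned, removals = remove_outliers(tidy)
        removals.to_csv(out / "outlier_removals.csv", index=False)
        binned = bin_weekly(cleaned)
        binned.to_csv(out / "binned.csv", index=False)
        timings[current] = time.perf_counter() - t0

        # --- quantify (synthetic demo stacks) -------------------------
        current = "quantify"
        t0 = time.perf_counter()
        rng = np.random.default_rng(stage_seed(config.seed, "quantify"))
        quant_rows = []
        for side in ("ipsilateral", "contralateral"):
            plan = ZStackPlan(cells=tuple(
                PlantedCell(center=(int(rng.integers(20, 108)),
                                    int(rng.integers(20, 108))),
                            radius=8, compartment="IBA1",
                            target_intensity=float(rng.integers(50, 200)),
                            nucleus_radius=3)
                for _ in range(4)))
            zs = generate_zstack(plan, rng)
            stack = ImageStack(planes=zs.planes, channel_roles=zs.channel_roles)
            res = quantify_compartment(stack, "IBA1", background_radius=None)
            quant_rows.append({"side": side, "compartment": res.compartment,
                               "median_AU": res.median, "mask_px": res.mask_px})
        pd.DataFrame(quant_rows).to_csv(out / "intensity.csv", index=False)
        timings[current] = time.perf_counter() - t0

        # --- morphometry ----------------------------------------------
        current = "morphometry"
        t0 = time.perf_counter()
        rng = np.random.default_rng(stage_seed(config.seed, "morphometry"))
        morph_rows = []
        for group, depth in config.morph_branch_depth.items():
            morphs = []
            for _ in range(config.morph_cells_per_group):
                mask, _info = generate_microglia_mask(
                    MorphParams(branch_depth=depth), rng)
                for cell in segment_cells(mask):
                    morphs.append(analyse_cell(cell, config.boxcount))
            summary = summarise_roi(morphs)
            morph_rows.append({"group": group, "n_cells": summary.n_cells,
                               "valid": summary.valid, **summary.means})
        morph_df = pd.DataFrame(morph_rows)
        morph_df.to_csv(out / "morphometry.csv", index=False)
        timings[current] = time.perf_counter() - t0

        # --- stats -----------------------------------------------------
        current = "stats"
        t0 = time.perf_counter()
        tica = binned[binned["measure"] == "tica_per_entry"].dropna(subset=["value"])
        anova_results = {}
        posthocs = {}
        if tica["group"].nunique() >= 2 and tica["bin"].nunique() >= 2:
            anova_results["tica_per_entry"] = mixed_anova(
                tica, dv="value", between="group", within="bin",
                subject="rat_id", gg_correct=config.gg_correct)
            for b, sub in tica.groupby("bin"):
                posthocs[f"tica_{b}"] = posthoc_holm(sub, dv="value", group="group")
        timings[current] = time.perf_counter() - t0

        # --- report ----------------------------------------------------
        current = "report"
        t0 = time.perf_counter()
        build_report(out, anova_results=anova_results, posthocs=posthocs,
                     weekly_counts=counts, binned=binned,
                     morphometry=morph_df,
                     intensity=pd.read_csv(out / "intensity.csv"))
        timings[current] = time.perf_counter() - t0
    except Exception as exc:
        (out / f"FAILED_{current}").write_text(str(exc))
        raise StageError(current, exc) from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
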