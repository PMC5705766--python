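"""End-to-end orchestration: generate -> validate -> memory -> pairs -> zipf
-> interact, with deterministic seeding and JSON report outputs.

Every report embeds the resolved generator config, the seeds used and a hash
of the placement table it was computed from, so identical configs reproduce
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import scene_model, synthetic_scenes
from .scene_model import ArrangementDataset, read_dataset, write_dataset
from .synthetic_scenes import (GeneratorConfig, exp1_config, exp2_config,
                               config_to_dict, config_from_dict)
from .memory_analysis import memory_report
from .pairing_analysis import pairing_report
from .zipf_fit import zipf_report
from .interaction_analysis import interaction_report

log = logging.getLogger("scenegram")


class ValidationFailure(RuntimeError):
    """Dataset failed structural validation."""


@dataclass
class RunConfig:
    preset: str = "exp1"                 # exp1 | exp2
    seed: int = 0                        # generation seed
    baseline_seed: int = 1               # baseline partner draw
    data_dir: str | None = None          # load instead of generate
    out_dir: str = "scenegram_out"
    generator_overrides: dict = field(default_factory=dict)
    stages: tuple = ("memory", "pairs", "zipf", "interact")
    ordered_pairs: bool = True

    def generator_config(self) -> GeneratorConfig:
        maker = exp1_config if self.preset == "exp1" else exp2_config
        return maker(seed=self.seed, **self.generator_overrides)


def _hash_placements(pl: pd.DataFrame) -> str:
    payload = pl.to_csv(index=False, float_format="%.12g").encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               allow_nan=True) + "\n")


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


def obtain_dataset(config: RunConfig) -> ArrangementDataset:
    if config.data_dir is not None:
        d = Path(config.data_dir)
        required = d / "placements.csv"
        if not required.exists():
            raise FileNotFoundError(
                f"generation disabled and {required} does not exist")
        log.info("loading dataset from %s", d)
        return read_dataset(d)
    gen = config.generator_config()
    log.info("generating %s dataset, seed=%d", config.preset, config.seed)
    if config.preset == "exp1":
        return synthetic_scenes.generate_exp1(gen)
    if config.preset == "exp2":
        return synthetic_scenes.generate_exp2(gen)
    raise ValueError(f"unknown preset {config.preset!r}")


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage, writing one JSON report per stage plus a
    combined summary and a MANIFEST recording completion state.

    Any stage error aborts the run; previously written outputs stay on disk
    and the MANIFEST names the failed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"preset": config.preset, "completed": [], "failed": None}
    summary: dict = {
        "preset": config.preset,
        "seeds": {"generation": config.seed,
                  "baseline": config.baseline_seed},
        "generator_config": (config_to_dict(config.generator_config())
                             if config.data_dir is None else None),
    }

    def finish(stage, err=None):
        if err is None:
            manifest["completed"].append(stage)
        else:
            manifest["failed"] = {"stage": stage, "error": str(err)}
        _dump(manifest, out / "MANIFEST.json")
        if err is not None:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    try:
        ds = obtain_dataset(config)
    except Exception as e:  # noqa: BLE001
        finish("generate", e)
    write_dataset(ds, out / "data")
    summary["inputs_hash"] = _hash_placements(ds.placements)
    finish("generate")

    report = scene_model.validate_dataset(ds)
    if not report.ok:
        _dump({"violations": report.violations}, out / "validation.json")
        finish("validate", ValidationFailure(
            f"{len(report.violations)} violations"))
    _dump({"violations": []}, out / "validation.json")
    finish("validate")

    build = ds.placements[ds.placements.phase == "build"]
    has_recall = (ds.placements.phase == "recall").any()

    if "memory" in config.stages and has_recall:
        try:
            mem = memory_report(build,
                                ds.placements[ds.placements.phase == "recall"],
                                seed=config.baseline_seed)
        except Exception as e:  # noqa: BLE001
            finish("memory", e)
        mem["records"].to_csv(out / "displacements.csv", index=False,
                              float_format="%.12g")
        _dump(_jsonable({k: v for k, v in mem.items()
                         if k not in ("records", "cells")}
                        | {"inputs_hash": summary["inputs_hash"]}),
              out / "memory.json")
        summary["memory"] = _jsonable(
            {"mean_displacement_m": mem["mean_displacement_m"],
             "contrasts": mem["contrasts"]})
        finish("memory")

    table = None
    if "pairs" in config.stages:
        try:
            pr = pairing_report(build, ordered=config.ordered_pairs)
        except Exception as e:  # noqa: BLE001
            finish("pairs", e)
        pr["pairs"].to_csv(out / "pairs.csv", index=False,
                           float_format="%.12g")
        pr["table"].to_csv(out / "pairfreq.csv", index=False)
        table = pr["table"]
        _dump(_jsonable({k: v for k, v in pr.items()
                         if k not in ("pairs", "table")}
                        | {"inputs_hash": summary["inputs_hash"]}),
              out / "pairs.json")
        summary["pairs"] = _jsonable(
            {"contrast": pr["contrast"], "mean_count": pr["mean_count"],
             "max_count": pr["max_count"]})
        finish("pairs")

    if "zipf" in config.stages and table is not None:
        try:
            zr = zipf_report(table)
        except Exception as e:  # noqa: BLE001
            finish("zipf", e)
        rf_rows = [
            {"condition": cond, "rank": int(r), "frequency": int(f)}
            for cond, res in zr.items()
            for r, f in zip(res["rank_frequency"].ranks,
                            res["rank_frequency"].frequencies)
        ]
        pd.DataFrame(rf_rows).to_csv(out / "rankfreq.csv", index=False)
        _dump(_jsonable({
            cond: {"zm": res["zm"].as_dict(), "zipf": res["zipf"].as_dict(),
                   "gof": res["gof"], "head_ratio": res["head_ratio"]}
            for cond, res in zr.items()} |
            {"inputs_hash": summary["inputs_hash"]}),
            out / "zipf.json")
        summary["zipf"] = _jsonable({
            cond: {"alpha": res["zm"].alpha, "beta": res["zm"].beta,
                   "gof_p": res["gof"]["p"]}
            for cond, res in zr.items()})
        finish("zipf")

    if "interact" in config.stages and len(ds.grabs):
        try:
            ir = interaction_report(
                ds.grabs, ds.searches if len(ds.searches) else None)
        except Exception as e:  # noqa: BLE001
            finish("interact", e)
        ir["first_grab_density"].to_csv(out / "first_grab_density.csv",
                                        index=False, float_format="%.12g")
        keep = {k: _jsonable(v) for k, v in ir.items()
                if not isinstance(v, pd.DataFrame)}
        _dump(keep | {"inputs_hash": summary["inputs_hash"]},
              out / "interact.json")
        summary["interact"] = keep
        finish("interact")

    _dump(_jsonable(summary), out / "summary.json")
    finish("summary")
    return summary
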