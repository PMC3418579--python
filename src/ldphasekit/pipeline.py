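"""End-to-end pipeline: simulate -> qc -> ld -> decay -> phase -> ne.

A single flat-key configuration drives every stage; the resolved config,
all produced files (with content hashes), and per-stage counts land in a
JSON manifest so a run is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import decay, ld, ne, phase, qc
from .panel_io import read_ped_map, write_ped_map, write_table
from .simulate import SimConfig, simulate_study

log = logging.getLogger("ldphasekit")

ALL_STAGES = ("simulate", "qc", "ld", "decay", "phase", "ne")


@dataclass
class RunConfig:
    stages: tuple = ALL_STAGES
    out_dir: str = "ldphase_run"
    seed: int = 0
    # simulation (used when 'simulate' is among the stages)
    sim: SimConfig = field(default_factory=SimConfig)
    # QC thresholds
    hwe_p: float = 0.01
    call_rate: float = 0.95
    maf: float = 0.05
    # LD estimation
    min_pair_n: int = 30
    max_distance_bp: int = 10_000_000
    # decay summaries
    bin_scheme: str = "table3"
    r2_threshold: float = 0.3
    # phase persistence
    min_r2_phase: float = 0.3
    # Ne trajectory
    generation_grid: tuple = (10, 25, 50, 100, 250, 500, 1000, 2000)
    correct_sample_size: bool = True
    # external inputs (label -> (ped, map)) for non-simulated runs
    inputs: dict = field(default_factory=dict)

    def flatten(self) -> dict:
        d = asdict(self)
        sim = d.pop("sim")
        d.update({f"sim.{k}": v for k, v in sim.items()})
        return d

    @classmethod
    def from_flat(cls, flat: dict) -> "RunConfig":
        sim_kwargs, run_kwargs = {}, {}
        for k, v in flat.items():
            if k.startswith("sim."):
                sim_kwargs[k[4:]] = v
            else:
                run_kwargs[k] = v
        for key in ("ne_schedule", "sample_sizes"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in sim_kwargs[key]
                )
        for key in ("stages", "generation_grid"):
            if key in run_kwargs:
                run_kwargs[key] = tuple(run_kwargs[key])
        return cls(sim=SimConfig(**sim_kwargs), **run_kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    produced: list[Path] = []
    counts: dict = {}
    panels: dict = {}
    maps: dict = {}
    ld_records: dict = {}
    try:
        stage = "simulate"
        if "simulate" in config.stages:
            sim_cfg = SimConfig(**{**config.sim.__dict__, "seed": config.seed})
            study = simulate_study(sim_cfg)
            for label in study.panels:
                ped = out / f"{label}.ped"
                mp = out / f"{label}.map"
                write_ped_map(study.panels[label], study.maps[label], ped, mp)
                produced += [ped, mp, mp.with_suffix(".map.alleles.json")]
                panels[label], maps[label] = study.panels[label], study.maps[label]
                counts[f"simulate.{label}.markers"] = study.maps[label].n_markers
                counts[f"simulate.{label}.individuals"] = study.panels[label].n_individuals
            truth_path = out / "truth.tsv"
            study.truth.to_csv(truth_path, sep="\t", index=False)
            produced.append(truth_path)
        elif config.inputs:
            for label, (ped, mp) in config.inputs.items():
                if not Path(ped).exists() or not Path(mp).exists():
                    raise FileNotFoundError(f"input for '{label}' not found: {ped}, {mp}")
                panels[label], maps[label] = read_ped_map(ped, mp)
        else:
            raise ValueError("no simulate stage and no external inputs configured")
        log.info("panels ready: %s", {k: p.n_individuals for k, p in panels.items()})

        stage = "qc"
        if "qc" in config.stages:
            th = {"hwe_p": config.hwe_p, "call_rate": config.call_rate, "maf": config.maf}
            for label in list(panels):
                panels[label], maps[label], report = qc.apply_qc(
                    panels[label], maps[label], th
                )
                path = out / f"{label}.qc_report.tsv"
                write_table(report.to_frame(), path, kind="qc_report")
                produced.append(path)
                counts[f"qc.{label}.survivors"] = len(report.survivors)
                for filt, n in report.removal_counts.items():
                    counts[f"qc.{label}.removed.{filt}"] = n
                log.info("qc %s: %d survivors of %d", label,
                         len(report.survivors), report.n_input)

        stage = "ld"
        if "ld" in config.stages:
            for label in panels:
                rec = ld.pairwise_ld(
                    panels[label], maps[label],
                    max_distance_bp=config.max_distance_bp,
                    min_pair_n=config.min_pair_n,
                )
                ld_records[label] = rec
                path = out / f"{label}.ld.tsv"
                write_table(rec, path, kind="ld")
                produced.append(path)
                counts[f"ld.{label}.pairs"] = len(rec)
                log.info("ld %s: %d pairs", label, len(rec))

        stage = "decay"
        if "decay" in config.stages and ld_records:
            scheme = (
                decay.figure2_scheme()
                if config.bin_scheme == "figure2"
                else decay.table3_scheme()
            )
            frames = []
            for label, rec in ld_records.items():
                binned = decay.assign_bins(rec, scheme)
                frames.append(decay.summarize(binned, threshold=config.r2_threshold,
                                              population=label))
            summary = pd.concat(frames, ignore_index=True)
            path = out / "decay_summary.tsv"
            write_table(summary, path, kind="decay_summary")
            produced.append(path)
            if len(ld_records) >= 2:
                stacked = pd.concat(
                    [rec.assign(population=label) for label, rec in ld_records.items()],
                    ignore_index=True,
                )
                fit = decay.fit_decay_model(stacked)
                anova_path = out / "anova.tsv"
                fit.anova.to_csv(anova_path, sep="\t")
                produced.append(anova_path)
                counts["decay.distance_slope"] = fit.distance_slope

        stage = "phase"
        if "phase" in config.stages and len(ld_records) >= 2:
            rows = []
            for la, lb in itertools.combinations(sorted(ld_records), 2):
                matched = phase.match_pairs(
                    ld_records[la], ld_records[lb],
                    orientation_a=maps[la].orientation(),
                    orientation_b=maps[lb].orientation(),
                )
                rows.append(
                    phase.phase_correlation(
                        matched, min_r2=config.min_r2_phase,
                        population_pair=f"{la}-{lb}",
                    )
                )
                counts[f"phase.{la}-{lb}.matched"] = len(matched)
            path = out / "phase.tsv"
            write_table(pd.concat(rows, ignore_index=True), path, kind="phase")
            produced.append(path)

        stage = "ne"
        if "ne" in config.stages and ld_records:
            for label, rec in ld_records.items():
                traj = ne.ne_trajectory(
                    rec, config.generation_grid,
                    sample_n=2 * panels[label].n_individuals,
                    correct_sample_size=config.correct_sample_size,
                )
                path = out / f"{label}.ne.tsv"
                write_table(traj, path, kind="ne")
                produced.append(path)
                counts[f"ne.{label}.points"] = len(traj)
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        log.removeHandler(handler)
        handler.close()
        raise StageError(stage, exc) from exc

    manifest = {
        "config": config.flatten(),
        "files": {str(p.relative_to(out)): _sha256(p) for p in produced},
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.removeHandler(handler)
    handler.close()
    return manifest
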