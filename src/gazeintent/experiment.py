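"""End-to-end experiment orchestration and report assembly.

One experiment: simulate sessions -> preprocess into streams and windows ->
train one or more architectures -> pick each network's operating threshold
on the validation stream -> evaluate on the continuous test stream ->
write metrics, threshold curves, per-timestep records, earliness (TAMC)
summaries and a cross-architecture comparison table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import evaluation, kinematics, networks, preprocess, simulate, training

log = logging.getLogger("gazeintent")


@dataclass
class ArchSpec:
    name: str
    kind: str
    config: object


@dataclass
class ExperimentConfig:
    n_sessions: int = 4
    seed: int = 0
    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    profile: simulate.ParticipantProfile = field(default_factory=simulate.ParticipantProfile)
    window: preprocess.WindowSpec = field(default_factory=preprocess.WindowSpec)
    ue: networks.UEConfig = field(default_factory=networks.UEConfig)
    train: training.TrainConfig = field(default_factory=training.TrainConfig)
    architectures: list[ArchSpec] = field(default_factory=lambda: [
        ArchSpec("Enc1", *networks.REFERENCE_CONFIGS["Enc1"])])
    n_passes: int = 30
    n_p: int = 10          # evaluate every n_p-th timestep of the streams
    tamc_reference_length: float = 151.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["architectures"] = [{"name": a.name, "kind": a.kind, "config": asdict(a.config)}
                              for a in self.architectures]
        return networks._pyify(d)


def simulate_sessions(cfg: ExperimentConfig) -> list[simulate.SessionLog]:
    root = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(cfg.n_sessions)]
    return [simulate.simulate_session(cfg.sim, cfg.profile, s) for s in seeds]


def run_experiment(cfg: ExperimentConfig, outdir: str | Path) -> dict:
    """Run the full pipeline; returns the report dict (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_dict(), "networks": {}}

    def stage(name):
        log.info("stage: %s", name)
        return time.perf_counter()

    t = stage("simulate")
    logs = simulate_sessions(cfg)
    report["simulate_seconds"] = time.perf_counter() - t

    t = stage("preprocess")
    try:
        ds = preprocess.prepare_datasets(logs, cfg.window)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[preprocess] {exc}") from exc
    report["preprocess_seconds"] = time.perf_counter() - t
    report["filter"] = asdict(ds.filter_stats)
    report["n_windows"] = {"train": len(ds.train), "val": len(ds.val), "test": len(ds.test)}

    rows = []
    for arch in cfg.architectures:
        name = arch.name
        t = stage(f"train {name}")
        try:
            net, hist = training.train_with_restarts(
                arch.kind, arch.config, cfg.ue, ds.train, ds.val, cfg.train)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"[train:{name}] {exc}") from exc
        networks.save_network(net, outdir / f"checkpoint_{name}",
                              extra={"norm_min": ds.norm.minimum.tolist(),
                                     "norm_max": ds.norm.maximum.tolist()})
        train_s = time.perf_counter() - t

        t = stage(f"threshold scan {name}")
        th_l, a_i, scan = evaluation.threshold_scan(
            net, ds.val_stream, n_passes=cfg.n_passes, n_p=cfg.n_p,
            rng=np.random.default_rng(cfg.seed + 1))
        scan.curves_frame().to_csv(outdir / f"curves_{name}.csv", index=False)

        t2 = stage(f"continuous eval {name}")
        se = evaluation.continuous_stream_eval(
            net, ds.test_stream, th_l, n_passes=cfg.n_passes, n_p=cfg.n_p,
            rng=np.random.default_rng(cfg.seed + 2))
        se.to_frame().to_csv(outdir / f"streameval_{name}.csv", index=False)
        metrics = evaluation.compute_metrics(se)

        times = kinematics.first_correct_times(se)
        tamc = None
        if times:
            tamc = kinematics.tamc_report(times, cfg.tamc_reference_length, cfg.sim.f_s)
            pd.DataFrame({"movement": list(times), "normalized_time": list(times.values())}
                         ).to_csv(outdir / f"tamc_times_{name}.csv", index=False)
            with open(outdir / f"tamc_{name}.json", "w") as fh:
                json.dump({"percentiles": tamc.percentiles, "ms_ahead": tamc.ms_ahead,
                           "reference_length": tamc.reference_length}, fh, indent=2)

        entry = {"kind": arch.kind, "P": net.n_parameters(),
                 "Th_L": th_l, "A_I_val": a_i, **metrics.to_dict(),
                 "epochs": len(hist.train_loss), "best_epoch": hist.best_epoch,
                 "train_seconds": train_s,
                 "eval_seconds": time.perf_counter() - t2}
        if tamc is not None:
            entry["tamc_percentiles"] = tamc.percentiles
        report["networks"][name] = entry
        with open(outdir / f"metrics_{name}.json", "w") as fh:
            json.dump(networks._pyify(entry), fh, indent=2)
        rows.append({"Network": name, "Th_L": round(th_l, 2),
                     "A_P": metrics.A_P, "A_M": metrics.A_M, "A_VP": metrics.A_VP,
                     "P": net.n_parameters()})

    pd.DataFrame(rows).to_csv(outdir / "comparison.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(networks._pyify(report), fh, indent=2)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    return report


def reevaluate_from_checkpoint(prefix: str | Path, stream: preprocess.FeatureStream,
                               th_l: float, n_passes: int = 30, n_p: int = 10,
                               seed: int = 0) -> evaluation.MetricsReport:
    """Reload a checkpoint and recompute metrics on a stream (round-trip audit)."""
    net = networks.load_network(prefix)
    se = evaluation.continuous_stream_eval(net, stream, th_l, n_passes=n_passes,
                                           n_p=n_p, rng=np.random.default_rng(seed))
    return evaluation.compute_metrics(se)
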