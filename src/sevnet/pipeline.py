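"""Staged pipeline: simulate -> metrics -> aggregate -> mine -> regress
-> tertiles -> sweep, with a machine-readable report.

Every stage is a pure function of its declared inputs plus the single run
seed, so re-running with the same config is bit-identical.  Stage outputs
are plain CSV/GeoJSON/JSON files in the output directory; a serialized
copy of the config is always written alongside them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .aggregation import DEFAULT_BUFFER_M, build_unit_table
from .network import SpatialNetwork
from .radial import DEFAULT_RADII, compute_link_metrics, metric_column
from .stats import ols_standardized, pearson_screen, radius_sweep, tertile_models
from .synthetic import GeneratorSpec, simulate

logger = logging.getLogger("sevnet")

__all__ = ["RunConfig", "run"]

ALL_STAGES = ("simulate", "metrics", "aggregate", "mine", "regress", "tertiles", "sweep")


@dataclass
class RunConfig:
    out_dir: str = "sevnet_out"
    network_path: str | None = None
    units_path: str | None = None
    outcomes_path: str | None = None
    metrics_path: str | None = None      # precomputed metric CSV (skip engine)
    unit_table_path: str | None = None   # precomputed unit table (skip aggregation)
    radii: tuple = tuple(DEFAULT_RADII)
    sweep_radii: tuple = tuple(range(100, 1501, 100))
    continuous: bool = True
    buffer_m: float = DEFAULT_BUFFER_M
    bonferroni_factor: int | None = None
    seed: int = 0
    stages: tuple = ALL_STAGES
    simulate_spec: dict = field(default_factory=dict)
    sweep_plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for key in ("radii", "sweep_radii", "stages"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("radii", "sweep_radii", "stages"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _load_network(cfg: RunConfig, out: Path) -> SpatialNetwork:
    path = cfg.network_path or out / "network.geojson"
    return sio.read_network_geojson(path)


def _load_units(cfg: RunConfig, out: Path):
    upath = cfg.units_path or out / "units.geojson"
    opath = cfg.outcomes_path or out / "outcomes.csv"
    units = sio.read_units_geojson(upath)
    return sio.attach_outcomes(units, sio.read_outcomes_csv(opath))


def run(config: RunConfig) -> dict:
    """Execute the toggled stages in order and return the report dict.

    A stage failure raises with the failing stage named; outputs of the
    stages already completed are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"seed": config.seed, "stages": []}

    stage = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            spec = GeneratorSpec(**{**config.simulate_spec, "seed": config.seed})
            world = simulate(spec, buffer_m=config.buffer_m)
            sio.write_network_geojson(world.net, out / "network.geojson")
            sio.write_units_geojson(world.units, out / "units.geojson")
            sio.write_outcomes_csv(world.outcomes, out / "outcomes.csv")
            logger.info("simulate: %d links, %d districts",
                        world.net.n_links, len(world.units))
            report["stages"].append(stage)

        if "metrics" in config.stages:
            stage = "metrics"
            net = _load_network(config, out)
            rows = compute_link_metrics(net, config.radii, config.continuous)
            sio.write_metrics_csv(rows, out / "metrics.csv")
            logger.info("metrics: %d rows, %d dropped destinations",
                        len(rows), int(rows["n_dropped"].sum()))
            report["stages"].append(stage)
            report["n_dropped_destinations"] = int(rows["n_dropped"].sum())

        if "aggregate" in config.stages:
            stage = "aggregate"
            net = _load_network(config, out)
            units = _load_units(config, out)
            rows = sio.read_metrics_csv(config.metrics_path or out / "metrics.csv")
            table = build_unit_table(units, net, rows, config.buffer_m, config.continuous)
            table.to_csv(out / "unit_table.csv", index=False)
            logger.info("aggregate: %d units, %d with zero links",
                        len(table), int((table["n_links"] == 0).sum()))
            report["stages"].append(stage)

        table_path = config.unit_table_path or out / "unit_table.csv"

        if "mine" in config.stages:
            stage = "mine"
            table = pd.read_csv(table_path)
            screen = pearson_screen(
                table,
                radii=config.radii,
                continuous=config.continuous,
                bonferroni_factor=config.bonferroni_factor,
            )
            screen.table.to_csv(out / "screen.csv", index=False)
            report["stages"].append(stage)
            report["screen"] = {
                "best": screen.best,
                "bonferroni_factor": screen.bonferroni_factor,
                "relaxed_factor": screen.relaxed_factor,
                "n": int(screen.table["n"].max()),
            }

        hull_col = metric_column("HullR", 600, config.continuous)

        if "regress" in config.stages:
            stage = "regress"
            table = pd.read_csv(table_path)
            models = {
                "cohesion ~ deprivation + HullR600c + urban":
                    ["deprivation", hull_col, "urban"],
                "cohesion ~ deprivation": ["deprivation"],
                "cohesion ~ HullR600c": [hull_col],
                "cohesion ~ urban": ["urban"],
            }
            summary, coef_rows = [], []
            for name, preds in models.items():
                res = ols_standardized(table["cohesion"], table[preds])
                summary.append({"model": name, "r2": res.r2,
                                "adj_r2": res.adj_r2, "n": res.n})
                for pred in preds:
                    coef_rows.append({
                        "model": name, "predictor": pred,
                        "coef": res.coef[pred], "se": res.bse[pred],
                        "t": res.tvalues[pred], "p": res.pvalues[pred],
                    })
            pd.DataFrame(summary).to_csv(out / "model_summary.csv", index=False)
            pd.DataFrame(coef_rows).to_csv(out / "coefficients.csv", index=False)
            report["stages"].append(stage)
            report["models"] = summary

        if "tertiles" in config.stages:
            stage = "tertiles"
            table = pd.read_csv(table_path)
            tert = tertile_models(table, predictor=hull_col)
            rows = []
            for t, res in enumerate(tert.models):
                row = {"tertile": t, "r2": res.r2, "r": tert.bivariate_r[t],
                       "n": res.n, "dropped": ";".join(res.dropped)}
                for pred in res.predictors:
                    row[f"coef_{pred}"] = res.coef[pred]
                    row[f"p_{pred}"] = res.pvalues[pred]
                rows.append(row)
            pd.DataFrame(rows).to_csv(out / "tertiles.csv", index=False)
            report["stages"].append(stage)
            report["tertiles"] = rows

        if "sweep" in config.stages:
            stage = "sweep"
            net = _load_network(config, out)
            units = _load_units(config, out)
            curve, best_r = radius_sweep(
                net, units, config.sweep_radii,
                buffer_m=config.buffer_m, continuous=config.continuous,
            )
            curve.to_csv(out / "sweep.csv", index=False)
            report["stages"].append(stage)
            report["sweep"] = {"best_radius_m": best_r}
            if config.sweep_plot:
                import matplotlib

                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                fig, ax = plt.subplots(figsize=(6, 4))
                ax.plot(curve["radius_m"], curve["r"], marker="o")
                ax.set_xlabel("network radius (m)")
                ax.set_ylabel("Pearson r with cohesion")
                ax.set_title("HullR vs cohesion across spatial scales")
                fig.tight_layout()
                fig.savefig(out / "sweep.png", dpi=150)
                plt.close(fig)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
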