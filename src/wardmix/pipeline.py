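"""End-to-end orchestration: simulate/load -> networks -> metrics -> mixing.

A run is driven by one :class:`RunConfig` (usually loaded from YAML) and a
single seed that fans out deterministically to every stochastic stage, so
one number reproduces a whole run.  All outputs are plain CSV/JSON (plus
optional PNG heatmaps); the returned manifest lists every artifact with
the config echo, package version and per-stage record counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

import wardmix
from wardmix.contact_network import build_network, export_edge_list, multiward_summary
from wardmix.encounter_model import EncounterBundle, read_bundle_dir, write_bundle, validate_bundle
from wardmix.mixing import (
    Scope,
    abx_mixing,
    abx_none_ratio,
    age_mixing,
    elixhauser_mixing,
    normalize,
    plot_matrix,
)
from wardmix.network_metrics import compute_metrics, metric_size_regression
from wardmix.synthetic_data import ARCHETYPES, archetype_config, generate_multi

log = logging.getLogger("wardmix")

AXES = ("age", "elixhauser", "abx")


@dataclass
class RunConfig:
    mode: str  # "synthetic" | "csv"
    window: tuple[date, date]
    out_dir: Path
    seed: int = 0
    archetypes: tuple[str, ...] = ()  # synthetic mode
    n_admissions: int = 400  # per archetype, synthetic mode
    data_dir: Path | None = None  # csv mode
    hospitals: tuple[str, ...] | None = None  # optional filter
    axes: tuple[str, ...] = AXES
    abx_timing: str = "per_day"
    plot: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "csv" and self.data_dir is None:
            raise ValueError("csv mode requires data_dir")
        if self.mode == "synthetic" and not self.archetypes:
            raise ValueError("synthetic mode requires at least one archetype")
        if self.window[0] > self.window[1]:
            raise ValueError("empty window")
        bad = set(self.axes) - set(AXES)
        if bad:
            raise ValueError(f"unknown axes {sorted(bad)}; options {AXES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            mode=d["mode"],
            window=(date.fromisoformat(d["window"][0]),
                    date.fromisoformat(d["window"][1])),
            out_dir=Path(d["out_dir"]),
            seed=int(d.get("seed", 0)),
            archetypes=tuple(d.get("archetypes", ())),
            n_admissions=int(d.get("n_admissions", 400)),
            data_dir=Path(d["data_dir"]) if d.get("data_dir") else None,
            hospitals=tuple(d["hospitals"]) if d.get("hospitals") else None,
            axes=tuple(d.get("axes", AXES)),
            abx_timing=d.get("abx_timing", "per_day"),
            plot=bool(d.get("plot", False)),
            log_level=d.get("log_level", "INFO"),
        )

    def echo(self) -> dict:
        # out_dir is deliberately omitted: the manifest lives inside it,
        # and two runs of one config into different directories must
        # produce byte-identical manifests
        return {
            "mode": self.mode,
            "window": [self.window[0].isoformat(), self.window[1].isoformat()],
            "seed": self.seed,
            "archetypes": list(self.archetypes),
            "n_admissions": self.n_admissions,
            "data_dir": str(self.data_dir) if self.data_dir else None,
            "hospitals": list(self.hospitals) if self.hospitals else None,
            "axes": list(self.axes),
            "abx_timing": self.abx_timing,
            "plot": self.plot,
        }


def _load_bundle(config: RunConfig) -> EncounterBundle:
    if config.mode == "csv":
        return read_bundle_dir(config.data_dir)
    configs = []
    for i, name in enumerate(config.archetypes):
        if name not in ARCHETYPES:
            raise ValueError(f"unknown archetype {name!r}; options {ARCHETYPES}")
        configs.append(archetype_config(name, config.n_admissions, config.seed + i))
    return generate_multi(configs)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; return (and write) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": wardmix.__version__,
        "seed": config.seed,
        "config": config.echo(),
        "outputs": {},
        "counts": {},
    }

    try:
        bundle = _load_bundle(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'load': {exc}") from exc
    violations = validate_bundle(bundle)
    if violations:
        raise RuntimeError(
            f"stage 'validate': {len(violations)} invariant violation(s); "
            f"first: {violations[0]}"
        )
    manifest["counts"]["admissions"] = len(bundle.admissions)
    manifest["counts"]["stays"] = len(bundle.stays)
    manifest["counts"]["exposures"] = len(bundle.exposures)
    log.info("loaded %d admissions, %d stays, %d exposures",
             len(bundle.admissions), len(bundle.stays), len(bundle.exposures))

    if config.mode == "synthetic":
        paths = write_bundle(bundle, out / "bundle")
        manifest["outputs"]["bundle"] = {
            k: str(v.relative_to(out)) for k, v in paths.items()
        }

    hospitals = config.hospitals or bundle.hospital_ids()
    metrics_rows = []
    total_events = 0
    for hid in hospitals:
        try:
            net = build_network(bundle, hid, config.window)
        except Exception as exc:
            raise RuntimeError(f"stage 'build-network' ({hid}): {exc}") from exc
        edge_path = out / f"network_{hid}.csv"
        export_edge_list(net, edge_path)
        manifest["outputs"][f"network_{hid}"] = str(edge_path.relative_to(out))
        total_events += sum(net.edge_weights().values())

        m = compute_metrics(net)
        mw = multiward_summary(net, bundle.stays_for_hospital(hid))
        n_patients = len(
            {a.patient_id for a in bundle.admissions
             if a.hospital_id == hid and a.admission_id in net.graph}
        )
        row = {"hospital_id": hid, "n_patients": n_patients, **m.as_dict(),
               "pct_multiunit_admissions": mw["pct_multiunit_admissions"],
               "pct_edges_touching_multiunit": mw["pct_edges_touching_multiunit"]}
        metrics_rows.append(row)
        log.info("%s: %d nodes, %d edges", hid, m.n_nodes, m.n_edges)

        scope = Scope(hospital_id=hid, window=config.window)
        for axis in config.axes:
            try:
                if axis == "age":
                    mat = age_mixing(bundle, scope)
                elif axis == "elixhauser":
                    mat = elixhauser_mixing(bundle, scope)
                else:
                    mat = abx_mixing(bundle, scope, timing_policy=config.abx_timing)
            except Exception as exc:
                raise RuntimeError(f"stage 'mixing' ({hid}, {axis}): {exc}") from exc
            mat = normalize(mat)
            mat_path = out / f"mixing_{hid}_{axis}.csv"
            mat.to_long().to_csv(mat_path, index=False)
            manifest["outputs"][f"mixing_{hid}_{axis}"] = str(mat_path.relative_to(out))
            if config.plot:
                png = out / f"mixing_{hid}_{axis}.png"
                plot_matrix(mat, png)
                manifest["outputs"][f"mixing_{hid}_{axis}_png"] = str(png.relative_to(out))
        if "abx" in config.axes:
            nr = abx_none_ratio(bundle, scope)
            manifest["counts"][f"abx_none_ratio_{hid}"] = nr["ratio"]

    manifest["counts"]["contact_events"] = total_events
    metrics_df = pd.DataFrame(metrics_rows)
    metrics_path = out / "network_metrics.csv"
    metrics_df.to_csv(metrics_path, index=False)
    manifest["outputs"]["network_metrics"] = str(metrics_path.relative_to(out))

    if len(metrics_rows) >= 3:
        reg_rows = []
        for metric in ("density", "mean_degree", "mean_betweenness"):
            sizes = metrics_df["n_patients"].to_numpy(dtype=float)
            if len(set(sizes)) > 1:
                res = metric_size_regression(
                    list(zip(sizes, metrics_df[metric].to_numpy(dtype=float)))
                )
                reg_rows.append({
                    "metric": metric,
                    "slope_per_100_patients": res.slope_per_100,
                    "ci95_low": res.ci95[0],
                    "ci95_high": res.ci95[1],
                    "p_value": res.p_value,
                    "n": res.n,
                })
        if reg_rows:
            reg_path = out / "size_regression.csv"
            pd.DataFrame(reg_rows).to_csv(reg_path, index=False)
            manifest["outputs"]["size_regression"] = str(reg_path.relative_to(out))

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = str(manifest_path.relative_to(out))
    return manifest
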