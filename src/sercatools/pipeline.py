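"""Config-driven orchestration of the full analysis battery.

One YAML config drives everything: for each trajectory (typically a
lipid-bound / lipid-free pair) the pipeline computes distance series and
occupancies, histograms, H-bond occupancies, RMSD time series, per-segment
RMSD profiles, conformational clustering, Cartesian PCA with Gaussianity
classification and inner products, and water-wire events.  Outputs are
per-analysis TSV tables, a comparative JSON summary that always carries
both trajectories' values side by side (with the crystal-reference column
when provided), and a log recording versions, seed and config hash — plus
the hydrogen-bond criterion and named-atom conventions actually used,
since those are the main unstated conventions in this kind of analysis.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import (
    HBondCriteria,
    distance_series,
    hbond_occupancy,
    histogram,
    occupancy,
)
from .core import SercatoolsError, Trajectory
from .io import default_segment_map, load_segment_map, read_structure, read_trajectory, write_structure
from .metrics import cluster_conformations, rmsd_timeseries, segment_rmsd_profile
from .pca import classify_gaussianity, components_needed, fit_pca, inner_products, project, variance_accounting
from .selection import select
from .wires import WireConfig, detect_events, lifetime_stats

__all__ = ["AnalysisConfig", "load_config", "validate_config", "run"]


class ConfigError(SercatoolsError):
    pass


@dataclass
class AnalysisConfig:
    """Parsed analysis configuration; see ``load_config`` for the schema."""

    structure: str
    trajectories: dict[str, str]
    output_dir: str
    frame_interval_ps: float | None = None
    segments: str | None = None            # path to a segment map, or None
    distances: list[dict] = field(default_factory=list)
    hbonds: list[dict] = field(default_factory=list)
    hbond_criteria: dict = field(default_factory=dict)
    rmsd: list[dict] = field(default_factory=list)
    segment_profile: dict | None = None
    cluster: dict | None = None
    pca: dict | None = None
    wires: list[dict] = field(default_factory=list)
    seed: int = 0
    raw: dict = field(default_factory=dict, repr=False)


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        cfg = AnalysisConfig(
            structure=raw["structure"],
            trajectories=dict(raw["trajectories"]),
            output_dir=raw.get("output_dir", "analysis_out"),
            frame_interval_ps=raw.get("frame_interval_ps"),
            segments=raw.get("segments"),
            distances=raw.get("distances", []) or [],
            hbonds=raw.get("hbonds", []) or [],
            hbond_criteria=raw.get("hbond_criteria", {}) or {},
            rmsd=raw.get("rmsd", []) or [],
            segment_profile=raw.get("segment_profile"),
            cluster=raw.get("cluster"),
            pca=raw.get("pca"),
            wires=raw.get("wires", []) or [],
            seed=int(raw.get("seed", 0)),
            raw=raw,
        )
    except KeyError as k:
        raise ConfigError(f"{path}: missing required config key {k}")
    return cfg


def _criteria(cfg: AnalysisConfig) -> HBondCriteria:
    c = cfg.hbond_criteria
    return HBondCriteria(
        d_max=float(c.get("d_max_nm", 0.35)),
        angle_min=float(c.get("angle_min_deg", 150.0)),
    )


def validate_config(cfg: AnalysisConfig) -> list[str]:
    """Parse all selections against the topology before any computation.

    Returns the list of selection expressions checked; raises ConfigError
    on the first one that fails (e.g. an undefined segment label).
    """
    top, _ = read_structure(cfg.structure)
    if cfg.segments:
        segmap = load_segment_map(cfg.segments)
    else:
        segmap = default_segment_map()
    try:
        top = top.with_segments(
            {k: v for k, v in segmap.items()
             if any(r in set(top.resids.tolist())
                    for lo, hi in v for r in range(lo, hi + 1))}
        )
    except SercatoolsError:
        pass
    checked: list[str] = []

    def check(expr: str, where: str):
        try:
            select(top, expr)
        except SercatoolsError as err:
            raise ConfigError(f"{where}: invalid selection {expr!r}: {err}")
        checked.append(expr)

    for d in cfg.distances:
        check(d["selA"], f"distances[{d.get('label')}]")
        check(d["selB"], f"distances[{d.get('label')}]")
    for h in cfg.hbonds:
        check(h["donor"], f"hbonds[{h.get('label')}]")
        check(h["acceptor"], f"hbonds[{h.get('label')}]")
    for r in cfg.rmsd:
        check(r["fit_sel"], f"rmsd[{r.get('label')}]")
        if r.get("measure_sel"):
            check(r["measure_sel"], f"rmsd[{r.get('label')}]")
    if cfg.segment_profile:
        check(cfg.segment_profile["fit_sel"], "segment_profile")
        for lab in cfg.segment_profile["segments"]:
            if lab not in top.segments:
                raise ConfigError(f"segment_profile: undefined segment {lab!r}")
    if cfg.cluster:
        check(cfg.cluster["sel"], "cluster")
    if cfg.pca:
        check(cfg.pca["sel"], "pca")
        if cfg.pca.get("fit_sel"):
            check(cfg.pca["fit_sel"], "pca")
    for w in cfg.wires:
        check(w["source"], f"wires[{w.get('label')}]")
        if w.get("sink"):
            check(w["sink"], f"wires[{w.get('label')}]")
    for d in cfg.distances:
        for lo, hi in d.get("occupancy_intervals", []):
            if lo < 0 or hi <= lo:
                raise ConfigError(
                    f"bad occupancy interval [{lo}, {hi}] in "
                    f"distances[{d.get('label')}]"
                )
    return checked


def _config_hash(cfg: AnalysisConfig) -> str:
    canon = json.dumps(cfg.raw, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run(cfg: AnalysisConfig) -> dict:
    """Execute the full battery; returns (and writes) the summary dict."""
    validate_config(cfg)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    top, ref_frame = read_structure(cfg.structure)
    segmap = load_segment_map(cfg.segments) if cfg.segments else default_segment_map()
    present = set(top.resids.tolist())
    segmap = {k: v for k, v in segmap.items()
              if any(r in present for lo, hi in v for r in range(lo, hi + 1))}
    if segmap:
        top = top.with_segments(segmap)
    criteria = _criteria(cfg)
    summary: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": {
            "sercatools": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
        "hbond_criteria": {"d_max_nm": criteria.d_max,
                           "angle_min_deg": criteria.angle_min},
        "trajectories": {},
    }
    log_lines = [f"sercatools {__version__}; config hash {summary['config_hash']}; "
                 f"seed {cfg.seed}",
                 f"H-bond criterion: d <= {criteria.d_max} nm, "
                 f"angle >= {criteria.angle_min} deg (distance-only when no H)"]

    for name, traj_path in cfg.trajectories.items():
        stage = "read_trajectory"
        try:
            traj = read_trajectory(traj_path, top, cfg.frame_interval_ps)
            res = _analyze_one(cfg, name, traj, ref_frame, criteria, outdir)
        except SercatoolsError as err:
            raise SercatoolsError(
                f"stage {stage!r} failed for trajectory {name!r} ({traj_path}): {err}"
            ) from err
        summary["trajectories"][name] = res
    _write_comparative_tables(cfg, summary, outdir)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    log_lines.append(f"analyzed {len(cfg.trajectories)} trajectories")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _analyze_one(cfg, name, traj: Trajectory, ref_frame, criteria, outdir: Path) -> dict:
    top = traj.topology
    out: dict = {"n_frames": traj.n_frames}
    stage = None
    try:
        stage = "distances"
        dist_out = {}
        for d in cfg.distances:
            label = d.get("label") or f"{d['selA']}--{d['selB']}"
            series = distance_series(
                traj, select(top, d["selA"]), select(top, d["selB"]),
                mode=d.get("mode", "min-heavy-atom"), pair_label=label,
                reference_value=d.get("reference_nm"),
            )
            entry: dict = {"mean_nm": float(series.values.mean()),
                           "reference_nm": d.get("reference_nm")}
            for lo, hi in d.get("occupancy_intervals", []):
                occ = occupancy(series, (float(lo), float(hi)))
                entry[f"occupancy[{lo},{hi}]"] = occ.fraction
            hist = histogram(series, float(d.get("bin_width_nm", 0.025)))
            pd.DataFrame({"frame": np.arange(len(series)),
                          "R_nm": series.values}).to_csv(
                outdir / f"{name}_dist_{_slug(label)}.tsv", sep="\t", index=False)
            pd.DataFrame({"bin_left_nm": hist.bin_edges[:-1],
                          "bin_right_nm": hist.bin_edges[1:],
                          "density_per_nm": hist.densities}).to_csv(
                outdir / f"{name}_hist_{_slug(label)}.tsv", sep="\t", index=False)
            dist_out[label] = entry
        out["distances"] = dist_out

        stage = "hbonds"
        hb_out = {}
        for h in cfg.hbonds:
            label = h.get("label") or f"{h['donor']}--{h['acceptor']}"
            occ = hbond_occupancy(traj, select(top, h["donor"]),
                                  select(top, h["acceptor"]), criteria)
            hb_out[label] = {"percent": occ.percent, "criterion": occ.criterion}
        out["hbonds"] = hb_out

        stage = "rmsd"
        rmsd_out = {}
        for r in cfg.rmsd:
            label = r.get("label") or r["fit_sel"]
            fit = select(top, r["fit_sel"])
            measure = select(top, r["measure_sel"]) if r.get("measure_sel") else None
            ts = rmsd_timeseries(traj, ref_frame, fit, measure)
            pd.DataFrame({"time_ns": traj.times, "rmsd_nm": ts}).to_csv(
                outdir / f"{name}_rmsd_{_slug(label)}.tsv", sep="\t", index=False)
            rmsd_out[label] = {"mean_nm": float(ts.mean()), "sd_nm": float(ts.std())}
        out["rmsd"] = rmsd_out

        if cfg.segment_profile:
            stage = "segment_profile"
            sp = cfg.segment_profile
            prof = segment_rmsd_profile(
                traj, ref_frame, sp["segments"], select(top, sp["fit_sel"]),
                measure=sp.get("measure", "backbone"))
            pd.DataFrame({"segment": prof.labels,
                          "mean_rmsd_nm": prof.mean_rmsd,
                          "sd_rmsd_nm": prof.sd_rmsd}).to_csv(
                outdir / f"{name}_segment_rmsd.tsv", sep="\t", index=False)
            out["segment_profile"] = prof.as_dict()

        if cfg.cluster:
            stage = "cluster"
            cl = cluster_conformations(traj, select(top, cfg.cluster["sel"]),
                                       float(cfg.cluster.get("cutoff_nm", 0.1)))
            out["clusters"] = {
                "populations": cl.populations.tolist(),
                "representatives": [c.representative for c in cl.clusters],
            }
            rep = cl.clusters[0].representative
            write_structure(outdir / f"{name}_representative.pdb",
                            top, traj.frames[rep])

        if cfg.pca:
            stage = "pca"
            out["pca"] = _pca_stage(cfg, name, traj, top, ref_frame, outdir)

        stage = "wires"
        wire_out = {}
        for w in cfg.wires:
            label = w.get("label") or w["source"]
            wc = WireConfig(
                source_sel=select(top, w["source"]),
                sink_sel=select(top, w["sink"]) if w.get("sink") else None,
                bulk_z=w.get("bulk_z_nm"),
                max_bridging_waters=int(w.get("max_waters", 4)),
                hbond_criteria=criteria,
                gap_merge_frames=int(w.get("gap_merge_frames", 0)),
                pore_radius=w.get("pore_radius_nm", 0.8),
            )
            events = detect_events(traj, wc)
            st = lifetime_stats(events)
            pd.DataFrame(
                [{"start": e.start_frame, "end": e.end_frame,
                  "lifetime_ps": e.lifetime,
                  "path_resids": " ".join(map(str, e.example_path))}
                 for e in events]
            ).to_csv(outdir / f"{name}_wires_{_slug(label)}.tsv",
                     sep="\t", index=False)
            wire_out[label] = {
                "n_events": st.count,
                "mean_lifetime_ps": st.mean_lifetime,
                "min_lifetime_ps": st.min_lifetime,
                "max_lifetime_ps": st.max_lifetime,
            }
        out["wires"] = wire_out
    except SercatoolsError as err:
        raise SercatoolsError(f"stage {stage!r}: {err}") from err
    return out


def _pca_stage(cfg, name, traj, top, ref_frame, outdir: Path) -> dict:
    p = cfg.pca
    sel = select(top, p["sel"])
    fit_sel = select(top, p["fit_sel"]) if p.get("fit_sel") else None
    model = fit_pca(traj, sel,
                    fit_reference=ref_frame if fit_sel is not None else None,
                    fit_sel=fit_sel)
    k = int(p.get("n_components", 10))
    k = min(k, model.n_components)
    curve = variance_accounting(model)
    res: dict = {
        "eigenvalues_nm2": model.eigenvalues[:k].tolist(),
        "variance_fractions": (model.eigenvalues[:k] / model.eigenvalues.sum()).tolist(),
        "cumulative_variance": curve[:k].tolist(),
        "components_needed": {
            str(f): components_needed(model, float(f))
            for f in p.get("variance_targets", [0.9, 0.95])
        },
        "classifications": [],
    }
    rows = []
    for j in range(k):
        proj = project(traj, model, j)
        fit = classify_gaussianity(proj, int(p.get("n_bins", 50)))
        res["classifications"].append(
            {"component": j + 1, "r_squared": fit.r_squared,
             "class": fit.classification})
        rows.append({"component": j + 1, "eigenvalue_nm2": model.eigenvalues[j],
                     "r_squared": fit.r_squared, "class": fit.classification})
    pd.DataFrame(rows).to_csv(outdir / f"{name}_pca.tsv", sep="\t", index=False)
    res["_model"] = model  # removed before JSON; used for inner products
    return res


def _write_comparative_tables(cfg, summary: dict, outdir: Path) -> None:
    names = list(summary["trajectories"])
    # distances side by side with the crystal reference column
    rows = []
    for d in cfg.distances:
        label = d.get("label") or f"{d['selA']}--{d['selB']}"
        row = {"pair": label, "crystal_reference_nm": d.get("reference_nm")}
        for n in names:
            row[f"mean_nm[{n}]"] = summary["trajectories"][n]["distances"][label]["mean_nm"]
        rows.append(row)
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "comparative_distances.tsv",
                                  sep="\t", index=False)
    # inner products between the two trajectories' PC sets
    models = {n: summary["trajectories"][n].get("pca", {}).pop("_model", None)
              for n in names}
    have = [n for n in names if models[n] is not None]
    if len(have) == 2:
        k = min(10, *(models[n].n_components for n in have))
        ip = inner_products(models[have[0]], models[have[1]], k)
        summary["inner_products"] = {
            "pair": have, "k": k, "matrix": ip.tolist(),
        }
        pd.DataFrame(ip).to_csv(outdir / "inner_products.tsv",
                                sep="\t", index=False, header=False)


def _slug(s: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in s)[:48]
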