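"""Config-driven pipeline: build -> simulate -> analyze -> report.

A single YAML config (validated against an explicit key schema, unknown
keys rejected) drives surface construction, Brownian-dynamics sampling
or trajectory loading, windowing, and the analysis stages.  All
randomness flows from one recorded root seed, so a rerun with the same
config is identical except for timestamps.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import samsurf
from samsurf import clustering, density_binding, dynamics, ordering
from samsurf import synthetic_surface as synth
from samsurf.traj_io import analysis_window, read_trajectory, select, write_trajectory

SCHEMA_VERSION = 1

_ALLOWED_KEYS = {
    "": {"schema_version", "seed", "output_dir", "surface", "potential", "bd",
         "trajectory", "window", "stages", "cluster", "ion_cluster", "density",
         "binding", "rdf", "angles", "msd", "paths"},
    "surface": {"box_x_nm", "box_y_nm", "box_z_nm", "n_cols", "n_rows",
                "ligand_fraction", "tether_mode"},
    "potential": {f.name for f in dataclasses.fields(synth.PotentialSpec)},
    "bd": {f.name for f in dataclasses.fields(synth.BDParams)},
    "trajectory": {"path", "format", "role_map", "dt_fallback"},
    "window": {"last_fraction", "time_range"},
    "cluster": {"cutoff", "roles", "min_size"},
    "ion_cluster": {"cutoff", "moiety_roles"},
    "density": {"bin_width", "species", "epsilon_frac", "region_method"},
    "binding": {"temperature", "z_int", "z_max"},
    "rdf": {"layer", "r_max", "dr", "mode"},
    "angles": {"contact_cutoff", "bin_width_deg"},
    "msd": {"layer", "max_lag", "min_duration", "fit_window", "bulk_normalize"},
    "paths": {"ions", "stride"},
}

_STAGES = ("cluster", "ion_cluster", "density", "binding", "rdf", "angles", "msd", "paths")


class StageError(RuntimeError):
    """Analysis failure carrying the name of the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    _validate_keys(cfg, "")
    if cfg.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {cfg.get('schema_version')}")
    return cfg


def _validate_keys(section: dict, name: str) -> None:
    if not isinstance(section, dict):
        raise ValueError(f"config section {name or '<root>'} must be a mapping")
    allowed = _ALLOWED_KEYS[name]
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} in section {name or '<root>'}; "
            f"allowed: {sorted(allowed)}"
        )
    for key, sub in section.items():
        if key in _ALLOWED_KEYS and key != "" and isinstance(sub, dict):
            _validate_keys(sub, key)


def _acquire_trajectory(cfg: dict, seed: int):
    if "trajectory" in cfg:
        tr = cfg["trajectory"]
        return read_trajectory(
            tr["path"], tr.get("format"), role_map_path=tr.get("role_map"),
            dt_fallback=tr.get("dt_fallback", 1.0),
        )
    surf_cfg = cfg.get("surface", {})
    surface = synth.build_surface_model(**surf_cfg)
    potential = synth.PotentialSpec(**cfg.get("potential", {}))
    bd_cfg = dict(cfg.get("bd", {}))
    bd_cfg.setdefault("rng_seed", seed)
    bd_cfg.setdefault("n_ions", surface.neutralizing_cation_count())
    params = synth.BDParams(**bd_cfg)
    return synth.bd_simulate(surface, potential, params)


def run_full_analysis(
    config_path: str | Path,
    output_dir: str | Path | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Execute the configured stages and write report.json plus CSV tables.

    Returns the report dict.  Any stage failure raises :class:`StageError`
    naming the stage, and nothing is written in that case.
    """
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 0))
    out = Path(output_dir or cfg.get("output_dir", "samsurf_out"))
    wanted = stages or cfg.get("stages") or list(_STAGES)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": samsurf.__version__,
        "config": cfg,
        "seed": seed,
        "results": {},
    }
    tables: dict[str, pd.DataFrame] = {}

    try:
        traj = _acquire_trajectory(cfg, seed)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("trajectory", exc) from exc

    win_cfg = cfg.get("window")
    if win_cfg:
        traj_w = analysis_window(
            traj,
            last_fraction=win_cfg.get("last_fraction"),
            time_range=tuple(win_cfg["time_range"]) if "time_range" in win_cfg else None,
        )
    else:
        traj_w = traj
    topo = traj_w.topology
    res = report["results"]

    for stage in wanted:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}; available: {_STAGES}")
        try:
            if stage == "cluster":
                c = cfg.get("cluster", {})
                params = clustering.ClusterParams(
                    cutoff=c.get("cutoff", 4.0),
                    role_set=frozenset(c.get("roles", ["phenyl_C"])),
                    min_size=c.get("min_size", 1),
                )
                parts = [
                    clustering.cluster_frame(f, topo, params) for f in traj_w.frames
                ]
                dist = clustering.cluster_size_distribution(parts, min_size=params.min_size)
                res["cluster"] = {
                    "mean_size": dist.mean_size,
                    "n_observations": dist.n_observations,
                    "cutoff": params.cutoff,
                }
                tables["cluster_size_distribution"] = dist.as_series().reset_index()
            elif stage == "ion_cluster":
                c = cfg.get("ion_cluster", {})
                cutoff = c.get("cutoff", 5.0)
                parts = [
                    clustering.ion_moiety_clusters(
                        f, topo, cutoff,
                        moiety_roles=c.get("moiety_roles", ["carboxylate_C", "carboxylate_O"]),
                    )
                    for f in traj_w.frames
                ]
                dist = clustering.cluster_size_distribution(parts)
                res["ion_cluster"] = {
                    "mean_size": dist.mean_size,
                    "n_observations": dist.n_observations,
                    "cutoff": cutoff,
                }
                tables["ion_cluster_size_distribution"] = dist.as_series().reset_index()
            elif stage == "density":
                c = cfg.get("density", {})
                bin_width = c.get("bin_width", 0.25)
                prof_tbl = {}
                for role in c.get("species", ["ion", "carboxylate_C"]):
                    sel = select(topo, role=role)
                    prof = density_binding.z_density_profile(
                        traj_w, sel, bin_width=bin_width, species=role
                    )
                    prof_tbl[role] = prof
                    tables[f"density_{role}"] = pd.DataFrame(
                        {"z": prof.z_centers, "density": prof.density}
                    )
                res["density"] = {
                    r: {"mean_atom_count": p.mean_atom_count()} for r, p in prof_tbl.items()
                }
                report["_profiles"] = prof_tbl
            elif stage == "binding":
                c = cfg.get("binding", {})
                profiles = report.get("_profiles", {})
                lig_roles = [
                    r for r in ("carboxylate_C", "carboxylate_O", "phenyl_C") if r in profiles
                ]
                z_int = c.get("z_int")
                if z_int is None:
                    if not lig_roles:
                        raise ValueError("binding needs a ligand density profile or explicit z_int")
                    z_int = max(
                        density_binding.find_bound_layer_edge(profiles[r]) for r in lig_roles
                    )
                z_max = c.get("z_max", traj_w.box.lz)
                ion_z = traj_w.positions_of(select(topo, role="ion"))[:, :, 2].ravel()
                bs = density_binding.binding_stats(
                    ion_z_samples=ion_z, z_int=z_int, z_max=z_max,
                    temperature=c.get("temperature", 300.0),
                )
                res["binding"] = {
                    "z_int": bs.z_int, "p_bound": bs.p_bound,
                    "delta_G_kJ_mol": bs.delta_G, "delta_G_kBT": bs.delta_G_kBT,
                    "temperature_K": bs.temperature, "unbounded": bs.unbounded_flag,
                }
            elif stage == "rdf":
                c = cfg.get("rdf", {})
                layer = tuple(c.get("layer", (0.0, 9.0)))
                pd_ = ordering.ion_ion_pair_distribution(
                    traj_w, select(topo, role="ion"), layer,
                    r_max=c.get("r_max", 12.0), dr=c.get("dr", 0.1),
                    mode=c.get("mode", "pair_density"),
                )
                res["rdf"] = {"mode": pd_.mode, "n_pairs": pd_.n_pairs}
                tables["ion_ion_rdf"] = pd.DataFrame({"r": pd_.r_centers, "value": pd_.value})
            elif stage == "angles":
                c = cfg.get("angles", {})
                ad = ordering.ion_carboxylate_angle_distribution(
                    traj_w, contact_cutoff=c.get("contact_cutoff", 3.2),
                    bin_width_deg=c.get("bin_width_deg", 5.0),
                )
                res["angles"] = {"n_contacts": ad.n_contacts}
                tables["ion_carboxylate_angles"] = pd.DataFrame(
                    {"theta_deg": ad.theta_centers, "density": ad.density}
                )
            elif stage == "msd":
                c = cfg.get("msd", {})
                layer = tuple(c.get("layer", (0.0, 9.0)))
                ions = select(topo, role="ion")
                segs = dynamics.layer_resident_segments(
                    traj_w, ions, layer[0], layer[1],
                    min_duration=c.get("min_duration", 10),
                )
                max_lag = c.get("max_lag", max(2, traj_w.n_frames // 5))
                msd = dynamics.lateral_msd(traj_w, segs, max_lag)
                fw = c.get("fit_window")
                D = dynamics.fit_diffusivity(msd, tuple(fw) if fw else None)
                res["msd"] = {
                    "D_A2_ps": D.D, "D_1e9_m2_s": D.D_1e9_m2_s,
                    "n_segments": len(segs), "fit_window_ps": list(D.fit_window),
                    "clamped": D.clamped,
                }
                tables["msd"] = pd.DataFrame(
                    {"lag_ps": msd.lag_times, "msd_A2": msd.msd, "n": msd.n_samples}
                )
            elif stage == "paths":
                c = cfg.get("paths", {})
                traces = dynamics.ion_paths(
                    traj_w, c.get("ions", [0]), stride=c.get("stride", 1)
                )
                res["paths"] = {
                    str(t.ion_id): {"path_length_A": t.path_length, "n_points": len(t.xy)}
                    for t in traces
                }
                for t in traces:
                    tables[f"path_ion{t.ion_id}"] = pd.DataFrame(
                        {"time_ps": t.times, "x": t.xy[:, 0], "y": t.xy[:, 1]}
                    )
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    report.pop("_profiles", None)
    report["generated_at"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
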