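"""End-to-end orchestration: build -> calibrate -> simulate -> analyze.

One run = one variant (wild-type, heated, per-residue stiffness edits,
contact edits), described by a single YAML config; "mutants" are declarative
config diffs (dihedral multipliers, extra/removed contacts, temperature)
rather than rebuilt structures. A run directory contains the serialized
model, the trajectory with its energy sidecar, the projected coordinate
table, the ensemble partition, residue/contact statistics, PMFs, and a JSON
report; every artifact is stamped with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coords as coords_mod
from . import ensembles as ens_mod
from . import localstats as ls_mod
from . import landscape as land_mod
from .dynamics import SimulationConfig, run_langevin, total_time
from .gomodel import build_double_well, model_from_json, model_to_json
from .structures import CalphaStructure, pseudodihedrals, read_calpha, write_calpha
from .synthetic import make_toy_two_state

DEFAULT_CONFIG: dict = {
    "toy": {"n_res": 44, "hinge_angle_open": 150.0, "hinge_angle_closed": 80.0,
            "seed": 1},
    "structures": None,  # {"open_pdb": ..., "closed_pdb": ..., "chain": "A"}
    "domain_map": None,   # defaults to the toy generator's map
    "exclusions": {},
    "ligand_pairs": "auto",  # toy-generated bridge pairs; or explicit list
    "model": {
        "contact_scale": 2.5,
        "eps_open": 0.0,
        "beta_mix": 0.1,
        "cutoff": 8.0,
        "min_separation": 3,
        "well_depth": 0.9,
        "interface_depth": 0.45,
        "dihedral_multipliers": {},
    },
    "calibration": {"enabled": True, "target_keq": 4.0, "n_steps": 400_000,
                    "tol_rel": 0.2, "max_iter": 6, "n_seeds": 3,
                    "burn_in": 0.1},
    "simulation": {"timestep": 15.0, "n_steps": 1_000_000, "temperature": 300.0,
                   "friction": 0.2, "save_stride": 100, "seed": 0},
    "analysis": {
        "ratio": 1.1,
        "characteristic_delta": 0.2,
        "compare_min_delta": 0.1,
        "display_floor": 0.5,
        "window_folded": 60.0,
        "window_rigid": 20.0,
        "domain_pairs": [["core", "lid"], ["core", "hinge"]],
        "shared_distance_rule": "own",
    },
}


def _deep_update(base: dict, overlay: dict) -> dict:
    out = dict(base)
    for k, v in (overlay or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    """Load a YAML run config, resolving an optional ``include`` base file."""
    if isinstance(path_or_dict, dict):
        doc = path_or_dict
    else:
        doc = yaml.safe_load(Path(path_or_dict).read_text()) or {}
        if "include" in doc:
            base_path = Path(path_or_dict).parent / doc.pop("include")
            doc = _deep_update(load_config(base_path), doc)
    return _deep_update(DEFAULT_CONFIG, doc)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _get_structures(config):
    if config.get("structures"):
        s = config["structures"]
        chain = s.get("chain", "A")
        open_s = read_calpha(Path(s["open_pdb"]).read_text(), chain)
        closed_s = read_calpha(Path(s["closed_pdb"]).read_text(), chain)
        ligand = config["ligand_pairs"] if config["ligand_pairs"] != "auto" else []
        dm = config.get("domain_map")
        if dm:
            dm = {k: [tuple(r) for r in v] for k, v in dm.items()}
            from dataclasses import replace
            excl = {k: [tuple(r) for r in v]
                    for k, v in (config.get("exclusions") or {}).items()}
            open_s = replace(open_s, domain_map=dm, exclusions=excl)
            closed_s = replace(closed_s, domain_map=dm, exclusions=excl)
        return open_s, closed_s, ligand
    toy = make_toy_two_state(**config["toy"])
    ligand = (toy.ligand_contacts if config["ligand_pairs"] == "auto"
              else config["ligand_pairs"])
    open_s, closed_s = toy.open_structure, toy.closed_structure
    if config.get("exclusions"):
        from dataclasses import replace
        excl = {k: [tuple(r) for r in v] for k, v in config["exclusions"].items()}
        open_s = replace(open_s, exclusions=excl)
        closed_s = replace(closed_s, exclusions=excl)
    return open_s, closed_s, ligand


def run(config, outdir) -> Path:
    """Execute the full pipeline into *outdir* and return its path."""
    config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    stage = "structures"
    try:
        open_s, closed_s, ligand = _get_structures(config)
        (outdir / "open.pdb").write_text(write_calpha(open_s))
        (outdir / "closed.pdb").write_text(write_calpha(closed_s))

        stage = "build"
        m = config["model"]
        model = build_double_well(
            open_s, closed_s, ligand_pairs=ligand,
            eps_open=m["eps_open"], beta_mix=m["beta_mix"],
            contact_scale=m["contact_scale"], cutoff=m["cutoff"],
            min_separation=m["min_separation"], well_depth=m["well_depth"],
            interface_depth=m.get("interface_depth", 0.45),
            dihedral_multipliers=m.get("dihedral_multipliers") or {},
        )

        sim = config["simulation"]
        sim_cfg = SimulationConfig(**sim)
        ana = config["analysis"]
        project_kwargs = dict(
            domain_pairs=[tuple(p) for p in ana["domain_pairs"]],
            ratio=ana["ratio"],
            shared_distance_rule=ana["shared_distance_rule"],
        )

        stage = "calibrate"
        cal = config["calibration"]
        calibration_trace = None
        if cal.get("enabled", True):
            cal_cfg = SimulationConfig(
                timestep=sim["timestep"], n_steps=cal["n_steps"],
                temperature=sim["temperature"], friction=sim["friction"],
                save_stride=sim["save_stride"], seed=sim["seed"] + 1,
            )
            eps, achieved, calibration_trace = ens_mod.calibrate(
                model, cal["target_keq"], cal_cfg,
                tol_rel=cal["tol_rel"], max_iter=cal["max_iter"],
                n_seeds=cal["n_seeds"], burn_in=cal["burn_in"],
                project_kwargs=project_kwargs,
            )
            model = model.with_eps_open(eps)
        (outdir / "model.json").write_text(model_to_json(model))

        stage = "simulate"
        traj = run_langevin(model, open_s.coords, sim_cfg)
        traj.save(outdir / "trajectory.npz")
        (outdir / "energies.tsv").write_text(traj.energies_tsv())

        stage = "project"
        table = coords_mod.project(traj.frames, model, open_s, closed_s,
                                   **project_kwargs)
        (outdir / "coords.tsv").write_text(table.to_tsv())

        stage = "partition"
        basins, paths, sep, part = ens_mod.analyze_two_state(table)
        (outdir / "partition.tsv").write_text(part.to_tsv())

        stage = "local_stats"
        angles = pseudodihedrals(traj.frames)
        refs = ls_mod.DihedralReference.from_structures(open_s, closed_s)
        pf = ls_mod.p_folded(angles, refs, part, ana["window_folded"],
                             open_s.residue_ids)
        pr = ls_mod.p_folded(angles, refs, part, ana["window_rigid"],
                             open_s.residue_ids)
        pf.to_csv(outdir / "p_folded.tsv", sep="\t", index=False)
        pr.to_csv(outdir / "p_rigid.tsv", sep="\t", index=False)
        union = list(model.potential_open.contacts)
        seen = {c.pair for c in union}
        union += [c for c in model.potential_closed.contacts
                  if c.pair not in seen]
        cp = ls_mod.contact_probabilities(traj.frames, union, part, ana["ratio"])
        cp = ls_mod.classify(cp, ana["characteristic_delta"],
                             ana["display_floor"])
        cp.to_csv(outdir / "contacts.tsv", sep="\t", index=False)

        stage = "landscape"
        pmfs = {}
        for a, b in project_kwargs["domain_pairs"]:
            col = f"r_cm_{a}_{b}"
            grid = land_mod.pmf(table[col], temperature=sim["temperature"],
                                axis_names=(col,), labels=part.labels)
            (outdir / f"pmf_{col}.tsv").write_text(grid.to_tsv())
            grid.plot(outdir / f"pmf_{col}.png")
            pmfs[col] = grid
        pair_cols = [f"r_cm_{a}_{b}" for a, b in project_kwargs["domain_pairs"]]
        if len(pair_cols) >= 2:
            grid2 = land_mod.pmf(table[pair_cols[1]], table[pair_cols[0]],
                                 temperature=sim["temperature"],
                                 axis_names=(pair_cols[1], pair_cols[0]),
                                 labels=part.labels)
            (outdir / "pmf_2d.tsv").write_text(grid2.to_tsv())
            grid2.plot(outdir / "pmf_2d.png")

        stage = "report"
        sigmas = {}
        ens_means = {}
        for col in pair_cols:
            series = table[col]
            for ens in ("O", "TS", "C"):
                if (part.labels == ens).any():
                    mean, sd = coords_mod.dispersion(series, part.labels, ens)
                    sigmas[f"sigma_{col}_{ens}"] = sd
                    ens_means[f"mean_{col}_{ens}"] = mean
        report = {
            "config_hash": chash,
            "seed": sim["seed"],
            "total_time_ns": total_time(sim_cfg),
            "eps_open": model.eps_open,
            "beta_mix": model.beta_mix,
            "calibration_trace": calibration_trace,
            "keq": part.keq,
            "counts": part.counts,
            "n_transition_paths": len(paths),
            "p_tp": sep.p_tp,
            "separatrix": {"slope": sep.slope, "intercept": sep.intercept,
                           "band_halfwidth": sep.band_halfwidth},
            "basins": {
                "open_center": np.asarray(basins.center_open).tolist(),
                "closed_center": np.asarray(basins.center_closed).tolist(),
                "open_radius": basins.radius_open,
                "closed_radius": basins.radius_closed,
            },
            "dispersion": sigmas,
            "ensemble_means": ens_means,
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return outdir


def compare_runs(run_a, run_b, outdir=None,
                 min_delta: float = ls_mod.COMPARE_MIN_DELTA) -> dict:
    """Difference tables between two completed runs (A - B, perturbed first).

    Returns the per-contact and per-residue delta tables; when *outdir* is
    given, writes them plus a paintable contact list.
    """
    run_a, run_b = Path(run_a), Path(run_b)
    ca = pd.read_csv(run_a / "contacts.tsv", sep="\t")
    cb = pd.read_csv(run_b / "contacts.tsv", sep="\t")
    fa = pd.read_csv(run_a / "p_folded.tsv", sep="\t")
    fb = pd.read_csv(run_b / "p_folded.tsv", sep="\t")
    if len(fa) != len(fb):
        raise ValueError("runs were made on structurally different systems")
    dp_contacts = ls_mod.compare(ca, cb, min_delta)
    dp_residues = ls_mod.compare_residues(fa, fb)
    out = {"dp_contacts": dp_contacts, "dp_residues": dp_residues}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dp_contacts.to_csv(outdir / "dp_contacts.tsv", sep="\t", index=False)
        dp_residues.to_csv(outdir / "dp_residues.tsv", sep="\t", index=False)
        (outdir / "dp_paintable.tsv").write_text(
            ls_mod.paintable_contact_list(dp_contacts))
    return out


def load_run_model(run_dir):
    return model_from_json((Path(run_dir) / "model.json").read_text())
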