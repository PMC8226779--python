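"""End-to-end orchestration of the analysis stages.

Stages run in a fixed dependency order (io → metrics/surface →
water_dynamics → landscape → mep).  Every JSON output carries the config
hash; all randomness derives from the single run seed through per-stage
offsets, so a rerun with the same config reproduces every summary
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import landscape as lsc
from . import metrics, surface, synthetic, water
from .config import RunConfig, stage_seed
from .io import load_topology, read_text_trajectory, read_trajectory
from .model import Trajectory, select

__all__ = ["run", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained with a FAILED marker."""


def _write_json(path: Path, payload: dict, cfg: RunConfig) -> None:
    payload = {"config_hash": cfg.config_hash, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _round(x) -> float:
    return float(np.round(float(x), 10))


def _load_inputs(cfg: RunConfig):
    if cfg.topology is not None:
        atoms = load_topology(
            cfg.topology,
            catalytic_residues=cfg.catalytic_residues,
            hydropathy_overrides=cfg.hydropathy_overrides,
            solvent_role_map=cfg.solvent_role_map,
        )
        if cfg.trajectory and str(cfg.trajectory).endswith(".txt"):
            traj = read_text_trajectory(cfg.trajectory)
        else:
            traj = read_trajectory(cfg.topology, cfg.trajectory)
        traj.atoms = atoms
        return traj
    # synthetic demo mode: a jittered toy peptide carries the protein stages
    traj = synthetic.gen_toy_peptide(
        n_frames=int(cfg.params.get("demo_frames", 20)),
        seed=stage_seed(cfg.seed, "io"),
        catalytic_residues=cfg.catalytic_residues or (1, 3, 5),
    )
    return traj


def _stage_metrics(cfg: RunConfig, traj: Trajectory, outdir: Path) -> dict:
    sel = select(traj.atoms, cfg.selections.get("metrics", "backbone"))
    rmsd = metrics.rmsd_series(traj, sel, ref_frame=0)
    rmsf = metrics.rmsf(traj, sel)
    pd.DataFrame({"time_ps": rmsd.times, "rmsd_A": rmsd.values}).to_csv(
        outdir / "rmsd.csv", index=False, float_format="%.8f"
    )
    pd.DataFrame(
        {
            "atom_id": sel,
            "residue_id": traj.atoms.residue_id[sel],
            "rmsf_A": rmsf.values,
        }
    ).to_csv(outdir / "rmsf.csv", index=False, float_format="%.8f")
    summary = {
        "rmsd_mean_A": _round(rmsd.values.mean()),
        "rmsd_max_A": _round(rmsd.values.max()),
        "rmsf_mean_A": _round(rmsf.values.mean()),
        "n_atoms": int(sel.size),
    }
    _write_json(outdir / "metrics.json", summary, cfg)
    return summary


def _stage_surface(cfg: RunConfig, traj: Trajectory, outdir: Path) -> dict:
    triad = tuple(cfg.catalytic_residues) or (1, 3, 5)
    n_points = int(cfg.params.get("sasa_points", 960))
    series = surface.surface_series(traj, traj.atoms, triad=triad, n_points=n_points)
    pd.DataFrame(
        {
            "time_ps": series.times,
            "sasa_nm2": series.sasa_total,
            "sa_philic_nm2": series.sa_philic,
            "sa_phobic_nm2": series.sa_phobic,
            "sa_catalytic_nm2": series.sa_catalytic,
            "ratio": series.ratio,
        }
    ).to_csv(outdir / "sasa.csv", index=False, float_format="%.8f")
    summary = {
        "sasa_mean_nm2": _round(series.sasa_total.mean()),
        "sa_philic_mean_nm2": _round(series.sa_philic.mean()),
        "sa_phobic_mean_nm2": _round(series.sa_phobic.mean()),
        "sa_catalytic_mean_nm2": _round(series.sa_catalytic.mean()),
        "ratio_mean": _round(np.nanmean(series.ratio)),
    }
    _write_json(outdir / "surface.json", summary, cfg)
    return summary


def _stage_water(cfg: RunConfig, outdir: Path, seed: int) -> dict:
    p = cfg.params.get("water_dynamics", {})
    # hydration-shell RDF round-trip
    shells = synthetic.gen_shell_waters(
        synthetic.ShellSpec(
            radii=tuple(p.get("radii", (3.75, 8.5))),
            sigmas=tuple(p.get("sigmas", (0.3, 0.3))),
            weights=tuple(p.get("weights", (0.5, 0.5))),
            n_waters=int(p.get("n_waters", 500)),
            n_frames=int(p.get("shell_frames", 100)),
            seed=seed,
        )
    )
    rdf = water.proximal_rdf(shells, np.arange(1, shells.n_atoms), np.array([0]))
    maxima = water.find_shells(rdf)
    pd.DataFrame({"r_A": rdf.r_centers, "g": rdf.g}).to_csv(
        outdir / "rdf.csv", index=False, float_format="%.8f"
    )
    # Einstein diffusion on a Brownian fixture
    D_true = float(p.get("D_cm2s", 0.5e-5))
    brown = synthetic.gen_brownian(
        synthetic.BrownianSpec(
            n_particles=int(p.get("n_particles", 128)),
            D=D_true,
            dt=1.0,
            n_frames=int(p.get("msd_frames", 1000)),
            box=40.0,
            seed=seed + 1,
        )
    )
    diff = water.einstein_diffusion(brown, np.arange(brown.n_atoms))
    pd.DataFrame({"lag_ps": diff.lags, "msd_A2": diff.msd}).to_csv(
        outdir / "msd.csv", index=False, float_format="%.8f"
    )
    # hydrogen-bond lifetimes on a telegraph fixture
    tau_true = float(p.get("tau_on_ps", 5.0))
    hmat = synthetic.gen_hb_telegraph(tau_true, 0.1, int(p.get("hb_frames", 5000)), 100, seed + 2)
    life_c = water.hb_lifetime(hmat, 0.1, "continuous")
    life_i = water.hb_lifetime(hmat, 0.1, "intermittent")
    # rotational relaxation
    Dr = float(p.get("D_r", 0.05))
    vecs = synthetic.gen_rotational_diffusion(Dr, 0.2, int(p.get("rcf_frames", 400)), 200, seed + 3)
    rcf = water.rotational_correlation(vecs, rank=1, dt=0.2, max_lag=100)
    pd.DataFrame({"lag_ps": rcf.lags, "C1": rcf.C}).to_csv(
        outdir / "rcf.csv", index=False, float_format="%.8f"
    )
    summary = {
        "rdf_maxima_A": [list(map(_round, m)) for m in maxima],
        "D_cm2s": _round(diff.D),
        "D_true_cm2s": D_true,
        "hb_tau_continuous_ps": _round(life_c.tau),
        "hb_tau_intermittent_ps": _round(life_i.tau),
        "hb_tau_true_ps": tau_true,
        "rcf_tau_ps": _round(rcf.tau),
        "rcf_tau_true_ps": _round(1.0 / (2.0 * Dr)),
        "msd_fit_r2": _round(diff.fit_r2),
    }
    _write_json(outdir / "water_dynamics.json", summary, cfg)
    return summary


def _stage_landscape(cfg: RunConfig, outdir: Path, seed: int) -> tuple[dict, lsc.Landscape2D]:
    p = cfg.params.get("landscape", {})
    spec = synthetic.PotentialSpec(
        form=p.get("form", "double_well"), temperature=cfg.temperature_K
    )
    samples = synthetic.gen_cv_samples(spec, int(p.get("n_samples", 20000)), seed)
    # sample every n-th point as an independent-frame series would be
    stride = int(p.get("stride", 1))
    land = lsc.boltzmann_landscape(
        samples[::stride],
        grid=tuple(p.get("grid", (50, 50))),
        temperature=cfg.temperature_K,
        smooth_sigma=float(p.get("smooth_sigma", 1.0)),
    )
    minima = lsc.find_minima(land)
    payload = {
        "x_edges": [_round(v) for v in land.x_edges],
        "y_edges": [_round(v) for v in land.y_edges],
        "E_kT": [[None if not np.isfinite(v) else _round(v) for v in row] for row in land.E],
        "minima": [[_round(v) for v in m] for m in minima],
        "temperature_K": cfg.temperature_K,
    }
    _write_json(outdir / "landscape.json", payload, cfg)
    return {"n_minima": len(minima), "minima": payload["minima"]}, land


def _stage_mep(cfg: RunConfig, land: lsc.Landscape2D, outdir: Path) -> dict:
    # pair up the meaningful basins only; shallow fringe minima from
    # histogram noise sit several kT up and are skipped
    cutoff = float(cfg.params.get("landscape", {}).get("basin_energy_cutoff", 2.0))
    minima = [m for m in lsc.find_minima(land) if m[2] <= cutoff]
    paths = []
    for i in range(len(minima)):
        for j in range(i + 1, len(minima)):
            a, b = minima[i], minima[j]
            entry = {
                "from": [_round(a[0]), _round(a[1])],
                "to": [_round(b[0]), _round(b[1])],
            }
            try:
                path = lsc.string_mep(land, (a[0], a[1]), (b[0], b[1]))
            except RuntimeError:
                entry["blocked"] = True
                paths.append(entry)
                continue
            entry["converged"] = bool(path.converged)
            if path.converged:
                ts, e_ts, is_saddle = lsc.transition_state(path, land)
                entry.update(
                    ts=[_round(ts[0]), _round(ts[1])],
                    barrier_kT=_round(e_ts - min(a[2], b[2])),
                    saddle=bool(is_saddle),
                )
            paths.append(entry)
            pd.DataFrame(
                {
                    "x": path.images[:, 0],
                    "y": path.images[:, 1],
                    "E_kT": path.energies,
                }
            ).to_csv(outdir / f"mep_{i}_{j}.csv", index=False, float_format="%.8f")
    summary = {"paths": paths}
    _write_json(outdir / "mep.json", summary, cfg)
    return summary


def run(cfg: RunConfig) -> dict:
    """Execute the enabled stages; returns the run report (also written as
    report.json)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.config_hash, "stages": {}}
    land = None
    try:
        traj = _load_inputs(cfg)
        report["stages"]["io"] = {
            "n_frames": traj.n_frames,
            "n_atoms": traj.n_atoms,
        }
        if "metrics" in cfg.stages:
            report["stages"]["metrics"] = _stage_metrics(cfg, traj, outdir)
        if "surface" in cfg.stages:
            report["stages"]["surface"] = _stage_surface(cfg, traj, outdir)
        if "water_dynamics" in cfg.stages:
            report["stages"]["water_dynamics"] = _stage_water(
                cfg, outdir, stage_seed(cfg.seed, "water_dynamics")
            )
        if "landscape" in cfg.stages:
            summary, land = _stage_landscape(cfg, outdir, stage_seed(cfg.seed, "landscape"))
            report["stages"]["landscape"] = summary
        if "mep" in cfg.stages:
            if land is None:
                raise PipelineError("mep stage requires the landscape stage")
            report["stages"]["mep"] = _stage_mep(cfg, land, outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise PipelineError(f"stage failure: {exc}") from exc
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
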