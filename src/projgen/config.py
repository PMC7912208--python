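"""Experiment configuration and end-to-end pipeline orchestration.

A run configuration is a YAML document with blocks

    model:      potential name + parameters, kind (overdamped/underdamped),
                beta, gamma
    simulation: dt, steps, seed, burn_in (optional)
    rc:         reaction-coordinate name
    basis:      family, centers (list or "linspace(a, b, n)"), bandwidth,
                optional grid (for 2D tensor products)
    estimator:  type (reversible/nonreversible/km), offsets, mass_tol, imag_tol
    analysis:   n_eigs, n_timescales, K (PCCA states), bins, km_offsets

All randomness flows from the single simulation seed.  ``run_experiment``
executes simulate -> assemble/solve (reference) -> offset scan -> binned KM
-> PCCA as requested and writes JSON/CSV results plus the resolved config
next to them; identical configs give byte-identical JSON outputs.
"""

from __future__ import annotations

import json
import re
import time
from pathlib import Path

import numpy as np
import yaml

from . import basis as basis_mod
from . import coordinates as coords
from . import effective, gedmd, metastability, models
from .io import write_trajectory

__all__ = ["load_config", "validate_config", "build_basis", "run_experiment"]

_LINSPACE = re.compile(r"linspace\(\s*([-\d.eE+]+)\s*,\s*([-\d.eE+]+)\s*,\s*(\d+)\s*\)")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    for block in ("model", "simulation", "rc", "basis", "estimator"):
        if block not in cfg:
            raise ValueError(f"config is missing the {block!r} block")
    sim = cfg["simulation"]
    if sim.get("steps", 0) < 1:
        raise ValueError("simulation.steps must be at least 1")
    if sim.get("dt", 0) <= 0:
        raise ValueError("simulation.dt must be positive")
    if cfg["model"].get("beta", 0) <= 0 or cfg["model"].get("gamma", 0) <= 0:
        raise ValueError("model.beta and model.gamma must be positive")


def _centers(spec) -> np.ndarray:
    if isinstance(spec, str):
        m = _LINSPACE.fullmatch(spec.strip())
        if not m:
            raise ValueError(f"cannot parse centers spec {spec!r}")
        return np.linspace(float(m.group(1)), float(m.group(2)), int(m.group(3)))
    return np.asarray(spec, dtype=float)


def build_basis(bcfg: dict) -> basis_mod.BasisSet:
    family = bcfg.get("family", "gaussian")
    conv = bcfg.get("rho_convention", "divide")
    if family in ("gaussian", "periodic_gaussian"):
        make = (basis_mod.gaussian_basis if family == "gaussian"
                else basis_mod.periodic_gaussian_basis)
        b1 = make(_centers(bcfg["centers"]), bcfg["bandwidth"], rho_convention=conv)
        if "centers_y" in bcfg:
            b2 = make(_centers(bcfg["centers_y"]), bcfg["bandwidth"], rho_convention=conv)
            return basis_mod.tensor_grid_basis(b1, b2)
        return b1
    if family == "hermite":
        return basis_mod.hermite_basis(bcfg["n_max"])
    raise ValueError(f"unknown basis family {bcfg['family']!r}")


def _build_model(mcfg: dict) -> models.SDEModel:
    pot = models.get_potential(mcfg["potential"], **mcfg.get("potential_params", {}))
    return models.make_model(mcfg.get("kind", "overdamped"), pot,
                             mcfg["beta"], mcfg["gamma"])


def run_experiment(cfg: dict, outdir) -> dict:
    """Run the configured pipeline and write results under ``outdir``."""
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = []

    def stage(name):
        log.append({"stage": name, "time": time.time()})

    def fail(name, exc):
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    results = {"config": cfg}
    try:
        stage("simulate")
        model = _build_model(cfg["model"])
        sim = cfg["simulation"]
        traj = models.simulate_em(model, dt=sim["dt"], n_steps=int(sim["steps"]),
                                  seed=int(sim["seed"]),
                                  burn_in=sim.get("burn_in"))
        if cfg.get("output", {}).get("save_trajectory"):
            write_trajectory(traj, outdir / "trajectory.npz")
    except Exception as exc:  # noqa: BLE001 - reported with stage name
        fail("simulate", exc)

    rc = coords.get_reaction_coordinate(cfg["rc"]["name"], dim_full=model.dim)
    basis = build_basis(cfg["basis"])
    est = cfg["estimator"]
    ana = cfg.get("analysis", {})
    mass_tol = est.get("mass_tol", 1e-10)
    imag_tol = est.get("imag_tol", 0.1)
    n_ts = ana.get("n_timescales", 3)

    try:
        stage("reference")
        ref_est = est.get("reference", "reversible")
        ref_traj, ref_model, ref_rc = traj, model, rc
        if ref_est == "ol-twin":
            # underdamped data: the exact-parameter reference comes from the
            # overdamped process with the same potential, beta and gamma
            ref_model = models.make_model("overdamped", model.potential,
                                          model.beta, model.gamma)
            ref_traj = models.simulate_em(ref_model, dt=sim["dt"],
                                          n_steps=int(sim["steps"]),
                                          seed=int(sim["seed"]) + 1,
                                          burn_in=sim.get("burn_in"))
            ref_est = "reversible"
            ref_rc = coords.get_reaction_coordinate(cfg["rc"]["name"],
                                                    dim_full=ref_model.dim)
        edmd = gedmd.GeneratorEDMD(basis=basis, rc=ref_rc, estimator=ref_est,
                                   model=ref_model, mass_tol=mass_tol,
                                   imag_tol=imag_tol).fit(ref_traj)
        reference = edmd.spectral_
        results["reference"] = {
            "eigenvalues": edmd.eigenvalues_.tolist(),
            "timescales": edmd.timescales_[:n_ts].tolist(),
            "rank": edmd.rank_,
        }
    except Exception as exc:
        fail("reference", exc)

    offsets = est.get("offsets", [])
    if offsets:
        try:
            stage("scan")
            scan = gedmd.offset_scan(traj, rc, basis, offsets, reference,
                                     n_timescales=n_ts, mass_tol=mass_tol,
                                     imag_tol=imag_tol)
            scan.to_csv(outdir / "offset_scan.csv", index=False)
            results["scan_file"] = "offset_scan.csv"
        except Exception as exc:
            fail("scan", exc)

    if ana.get("km_offset") is not None and rc.dim_reduced == 1:
        try:
            stage("km")
            km = effective.KramersMoyal(rc=rc, offset=ana["km_offset"],
                                        n_bins=ana.get("bins", 50)).fit(traj)
            import pandas as pd
            pd.DataFrame({
                "bin_center": km.bin_centers_[:, 0],
                "drift": km.drift_[:, 0],
                "diffusion": km.diffusion_[:, 0, 0],
                "count": km.counts_,
            }).to_csv(outdir / "km_bins.csv", index=False)
            results["km_file"] = "km_bins.csv"
        except Exception as exc:
            fail("km", exc)

    K = ana.get("K")
    if K:
        try:
            stage("pcca")
            if rc.dim_reduced == 1:
                lo, hi = ana.get("grid", (-np.pi, np.pi))
                Z = np.linspace(lo, hi, ana.get("grid_n", 200))[:, None]
            else:
                lo, hi = ana.get("grid", (-np.pi, np.pi))
                g = np.linspace(lo, hi, ana.get("grid_n", 40))
                Z = np.column_stack([a.ravel() for a in np.meshgrid(g, g, indexing="ij")])
            order = np.argsort(np.abs(reference.eigenvalues))
            funs = reference.eigenfunctions(Z)[:, order[:K]]
            res = metastability.pcca(funs, K)
            np.savetxt(outdir / "memberships.csv",
                       np.column_stack([Z, res.memberships]), delimiter=",",
                       header=",".join([f"z{i}" for i in range(Z.shape[1])]
                                       + [f"chi{j}" for j in range(K)]))
            results["pcca"] = {"K": K, "violation": res.violation,
                               "n_transition": int(res.transition_mask.sum())}
        except Exception as exc:
            fail("pcca", exc)

    results["log"] = [{"stage": s["stage"]} for s in log]
    results["seed"] = int(sim["seed"])
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return results
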