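"""End-to-end orchestration: simulate → reduce → fit kinetics → fit ensembles → geometry.

A single TOML config drives a full run.  One master seed derives
per-stage seeds by stable hashing of the stage name, so any stage can be
re-run in isolation and a rerun with the same config reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tomllib
from typing import Any

import numpy as np

from . import (
    ensemble_fit,
    geometry,
    io_formats,
    kinetics,
    reduction,
    synthetic_data,
)
from .models import ScatteringCurve
from .scattering_calc import QGridSpec

__all__ = ["load_config", "stage_seed", "run_full"]

log = logging.getLogger("trxss")


def load_config(path: str | os.PathLike) -> dict[str, Any]:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _times_from_config(sim: dict[str, Any]) -> np.ndarray:
    return np.logspace(
        np.log10(sim.get("t_min", 1e-7)),
        np.log10(sim.get("t_max", 5.0)),
        int(sim.get("n_times", 25)),
    )


def run_full(config: dict[str, Any], outdir: str | None = None) -> dict[str, Any]:
    """Execute the pipeline stages named in ``config``; return the run manifest.

    Stages: ``simulate`` (synthetic truth, dataset, conformer
    ensembles), ``reduce`` (heating subtraction), ``kinetics``
    (two-state decomposition), ``ensemble`` (pair search against the
    recovered basis spectra; skipped with a logged notice when the block
    is absent), ``geometry`` (Δψ/Δχ statistics over accepted pairs).
    Any stage failure aborts with the stage name and cause.
    """
    run_cfg = config.get("run", {})
    master_seed = int(run_cfg.get("seed", 0))
    outdir = outdir or run_cfg.get("outdir")
    if outdir:
        os.makedirs(outdir, exist_ok=True)
    manifest: dict[str, Any] = {"seed": master_seed, "stages": {}}

    def fail(stage: str, err: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # --- simulate -----------------------------------------------------
    sim = config.get("simulate")
    if sim is None:
        raise ValueError("config requires a [simulate] block (or supply data paths)")
    try:
        seed = stage_seed(master_seed, "simulate")
        grid = QGridSpec(
            n_points=int(sim.get("n_q", 151)),
            q_min=float(sim.get("q_min", 0.0)),
            q_max=float(sim.get("q_max", 2.3)),
        )
        truth, base, light_int, light_fin = synthetic_data.make_truth(
            seed=seed,
            grid=grid,
            tau1=float(sim.get("tau1", 2e-6)),
            tau2=float(sim.get("tau2", 0.25)),
            turnover=float(sim.get("turnover", 0.7)),
            n_res_per_chain=int(sim.get("n_res_per_chain", 385)),
        )
        times = _times_from_config(sim)
        dataset = synthetic_data.generate_dataset(
            truth,
            times,
            noise_sigma=float(sim.get("noise_sigma", 0.02)),
            heating_amp=float(sim.get("heating_amp", 0.05)),
            seed=seed,
        )
        n_dark = int(sim.get("n_dark", 8))
        n_light = int(sim.get("n_light", 8))
        dark, light = synthetic_data.make_ensembles(
            base,
            n_dark=n_dark,
            n_light=n_light,
            light_dpsi_mean=float(sim.get("light_dpsi_mean", 11.0)),
            spread=float(sim.get("spread", 1.5)),
            jitter=float(sim.get("jitter", 0.3)),
            seed=seed,
        )
        manifest["stages"]["simulate"] = {
            "seed": seed,
            "tau1": truth.tau1,
            "tau2": truth.tau2,
            "turnover": truth.turnover,
            "n_dark": n_dark,
            "n_light": n_light,
            "n_times": len(times),
        }
        if outdir:
            io_formats.write_curve_table(dataset, os.path.join(outdir, "dataset.tsv"))
        log.info("simulate: %d delays, ensembles %dx%d", len(times), n_dark, n_light)
    except Exception as err:  # noqa: BLE001 - stage boundary
        fail("simulate", err)

    # --- reduce -------------------------------------------------------
    try:
        red_cfg = config.get("reduce", {})
        band = tuple(red_cfg.get("heat_band", (1.5, 2.2)))
        if truth.heating_ref.q.max() >= band[0]:
            reduced, scales = reduction.subtract_heating(
                dataset, truth.heating_ref, band
            )
        else:
            reduced, scales = dataset, np.zeros(dataset.n_t)
        manifest["stages"]["reduce"] = {
            "heating_scales_max": float(np.max(np.abs(scales))),
        }
        log.info("reduce: max heating scale %.3g", np.max(np.abs(scales)))
    except Exception as err:  # noqa: BLE001
        fail("reduce", err)

    # --- kinetics -----------------------------------------------------
    try:
        kin_cfg = config.get("kinetics", {})
        data_for_fit = reduced
        degree = kin_cfg.get("poly_degree")
        if degree is not None:
            data_for_fit = kinetics.smooth_polynomial(reduced, int(degree))
        decomp = kinetics.fit_decomposition(
            data_for_fit, n_grid=int(kin_cfg.get("n_grid", 25))
        )
        manifest["stages"]["kinetics"] = {
            "tau1": decomp.model.tau1,
            "tau2": decomp.model.tau2,
            "residual_norm": decomp.residual_norm,
            "converged": decomp.converged,
        }
        log.info(
            "kinetics: tau1=%.3g s tau2=%.3g s", decomp.model.tau1, decomp.model.tau2
        )
    except Exception as err:  # noqa: BLE001
        fail("kinetics", err)

    # --- ensemble fitting --------------------------------------------
    ens_cfg = config.get("ensemble")
    accepted = None
    if ens_cfg is None:
        log.info("ensemble: no [ensemble] block in config; stage skipped")
        manifest["stages"]["ensemble"] = {"skipped": True}
        manifest["stages"]["geometry"] = {"skipped": True}
    else:
        try:
            fit_grid = QGridSpec(
                n_points=int(ens_cfg.get("n_q", 101)),
                q_min=float(ens_cfg.get("q_min", 0.0)),
                q_max=float(ens_cfg.get("q_max", 1.0)),
            )
            n_pairs = len(dark) * len(light)
            cfg = ensemble_fit.FitConfig(
                n_keep=min(int(ens_cfg.get("n_keep", 100)), n_pairs),
                turnover=truth.turnover,
            )
            qgrid = fit_grid.make()
            dark_curves = ensemble_fit.compute_member_curves(dark, fit_grid)
            light_curves = ensemble_fit.compute_member_curves(light, fit_grid)
            # one search per kinetic state, targeting the recovered basis
            # spectra interpolated onto the evaluation grid
            accepted = {}
            ens_summary: dict[str, Any] = {"n_pairs_scored": n_pairs}
            for name, basis in (
                ("int", decomp.basis_int),
                ("fin", decomp.basis_fin),
            ):
                target = ScatteringCurve(
                    qgrid, np.interp(qgrid, basis.q, basis.I)
                ).restrict(*cfg.q_fit_range)
                pairs = ensemble_fit.pair_search(
                    dark,
                    light,
                    target,
                    cfg=cfg,
                    grid=fit_grid,
                    dark_curves=dark_curves,
                    light_curves=light_curves,
                )
                accepted[name] = ensemble_fit.select_top(pairs, cfg.n_keep)
                ens_summary[name] = {
                    "n_accepted": len(accepted[name]),
                    "best_R": accepted[name][0].R,
                    "best_c": accepted[name][0].c,
                }
                log.info(
                    "ensemble[%s]: scored %d pairs, kept %d (best R %.4f)",
                    name,
                    len(pairs),
                    len(accepted[name]),
                    accepted[name][0].R,
                )
            manifest["stages"]["ensemble"] = ens_summary
        except Exception as err:  # noqa: BLE001
            fail("ensemble", err)

        # --- geometry -------------------------------------------------
        try:
            ranges = geometry.ResidueRanges.defaults(base.chains[:2])
            geo_summary = {}
            for name, fits in accepted.items():
                d_psi = []
                d_chi = []
                pair_structs = []
                for fit in fits:
                    dm = dark.members[fit.dark_index]
                    lm = light.members[fit.light_index]
                    d_psi.append(
                        geometry.psi_dihedral(lm, ranges)
                        - geometry.psi_dihedral(dm, ranges)
                    )
                    d_chi.append(
                        geometry.chi_angle(lm, ranges)
                        - geometry.chi_angle(dm, ranges)
                    )
                    pair_structs.append((dm, lm))
                field = geometry.mean_displacement(pair_structs, ranges.get("lov"))
                geo_summary[name] = {
                    "mean_delta_psi": float(np.mean(d_psi)),
                    "mean_delta_chi": float(np.mean(d_chi)),
                    "max_mean_displacement": float(field.magnitude.max()),
                }
                log.info(
                    "geometry[%s]: mean dpsi %.2f deg",
                    name,
                    float(np.mean(d_psi)),
                )
            manifest["stages"]["geometry"] = geo_summary
        except Exception as err:  # noqa: BLE001
            fail("geometry", err)

    if outdir:
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest
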