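"""End-to-end pipeline: simulate -> analyze -> diffuse -> merge -> map.

Two modes, selected by the configuration:

* fixed-phenotype (``yp`` or ``tb`` set): all cells share one CheY-P
  level; stages stop after the diffusion fits.
* population (neither set): protein numbers are sampled per cell, the
  pathway model supplies each cell's CheY-P, trajectories are simulated
  at those levels, and the estimated tumble biases are merged back with
  the true protein numbers to build the phenotype maps and the global
  log-linear fit.

Every stage communicates through the declared table schemas only; a JSON
manifest records seeds, parameter hashes, and row counts so a run can be
reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import RunConfig
from .diffusion import approx_diffusion, correlation_curves, fit_motility_model
from .maps import fit_loglinear, local_linear_mean, local_residual_sd
from .noise import simulate_population_phenotypes
from .simulate import adaptive_motor, simulate_cells, yp_for_bias
from .tracks import (
    ShortTrajectoryError,
    annotate_states,
    fit_behavior_model,
    summarize_motility,
)

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _params_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {
            g: dataclasses.asdict(getattr(cfg, g))
            for g in ("motor", "swim", "pathway", "noise")
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full in-silico experiment described by ``cfg``.

    Returns the manifest dictionary (also written to ``manifest.json`` in
    the output directory).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tumblekit_version": __version__,
        "seed": cfg.seed,
        "params_hash": _params_hash(cfg),
        "stages": {},
    }

    # --- simulate -------------------------------------------------------
    population_mode = cfg.yp is None and cfg.tb is None
    numbers = None
    if population_mode:
        pop = simulate_population_phenotypes(
            cfg.noise, cfg.pathway, cfg.n_cells, cfg.seed,
            with_lna=cfg.with_lna, mp=None,
        )
        io.write_table(pop, out / "population.csv", "population")
        numbers = pop
        yps = np.nan_to_num(pop.Yp_eff.to_numpy(), nan=0.0)
        manifest["stages"]["population"] = {
            "n_cells": len(pop),
            "n_failed": pop.attrs["n_failed"],
        }
    else:
        yp = cfg.yp if cfg.yp is not None else yp_for_bias(cfg.tb, cfg.motor)
        yps = np.full(cfg.n_cells, yp)
        manifest["stages"]["population"] = {"fixed_yp": float(yp)}

    # population mode: per-cell CheY-P comes from the pathway model, whose
    # tumble-bias readout is the adaptive (reduced-gain) motor curve, so
    # the trajectories are switched with the matching adapted motor
    sim_mp = adaptive_motor(cfg.motor) if population_mode else cfg.motor
    trajs = simulate_cells(
        yps, cfg.n_cells, cfg.duration, cfg.seed, mp=sim_mp, sp=cfg.swim
    )
    if population_mode and numbers is not None:
        for tr, cid in zip(trajs, numbers.cell_id):
            tr.cell_id = str(cid)
    io.write_trajectories(trajs, out / "trajectories.csv")
    manifest["stages"]["simulate"] = {"n_cells": len(trajs)}

    if not trajs:
        for name, schema in (
            ("summaries.csv", "summaries"),
            ("motility_fits.csv", "motility_fits"),
        ):
            io.write_table(pd.DataFrame(columns=io.SCHEMAS[schema]), out / name, schema)
        manifest["stages"]["analyze"] = {"n_cells": 0}
        manifest["stages"]["diffuse"] = {"n_cells": 0}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    # --- analyze --------------------------------------------------------
    model = fit_behavior_model(trajs, tol=cfg.tol, seed=cfg.seed)
    model.save(out / "behavior_model.json")
    summaries = []
    ann_frames = []
    n_short = 0
    for tr in trajs:
        ann = annotate_states(tr, model)
        ann_frames.append(io.annotation_to_frame(tr, ann))
        try:
            summaries.append(
                summarize_motility(tr, ann, min_duration=cfg.min_duration)
            )
        except ShortTrajectoryError as err:
            n_short += 1
            logger.info("discarded: %s", err)
    io.write_table(
        pd.concat(ann_frames, ignore_index=True), out / "annotations.csv", "annotations"
    )
    sum_df = io.summaries_to_frame(summaries)
    io.write_table(sum_df, out / "summaries.csv", "summaries")
    manifest["stages"]["analyze"] = {
        "n_cells": len(summaries),
        "n_short_discarded": n_short,
        "classifier_converged": model.converged,
    }

    # --- diffuse --------------------------------------------------------
    summ_by_id = {s.cell_id: s for s in summaries}
    fit_rows = []
    for tr in trajs:
        curves = correlation_curves(tr, max_lag=cfg.max_lag)
        fit = fit_motility_model(curves, cell_id=tr.cell_id)
        d_apx = np.nan
        summ = summ_by_id.get(tr.cell_id)
        if (
            summ is not None
            and np.isfinite(summ.mean_cos_turn)
            and summ.mean_cos_turn < 1
            and np.isfinite(summ.mean_speed)
        ):
            d_apx = approx_diffusion(
                summ.mean_speed, summ.mean_run_time, summ.mean_cos_turn
            )
        fit_rows.append(
            {
                "cell_id": fit.cell_id,
                "v0": fit.v0,
                "tau_persist": fit.tau_persist,
                "omega": fit.omega,
                "D_eff": fit.D_eff,
                "D_apx": d_apx,
                "fit_quality": fit.fit_quality,
                "converged": fit.converged,
            }
        )
    io.write_table(
        pd.DataFrame(fit_rows), out / "motility_fits.csv", "motility_fits"
    )
    manifest["stages"]["diffuse"] = {"n_cells": len(fit_rows)}

    # --- merge + map (population mode only) -----------------------------
    if population_mode and numbers is not None:
        merged = sum_df.merge(
            numbers[["cell_id", "N_R", "N_B", "Yp_eff", "tb"]], on="cell_id"
        )
        merged.to_csv(out / "merged_cells.csv", index=False)
        manifest["stages"]["merge"] = {"n_cells": len(merged)}
        if len(merged) >= 30:
            mean_map = local_linear_mean(
                merged.N_R, merged.N_B, merged.tumble_bias, bandwidth=cfg.bandwidth
            )
            sd_map = local_residual_sd(
                merged.N_R, merged.N_B, merged.tumble_bias, bandwidth=cfg.bandwidth
            )
            io.write_table(io.map_to_frame(mean_map), out / "mean_tb_map.csv", "maps")
            io.write_table(io.map_to_frame(sd_map), out / "resid_sd_map.csv", "maps")
            fit = fit_loglinear(
                merged.N_R, merged.N_B, merged.tumble_bias,
                n_boot=200, seed=cfg.seed,
            )
            (out / "loglinear_fit.json").write_text(
                json.dumps(
                    {"a": fit.a, "b": fit.b, "c": fit.c, "ci": fit.ci,
                     "n_cells": fit.n_cells},
                    indent=2,
                )
            )
            manifest["stages"]["map"] = {"c": fit.c, "n_cells": fit.n_cells}
        else:
            manifest["stages"]["map"] = {"skipped": "fewer than 30 cells"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
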