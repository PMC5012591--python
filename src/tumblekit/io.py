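"""Table formats and readers/writers.

All tables are plain CSV with a header row and SI-style units (s, um,
uM).  Schemas are validated on read; missing required columns raise a
``SchemaError`` naming the offenders.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import Trajectory
from .tracks import MotilitySummary, StateAnnotation

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "write_trajectories",
    "read_trajectories",
    "summaries_to_frame",
    "annotation_to_frame",
]

SCHEMAS = {
    "trajectories": ["cell_id", "t", "x", "y", "truth_state"],
    "annotations": ["cell_id", "t", "state", "p_S", "p_I", "p_T"],
    "summaries": [
        "cell_id", "tumble_bias", "mean_run_time", "mean_speed",
        "mean_cos_turn", "n_frames", "duration",
    ],
    "motility_fits": [
        "cell_id", "v0", "tau_persist", "omega", "D_eff", "D_apx",
        "fit_quality", "converged",
    ],
    "population": [
        "cell_id", "N_R", "N_B", "N_A", "N_Y", "N_Z", "N_T",
        "Yp_ss", "varYp", "n_eff", "Yp_eff", "tb",
    ],
    "maps": ["log10_NR", "log10_NB", "value", "supported"],
}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _check(df: pd.DataFrame, schema: str) -> None:
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"table does not match schema {schema!r}: missing columns {missing}"
        )


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    _check(df, schema)
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path, schema: str) -> pd.DataFrame:
    # round_trip parsing keeps write->read lossless at full float precision
    df = pd.read_csv(path, float_precision="round_trip")
    _check(df, schema)
    return df


def write_trajectories(trajs: Iterable[Trajectory], path) -> None:
    frames = []
    for tr in trajs:
        truth = (
            tr.truth_state
            if tr.truth_state is not None
            else np.full(len(tr), "", dtype=object)
        )
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "t": tr.t,
                    "x": tr.x,
                    "y": tr.y,
                    "truth_state": truth,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=SCHEMAS["trajectories"]
    )
    write_table(df, path, "trajectories")


def read_trajectories(path) -> list[Trajectory]:
    df = read_table(path, "trajectories")
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        truth = grp["truth_state"].astype(object).where(grp["truth_state"].notna(), "")
        has_truth = bool((truth != "").any())
        out.append(
            Trajectory(
                t=grp["t"].to_numpy(),
                x=grp["x"].to_numpy(),
                y=grp["y"].to_numpy(),
                truth_state=truth.to_numpy() if has_truth else None,
                cell_id=str(cid),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[MotilitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": s.cell_id,
                "tumble_bias": s.tumble_bias,
                "mean_run_time": s.mean_run_time,
                "mean_speed": s.mean_speed,
                "mean_cos_turn": s.mean_cos_turn,
                "n_frames": s.n_frames,
                "duration": s.duration,
                "n_tumbles": s.n_tumbles,
            }
            for s in summaries
        ]
    )


def annotation_to_frame(
    traj: Trajectory, ann: StateAnnotation
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": traj.cell_id,
            "t": traj.t,
            "state": ann.state,
            "p_S": ann.posterior[:, 0],
            "p_I": ann.posterior[:, 1],
            "p_T": ann.posterior[:, 2],
        }
    )


def map_to_frame(pm) -> pd.DataFrame:
    """Gridded PhenotypeMap -> long-format table."""
    GX, GY = np.meshgrid(pm.grid_logR, pm.grid_logB)
    return pd.DataFrame(
        {
            "log10_NR": GX.ravel(),
            "log10_NB": GY.ravel(),
            "value": pm.values.ravel(),
            "supported": pm.support_mask.ravel(),
        }
    )
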