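"""Replicated runs, convergence detection and one-at-a-time parameter sweeps.

The robustness analysis varies each population-level parameter over its
documented range while holding the others at their defaults, runs several
replicate simulations per setting, and summarizes the end state of every
run.  "Reaching a stable distribution" is operationalized as windowed-mean
stability: a trajectory series has converged once its rolling mean stays
within a relative tolerance of its final value for the rest of the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ExtinctionError, run_simulation, summaries_to_frame
from .model import PARAM_RANGES, SimParams

__all__ = [
    "SweepSpec",
    "NOT_CONVERGED",
    "replicate_seed",
    "run_replicates",
    "detect_convergence",
    "sweep",
    "default_sweep_values",
]

#: Sentinel returned when a series never satisfies the stability criterion.
NOT_CONVERGED = -1

#: Final-window mean fitness below which a run is flagged as collapsed
#: (the population can no longer sustain division).
COLLAPSE_FITNESS = 0.01


@dataclass(frozen=True)
class SweepSpec:
    """One-at-a-time sweep specification.

    ``values`` maps parameter names to the value lists to sweep; each
    setting overrides a single parameter of ``base``.  Replicate seeds are
    derived from ``base.seed`` and the (setting, replicate) index so no
    RNG stream is reused.
    """

    base: SimParams = field(default_factory=SimParams)
    values: dict[str, list[float]] = field(default_factory=dict)
    replicates: int = 5

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.values) - set(PARAM_RANGES)
        if unknown:
            raise ValueError(f"unknown sweep parameters: {sorted(unknown)}")

    def settings(self) -> list[tuple[str, float, SimParams]]:
        """Expand to (parameter, value, params) rows, defaults first."""
        out: list[tuple[str, float, SimParams]] = [("default", np.nan, self.base)]
        for name, vals in self.values.items():
            for v in vals:
                v = int(v) if name in ("I", "M") else float(v)
                out.append((name, float(v), self.base.with_(**{name: v})))
        return out


def default_sweep_values(n_per_param: int = 2) -> dict[str, list[float]]:
    """Endpoints (or an evenly spaced grid) of each documented parameter range."""
    out = {}
    for name, (lo, hi) in PARAM_RANGES.items():
        vals = np.linspace(lo, hi, n_per_param)
        if name in ("I", "M"):
            vals = np.unique(np.round(vals).astype(int))
        out[name] = [float(v) for v in vals]
    return out


def replicate_seed(base_seed: int, setting: int, replicate: int) -> int:
    """Deterministic per-(setting, replicate) seed with no collisions."""
    ss = np.random.SeedSequence([int(base_seed), int(setting), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def detect_convergence(
    trajectory: pd.DataFrame,
    window: int = 2000,
    tol: float = 0.05,
    series: tuple[str, ...] = ("mean_E", "mean_X", "mean_N"),
) -> dict[str, int]:
    """First iteration at which each series' windowed mean stays within
    ``tol`` (relative) of its final value for the rest of the run.

    ``window`` is in iterations; it is converted to recorded rows using
    the trajectory's recording cadence.  Returns NOT_CONVERGED (-1) for a
    series that never stabilizes.
    """
    if len(trajectory) == 0:
        raise ValueError("trajectory is empty")
    iters = trajectory["iteration"].to_numpy()
    cadence = int(iters[1] - iters[0]) if len(iters) > 1 else 1
    w = max(1, int(round(window / max(cadence, 1))))
    if w > len(trajectory):
        raise ValueError(f"window of {w} rows exceeds trajectory length {len(trajectory)}")
    out: dict[str, int] = {}
    for col in series:
        x = trajectory[col].to_numpy(dtype=float)
        roll = pd.Series(x).rolling(w, min_periods=1).mean().to_numpy()
        final = roll[-1]
        scale = max(abs(final), 1e-12)
        ok = np.abs(roll - final) <= tol * scale
        # converged at the first index after the last deviating windowed mean,
        # provided at least one full window of stability follows it
        bad = np.flatnonzero(~ok)
        if bad.size == 0:
            out[col] = int(iters[0])
        elif bad[-1] + 1 > len(x) - w:
            out[col] = NOT_CONVERGED
        else:
            out[col] = int(iters[bad[-1] + 1])
    return out


def _end_state_row(traj: pd.DataFrame, final_window: int, conv_window: int, conv_tol: float) -> dict:
    cadence = (
        int(traj["iteration"].iloc[1] - traj["iteration"].iloc[0]) if len(traj) > 1 else 1
    )
    tail_rows = max(1, int(round(final_window / max(cadence, 1))))
    tail = traj.tail(tail_rows)
    try:
        conv = detect_convergence(traj, window=conv_window, tol=conv_tol)
    except ValueError:
        conv = {k: NOT_CONVERGED for k in ("mean_E", "mean_X", "mean_N")}
    return {
        "end_mean_X": float(tail["mean_X"].mean()),
        "end_mean_E": float(tail["mean_E"].mean()),
        "end_mean_N": float(tail["mean_N"].mean()),
        "end_mean_F": float(tail["mean_F"].mean()),
        "conv_iter_E": conv["mean_E"],
        "conv_iter_X": conv["mean_X"],
        "conv_iter_N": conv["mean_N"],
        "collapsed": bool(tail["mean_F"].mean() < COLLAPSE_FITNESS),
    }


def run_replicates(
    params: SimParams,
    n: int = 5,
    record_every: int = 100,
    final_window: int = 1000,
    conv_window: int = 2000,
    conv_tol: float = 0.05,
    setting_index: int = 0,
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Run ``n`` independently seeded replicates of one parameter setting.

    Returns (end-state table with one row per replicate, list of
    per-replicate trajectory frames).  End-state means are averaged over
    the trailing ``final_window`` iterations of each trajectory.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, trajs = [], []
    for rep in range(n):
        seed = replicate_seed(params.seed, setting_index, rep)
        p = params.with_(seed=seed)
        extinct = False
        try:
            traj = summaries_to_frame(run_simulation(p, record_every=record_every))
        except ExtinctionError:
            extinct = True
            traj = pd.DataFrame()
        row = {"replicate": rep, "seed": seed, "extinct": extinct}
        if not extinct:
            row.update(_end_state_row(traj, final_window, conv_window, conv_tol))
        rows.append(row)
        trajs.append(traj)
    return pd.DataFrame(rows), trajs


def sweep(
    spec: SweepSpec,
    record_every: int = 100,
    final_window: int = 1000,
    conv_window: int = 2000,
    conv_tol: float = 0.05,
) -> pd.DataFrame:
    """One-at-a-time sweep over the spec's value lists.

    Each setting overrides a single parameter of the base configuration
    and is run for ``spec.replicates`` independently seeded replicates.
    Returns one row per (setting, replicate).
    """
    frames = []
    for s_idx, (name, value, params) in enumerate(spec.settings()):
        table, _ = run_replicates(
            params,
            n=spec.replicates,
            record_every=record_every,
            final_window=final_window,
            conv_window=conv_window,
            conv_tol=conv_tol,
            setting_index=s_idx,
        )
        table.insert(0, "parameter", name)
        table.insert(1, "value", value)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)
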