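"""Experiment drivers: amplitude sweeps, time courses, temptation sweeps,
extinction thresholds, and the amplitude-temptation phase diagram.

Two named protocols are provided.  ``desk`` (L=50, 5000 MCS, 500-MCS
window, 3 replicates) is the routine scale used by the test-suite and the
reproduction scripts; ``reference`` (L=100, 61000 MCS, 1000-MCS window, 10
replicates) is the full reference protocol, preserved as an opt-in.

Seed splitting: a sweep with global seed ``s`` gives the replicate ``r`` of
grid point ``p`` the stream ``SeedSequence(s, spawn_key=(p, r))``, so adding
replicates or grid points never perturbs existing realizations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .dynamics import run
from .model import GameParams, LatticeSpec, WeightParams
from .observables import Trajectory

PROTOCOLS: dict[str, dict] = {
    "desk": dict(L=50, total_mcs=5000, measure_window=500, replicates=3),
    "reference": dict(L=100, total_mcs=61000, measure_window=1000, replicates=10),
}


def make_config(
    b: float,
    delta: float,
    Delta: float,
    protocol: str = "desk",
    init_mode: str = "random",
    seed: int = 0,
    **overrides,
) -> RunConfig:
    """Build a RunConfig from a named protocol plus per-field overrides."""
    p = dict(PROTOCOLS[protocol])
    p.update(overrides)
    return RunConfig(
        lattice=LatticeSpec(L=p["L"]),
        game=GameParams(b=b),
        weight=WeightParams(delta=delta, Delta=Delta),
        init_mode=init_mode,
        total_mcs=p["total_mcs"],
        measure_window=p["measure_window"],
        replicates=p["replicates"],
        seed=seed,
    )


@dataclass
class SweepResult:
    """Tidy per-replicate stationary rho_C over a parameter grid.

    ``data`` has one row per (grid point, replicate) with columns
    ``b, delta, Delta, ratio, replicate, rho``; ``axis`` names the swept
    column (``ratio`` or ``b``).
    """

    data: pd.DataFrame
    axis: str

    def aggregate(self) -> pd.DataFrame:
        """Per-point mean, standard error (NaN for a single replicate) and n."""
        g = self.data.groupby(self.axis)["rho"]
        out = g.agg(mean="mean", n="count")
        out["sem"] = g.sem(ddof=1)
        return out.reset_index()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _point_seed(seed: int, point: int, replicate: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=(point, replicate))


def _stationary_replicates(cfg: RunConfig, point: int, early_stop: bool) -> list[float]:
    vals = []
    for r in range(cfg.replicates):
        traj = run(cfg, _point_seed(cfg.seed, point, r), early_stop=early_stop)
        vals.append(traj.stationary(cfg.measure_window))
    return vals


def sweep_amplitude(
    b: float,
    delta: float,
    ratio_grid: Sequence[float],
    config: RunConfig | None = None,
    *,
    protocol: str = "desk",
    seed: int = 0,
    early_stop: bool = True,
) -> SweepResult:
    """Stationary rho_C versus link-weight amplitude Delta/delta at fixed b, delta.

    Each grid ratio rho runs ``replicates`` realizations with
    ``Delta = ratio * delta``.  ``delta > 0`` is required: the amplitude
    ratio is undefined at delta = 0.
    """
    if delta == 0.0:
        raise ValueError("amplitude sweep requires delta > 0 (Delta/delta undefined at delta = 0)")
    if any(r < 0 for r in ratio_grid):
        raise ValueError("amplitude ratios must be >= 0")
    rows = []
    for p, ratio in enumerate(ratio_grid):
        cfg = (
            make_config(b, delta, ratio * delta, protocol=protocol, seed=seed)
            if config is None
            else _with_params(config, b=b, delta=delta, Delta=ratio * delta)
        )
        for r, rho in enumerate(_stationary_replicates(cfg, p, early_stop)):
            rows.append(
                dict(ratio=ratio, b=b, delta=delta, Delta=ratio * delta, replicate=r, rho=rho, N=cfg.lattice.N)
            )
    return SweepResult(data=pd.DataFrame(rows), axis="ratio")


def _with_params(config: RunConfig, b: float, delta: float, Delta: float) -> RunConfig:
    return RunConfig(
        lattice=config.lattice,
        game=GameParams(b=b),
        weight=WeightParams(delta=delta, Delta=Delta),
        init_mode=config.init_mode,
        total_mcs=config.total_mcs,
        measure_window=config.measure_window,
        replicates=config.replicates,
        seed=config.seed,
    )


def time_course(
    config: RunConfig,
    snapshot_steps: Iterable[int] = (),
    *,
    record_weight_stats: bool = False,
    replicate: int = 0,
) -> Trajectory:
    """Per-MCS rho_C series (no early stop) plus snapshots at the requested steps."""
    return run(
        config,
        _point_seed(config.seed, 0, replicate),
        snapshot_steps=tuple(snapshot_steps),
        record_weight_stats=record_weight_stats,
        early_stop=False,
    )


def sweep_temptation(
    delta: float,
    Delta_list: Sequence[float],
    b_grid: Sequence[float],
    config: RunConfig | None = None,
    *,
    protocol: str = "desk",
    seed: int = 0,
    early_stop: bool = True,
) -> SweepResult:
    """Stationary rho_C versus temptation b, one curve per weight step Delta."""
    if any(not 1.0 < b < 2.0 for b in b_grid):
        raise ValueError("temptation values must satisfy 1 < b < 2")
    rows = []
    point = 0
    for Delta in Delta_list:
        for b in b_grid:
            cfg = (
                make_config(b, delta, Delta, protocol=protocol, seed=seed)
                if config is None
                else _with_params(config, b=b, delta=delta, Delta=Delta)
            )
            for r, rho in enumerate(_stationary_replicates(cfg, point, early_stop)):
                ratio = Delta / delta if delta > 0 else np.nan
                rows.append(
                    dict(b=b, delta=delta, Delta=Delta, ratio=ratio, replicate=r, rho=rho, N=cfg.lattice.N)
                )
            point += 1
    return SweepResult(data=pd.DataFrame(rows), axis="b")


def find_extinction_threshold(
    result: SweepResult | pd.DataFrame,
    target: str = "cooperators",
    tol: float | None = None,
) -> float | None:
    """Critical temptation at which the target strategy goes extinct.

    For cooperators: the largest b whose mean stationary rho_C exceeds the
    extinction tolerance, linearly interpolated to the crossing with the
    next grid point.  For defectors: same with rho_C measured against
    ``1 - tol`` (full cooperator dominance).  Returns ``None`` when the
    transition is not bracketed by the scanned b range (including a curve
    that never rises above the tolerance).

    ``tol`` defaults to ``1/N^2`` so that any surviving individual of the
    target strategy anywhere in the window counts as non-extinct.  Raising
    the tolerance can only lower the cooperator threshold.
    """
    if isinstance(result, SweepResult):
        if result.axis != "b":
            raise ValueError("extinction threshold requires a sweep over b")
        if tol is None:
            tol = 1.0 / float(result.data["N"].min()) ** 2
        agg = result.aggregate()
    else:
        agg = result
    b = np.asarray(agg["b"] if "b" in agg else agg.iloc[:, 0], dtype=float)
    rho = np.asarray(agg["mean"], dtype=float)
    order = np.argsort(b)
    b, rho = b[order], rho[order]
    if tol is None:
        tol = 1.0 / 2500.0**2  # desk-lattice default when the table carries no N
    if target == "cooperators":
        level = tol
        survives = rho > level
    elif target == "defectors":
        level = 1.0 - tol
        survives = rho > level
    else:
        raise ValueError("target must be 'cooperators' or 'defectors'")
    if not survives.any():
        return None
    i = int(np.flatnonzero(survives)[-1])
    if i == len(b) - 1:
        return None  # transition above the scanned range
    # linear interpolation of rho between the bracketing grid points
    frac = (rho[i] - level) / (rho[i] - rho[i + 1])
    return float(b[i] + frac * (b[i + 1] - b[i]))


@dataclass
class PhaseDiagram:
    """Stationary rho_C over the (Delta/delta, b) grid with extinction boundaries."""

    ratio_grid: np.ndarray
    b_grid: np.ndarray
    rho: np.ndarray  # (len(ratio_grid), len(b_grid)) mean stationary rho_C
    boundaries: pd.DataFrame  # columns ratio, b_c_cooperators, b_c_defectors
    data: pd.DataFrame  # tidy per-replicate rows


def phase_diagram(
    ratio_grid: Sequence[float],
    b_grid: Sequence[float],
    delta: float,
    config: RunConfig | None = None,
    *,
    protocol: str = "desk",
    seed: int = 0,
    tol: float | None = None,
    early_stop: bool = True,
) -> PhaseDiagram:
    """Map stationary rho_C over the amplitude-temptation plane and extract,
    per amplitude ratio, the cooperator- and defector-extinction boundaries."""
    if len(ratio_grid) == 0 or len(b_grid) == 0:
        raise ValueError("grids must be non-empty")
    if delta <= 0.0:
        raise ValueError("phase diagram requires delta > 0")
    frames = []
    rho_mat = np.empty((len(ratio_grid), len(b_grid)))
    bounds = []
    for ir, ratio in enumerate(ratio_grid):
        sweep = sweep_temptation(
            delta,
            [ratio * delta],
            b_grid,
            config,
            protocol=protocol,
            seed=seed + ir,
            early_stop=early_stop,
        )
        sweep.data["ratio"] = ratio
        frames.append(sweep.data)
        agg = sweep.aggregate()
        rho_mat[ir] = agg.sort_values("b")["mean"].to_numpy()
        bounds.append(
            dict(
                ratio=ratio,
                b_c_cooperators=find_extinction_threshold(sweep, "cooperators", tol),
                b_c_defectors=find_extinction_threshold(sweep, "defectors", tol),
            )
        )
    return PhaseDiagram(
        ratio_grid=np.asarray(ratio_grid, dtype=float),
        b_grid=np.asarray(b_grid, dtype=float),
        rho=rho_mat,
        boundaries=pd.DataFrame(bounds),
        data=pd.concat(frames, ignore_index=True),
    )
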