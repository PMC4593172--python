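"""Measurement: cooperation fraction, stationary averages, weight statistics, snapshots."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import SimState, WeightParams


def cooperation_fraction(state: SimState) -> float:
    """Fraction of cooperators rho_C = (# C sites) / N."""
    return float(np.count_nonzero(state.strategies)) / state.spec.N


@dataclass(frozen=True)
class Snapshot:
    """Immutable copy of the strategy field at a given MCS (1=C, 0=D)."""

    mcs: int
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid.setflags(write=False)


def capture_snapshot(state: SimState) -> Snapshot:
    return Snapshot(mcs=state.mcs, grid=state.strategies.copy())


@dataclass
class Trajectory:
    """Per-MCS time series of rho_C; index t holds rho_C after t MCS (t=0 initial)."""

    rho: np.ndarray
    mean_weight: np.ndarray | None = None
    var_weight: np.ndarray | None = None
    snapshots: list[Snapshot] = field(default_factory=list)
    seed: int | None = None
    fixated_at: int | None = None  # MCS at which the strategy field became uniform
    final_state: SimState | None = None

    @property
    def mcs(self) -> np.ndarray:
        return np.arange(len(self.rho))

    def stationary(self, window: int) -> float:
        return stationary_fraction(self, window)

    def to_csv(self, path: str | Path) -> None:
        """Columns mcs, rho_c, mean_weight, var_weight ('.' decimal, no locale)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["mcs", "rho_c", "mean_weight", "var_weight"])
            for t in range(len(self.rho)):
                mw = "" if self.mean_weight is None else repr(float(self.mean_weight[t]))
                vw = "" if self.var_weight is None else repr(float(self.var_weight[t]))
                writer.writerow([t, repr(float(self.rho[t])), mw, vw])


def stationary_fraction(traj: Trajectory, window: int) -> float:
    """Mean rho_C over the trailing ``window`` MCS of the trajectory."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(traj.rho):
        raise ValueError(f"window {window} exceeds trajectory length {len(traj.rho)}")
    return float(np.mean(traj.rho[-window:]))


@dataclass(frozen=True)
class WeightSummary:
    """Histogram, mean and population variance of the 4 L^2 edge weights."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    variance: float


def weight_bin_edges(wp: WeightParams, bins: int | None = None) -> np.ndarray:
    """Histogram bin edges over [1-delta, 1+delta].

    When ``Delta > 0`` the attainable weights live on the lattice
    ``{1 - delta + m Delta}`` (clamped), so the default aligns bin edges to
    half-integer multiples of Delta: each attainable value falls in the
    middle of its own bin, avoiding split-value artifacts.  Explicit
    ``bins`` (or a frozen weight field) falls back to uniform binning.
    """
    lo, hi = 1.0 - wp.delta, 1.0 + wp.delta
    if bins is not None:
        if bins < 1:
            raise ValueError("bins must be >= 1")
        return np.linspace(lo, hi, bins + 1)
    if wp.frozen:
        return np.linspace(lo if lo < hi else lo - 0.5, hi if hi > lo else hi + 0.5, 65)
    n = int(np.ceil(2.0 * wp.delta / wp.Delta))
    return lo - 0.5 * wp.Delta + np.arange(n + 2) * wp.Delta


def weight_summary(state: SimState, wp: WeightParams, bins: int | None = None) -> WeightSummary:
    w = state.edge_weights
    edges = weight_bin_edges(wp, bins)
    counts, _ = np.histogram(w, bins=edges)
    # histogram must conserve mass; clamped values sit strictly inside the range
    assert int(counts.sum()) == w.size, "weight histogram lost mass"
    variance = float(np.var(w))  # population variance over all 4L^2 edges
    assert variance <= wp.delta**2 + 1e-12, (
        "edge-weight variance exceeds the hard bound delta^2 for a variable "
        "confined to [1-delta, 1+delta]"
    )
    return WeightSummary(bin_edges=edges, counts=counts, mean=float(np.mean(w)), variance=variance)


def weight_summary_to_csv(summary: WeightSummary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_left", "bin_right", "count"])
        for i, c in enumerate(summary.counts):
            writer.writerow([repr(float(summary.bin_edges[i])), repr(float(summary.bin_edges[i + 1])), int(c)])


def snapshot_to_text(snap: Snapshot, path: str | Path) -> None:
    """Plain-text integer matrix, one row per lattice row (0=D, 1=C)."""
    np.savetxt(path, snap.grid, fmt="%d")


def snapshot_to_image(snap: Snapshot, path: str | Path) -> None:
    """Two-color portable image: blue cooperators, red defectors (PNG),
    or grayscale PGM (white cooperators) when the suffix is .pgm."""
    path = Path(path)
    if path.suffix == ".pgm":
        grid = snap.grid.astype(np.uint8) * 255
        with open(path, "w") as fh:
            fh.write(f"P2\n{grid.shape[1]} {grid.shape[0]}\n255\n")
            np.savetxt(fh, grid, fmt="%d")
        return
    from PIL import Image

    rgb = np.empty((*snap.grid.shape, 3), dtype=np.uint8)
    rgb[snap.grid == 1] = (31, 119, 180)  # cooperators: blue
    rgb[snap.grid == 0] = (214, 39, 40)  # defectors: red
    Image.fromarray(rgb).save(path)
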