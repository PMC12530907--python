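"""Two-way probability grid sweep and cost-threshold detection.

The two transition probabilities are varied independently on a grid —
sentinel-node-not-found rate ``q`` from 0% to 5.7% in 0.5% steps (the 5.7%
endpoint is included explicitly since the range is not divisible by the
step) and occult-metastasis rate ``p`` from 9% to 100% in 1% steps — and
each cell is an independent two-arm simulation.  Along a fixed-``q`` slice,
two thresholds are read off in increasing ``p``: where the SLNB strategy's
cost advantage stops being significant, and where upfront SND becomes
significantly cheaper (the cost crossover).  Because single-cell
significance flips are stochastic, thresholds require a sustained run of
qualifying cells (default 3) rather than a first occurrence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .strategy import CellResult, StrategyParameters, simulate_cell

__all__ = [
    "GridSpec",
    "GridResult",
    "Thresholds",
    "default_grid",
    "run_grid",
    "find_thresholds",
    "plot_cost_curve",
]


@dataclass(frozen=True)
class GridSpec:
    """Ordered probability axes of the two-way sensitivity grid."""

    p_values: tuple[float, ...]
    q_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, vals in (("p_values", self.p_values), ("q_values", self.q_values)):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} must be non-empty")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def n_cells(self) -> int:
        return len(self.p_values) * len(self.q_values)


def default_grid() -> GridSpec:
    """The default sweep: p = 9%..100% step 1% (92 values), q = 0%..5.5%
    step 0.5% plus the 5.7% endpoint (13 values); 1,196 cells."""
    p = np.round(np.arange(9, 101) / 100.0, 2).tolist()
    q = np.append(np.round(np.arange(0, 12) * 0.005, 4), 0.057).tolist()
    return GridSpec(p_values=tuple(p), q_values=tuple(q))


@dataclass(frozen=True)
class GridResult:
    """All per-cell comparisons plus the metadata needed to reproduce them."""

    spec: GridSpec
    cells: tuple[CellResult, ...]
    master_seed: int
    n_per_arm: int
    alpha: float
    test_method: str

    def __post_init__(self) -> None:
        if len(self.cells) != self.spec.n_cells:
            raise ValueError(
                f"expected {self.spec.n_cells} cells, got {len(self.cells)}"
            )

    def slice_at_q(self, q_value: float) -> list[CellResult]:
        """Cells at one ``q``, ordered by increasing ``p``."""
        if q_value not in self.spec.q_values:
            raise KeyError(
                f"q={q_value} not on the grid (q_values={self.spec.q_values})"
            )
        cells = [c for c in self.cells if c.q_notfound == q_value]
        return sorted(cells, key=lambda c: c.p_occult)

    def to_frame(self) -> pd.DataFrame:
        """One row per cell (CSV-ready)."""
        return pd.DataFrame([asdict(c) for c in self.cells])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_grid(
    grid: GridSpec,
    params: StrategyParameters,
    master_seed: int,
) -> GridResult:
    """Simulate every (p, q) cell of ``grid`` under the ``params`` template.

    Each cell uses an independent substream keyed by its grid coordinates,
    so the sweep is deterministic under ``master_seed`` and cell results do
    not depend on evaluation order.
    """
    cells = []
    for j, q in enumerate(grid.q_values):
        for i, p in enumerate(grid.p_values):
            cell_params = replace(params, p_occult=float(p), q_notfound=float(q))
            seed = np.random.SeedSequence([master_seed, i, j])
            try:
                cells.append(simulate_cell(cell_params, seed))
            except ValueError as exc:
                raise ValueError(f"cell (p={p}, q={q}) failed: {exc}") from exc
    return GridResult(
        spec=grid,
        cells=tuple(cells),
        master_seed=master_seed,
        n_per_arm=params.n_per_arm,
        alpha=params.alpha,
        test_method=params.test_method,
    )


@dataclass(frozen=True)
class Thresholds:
    """Detected thresholds along one q-slice, as probabilities (or ``None``
    when no sustained run qualifies)."""

    q_value: float
    first_nonsignificant_p: Optional[float]
    first_reversal_p: Optional[float]
    run_length: int

    def to_dict(self) -> dict:
        return asdict(self)


def _first_sustained_run(flags: Sequence[bool], run_length: int) -> Optional[int]:
    """Index starting the first run of >= run_length consecutive True."""
    run = 0
    for i, f in enumerate(flags):
        run = run + 1 if f else 0
        if run >= run_length:
            return i - run_length + 1
    return None


def find_thresholds(
    grid_result: GridResult, q_value: float, run_length: int = 3
) -> Thresholds:
    """Scan a q-slice in increasing ``p`` for the two sustained transitions.

    * ``first_nonsignificant_p``: smallest ``p`` starting a run of
      ``run_length`` cells that are *not* (significant and SLNB-cheaper) —
      the SLNB cost advantage is no longer demonstrable.
    * ``first_reversal_p``: smallest ``p`` starting a run of ``run_length``
      cells that are significant and SND-cheaper — the cost crossover.

    Whenever both exist, the first precedes (or equals) the second, since a
    reversal run also qualifies as a non-significant-advantage run.
    """
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    cells = grid_result.slice_at_q(q_value)
    not_advantage = [not (c.significant and c.direction == "slnb_cheaper") for c in cells]
    reversal = [c.significant and c.direction == "snd_cheaper" for c in cells]
    i_ns = _first_sustained_run(not_advantage, run_length)
    i_rev = _first_sustained_run(reversal, run_length)
    return Thresholds(
        q_value=q_value,
        first_nonsignificant_p=cells[i_ns].p_occult if i_ns is not None else None,
        first_reversal_p=cells[i_rev].p_occult if i_rev is not None else None,
        run_length=run_length,
    )


def plot_cost_curve(
    grid_result: GridResult,
    q_value: float,
    path: str | Path,
    run_length: int = 3,
) -> None:
    """Plot mean cost per arm against the occult-metastasis probability at
    one ``q``, shading the band where the cost difference is not significant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = grid_result.slice_at_q(q_value)
    p = [c.p_occult * 100 for c in cells]
    thr = find_thresholds(grid_result, q_value, run_length)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(p, [c.mean_slnb for c in cells], label="SLNB strategy", color="tab:blue")
    ax.plot(p, [c.mean_snd for c in cells], label="Upfront SND", color="tab:orange")
    if thr.first_nonsignificant_p is not None:
        lo = thr.first_nonsignificant_p * 100
        hi = (thr.first_reversal_p or cells[-1].p_occult) * 100
        ax.axvspan(lo, hi, color="grey", alpha=0.25, label="no significant difference")
        ax.axvline(lo, color="grey", ls="--", lw=1)
        ax.axvline(hi, color="grey", ls="--", lw=1)
    ax.set_xlabel("Probability of occult neck metastasis (%)")
    ax.set_ylabel("Mean cost per patient (R$)")
    ax.set_title(f"Strategy cost vs occult-metastasis probability (q = {q_value:.1%})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
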