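"""CSV and figure exports for simulation results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .angles import orientation_histogram

__all__ = [
    "write_quiver_csv",
    "write_histogram_csv",
    "write_result",
    "plot_quiver",
    "plot_orientation_histogram",
]


def write_quiver_csv(cells: pd.DataFrame, path) -> None:
    """Per-cell ``x, y, theta_rad`` table for quiver-style plotting."""
    cells[["x", "y", "theta"]].rename(columns={"theta": "theta_rad"}).to_csv(
        path, index=False
    )


def write_histogram_csv(angles, path, bin_width_deg: float = 10.0) -> None:
    counts, edges = orientation_histogram(angles, bin_width_deg)
    pd.DataFrame(
        {"bin_lo_deg": edges[:-1], "bin_hi_deg": edges[1:], "count": counts}
    ).to_csv(path, index=False)


def write_result(result, out_dir) -> Path:
    """Write a result bundle: summary JSON, per-snapshot cell tables, events.

    Returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = result.config.n_ticks
    summary = {
        "seed": result.seed,
        "n_ticks": n,
        "initial_count": int(result.counts[0]),
        "final_count": int(result.counts[-1]),
        "fold_change_final": result.fold_change(n),
        "final_density_per_mm2": result.density_per_mm2(n),
        "theta_p_rad": result.principal.theta_p,
        "theta_csa_rad": result.principal.theta_csa,
        "eps_max_amplitude": result.principal.eps_max,
        "counts": [int(c) for c in result.counts],
    }
    (out / "result.json").write_text(json.dumps(summary, indent=2))
    for tick, cells in result.snapshots.items():
        cells.to_csv(out / f"cells_{tick}.csv", index=False)
        write_quiver_csv(cells, out / f"quiver_{tick}.csv")
    result.events.to_csv(out / "events.csv", index=False)
    write_histogram_csv(result.population.theta, out / f"histogram_{n}.csv")
    if result.fiber_field is not None:
        result.fiber_field.export_vertices(out / "fiber_vertices.csv")
    return out


def plot_quiver(cells: pd.DataFrame, ax=None, **kwargs):
    """Quiver plot of cell orientation axes (headless-safe)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    u = np.cos(cells["theta"])
    v = np.sin(cells["theta"])
    kwargs.setdefault("headwidth", 1)
    kwargs.setdefault("pivot", "mid")
    ax.quiver(cells["x"], cells["y"], u, v, **kwargs)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    return ax


def plot_orientation_histogram(angles, ax=None, bin_width_deg: float = 10.0):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    counts, edges = orientation_histogram(angles, bin_width_deg)
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="k")
    ax.set_xlabel("orientation (deg)")
    ax.set_ylabel("cells")
    return ax
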