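"""Shared fixtures: small synthetic tissues and brute-force oracles.

The oracles deliberately use O(n^2) loops and no spatial indexing so they
stay independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spatialscore import CellTable, ScoreTriplet, SimulationConfig, simulate_spots


# ---------------------------------------------------------------------------
# oracles


def brute_force_nearest(df: pd.DataFrame, target_type: str) -> np.ndarray:
    """Per-row nearest same-spot target distance, self excluded; NaN if none.

    Quadratic scan per spot over plain arrays — no spatial index."""
    out = np.full(len(df), np.nan)
    arr = df.reset_index(drop=True)
    spots = arr["spot_id"].to_numpy()
    types = arr["cell_type"].to_numpy()
    xs, ys = arr["x"].to_numpy(float), arr["y"].to_numpy(float)
    for spot in np.unique(spots):
        rows = np.flatnonzero(spots == spot)
        tgt = rows[types[rows] == target_type]
        if len(tgt) == 0:
            continue
        for i in rows:
            best = np.inf
            for j in tgt:
                if j == i:
                    continue
                d = np.hypot(xs[i] - xs[j], ys[i] - ys[j])
                if d < best:
                    best = d
            if np.isfinite(best):
                out[i] = best
    return out


def brute_force_ratios(df: pd.DataFrame, triplet: ScoreTriplet) -> pd.Series:
    """SpatialScore for CT1 cells via the quadratic oracle (NaN if undefined)."""
    d2 = brute_force_nearest(df, triplet.ct2)
    d3 = brute_force_nearest(df, triplet.ct3)
    mask = (df["cell_type"] == triplet.ct1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = d2 / d3
    return pd.Series(r[mask], index=df["cell_id"][mask])


def brute_force_windows(df: pd.DataFrame, w: int, types: list[str]) -> np.ndarray:
    """Window composition vectors via explicit sorting per cell."""
    arr = df.reset_index(drop=True)
    out = np.zeros((len(arr), len(types)))
    for i in range(len(arr)):
        same = arr[arr["spot_id"] == arr.loc[i, "spot_id"]]
        d = np.hypot(same["x"] - arr.loc[i, "x"], same["y"] - arr.loc[i, "y"])
        order = np.argsort(d.to_numpy(), kind="stable")
        chosen = same.iloc[order[: min(w, len(same))]]
        for t, n in chosen["cell_type"].value_counts().items():
            out[i, types.index(t)] = n / len(chosen)
    return out


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def triplet() -> ScoreTriplet:
    return ScoreTriplet("PD-1+ CD4 T", "tumor", "Treg")


@pytest.fixture(scope="session")
def random_spots() -> CellTable:
    """20 CSR spots of <=200 cells each, used for oracle comparisons."""
    cfg = SimulationConfig(seed=20, cells_per_spot=180)
    return simulate_spots(cfg, 20, label="OR")


@pytest.fixture(scope="session")
def attracted_spots() -> CellTable:
    cfg = SimulationConfig(
        seed=21,
        cells_per_spot=250,
        attraction={("PD-1+ CD4 T", "tumor"): (3.0, 10.0)},
    )
    return simulate_spots(cfg, 10, label="AT")


def make_cells(records: list[dict], **kwargs) -> CellTable:
    """Tiny hand-written tables for arithmetic examples."""
    defaults = {
        "spot_id": "s1",
        "patient_id": "p1",
        "group": "responder",
        "timepoint": "pre",
        "size": 50.0,
    }
    rows = []
    for i, r in enumerate(records):
        row = dict(defaults)
        row["cell_id"] = f"c{i}"
        row.update(r)
        rows.append(row)
    return CellTable(pd.DataFrame(rows), **kwargs)
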