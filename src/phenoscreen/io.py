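"""Readers and writers for the screen's file formats.

All formats are plain text: ``cells.csv`` (one row per segmented cell),
``growth.csv`` (long-format OD600 time series), ``truth.json``
(generative ground truth of synthetic screens), plus the strain-level
``features.csv`` / ``scores.csv`` / ``islands.csv`` tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .growth import GrowthCurve
from .synthetic import ScreenTruth, StrainSpec

CELL_COLUMNS = [
    "strain_id", "plate", "well", "image_time_min", "od_imaging", "cell_id",
    "length_um", "width_um", "area_um2", "perimeter_um", "constriction_degree",
    "division_ratio", "nucleoid_count", "nucleoid_area_um2",
    "nucleoid_constriction_degree", "dapi_total", "phase_mean",
    "intracell_width_cv", "contour_phase_mean",
]


def write_cells(cells: dict[str, pd.DataFrame], path) -> None:
    table = pd.concat(cells.values(), ignore_index=True)
    cols = [c for c in CELL_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_cells(path) -> dict[str, pd.DataFrame]:
    table = pd.read_csv(path)
    return {sid: sub.reset_index(drop=True) for sid, sub in table.groupby("strain_id", sort=False)}


def write_growth(curves: dict[str, GrowthCurve], path) -> None:
    rows = []
    for sid, c in curves.items():
        rows.append(pd.DataFrame({"strain_id": sid, "time_min": c.times, "od600": c.od}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_growth(path) -> dict[str, GrowthCurve]:
    table = pd.read_csv(path)
    out = {}
    for sid, sub in table.groupby("strain_id", sort=False):
        out[sid] = GrowthCurve(
            strain_id=str(sid),
            times=sub["time_min"].to_numpy(),
            od=sub["od600"].to_numpy(),
        )
    return out


def write_truth(truth: ScreenTruth, path) -> None:
    d = {
        "seed": truth.seed,
        "n_cells_mean": truth.n_cells_mean,
        "n_cells_sd": truth.n_cells_sd,
        "wt_ids": sorted(truth.wt_ids),
        "plate_map": {k: list(v) for k, v in truth.plate_map.items()},
        "specs": [asdict(s) for s in truth.specs],
    }
    Path(path).write_text(json.dumps(d, indent=1))


def read_truth(path) -> ScreenTruth:
    d = json.loads(Path(path).read_text())
    specs = []
    for s in d["specs"]:
        s["growth_params"] = tuple(s["growth_params"])
        specs.append(StrainSpec(**s))
    return ScreenTruth(
        specs=specs,
        wt_ids=set(d["wt_ids"]),
        plate_map={k: (int(v[0]), str(v[1])) for k, v in d["plate_map"].items()},
        seed=int(d["seed"]),
        n_cells_mean=float(d["n_cells_mean"]),
        n_cells_sd=float(d["n_cells_sd"]),
    )
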