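"""Table, image-stack and configuration I/O.

All tables are delimited text (tab-separated) with mandatory headers and
lossless round-tripping of numeric fields at full precision; image stacks
are multi-page TIFF.  Parse errors name the offending column or row.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fret import FRETRecord
from .geometry import OligomerChainModel
from .msd import Track

__all__ = [
    "write_table", "read_table",
    "write_tiff_stack", "read_tiff_stack",
    "tracks_to_table", "tracks_from_table",
    "fret_records_to_table", "fret_records_from_table",
    "measurements_to_table",
    "load_chain_model",
]

_FLOAT_FMT = "%.17g"


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path, required: list[str] | None = None,
               numeric: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in required or []:
        if col not in df.columns:
            raise ValueError(f"table {path} is missing required column {col!r}")
    for col in numeric or []:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric value in column {col!r} at row {int(bad[0])}"
            ) from None
    return df


def write_tiff_stack(path, stack: np.ndarray) -> None:
    """Write a float stack as 16-bit multi-page TIFF (clipped at 0)."""
    data = np.clip(np.asarray(stack), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))


def read_tiff_stack(path) -> np.ndarray:
    arr = tifffile.imread(path).astype(float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for time, (x, y) in zip(t.times_s, t.positions_nm):
            rows.append((t.track_id, t.dataset_id, time, x, y))
    return pd.DataFrame(rows, columns=["track_id", "dataset_id", "time_s",
                                       "x_nm", "y_nm"])


def tracks_from_table(df: pd.DataFrame) -> list[Track]:
    out = []
    for (ds, tid), g in df.groupby(["dataset_id", "track_id"], sort=False):
        g = g.sort_values("time_s")
        out.append(Track(track_id=str(tid), dataset_id=str(ds),
                         times_s=g["time_s"].to_numpy(),
                         positions_nm=g[["x_nm", "y_nm"]].to_numpy()))
    return out


def fret_records_to_table(records: list[FRETRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.cell_id, r.tau_d_ns, r.tau_da_ns, r.density_per_R02)
         for r in records],
        columns=["cell_id", "tau_d_ns", "tau_da_ns", "density_per_R02"],
    )


def fret_records_from_table(df: pd.DataFrame) -> list[FRETRecord]:
    return [
        FRETRecord(tau_d_ns=row.tau_d_ns, tau_da_ns=row.tau_da_ns,
                   density_per_R02=row.density_per_R02,
                   cell_id=str(getattr(row, "cell_id", "")))
        for row in df.itertuples()
    ]


def measurements_to_table(fits) -> pd.DataFrame:
    """One row per accepted complex: id, separation, pair error, diagnostics."""
    return pd.DataFrame(
        [(f.complex_id, f.separation_nm, f.sigma_pair_nm, f.fwhm_nm,
          f.I1, f.I2, f.converged, f.degenerate) for f in fits],
        columns=["complex_id", "d_nm", "sigma_pair_nm", "fwhm_nm",
                 "I1", "I2", "converged", "degenerate"],
    )


def load_chain_model(path=None) -> OligomerChainModel:
    """Chain-model constants from a plain-text key=value config file; the
    packaged default pins the published calibration."""
    if path is None:
        ref = importlib.resources.files("flimp") / "chain_defaults.cfg"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    values = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    return OligomerChainModel(
        tetramer_anchor_nm=float(values["tetramer_anchor_nm"]),
        per_dimer_increment_nm=float(values["per_dimer_increment_nm"]),
        dye_contribution_nm=float(values["dye_contribution_nm"]),
    )
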