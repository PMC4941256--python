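"""Tidy-CSV readers and writers shared by every stage.

Observable series and datasets use one long-format schema:

    time_h, stream, variable, generation, replicate, value

with ``stream`` in {fc, tl, count}, ``variable`` in {pct_G1, pct_S,
pct_G2M, n, n_total} and ``generation`` an integer (-1 where it does not
apply).  Dose-response grids use ``dose_A, dose_B, replicate, inhibition``.
Every file starts with ``#``-prefixed provenance header lines
(key: value), ignored by the readers' comment handling but returned as a
dict when asked for.
"""

from __future__ import annotations

import hashlib
import io as _io

import numpy as np
import pandas as pd

from .core import ObservableSeries

DATASET_COLUMNS = ["time_h", "stream", "variable", "generation", "replicate", "value"]
GRID_COLUMNS = ["dose_A", "dose_B", "replicate", "inhibition"]


def provenance_header(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def config_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_tidy(df: pd.DataFrame, path, meta: dict | None = None):
    with open(path, "w") as fh:
        if meta:
            fh.write(provenance_header(meta))
        df.to_csv(fh, index=False)


def read_tidy(path, with_meta: bool = False):
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            stripped = line[1:].strip()
            if ":" in stripped:
                k, v = stripped.split(":", 1)
                meta[k.strip()] = v.strip()
        else:
            body.append(line)
    df = pd.read_csv(_io.StringIO("".join(body)))
    return (df, meta) if with_meta else df


def series_to_frame(series: ObservableSeries, design=None) -> pd.DataFrame:
    """Noise-free observables as a tidy frame (replicate = 0 throughout).

    With a design, FC/count rows are restricted to the design's sampling
    times and TL rows to the TL times; otherwise every recorded time is
    emitted on all streams.
    """
    rows = []
    t = series.times

    def _sel(wanted):
        if wanted is None:
            return np.arange(len(t))
        wanted = np.asarray(wanted, dtype=float)
        return np.array([int(np.argmin(np.abs(t - w))) for w in wanted])

    fc_idx = _sel(None if design is None else design.fc_times)
    tl_idx = _sel(None if design is None else design.tl_times)
    ct_idx = _sel(None if design is None else design.count_times)

    for i in fc_idx:
        for var, arr in (
            ("pct_G1", series.pct_G1),
            ("pct_S", series.pct_S),
            ("pct_G2M", series.pct_G2M),
        ):
            rows.append((t[i], "fc", var, -1, 0, arr[i]))
    for i in tl_idx:
        for g in range(series.n_by_generation.shape[1]):
            rows.append((t[i], "tl", "n", g, 0, series.n_by_generation[i, g]))
    for i in ct_idx:
        rows.append((t[i], "count", "n_total", -1, 0, series.n_total[i]))
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)
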