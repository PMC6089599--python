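"""Tidy-CSV serialization of fluorescence traces.

One row per sample, UTF-8, RFC-4180 quoting via pandas.  Columns:
time_s, value, trace_id, modality, stage, jabba_copies, h2av_copies,
embryo, nucleus, seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .simulate import FluorescenceTrace, TraceMeta

__all__ = ["traces_to_frame", "frame_to_traces", "write_traces", "read_traces"]

TRACE_COLUMNS = [
    "time_s",
    "value",
    "trace_id",
    "modality",
    "stage",
    "jabba_copies",
    "h2av_copies",
    "embryo",
    "nucleus",
    "seed",
]


def traces_to_frame(traces: Sequence[FluorescenceTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        m = tr.meta
        for t, v in zip(tr.times, tr.values):
            rows.append(
                {
                    "time_s": float(t),
                    "value": float(v),
                    "trace_id": tr.trace_id,
                    "modality": m.modality,
                    "stage": m.stage,
                    "jabba_copies": m.jabba_copies,
                    "h2av_copies": m.h2av_copies,
                    "embryo": m.embryo_id,
                    "nucleus": m.nucleus_id if m.nucleus_id is not None else "",
                    "seed": m.seed,
                }
            )
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def frame_to_traces(df: pd.DataFrame) -> list[FluorescenceTrace]:
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table is missing columns: {sorted(missing)}")
    traces = []
    for trace_id, g in df.groupby("trace_id", sort=True):
        g = g.sort_values("time_s")
        first = g.iloc[0]
        nucleus = str(first["nucleus"]) if str(first["nucleus"]) not in ("", "nan") else None
        meta = TraceMeta(
            modality=str(first["modality"]),
            jabba_copies=int(first["jabba_copies"]),
            h2av_copies=int(first["h2av_copies"]),
            stage=str(first["stage"]),
            embryo_id=str(first["embryo"]),
            nucleus_id=nucleus,
            seed=int(first["seed"]),
        )
        traces.append(
            FluorescenceTrace(
                times=g["time_s"].to_numpy(float),
                values=g["value"].to_numpy(float),
                meta=meta,
            )
        )
    return traces


def write_traces(traces: Sequence[FluorescenceTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[FluorescenceTrace]:
    return frame_to_traces(pd.read_csv(path, keep_default_na=False))
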