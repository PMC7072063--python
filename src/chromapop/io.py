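"""CSV interchange for event tables, population tables and culture series.

CSV is the canonical interchange format so that pipelines and tests never
depend on binary fixtures.  Event files carry the columns ``event_id``,
``FSC-A``, ``FSC-H``, ``SSC-A`` and one column per fluorescence channel
named by its filter (e.g. ``FL_525_40``); the panel maps filter columns to
channel names on read.  Numbers are serialized with 9 significant digits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .panel import PanelConfig, SCATTER_COLUMNS
from .sample import FlowSample

_FLOAT_FMT = "%.9g"


def write_events(sample: FlowSample, path, panel: PanelConfig) -> None:
    """Write a FlowSample to the CSV event dialect."""
    out = sample.events.copy()
    out = out.rename(columns=panel.column_map)
    cols = ["event_id", *SCATTER_COLUMNS, *[panel.column_map.get(c, c) for c in sample.fluorescence_columns]]
    out.insert(0, "event_id", range(len(out)))
    out[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events(
    path, panel: PanelConfig, dialect: str = "csv", time_h: float = 0.0, culture_id: str = ""
) -> FlowSample:
    """Read an event table; filter-named columns are mapped to channel names.

    Only the CSV dialect is implemented; ``dialect="fcs"`` raises
    NotImplementedError.  Unknown columns and malformed (non-numeric /
    non-finite) rows raise with a descriptive message.
    """
    if dialect == "fcs":
        raise NotImplementedError("FCS I/O is not implemented; use the CSV dialect")
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"empty event file: {path}")
    inverse = {v: k for k, v in panel.column_map.items()}
    known = set(inverse) | set(panel.channel_names) | set(SCATTER_COLUMNS) | {"event_id"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown column(s) in {path.name}: {', '.join(unknown)}")
    df = df.rename(columns=inverse).drop(columns=["event_id"], errors="ignore")
    df = df.apply(pd.to_numeric, errors="coerce")
    bad = df.isna().any(axis=1)
    if bad.any():
        df = df.loc[~bad].reset_index(drop=True)
    sample = FlowSample(events=df, time_h=time_h, culture_id=culture_id)
    sample.meta["rejected_rows"] = int(bad.sum())
    return sample


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_manifest(path, config_repr: str, seed: int, extra: dict | None = None) -> dict:
    """Write a run manifest (config hash, seed, package version) as JSON."""
    from . import __version__

    manifest = {
        "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
        "seed": seed,
        "chromapop_version": __version__,
        **(extra or {}),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
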