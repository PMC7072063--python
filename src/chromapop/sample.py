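"""FlowSample: one cytometry acquisition with provenance flags."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import SCATTER_COLUMNS


@dataclass
class FlowSample:
    """An event table plus acquisition metadata.

    ``events`` holds one row per event with scatter columns
    (FSC-A, FSC-H, SSC-A) and one column per fluorescence channel
    (named by channel name, e.g. "Venus").  ``compensated`` and
    ``normalized`` record what processing has already been applied so
    that stages refuse to run twice.
    """

    events: pd.DataFrame
    time_h: float = 0.0
    culture_id: str = ""
    compensated: bool = False
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.events) == 0:
            raise ValueError("FlowSample requires at least one event")
        values = self.events.select_dtypes("number").to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValueError("event table contains non-finite intensities")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def fluorescence_columns(self) -> list[str]:
        return [c for c in self.events.columns if c not in SCATTER_COLUMNS]

    def with_events(self, events: pd.DataFrame, **flags) -> "FlowSample":
        """Copy of this sample with a new event table (and updated flags)."""
        return replace(self, events=events, **flags)
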