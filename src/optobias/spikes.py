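"""Per-trial spike-time containers and their plain-text sidecar format.

Spike times are in ms relative to stimulus onset (t = 0).  The stimulus
offset marker per trial equals that trial's duration, so trains can be
re-aligned to offset for post-stimulus (rebound) analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class SpikeTrainSet:
    """Spike trains for a set of trials, aligned to stimulus onset."""

    trains: list[np.ndarray]
    offsets_ms: np.ndarray
    trial_index: np.ndarray | None = None
    session_id: list[str] | None = None

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        self.offsets_ms = np.asarray(self.offsets_ms, dtype=float)
        if len(self.trains) != len(self.offsets_ms):
            raise ValueError("one offset marker required per trial")
        if not np.all(np.isfinite(self.offsets_ms)):
            raise ValueError("alignment markers must be finite")
        for i, t in enumerate(self.trains):
            if np.any(np.diff(t) < 0):
                raise ValueError(f"spike times not sorted in trial {i}")

    def __len__(self) -> int:
        return len(self.trains)

    def aligned(self, event: str = "onset") -> list[np.ndarray]:
        """Trains re-referenced to 'onset' (identity) or 'offset'."""
        if event == "onset":
            return self.trains
        if event == "offset":
            return [t - off for t, off in zip(self.trains, self.offsets_ms)]
        raise ValueError(f"unknown alignment event {event!r}")


def write_spike_sidecar(spikes: SpikeTrainSet, path: str | Path) -> Path:
    """One line per trial: ``trial_index: offset_ms | t1,t2,...`` (ms)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    idx = (
        spikes.trial_index
        if spikes.trial_index is not None
        else np.arange(1, len(spikes) + 1)
    )
    with open(path, "w", encoding="utf-8") as fh:
        for i, train, off in zip(idx, spikes.trains, spikes.offsets_ms):
            ts = ",".join(f"{t:.3f}" for t in train)
            fh.write(f"{int(i)}: {off:.3f} | {ts}\n")
    return path


def read_spike_sidecar(path: str | Path) -> SpikeTrainSet:
    path = Path(path)
    idx: list[int] = []
    trains: list[np.ndarray] = []
    offsets: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            head, _, rest = line.partition(":")
            off_s, _, ts = rest.partition("|")
            idx.append(int(head))
            offsets.append(float(off_s))
            ts = ts.strip()
            trains.append(
                np.array([float(x) for x in ts.split(",")] if ts else [], dtype=float)
            )
    return SpikeTrainSet(trains, np.array(offsets), trial_index=np.array(idx))
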