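"""Core data containers: kinematics, trial tables, and binned sessions.

A :class:`BinnedSession` is the unit of analysis everywhere in the package:
a time-aligned matrix of 50 ms-binned spiking-band-power features together
with the synchronized finger kinematics and the trial table of the target
task.  Sessions round-trip through a simple HDF5 container so that real
recordings stored in the same layout can be analyzed with the identical
code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

#: Columns required of every trial table.
TRIAL_COLUMNS = (
    "start_bin",
    "end_bin",
    "target_idx",
    "target_mrs",
    "target_width",
    "success",
    "context",
)


@dataclass
class Kinematics:
    """Binned 2-DOF finger kinematics.

    position is in "flex" units (fraction of the movement range, 0 = full
    extension, 1 = full flexion); velocity is its discrete derivative in
    flex/s.  Column 0 is the index (IDX) finger group, column 1 the
    middle-ring-small (MRS) group.
    """

    position: np.ndarray  # (T, 2)
    velocity: np.ndarray  # (T, 2) flex/s
    bin_ms: float = 50.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.position.shape != self.velocity.shape:
            raise ValueError("position and velocity shapes differ")
        if self.position.ndim != 2:
            raise ValueError("kinematics must be (T, n_dof) arrays")

    @property
    def n_bins(self) -> int:
        return self.position.shape[0]

    @property
    def n_dof(self) -> int:
        return self.position.shape[1]

    @classmethod
    def from_position(cls, position: np.ndarray, bin_ms: float = 50.0) -> "Kinematics":
        """Derive velocity as the backward difference of position.

        The first bin has zero velocity (no preceding sample).
        """
        position = np.asarray(position, dtype=float)
        dt = bin_ms / 1000.0
        velocity = np.zeros_like(position)
        velocity[1:] = np.diff(position, axis=0) / dt
        return cls(position=position, velocity=velocity, bin_ms=bin_ms)


class TrialTable:
    """Table of task trials, one row per trial.

    Wraps a :class:`pandas.DataFrame` with the columns in
    :data:`TRIAL_COLUMNS`.  Bin spans are half-open ``[start_bin, end_bin)``
    and trials are contiguous and non-overlapping.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(TRIAL_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, key):
        return self.frame[key]

    @property
    def n_trials(self) -> int:
        return len(self.frame)

    def validate(self, n_bins: int | None = None) -> None:
        f = self.frame
        if not (f["end_bin"] > f["start_bin"]).all():
            raise ValueError("empty or inverted trial span")
        if len(f) > 1 and not (
            f["start_bin"].to_numpy()[1:] == f["end_bin"].to_numpy()[:-1]
        ).all():
            raise ValueError("trials must be contiguous and non-overlapping")
        half = f["target_width"].to_numpy() / 2.0
        for col in ("target_idx", "target_mrs"):
            c = f[col].to_numpy()
            if ((c - half) < -1e-12).any() or ((c + half) > 1 + 1e-12).any():
                raise ValueError(f"{col} target extends outside [0, 1]")
        if n_bins is not None and (f["end_bin"] > n_bins).any():
            raise ValueError("trial bin indices exceed session length")

    def bin_context(self, n_bins: int) -> np.ndarray:
        """Per-bin context label derived from trial membership."""
        out = np.empty(n_bins, dtype=object)
        for _, row in self.frame.iterrows():
            out[int(row.start_bin) : int(row.end_bin)] = row.context
        return out

    def bin_trial_index(self, n_bins: int) -> np.ndarray:
        """Per-bin trial index (-1 outside any trial)."""
        out = np.full(n_bins, -1, dtype=int)
        for i, row in self.frame.iterrows():
            out[int(row.start_bin) : int(row.end_bin)] = i
        return out

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_records(cls, records: list[dict]) -> "TrialTable":
        return cls(pd.DataFrame.from_records(records, columns=list(TRIAL_COLUMNS)))


@dataclass
class BinnedSession:
    """One recording (or simulated) session in binned form."""

    sbp: np.ndarray  # (T, C), nonnegative
    kinematics: Kinematics
    trials: TrialTable
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sbp = np.asarray(self.sbp, dtype=float)
        if self.sbp.shape[0] != self.kinematics.n_bins:
            raise ValueError("sbp and kinematics disagree on bin count")
        if np.isnan(self.sbp).any():
            raise ValueError("sbp contains missing values")
        self.trials.validate(n_bins=self.n_bins)

    @property
    def n_bins(self) -> int:
        return self.sbp.shape[0]

    @property
    def n_channels(self) -> int:
        return self.sbp.shape[1]

    @property
    def bin_ms(self) -> float:
        return self.kinematics.bin_ms

    @property
    def contexts(self) -> list[str]:
        """Distinct context labels in block (first-appearance) order."""
        seen: list[str] = []
        for c in self.trials["context"]:
            if c not in seen:
                seen.append(c)
        return seen

    def trial_bins(self, trial_indices: np.ndarray | list[int]) -> np.ndarray:
        """Bin indices covered by the given trials, in session order."""
        f = self.trials.frame
        spans = [
            np.arange(int(f.start_bin.iloc[i]), int(f.end_bin.iloc[i]))
            for i in trial_indices
        ]
        if not spans:
            return np.empty(0, dtype=int)
        return np.concatenate(spans)

    # ------------------------------------------------------------------ I/O

    def save(self, path: str | Path) -> None:
        """Write the session to the HDF5 container layout."""
        with h5py.File(path, "w") as h5:
            h5.create_dataset("sbp", data=self.sbp)
            h5.create_dataset("position", data=self.kinematics.position)
            h5.create_dataset("velocity", data=self.kinematics.velocity)
            grp = h5.create_group("trials")
            f = self.trials.frame
            for col in TRIAL_COLUMNS:
                if col == "context":
                    continue
                grp.create_dataset(col, data=f[col].to_numpy())
            h5.create_dataset(
                "context",
                data=np.array([s.encode() for s in f["context"]]),
            )
            h5.attrs["bin_ms"] = self.bin_ms
            h5.attrs["schema_version"] = SCHEMA_VERSION
            for key, val in self.metadata.items():
                if isinstance(val, (str, int, float, np.integer, np.floating)):
                    h5.attrs[key] = val

    @classmethod
    def load(cls, path: str | Path) -> "BinnedSession":
        with h5py.File(path, "r") as h5:
            sbp = h5["sbp"][:]
            bin_ms = float(h5.attrs["bin_ms"])
            kin = Kinematics(
                position=h5["position"][:],
                velocity=h5["velocity"][:],
                bin_ms=bin_ms,
            )
            cols = {
                col: h5["trials"][col][:]
                for col in TRIAL_COLUMNS
                if col != "context"
            }
            cols["context"] = [s.decode() for s in h5["context"][:]]
            trials = TrialTable(pd.DataFrame(cols))
            metadata = {
                k: v for k, v in h5.attrs.items() if k not in ("schema_version",)
            }
        return cls(sbp=sbp, kinematics=kin, trials=trials, metadata=metadata)
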