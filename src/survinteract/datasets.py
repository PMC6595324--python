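"""Trial dataset container and plain-text (CSV) I/O.

A :class:`TrialDataset` holds one two-arm randomized trial with a single
continuous biomarker and a right-censored time-to-event outcome.  All
interaction tests in this package consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CSV_COLUMNS = ["subject_id", "biomarker", "treatment", "time", "event"]


@dataclass(frozen=True)
class TrialDataset:
    """Per-subject data of a two-arm trial with a continuous biomarker.

    Parameters
    ----------
    z : array of float
        Biomarker values, one per subject, in ``[0, 1]`` (any positive
        range is accepted for imported data; the fractional-polynomial
        methods require strictly positive values).
    arm : array of int
        Treatment allocation, 0 = control, 1 = experimental.
    time : array of float
        Observed follow-up time, strictly positive.
    event : array of int
        1 if the event was observed at ``time``, 0 if censored.
    subject_id : array of int, optional
        Subject identifiers; defaults to ``0..n-1``.
    """

    z: np.ndarray
    arm: np.ndarray
    time: np.ndarray
    event: np.ndarray
    subject_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        arm = np.asarray(self.arm, dtype=int)
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        n = z.shape[0]
        if not (arm.shape[0] == time.shape[0] == event.shape[0] == n):
            raise ValueError("all columns must have the same length")
        if n < 2:
            raise ValueError("a trial needs at least two subjects")
        if np.any(time <= 0):
            raise ValueError("observed times must be strictly positive")
        if not np.isin(arm, (0, 1)).all():
            raise ValueError("treatment arm must be 0 or 1")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        if np.any(~np.isfinite(z)):
            raise ValueError("biomarker values must be finite")
        if arm.min() == arm.max():
            raise ValueError("both treatment arms must be represented")
        sid = self.subject_id
        sid = np.arange(n) if sid is None else np.asarray(sid, dtype=int)
        if sid.shape[0] != n:
            raise ValueError("subject_id length mismatch")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "arm", arm)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        object.__setattr__(self, "subject_id", sid)

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "biomarker": self.z,
                "treatment": self.arm,
                "time": self.time,
                "event": self.event,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialDataset":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return cls(
            z=df["biomarker"].to_numpy(dtype=float),
            arm=df["treatment"].to_numpy(dtype=int),
            time=df["time"].to_numpy(dtype=float),
            event=df["event"].to_numpy(dtype=int),
            subject_id=df["subject_id"].to_numpy(dtype=int),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TrialDataset":
        return cls.from_frame(pd.read_csv(path))

    def subset(self, idx) -> "TrialDataset":
        """Dataset restricted to the given index array (e.g. one window)."""
        return TrialDataset(
            z=self.z[idx],
            arm=self.arm[idx],
            time=self.time[idx],
            event=self.event[idx],
            subject_id=self.subject_id[idx],
        )
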