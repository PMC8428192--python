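"""Beat-annotation and sleep-stage input, eligibility, and NN-series extraction.

Beat annotations are per-beat records of (time in seconds from recording
start, label) where the label classifies the QRS complex as normal sinus
(``N``), supraventricular ectopic (``S``), ventricular ectopic (``V``) or
artifact/unreadable (``A``).  Sleep stages are scored in fixed 30-s epochs.
The normal-to-normal (NN) interval series used by the fragmentation and HRV
modules is extracted between sleep onset (start of the first non-Wake epoch)
and sleep termination (end of the last non-Wake epoch); intervening wake
time is retained.

An NN interval requires both bounding beats to be labeled N.  Every excluded
beat (ectopic or artifact) and every implausibly long inter-beat gap breaks
the series into *runs*: downstream successive-difference statistics are only
taken within a run, never across an excluded beat.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BEAT_LABELS = frozenset({"N", "S", "V", "A"})

#: stages recognised in 30-s epoch files
SLEEP_STAGES = ("Wake", "N1", "N2", "N3", "REM")

EPOCH_SECONDS = 30.0

#: inter-beat intervals longer than this are treated as annotation gaps,
#: discarded, and force a run boundary (physiologic NN rarely exceeds 3 s)
MAX_NN_MS = 3000.0

_STAGE_TOKENS = {
    "W": "Wake", "WAKE": "Wake", "0": "Wake",
    "1": "N1", "N1": "N1",
    "2": "N2", "N2": "N2",
    "3": "N3", "N3": "N3", "4": "N3",
    "R": "REM", "REM": "REM", "5": "REM",
}


class BeatFileError(ValueError):
    """Raised for malformed beat-annotation input."""


@dataclass
class BeatAnnotationList:
    """Per-beat times (s) and labels plus the source-ECG sampling frequency."""

    times: np.ndarray
    labels: np.ndarray
    sampling_frequency: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.times.ndim != 1 or self.times.shape != self.labels.shape:
            raise BeatFileError("times and labels must be 1-D and equal length")
        if self.sampling_frequency <= 0:
            raise BeatFileError("sampling frequency must be positive")
        bad = np.flatnonzero(np.diff(self.times) <= 0)
        if bad.size:
            raise BeatFileError(
                f"beat times not strictly increasing at row {bad[0] + 1}"
            )
        unknown = set(self.labels) - VALID_BEAT_LABELS
        if unknown:
            raise BeatFileError(f"invalid beat labels {sorted(unknown)}")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SleepEpochs:
    """Ordered sleep stages, one per 30-s epoch."""

    stages: tuple[str, ...]
    epoch_duration: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if not self.stages:
            raise ValueError("empty sleep-stage sequence")
        if self.epoch_duration != EPOCH_SECONDS:
            raise ValueError("epoch duration must be 30 s")
        bad = set(self.stages) - set(SLEEP_STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stages)


@dataclass
class NNSeries:
    """Contiguity-aware sequence of NN intervals.

    Attributes
    ----------
    intervals : ndarray
        NN durations in ms.
    end_times : ndarray
        Time (s) of each interval's terminating beat.
    run_id : ndarray of int
        Maximal contiguous runs of NN intervals; a new run starts after
        every excluded beat or gap.  Non-decreasing.
    sampling_frequency : float
        Source-ECG sampling frequency (Hz); sets the no-change quantum.
    onset_s, termination_s : float or None
        Sleep window bounds, when known (set by :func:`extract_sleep_nn`).
    """

    intervals: np.ndarray
    end_times: np.ndarray
    run_id: np.ndarray
    sampling_frequency: float
    onset_s: float | None = None
    termination_s: float | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.end_times = np.asarray(self.end_times, dtype=float)
        self.run_id = np.asarray(self.run_id, dtype=int)
        if not (self.intervals.shape == self.end_times.shape == self.run_id.shape):
            raise ValueError("intervals, end_times, run_id must have equal length")
        if np.any(self.intervals <= 0):
            raise ValueError("NN intervals must be positive")
        if np.any(np.diff(self.run_id) < 0):
            raise ValueError("run_id must be non-decreasing")
        if self.sampling_frequency <= 0:
            raise ValueError("sampling frequency must be positive")

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def start_s(self) -> float:
        """Anchor time of the series (sleep onset when known)."""
        if self.onset_s is not None:
            return self.onset_s
        if len(self) == 0:
            return 0.0
        return float(self.end_times[0] - self.intervals[0] / 1000.0)

    def run_slices(self) -> list[slice]:
        """Slices delimiting each maximal contiguous run, in order."""
        if len(self) == 0:
            return []
        bounds = np.flatnonzero(np.diff(self.run_id)) + 1
        edges = [0, *bounds.tolist(), len(self)]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "end_time_s": self.end_times,
                "nn_ms": self.intervals,
                "run_id": self.run_id,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_nn_csv(
    path: str | Path,
    sampling_frequency: float,
    onset_s: float | None = None,
    termination_s: float | None = None,
) -> NNSeries:
    """Read an NN series from the interchange CSV (end_time_s, nn_ms, run_id)."""
    df = pd.read_csv(path)
    required = {"end_time_s", "nn_ms", "run_id"}
    if not required.issubset(df.columns):
        raise BeatFileError(f"NN CSV must have columns {sorted(required)}")
    return NNSeries(
        intervals=df["nn_ms"].to_numpy(float),
        end_times=df["end_time_s"].to_numpy(float),
        run_id=df["run_id"].to_numpy(int),
        sampling_frequency=sampling_frequency,
        onset_s=onset_s,
        termination_s=termination_s,
    )


def read_beat_annotations(
    path: str | Path,
    sampling_frequency: float,
    dialect: str = "csv",
) -> BeatAnnotationList:
    """Read a two-column (time, label) beat-annotation file.

    ``dialect='csv'`` expects comma separation, ``dialect='wfdb-like'``
    whitespace separation; an optional header row is skipped.  Labels outside
    {N, S, V, A} are mapped to A (artifact) with a warning.
    """
    path = Path(path)
    if dialect not in {"csv", "wfdb-like"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else None
    times: list[float] = []
    labels: list[str] = []
    with open(path) as fh:
        for row_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise BeatFileError(f"{path}: row {row_no}: expected 2 columns")
            t_str, label = parts[0].strip(), parts[1].strip()
            try:
                t = float(t_str)
            except ValueError:
                if row_no == 1:  # header
                    continue
                raise BeatFileError(f"{path}: row {row_no}: bad time {t_str!r}")
            if label not in VALID_BEAT_LABELS:
                warnings.warn(
                    f"{path}: row {row_no}: unknown beat label {label!r} mapped to A",
                    stacklevel=2,
                )
                label = "A"
            times.append(t)
            labels.append(label)
    if not times:
        raise BeatFileError(f"{path}: no beat annotations found")
    arr = np.asarray(times)
    bad = np.flatnonzero(np.diff(arr) <= 0)
    if bad.size:
        raise BeatFileError(
            f"{path}: beat times not strictly increasing at row {bad[0] + 2}"
        )
    return BeatAnnotationList(arr, np.asarray(labels, dtype=object), sampling_frequency)


def read_sleep_epochs(path: str | Path) -> SleepEpochs:
    """Read 30-s sleep stages, one token per line (W/1/2/3/R) or CSV
    (epoch_index,stage)."""
    path = Path(path)
    stages: list[str] = []
    with open(path) as fh:
        for row_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            token = line.split(",")[-1].strip() if "," in line else line
            key = token.upper()
            if key in ("STAGE",):  # header
                continue
            if key not in _STAGE_TOKENS:
                raise ValueError(f"{path}: row {row_no}: unknown stage {token!r}")
            stages.append(_STAGE_TOKENS[key])
    return SleepEpochs(tuple(stages))


def eligible_subject(epochs: SleepEpochs) -> tuple[bool, float]:
    """Apply the minimum-sleep eligibility rule.

    Returns (eligible, combined sleep minutes), where combined sleep is all
    REM plus non-REM epochs (everything scored other than Wake).  Subjects
    with under 2 h of combined sleep are ineligible.
    """
    n_sleep = sum(1 for s in epochs.stages if s != "Wake")
    minutes = 0.5 * n_sleep
    return minutes >= 120.0, minutes


def sleep_window(epochs: SleepEpochs) -> tuple[float, float]:
    """(onset, termination) in seconds: start of first and end of last
    non-Wake epoch.  Raises if no sleep was scored."""
    sleep_idx = [i for i, s in enumerate(epochs.stages) if s != "Wake"]
    if not sleep_idx:
        raise ValueError("no non-Wake epochs: sleep onset undefined")
    onset = sleep_idx[0] * EPOCH_SECONDS
    termination = (sleep_idx[-1] + 1) * EPOCH_SECONDS
    return onset, termination


def extract_sleep_nn(beats: BeatAnnotationList, epochs: SleepEpochs) -> NNSeries:
    """Extract the NN-interval series between sleep onset and termination.

    Both bounding beats of a kept interval must be labeled N and lie inside
    the sleep window; wake time after onset is retained.  A new run starts
    after every excluded beat and after any inter-beat gap above
    ``MAX_NN_MS`` (discarded as an annotation gap).
    """
    onset, termination = sleep_window(epochs)
    intervals: list[float] = []
    end_times: list[float] = []
    run_ids: list[int] = []
    run = 0
    open_run = False  # whether the previous beat can bound the next interval
    prev_t: float | None = None
    for t, label in zip(beats.times, beats.labels):
        if t < onset or t > termination or label != "N":
            # excluded beat: close any open run
            if open_run and intervals:
                run += 1
            open_run = False
            prev_t = None
            continue
        if prev_t is not None:
            nn_ms = (t - prev_t) * 1000.0
            if nn_ms > MAX_NN_MS:
                if open_run and intervals:
                    run += 1
                logger.debug("gap of %.0f ms at t=%.2f s: run boundary", nn_ms, t)
            else:
                intervals.append(nn_ms)
                end_times.append(t)
                run_ids.append(run)
                open_run = True
        prev_t = t
    if not intervals:
        raise ValueError("no NN data in sleep period")
    # renumber runs densely from 0
    ids = np.asarray(run_ids)
    _, dense = np.unique(ids, return_inverse=True)
    return NNSeries(
        intervals=np.asarray(intervals),
        end_times=np.asarray(end_times),
        run_id=dense,
        sampling_frequency=beats.sampling_frequency,
        onset_s=onset,
        termination_s=termination,
    )
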