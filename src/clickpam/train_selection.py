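"""Grouping click candidates into trains and qualifying them.

A click train is a regular sequence of clicks from one scanning pass of
an animal.  Trains qualify for analysis when they hold at least eight
clicks, their mean inter-click interval (ICI) lies strictly between
10 ms and 0.1 s (which excludes buzzes and burst pulses), and the train
is "loud and clear": at least 10 dB above the broadband background.  To
limit over-representation of single encounters, at most twice the
estimated group size of qualified trains is kept per recording session,
drawn uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import AudioRecording
from .click_detection import ClickCandidate, NoiseSpectrum

__all__ = [
    "ClickTrain",
    "SessionRecord",
    "group_into_trains",
    "qualify_train",
    "cap_trains_per_session",
    "read_session_table",
    "trains_to_frame",
]

MIN_CLICKS = 8
ICI_LOW_S = 0.01
ICI_HIGH_S = 0.1
SNR_MARGIN_DB = 10.0
DEFAULT_MAX_GAP_S = 0.3


@dataclass
class ClickTrain:
    """An ordered run of click candidates from one encounter pass."""

    clicks: list[ClickCandidate]
    session_id: str = ""
    train_id: str = ""
    species_label: str | None = None
    qualified: bool = False
    rejection_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [c.time_s for c in self.clicks]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("train clicks must be strictly time-ordered")

    @property
    def n_clicks(self) -> int:
        return len(self.clicks)

    @property
    def ici_series(self) -> np.ndarray:
        """Inter-click intervals in seconds (length n_clicks - 1)."""
        times = np.array([c.time_s for c in self.clicks])
        return np.diff(times)

    @property
    def mean_ici(self) -> float:
        ici = self.ici_series
        return float(ici.mean()) if ici.size else np.nan


@dataclass
class SessionRecord:
    """Metadata of one recording session (one species group encounter)."""

    species: str
    session_number: int
    date: str = ""
    start_time: str = ""
    latitude: str | None = None
    longitude: str | None = None
    group_size: int = 1
    n_trains: int = 0
    n_selected_trains: int = 0

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")


def group_into_trains(
    cands: list[ClickCandidate],
    max_gap: float = DEFAULT_MAX_GAP_S,
    session_id: str = "",
) -> list[ClickTrain]:
    """Split time-sorted candidates into trains at gaps longer than ``max_gap``.

    The default gap of 0.3 s is three times the 0.1 s ICI ceiling for a
    qualified train, so slow trains are never split while distinct passes
    are separated.
    """
    if not cands:
        return []
    times = [c.time_s for c in cands]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("candidates must be time-sorted")
    trains: list[ClickTrain] = []
    current = [cands[0]]
    for prev, cand in zip(cands, cands[1:]):
        if cand.time_s - prev.time_s > max_gap:
            trains.append(current)
            current = [cand]
        else:
            current.append(cand)
    trains.append(current)
    return [
        ClickTrain(clicks=c, session_id=session_id, train_id=f"{session_id}t{i:03d}")
        for i, c in enumerate(trains)
    ]


def _train_level_db(train: ClickTrain, rec: AudioRecording, half_width: int = 16) -> float:
    """Broadband train level: RMS over short windows around each click peak."""
    chunks = []
    for c in train.clicks:
        lo = max(0, c.time_index - half_width)
        hi = min(rec.n_samples, c.time_index + half_width)
        chunks.append(rec.samples[lo:hi])
    x = np.concatenate(chunks)
    rms = float(np.sqrt(np.mean(x**2)))
    return 20.0 * np.log10(rms) if rms > 0 else -np.inf


def qualify_train(
    train: ClickTrain,
    rec: AudioRecording | None = None,
    noise: NoiseSpectrum | None = None,
) -> ClickTrain:
    """Apply the train-qualification rules, recording every failure.

    Rules: at least 8 clicks; mean ICI strictly between 10 ms and 0.1 s;
    and, when a recording and noise spectrum are supplied, train level at
    least 10 dB above the broadband background.  The level comparison is
    an automated surrogate for screening by ear and eye: click-window RMS
    against the RMS implied by the integrated noise spectrum.
    """
    if train.n_clicks == 0:
        raise ValueError("cannot qualify an empty train")
    reasons: list[str] = []
    if train.n_clicks < MIN_CLICKS:
        reasons.append("too_few_clicks")
    mean_ici = train.mean_ici
    if np.isnan(mean_ici) or mean_ici <= ICI_LOW_S:
        reasons.append("ici_too_short")
    elif mean_ici >= ICI_HIGH_S:
        reasons.append("ici_too_long")
    if rec is not None and noise is not None:
        level = _train_level_db(train, rec)
        if level < noise.broadband_level_db() + SNR_MARGIN_DB:
            reasons.append("low_snr")
    return replace(train, qualified=not reasons, rejection_reasons=reasons)


def cap_trains_per_session(
    trains: list[ClickTrain],
    session: SessionRecord,
    seed: int,
) -> list[ClickTrain]:
    """Randomly keep at most twice the group size of trains per session.

    Returns min(n_trains, 2 x group_size) trains in their original order;
    the subset is reproducible from ``seed``.
    """
    limit = 2 * session.group_size
    if len(trains) <= limit:
        return list(trains)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(trains), size=limit, replace=False))
    return [trains[i] for i in keep]


def read_session_table(path: str | Path) -> list[SessionRecord]:
    """Read session metadata from a CSV with encounter-log columns.

    Expected columns: species, session, date, start_time, latitude,
    longitude, group_size, n_trains, n_selected_trains (the last three
    optional except group_size).
    """
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            SessionRecord(
                species=str(row["species"]),
                session_number=int(row["session"]),
                date=str(row.get("date", "")),
                start_time=str(row.get("start_time", "")),
                latitude=row.get("latitude"),
                longitude=row.get("longitude"),
                group_size=int(row["group_size"]),
                n_trains=int(row.get("n_trains", 0) or 0),
                n_selected_trains=int(row.get("n_selected_trains", 0) or 0),
            )
        )
    return records


def trains_to_frame(trains: list[ClickTrain]) -> pd.DataFrame:
    """Summary table of trains: id, session, click count, mean ICI (ms)."""
    return pd.DataFrame(
        {
            "train_id": [t.train_id for t in trains],
            "session_id": [t.session_id for t in trains],
            "n_clicks": [t.n_clicks for t in trains],
            "mean_ici_ms": [1e3 * t.mean_ici for t in trains],
            "qualified": [t.qualified for t in trains],
            "rejection_reasons": [";".join(t.rejection_reasons) for t in trains],
        }
    )
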