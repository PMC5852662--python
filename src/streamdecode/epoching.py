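"""Triplet-locked epoching, press-guard exclusion, and percept labeling.

Each 600 ms epoch begins at a triplet onset (no baseline correction; the
stimulus repeats without a usable silent baseline, and the press guard
ensures carry-over only ever comes from triplets with the same reported
percept, making epoch time effectively circular). Epochs beginning less
than 1500 ms after a button press (or sequence start) or ending less than
1500 ms before a press (or sequence end) are excluded, which makes 3600 ms
the shortest possible onset-to-onset interval between retained epochs
carrying different percept reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import INTEGRATED, SEGREGATED, ReportStream
from .io import ContinuousRecording
from .synthetic_data import TRIPLET_PERIOD, StimulusTimeline

GUARD_DEFAULT = 1.5
MIN_CELL_DEFAULT = 55


@dataclass
class EpochSet:
    """Triplet-locked epochs with per-epoch metadata.

    ``labels`` holds "integrated"/"segregated" (or "" before labeling),
    ``retained`` the guard mask. Analyses operate on ``retained`` epochs
    only; the full set is kept so masks are checkable against reports.
    """

    data: np.ndarray  # (n_epochs, n_samples)
    onsets: np.ndarray  # seconds, within-sequence
    sample_rate: float
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    retained: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    delta_f: np.ndarray = field(default_factory=lambda: np.array([]))
    condition: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    sequence_id: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    participant_id: str = ""

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        if self.labels.size == 0:
            self.labels = np.array([""] * n, dtype=object)
        if self.retained.size == 0:
            self.retained = np.ones(n, dtype=bool)
        if self.delta_f.size == 0:
            self.delta_f = np.zeros(n)
        if self.condition.size == 0:
            self.condition = np.array([""] * n, dtype=object)
        if self.sequence_id.size == 0:
            self.sequence_id = np.array([""] * n, dtype=object)

    @property
    def n_epochs(self) -> int:
        return int(self.data.shape[0])


def concatenate_epochs(sets: list[EpochSet]) -> EpochSet:
    if not sets:
        raise ValueError("no epoch sets to concatenate")
    return EpochSet(
        data=np.concatenate([s.data for s in sets]),
        onsets=np.concatenate([s.onsets for s in sets]),
        sample_rate=sets[0].sample_rate,
        labels=np.concatenate([s.labels for s in sets]),
        retained=np.concatenate([s.retained for s in sets]),
        delta_f=np.concatenate([s.delta_f for s in sets]),
        condition=np.concatenate([s.condition for s in sets]),
        sequence_id=np.concatenate([s.sequence_id for s in sets]),
        participant_id=sets[0].participant_id,
    )


def extract_epochs(
    rec: ContinuousRecording, timeline: StimulusTimeline
) -> EpochSet:
    """One 600 ms epoch per triplet onset, no baseline correction.

    Onsets (seconds) are mapped to sample indices by rounding to the nearest
    sample; the epoch window is half-open, [onset, onset + 0.6).
    """
    fs = rec.sample_rate
    n_samp = int(round(TRIPLET_PERIOD * fs))
    starts = np.round(timeline.triplet_onsets * fs).astype(int)
    bad = starts + n_samp > rec.n_samples
    if np.any(bad):
        raise ValueError(
            "epochs extend beyond recording end at onsets "
            f"{timeline.triplet_onsets[bad].tolist()}"
        )
    idx = starts[:, None] + np.arange(n_samp)[None, :]
    return EpochSet(
        data=rec.data[idx],
        onsets=timeline.triplet_onsets.copy(),
        sample_rate=fs,
        delta_f=np.full(timeline.n_triplets, timeline.delta_f),
        sequence_id=np.array([timeline.sequence_id] * timeline.n_triplets, dtype=object),
    )


def apply_exclusion(
    epochs: EpochSet,
    reports: ReportStream,
    guard: float = GUARD_DEFAULT,
    epoch_length: float = TRIPLET_PERIOD,
) -> np.ndarray:
    """Press-guard mask: retained iff onset >= last press + guard and
    onset + epoch_length <= next press - guard, with sequence start and end
    treated as presses."""
    boundaries = np.concatenate(
        [[0.0], reports.press_times, [reports.sequence_duration]]
    )
    onsets = epochs.onsets
    ends = onsets + epoch_length
    # last boundary at or before onset; first boundary strictly after onset
    last_idx = np.searchsorted(boundaries, onsets, side="right") - 1
    last = boundaries[np.clip(last_idx, 0, len(boundaries) - 1)]
    next_idx = np.clip(last_idx + 1, 0, len(boundaries) - 1)
    nxt = boundaries[next_idx]
    return (onsets >= last + guard) & (ends <= nxt - guard)


def label_epochs(
    epochs: EpochSet,
    reports: ReportStream,
    exclude_before_first_segregated: bool = False,
) -> np.ndarray:
    """Percept labels: the most recent press at or before each epoch onset;
    epochs before the first report count as integrated. With
    ``exclude_before_first_segregated`` the pre-first-segregated integrated
    epochs are labeled "" (the sensitivity analysis that treats the initial
    integrated phase separately)."""
    times = reports.press_times
    percepts = np.array([p for _, p in reports.presses], dtype=object)
    if percepts.size == 0:
        labels = np.array([INTEGRATED] * epochs.n_epochs, dtype=object)
    else:
        idx = np.searchsorted(times, epochs.onsets, side="right") - 1
        labels = np.where(
            idx >= 0, percepts[np.clip(idx, 0, None)], INTEGRATED
        ).astype(object)
    if exclude_before_first_segregated:
        seg_times = times[percepts == SEGREGATED]
        first_seg = seg_times[0] if seg_times.size else np.inf
        labels[epochs.onsets < first_seg] = ""
    return labels


def cell_counts(epochs: EpochSet, condition: str = "neutral") -> dict:
    """Retained-epoch counts per (delta_f, percept) cell in one condition."""
    counts: dict[tuple[float, str], int] = {}
    sel = epochs.retained & (epochs.condition == condition)
    for df in np.unique(epochs.delta_f[sel]):
        for percept in (INTEGRATED, SEGREGATED):
            counts[(float(df), percept)] = int(
                np.sum(sel & (epochs.delta_f == df) & (epochs.labels == percept))
            )
    return counts


def min_cell_count_gate(
    epochs: EpochSet, threshold: int = MIN_CELL_DEFAULT, condition: str = "neutral"
) -> bool:
    """Participant enters the neural analyses only if every neutral
    delta_f x percept cell holds at least ``threshold`` retained epochs."""
    counts = cell_counts(epochs, condition)
    if not counts:
        return threshold <= 0
    return all(c >= threshold for c in counts.values())
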