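"""Epoch container, band-pass filtering, and sub-stage segmentation.

Trials are filtered over their full length before any segmentation so
that filter transients stay outside the short sub-stage windows, and
sample windows are half-open ``[start, end)`` so the three sub-stages
partition a trial without overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from phasenet.montage import Montage

__all__ = [
    "EpochSet",
    "SubStageWindow",
    "DEFAULT_WINDOWS",
    "select_correct",
    "bandpass_beta",
    "segment",
]

logger = logging.getLogger(__name__)

HANDS = ("left", "right")
ANGLES = (0, 60, 120, 180, 240, 300)

REQUIRED_META = ("hand", "angle", "correct")


@dataclass
class EpochSet:
    """Stack of fixed-length multichannel trials with stimulus metadata.

    Attributes
    ----------
    data
        ``(n_trials, n_channels, n_samples)`` real array.
    fs
        Sampling rate in Hz.
    montage
        Channel montage; ``montage.labels`` indexes axis 1.
    meta
        One row per trial with at least columns
        ``hand`` (``left``/``right``), ``angle`` (degrees, int) and
        ``correct`` (bool).
    subject_id, group
        Cohort bookkeeping; ``group`` is ``control`` or ``patient``.
    """

    data: np.ndarray
    fs: float
    montage: Montage
    meta: pd.DataFrame
    subject_id: str = "S0"
    group: str = "control"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[1]} channels but montage has "
                f"{self.montage.n_channels}"
            )
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("meta length must equal trial count")
        missing = [c for c in REQUIRED_META if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta missing columns: {missing}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **kwargs) -> "EpochSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SubStageWindow:
    """Named post-stimulus window; ``[start_ms, end_ms)``."""

    name: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_ms < self.end_ms:
            raise ValueError(f"invalid window {self.name}: [{self.start_ms}, {self.end_ms})")

    def sample_slice(self, fs: float) -> slice:
        # half-open sample interval, 0-based
        return slice(int(round(self.start_ms * fs / 1000.0)),
                     int(round(self.end_ms * fs / 1000.0)))


DEFAULT_WINDOWS = (
    SubStageWindow("Beginning", 0, 300),
    SubStageWindow("Middle", 300, 800),
    SubStageWindow("End", 800, 1200),
)


def select_correct(epochs: EpochSet) -> EpochSet:
    """Drop trials with an incorrect behavioural response.

    Metadata rows stay aligned with the retained trials.  Any
    (hand, angle) cell left empty is logged as missing so downstream
    averaging can flag it.
    """
    mask = epochs.meta["correct"].to_numpy(dtype=bool)
    kept = epochs.data[mask]
    meta = epochs.meta.loc[mask].reset_index(drop=True)
    for hand in HANDS:
        for angle in ANGLES:
            cell = (meta["hand"] == hand) & (meta["angle"] == angle)
            had = ((epochs.meta["hand"] == hand) & (epochs.meta["angle"] == angle)).any()
            if had and not cell.any():
                logger.warning(
                    "subject %s: no correct trials left for cell (%s, %d)",
                    epochs.subject_id, hand, angle,
                )
    return epochs.copy_with(data=kept, meta=meta)


def _beta_sos(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band edges ({low}, {high}) must lie inside (0, fs/2={fs / 2})")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_beta(epochs: EpochSet, low: float = 13.0, high: float = 30.0,
                  order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass, per channel per trial.

    A forward-backward 4th-order Butterworth (effective 8th order) keeps
    phases undistorted, which matters because phases are the analysis
    target.  Output length equals input length.
    """
    sos = _beta_sos(low, high, epochs.fs, order=order)
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.copy_with(data=filtered)


def segment(epochs: EpochSet, windows=DEFAULT_WINDOWS) -> dict[str, EpochSet]:
    """Slice every trial into named sub-stage windows.

    Windows must be non-overlapping and lie within the trial; the
    mapping from milliseconds to samples is half-open, so the defaults
    give 300/500/400-sample segments at 1000 Hz.
    """
    windows = tuple(windows)
    spans = sorted((w.start_ms, w.end_ms, w.name) for w in windows)
    for (s0, e0, n0), (s1, e1, n1) in zip(spans, spans[1:]):
        if e0 > s1:
            raise ValueError(f"windows {n0} and {n1} overlap")
    duration_ms = epochs.n_samples / epochs.fs * 1000.0
    out: dict[str, EpochSet] = {}
    for w in windows:
        if w.end_ms > duration_ms + 1e-9:
            raise ValueError(f"window {w.name} ends beyond trial ({duration_ms} ms)")
        sl = w.sample_slice(epochs.fs)
        out[w.name] = epochs.copy_with(data=epochs.data[:, :, sl])
    return out
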