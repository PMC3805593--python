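"""Instantaneous phases, mean phase coherence, and association matrices.

Phases come from the analytic signal (Hilbert transform); pairwise
synchrony is the mean phase coherence (MPC): the modulus of the
time-averaged unit phasor of the 1:1 phase difference.  Per-trial
channel-by-channel MPC matrices are averaged within each (hand, angle)
stimulus type to give twelve association matrices per subject per
sub-stage, and summarized into left-intra / right-intra /
inter-hemispheric means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from phasenet.montage import Montage
from phasenet.preprocess import ANGLES, HANDS

__all__ = [
    "PhaseSegment",
    "AssociationMatrix",
    "HemisphericPSI",
    "analytic_phase",
    "mpc",
    "psi_matrix",
    "average_by_type",
    "hemispheric_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class PhaseSegment:
    """Instantaneous phases with a per-(trial, channel) validity mask.

    ``phases`` has the same shape as the source segment, wrapped to
    (-pi, pi].  Channels whose signal was identically zero have
    undefined phase and are marked invalid.
    """

    phases: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.phases.shape[:-1] != self.valid.shape:
            raise ValueError("valid mask must match phases without the sample axis")


@dataclass
class AssociationMatrix:
    """Symmetric channel-by-channel PSI matrix with zero diagonal."""

    psi: np.ndarray
    labels: tuple[str, ...]
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        psi = np.asarray(self.psi, dtype=float)
        if psi.ndim != 2 or psi.shape[0] != psi.shape[1]:
            raise ValueError("psi must be square")
        if psi.shape[0] != len(self.labels):
            raise ValueError("labels must match matrix dimension")
        if not np.allclose(psi, psi.T, equal_nan=True):
            raise ValueError("psi must be symmetric")
        off = psi[~np.eye(psi.shape[0], dtype=bool)]
        finite = off[np.isfinite(off)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("off-diagonal PSI values must lie in [0, 1]")
        self.psi = psi

    @property
    def n_channels(self) -> int:
        return self.psi.shape[0]


@dataclass(frozen=True)
class HemisphericPSI:
    """Mean PSI of the left-intra, right-intra and inter pair classes."""

    psi_L: float
    psi_R: float
    psi_I: float


def analytic_phase(segment: np.ndarray) -> PhaseSegment:
    """Instantaneous phase of every channel via the analytic signal.

    ``segment`` is ``(..., samples)`` real (typically trials x channels
    x samples); the Hilbert transform runs along the last axis.  Callers
    analysing sub-stage windows should transform the full trial first
    and slice afterwards, so that edge artifacts stay away from short
    windows.
    """
    segment = np.asarray(segment, dtype=float)
    analytic = hilbert(segment, axis=-1)
    phases = np.angle(analytic)
    valid = ~np.all(segment == 0.0, axis=-1)
    if not valid.all():
        logger.warning("analytic_phase: %d all-zero signal(s); phase undefined",
                       int((~valid).sum()))
    return PhaseSegment(phases=phases, valid=valid)


def mpc(phi1: np.ndarray, phi2: np.ndarray) -> np.ndarray | float:
    """Mean phase coherence of two phase sequences.

    ``|<exp(i (phi1 - phi2))>|`` averaged over the last axis; 1 means a
    constant phase difference, 0 no phase locking.  Leading axes are
    broadcast, so a whole trial stack can be evaluated in one call.
    """
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    if phi1.shape[-1] != phi2.shape[-1]:
        raise ValueError(
            f"phase sequences differ in length: {phi1.shape[-1]} vs {phi2.shape[-1]}")
    if phi1.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    value = np.abs(np.mean(np.exp(1j * (phi1 - phi2)), axis=-1))
    return float(value) if value.ndim == 0 else value


def psi_matrix(phases: PhaseSegment | np.ndarray) -> np.ndarray:
    """Per-trial association matrices from a phase segment.

    Input ``(trials, channels, samples)`` (a bare trial ``(channels,
    samples)`` is promoted); output ``(trials, channels, channels)``
    symmetric with zero diagonal.  Exactly ``n (n - 1) / 2`` MPC
    evaluations are performed, one per unordered channel pair; pairs
    involving an invalid (all-zero) channel are NaN.
    """
    if isinstance(phases, PhaseSegment):
        arr, valid = phases.phases, phases.valid
    else:
        arr = np.asarray(phases, dtype=float)
        valid = None
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
        valid = None if valid is None else valid[None]
    trials, n, _ = arr.shape
    if n < 2:
        raise ValueError("need at least 2 channels")
    out = np.zeros((trials, n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = mpc(arr[:, i, :], arr[:, j, :])
            out[:, i, j] = v
            out[:, j, i] = v
    if valid is not None and not valid.all():
        for t in range(trials):
            bad = np.flatnonzero(~valid[t])
            for b in bad:
                out[t, b, :] = np.nan
                out[t, :, b] = np.nan
            out[t][np.diag_indices(n)] = 0.0
    return out[0] if squeeze else out


def average_by_type(per_trial: np.ndarray, meta: pd.DataFrame,
                    labels: tuple[str, ...] | None = None,
                    context: dict | None = None,
                    ) -> dict[tuple[str, int], AssociationMatrix]:
    """Element-wise mean of per-trial matrices within each stimulus type.

    Returns one matrix per (hand, angle) cell present in the design —
    twelve for the full 2 x 6 layout.  Empty cells are logged and
    omitted from the result.
    """
    per_trial = np.asarray(per_trial, dtype=float)
    if per_trial.ndim != 3 or len(meta) != per_trial.shape[0]:
        raise ValueError("per_trial must be (trials, n, n) aligned with meta")
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(per_trial.shape[1]))
    context = context or {}
    out: dict[tuple[str, int], AssociationMatrix] = {}
    hands = [h for h in HANDS if (meta["hand"] == h).any()] or list(HANDS)
    angles = [a for a in ANGLES if (meta["angle"] == a).any()] or list(ANGLES)
    for hand in hands:
        for angle in angles:
            mask = ((meta["hand"] == hand) & (meta["angle"] == angle)).to_numpy()
            if not mask.any():
                logger.warning("average_by_type: empty cell (%s, %d)%s",
                               hand, angle,
                               f" for {context}" if context else "")
                continue
            mean = np.nanmean(per_trial[mask], axis=0)
            np.fill_diagonal(mean, 0.0)
            out[(hand, angle)] = AssociationMatrix(
                psi=mean, labels=labels,
                context={**context, "hand": hand, "angle": angle})
    return out


def hemispheric_summary(matrix: AssociationMatrix | np.ndarray,
                        montage: Montage) -> HemisphericPSI:
    """Mean PSI over the left-intra, right-intra and inter pair classes.

    Midline channels belong to no class, so the three classes partition
    the non-midline pairs (66 / 66 / 144 for the default montage).
    """
    psi = matrix.psi if isinstance(matrix, AssociationMatrix) else np.asarray(matrix)
    if psi.shape[0] != montage.n_channels:
        raise ValueError("matrix dimension does not match montage")
    classes = montage.pair_classes()

    def class_mean(pairs: list[tuple[int, int]]) -> float:
        vals = np.array([psi[i, j] for i, j in pairs])
        return float(np.nanmean(vals))

    return HemisphericPSI(
        psi_L=class_mean(classes["left"]),
        psi_R=class_mean(classes["right"]),
        psi_I=class_mean(classes["inter"]),
    )
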