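"""Synthetic cohorts: stimulus schedules and coupled-oscillator epochs.

Signal model
------------
Every channel rides a shared, slowly drifting carrier phase; channels in
the same hemisphere additionally share a slow hemispheric drift, which
makes intra-hemispheric pairs more coherent than inter-hemispheric ones.
On top of that, each channel receives independent per-sample von Mises
phase jitter whose concentration ``kappa`` is piecewise constant over
the three sub-stage windows (blended with a short raised-cosine ramp at
the boundaries) and is modulated multiplicatively by stimulus angle,
group and an optional per-channel gain.

For two channels in the same hemisphere the phase difference reduces to
the difference of the two jitter streams, so the expected mean phase
coherence of a pair has a numerically computable form — the mean
resultant length of the jitter difference — which is what makes this
generator usable as a ground-truth oracle: for von Mises jitter with
concentrations ``k1, k2`` the large-sample pair MPC tends to
``(I1(k1)/I0(k1)) * (I1(k2)/I0(k2))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import i0e, i1e

from phasenet.montage import Montage, default_montage
from phasenet.preprocess import ANGLES, DEFAULT_WINDOWS, EpochSet, HANDS, SubStageWindow

__all__ = [
    "PAPER_ANGLE_PROBS",
    "StimulusSchedule",
    "CouplingSpec",
    "CohortSpec",
    "make_schedule",
    "generate_epoch",
    "generate_cohort",
    "control_preset",
    "patient_preset",
    "vonmises_resultant",
    "expected_pair_mpc",
]

#: Angle presentation probabilities of the emulated block design.
PAPER_ANGLE_PROBS: dict[int, float] = {
    0: 0.25, 60: 0.125, 120: 0.125, 180: 0.25, 240: 0.125, 300: 0.125,
}

#: kappa values at or above this are treated as "jitter off".
_KAPPA_INF = 1e6

_STAGES = ("Beginning", "Middle", "End")


def vonmises_resultant(kappa: float) -> float:
    """Mean resultant length I1(kappa)/I0(kappa) of a von Mises sample."""
    if kappa >= _KAPPA_INF or math.isinf(kappa):
        return 1.0
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    return float(i1e(kappa) / i0e(kappa))


def expected_pair_mpc(kappa1: float, kappa2: float | None = None) -> float:
    """Asymptotic (many-sample) MPC of a jittered channel pair.

    The phase difference of two channels with independent von Mises
    jitter has mean resultant length equal to the product of the two
    per-channel resultants.
    """
    if kappa2 is None:
        kappa2 = kappa1
    return vonmises_resultant(kappa1) * vonmises_resultant(kappa2)


# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered (hand, angle) trial list for one block."""

    trials: tuple[tuple[str, int], ...]
    block_size: int

    def __len__(self) -> int:
        return len(self.trials)

    def counts(self) -> dict[tuple[str, int], int]:
        out: dict[tuple[str, int], int] = {}
        for t in self.trials:
            out[t] = out.get(t, 0) + 1
        return out


def make_schedule(block_size: int,
                  probabilities: dict[int, float] | None = None,
                  seed: int | np.random.Generator = 0) -> StimulusSchedule:
    """Seeded random permutation of an exact stimulus multiset.

    Each angle appears ``probabilities[angle] * block_size`` times,
    split equally between hands; both products must be integers.  Only
    the presentation order is random — the multiset is deterministic.
    """
    if probabilities is None:
        probabilities = PAPER_ANGLE_PROBS
    total = sum(probabilities.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"angle probabilities sum to {total}, expected 1")
    multiset: list[tuple[str, int]] = []
    for angle, prob in probabilities.items():
        count = prob * block_size
        if abs(count - round(count)) > 1e-9:
            raise ValueError(
                f"angle {angle}: expected count {count} is not an integer "
                f"(block_size={block_size}, p={prob})"
            )
        count = int(round(count))
        if count % 2:
            raise ValueError(
                f"angle {angle}: count {count} cannot be split equally "
                f"between hands"
            )
        for hand in HANDS:
            multiset.extend([(hand, angle)] * (count // 2))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(multiset))
    trials = tuple(multiset[i] for i in order)
    return StimulusSchedule(trials=trials, block_size=block_size)


# ---------------------------------------------------------------------------
# coupling and cohort specifications
# ---------------------------------------------------------------------------

def _default_angle_gain() -> dict[int, float]:
    # coupling strengthens with rotation angle, peaking at 180 degrees
    return {0: 0.85, 60: 0.95, 120: 1.05, 180: 1.20, 240: 1.05, 300: 0.95}


def _unit_group_gain() -> dict[str, dict[str, float]]:
    return {g: {s: 1.0 for s in _STAGES} for g in ("control", "patient")}


@dataclass
class CouplingSpec:
    """Parameters of the coupled-oscillator signal model.

    Attributes
    ----------
    kappa
        Per-sub-stage von Mises jitter concentration (larger = tighter
        coupling).  A scalar applies to all three sub-stages.
    carrier_freq
        Carrier frequency in Hz; must lie strictly inside (13, 30).
    noise_sd
        Standard deviation of additive white noise.
    angle_gain
        Multiplicative kappa modifier per stimulus angle.
    group_gain
        ``group -> sub-stage -> multiplicative kappa modifier``.
    channel_gain
        Optional per-channel-label kappa multiplier (nodal asymmetry
        hook, e.g. boosting right-parietal coupling).
    drift_rate
        Random-walk rate (rad / sqrt(s)) of the shared carrier phase.
    hemisphere_drift_rate
        Extra per-hemisphere drift rate; lowers inter-hemispheric MPC.
    subject_kappa_sd
        Log-normal sigma of a per-subject kappa multiplier.
    carrier_jitter_hz
        Half-width of the uniform per-subject carrier detuning.
    ramp_ms
        Raised-cosine blend length at sub-stage boundaries.
    """

    kappa: dict[str, float] | float = 2.0
    carrier_freq: float = 20.0
    noise_sd: float = 0.1
    angle_gain: dict[int, float] = field(default_factory=_default_angle_gain)
    group_gain: dict[str, dict[str, float]] = field(default_factory=_unit_group_gain)
    channel_gain: dict[str, float] = field(default_factory=dict)
    drift_rate: float = 1.0
    hemisphere_drift_rate: float = 1.5
    subject_kappa_sd: float = 0.15
    carrier_jitter_hz: float = 0.5
    ramp_ms: float = 20.0

    def __post_init__(self) -> None:
        if not 13.0 < self.carrier_freq < 30.0:
            raise ValueError("carrier_freq must lie in the open interval (13, 30) Hz")
        if isinstance(self.kappa, (int, float)):
            self.kappa = {s: float(self.kappa) for s in _STAGES}
        for stage, k in self.kappa.items():
            if k < 0:
                raise ValueError(f"kappa[{stage}] must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def kappa_for(self, stage: str, angle: int, group: str,
                  channel: str | None = None) -> float:
        k = self.kappa[stage]
        k *= self.angle_gain.get(angle, 1.0)
        k *= self.group_gain.get(group, {}).get(stage, 1.0)
        if channel is not None:
            k *= self.channel_gain.get(channel, 1.0)
        return k


@dataclass
class CohortSpec:
    """Two-group study layout: subjects, blocks and trial counts."""

    n_per_group: int = 11
    blocks_per_subject: dict[str, int] = field(
        default_factory=lambda: {"control": 6, "patient": 2})
    block_size: int = 96
    probabilities: dict[int, float] = field(
        default_factory=lambda: dict(PAPER_ANGLE_PROBS))
    accuracy: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "patient": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        for g, b in self.blocks_per_subject.items():
            if b < 1:
                raise ValueError(f"blocks for group {g} must be >= 1")


def control_preset() -> CouplingSpec:
    """Default coupling of the healthy cohort."""
    return CouplingSpec(kappa={"Beginning": 1.5, "Middle": 2.5, "End": 2.0})


def patient_preset(nodal_boost: float = 1.0) -> CouplingSpec:
    """Patient cohort: coupling reduced only in the Middle window.

    ``nodal_boost`` > 1 additionally strengthens right-parietal channel
    coupling (P4, P8, CP6) in every window — an opt-in asymmetry hook;
    it is off by default so the group contrast stays confined to the
    Middle sub-stage.
    """
    spec = CouplingSpec(kappa={"Beginning": 1.5, "Middle": 2.5, "End": 2.0})
    spec.group_gain = {
        "control": {s: 1.0 for s in _STAGES},
        "patient": {"Beginning": 1.0, "Middle": 0.3, "End": 1.0},
    }
    if nodal_boost != 1.0:
        spec.channel_gain = {"P4": nodal_boost, "P8": nodal_boost,
                             "CP6": nodal_boost}
    return spec


# ---------------------------------------------------------------------------
# epoch generation
# ---------------------------------------------------------------------------

def _kappa_profile(kappas: list[float], windows: tuple[SubStageWindow, ...],
                   n_samples: int, fs: float, ramp_ms: float) -> np.ndarray:
    """Per-sample kappa: piecewise constant, raised-cosine blended."""
    prof = np.empty(n_samples)
    for k, w in zip(kappas, windows):
        sl = w.sample_slice(fs)
        prof[sl.start:min(sl.stop, n_samples)] = k
    ramp = int(round(ramp_ms * fs / 1000.0))
    if ramp > 0:
        # the ramp lives entirely inside the NEW window, so each window's
        # leading edge transitions smoothly while the previous window
        # keeps its own coupling level to the last sample
        for idx in range(1, len(windows)):
            b = windows[idx].sample_slice(fs).start
            lo, hi = b, min(b + ramp, n_samples)
            if hi <= lo:
                continue
            x = (np.arange(lo, hi) - lo + 1) / (hi - lo)
            blend = 0.5 * (1 - np.cos(np.pi * x))
            prof[lo:hi] = kappas[idx - 1] * (1 - blend) + kappas[idx] * blend
    return prof


def _vonmises_jitter(rng: np.random.Generator, kappa: np.ndarray) -> np.ndarray:
    """Von Mises(0, kappa) draws; kappa >= _KAPPA_INF means no jitter."""
    kappa = np.asarray(kappa, dtype=float)
    out = np.zeros_like(kappa)
    # tolerance absorbs float error from blending two at-threshold values
    finite = kappa < 0.99 * _KAPPA_INF
    if finite.any():
        out[finite] = rng.vonmises(0.0, kappa[finite])
    return out


def generate_epoch(schedule_entry: tuple[str, int],
                   coupling: CouplingSpec,
                   montage: Montage | None = None,
                   fs: float = 1000.0,
                   duration_ms: float = 1200.0,
                   seed: int | np.random.Generator = 0,
                   group: str = "control",
                   windows: tuple[SubStageWindow, ...] = DEFAULT_WINDOWS,
                   carrier_offset_hz: float = 0.0,
                   subject_gain: float = 1.0,
                   return_phases: bool = False):
    """Simulate one trial: ``(channels, samples)`` real matrix.

    With ``return_phases=True`` also returns the model phases (before
    additive noise), from which pairwise MPC can be computed exactly.
    """
    if fs <= 0 or duration_ms <= 0:
        raise ValueError("fs and duration_ms must be positive")
    if max(w.end_ms for w in windows) > duration_ms:
        raise ValueError("duration must cover all sub-stage windows")
    montage = montage or default_montage()
    hand, angle = schedule_entry
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(round(duration_ms * fs / 1000.0))
    t = np.arange(n) / fs
    freq = coupling.carrier_freq + carrier_offset_hz
    dt_sqrt = 1.0 / math.sqrt(fs)

    theta = np.cumsum(rng.normal(0.0, coupling.drift_rate * dt_sqrt, size=n))
    hemi_drift = {
        h: np.cumsum(rng.normal(0.0, coupling.hemisphere_drift_rate * dt_sqrt, size=n))
        for h in ("left", "right")
    }
    hemi_drift["midline"] = np.zeros(n)

    phases = np.empty((montage.n_channels, n))
    for ci, label in enumerate(montage.labels):
        kappas = [
            min(subject_gain * coupling.kappa_for(w.name, angle, group, label),
                _KAPPA_INF)
            if math.isfinite(coupling.kappa_for(w.name, angle, group, label))
            else _KAPPA_INF
            for w in windows
        ]
        prof = _kappa_profile(kappas, windows, n, fs, coupling.ramp_ms)
        jitter = _vonmises_jitter(rng, prof)
        hemi = montage.hemisphere_of[label]
        phases[ci] = 2 * np.pi * freq * t + theta + hemi_drift[hemi] + jitter

    data = np.sin(phases)
    if coupling.noise_sd > 0:
        data = data + rng.normal(0.0, coupling.noise_sd, size=data.shape)
    if return_phases:
        return data, phases
    return data


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec,
                    control_coupling: CouplingSpec | None = None,
                    patient_coupling: CouplingSpec | None = None,
                    montage: Montage | None = None,
                    fs: float = 1000.0,
                    duration_ms: float = 1200.0,
                    windows: tuple[SubStageWindow, ...] = DEFAULT_WINDOWS,
                    ) -> list[EpochSet]:
    """Generate the full two-group cohort, one :class:`EpochSet` per subject.

    All randomness derives from ``spec.seed`` through a fixed
    ``SeedSequence`` spawn tree (cohort -> subject -> trial), so the
    same spec reproduces the dataset exactly.
    """
    control_coupling = control_coupling or control_preset()
    patient_coupling = patient_coupling or patient_preset()
    montage = montage or default_montage()

    root = np.random.SeedSequence(spec.seed)
    groups = [("control", control_coupling), ("patient", patient_coupling)]
    subject_seeds = root.spawn(2 * spec.n_per_group)

    cohort: list[EpochSet] = []
    si = 0
    for group, coupling in groups:
        for gi in range(spec.n_per_group):
            ss = subject_seeds[si]
            si += 1
            rng = np.random.default_rng(ss)
            subject_gain = float(np.exp(rng.normal(0.0, coupling.subject_kappa_sd)))
            carrier_offset = float(rng.uniform(-coupling.carrier_jitter_hz,
                                               coupling.carrier_jitter_hz))
            n_blocks = spec.blocks_per_subject[group]
            acc = spec.accuracy.get(group, 1.0)

            trials, rows = [], []
            for block in range(n_blocks):
                sched = make_schedule(spec.block_size, spec.probabilities, seed=rng)
                for ti, (hand, angle) in enumerate(sched.trials):
                    epoch = generate_epoch(
                        (hand, angle), coupling, montage, fs=fs,
                        duration_ms=duration_ms, seed=rng, group=group,
                        windows=windows, carrier_offset_hz=carrier_offset,
                        subject_gain=subject_gain,
                    )
                    trials.append(epoch)
                    rows.append({
                        "block": block, "trial": ti, "hand": hand,
                        "angle": angle,
                        "correct": bool(rng.random() < acc),
                    })
            sid = f"{'C' if group == 'control' else 'P'}{gi + 1:02d}"
            cohort.append(EpochSet(
                data=np.stack(trials), fs=fs, montage=montage,
                meta=pd.DataFrame(rows), subject_id=sid, group=group,
            ))
    return cohort
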