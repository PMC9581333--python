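"""Synthetic induction-current sessions with exact ground truth.

The magnet/coil apparatus converts hind-limb movement into an induction
current.  Scratching appears in that current as oscillation bursts at the
paw-oscillation ("beat") rate of roughly 10-20 Hz; a run of beats is a bout,
and one or more bouts between a paw lift and paw-down form a scratch event.
Locomotion and grooming produce slower (sub-10 Hz) oscillations and are the
confounders the frequency band is meant to reject.

This module renders such sessions from an explicit event/bout/beat schedule
so every downstream stage can be validated against exact annotations.  Each
beat is rendered as one Hann-windowed cosine cycle at the bout's frequency;
confounders are Hann-windowed tone bursts in their own band; white Gaussian
noise is added on top.  No attempt is made to model coil physics - the
simulator targets the detector's decision variables (band, rhythmicity,
amplitude) only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfounderSpec",
    "SignalParams",
    "SignalTrace",
    "BoutTruth",
    "EventTruth",
    "ConfounderInterval",
    "GroundTruth",
    "ScheduleInfeasibleError",
    "simulate_session",
    "DEFAULT_CONFOUNDERS",
]

#: minimum silent gap (s) enforced between any two scheduled items (events or
#: confounder bursts) so that filter transients of one burst cannot bleed into
#: the next and so that distinct events stay distinct under the default
#: 1 s event-gap rule of the detector
MIN_SCHEDULE_GAP_S = 1.5

#: generated bouts must satisfy the 40 % inter-beat-interval CV rule with a
#: margin, so that beat-time quantization at the sampling grid cannot push a
#: rendered bout over the detector's limit
GENERATOR_CV_CAP = 0.38


class ScheduleInfeasibleError(ValueError):
    """Raised when the requested events/confounders cannot fit in the session."""


@dataclass(frozen=True)
class ConfounderSpec:
    """A class of sub-scratch-band movement artifact.

    kind            label carried into the ground truth ("locomotion"/"grooming")
    freq_range      oscillation band of the artifact, Hz
    rate_per_min    expected number of bursts per minute (Poisson)
    amplitude       burst amplitude relative to ``bout_amplitude`` units
    duration_range  burst duration drawn uniformly from this range, s
    """

    kind: str
    freq_range: tuple[float, float]
    rate_per_min: float
    amplitude: float
    duration_range: tuple[float, float] = (1.0, 4.0)


#: locomotion is slow (1-4 Hz) and high amplitude, grooming intermediate
#: (5-8 Hz); both sit below the 10-20 Hz scratch band so the band filter is
#: the operative discriminator
DEFAULT_CONFOUNDERS: tuple[ConfounderSpec, ...] = (
    ConfounderSpec("locomotion", (1.0, 4.0), 0.5, 2.0, (2.0, 5.0)),
    ConfounderSpec("grooming", (5.0, 8.0), 1.0, 1.0, (1.0, 3.0)),
)


@dataclass
class SignalParams:
    """Parameters of one simulated 30-min session.

    Defaults are the study conditions: a 30 min (1800 s) post-injection
    window, scratch beats at 10-20 Hz, and a 200 Hz sampling rate (ten times
    the top of the scratch band; the acquisition rate of the original
    apparatus is not part of the record, so it is configurable).
    """

    sampling_rate: float = 200.0
    duration_s: float = 1800.0
    beat_freq_range: tuple[float, float] = (10.0, 20.0)
    beat_jitter_cv: float = 0.15
    beats_per_bout_range: tuple[int, int] = (4, 30)
    bouts_per_event_range: tuple[int, int] = (1, 5)
    intra_event_gap_s: tuple[float, float] = (0.2, 0.8)
    n_events: int = 40
    confounder_spec: tuple[ConfounderSpec, ...] = DEFAULT_CONFOUNDERS
    noise_sd: float = 0.1
    bout_amplitude: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        f_lo, f_hi = self.beat_freq_range
        if not (f_lo < f_hi):
            raise ValueError("beat_freq_range must satisfy f_lo < f_hi")
        if self.sampling_rate < 4.0 * f_hi:
            raise ValueError("sampling_rate must be >= 4 * f_hi to resolve beats")
        if not (0.0 <= self.beat_jitter_cv < 1.0):
            raise ValueError("beat_jitter_cv must be in [0, 1)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.beats_per_bout_range[0] < 3:
            raise ValueError("bouts need >= 3 beats for a defined interval CV")
        if self.n_events < 0 or self.noise_sd < 0:
            raise ValueError("n_events and noise_sd must be nonnegative")


@dataclass
class SignalTrace:
    """Uniformly sampled induction-current series, t = 0 at injection."""

    signal: np.ndarray
    sampling_rate: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.signal.size) / self.sampling_rate

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.sampling_rate


@dataclass
class BoutTruth:
    onset_s: float                # rendered support start
    offset_s: float               # rendered support end
    beat_times_s: np.ndarray      # strictly increasing cycle anchors

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.onset_s + self.offset_s)

    def interval_cv(self) -> float:
        iv = np.diff(self.beat_times_s)
        return float(np.std(iv, ddof=1) / np.mean(iv))

    def to_dict(self) -> dict:
        return {
            "onset_s": self.onset_s,
            "offset_s": self.offset_s,
            "beat_times_s": [float(t) for t in self.beat_times_s],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoutTruth":
        return cls(d["onset_s"], d["offset_s"], np.asarray(d["beat_times_s"], float))


@dataclass
class EventTruth:
    lift_s: float
    down_s: float
    bouts: list[BoutTruth]

    def to_dict(self) -> dict:
        return {
            "lift_s": self.lift_s,
            "down_s": self.down_s,
            "bouts": [b.to_dict() for b in self.bouts],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventTruth":
        return cls(d["lift_s"], d["down_s"], [BoutTruth.from_dict(b) for b in d["bouts"]])


@dataclass
class ConfounderInterval:
    onset_s: float
    offset_s: float
    kind: str

    def to_dict(self) -> dict:
        return {"onset_s": self.onset_s, "offset_s": self.offset_s, "kind": self.kind}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfounderInterval":
        return cls(d["onset_s"], d["offset_s"], d["kind"])


@dataclass
class GroundTruth:
    """Exact annotation of a simulated session (events -> bouts -> beats)."""

    events: list[EventTruth] = field(default_factory=list)
    confounders: list[ConfounderInterval] = field(default_factory=list)

    @property
    def bouts(self) -> list[BoutTruth]:
        return [b for e in self.events for b in e.bouts]

    @property
    def n_bouts(self) -> int:
        return sum(len(e.bouts) for e in self.events)

    @property
    def n_beats(self) -> int:
        return sum(len(b.beat_times_s) for e in self.events for b in e.bouts)

    def to_dict(self) -> dict:
        return {
            "events": [e.to_dict() for e in self.events],
            "confounders": [c.to_dict() for c in self.confounders],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            [EventTruth.from_dict(e) for e in d.get("events", [])],
            [ConfounderInterval.from_dict(c) for c in d.get("confounders", [])],
        )


# ---------------------------------------------------------------------------
# schedule construction


def _draw_bout(rng: np.random.Generator, p: SignalParams) -> tuple[np.ndarray, float]:
    """Relative beat times of one bout and the bout's cycle period.

    The bout frequency is drawn from the interior of the band and the
    jittered inter-beat intervals are clipped 1.5 samples inside
    [1/f_hi, 1/f_lo]; jitter is redrawn until the interval CV falls under
    GENERATOR_CV_CAP.  Both margins make every generated bout detectable by
    construction at default detector settings, even after beat times are
    quantized to the sampling grid.
    """
    f_lo, f_hi = p.beat_freq_range
    span = f_hi - f_lo
    f = rng.uniform(f_lo + 0.10 * span, f_hi - 0.20 * span)
    dt = 1.0 / p.sampling_rate
    iv_lo = 1.0 / f_hi + 1.5 * dt
    iv_hi = 1.0 / f_lo - 1.5 * dt
    if iv_lo >= iv_hi:
        raise ValueError("sampling rate too low for in-band interval margins")
    n_beats = int(rng.integers(p.beats_per_bout_range[0], p.beats_per_bout_range[1] + 1))
    period = 1.0 / f
    for _ in range(1000):
        iv = rng.normal(period, p.beat_jitter_cv * period, size=n_beats - 1)
        iv = np.clip(iv, iv_lo, iv_hi)
        cv = float(np.std(iv, ddof=1) / np.mean(iv)) if n_beats > 2 else 0.0
        if cv <= GENERATOR_CV_CAP:
            break
    else:  # pragma: no cover - jitter_cv near 1 only
        raise RuntimeError("could not draw an in-spec bout; lower beat_jitter_cv")
    beats = np.concatenate([[0.0], np.cumsum(iv)])
    return beats, period


def _build_event(rng: np.random.Generator, p: SignalParams) -> tuple[list[tuple[np.ndarray, float]], float]:
    """One event as a list of (relative beat times, period) plus its duration."""
    n_bouts = int(rng.integers(p.bouts_per_event_range[0], p.bouts_per_event_range[1] + 1))
    bouts: list[tuple[np.ndarray, float]] = []
    t = 0.0
    for i in range(n_bouts):
        beats, period = _draw_bout(rng, p)
        if i > 0:
            t += rng.uniform(*p.intra_event_gap_s)
        bouts.append((beats + t + period / 2.0, period))
        t = bouts[-1][0][-1] + period / 2.0
    return bouts, t


def _place_items(
    rng: np.random.Generator, durations: list[float], total_s: float
) -> list[float]:
    """Random non-overlapping start times with MIN_SCHEDULE_GAP_S spacing."""
    n = len(durations)
    if n == 0:
        return []
    occupied = sum(durations) + MIN_SCHEDULE_GAP_S * (n + 1)
    free = total_s - occupied
    if free < 0:
        raise ScheduleInfeasibleError(
            f"schedule infeasible: {sum(durations):.1f} s of activity plus spacing "
            f"does not fit in {total_s:.1f} s"
        )
    # split the free time into n+1 random gaps
    w = rng.dirichlet(np.ones(n + 1)) * free
    starts = []
    t = 0.0
    for i in range(n):
        t += w[i] + MIN_SCHEDULE_GAP_S
        starts.append(t)
        t += durations[i]
    return starts


# ---------------------------------------------------------------------------
# rendering


def _render_beat(signal: np.ndarray, fs: float, t_beat: float, period: float, amp: float) -> None:
    """Add one Hann-windowed cosine cycle centred at ``t_beat`` in place."""
    half = period / 2.0
    i0 = max(0, int(math.ceil((t_beat - half) * fs)))
    i1 = min(signal.size - 1, int(math.floor((t_beat + half) * fs)))
    if i1 < i0:
        return
    tau = np.arange(i0, i1 + 1) / fs - t_beat
    window = 0.5 * (1.0 + np.cos(2.0 * np.pi * tau / (2.0 * half)))
    signal[i0 : i1 + 1] += amp * window * np.cos(2.0 * np.pi * tau / period)


def _render_tone_burst(
    signal: np.ndarray, fs: float, t0: float, t1: float, freq: float, amp: float, phase: float
) -> None:
    i0 = max(0, int(math.ceil(t0 * fs)))
    i1 = min(signal.size - 1, int(math.floor(t1 * fs)))
    if i1 <= i0:
        return
    tt = np.arange(i0, i1 + 1) / fs
    window = 0.5 * (1.0 - np.cos(2.0 * np.pi * (tt - t0) / (t1 - t0)))
    signal[i0 : i1 + 1] += amp * window * np.cos(2.0 * np.pi * freq * (tt - t0) + phase)


# ---------------------------------------------------------------------------


def simulate_session(params: SignalParams) -> tuple[SignalTrace, GroundTruth]:
    """Render one session and its exact annotation.

    Identical ``params`` (including ``seed``) give bit-identical output.
    Raises :class:`ScheduleInfeasibleError` when the requested activity
    cannot fit into ``duration_s`` without overlap.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.sampling_rate * params.duration_s))
    signal = np.zeros(n)

    # draw the content of every item first, then place all items jointly
    events = [_build_event(rng, params) for _ in range(params.n_events)]
    conf_items: list[tuple[ConfounderSpec, float, float, float]] = []
    for spec in params.confounder_spec:
        k = rng.poisson(spec.rate_per_min * params.duration_s / 60.0)
        for _ in range(k):
            dur = rng.uniform(*spec.duration_range)
            freq = rng.uniform(*spec.freq_range)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            conf_items.append((spec, dur, freq, phase))

    durations = [ev[1] for ev in events] + [c[1] for c in conf_items]
    order = rng.permutation(len(durations))
    starts_perm = _place_items(rng, [durations[i] for i in order], params.duration_s)
    starts = [0.0] * len(durations)
    for pos, idx in enumerate(order):
        starts[idx] = starts_perm[pos]

    truth = GroundTruth()
    for (bouts, _dur), start in zip(events, starts[: len(events)]):
        ev_bouts = []
        for beats_rel, period in bouts:
            beats_abs = beats_rel + start
            for tb in beats_abs:
                _render_beat(signal, params.sampling_rate, tb, period, params.bout_amplitude)
            ev_bouts.append(
                BoutTruth(
                    onset_s=float(beats_abs[0] - period / 2.0),
                    offset_s=float(beats_abs[-1] + period / 2.0),
                    beat_times_s=beats_abs,
                )
            )
        truth.events.append(
            EventTruth(
                lift_s=max(0.0, ev_bouts[0].onset_s - 0.1),
                down_s=min(params.duration_s, ev_bouts[-1].offset_s + 0.1),
                bouts=ev_bouts,
            )
        )
    for (spec, dur, freq, phase), start in zip(conf_items, starts[len(events):]):
        _render_tone_burst(
            signal, params.sampling_rate, start, start + dur, freq,
            spec.amplitude * params.bout_amplitude, phase,
        )
        truth.confounders.append(ConfounderInterval(start, start + dur, spec.kind))

    truth.events.sort(key=lambda e: e.lift_s)
    truth.confounders.sort(key=lambda c: c.onset_s)
    if params.noise_sd > 0:
        signal += rng.normal(0.0, params.noise_sd, size=n)
    return SignalTrace(signal=signal, sampling_rate=params.sampling_rate), truth


def default_validation_seeds() -> tuple[int, ...]:
    """Seeds of the default 20-session detector validation suite."""
    return tuple(range(1, 21))
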