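"""Ground-truth smFRET trace simulator.

Emulates the statistical structure of two-channel intensity trajectories
from surface-tethered target DNA observed during real-time injection of
fluorescently labeled intasomes:

* memoryless two-state binding kinetics (unbound <-> bound) with rates
  ``k_on`` and ``k_off``, disabled before the injection time;
* an absorbing strand-transfer (STC) branch entered with probability
  ``p_stc_per_binding`` at each binding event;
* anti-correlated donor/acceptor emission partitioned by the true FRET
  efficiency of the occupying state, exactly time-averaged over sub-frame
  state changes;
* a simultaneous background step in both channels at injection;
* step photobleaching of either fluorophore;
* transient "pseudo-FRET" excursions from aggregates that saturate the
  donor channel and bleed into the acceptor channel at E ~= 0.06;
* additive Gaussian camera noise.

Random number consumption order (fixed so seeds are portable): the trace
seed spawns three independent streams, consumed in the order
(1) state path — per cycle: unbound dwell, STC-conversion uniform, then
bound dwell if not absorbed; then donor bleach time, acceptor bleach
time; (2) per-frame channel noise, donor stream then acceptor stream;
(3) pseudo-FRET excursions — count, start times, durations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .traces import IntensityTrace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_state_path",
    "emit_intensities",
    "inject_pseudo_fret",
    "simulate_trace",
    "simulate_cohort",
]

#: FRET efficiency of aggregate bleed-through excursions.
PSEUDO_FRET = 0.06


@dataclass
class SimConfig:
    """Generating parameters for one simulated molecule or cohort.

    Defaults correspond to a 1 nt gap-like target observed at the slow
    (1 s) frame rate: bound-state lifetime tau_on = 1/k_off = 0.5 s,
    unbound lifetime tau_off = 1/k_on = 15 s, target-capture FRET 0.16.
    """

    frame_interval: float = 1.0
    duration: float = 600.0
    injection_time: float = 30.0
    k_on: float = 1.0 / 15.0
    k_off: float = 2.0
    p_stc_per_binding: float = 0.0
    fret_states: dict = field(
        default_factory=lambda: {
            "unbound": 0.0,
            "tcc": 0.16,
            "stc": 0.16,
            "pseudo": PSEUDO_FRET,
        }
    )
    total_intensity: float = 1000.0
    noise_sd: float = 50.0
    background: float = 50.0
    injection_step: float = 200.0
    bleach_rate_donor: float = 0.0
    bleach_rate_acceptor: float = 0.0
    aggregate_rate: float = 0.01
    aggregate_duration_mean: float = 1.0
    saturation_level: float = 10000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for name in (
            "injection_time",
            "k_on",
            "k_off",
            "p_stc_per_binding",
            "noise_sd",
            "bleach_rate_donor",
            "bleach_rate_acceptor",
            "aggregate_rate",
            "aggregate_duration_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.p_stc_per_binding <= 1:
            raise ValueError("p_stc_per_binding must be a probability")
        for k, v in self.fret_states.items():
            if not 0 <= v <= 1:
                raise ValueError(f"fret_states[{k!r}]={v} outside [0, 1]")
        n = self.duration / self.frame_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("frame_interval must divide duration exactly")
        if self.injection_time >= self.duration:
            raise ValueError("injection_time must fall inside the trace")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    @property
    def injection_frame(self) -> int:
        return int(round(self.injection_time / self.frame_interval))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GroundTruth:
    """True state path and event times for one simulated molecule."""

    intervals: list  # ordered (label, start, end); tiles [0, duration]
    stc: bool
    bleach_donor: float  # inf if never bleaches
    bleach_acceptor: float
    pseudo_excursions: list = field(default_factory=list)  # (start, end)

    def __post_init__(self) -> None:
        t = 0.0
        for _, start, end in self.intervals:
            if not np.isclose(start, t) or end < start:
                raise ValueError("intervals must tile [0, duration] without overlap")
            t = end
        has_stc = any(lbl == "stc" for lbl, _, _ in self.intervals)
        if has_stc != self.stc:
            raise ValueError("stc flag inconsistent with intervals")

    @property
    def duration(self) -> float:
        return self.intervals[-1][2]

    def bound_intervals(self) -> list:
        return [(s, e) for lbl, s, e in self.intervals if lbl in ("tcc", "stc")]


def simulate_state_path(config: SimConfig, rng: Optional[np.random.Generator] = None) -> GroundTruth:
    """Sample the continuous-time binding/strand-transfer state path.

    Alternating unbound/bound intervals with exponential dwell times
    (rates ``k_on``, ``k_off``); each binding converts to an absorbing
    STC with probability ``p_stc_per_binding``.  No events occur before
    ``injection_time`` (no intasomes present yet).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    T = config.duration
    intervals: list = []
    t = config.injection_time
    stc = False
    if t > 0:
        intervals.append(["unbound", 0.0, min(t, T)])
    while t < T:
        # unbound dwell
        if config.k_on == 0:
            if intervals and intervals[-1][0] == "unbound":
                intervals[-1][2] = T
            else:
                intervals.append(["unbound", t, T])
            t = T
            break
        dwell = rng.exponential(1.0 / config.k_on)
        end = min(t + dwell, T)
        if intervals and intervals[-1][0] == "unbound":
            intervals[-1][2] = end
        else:
            intervals.append(["unbound", t, end])
        t = end
        if t >= T:
            break
        # binding event: absorbing STC with probability p
        if rng.uniform() < config.p_stc_per_binding:
            intervals.append(["stc", t, T])
            stc = True
            t = T
            break
        if config.k_off == 0:
            intervals.append(["tcc", t, T])
            t = T
            break
        dwell = rng.exponential(1.0 / config.k_off)
        end = min(t + dwell, T)
        intervals.append(["tcc", t, end])
        t = end
    bleach_d = rng.exponential(1.0 / config.bleach_rate_donor) if config.bleach_rate_donor > 0 else np.inf
    bleach_a = rng.exponential(1.0 / config.bleach_rate_acceptor) if config.bleach_rate_acceptor > 0 else np.inf
    return GroundTruth(
        intervals=[tuple(iv) for iv in intervals],
        stc=stc,
        bleach_donor=float(bleach_d),
        bleach_acceptor=float(bleach_a),
    )


def _frame_signals(truth: GroundTruth, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-frame time integrals of emission.

    Returns (bound, fret): per frame, the fraction of the frame spent in
    an emitting (bound, donor-alive) state, and the time integral of the
    true FRET level over that emitting time (divided by the frame
    length).  Energy transfer stops at the acceptor bleach; all emission
    stops at the donor bleach.
    """
    dt = config.frame_interval
    n = config.n_frames
    bound = np.zeros(n)
    fret = np.zeros(n)
    for label, start, end in truth.intervals:
        if label == "unbound" or end <= start:
            continue
        E = config.fret_states.get(label, 0.0)
        end_emit = min(end, truth.bleach_donor)
        end_fret = min(end_emit, truth.bleach_acceptor)
        f0 = int(start / dt)
        f1 = min(int(np.ceil(end_emit / dt)), n)
        for f in range(f0, f1):
            lo = max(start, f * dt)
            hi = min(end_emit, (f + 1) * dt)
            if hi > lo:
                bound[f] += (hi - lo) / dt
            hi_f = min(end_fret, (f + 1) * dt)
            if hi_f > lo:
                fret[f] += E * (hi_f - lo) / dt
    return bound, fret


def emit_intensities(truth: GroundTruth, config: SimConfig, rng: Optional[np.random.Generator] = None) -> IntensityTrace:
    """Render the state path into a noisy two-channel intensity trace.

    The donor dye rides on the binding partner, so emission exists only
    while bound: per frame the true FRET E of the occupying state
    partitions the total emission as acceptor = E*I_total and
    donor = (1-E)*I_total, exactly time-averaged over sub-frame state
    changes; unbound stretches show only background.  Both channels gain
    a constant background step at injection; after a donor bleach both
    channels fall to background, after an acceptor bleach transfer stops
    and the donor carries the full intensity.
    """
    if not np.isclose(truth.duration, config.duration):
        raise ValueError("truth and config disagree on duration")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_frames
    dt = config.frame_interval
    bound, fret = _frame_signals(truth, config)
    times = np.arange(n) * dt
    I = config.total_intensity
    donor = (bound - fret) * I
    acceptor = fret * I
    bg = config.background + config.injection_step * (times + dt / 2 >= config.injection_time)
    donor = donor + bg
    acceptor = acceptor + bg
    if config.noise_sd > 0:
        donor = donor + rng.normal(0.0, config.noise_sd, n)
        acceptor = acceptor + rng.normal(0.0, config.noise_sd, n)
    return IntensityTrace(dt, donor, acceptor, injection_frame=config.injection_frame)


def inject_pseudo_fret(
    trace: IntensityTrace,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[IntensityTrace, list]:
    """Overlay aggregate pseudo-FRET excursions on a trace.

    Excursion starts are Poisson-placed over the post-injection window at
    ``aggregate_rate`` per second with exponential durations; during an
    excursion the donor channel saturates at ``saturation_level`` and the
    acceptor receives bleed-through sized so the background-corrected
    FRET equals ~0.06.  Excursion statistics are independent of the
    molecule's binding kinetics.  Returns the modified trace and the list
    of (start_s, end_s) excursion windows.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if config.aggregate_rate == 0:
        return trace, []
    window = config.duration - config.injection_time
    count = rng.poisson(config.aggregate_rate * window)
    starts = np.sort(rng.uniform(config.injection_time, config.duration, count))
    durations = rng.exponential(config.aggregate_duration_mean, count)
    donor = trace.donor.copy()
    acceptor = trace.acceptor.copy()
    dt = trace.frame_interval
    times = np.arange(len(trace)) * dt
    p = PSEUDO_FRET
    excursions = []
    for s, d in zip(starts, durations):
        e = min(s + d, config.duration)
        excursions.append((float(s), float(e)))  # ground truth keeps sub-frame events
        sel = (times + dt / 2 >= s) & (times + dt / 2 < e)
        if not sel.any():
            continue
        bg = config.background + config.injection_step
        donor[sel] = bg + config.saturation_level
        acceptor[sel] = bg + config.saturation_level * p / (1.0 - p)
    out = IntensityTrace(dt, donor, acceptor, injection_frame=trace.injection_frame)
    return out, excursions


def simulate_trace(config: SimConfig, seed: Optional[int] = None) -> tuple[IntensityTrace, GroundTruth]:
    """Simulate one molecule end to end (path -> emission -> pseudo-FRET)."""
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    rng_path, rng_noise, rng_pseudo = (np.random.default_rng(c) for c in ss.spawn(3))
    truth = simulate_state_path(config, rng_path)
    trace = emit_intensities(truth, config, rng_noise)
    trace, excursions = inject_pseudo_fret(trace, config, rng_pseudo)
    truth.pseudo_excursions = excursions
    return trace, truth


def simulate_cohort(config: SimConfig, n_traces: int, seed: Optional[int] = None) -> list:
    """Simulate ``n_traces`` independent molecules; returns (trace, truth) pairs."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    out = []
    for child in root.spawn(n_traces):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(simulate_trace(config, seed=child_seed))
    return out
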