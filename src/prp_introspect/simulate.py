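"""Generative simulator for introspective dual-task (PRP) experiments.

One simulated trial has two layers:

1. **Objective layer** — a central-bottleneck reaction-time model.  Each
   task consists of a perceptual (P), central (C) and motor (M) stage.  P and
   M stages of the two tasks can overlap freely, but the two central stages
   are strictly serial: central processing of Task 2 cannot start before
   central processing of Task 1 has finished.  With stimulus onset asynchrony
   ``soa`` this gives (times relative to S1 onset)::

       RT1 = P1 + C1 + M1
       C2 starts at max(soa + P2, P1 + C1)
       RT2 = max(soa + P2, P1 + C1) + C2 + M2 - soa

   so RT2 grows as the SOA shrinks (the PRP effect) while RT1 is unaffected.

2. **Introspective layer** — a model of how the participant later recreates
   the trial on a timeline.  Three models are implemented:

   * ``veridical`` — markers at the true event times plus i.i.d. Gaussian
     noise; the null model for parameter-recovery tests.
   * ``conscious_bottleneck`` — S2 cannot be consciously perceived while
     Task 1 central processing is ongoing, so the reported S2 time is
     ``max(t_S2, t_S1 + P1 + C1)``; the other three markers are veridical.
     At short SOA this erases the SOA effect on the reported RT2.
   * ``memory`` — a working-memory account: markers are pulled toward an
     evenly spaced layout over the trial (order preserved, structure lost)
     and marker noise shrinks when the trial offers more time to encode and
     rehearse it — larger central gap, longer SOA — and is smaller overall
     when the trial events form an auditory sequence (VA order) than when a
     visual event interrupts it (AV order).

Datasets are emitted as tidy one-row-per-trial DataFrames with the on-disk
CSV schema used throughout the package (see :func:`simulate_dataset`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeline import TimelineReport, encode

__all__ = [
    "StageDurations",
    "MemoryModelParams",
    "SimConfig",
    "TrialEvents",
    "simulate_trial_rts",
    "simulate_dataset",
    "simulate_study",
    "introspect_veridical",
    "introspect_conscious_bottleneck",
    "introspect_memory",
    "TRIAL_COLUMNS",
]

#: Exact column order of the tidy trial CSV.
TRIAL_COLUMNS = [
    "participant",
    "experiment",
    "modality_order",
    "soa",
    "t_S1",
    "t_S2",
    "t_R1",
    "t_R2",
    "correct1",
    "correct2",
    "iS1_px",
    "iS2_px",
    "iR1_px",
    "iR2_px",
    "timeline_px",
    "trial_duration_ms",
    "total_estimate_ms",
]


@dataclass(frozen=True)
class StageDurations:
    """Durations (ms) of the six processing stages of one dual-task trial."""

    P1: float
    C1: float
    M1: float
    P2: float
    C2: float
    M2: float

    def __post_init__(self) -> None:
        for name in ("P1", "C1", "M1", "P2", "C2", "M2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"stage duration {name}={v} must be positive and finite")


@dataclass(frozen=True)
class TrialEvents:
    """Objective timing (ms from frame onset) and labels of one trial."""

    t_S1: float
    t_S2: float
    t_R1: float
    t_R2: float
    soa: float
    correct1: bool = True
    correct2: bool = True
    participant: str = "p00"
    trial_index: int = 0
    modality_order: str = "AV"


@dataclass(frozen=True)
class MemoryModelParams:
    """Parameters of the memory introspection model.

    ``sigma_base_*`` are marker-noise scales (ms) per modality order;
    ``beta_gap`` (per sqrt-ms) and ``beta_soa`` (per long-SOA trial) shrink
    the noise as rehearsal time grows; ``lambda_compress_*`` in [0, 1] pull
    the markers toward even spacing across the timeline.  Defaults encode
    the qualitative picture that an auditory event sequence (VA order) is
    easier to hold in memory: smaller base noise, less compression, and
    effectively weaker gap/SOA modulation (the modulation is multiplicative,
    so its absolute size scales with the base noise).
    """

    sigma_base_AV: float = 280.0
    sigma_base_VA: float = 90.0
    beta_gap: float = 0.03
    beta_soa: float = 0.35
    lambda_compress_AV: float = 0.20
    lambda_compress_VA: float = 0.08

    def __post_init__(self) -> None:
        if self.sigma_base_AV <= 0 or self.sigma_base_VA <= 0:
            raise ValueError("sigma_base values must be positive")
        for lam in (self.lambda_compress_AV, self.lambda_compress_VA):
            if not (0.0 <= lam <= 1.0):
                raise ValueError("lambda_compress values must lie in [0, 1]")

    def sigma_base(self, modality_order: str) -> float:
        return self.sigma_base_AV if modality_order == "AV" else self.sigma_base_VA

    def lambda_compress(self, modality_order: str) -> float:
        return (
            self.lambda_compress_AV
            if modality_order == "AV"
            else self.lambda_compress_VA
        )


# Default per-stage lognormal moments (mean, sd) in ms, chosen so that
# simulated RT1 falls around 500-700 ms and the PRP effect around 200-400 ms
# at soa 50 vs 1250 ms, with inter-response intervals rarely below 100 ms.
DEFAULT_STAGE_MEANS = {"P1": 90.0, "C1": 300.0, "M1": 150.0, "P2": 90.0, "C2": 250.0, "M2": 150.0}
DEFAULT_STAGE_SDS = {"P1": 20.0, "C1": 60.0, "M1": 30.0, "P2": 20.0, "C2": 50.0, "M2": 30.0}


@dataclass
class SimConfig:
    """Full description of one simulated experiment.

    The defaults mirror the study design: 16 participants, SOA levels
    50/1250 ms with 72 trials per SOA cell, 1000 ms fore- and endperiods,
    and contamination rates at the levels the screening stage is meant to
    absorb (per-sub-task error rate 0.062 gives ~12% trials with an error in
    either sub-task; grouped responses and unmoved-marker trials are rare).
    """

    n_participants: int = 16
    trials_per_cell: int = 72
    soa_levels: tuple = (50.0, 1250.0)
    modality_order: str = "AV"
    stage_means: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_MEANS))
    stage_sds: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_SDS))
    foreperiod: float = 1000.0
    endperiod: float = 1000.0
    error_rate: float = 0.062
    group_rate: float = 0.003
    unmoved_rate: float = 0.002
    lapse_rate: float = 0.02
    lapse_mean_ms: float = 300.0
    introspection_model: str = "memory"
    sigma: float = 60.0
    memory_params: MemoryModelParams = field(default_factory=MemoryModelParams)
    participant_speed_sd: float = 0.08
    participant_noise_sd: float = 0.25
    timeline_px: float = 1000.0
    experiment: str = "sim"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "group_rate", "unmoved_rate", "lapse_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} must be a probability in [0, 1]")
        self.soa_levels = tuple(float(s) for s in self.soa_levels)
        if list(self.soa_levels) != sorted(self.soa_levels):
            raise ValueError("soa_levels must be sorted ascending")
        if self.modality_order not in ("AV", "VA"):
            raise ValueError("modality_order must be 'AV' or 'VA'")
        if self.introspection_model not in ("veridical", "conscious_bottleneck", "memory"):
            raise ValueError(f"unknown introspection_model {self.introspection_model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["soa_levels"] = list(self.soa_levels)
        return d


def _lognormal_moments(mean: float, sd: float):
    """(mu, sigma) of a lognormal with the given arithmetic mean and sd."""
    var = np.log1p((sd / mean) ** 2)
    return np.log(mean) - var / 2.0, np.sqrt(var)


def _bottleneck_rts(P1, C1, M1, P2, C2, M2, soa):
    """Closed-form central-bottleneck RTs; broadcasts over arrays."""
    rt1 = P1 + C1 + M1
    c2_start = np.maximum(soa + P2, P1 + C1)  # relative to S1 onset
    rt2 = c2_start + C2 + M2 - soa
    return rt1, rt2


def simulate_trial_rts(
    stages: StageDurations, soa: float, foreperiod: float = 1000.0
) -> TrialEvents:
    """Objective event times of one trial under the central bottleneck model.

    ``t_S1`` equals the foreperiod; ``t_S2 = t_S1 + soa``; the responses
    follow from the stage durations with Task 2 central processing deferred
    until Task 1 central processing has finished.
    """
    rt1, rt2 = _bottleneck_rts(
        stages.P1, stages.C1, stages.M1, stages.P2, stages.C2, stages.M2, soa
    )
    t_s1 = float(foreperiod)
    return TrialEvents(
        t_S1=t_s1,
        t_S2=t_s1 + soa,
        t_R1=t_s1 + float(rt1),
        t_R2=t_s1 + soa + float(rt2),
        soa=float(soa),
    )


def _trial_duration(t_r1, t_r2, endperiod):
    """Frame duration: foreperiod is already inside the event times."""
    return np.maximum(t_r1, t_r2) + endperiod


def _even_targets(times: np.ndarray, duration: np.ndarray) -> np.ndarray:
    """Evenly spaced marker times over the trial, in true temporal order.

    ``times`` is (n, 4); the k-th event in temporal order is mapped to
    ``duration * (k + 1) / 5`` so that even a fully compressed report keeps
    the correct event order but a flat, structureless spacing.
    """
    order = np.argsort(np.argsort(times, axis=1), axis=1)  # temporal ranks
    return duration[:, None] * (order + 1) / 5.0


def _memory_sigma(params: MemoryModelParams, modality_order: str, gap_ms, is_long):
    """Marker noise scale (ms) of the memory model."""
    return params.sigma_base(modality_order) * np.exp(
        -params.beta_gap * np.sqrt(np.asarray(gap_ms, dtype=float))
        - params.beta_soa * np.asarray(is_long, dtype=float)
    )


def _report_from_times(marker_ms: np.ndarray, duration: float, timeline_px: float) -> TimelineReport:
    s1, s2, r1, r2 = (encode(t, timeline_px, duration, clip=True) for t in marker_ms)
    return TimelineReport(
        iS1_px=s1,
        iS2_px=s2,
        iR1_px=r1,
        iR2_px=r2,
        timeline_px=timeline_px,
        trial_duration_ms=duration,
    )


def introspect_veridical(
    events: TrialEvents,
    sigma: float,
    rng: np.random.Generator,
    timeline_px: float = 1000.0,
    endperiod: float = 1000.0,
) -> TimelineReport:
    """Null introspection model: true event times plus i.i.d. noise."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    times = np.array([events.t_S1, events.t_S2, events.t_R1, events.t_R2])
    duration = float(_trial_duration(events.t_R1, events.t_R2, endperiod))
    noisy = times + rng.normal(0.0, sigma, size=4) if sigma > 0 else times
    return _report_from_times(np.clip(noisy, 0.0, duration), duration, timeline_px)


def introspect_conscious_bottleneck(
    events: TrialEvents,
    stages: StageDurations,
    sigma: float,
    rng: np.random.Generator,
    timeline_px: float = 1000.0,
    endperiod: float = 1000.0,
) -> TimelineReport:
    """Conscious-bottleneck introspection: S2 perceived no earlier than the
    end of Task 1 central processing (``t_S1 + P1 + C1``); other markers
    veridical.  ``stages`` must be the same draw that produced ``events``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    perceived_s2 = max(events.t_S2, events.t_S1 + stages.P1 + stages.C1)
    times = np.array([events.t_S1, perceived_s2, events.t_R1, events.t_R2])
    duration = float(_trial_duration(events.t_R1, events.t_R2, endperiod))
    noisy = times + rng.normal(0.0, sigma, size=4) if sigma > 0 else times
    return _report_from_times(np.clip(noisy, 0.0, duration), duration, timeline_px)


def introspect_memory(
    events: TrialEvents,
    params: MemoryModelParams,
    modality_order: str,
    rng: np.random.Generator,
    timeline_px: float = 1000.0,
    endperiod: float = 1000.0,
    long_soa_ms: float = 1000.0,
) -> TimelineReport:
    """Memory introspection model (see module docstring).

    Marker time = (1-λ)·true time + λ·evenly spaced position, plus Gaussian
    noise whose scale shrinks with the central gap and for long-SOA trials.
    """
    times = np.array([[events.t_S1, events.t_S2, events.t_R1, events.t_R2]])
    duration = np.asarray([_trial_duration(events.t_R1, events.t_R2, endperiod)])
    gap = abs(events.t_S2 - events.t_R1)
    sig = float(_memory_sigma(params, modality_order, gap, events.soa >= long_soa_ms))
    lam = params.lambda_compress(modality_order)
    mean = (1.0 - lam) * times + lam * _even_targets(times, duration)
    noisy = mean[0] + rng.normal(0.0, sig, size=4)
    return _report_from_times(
        np.clip(noisy, 0.0, duration[0]), float(duration[0]), timeline_px
    )


def _simulate_participant(
    cfg: SimConfig, pid: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Vectorised simulation of one participant's trial table."""
    n_cells = len(cfg.soa_levels)
    n = cfg.trials_per_cell * n_cells
    soa = np.repeat(np.asarray(cfg.soa_levels, dtype=float), cfg.trials_per_cell)

    # stable individual differences: overall speed and introspective noise
    speed = float(np.exp(rng.normal(0.0, cfg.participant_speed_sd)))
    noise_fac = float(np.exp(rng.normal(0.0, cfg.participant_noise_sd)))

    stages = {}
    for name in ("P1", "C1", "M1", "P2", "C2", "M2"):
        mu, s = _lognormal_moments(cfg.stage_means[name] * speed, cfg.stage_sds[name])
        stages[name] = rng.lognormal(mu, s, size=n)

    # occasional attentional lapses: an exponential delay added to a central
    # stage, producing the slow right tail real RT distributions show
    for name in ("C1", "C2"):
        lapse = rng.random(n) < cfg.lapse_rate
        stages[name] = stages[name] + lapse * rng.exponential(cfg.lapse_mean_ms, size=n)

    rt1, rt2 = _bottleneck_rts(
        stages["P1"], stages["C1"], stages["M1"],
        stages["P2"], stages["C2"], stages["M2"], soa,
    )
    t_s1 = np.full(n, cfg.foreperiod)
    t_s2 = t_s1 + soa
    t_r1 = t_s1 + rt1
    t_r2 = t_s2 + rt2

    # contamination: grouped responses (inter-response interval < 100 ms,
    # possibly reversed), then independent per-sub-task errors
    grouped = rng.random(n) < cfg.group_rate
    t_r2 = np.where(grouped, t_r1 + rng.uniform(-80.0, 99.0, size=n), t_r2)
    correct1 = rng.random(n) >= cfg.error_rate
    correct2 = rng.random(n) >= cfg.error_rate

    duration = _trial_duration(t_r1, t_r2, cfg.endperiod)
    times = np.column_stack([t_s1, t_s2, t_r1, t_r2])

    if cfg.introspection_model == "veridical":
        marker_ms = times + rng.normal(0.0, cfg.sigma * noise_fac, size=times.shape)
    elif cfg.introspection_model == "conscious_bottleneck":
        perceived = times.copy()
        perceived[:, 1] = np.maximum(t_s2, t_s1 + stages["P1"] + stages["C1"])
        marker_ms = perceived + rng.normal(0.0, cfg.sigma * noise_fac, size=times.shape)
    else:  # memory
        p = cfg.memory_params
        gap = np.abs(t_s2 - t_r1)
        is_long = soa >= 1000.0 if len(cfg.soa_levels) > 1 else np.zeros(n, bool)
        sig = _memory_sigma(p, cfg.modality_order, gap, is_long) * noise_fac
        lam = p.lambda_compress(cfg.modality_order)
        mean = (1.0 - lam) * times + lam * _even_targets(times, duration)
        marker_ms = mean + rng.normal(0.0, 1.0, size=times.shape) * sig[:, None]

    marker_ms = np.clip(marker_ms, 0.0, duration[:, None])
    marker_px = marker_ms / duration[:, None] * cfg.timeline_px

    unmoved = rng.random(n) < cfg.unmoved_rate
    marker_px[unmoved] = cfg.timeline_px / 2.0

    total_estimate = np.clip(
        duration * np.exp(rng.normal(0.0, 0.2, size=n)), 2000.0, 6000.0
    )

    return pd.DataFrame(
        {
            "participant": pid,
            "experiment": cfg.experiment,
            "modality_order": cfg.modality_order,
            "soa": soa,
            "t_S1": t_s1,
            "t_S2": t_s2,
            "t_R1": t_r1,
            "t_R2": t_r2,
            "correct1": correct1,
            "correct2": correct2,
            "iS1_px": marker_px[:, 0],
            "iS2_px": marker_px[:, 1],
            "iR1_px": marker_px[:, 2],
            "iR2_px": marker_px[:, 3],
            "timeline_px": cfg.timeline_px,
            "trial_duration_ms": duration,
            "total_estimate_ms": total_estimate,
        }
    )


def simulate_dataset(config: SimConfig) -> pd.DataFrame:
    """Simulate a complete experiment as a tidy one-row-per-trial table.

    The design is balanced over ``soa_levels x trials_per_cell`` within each
    participant, and the output is byte-identical for a given
    ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    frames = [
        _simulate_participant(config, f"{config.experiment}_p{i:02d}", rng)
        for i in range(config.n_participants)
    ]
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]


def simulate_study(
    n_av: int = 2,
    n_va: int = 3,
    seed: int = 0,
    introspection_model: str = "memory",
    **overrides,
) -> pd.DataFrame:
    """Simulate a multi-experiment study (default: 2 AV + 3 VA experiments,
    mirroring the five-experiment single-trial dataset) and concatenate the
    tables.  Each experiment gets an independent seed derived from ``seed``."""
    seq = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in seq.generate_state(n_av + n_va)]
    frames = []
    labels = [("AV", f"sim_av{i+1}") for i in range(n_av)] + [
        ("VA", f"sim_va{i+1}") for i in range(n_va)
    ]
    for (order, label), s in zip(labels, seeds):
        cfg = SimConfig(
            modality_order=order,
            experiment=label,
            rng_seed=s,
            introspection_model=introspection_model,
            **overrides,
        )
        frames.append(simulate_dataset(cfg))
    return pd.concat(frames, ignore_index=True)
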