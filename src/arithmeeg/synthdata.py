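"""Synthetic multi-participant EEG + behavior generator.

Emulates the statistical structure the downstream analysis assumes: 31
participants solving 80 arithmetic problems each while 32-channel EEG is
recorded at 512 Hz.  Per trial the generator injects band-limited
oscillations whose amplitude steps from a baseline level ``a_B`` (during
fixation) to an activity level ``a_A`` (while the problem is on screen),
with the configured target ERD/ERS equal to ``(a_A^2 - a_B^2)/a_B^2 * 100``.
Background activity is 1/f ("pink") noise; ocular artifacts are stereotyped
biphasic blink transients projected dominantly onto frontal channels.
Response times are inverse-Gaussian, correctness is Bernoulli, and verbal
strategy reports agree with the size-based expectation up to configurable
misreport/"unknown" rates.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import stats as sps

from .erders import BANDS, DEFAULT_ROI_MAP
from .stimuli import (
    ArithmeticProblem,
    Operation,
    SizeClass,
    load_problem_set,
    problems_by_block,
)

__all__ = [
    "BIOSEMI32",
    "EffectSpec",
    "SimulationConfig",
    "TrialEvent",
    "Recording",
    "SimulatedParticipant",
    "generate_behavior",
    "simulate_participant",
    "simulate_dataset",
    "simulate_null_erders",
    "REFERENCE_STRATEGY_CROSSTAB",
]

# 32-channel extended 10-20 montage (BioSemi ordering)
BIOSEMI32: tuple[str, ...] = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)

STRATEGIES = ("retrieve", "procedure")
REPORTS = ("retrieve", "procedure", "unknown")

#: Size-by-report trial counts (rows: large, small; columns: procedure,
#: retrieval, unknown) of the study dataset this generator emulates.  The
#: default misreport and unknown rates below are calibrated to this table.
REFERENCE_STRATEGY_CROSSTAB = np.array(
    [[1080, 144, 16], [148, 1076, 16]]
)


def size_expected_strategy(size: SizeClass) -> str:
    """Design expectation: small problems -> retrieval, large -> procedure."""
    return "retrieve" if size is SizeClass.SMALL else "procedure"


@dataclass(frozen=True)
class EffectSpec:
    """A target ERD/ERS (%) for a band, optionally restricted by condition.

    ``None`` fields match every level; when several specs match, the most
    specific one (most non-None fields) wins.
    """

    band: str
    erders: float
    strategy: str | None = None
    operation: str | None = None
    roi: str | None = None
    hemisphere: str | None = None

    def __post_init__(self) -> None:
        if self.erders <= -100.0:
            raise ValueError(
                f"ERD target {self.erders}% implies negative power (<= -100%)"
            )

    def matches(self, strategy: str, operation: str, roi: str, hemisphere: str) -> bool:
        return (
            (self.strategy is None or self.strategy == strategy)
            and (self.operation is None or self.operation == operation)
            and (self.roi is None or self.roi == roi)
            and (self.hemisphere is None or self.hemisphere == hemisphere)
        )

    @property
    def specificity(self) -> int:
        return sum(
            f is not None
            for f in (self.strategy, self.operation, self.roi, self.hemisphere)
        )


def _default_band_effects() -> tuple[EffectSpec, ...]:
    # Condition targets motivated by the strategy-dependent oscillatory
    # patterns the paradigm is designed to elicit: stronger theta ERS for
    # retrieval, stronger alpha ERD for procedures.
    return (
        EffectSpec("theta", 22.0, strategy="retrieve"),
        EffectSpec("theta", 11.0, strategy="procedure"),
        EffectSpec("lower_alpha", 3.5, strategy="retrieve"),
        EffectSpec("lower_alpha", -1.8, strategy="procedure"),
        EffectSpec("upper_alpha", -8.8, strategy="retrieve"),
        EffectSpec("upper_alpha", -11.5, strategy="procedure"),
    )


def _default_rt_params() -> dict[tuple[str, str], tuple[float, float]]:
    # (mean, shape) of the inverse-Gaussian RT distribution per condition,
    # seconds.  Means follow the per-condition RT summary of the emulated
    # study; shapes are chosen to give realistic right skew (var = mu^3/shape).
    return {
        ("retrieve", "subtraction"): (2.07, 8.0),
        ("retrieve", "multiplication"): (2.18, 8.0),
        ("procedure", "subtraction"): (6.44, 10.0),
        ("procedure", "multiplication"): (10.05, 12.0),
    }


def _default_acc_probs() -> dict[tuple[str, str], float]:
    return {
        ("retrieve", "subtraction"): 0.980,
        ("retrieve", "multiplication"): 0.978,
        ("procedure", "subtraction"): 0.910,
        ("procedure", "multiplication"): 0.915,
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults reproduce the emulated study's design: 31 participants, 512 Hz,
    32-channel extended 10-20 montage, inverse-Gaussian RTs and binomial
    correctness with the per-condition parameters of the study's behavioral
    summary, and strategy misreport/unknown rates calibrated to its printed
    size-by-report cross-tabulation (292/2480 and 32/2480).
    """

    n_participants: int = 31
    sampling_rate: float = 512.0
    montage: tuple[str, ...] = BIOSEMI32
    band_effects: tuple[EffectSpec, ...] = field(default_factory=_default_band_effects)
    rt_params: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_rt_params
    )
    acc_probs: dict[tuple[str, str], float] = field(default_factory=_default_acc_probs)
    misreport_rate: float = 292 / 2480
    unknown_rate: float = 32 / 2480
    blink_rate: float = 10.0  # blinks per minute
    blink_amplitude: float = 250.0  # blink peak at Fp1/Fp2, uV
    n_ocular_sources: int = 2  # 1-3: blinks, saccades, slow drift
    osc_amplitude: float = 40.0  # baseline oscillation amplitude a_B, uV
    noise_sd: float = 10.0  # broadband pink-noise SD per channel, uV
    noise_exponent: float = 1.0  # 1/f power slope
    fixation_s: float = 1.5
    report_s: float = 2.0  # verbal strategy-report phase (untimed in the task)
    blank_s: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("misreport_rate", "unknown_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.misreport_rate + self.unknown_rate > 1:
            raise ValueError("misreport_rate + unknown_rate > 1")
        for cond, (mean, shape) in self.rt_params.items():
            if mean <= 0 or shape <= 0:
                raise ValueError(f"rt_params[{cond}] must be positive")
        for cond, p in self.acc_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"acc_probs[{cond}] must be in [0, 1]")
        if not 1 <= self.n_ocular_sources <= 3:
            raise ValueError("n_ocular_sources must be in 1..3")
        highest_edge = max(b.high for b in BANDS.values())
        if self.sampling_rate <= 2 * highest_edge:
            raise ValueError("sampling_rate must exceed twice the highest band edge")

    def effect_for(
        self, band: str, strategy: str, operation: str, roi: str, hemisphere: str
    ) -> float:
        """Target ERD/ERS (%) for a condition cell; 0 when no spec matches."""
        matching = [
            s
            for s in self.band_effects
            if s.band == band and s.matches(strategy, operation, roi, hemisphere)
        ]
        if not matching:
            return 0.0
        return max(matching, key=lambda s: s.specificity).erders


@dataclass
class TrialEvent:
    """One trial: problem, timing, behavior, and verbal strategy report."""

    participant: str
    problem: ArithmeticProblem
    onset: float  # problem onset, seconds from recording start
    rt: float  # response time, seconds
    correct: bool
    report: str  # retrieve | procedure | unknown

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError("rt must be positive")
        if self.report not in REPORTS:
            raise ValueError(f"unknown report {self.report!r}")


@dataclass
class Recording:
    """Continuous multi-channel EEG in microvolts.

    ``samples`` has one row per montage channel; ``artifact_mask`` holds
    half-open (start, end) time intervals in seconds.
    """

    samples: np.ndarray
    channels: tuple[str, ...]
    sfreq: float
    bad_channels: set[str] = field(default_factory=set)
    artifact_mask: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.samples.shape[0] != len(self.channels):
            raise ValueError("one row per channel required")
        for t0, t1 in self.artifact_mask:
            if not 0 <= t0 < t1 <= self.duration + 1e-9:
                raise ValueError(f"mask interval ({t0}, {t1}) outside recording")

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.sfreq

    @property
    def good_channels(self) -> list[str]:
        return [ch for ch in self.channels if ch not in self.bad_channels]

    def copy(self) -> "Recording":
        return Recording(
            self.samples.copy(),
            self.channels,
            self.sfreq,
            set(self.bad_channels),
            list(self.artifact_mask),
        )


@dataclass
class GroundTruth:
    """Generator-internal signals for validation tests."""

    clean: np.ndarray  # noise + oscillations, no ocular artifacts
    ocular: np.ndarray  # ocular contribution alone
    blink_times: list[float]  # blink peak times, seconds


@dataclass
class SimulatedParticipant:
    participant: str
    recording: Recording
    events: list[TrialEvent]
    ground_truth: GroundTruth | None = None


def generate_behavior(
    condition: tuple[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[float, bool, str]:
    """Draw (rt, correct, report) for one trial of a given condition.

    ``condition`` is the size-based (strategy, operation) pair.  The report
    equals the size-consistent strategy with probability
    ``1 - misreport_rate - unknown_rate``.
    """
    strategy, operation = condition
    mean, shape = config.rt_params[condition]
    # scipy's invgauss(mu, scale): mean = mu * scale; standard IG(mean, shape)
    # corresponds to mu = mean/shape, scale = shape.
    rt = float(sps.invgauss.rvs(mean / shape, scale=shape, random_state=rng))
    correct = bool(rng.random() < config.acc_probs[condition])
    u = rng.random()
    if u < config.unknown_rate:
        report = "unknown"
    elif u < config.unknown_rate + config.misreport_rate:
        report = "procedure" if strategy == "retrieve" else "retrieve"
    else:
        report = strategy
    return rt, correct, report


# ---------------------------------------------------------------------------
# signal building blocks


def _pink_noise(
    n_channels: int, n_times: int, sfreq: float, sd: float, exponent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """1/f^exponent (power) noise, flattened below 0.5 Hz, scaled to sd."""
    white = rng.standard_normal((n_channels, n_times))
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    f_eff = np.maximum(freqs[nz], 0.5)
    shaping[nz] = f_eff ** (-exponent / 2.0)
    shaping[0] = 0.0
    spectrum = np.fft.rfft(white, axis=1) * shaping
    noise = np.fft.irfft(spectrum, n=n_times, axis=1)
    noise *= sd / noise.std(axis=1, keepdims=True)
    return noise


def _blink_waveform(sfreq: float) -> np.ndarray:
    """Stereotyped ~300 ms biphasic blink transient (unit peak).

    Main lobe FWHM ~150 ms with a shallow undershoot, putting most of its
    energy below 3 Hz as for real blinks.
    """
    t = np.arange(int(0.55 * sfreq)) / sfreq
    w = np.exp(-((t - 0.18) ** 2) / (2 * 0.065**2)) - 0.3 * np.exp(
        -((t - 0.33) ** 2) / (2 * 0.09**2)
    )
    return w / np.abs(w).max()


def _ocular_topographies(channels: Sequence[str]) -> np.ndarray:
    """Fixed mixing vectors for up to three ocular sources (rows)."""
    blink = {
        "Fp1": 1.0, "Fp2": 1.0, "AF3": 0.75, "AF4": 0.75, "F7": 0.4,
        "F8": 0.4, "F3": 0.45, "F4": 0.45, "Fz": 0.5, "FC1": 0.15,
        "FC2": 0.15, "FC5": 0.12, "FC6": 0.12,
    }
    saccade = {  # horizontal eye movement: left/right antisymmetric
        "F7": 1.0, "F8": -1.0, "Fp1": 0.45, "Fp2": -0.45, "AF3": 0.35,
        "AF4": -0.35, "F3": 0.25, "F4": -0.25, "T7": 0.3, "T8": -0.3,
    }
    drift = {"Fp1": 0.6, "Fp2": 0.6, "AF3": 0.5, "AF4": 0.5, "Fz": 0.35}
    topo = np.zeros((3, len(channels)))
    for row, spec in enumerate((blink, saccade, drift)):
        for ch, w in spec.items():
            if ch in channels:
                topo[row, list(channels).index(ch)] = w
        topo[row] += 0.02  # faint projection everywhere (volume conduction)
    return topo


def _trial_order(
    problems: Sequence[ArithmeticProblem], seed: int, participant_index: int
) -> list[ArithmeticProblem]:
    """Fixed pseudo-random order within blocks (same for all participants);
    block order counter-balanced (ABCD vs CDAB) across participants."""
    by_block = problems_by_block(problems)
    order_rng = np.random.default_rng([seed, 7919])
    within = {b: order_rng.permutation(len(ps)) for b, ps in by_block.items()}
    blocks = ("A", "B", "C", "D") if participant_index % 2 == 0 else ("C", "D", "A", "B")
    ordered: list[ArithmeticProblem] = []
    for b in blocks:
        ordered.extend(by_block[b][i] for i in within[b])
    return ordered


_LEAD_IN_S = 4.0  # quiet head/tail so baseline/filter edges stay in-bounds
_OSC_PRE_S = 2.5  # oscillation starts this long before problem onset
_OSC_POST_S = 0.5  # and outlasts the response by this much


def simulate_participant(
    config: SimulationConfig,
    problems: Sequence[ArithmeticProblem],
    participant_index: int,
    *,
    return_ground_truth: bool = False,
) -> SimulatedParticipant:
    """Simulate one participant: continuous EEG plus the trial-event table."""
    pid = f"p{participant_index + 1:02d}"
    rng = np.random.default_rng([config.seed, 1000 + participant_index])
    sfreq = config.sampling_rate
    channels = config.montage
    n_ch = len(channels)

    ordered = _trial_order(problems, config.seed, participant_index)

    # behavior + timeline
    events: list[TrialEvent] = []
    t = _LEAD_IN_S + config.fixation_s
    for problem in ordered:
        strategy = size_expected_strategy(problem.size)
        condition = (strategy, problem.operation.value)
        rt, correct, report = generate_behavior(condition, config, rng)
        events.append(TrialEvent(pid, problem, onset=t, rt=rt, correct=correct, report=report))
        t += rt + config.report_s + config.blank_s + config.fixation_s
    duration = t + _LEAD_IN_S
    n_times = int(round(duration * sfreq))

    data = _pink_noise(n_ch, n_times, sfreq, config.noise_sd, config.noise_exponent, rng)

    # per-trial band-limited oscillations on ROI channels
    roi_of_channel: dict[str, tuple[str, str]] = {}
    for key, chans in DEFAULT_ROI_MAP.items():
        for ch in chans:
            roi_of_channel[ch] = key
    band_centers = {"theta": 4.5, "lower_alpha": 9.0, "upper_alpha": 11.5}
    time = np.arange(n_times) / sfreq
    for ev in events:
        strategy = size_expected_strategy(ev.problem.size)
        operation = ev.problem.operation.value
        i0 = int(round((ev.onset - _OSC_PRE_S) * sfreq))
        i_on = int(round(ev.onset * sfreq))
        i1 = min(int(round((ev.onset + ev.rt + _OSC_POST_S) * sfreq)), n_times)
        seg_t = time[i0:i1]
        for band, f0 in band_centers.items():
            a_b = config.osc_amplitude
            for ci, ch in enumerate(channels):
                key = roi_of_channel.get(ch)
                if key is None:
                    continue  # midline channels carry no injected oscillation
                roi, hemi = key
                target = config.effect_for(band, strategy, operation, roi, hemi)
                a_a = a_b * np.sqrt(1.0 + target / 100.0)
                amp = np.where(seg_t < ev.onset, a_b, a_a)
                phase = rng.uniform(0, 2 * np.pi)
                data[ci, i0:i1] += amp * np.sin(2 * np.pi * f0 * seg_t + phase)

    clean = data.copy() if return_ground_truth else None

    # ocular artifacts
    ocular = np.zeros_like(data)
    topo = _ocular_topographies(channels)[: config.n_ocular_sources]
    blink_times: list[float] = []
    if config.blink_rate > 0:
        wave = _blink_waveform(sfreq)
        n_blinks = rng.poisson(config.blink_rate / 60.0 * duration)
        starts = np.sort(rng.uniform(0, duration - 0.6, size=n_blinks))
        blink_src = np.zeros(n_times)
        for s in starts:
            i0 = int(round(s * sfreq))
            blink_src[i0 : i0 + wave.size] += wave
            blink_times.append(s + 0.18)
        ocular += config.blink_amplitude * np.outer(topo[0], blink_src)
        if config.n_ocular_sources >= 2:
            # horizontal saccades: smoothed random telegraph signal
            n_sacc = max(int(duration / 2.0), 1)
            levels = rng.choice([-1.0, 0.0, 0.0, 1.0], size=n_sacc)
            sacc = np.repeat(levels, int(np.ceil(n_times / n_sacc)))[:n_times]
            k = int(0.15 * sfreq)
            sacc = np.convolve(sacc, np.ones(k) / k, mode="same")
            ocular += 40.0 * np.outer(topo[1], sacc)
        if config.n_ocular_sources >= 3:
            drift = _pink_noise(1, n_times, sfreq, 1.0, 3.0, rng)[0]
            ocular += 20.0 * np.outer(topo[2], drift)
        data += ocular

    recording = Recording(data, tuple(channels), sfreq)
    gt = (
        GroundTruth(clean=clean, ocular=ocular, blink_times=blink_times)
        if return_ground_truth
        else None
    )
    return SimulatedParticipant(pid, recording, events, gt)


def simulate_dataset(
    config: SimulationConfig,
    problems: Sequence[ArithmeticProblem] | None = None,
    *,
    return_ground_truth: bool = False,
) -> Iterator[SimulatedParticipant]:
    """Yield simulated participants one at a time (recordings are large)."""
    if problems is None:
        problems = load_problem_set()
    for i in range(config.n_participants):
        yield simulate_participant(
            config, problems, i, return_ground_truth=return_ground_truth
        )


def simulate_null_erders(
    n_participants: int,
    rng: np.random.Generator,
    *,
    sd_participant: float = 8.0,
    sd_resid: float = 15.0,
    band: str = "theta",
) -> "pd.DataFrame":
    """ERD/ERS record table with no condition effects (calibration nulls).

    Each record is participant intercept + i.i.d. noise over the full
    participant x strategy x operation x ROI x hemisphere factorial.
    """
    import pandas as pd

    rows = []
    intercepts = rng.normal(0.0, sd_participant, size=n_participants)
    from .erders import HEMISPHERES, ROIS

    for i in range(n_participants):
        for strategy in STRATEGIES:
            for operation in ("subtraction", "multiplication"):
                for roi in ROIS:
                    for hemi in HEMISPHERES:
                        rows.append(
                            {
                                "participant": f"p{i + 1:02d}",
                                "strategy": strategy,
                                "operation": operation,
                                "band": band,
                                "roi": roi,
                                "hemisphere": hemi,
                                "value": intercepts[i] + rng.normal(0.0, sd_resid),
                                "n_trials": 0,
                            }
                        )
    return pd.DataFrame(rows)
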