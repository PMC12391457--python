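"""Interaction-session simulator with injectable group effects.

The simulator emulates the assessment battery's raw event streams.
Motor degradation in disease-labelled participants is modelled as

* an inflated pointer-noise standard deviation (bradykinesia-adjacent
  loss of fine control), via ``pd_deviation_scale``;
* a sinusoidal tremor component (default 5 Hz) added to the tracing
  offset, via ``pd_tremor_amp``;
* slowed timing, via ``pd_time_scale`` multiplying trace durations and
  key/click response times; and
* an elevated false-key-press probability.

Hardware heterogeneity enters through per-device additive response
latency and multiplicative pointer-noise scaling, plus an optional
per-device attenuation of the disease effects themselves
(``device_pd_signal_scale``) used to inject a device that masks the
disease signal.  A non-dominant-hand penalty inflates pointer noise for
participants whose dominant hand differs from the hand the pointing
device is configured for (``task_hand``, default right).

Pointer noise follows a stationary AR(1) Gaussian process
(autocorrelation 0.9 per sample at 60 Hz), applied vertically for the
straight/sine paths and radially for the spiral, so traces are smooth
rather than white-noise jittery.

Between-subject heterogeneity — without which any group shift, however
small, would be perfectly separable from near-noise-free session
averages — is modelled as lognormal person-level multipliers on
baseline pointer noise and timing, drawn once per participant per
session (mean 1, coefficients of variation ``subject_noise_cv`` and
``subject_time_cv``).  Person effects are independent of every group
attribute, so they preserve group exchangeability.

With all multipliers at 1 and all additive terms at 0
(:meth:`EffectConfig.null`) the generated data are exchangeable across
disease status and every group attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

from .cohort import Participant
from .session import (
    ClickTaskRecord,
    KeyTaskRecord,
    LEVELS,
    MemoryTaskRecord,
    MouseTrace,
    PATH_KINDS,
    KEY_TASK_KINDS,
    Session,
)

DEFAULT_SCREEN = (1280, 800)

PROMPTS_PER_LEVEL = 10
CLICK_TARGETS = 10
MEMORY_CAP = 10
MEMORY_START = 3

_KEY_ALPHABET = list("asdfghjkl")

# Base trace duration in seconds per path kind; levels lengthen them.
_BASE_DURATION_S = {"straight": 2.5, "sine": 3.0, "spiral": 4.0}
_LEVEL_FACTOR = {1: 1.0, 2: 1.25, 3: 1.5}


class EffectConfigError(ValueError):
    """An effect configuration outside its valid domain."""


@dataclass(frozen=True)
class SubjectEffects:
    """Person-level baseline multipliers, mean 1 across a cohort."""
    noise: float = 1.0
    time: float = 1.0


def _unit_device_map() -> Dict[str, float]:
    return {"Windows": 1.0, "Mac": 1.0, "Linux": 1.0}


def _zero_device_map() -> Dict[str, float]:
    return {"Windows": 0.0, "Mac": 0.0, "Linux": 0.0}


@dataclass
class EffectConfig:
    """Injectable effect sizes for the session simulator.

    Defaults carry a moderate disease signal and *no* group effects:
    device and handedness enter only when explicitly configured.
    """

    # Disease effects
    pd_deviation_scale: float = 1.8  # multiplier on tracing-noise s.d.
    pd_tremor_amp: float = 6.0      # px
    pd_tremor_freq: float = 5.0     # Hz
    pd_time_scale: float = 1.3      # multiplier on durations / RTs
    pd_false_press_boost: float = 0.06
    pd_memory_penalty: float = 1.0  # reduction of digit-span capacity

    # Hardware / handedness effects
    device_latency_ms: Dict[str, float] = field(default_factory=_zero_device_map)
    device_noise_scale: Dict[str, float] = field(default_factory=_unit_device_map)
    device_pd_signal_scale: Dict[str, float] = field(default_factory=_unit_device_map)
    hand_nondominant_penalty: float = 1.0
    task_hand: str = "right"

    # Baselines (group-independent)
    base_noise_sd: float = 4.0      # px
    base_rt_ms: float = 450.0
    rt_noise_sd_ms: float = 60.0
    base_false_press_rate: float = 0.02
    memory_capacity: float = 7.0

    # Between-subject variability (coefficient of variation of the
    # lognormal person-level baseline multipliers; group-independent)
    subject_noise_cv: float = 0.25
    subject_time_cv: float = 0.15

    # Sampling model
    sample_rate_hz: float = 60.0
    ar_coeff: float = 0.9

    def validate(self) -> None:
        multipliers = {
            "pd_deviation_scale": self.pd_deviation_scale,
            "pd_time_scale": self.pd_time_scale,
            "hand_nondominant_penalty": self.hand_nondominant_penalty,
            **{f"device_noise_scale[{k}]": v for k, v in self.device_noise_scale.items()},
            **{f"device_pd_signal_scale[{k}]": v
               for k, v in self.device_pd_signal_scale.items()},
        }
        for name, v in multipliers.items():
            if v < 0:
                raise EffectConfigError(f"{name} must be >= 0, got {v}")
        for name, v in (
            ("pd_tremor_amp", self.pd_tremor_amp),
            ("pd_tremor_freq", self.pd_tremor_freq),
            ("base_noise_sd", self.base_noise_sd),
            ("rt_noise_sd_ms", self.rt_noise_sd_ms),
        ):
            if v < 0:
                raise EffectConfigError(f"{name} must be >= 0, got {v}")
        if self.base_rt_ms <= 0 or self.sample_rate_hz <= 0:
            raise EffectConfigError("base_rt_ms and sample_rate_hz must be positive")
        if not 0 <= self.ar_coeff < 1:
            raise EffectConfigError("ar_coeff must be in [0, 1)")
        if not 0 <= self.base_false_press_rate <= 1:
            raise EffectConfigError("base_false_press_rate must be in [0, 1]")

    @classmethod
    def null(cls) -> "EffectConfig":
        """All multipliers 1, all additive effects 0: fully group- and
        disease-exchangeable data."""
        return cls(
            pd_deviation_scale=1.0,
            pd_tremor_amp=0.0,
            pd_time_scale=1.0,
            pd_false_press_boost=0.0,
            pd_memory_penalty=0.0,
        )

    @classmethod
    def group_null(cls) -> "EffectConfig":
        """Disease effects at their defaults, every device/hand effect
        off: data informative about disease but exchangeable across
        groups conditional on label."""
        return cls()

    def with_device_suppression(self, device: str, scale: float) -> "EffectConfig":
        """Copy with the disease signal attenuated on one device."""
        m = dict(self.device_pd_signal_scale)
        m[device] = scale
        return replace(self, device_pd_signal_scale=m)

    def draw_subject(self, rng: np.random.Generator) -> "SubjectEffects":
        """Person-level baseline multipliers (lognormal, mean 1)."""
        def draw(cv: float) -> float:
            if cv <= 0:
                return 1.0
            sigma = np.sqrt(np.log1p(cv * cv))
            return float(np.exp(rng.normal(-sigma * sigma / 2.0, sigma)))

        return SubjectEffects(noise=draw(self.subject_noise_cv),
                              time=draw(self.subject_time_cv))

    # -- per-participant effective parameters ---------------------------------

    def _pd_signal(self, participant: Participant) -> float:
        if not participant.is_pd:
            return 0.0
        return self.device_pd_signal_scale.get(participant.device, 1.0)

    def noise_sd(self, participant: Participant,
                 subject: "SubjectEffects | None" = None) -> float:
        sig = self._pd_signal(participant)
        sd = self.base_noise_sd * (subject.noise if subject else 1.0)
        sd *= 1.0 + (self.pd_deviation_scale - 1.0) * sig
        sd *= self.device_noise_scale.get(participant.device, 1.0)
        if participant.hand != self.task_hand:
            sd *= self.hand_nondominant_penalty
        return sd

    def tremor_amp(self, participant: Participant) -> float:
        return self.pd_tremor_amp * self._pd_signal(participant)

    def time_factor(self, participant: Participant,
                    subject: "SubjectEffects | None" = None) -> float:
        sig = self._pd_signal(participant)
        base = subject.time if subject else 1.0
        return base * (1.0 + (self.pd_time_scale - 1.0) * sig)

    def response_time_ms(self, participant: Participant,
                         subject: "SubjectEffects | None" = None) -> float:
        return (
            self.base_rt_ms * self.time_factor(participant, subject)
            + self.device_latency_ms.get(participant.device, 0.0)
        )

    def false_press_rate(self, participant: Participant) -> float:
        rate = self.base_false_press_rate
        rate += self.pd_false_press_boost * self._pd_signal(participant)
        return min(rate, 1.0)

    def memory_span(self, participant: Participant) -> float:
        return self.memory_capacity - self.pd_memory_penalty * self._pd_signal(participant)


# -- centerline geometry -------------------------------------------------------

def centerline(path_kind: str, level: int, screen: Tuple[int, int]):
    """Return (params, fn) where fn maps a [0, 1] progress grid to (x, y)."""
    w, h = screen
    x0, x1 = 0.1 * w, 0.9 * w
    if path_kind == "straight":
        params = {"y0": h / 2.0, "x0": x0, "x1": x1}

        def fn(u: np.ndarray):
            return x0 + u * (x1 - x0), np.full_like(u, h / 2.0)

    elif path_kind == "sine":
        amp = 0.08 * h * level
        cycles = 1 + level
        params = {"y0": h / 2.0, "amp": amp, "cycles": cycles, "x0": x0, "x1": x1}

        def fn(u: np.ndarray):
            x = x0 + u * (x1 - x0)
            return x, h / 2.0 + amp * np.sin(2 * np.pi * cycles * u)

    elif path_kind == "spiral":
        theta_max = 2 * np.pi * (1 + 0.5 * level)
        r_max = 0.35 * min(w, h)
        b = r_max / theta_max
        params = {"cx": w / 2.0, "cy": h / 2.0, "b": b, "theta_max": theta_max}

        def fn(u: np.ndarray):
            theta = u * theta_max
            r = b * theta
            return w / 2.0 + r * np.cos(theta), h / 2.0 + r * np.sin(theta)

    else:
        raise ValueError(f"unknown path_kind {path_kind!r}")
    return params, fn


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    eps = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = eps[0] * sd
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + innov_sd * eps[i]
    return out


# -- task simulators -----------------------------------------------------------

def simulate_trace(
    participant: Participant,
    path_kind: str,
    level: int,
    effects: EffectConfig,
    screen: Tuple[int, int] = DEFAULT_SCREEN,
    seed: int | np.random.Generator = 0,
    subject: SubjectEffects = SubjectEffects(),
) -> MouseTrace:
    """Simulate one tracing task: centerline + AR(1) offset + tremor."""
    effects.validate()
    if screen[0] <= 0 or screen[1] <= 0:
        raise ValueError("screen dimensions must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    params, fn = centerline(path_kind, level, screen)

    duration = _BASE_DURATION_S[path_kind] * _LEVEL_FACTOR[level]
    n = max(2, int(round(duration * effects.sample_rate_hz)))
    u = np.linspace(0.0, 1.0, n)
    cx, cy = fn(u)

    dt_ms = 1000.0 / effects.sample_rate_hz * effects.time_factor(participant, subject)
    t = np.arange(n) * dt_ms

    offset = _ar1(rng, n, effects.noise_sd(participant, subject), effects.ar_coeff)
    amp = effects.tremor_amp(participant)
    if amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        offset = offset + amp * np.sin(
            2 * np.pi * effects.pd_tremor_freq * t / 1000.0 + phase
        )

    if path_kind == "spiral":
        # radial offset preserves the sample angle, so deviations stay radial
        theta = u * params["theta_max"]
        x = params["cx"] + (params["b"] * theta + offset) * np.cos(theta)
        y = params["cy"] + (params["b"] * theta + offset) * np.sin(theta)
    else:
        x, y = cx, cy + offset

    x = np.clip(x, 0, screen[0])
    samples = np.column_stack([t, x, y])
    return MouseTrace(path_kind=path_kind, level=level, samples=samples,
                      centerline_params=params)


def simulate_key_task(
    participant: Participant,
    task_kind: str,
    level: int,
    effects: EffectConfig,
    seed: int | np.random.Generator = 0,
    subject: SubjectEffects = SubjectEffects(),
) -> KeyTaskRecord:
    """Simulate one key-press task level: prompts and matched presses."""
    effects.validate()
    if task_kind not in KEY_TASK_KINDS:
        raise ValueError(f"unknown task_kind {task_kind!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if task_kind == "constant":
        alphabet = ["f"]
    elif task_kind == "two_letter":
        alphabet = ["f", "j"]
    else:
        alphabet = _KEY_ALPHABET

    spacing = 1500.0
    base_rt = effects.response_time_ms(participant, subject)
    false_rate = effects.false_press_rate(participant)

    prompts: List[Tuple[float, str]] = []
    presses: List[Tuple[float, str]] = []
    t = 0.0
    for _ in range(PROMPTS_PER_LEVEL):
        expected = alphabet[int(rng.integers(len(alphabet)))]
        rt = base_rt + rng.normal(0.0, effects.rt_noise_sd_ms)
        rt = max(rt, 50.0)
        if rng.uniform() < false_rate:
            wrong = [k for k in _KEY_ALPHABET if k != expected]
            key = wrong[int(rng.integers(len(wrong)))]
        else:
            key = expected
        prompts.append((t, expected))
        presses.append((t + rt, key))
        t += spacing
    return KeyTaskRecord(task_kind=task_kind, level=level,
                         prompts=prompts, presses=presses)


def simulate_click_task(
    participant: Participant,
    effects: EffectConfig,
    screen: Tuple[int, int] = DEFAULT_SCREEN,
    seed: int | np.random.Generator = 0,
    subject: SubjectEffects = SubjectEffects(),
) -> ClickTaskRecord:
    effects.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w, h = screen
    base_rt = 1.2 * effects.response_time_ms(participant, subject)
    sd = effects.noise_sd(participant, subject)

    targets: List[Tuple[float, float, float]] = []
    clicks: List[Tuple[float, float, float, bool]] = []
    t = 0.0
    for _ in range(CLICK_TARGETS):
        tx = rng.uniform(0.1 * w, 0.9 * w)
        ty = rng.uniform(0.1 * h, 0.9 * h)
        rt = max(base_rt + rng.normal(0.0, effects.rt_noise_sd_ms), 80.0)
        cxp = tx + rng.normal(0.0, sd)
        cyp = ty + rng.normal(0.0, sd)
        hit = bool(np.hypot(cxp - tx, cyp - ty) <= 30.0)
        targets.append((t, tx, ty))
        clicks.append((t + rt, cxp, cyp, hit))
        t += 1500.0
    return ClickTaskRecord(targets=targets, clicks=clicks)


def simulate_memory_task(
    participant: Participant,
    effects: EffectConfig,
    seed: int | np.random.Generator = 0,
) -> MemoryTaskRecord:
    """Digit-span run: lengths increase until the first failure or the cap."""
    effects.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    span = effects.memory_span(participant)
    trials: List[Tuple[int, bool]] = []
    max_reached = MEMORY_START - 1
    for length in range(MEMORY_START, MEMORY_CAP + 1):
        p_correct = 1.0 / (1.0 + np.exp(length - span))
        correct = bool(rng.uniform() < p_correct)
        trials.append((length, correct))
        if not correct:
            break
        max_reached = length
    return MemoryTaskRecord(trials=trials, max_length_reached=max_reached)


def simulate_session(
    participant: Participant,
    effects: EffectConfig,
    screen: Tuple[int, int] = DEFAULT_SCREEN,
    seed: int = 0,
) -> Session:
    """Assemble the full 7-task battery (3×3 traces, 3×3 key tasks, one
    click run, one memory run) for one participant. Deterministic given
    ``seed``."""
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, _stable_hash(participant.id)])
    children = ss.spawn(21)
    subject = effects.draw_subject(np.random.default_rng(children[20]))
    idx = 0
    traces: List[MouseTrace] = []
    for kind in PATH_KINDS:
        for level in LEVELS:
            traces.append(
                simulate_trace(participant, kind, level, effects, screen,
                               np.random.default_rng(children[idx]), subject)
            )
            idx += 1
    key_tasks: List[KeyTaskRecord] = []
    for kind in KEY_TASK_KINDS:
        for level in LEVELS:
            key_tasks.append(
                simulate_key_task(participant, kind, level, effects,
                                  np.random.default_rng(children[idx]), subject)
            )
            idx += 1
    click = simulate_click_task(participant, effects, screen,
                                np.random.default_rng(children[idx]), subject)
    memory = simulate_memory_task(participant, effects,
                                  np.random.default_rng(children[idx + 1]))
    return Session(
        participant_id=participant.id,
        screen=screen,
        trace_tasks=traces,
        key_tasks=key_tasks,
        click_task=click,
        memory_task=memory,
    )


def simulate_cohort_sessions(
    cohort: List[Participant],
    effects: EffectConfig,
    screen: Tuple[int, int] = DEFAULT_SCREEN,
    seed: int = 0,
) -> List[Session]:
    return [simulate_session(p, effects, screen, seed) for p in cohort]


def _stable_hash(s: str) -> int:
    # process-independent string hash (builtin hash is salted)
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h
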