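"""Feature registry and extraction: 79 features per participant.

The registry covers five categories — mouse movement, mouse click,
keyboard, memory and demographic.  Its core is the named deviation and
timing statistics of the tracing tasks (total / net / maximum / average
absolute / signed mean / maximum pixel deviation from the centerline,
raw and width-normalised tracing times), completed systematically
across the three paths and three keyboard tasks:

* per tracing path (straight line, sine wave, spiral): 8 deviation
  statistics, raw + normalised time, and 4 kinematic statistics
  (3 x 14 = 42), plus 2 cross-task aggregates;
* per keyboard task (constant key, two-letter, random): 8 response-time
  / accuracy / false-press statistics (3 x 8 = 24), plus 2 aggregates;
* 3 click features, 2 memory features, 4 demographic attributes.

Deviation is measured vertically for the straight/sine paths and
radially for the spiral; percentage features are expressed relative to
screen height, so they are invariant under uniform rescaling of screen
and offsets.  Per-path statistics are averaged over the three difficulty
levels; keyboard statistics pool presses over levels.

Missing values are carried as NaN plus an explicit missing mask — never
silent zeros; imputation happens downstream on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .cohort import Participant
from .session import KeyTaskRecord, MouseTrace, Session

REGISTRY_SCHEMA = "motorfair.registry.v1"
N_FEATURES = 79
DEFAULT_BAND_HALFWIDTH = 15.0  # px

_PATHS = (("straight", "straight_line"), ("sine", "sine_wave"), ("spiral", "spiral"))
_KEYTASKS = (("constant", "constant_key"), ("two_letter", "two_letter_key"),
             ("random", "random_key"))

# tracing-time names are irregular ("a" vs "the") and frozen in the
# v1 registry; renaming them would break downstream column contracts
_TIME_NAME = {
    "straight_line": ("time_to_trace_a_straight_line",
                      "time_to_trace_a_straight_line_normalized"),
    "sine_wave": ("time_to_trace_the_sine_wave",
                  "time_to_trace_the_sine_wave_normalized"),
    "spiral": ("time_to_trace_a_spiral", "time_to_trace_the_spiral_normalized"),
}
# the constant-key press-rate name is likewise irregular and frozen
_PRESS_RATE_NAME = {
    "constant_key": "correct_the_press_rate_constant_key",
    "two_letter_key": "correct_press_rate_two_letter_key",
    "random_key": "correct_press_rate_random_key",
}


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    category: str  # mouse_movement | mouse_click | keyboard | memory | demographic
    unit: str


@dataclass
class FeatureRegistry:
    entries: List[FeatureEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in registry")

    @property
    def names(self) -> List[str]:
        return [e.name for e in self.entries]

    def subset(self, categories: Iterable[str]) -> "FeatureRegistry":
        cats = set(categories)
        return FeatureRegistry([e for e in self.entries if e.category in cats])

    @classmethod
    def default(cls) -> "FeatureRegistry":
        entries: List[FeatureEntry] = []
        for _, suffix in _PATHS:
            entries += [
                FeatureEntry(f"total_deviation_{suffix}", "mouse_movement", "pct_screen_height"),
                FeatureEntry(f"net_deviation_{suffix}", "mouse_movement", "pct_screen_height"),
                FeatureEntry(f"maximum_deviation_{suffix}", "mouse_movement", "pct_screen_height"),
                FeatureEntry(f"average_absolute_deviation_{suffix}", "mouse_movement", "pct_screen_height"),
                FeatureEntry(f"mean_deviation_{suffix}", "mouse_movement", "fraction_screen_height"),
                FeatureEntry(f"std_deviation_{suffix}", "mouse_movement", "pct_screen_height"),
                FeatureEntry(f"maximum_pixel_deviation_{suffix}", "mouse_movement", "px"),
                FeatureEntry(f"points_inside_{suffix}", "mouse_movement", "count"),
                FeatureEntry(_TIME_NAME[suffix][0], "mouse_movement", "s"),
                FeatureEntry(_TIME_NAME[suffix][1], "mouse_movement", "s_per_px"),
                FeatureEntry(f"mean_speed_{suffix}", "mouse_movement", "px_per_s"),
                FeatureEntry(f"maximum_speed_{suffix}", "mouse_movement", "px_per_s"),
                FeatureEntry(f"path_length_{suffix}", "mouse_movement", "px"),
                FeatureEntry(f"sample_count_{suffix}", "mouse_movement", "count"),
            ]
        entries += [
            FeatureEntry("average_tracing_time_for_all_tasks", "mouse_movement", "s"),
            FeatureEntry("average_points_inside_all_lines", "mouse_movement", "count"),
        ]
        for _, suffix in _KEYTASKS:
            entries += [
                FeatureEntry(f"average_response_time_{suffix}", "keyboard", "s"),
                FeatureEntry(f"std_response_time_{suffix}", "keyboard", "s"),
                FeatureEntry(f"minimum_response_time_{suffix}", "keyboard", "s"),
                FeatureEntry(f"maximum_response_time_{suffix}", "keyboard", "s"),
                FeatureEntry(f"correct_press_count_{suffix}", "keyboard", "count"),
                FeatureEntry(_PRESS_RATE_NAME[suffix], "keyboard", "presses_per_s"),
                FeatureEntry(f"false_press_count_{suffix}", "keyboard", "count"),
                FeatureEntry(f"false_press_ratio_{suffix}", "keyboard", "ratio"),
            ]
        entries += [
            FeatureEntry("average_response_time_all_tests", "keyboard", "s"),
            FeatureEntry("average_false_presses_all_tests", "keyboard", "count"),
            FeatureEntry("total_click_time_for_all_tests", "mouse_click", "s"),
            FeatureEntry("total_click_reaction_time", "mouse_click", "s"),
            FeatureEntry("click_hit_rate", "mouse_click", "ratio"),
            FeatureEntry("memory_max_length_reached", "memory", "count"),
            FeatureEntry("memory_error_count", "memory", "count"),
            FeatureEntry("sex", "demographic", "categorical"),
            FeatureEntry("race_binary", "demographic", "categorical"),
            FeatureEntry("device", "demographic", "categorical"),
            FeatureEntry("hand", "demographic", "categorical"),
        ]
        reg = cls(entries)
        assert len(reg.entries) == N_FEATURES
        return reg

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"name": [e.name for e in self.entries],
             "category": [e.category for e in self.entries],
             "unit": [e.unit for e in self.entries]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureRegistry":
        df = pd.read_csv(path)
        return cls([FeatureEntry(r.name, r.category, r.unit) for r in df.itertuples()])


@dataclass
class FeatureVector:
    participant_id: str
    values: Dict[str, object]
    missing_mask: Set[str] = field(default_factory=set)


@dataclass
class DeviationSeries:
    """Per-sample signed offsets from the path centerline."""
    d: np.ndarray          # px, signed
    screen_height: float   # px
    window_width: float    # px
    n_excluded: int = 0


# -- deviation geometry --------------------------------------------------------

def signed_deviations(trace: MouseTrace, screen: Tuple[int, int]) -> DeviationSeries:
    """Signed per-sample deviation: vertical for straight/sine, radial
    (distance minus centerline radius at the matched unwrapped angle)
    for the spiral."""
    w, h = screen
    t, x, y = trace.samples[:, 0], trace.samples[:, 1], trace.samples[:, 2]
    p = trace.centerline_params
    excluded = 0
    if trace.path_kind == "straight":
        d = y - p["y0"]
    elif trace.path_kind == "sine":
        x0, x1 = p["x0"], p["x1"]
        inside = (x >= x0) & (x <= x1)
        excluded = int((~inside).sum())
        u = np.clip((x[inside] - x0) / (x1 - x0), 0.0, 1.0)
        center = p["y0"] + p["amp"] * np.sin(2 * np.pi * p["cycles"] * u)
        d = y[inside] - center
    elif trace.path_kind == "spiral":
        dx, dy = x - p["cx"], y - p["cy"]
        r = np.hypot(dx, dy)
        theta = np.unwrap(np.arctan2(dy, dx))
        theta = theta - theta[0]  # spiral starts at angle 0 at the origin
        d = r - p["b"] * theta
    else:
        raise ValueError(f"unknown path_kind {trace.path_kind!r}")
    return DeviationSeries(d=np.asarray(d, dtype=float), screen_height=float(h),
                           window_width=float(w), n_excluded=excluded)


def deviation_features(dev: DeviationSeries) -> Dict[str, float]:
    """The six centerline-deviation statistics of one trace.

    total/net/max/avg_abs are percentages of screen height; mean is the
    signed fraction of screen height; max_pixel is in raw pixels.
    """
    if len(dev.d) == 0:
        return {k: np.nan for k in ("total", "net", "max", "avg_abs", "mean",
                                    "max_pixel", "std")}
    d, H = dev.d, dev.screen_height
    absd = np.abs(d)
    return {
        "total": float(absd.sum() / H * 100.0),
        "net": float(abs(d.sum()) / H * 100.0),
        "max": float(absd.max() / H * 100.0),
        "avg_abs": float(absd.mean() / H * 100.0),
        "mean": float(d.mean() / H),
        "max_pixel": float(absd.max()),
        "std": float(d.std() / H * 100.0),
    }


def points_inside(dev: DeviationSeries, band_halfwidth: float = DEFAULT_BAND_HALFWIDTH) -> int:
    """Number of samples within ±band_halfwidth px of the centerline."""
    if band_halfwidth <= 0:
        raise ValueError("band_halfwidth must be positive")
    return int((np.abs(dev.d) <= band_halfwidth).sum())


# -- per-trace helpers ---------------------------------------------------------

def _trace_time_s(trace: MouseTrace) -> float:
    t = trace.samples[:, 0]
    if len(t) < 2:
        return np.nan
    return float((t[-1] - t[0]) / 1000.0)


def _trace_kinematics(trace: MouseTrace) -> Dict[str, float]:
    t = trace.samples[:, 0] / 1000.0
    xy = trace.samples[:, 1:3]
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dt = np.diff(t)
    speeds = steps / np.where(dt > 0, dt, np.nan)
    return {
        "mean_speed": float(np.nanmean(speeds)) if len(speeds) else np.nan,
        "maximum_speed": float(np.nanmax(speeds)) if len(speeds) else np.nan,
        "path_length": float(steps.sum()),
        "sample_count": float(len(trace.samples)),
    }


def timing_features(session: Session) -> Dict[str, float]:
    """Raw and width-normalised tracing times per path kind (averaged
    over levels) plus the all-task average."""
    out: Dict[str, float] = {}
    w = float(session.screen[0])
    all_times: List[float] = []
    for kind, suffix in _PATHS:
        times = [_trace_time_s(t) for t in session.traces_of_kind(kind)]
        times = [t for t in times if np.isfinite(t)]
        raw_name, norm_name = _TIME_NAME[suffix]
        if times:
            raw = float(np.mean(times))
            out[raw_name] = raw
            out[norm_name] = raw / w
            all_times.extend(times)
        else:
            out[raw_name] = np.nan
            out[norm_name] = np.nan
    out["average_tracing_time_for_all_tasks"] = (
        float(np.mean(all_times)) if all_times else np.nan
    )
    return out


def points_inside_features(
    session: Session, band_halfwidth: float = DEFAULT_BAND_HALFWIDTH
) -> Dict[str, float]:
    out: Dict[str, float] = {}
    counts_all: List[int] = []
    for kind, suffix in _PATHS:
        counts = [
            points_inside(signed_deviations(t, session.screen), band_halfwidth)
            for t in session.traces_of_kind(kind)
        ]
        out[f"points_inside_{suffix}"] = float(np.mean(counts)) if counts else np.nan
        counts_all.extend(counts)
    out["average_points_inside_all_lines"] = (
        float(np.mean(counts_all)) if counts_all else np.nan
    )
    return out


def _match_presses(task: KeyTaskRecord) -> List[Tuple[float, str, str]]:
    """Match each prompt to the first unconsumed press at or after it.

    Returns (rt_s, expected_key, pressed_key) per matched prompt.
    """
    presses = sorted(task.presses)
    used = [False] * len(presses)
    matched = []
    for t_prompt, expected in sorted(task.prompts):
        for i, (t_press, key) in enumerate(presses):
            if not used[i] and t_press >= t_prompt:
                used[i] = True
                matched.append(((t_press - t_prompt) / 1000.0, expected, key))
                break
    return matched


def keyboard_features(session: Session) -> Dict[str, float]:
    out: Dict[str, float] = {}
    rts_by_task: List[float] = []
    false_by_task: List[float] = []
    for kind, suffix in _KEYTASKS:
        matched: List[Tuple[float, str, str]] = []
        for task in session.key_tasks_of_kind(kind):
            matched.extend(_match_presses(task))
        if not matched:
            for stat in ("average_response_time", "std_response_time",
                         "minimum_response_time", "maximum_response_time",
                         "correct_press_count", "false_press_count",
                         "false_press_ratio"):
                out[f"{stat}_{suffix}"] = np.nan
            out[_PRESS_RATE_NAME[suffix]] = np.nan
            continue
        rts = np.array([m[0] for m in matched])
        correct = sum(1 for m in matched if m[2] == m[1])
        false = len(matched) - correct
        avg_rt = float(rts.mean())
        out[f"average_response_time_{suffix}"] = avg_rt
        out[f"std_response_time_{suffix}"] = float(rts.std())
        out[f"minimum_response_time_{suffix}"] = float(rts.min())
        out[f"maximum_response_time_{suffix}"] = float(rts.max())
        out[f"correct_press_count_{suffix}"] = float(correct)
        out[_PRESS_RATE_NAME[suffix]] = (
            correct / avg_rt if avg_rt > 0 else np.nan
        )
        out[f"false_press_count_{suffix}"] = float(false)
        out[f"false_press_ratio_{suffix}"] = false / len(matched)
        rts_by_task.append(avg_rt)
        false_by_task.append(float(false))
    out["average_response_time_all_tests"] = (
        float(np.mean(rts_by_task)) if rts_by_task else np.nan
    )
    out["average_false_presses_all_tests"] = (
        float(np.mean(false_by_task)) if false_by_task else np.nan
    )
    return out


def click_features(session: Session) -> Dict[str, float]:
    """Click-game totals: all-target click latency, reaction time over
    successful clicks, and the hit rate."""
    task = session.click_task
    nan = {"total_click_time_for_all_tests": np.nan,
           "total_click_reaction_time": np.nan,
           "click_hit_rate": np.nan}
    if task is None or not task.targets:
        return nan
    lat = [(c[0] - t[0]) / 1000.0 for t, c in zip(task.targets, task.clicks)]
    hits = [bool(c[3]) for c in task.clicks]
    return {
        "total_click_time_for_all_tests": float(np.sum(lat)),
        "total_click_reaction_time": float(
            np.sum([l for l, h in zip(lat, hits) if h])
        ),
        "click_hit_rate": float(np.mean(hits)),
    }


def memory_features(session: Session) -> Dict[str, float]:
    task = session.memory_task
    if task is None or not task.trials:
        return {"memory_max_length_reached": np.nan, "memory_error_count": np.nan}
    return {
        "memory_max_length_reached": float(task.max_length_reached),
        "memory_error_count": float(sum(1 for _, ok in task.trials if not ok)),
    }


# -- top level -----------------------------------------------------------------

def extract_features(
    session: Session,
    participant: Participant,
    registry: FeatureRegistry | None = None,
    include_demographics: bool = True,
    include_memory: bool = True,
    band_halfwidth: float = DEFAULT_BAND_HALFWIDTH,
) -> FeatureVector:
    """Compute the registry's features, in registry order, for one session."""
    registry = registry or FeatureRegistry.default()
    values: Dict[str, object] = {}

    for kind, suffix in _PATHS:
        traces = session.traces_of_kind(kind)
        stats = [deviation_features(signed_deviations(t, session.screen))
                 for t in traces]
        kin = [_trace_kinematics(t) for t in traces]
        agg = lambda key, rows: (float(np.nanmean([r[key] for r in rows]))
                                 if rows else np.nan)
        values[f"total_deviation_{suffix}"] = agg("total", stats)
        values[f"net_deviation_{suffix}"] = agg("net", stats)
        values[f"maximum_deviation_{suffix}"] = agg("max", stats)
        values[f"average_absolute_deviation_{suffix}"] = agg("avg_abs", stats)
        values[f"mean_deviation_{suffix}"] = agg("mean", stats)
        values[f"std_deviation_{suffix}"] = agg("std", stats)
        values[f"maximum_pixel_deviation_{suffix}"] = agg("max_pixel", stats)
        for key in ("mean_speed", "maximum_speed", "path_length", "sample_count"):
            values[f"{key}_{suffix}"] = agg(key, kin)

    values.update(timing_features(session))
    values.update(points_inside_features(session, band_halfwidth))
    values.update(keyboard_features(session))
    values.update(click_features(session))
    if include_memory:
        values.update(memory_features(session))
    else:
        values.update({"memory_max_length_reached": np.nan,
                       "memory_error_count": np.nan})
    if include_demographics:
        values.update({"sex": participant.sex,
                       "race_binary": participant.race_binary,
                       "device": participant.device,
                       "hand": participant.hand})

    names = registry.names if include_demographics else [
        e.name for e in registry.entries if e.category != "demographic"
    ]
    ordered = {name: values.get(name, np.nan) for name in names}
    missing = {
        name for name, v in ordered.items()
        if not isinstance(v, str) and (v is None or not np.isfinite(v))
    }
    return FeatureVector(participant_id=session.participant_id,
                         values=ordered, missing_mask=missing)


def extract_feature_table(
    sessions: Sequence[Session],
    cohort: Sequence[Participant],
    registry: FeatureRegistry | None = None,
    include_demographics: bool = True,
    include_memory: bool = True,
    band_halfwidth: float = DEFAULT_BAND_HALFWIDTH,
) -> pd.DataFrame:
    """Feature matrix: one row per participant, ``participant_id`` first,
    then the registry columns in order."""
    registry = registry or FeatureRegistry.default()
    by_id = {p.id: p for p in cohort}
    rows = []
    for s in sessions:
        fv = extract_features(s, by_id[s.participant_id], registry,
                              include_demographics, include_memory, band_halfwidth)
        rows.append({"participant_id": fv.participant_id, **fv.values})
    return pd.DataFrame(rows)


class SessionFeatureExtractor:
    """Stateless transformer from sessions to the tabular feature matrix.

    sklearn-style surface (``get_params`` / ``set_params`` / ``transform``)
    so the extractor can sit at the head of a pipeline.
    """

    def __init__(self, include_demographics: bool = True,
                 include_memory: bool = True,
                 band_halfwidth: float = DEFAULT_BAND_HALFWIDTH):
        self.include_demographics = include_demographics
        self.include_memory = include_memory
        self.band_halfwidth = band_halfwidth

    def get_params(self, deep: bool = True) -> Dict[str, object]:
        return {"include_demographics": self.include_demographics,
                "include_memory": self.include_memory,
                "band_halfwidth": self.band_halfwidth}

    def set_params(self, **params) -> "SessionFeatureExtractor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "SessionFeatureExtractor":
        return self

    def transform(self, sessions: Sequence[Session],
                  cohort: Sequence[Participant]) -> pd.DataFrame:
        return extract_feature_table(
            sessions, cohort, FeatureRegistry.default(),
            self.include_demographics, self.include_memory, self.band_halfwidth,
        )
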