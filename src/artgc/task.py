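"""The behavioral trial: working memory, comparison, and response.

Protocol (sequential color-discrimination with an intervening word):

1. *Reference phase* — the reference color drives the color module to
   resonance and the winning category is latched into the working-memory
   layer F5 (one node per F2 category; once loaded it stays constant for
   the trial).  The phase is simulated once per reference color and cached.
2. *Word phase* — the word glyph drives the VWF module to resonance; the
   resonant word node excites the associative map, which returns the
   expectation drive over color F2.  Neutral words return a zero drive.
3. *Main phase* — the expectation primes the color module from t = 0; the
   target square appears at ``target_onset``.  A mismatching expectation
   triggers the orienting subsystem (one reset), delaying the rise of the
   correct category.
4. *Response* — comparison layers C1 (logical AND of F2 and F5, realized by
   summation against an elevated threshold) and C2 (logical OR) feed two
   leaky competing accumulators (Same / Different).  The Different unit's
   input threshold is elevated so a single active C2 node is insufficient.
   The first accumulator to cross the motor threshold issues the response.

Comparison input from F2 is vetoed while a vigilance mismatch is pending,
so the response network reads only classified percepts.  Crossing times
are mapped to milliseconds by one affine calibration per batch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .circuit import RESONANT_OUTPUT
from .config import ResponseConfig
from .dynamics import LayerState, TraceRecorder
from .system import ModelSystem

__all__ = [
    "CONDITIONS",
    "SPEEDS",
    "TrialSpec",
    "WorkingMemoryState",
    "Calibration",
    "ResponseOutcome",
    "load_working_memory",
    "c1_and",
    "c2_or",
    "accumulate",
    "to_milliseconds",
    "run_trial",
    "condition_contrast",
    "run_grid",
    "calibrate",
    "run_experiment",
]

CONDITIONS = ("match", "mismatch", "neutral")
SPEEDS = ("fast", "medium", "slow")

#: Default word per condition when the trial spec leaves it implicit.
_DEFAULT_NEUTRAL_WORD = "best"


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the color-discrimination task."""

    condition: str
    r_speed: str = "medium"
    reference_color: str = "red"
    target_color: str = "red"
    word: Optional[str] = None  # resolved from condition when omitted
    target_onset: float = 40.0
    max_duration: float = 250.0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.r_speed not in SPEEDS:
            raise ValueError(f"unknown R-node speed {self.r_speed!r}")
        if self.target_onset < 0 or self.max_duration <= self.target_onset:
            raise ValueError("require 0 <= target_onset < max_duration")

    def resolve_word(self, system: ModelSystem) -> str:
        """The word shown in this trial, consistent with the condition."""
        if self.word is not None:
            role = system.word_role(self.word)
            if self.condition == "neutral" and role != "neutral":
                raise ValueError(
                    f"neutral trials need a neutral word, got {self.word!r}"
                )
            if self.condition == "match" and self.word != self.target_color:
                raise ValueError("match trials need the word naming the target")
            if self.condition == "mismatch" and (
                role != "color" or self.word == self.target_color
            ):
                raise ValueError(
                    "mismatch trials need a color word different from the target"
                )
            return self.word
        if self.condition == "match":
            return self.target_color
        if self.condition == "mismatch":
            from .stimuli import COLOR_WORDS

            return next(w for w in COLOR_WORDS if w != self.target_color)
        return _DEFAULT_NEUTRAL_WORD


@dataclass(frozen=True)
class WorkingMemoryState:
    """F5 latch: the reference category, constant for the trial."""

    f5_outputs: np.ndarray

    def __post_init__(self) -> None:
        if not np.isin(self.f5_outputs, (0.0, 1.0)).all():
            raise ValueError("F5 outputs are a binary latch")


def load_working_memory(resonant_f2: LayerState) -> WorkingMemoryState:
    """Latch the resonant F2 pattern into F5 (refused outside resonance)."""
    out = resonant_f2.outputs
    if out.max(initial=0.0) < RESONANT_OUTPUT:
        raise RuntimeError(
            "working memory can only be loaded from a resonant F2 state"
        )
    return WorkingMemoryState((out >= RESONANT_OUTPUT).astype(float))


@dataclass(frozen=True)
class Calibration:
    """Affine simulation-time -> millisecond map, fixed once per batch."""

    slope: float
    intercept: float
    batch_id: str = "default"

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")


def to_milliseconds(crossing_time: float, calibration: Calibration) -> float:
    if crossing_time < 0:
        raise ValueError("crossing times are non-negative")
    return calibration.intercept + calibration.slope * crossing_time


def c1_and(f2_out: np.ndarray, f5_out: np.ndarray, threshold: float = 1.2) -> np.ndarray:
    """AND comparison: summation against an elevated threshold.

    A node responds only when its F2 and F5 inputs are *both* active, since
    neither input alone can reach the threshold.
    """
    if f2_out.shape != f5_out.shape:
        raise ValueError("C1 inputs must have equal length")
    return np.maximum(f2_out + f5_out - threshold, 0.0)


def c2_or(f2_out: np.ndarray, f5_out: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """OR comparison: a node saturates to ~1 when either input is active."""
    if f2_out.shape != f5_out.shape:
        raise ValueError("C2 inputs must have equal length")
    s = np.maximum(f2_out + f5_out - threshold, 0.0)
    return np.maximum(2.0 / (1.0 + np.exp(-s / 0.02)) - 1.0, 0.0)


def accumulate(
    c1: np.ndarray,
    c2: np.ndarray,
    same_state: float,
    diff_state: float,
    dt: float,
    params: ResponseConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """One step of the two leaky competing accumulators.

    The Same unit integrates total C1 evidence; the Different unit
    integrates total C2 evidence in excess of its elevated input gate, so
    one active C2 node (reference alone, or a confirmed match) drives it
    not at all, while two simultaneously active C2 nodes do.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    i_same = params.same_gain * float(np.sum(c1))
    i_diff = params.diff_gain * max(
        float(np.sum(c2)) - params.diff_input_gate, 0.0
    )
    noise_s = noise_d = 0.0
    if rng is not None and params.noise_sd > 0:
        noise_s, noise_d = rng.normal(0.0, params.noise_sd, size=2) * np.sqrt(dt)
    ds = (
        -params.leak * same_state
        + i_same
        - params.mutual_inhibition * diff_state
    ) * dt / params.time_constant + noise_s
    dd = (
        -params.leak * diff_state
        + i_diff
        - params.mutual_inhibition * same_state
    ) * dt / params.time_constant + noise_d
    return max(same_state + ds, 0.0), max(diff_state + dd, 0.0)


@dataclass
class ResponseOutcome:
    """Result of one trial: the response, its latency, and the full trace."""

    choice: str  # "same" | "different" | "none"
    crossing_time: float
    rt_ms: float
    n_resets: int
    condition: str
    r_speed: str
    trace: object = field(repr=False, default=None)
    calibration: Optional[Calibration] = None
    f2_full_time: float = float("nan")  # winner's rise to full amplitude
    word: str = ""

    def with_calibration(self, calibration: Calibration) -> "ResponseOutcome":
        rt = (
            to_milliseconds(self.crossing_time, calibration)
            if self.choice != "none"
            else float("nan")
        )
        return ResponseOutcome(
            self.choice,
            self.crossing_time,
            rt,
            self.n_resets,
            self.condition,
            self.r_speed,
            self.trace,
            calibration,
            self.f2_full_time,
            self.word,
        )


# ---------------------------------------------------------------------------
# Trial phases
# ---------------------------------------------------------------------------


def run_reference_phase(
    system: ModelSystem, reference_color: str
) -> WorkingMemoryState:
    """Resonate on the reference color and latch F2 into working memory.

    Cached per reference color: the reference presentation precedes every
    trial identically, so it is simulated once per batch.
    """
    cache = getattr(system, "_wm_cache", None)
    if cache is None:
        cache = {}
        system._wm_cache = cache
    if reference_color in cache:
        return cache[reference_color]
    dt = system.config.timing.dt
    mod = system.color
    mod.reset_state()
    mod.set_priming(np.array([]))
    mod.register_input(system.hue_pattern(reference_color).activations)
    mod.run(system.config.timing.reference_phase, dt)
    wm = load_working_memory(mod.f2)
    mod.reset_state()
    mod.register_input(np.array([]))
    cache[reference_color] = wm
    return wm


def run_word_phase(system: ModelSystem, word: str) -> np.ndarray:
    """Recognize the word in the VWF module; return the color-F2 expectation.

    The resonant word node excites its concept node in the associative map,
    which fans out over the hue categories of the named color.  Cached per
    word (the VWF module settles to the same resonant state every time).
    """
    cache = getattr(system, "_prime_cache", None)
    if cache is None:
        cache = {}
        system._prime_cache = cache
    if word in cache:
        return cache[word]
    dt = system.config.timing.dt
    mod = system.vwf
    mod.reset_state()
    mod.register_input(system.word_template(word).flat)
    mod.run(system.config.timing.word_phase, dt)
    winner = int(np.argmax(mod.f2.outputs))
    if mod.f2.outputs[winner] < RESONANT_OUTPUT:
        raise RuntimeError(f"VWF module failed to resonate on {word!r}")
    if winner != system.word_index[word]:
        raise RuntimeError(
            f"VWF module recognized {word!r} as category {winner}"
        )
    priming = system.priming_from_word(word)
    mod.reset_state()
    mod.register_input(np.array([]))
    cache[word] = priming
    return priming


def run_trial(
    spec: TrialSpec,
    system: ModelSystem,
    calibration: Optional[Calibration] = None,
    record: bool = True,
) -> ResponseOutcome:
    """Execute one full trial and return its outcome with trace."""
    cfg = system.config
    dt = cfg.timing.dt
    rp = cfg.response
    word = spec.resolve_word(system)

    wm = run_reference_phase(system, spec.reference_color)
    priming = run_word_phase(system, word)
    target = system.hue_pattern(spec.target_color).activations

    mod = system.color
    mod.reset_state()
    mod.register_input(np.array([]))
    mod.set_priming(priming)

    rng = (
        np.random.default_rng(cfg.noise_seed)
        if cfg.noise_seed is not None and rp.noise_sd > 0
        else None
    )
    recorder = TraceRecorder() if record else None
    same = diff = 0.0
    n_resets = 0
    r_was_supra = False
    target_on = False
    choice, crossing = "none", float("nan")
    f2_full_time = float("nan")
    winner_idx: Optional[int] = None

    n_steps = int(round(spec.max_duration / dt))
    for k in range(n_steps + 1):
        t = k * dt
        if not target_on and t >= spec.target_onset:
            mod.register_input(target)
            target_on = True

        # comparison + response read the *current* outputs
        veto = max(1.0 - mod.mismatch() / rp.mismatch_veto_scale, 0.0)
        f2_eff = mod.f2.outputs * veto
        c1 = c1_and(f2_eff, wm.f5_outputs, rp.c1_threshold)
        c2 = c2_or(f2_eff, wm.f5_outputs, rp.c2_threshold)

        if recorder is not None:
            states = {("color", n): s for n, s in mod.layer_states().items()}
            states[("response", "c1")] = LayerState(c1, c1)
            states[("response", "c2")] = LayerState(c2, c2)
            states[("response", "f5")] = LayerState(
                wm.f5_outputs, wm.f5_outputs
            )
            acc = np.array([same, diff])
            states[("response", "accumulators")] = LayerState(acc, acc)
            recorder.record(t, states)

        if mod.r_supra and not r_was_supra:
            n_resets += 1
        r_was_supra = mod.r_supra

        if np.isnan(f2_full_time) and target_on:
            # rise time of the category tuned to the *target* hue
            target_idx = system.hue_index[
                system.hue_pattern(spec.target_color).hue_label
            ]
            if mod.f2.outputs[target_idx] >= RESONANT_OUTPUT:
                winner_idx = target_idx
                f2_full_time = t

        if same >= rp.motor_threshold or diff >= rp.motor_threshold:
            choice = "same" if same >= diff else "different"
            crossing = t
            break
        if k == n_steps:
            break

        same, diff = accumulate(c1, c2, same, diff, dt, rp, rng)
        mod.step(dt)

    mod.set_priming(np.array([]))
    mod.register_input(np.array([]))
    trace = recorder.build() if recorder is not None else None
    outcome = ResponseOutcome(
        choice=choice,
        crossing_time=crossing,
        rt_ms=float("nan"),
        n_resets=n_resets,
        condition=spec.condition,
        r_speed=spec.r_speed,
        trace=trace,
        calibration=None,
        f2_full_time=f2_full_time,
        word=word,
    )
    if calibration is not None and choice != "none":
        outcome = outcome.with_calibration(calibration)
    return outcome


# ---------------------------------------------------------------------------
# Experiment batch
# ---------------------------------------------------------------------------


def run_grid(
    system: ModelSystem,
    speeds: Iterable[str] = SPEEDS,
    conditions: Iterable[str] = CONDITIONS,
    reference_color: str = "red",
    target_color: str = "red",
    record: bool = False,
) -> Dict[Tuple[str, str], ResponseOutcome]:
    """Run the conditions x speeds grid of same-response trials."""
    outcomes = {}
    for speed, cond in itertools.product(speeds, conditions):
        system.color.set_r_preset(speed)
        spec = TrialSpec(
            condition=cond,
            r_speed=speed,
            reference_color=reference_color,
            target_color=target_color,
            target_onset=system.config.timing.target_onset,
            max_duration=system.config.timing.max_duration,
        )
        outcomes[(speed, cond)] = run_trial(spec, system, record=record)
    return outcomes


def calibrate(
    outcomes: Mapping[Tuple[str, str], ResponseOutcome],
    anchor_interference_ms: float = 60.0,
    neutral_rt_ms: float = 500.0,
    batch_id: str = "default",
) -> Calibration:
    """Fix the time -> ms map on the medium-speed interference contrast.

    The slope maps the medium-speed (mismatch - neutral) crossing-time
    difference onto ``anchor_interference_ms``; the contrasts at the other
    two speeds, and the facilitation at every speed, remain independent
    predictions.  The intercept only positions the neutral reaction time.
    """
    mm = outcomes[("medium", "mismatch")].crossing_time
    neu = outcomes[("medium", "neutral")].crossing_time
    delta = mm - neu
    if not delta > 0:
        raise RuntimeError(
            "cannot calibrate: medium-speed mismatch is not slower than neutral"
        )
    slope = anchor_interference_ms / delta
    intercept = neutral_rt_ms - slope * neu
    return Calibration(slope, intercept, batch_id)


def condition_contrast(
    outcomes: Mapping[str, ResponseOutcome], speed: str
) -> Tuple[float, float]:
    """(facilitation, interference) in ms for one speed preset.

    facilitation = rt(neutral) - rt(match);
    interference = rt(mismatch) - rt(neutral).
    All outcomes must share one calibration batch.
    """
    cals = {o.calibration for o in outcomes.values()}
    if len(cals) != 1 or None in cals:
        raise ValueError("contrasts require one shared calibration batch")
    for cond in CONDITIONS:
        if outcomes[cond].r_speed != speed:
            raise ValueError(f"outcome for {cond!r} is not from speed {speed!r}")
    fac = outcomes["neutral"].rt_ms - outcomes["match"].rt_ms
    inter = outcomes["mismatch"].rt_ms - outcomes["neutral"].rt_ms
    return fac, inter


def run_experiment(
    system: ModelSystem, record: bool = False
) -> Tuple[pd.DataFrame, Dict[str, Tuple[float, float]], Calibration]:
    """The full behavioral batch: grid, calibration, per-speed contrasts.

    Returns a tidy results table (one row per condition x speed), the
    facilitation/interference contrasts per speed, and the batch
    calibration.
    """
    cfg = system.config
    raw = run_grid(system, record=record)
    cal = calibrate(
        raw,
        cfg.calibration.anchor_interference_ms,
        cfg.calibration.neutral_rt_ms,
        batch_id=cfg.config_hash(),
    )
    outcomes = {k: o.with_calibration(cal) for k, o in raw.items()}
    rows = []
    for (speed, cond), o in outcomes.items():
        rows.append(
            {
                "condition": cond,
                "r_speed": speed,
                "response": o.choice,
                "crossing_time": o.crossing_time,
                "rt_ms": o.rt_ms,
                "n_resets": o.n_resets,
            }
        )
    results = pd.DataFrame(rows)
    contrasts = {
        speed: condition_contrast(
            {c: outcomes[(speed, c)] for c in CONDITIONS}, speed
        )
        for speed in SPEEDS
    }
    return results, contrasts, cal
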