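"""One complete ART module: registration, matching, choice, and reset.

The attentional subsystem is a three-layer hierarchy.  ``F0`` registers the
sensory pattern and contrast-enhances it (self-excitation plus a mild
off-surround; small uniform noise stays below the output threshold).  ``F1``
combines the ``F0`` pattern with top-down expectation read out from the
category layer ``F2`` and computes their logical AND: the non-specific gain
node ``G1``, driven by ``F2``, inhibits ``F1`` strongly enough that top-down
excitation alone can never push an ``F1`` node above threshold (this is
what prevents internally generated expectation from masquerading as a
percept), while nodes receiving *both* bottom-up and top-down excitation
stay supra-threshold.  ``F2`` is a recurrent competitive field with
faster-than-linear feedback, so with sensory input present exactly one
category wins at full amplitude; without input the tonic gain node ``G2``
(itself shut off by ``F0`` activity) holds any primed category in a weak
but supra-threshold band.

The orienting subsystem watches the ratio of matched (``F1``) to registered
(``F0``) activity.  The reset node ``R`` integrates the rectified mismatch
``rho * sum(F0) - sum(F1)`` together with recurrent excitation from ``F2``
against a tonic inhibition, so it can only fire when a mismatch coincides
with an active category — never on the first feedforward wave.  When ``R``
crosses threshold, the ``F3`` layer latches the currently active ``F2``
node(s) and inhibits them for the remainder of the trial, freeing the field
to search for a better-matching category.

All nodes obey the bounded shunting equation of :mod:`artgc.dynamics`; the
update is synchronous (every layer reads the previous step's outputs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from .dynamics import (
    LayerState,
    ShuntingParams,
    TraceRecorder,
    layer_sum,
    output_signal,
    shunting_step,
)

__all__ = [
    "R_TIME_CONSTANTS",
    "ARTWeights",
    "ARTLayerSpec",
    "ARTParams",
    "ARTModule",
    "mismatch_drive",
    "resonance_status",
    "learn",
    "NoCategoryAvailable",
]

#: Reset-node time-constant presets (fast : medium : slow = 1 : 2 : 4).
R_TIME_CONSTANTS = {"fast": 20.0, "medium": 40.0, "slow": 80.0}

#: F2 output level above which a category counts as fully resonant.
RESONANT_OUTPUT = 0.5

#: F2 output band (exclusive upper edge) for priming without input.
WEAK_OUTPUT_BAND = 0.2


class NoCategoryAvailable(RuntimeError):
    """All committed candidates are latched; search cannot proceed."""


@dataclass
class ARTWeights:
    """Adaptive bottom-up and top-down weights of one ART module.

    ``bottom_up`` is (categories x features), row-normalized so the filtered
    signal a category receives is the mean matched activity over its
    template.  ``top_down`` is the binary expectation template read out when
    a category is active.  Uncommitted categories carry uniform weights.
    """

    bottom_up: np.ndarray
    top_down: np.ndarray
    committed: np.ndarray

    def __post_init__(self) -> None:
        for name in ("bottom_up", "top_down"):
            w = getattr(self, name)
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError(f"{name} weights must lie in [0, 1]")
        if self.bottom_up.shape != self.top_down.shape:
            raise ValueError("bottom-up and top-down shapes differ")
        if self.committed.shape[0] != self.bottom_up.shape[0]:
            raise ValueError("committed flags do not match category count")

    @property
    def n_categories(self) -> int:
        return self.bottom_up.shape[0]

    @property
    def n_features(self) -> int:
        return self.bottom_up.shape[1]

    @classmethod
    def from_templates(cls, templates: np.ndarray) -> "ARTWeights":
        """Commit one category per binary template row."""
        t = np.asarray(templates, dtype=float)
        if not np.isin(t, (0.0, 1.0)).all():
            raise ValueError("templates must be binary")
        sums = t.sum(axis=1)
        if np.any(sums < 1):
            raise ValueError("each template needs at least one active feature")
        return cls(
            bottom_up=t / sums[:, None],
            top_down=t.copy(),
            committed=np.ones(t.shape[0], dtype=bool),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "bottom_up": self.bottom_up.tolist(),
                    "top_down": self.top_down.tolist(),
                    "committed": self.committed.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "ARTWeights":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["bottom_up"], dtype=float),
            np.asarray(d["top_down"], dtype=float),
            np.asarray(d["committed"], dtype=bool),
        )


@dataclass(frozen=True)
class ARTLayerSpec:
    params: ShuntingParams
    signal_kind: str = "threshold-linear"
    signal_gain: float = 1.0


def _spec(theta, tau, gain=1.0, kind="threshold-linear", lower=0.0):
    return ARTLayerSpec(
        ShuntingParams(
            decay_rate=1.0,
            upper_bound=1.0,
            lower_bound=lower,
            output_threshold=theta,
            time_constant=tau,
        ),
        kind,
        gain,
    )


@dataclass(frozen=True)
class ARTParams:
    """All constants of one ART module.

    Defaults realize the canonical behaviors on the default stimuli: noise
    suppression at F0, AND-matching at F1, winner-take-all choice at F2, a
    weak supra-threshold priming band under G2, and coincidence-gated reset.
    """

    # --- input layer -------------------------------------------------
    f0: ARTLayerSpec = field(default_factory=lambda: _spec(0.2, 0.5))
    f0_input_gain: float = 2.0
    f0_self_excitation: float = 0.5
    f0_off_surround: float = 0.05
    # --- matching layer ----------------------------------------------
    # The negative lower bound makes G1 inhibition subtractive near rest,
    # so G1 can cancel top-down excitation outright.
    f1: ARTLayerSpec = field(
        default_factory=lambda: _spec(0.22, 0.5, gain=7.0, lower=-1.0)
    )
    f1_from_f0: float = 4.0
    f1_from_f2: float = 0.7
    f1_from_g1: float = 1.22
    # --- gain controls ------------------------------------------------
    g1: ARTLayerSpec = field(default_factory=lambda: _spec(0.02, 1.5))
    g1_from_f2: float = 14.0
    g1_from_priming: float = 0.0
    g2: ARTLayerSpec = field(default_factory=lambda: _spec(0.02, 0.5))
    g2_tonic: float = 1.0
    g2_from_f2: float = 0.5
    g2_gate_from_f0: float = 1.0
    # --- category layer ----------------------------------------------
    f2: ARTLayerSpec = field(default_factory=lambda: _spec(0.03, 1.0))
    f2_from_f1: float = 0.3
    f2_recurrent: float = 40.0
    f2_recurrent_threshold: float = 0.10
    f2_lateral: float = 0.4
    f2_from_g2: float = 15.0
    f2_latch_inhibition: float = 10.0
    f2_tie_bias: float = 1e-3
    f3_latch_floor: float = 0.02  # minimal F2 potential the F3 gate reads
    # --- orienting subsystem -----------------------------------------
    r: ARTLayerSpec = field(default_factory=lambda: _spec(0.35, 40.0, kind="step"))
    r_from_mismatch: float = 2.0
    r_from_f2: float = 1.5
    r_tonic: float = 3.0
    vigilance: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.vigilance <= 1.0:
            raise ValueError(f"vigilance must lie in (0, 1], got {self.vigilance}")


def mismatch_drive(
    f0: LayerState, f1: LayerState, vigilance: float
) -> float:
    """Rectified vigilance-weighted mismatch, normalized by registered input.

    R compares the *ratio* of matched (F1) to registered (F0) total output
    against the vigilance rho: the drive is
    ``max(rho*sum(F0) - sum(F1), 0) / sum(F0)`` (zero without input), so it
    is invariant to the size of the input layer and bounded by rho.  Zero
    whenever matched activity reaches the vigilance fraction of the input;
    equality at the boundary counts as a match.
    """
    s0 = layer_sum(f0)
    if s0 <= 0.0:
        return 0.0
    return max(vigilance * s0 - layer_sum(f1), 0.0) / s0


class ARTModule:
    """Real-time state and synchronous dynamics of one ART module."""

    def __init__(
        self,
        name: str,
        n_input: int,
        weights: ARTWeights,
        params: Optional[ARTParams] = None,
        r_preset: str = "medium",
        r_time_constants: Optional[Dict[str, float]] = None,
    ) -> None:
        if weights.n_features != n_input:
            raise ValueError(
                f"weights expect {weights.n_features} features, module has "
                f"{n_input} input nodes"
            )
        self.name = name
        self.n_input = n_input
        self.weights = weights
        self.params = params or ARTParams()
        self.r_time_constants = dict(r_time_constants or R_TIME_CONSTANTS)
        if sorted(self.r_time_constants) != sorted(R_TIME_CONSTANTS):
            raise ValueError(
                f"R presets must be exactly {sorted(R_TIME_CONSTANTS)}"
            )
        if not (
            self.r_time_constants["fast"]
            < self.r_time_constants["medium"]
            < self.r_time_constants["slow"]
        ):
            raise ValueError("R presets must satisfy tau_fast < tau_medium < tau_slow")
        self.set_r_preset(r_preset)
        # Deterministic tie-break: an infinitesimal excitatory bias that
        # decreases with category index, so exactly tied candidates resolve
        # to the lowest index.
        m = weights.n_categories
        self._tie_bias = self.params.f2_tie_bias * (m - np.arange(m)) / m
        # gain modulation hooks (used by the metabolic-proxy experiments)
        self.g1_drive_scale = 1.0
        self.g1_extra_drive = 0.0
        self.g2_drive_scale = 1.0
        self.reset_state()

    # -- configuration -------------------------------------------------

    def set_r_preset(self, preset: str) -> None:
        if preset not in self.r_time_constants:
            raise ValueError(
                f"unknown R-node speed preset {preset!r}; "
                f"expected one of {sorted(self.r_time_constants)}"
            )
        self.r_preset = preset
        p = self.params
        self.params = replace(
            p,
            r=ARTLayerSpec(
                replace(p.r.params, time_constant=self.r_time_constants[preset]),
                p.r.signal_kind,
                p.r.signal_gain,
            ),
        )

    def reset_state(self, clear_latch: bool = True) -> None:
        """Zero all potentials; optionally clear the F3 latch (trial start)."""
        m = self.weights.n_categories
        self.f0 = LayerState.zeros(self.n_input)
        self.f1 = LayerState.zeros(self.n_input)
        self.f2 = LayerState.zeros(m)
        self.f3 = LayerState.zeros(m)
        self.g1 = LayerState.zeros(1)
        self.g2 = LayerState.zeros(1)
        self.r = LayerState.zeros(1)
        self._input = np.zeros(self.n_input)
        self._priming = np.zeros(m)
        self._r_was_supra = False
        if clear_latch:
            self.latched = np.zeros(m, dtype=bool)
        elif not hasattr(self, "latched"):
            self.latched = np.zeros(m, dtype=bool)

    # -- external drives ----------------------------------------------

    def register_input(self, pattern) -> None:
        """Present a sensory pattern at F0 (empty array clears the input)."""
        p = np.asarray(pattern, dtype=float)
        if p.size == 0:
            self._input = np.zeros(self.n_input)
            return
        if p.shape != (self.n_input,):
            raise ValueError(
                f"input pattern has length {p.shape}, F0 has {self.n_input} nodes"
            )
        if np.any(p < 0):
            raise ValueError("input patterns must be non-negative")
        self._input = p.copy()

    def set_priming(self, drive) -> None:
        """Apply an expectation drive over F2 (from the associative map)."""
        d = np.asarray(drive, dtype=float)
        if d.size == 0:
            self._priming = np.zeros(self.weights.n_categories)
            return
        if d.shape != (self.weights.n_categories,):
            raise ValueError("priming drive length must equal F2 size")
        if np.any(d < 0):
            raise ValueError("priming drive must be non-negative")
        self._priming = d.copy()

    # -- dynamics ------------------------------------------------------

    @property
    def r_supra(self) -> bool:
        return bool(self.r.potentials[0] > self.params.r.params.output_threshold)

    def mismatch(self) -> float:
        return mismatch_drive(self.f0, self.f1, self.params.vigilance)

    def step(self, dt: float) -> None:
        """One synchronous explicit-Euler update of every node in the module."""
        p = self.params
        w = self.weights
        f0_out = self.f0.outputs
        f1_out = self.f1.outputs
        f2_out = self.f2.outputs
        g1_out = self.g1.outputs[0]
        g2_out = self.g2.outputs[0]
        sum_f0 = float(f0_out.sum())
        sum_f2 = float(f2_out.sum())
        drive = self.mismatch()

        # F0: on-center (input + self-excitation) / off-surround field.
        e0 = p.f0_input_gain * self._input + p.f0_self_excitation * f0_out
        i0 = p.f0_off_surround * (sum_f0 - f0_out)
        new_f0 = shunting_step(
            self.f0, e0, i0, p.f0.params, dt, p.f0.signal_kind, p.f0.signal_gain
        )

        # F1: bottom-up + top-down expectation, non-specific G1 inhibition.
        top_down = w.top_down.T @ f2_out
        e1 = p.f1_from_f0 * f0_out + p.f1_from_f2 * top_down
        i1 = np.full(self.n_input, p.f1_from_g1 * g1_out)
        new_f1 = shunting_step(
            self.f1, e1, i1, p.f1.params, dt, p.f1.signal_kind, p.f1.signal_gain
        )

        # Gain controls.  G1 tracks total F2 output (and the expectation
        # drive feeding F2); G2 is tonically driven, weakly excited by F2,
        # and multiplicatively gated off by F0 activity.
        e_g1 = np.array(
            [
                self.g1_drive_scale
                * (
                    p.g1_from_f2 * sum_f2
                    + p.g1_from_priming * float(self._priming.sum())
                )
                + self.g1_extra_drive
            ]
        )
        new_g1 = shunting_step(
            self.g1, e_g1, np.zeros(1), p.g1.params, dt,
            p.g1.signal_kind, p.g1.signal_gain,
        )
        gate = max(1.0 - p.g2_gate_from_f0 * sum_f0, 0.0)
        e_g2 = np.array(
            [self.g2_drive_scale * gate * (p.g2_tonic + p.g2_from_f2 * sum_f2)]
        )
        new_g2 = shunting_step(
            self.g2, e_g2, np.zeros(1), p.g2.params, dt,
            p.g2.signal_kind, p.g2.signal_gain,
        )

        # F2: recurrent competitive field (faster-than-linear feedback).
        rec = output_signal(
            self.f2.potentials,
            replace(p.f2.params, output_threshold=p.f2_recurrent_threshold),
            "faster-than-linear",
            p.f2_recurrent,
        )
        # F3's latch clamps a reset category outright: its excitatory drive
        # is gated off and strong inhibition drains it, so a latched node's
        # output is exactly zero for the remainder of the trial.
        e2 = (
            p.f2_from_f1 * (w.bottom_up @ f1_out)
            + self._priming
            + rec
            + self._tie_bias
        ) * (~self.latched)
        i2 = (
            p.f2_lateral * (rec.sum() - rec)
            + p.f2_from_g2 * g2_out
            + p.f2_latch_inhibition * self.latched
        )
        new_f2 = shunting_step(
            self.f2, e2, i2, p.f2.params, dt, p.f2.signal_kind, p.f2.signal_gain
        )

        # R: mismatch + F2 recurrence against tonic inhibition.
        e_r = np.array([p.r_from_mismatch * drive + p.r_from_f2 * sum_f2])
        new_r = shunting_step(
            self.r, e_r, np.array([p.r_tonic]), p.r.params, dt,
            p.r.signal_kind, p.r.signal_gain,
        )

        self.f0, self.f1, self.f2 = new_f0, new_f1, new_f2
        self.g1, self.g2, self.r = new_g1, new_g2, new_r
        self.f3_reset()

    def f3_reset(self) -> None:
        """Coincidence-gated category latch.

        An F3 node fires iff its F2 twin is active at the moment R *becomes*
        supra-threshold (rising edge); the fired node enters the latch set
        and its F2 twin is inhibited below threshold for the rest of the
        trial.  The F3 gate reads the F2 membrane state with a low floor
        (``f3_latch_floor``), so every category participating in the
        erroneous expectation — including siblings held down by the current
        winner's lateral inhibition — is removed in one reset.  While R
        stays supra-threshold no further latching occurs, so the next
        category sought by the field is not clipped during R's decay.
        """
        supra_now = self.r_supra
        if supra_now and not self._r_was_supra:
            active = self.f2.potentials > self.params.f3_latch_floor
            newly = active & ~self.latched
            self.latched |= newly
            self.f3 = LayerState(
                self.latched.astype(float), self.latched.astype(float)
            )
            if self.latched.all():
                raise NoCategoryAvailable(
                    f"module {self.name!r}: every committed category is "
                    "latched; no category available"
                )
        self._r_was_supra = supra_now

    def layer_states(self) -> Dict[str, LayerState]:
        return {
            "f0": self.f0,
            "f1": self.f1,
            "f2": self.f2,
            "f3": self.f3,
            "g1": self.g1,
            "g2": self.g2,
            "r": self.r,
            "mismatch": LayerState(
                np.array([self.mismatch()]), np.array([self.mismatch()])
            ),
        }

    def run(
        self,
        duration: float,
        dt: float = 0.01,
        recorder: Optional[TraceRecorder] = None,
        t0: float = 0.0,
        record_every: int = 1,
    ) -> float:
        """Integrate the module alone for ``duration``; returns the end time."""
        n_steps = int(round(duration / dt))
        for k in range(n_steps):
            if recorder is not None and k % record_every == 0:
                recorder.record(
                    t0 + k * dt,
                    {(self.name, n): s for n, s in self.layer_states().items()},
                )
            self.step(dt)
        if recorder is not None:
            recorder.record(
                t0 + n_steps * dt,
                {(self.name, n): s for n, s in self.layer_states().items()},
            )
        return t0 + n_steps * dt


def resonance_status(module: ARTModule, trace, window: float) -> str:
    """Classify the module's state over the trailing ``window`` of a trace.

    Returns ``"resonant(i)"`` when category ``i`` held full-amplitude output
    with zero mismatch for the whole window, ``"searching"`` when the reset
    node was supra-threshold within the window, ``"priming"`` for weak F2
    output without sensory input, else ``"idle"``.
    """
    t1 = trace.times[-1]
    tail = trace.window(t1 - window, t1)
    name = module.name
    r_theta = module.params.r.params.output_threshold
    if np.any(tail.potentials[(name, "r")][:, 0] > r_theta):
        return "searching"
    f2_out = tail.outputs[(name, "f2")]
    drive = tail.potentials[(name, "mismatch")][:, 0]
    full = np.all(f2_out.max(axis=1) >= RESONANT_OUTPUT) and np.all(drive == 0.0)
    if full:
        return f"resonant({int(np.argmax(f2_out[-1]))})"
    f0_out = tail.outputs[(name, "f0")]
    weak = (f2_out[-1].max() > 0.0) and (f2_out[-1].max() < WEAK_OUTPUT_BAND)
    if weak and not np.any(f0_out > 0.0):
        return "priming"
    return "idle"


def learn(module: ARTModule) -> ARTWeights:
    """Fast learning at resonance: the winner's template contracts to the
    intersection of template and current F1 supra-threshold activity;
    bottom-up weights are re-normalized.  Refused outside resonance, which
    is what guarantees that established codes are never recoded by
    mismatched inputs.
    """
    f2_out = module.f2.outputs
    if f2_out.max() < RESONANT_OUTPUT or module.mismatch() > 0.0:
        raise RuntimeError("learning is only permitted in a resonant state")
    winner = int(np.argmax(f2_out))
    w = module.weights
    f1_active = (module.f1.outputs > 0.0).astype(float)
    new_template = w.top_down[winner] * f1_active
    if new_template.sum() < 1:
        raise RuntimeError("fast learning would erase the template entirely")
    top_down = w.top_down.copy()
    bottom_up = w.bottom_up.copy()
    top_down[winner] = new_template
    bottom_up[winner] = new_template / new_template.sum()
    committed = w.committed.copy()
    committed[winner] = True
    return ARTWeights(bottom_up, top_down, committed)
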